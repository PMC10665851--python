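"""Per-SNP Spearman genome scan on standardized allele frequencies.

Associates each SNP's structure-standardized population allele
frequencies with a population-level trait (the growth-response index by
default) via Spearman's rank correlation.  Structure correction lives
entirely in the standardization; the scan itself is a plain rank
correlation per SNP, with QQ diagnostics on the resulting p-values.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .types import PGRScanError, StdFreqPanel

__all__ = ["spearman", "genome_scan", "qq_diagnostic"]

#: maximum n for exact permutation enumeration of the Spearman p-value
EXACT_N_MAX = 8


def _t_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return float(2.0 * stats.t.sf(np.inf, n - 2))  # 0.0 in the limit
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Mid-ranks are used for ties; rho is the Pearson correlation of the
    ranks.  For n <= 8 without ties the p-value is exact (enumeration
    of all n! rank permutations); otherwise it uses the t approximation
    t = rho sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise PGRScanError("spearman needs n >= 4")
    if len(y) != n:
        raise PGRScanError("length mismatch")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise PGRScanError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PGRScanError("constant input: Spearman rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= EXACT_N_MAX and no_ties:
        # exact null distribution of rho over all permutations of one ranking
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
        obs = abs(float(rx_c @ ry_c))
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            stat = abs(float(rx_c @ ry_c[list(perm)]))
            if stat >= obs - 1e-12 * denom:
                count += 1
            total += 1
        return rho, count / total
    return rho, _t_pvalue(rho, n)


def genome_scan(std: StdFreqPanel, trait: pd.Series, trait_label: str = "") -> pd.DataFrame:
    """Spearman rho and p per SNP between standardized frequencies and a trait.

    ``trait`` must be indexed by population id in the same order as the
    panel's populations (checked by id, order-insensitively reindexed).
    Constant (monomorphic) SNP rows are flagged and given rho = 0,
    p = 1 by convention rather than dropped.
    """
    pops = std.populations
    if set(trait.index) != set(pops):
        raise PGRScanError(
            "population sets of trait and panel differ: "
            f"{sorted(set(pops) ^ set(trait.index))[:5]} ..."
        )
    tvals = trait.reindex(pops).to_numpy(dtype=float)
    if np.ptp(tvals) == 0:
        raise PGRScanError("trait is constant across populations")
    Z = std.z.to_numpy(dtype=float)
    S, n = Z.shape
    R = np.apply_along_axis(stats.rankdata, 1, Z)
    rt = stats.rankdata(tvals)
    rt_c = rt - rt.mean()
    R_c = R - R.mean(axis=1, keepdims=True)
    num = R_c @ rt_c
    den = np.sqrt((R_c**2).sum(axis=1) * float(rt_c @ rt_c))
    constant = den == 0
    rho = np.zeros(S)
    np.divide(num, den, out=rho, where=~constant)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0, np.finfo(float).tiny, p)
    p = np.where(constant, 1.0, p)
    rho = np.where(constant, 0.0, rho)
    out = std.snp_map.copy()
    out["rho"] = rho
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["n_pop"] = n
    out["flag"] = np.where(constant, "constant", "")
    out["trait"] = trait_label
    return out


def qq_diagnostic(scan: pd.DataFrame) -> tuple[float, float]:
    """Genomic inflation factor and KS distance of p-values from Uniform(0,1).

    lambda_gc is the median of chi-square(1) quantiles implied by the
    p-values over the null median 0.4549; values near 1 indicate no
    excess of low p-values.
    """
    p = scan["p"].to_numpy(dtype=float)
    if len(p) < 100:
        raise PGRScanError("QQ diagnostics need >= 100 SNPs")
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    lambda_gc = float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
    ks = float(stats.kstest(p, "uniform").statistic)
    return lambda_gc, ks
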