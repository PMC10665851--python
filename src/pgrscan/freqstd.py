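"""Structure-standardized allele frequencies and the XtX statistic.

The across-population covariance of scaled allele-frequency deviations
is estimated by a method of moments (a deterministic surrogate for the
Bayesian hierarchical treatment of the same quantity; externally
computed standardized frequencies can be ingested instead for
fidelity-critical uses).  Standardization whitens per-SNP deviation
vectors with the lower Cholesky factor of the covariance; XtX is the
squared norm of the whitened vector, an Fst-analogue corrected for
shared population history.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import linalg

from .types import CovModel, PGRScanError, PopFreqPanel, StdFreqPanel

#: frequencies at the boundary are clipped here before standardization
CLIP = (0.001, 0.999)

#: ridge added to the covariance estimate: RIDGE_REL * trace(omega)/P on the diagonal
RIDGE_REL = 1e-6

__all__ = ["estimate_cov", "standardize", "top_fraction_mask", "scaled_deviations"]


def scaled_deviations(freqs: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """(p - pi) / sqrt(pi (1 - pi)) per SNP row."""
    return (freqs - pi[:, None]) / np.sqrt(pi * (1.0 - pi))[:, None]


def _mom_omega(D: np.ndarray, ridge_rel: float) -> np.ndarray:
    P = D.shape[1]
    omega = (D.T @ D) / D.shape[0]
    eps = ridge_rel * np.trace(omega) / P
    if eps <= 0:
        warnings.warn("degenerate covariance (zero trace); applying absolute ridge floor")
        eps = 1e-12
    return omega + eps * np.eye(P)


def estimate_cov(
    panel: PopFreqPanel, ridge_rel: float = RIDGE_REL, trim_q: float = 0.01
) -> CovModel:
    """Method-of-moments across-population covariance of allele frequencies.

    pi is the across-population mean per SNP; omega averages the outer
    products of scaled deviation vectors over SNPs, with a small ridge
    (``ridge_rel * trace/P`` on the diagonal) to guarantee positive
    definiteness.  Centering on the per-SNP mean makes omega singular
    along the all-ones direction; the ridge floors it, and deviation
    vectors are orthogonal to that direction so downstream whitening is
    unaffected.

    The estimate is for the shared (neutral) covariation of allele
    frequencies, so strongly differentiated SNPs are excluded from it:
    after a preliminary pass, SNPs in the top ``trim_q`` fraction of
    preliminary XtX are dropped and omega re-estimated (``trim_q=0``
    disables the refinement).
    """
    S, P = panel.freqs.shape
    if S < P:
        raise PGRScanError(f"need at least as many SNPs ({S}) as populations ({P})")
    freqs = np.clip(panel.freqs.to_numpy(dtype=float), *CLIP)
    pi = freqs.mean(axis=1)
    D = scaled_deviations(freqs, pi)
    omega = _mom_omega(D, ridge_rel)
    if trim_q > 0 and S - int(np.floor(trim_q * S)) >= P:
        L = np.linalg.cholesky(omega)
        z = linalg.solve_triangular(L, D.T, lower=True).T
        xtx0 = np.einsum("ij,ij->i", z, z)
        mask, _ = top_fraction_mask(xtx0, q=trim_q)
        omega = _mom_omega(D[~mask], ridge_rel)
    return CovModel(omega=omega, populations=panel.populations, pi=pi)


def standardize(panel: PopFreqPanel, cov: CovModel) -> StdFreqPanel:
    """Whiten per-SNP frequency deviations; XtX = squared norm per SNP.

    z_s = L^-1 (p_s - pi_s 1) / sqrt(pi_s (1 - pi_s)) with L the lower
    Cholesky factor of omega.  pi comes from ``cov`` when present
    (else the per-SNP across-population mean).  Frequencies at 0/1 are
    clipped to ``CLIP`` first.
    """
    if cov.populations != panel.populations:
        raise PGRScanError("population sets of panel and covariance model differ")
    freqs = np.clip(panel.freqs.to_numpy(dtype=float), *CLIP)
    if cov.pi is not None:
        if len(cov.pi) != panel.n_snp:
            raise PGRScanError("cov.pi length does not match panel SNP count")
        pi = cov.pi
    else:
        pi = freqs.mean(axis=1)
    D = scaled_deviations(freqs, pi)
    L = cov.cholesky()
    Z = linalg.solve_triangular(L, D.T, lower=True).T
    xtx = np.einsum("ij,ij->i", Z, Z)
    zdf = pd.DataFrame(Z, index=panel.freqs.index, columns=panel.freqs.columns)
    return StdFreqPanel(
        z=zdf,
        xtx=pd.Series(xtx, index=panel.freqs.index, name="xtx"),
        cov=cov,
        snp_map=panel.snp_map,
    )


def top_fraction_mask(xtx: np.ndarray | pd.Series, q: float = 0.01) -> tuple[np.ndarray, int]:
    """Mask of the floor(q*S) largest XtX values; cutoff ties broken by genome order.

    Returns (mask, count).  SNPs are assumed to be in genome order;
    among equal values the earlier SNP wins (first-come).
    """
    if not (0.0 < q < 1.0):
        raise PGRScanError("q must lie in (0, 1)")
    values = np.asarray(xtx, dtype=float)
    S = len(values)
    count = int(np.floor(q * S))
    if count == 0:
        raise PGRScanError(f"top fraction q={q} of S={S} SNPs selects 0 SNPs")
    order = np.lexsort((np.arange(S), -values))
    mask = np.zeros(S, dtype=bool)
    mask[order[:count]] = True
    return mask, count
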