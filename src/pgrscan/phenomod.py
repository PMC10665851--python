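"""Fixed-effects linear modelling of ordinal growth scores.

Implements the phenotype side of the pipeline: least-squares-mean
genotypic values per population or accession, the split-plot ANOVA of
the full design (block and treatment tested against the block x
treatment stratum), Henderson-III variance components and broad-sense
heritability, the growth-response index (percent change under
inoculation relative to mock), and the trade-off rank correlation
between response and growth under mock conditions.

Ordinal 1-7 scores are analyzed as numeric responses in ordinary
least squares, with germination date and the per-plate control-mean
score as covariates; all factors are fixed effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    INOCULATED,
    MOCK,
    PGRScanError,
    RankDeficiencyError,
    VarianceComponents,
)

__all__ = [
    "fit_lsmeans",
    "splitplot_anova",
    "variance_components",
    "heritability",
    "heritability_pvalue",
    "compute_pgr",
    "tradeoff_test",
]


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _dummies(values: pd.Series, levels: list) -> np.ndarray:
    """Drop-first dummy encoding with explicit level order."""
    arr = np.zeros((len(values), len(levels) - 1))
    index = {lv: i for i, lv in enumerate(levels)}
    codes = values.map(index).to_numpy()
    for j in range(1, len(levels)):
        arr[:, j - 1] = codes == j
    return arr


def _deviation(values: pd.Series, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) encoding: level 0 is -1 on every contrast.

    With this coding, dropping a factor's columns from a model that
    contains its interactions tests the factor's *main* effect averaged
    over the other factors' levels (the Type-III convention), not the
    simple effect at reference levels.
    """
    arr = np.zeros((len(values), len(levels) - 1))
    index = {lv: i for i, lv in enumerate(levels)}
    codes = values.map(index).to_numpy()
    for j in range(1, len(levels)):
        arr[:, j - 1] = np.where(codes == j, 1.0, np.where(codes == 0, -1.0, 0.0))
    return arr


def _sse(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of an OLS fit."""
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _subset(scores: pd.DataFrame, dai: int, treatment: str | None = None) -> pd.DataFrame:
    df = scores[(scores["dai"] == dai) & (~scores["is_control"])]
    if treatment is not None:
        df = df[df["treatment"] == treatment]
    if df.empty:
        raise PGRScanError(f"no non-control scores for dai={dai}, treatment={treatment}")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# LS-mean genotypic values
# ---------------------------------------------------------------------------

def fit_lsmeans(
    scores: pd.DataFrame,
    model: str = "model2",
    dai: int = 14,
    treatments: list[str] | None = None,
) -> pd.DataFrame:
    """Genotypic values as least-squares means, per treatment.

    Both models regress score on block, accession (which, being nested,
    carries the population term as well), germination date and the
    plate control-mean covariate, separately within each treatment.
    LS-means are evaluated at equal weight over blocks and at the
    observed means of the covariates.  ``model="model2"`` returns
    population-level values (equal-weight average of the member
    accessions' LS-means); ``model="model5"`` returns accession-level
    values.

    Returns a tidy frame (level, unit, treatment, dai, value).
    """
    if model not in ("model2", "model5"):
        raise PGRScanError(f"unknown model {model!r}")
    out = []
    for trt in treatments or sorted(scores["treatment"].unique()):
        df = _subset(scores, dai, trt)
        blocks = sorted(df["block"].unique())
        accs = sorted(df["accession_id"].unique())
        y = df["score"].to_numpy(dtype=float)
        Xb = _dummies(df["block"], blocks)
        Xa = _dummies(df["accession_id"], accs)
        # covariates with no variation carry no information and are dropped
        covs = [
            df[c].to_numpy(dtype=float)
            for c in ("germ_day", "plate_control_mean")
            if np.ptp(df[c].to_numpy(dtype=float)) > 0
        ]
        X = np.column_stack([np.ones(len(df)), Xb, Xa] + covs)
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise RankDeficiencyError(
                f"model matrix rank {rank} < {X.shape[1]} columns for "
                f"treatment={trt}, dai={dai}: block/accession/covariate terms "
                "are confounded (e.g. a constant covariate or an accession "
                "observed in a single block)"
            )
        # prediction grid: every accession x every block, covariates at mean
        nb, na = len(blocks), len(accs)
        G = np.zeros((na * nb, X.shape[1]))
        G[:, 0] = 1.0
        for i, _ in enumerate(accs):
            for j, _ in enumerate(blocks):
                r = i * nb + j
                if j > 0:
                    G[r, 1 + (j - 1)] = 1.0
                if i > 0:
                    G[r, 1 + (nb - 1) + (i - 1)] = 1.0
        for k, cov in enumerate(covs):
            G[:, 1 + (nb - 1) + (na - 1) + k] = cov.mean()
        acc_lsm = (G @ beta).reshape(na, nb).mean(axis=1)
        acc_values = pd.Series(acc_lsm, index=accs)
        if model == "model5":
            for a, v in acc_values.items():
                out.append(("accession", a, trt, dai, float(v)))
        else:
            pop_of = df.drop_duplicates("accession_id").set_index("accession_id")[
                "population_id"
            ]
            pops = acc_values.groupby(pop_of.reindex(acc_values.index)).mean()
            for p, v in pops.items():
                out.append(("population", p, trt, dai, float(v)))
    gv = pd.DataFrame(out, columns=["level", "unit", "treatment", "dai", "value"])
    if not np.all(np.isfinite(gv["value"])):
        raise PGRScanError("non-finite LS-means")
    return gv


# ---------------------------------------------------------------------------
# split-plot ANOVA (full model)
# ---------------------------------------------------------------------------

def splitplot_anova(scores: pd.DataFrame, dai: int = 14, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Split-plot ANOVA of the full fixed-effects model at one dai.

    Terms: block, treatment, block x treatment, population,
    treatment x population, accession(population),
    treatment x accession(population), germination date, control-score
    covariate.  Each term's sum of squares is a model comparison
    (full model vs. full model without that term); block and treatment
    are tested against the block x treatment mean square (split-plot
    stratum), all other terms against the residual mean square.
    """
    df = _subset(scores, dai)
    blocks = sorted(df["block"].unique())
    trts = sorted(df["treatment"].unique())
    pops = sorted(df["population_id"].unique())
    if len(blocks) < 2 or len(trts) < 2:
        raise PGRScanError("split-plot ANOVA needs >= 2 blocks and both treatments")

    y = df["score"].to_numpy(dtype=float)
    B = _deviation(df["block"], blocks)
    T = _deviation(df["treatment"], trts)
    BT = B * T  # works because T has a single column
    P = _deviation(df["population_id"], pops)
    TP = P * T
    # accession contrasts nested within population: deviation-coded within pop
    acc_cols = []
    for p in pops:
        in_p = df["population_id"] == p
        accs_p = sorted(df.loc[in_p, "accession_id"].unique())
        if len(accs_p) > 1:
            block_p = _deviation(
                df["accession_id"].where(in_p, accs_p[1]), accs_p
            )
            # zero out rows outside the population (they are not -1 baselines)
            block_p[~in_p.to_numpy()] = 0.0
            acc_cols.append(block_p)
    A = np.column_stack(acc_cols) if acc_cols else np.zeros((len(df), 0))
    TA = A * T
    germ = df["germ_day"].to_numpy(dtype=float)
    ctrl = df["plate_control_mean"].to_numpy(dtype=float)
    germ = germ - germ.mean()
    ctrl = ctrl - ctrl.mean()

    term_blocks = {
        "Block": B,
        "Treatment": T,
        "Block x Treatment": BT,
        "Population": P,
        "Treatment x Population": TP,
        "Accession(Population)": A,
        "Treatment x Accession(Population)": TA,
        "Germination date": germ[:, None],
        "Control score": ctrl[:, None],
    }
    term_blocks = {k: v for k, v in term_blocks.items() if v.shape[1] > 0}
    names = list(term_blocks)
    X_full = np.column_stack([np.ones(len(df))] + [term_blocks[k] for k in names])
    sse_full, rank_full = _sse(y, X_full)
    df_resid = len(df) - rank_full
    if df_resid <= 0:
        raise PGRScanError("saturated model: no residual degrees of freedom")
    mse = sse_full / df_resid

    ss, dfs = {}, {}
    for k in names:
        X_red = np.column_stack(
            [np.ones(len(df))] + [term_blocks[j] for j in names if j != k]
        )
        sse_red, rank_red = _sse(y, X_red)
        ss[k] = max(sse_red - sse_full, 0.0)
        dfs[k] = rank_full - rank_red
    if dfs.get("Block x Treatment", 0) == 0:
        raise PGRScanError("block x treatment stratum has 0 degrees of freedom")
    ms_bt = ss["Block x Treatment"] / dfs["Block x Treatment"]

    rows = []
    for k in names:
        if dfs[k] == 0:
            continue
        if k in ("Block", "Treatment"):
            denom, df_den, stratum = ms_bt, dfs["Block x Treatment"], "block x treatment"
        else:
            denom, df_den, stratum = mse, df_resid, "residual"
        F = (ss[k] / dfs[k]) / denom
        p = float(stats.f.sf(F, dfs[k], df_den))
        rows.append((k, dfs[k], df_den, ss[k], F, p, stratum))
    table = pd.DataFrame(
        rows, columns=["term", "df_num", "df_den", "ss", "F", "p", "stratum"]
    )
    # Benjamini-Hochberg flag across the table's terms
    p = table["p"].to_numpy()
    order = np.argsort(p)
    m = len(p)
    crit = fdr_alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= crit
    thresh = p[order][passed].max() if passed.any() else -1.0
    table["fdr_significant"] = table["p"] <= thresh
    return table


# ---------------------------------------------------------------------------
# variance components and heritability
# ---------------------------------------------------------------------------

def _q_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of X (SVD-based, rank-safe)."""
    from scipy.linalg import orth

    return orth(X)


def _henderson3(r: np.ndarray, Zb: np.ndarray, Za: np.ndarray) -> tuple[float, float, float]:
    """Fitting-constants (Henderson III) estimates of (VB, VF, VR).

    Model: r = mu + block + accession + e with block and accession
    random.  SS(accession | block) is free of the block component and
    vice versa, so each quadratic form yields one linear equation in
    (component, VR); negative solutions are truncated at zero.
    """
    n = len(r)
    one = np.ones((n, 1))
    Q_b = _q_basis(np.column_stack([one, Zb]))
    Q_a = _q_basis(np.column_stack([one, Za]))
    Q_ba = _q_basis(np.column_stack([one, Zb, Za]))

    def proj_ss(Q: np.ndarray, v: np.ndarray) -> float:
        w = Q.T @ v
        return float(w @ w)

    tss = float(r @ r)
    sse_full = tss - proj_ss(Q_ba, r)
    df_full = n - Q_ba.shape[1]
    if df_full <= 0:
        raise PGRScanError("no residual degrees of freedom for variance components")
    vr = sse_full / df_full

    def component(Z: np.ndarray, Q_other: np.ndarray) -> float:
        ss = proj_ss(Q_ba, r) - proj_ss(Q_other, r)
        dof = Q_ba.shape[1] - Q_other.shape[1]
        if dof <= 0:
            return 0.0
        # trace of Z' (P_full - P_other) Z
        tr = float(np.sum((Q_ba.T @ Z) ** 2) - np.sum((Q_other.T @ Z) ** 2))
        if tr <= 0:
            return 0.0
        return max((ss - vr * dof) / tr, 0.0)

    va = component(Za, Q_b)
    vb = component(Zb, Q_a)
    return vb, va, vr


def _reml_refine(
    r: np.ndarray, Zb: np.ndarray, Za: np.ndarray,
    start: tuple[float, float, float], n_iter: int = 200, tol: float = 1e-8,
) -> tuple[float, float, float]:
    """EM-REML for the two-variance-component model, started at MoM values."""
    n = len(r)
    X = np.ones((n, 1))
    vb, va, vr = (max(v, 1e-6) for v in start)
    Z = np.column_stack([Zb, Za])
    qb, qa = Zb.shape[1], Za.shape[1]
    W = np.column_stack([X, Z])
    WtW = W.T @ W
    Wty = W.T @ r
    p = X.shape[1]
    for _ in range(n_iter):
        lam = np.concatenate([np.full(qb, vr / vb), np.full(qa, vr / va)])
        M = WtW.copy()
        M[p:, p:] += np.diag(lam)
        C = np.linalg.inv(M)
        sol = C @ Wty
        u = sol[p:]
        ub, ua = u[:qb], u[qb:]
        Cuu = C[p:, p:]
        tr_b = float(np.trace(Cuu[:qb, :qb]))
        tr_a = float(np.trace(Cuu[qb:, qb:]))
        vb_new = (float(ub @ ub) + vr * tr_b) / qb
        va_new = (float(ua @ ua) + vr * tr_a) / qa
        e = r - W @ sol
        vr_new = (float(e @ r)) / (n - p)
        if (abs(vb_new - vb) + abs(va_new - va) + abs(vr_new - vr)) < tol:
            vb, va, vr = vb_new, va_new, vr_new
            break
        vb, va, vr = max(vb_new, 1e-10), max(va_new, 1e-10), max(vr_new, 1e-10)
    return vb, va, vr


def variance_components(
    scores: pd.DataFrame,
    dai: int,
    treatment: str,
    reml: bool = False,
) -> VarianceComponents:
    """Block / accession / residual variance components within one treatment.

    Germination date and the control-score covariate are regressed out
    first; block and accession components are then estimated on the
    residuals by the fitting-constants method of moments (optionally
    refined by EM-REML), with negative estimates truncated at zero.
    """
    df = _subset(scores, dai, treatment)
    blocks = sorted(df["block"].unique())
    accs = sorted(df["accession_id"].unique())
    if len(blocks) < 2 or len(accs) < 2:
        raise PGRScanError("variance components need >= 2 blocks and >= 2 accessions")
    y = df["score"].to_numpy(dtype=float)
    X3 = np.column_stack(
        [np.ones(len(df)), df["germ_day"].astype(float), df["plate_control_mean"].astype(float)]
    )
    beta, _, rank, _ = np.linalg.lstsq(X3, y, rcond=None)
    r = y - X3 @ beta

    Zb = pd.get_dummies(df["block"]).to_numpy(dtype=float)
    Za = pd.get_dummies(df["accession_id"]).to_numpy(dtype=float)
    vb, va, vr = _henderson3(r, Zb, Za)
    if reml:
        vb, va, vr = _reml_refine(r, Zb, Za, (vb, va, vr))
    return VarianceComponents(
        VF=va, VB=vb, VR=vr, b_blocks=len(blocks), n_blocks=len(blocks)
    )


def heritability(vc: VarianceComponents, reading: str = "vr-over-n") -> float:
    """Broad-sense heritability H2 = VF / (VF + VB/B + VR/N), clamped to [0, 1].

    ``reading="vr-over-bn"`` switches the residual denominator to B*N
    (the alternate reading of the replicate-averaging formula).
    """
    if vc.b_blocks == 0 or vc.n_blocks == 0:
        raise PGRScanError("B and N must be positive")
    if reading == "vr-over-n":
        denom = vc.VF + vc.VB / vc.b_blocks + vc.VR / vc.n_blocks
    elif reading == "vr-over-bn":
        denom = vc.VF + vc.VB / vc.b_blocks + vc.VR / (vc.b_blocks * vc.n_blocks)
    else:
        raise PGRScanError(f"unknown reading {reading!r}")
    if denom <= 0:
        return 0.0
    return float(np.clip(vc.VF / denom, 0.0, 1.0))


def heritability_pvalue(
    scores: pd.DataFrame,
    dai: int,
    treatment: str,
    n_perm: int = 199,
    seed: int = 0,
    reading: str = "vr-over-n",
) -> tuple[float, float]:
    """Permutation p-value for H2: accession labels shuffled within block.

    Covariate effects are removed once (they are label-invariant), then
    residuals are permuted within each block — equivalent to permuting
    accession labels within block — and H2 recomputed against fixed
    design factors.  Returns (H2_observed, p) with the add-one rule.
    """
    if n_perm < 99:
        raise PGRScanError("n_perm must be >= 99")
    df = _subset(scores, dai, treatment)
    blocks = sorted(df["block"].unique())
    y = df["score"].to_numpy(dtype=float)
    X3 = np.column_stack(
        [np.ones(len(df)), df["germ_day"].astype(float), df["plate_control_mean"].astype(float)]
    )
    beta, *_ = np.linalg.lstsq(X3, y, rcond=None)
    r = y - X3 @ beta
    Zb = pd.get_dummies(df["block"]).to_numpy(dtype=float)
    Za = pd.get_dummies(df["accession_id"]).to_numpy(dtype=float)
    nb = len(blocks)

    def h2_of(res: np.ndarray) -> float:
        vb, va, vr = _henderson3(res, Zb, Za)
        return heritability(
            VarianceComponents(VF=va, VB=vb, VR=vr, b_blocks=nb, n_blocks=nb),
            reading=reading,
        )

    h2_obs = h2_of(r)
    rng = np.random.default_rng(seed)
    block_idx = [np.flatnonzero(df["block"] == b) for b in blocks]
    count = 0
    for _ in range(n_perm):
        rp = r.copy()
        for idx in block_idx:
            rp[idx] = rp[rng.permutation(idx)]
        if h2_of(rp) >= h2_obs:
            count += 1
    return h2_obs, (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# growth-response index and trade-off
# ---------------------------------------------------------------------------

def compute_pgr(gv: pd.DataFrame) -> pd.DataFrame:
    """Percent growth response: (inoculated - mock) / mock * 100 per unit x dai."""
    wide = gv.pivot_table(
        index=["level", "unit", "dai"], columns="treatment", values="value"
    )
    if MOCK not in wide.columns or INOCULATED not in wide.columns:
        raise PGRScanError("both treatments required to compute the growth response")
    if wide[[MOCK, INOCULATED]].isna().any().any():
        raise PGRScanError("missing genotypic value for some unit x treatment x dai")
    if (wide[MOCK] == 0).any():
        raise PGRScanError("mock genotypic value of 0: growth response undefined")
    pgr = ((wide[INOCULATED] - wide[MOCK]) / wide[MOCK] * 100.0).rename("pgr")
    return pgr.reset_index()


def tradeoff_test(
    pgr: pd.DataFrame, gv: pd.DataFrame, dai: int, level: str = "population"
) -> tuple[float, float]:
    """Spearman correlation between growth response and mock genotypic value."""
    from .scan import spearman

    mock = gv[(gv["treatment"] == MOCK) & (gv["dai"] == dai) & (gv["level"] == level)]
    resp = pgr[(pgr["dai"] == dai) & (pgr["level"] == level)]
    merged = resp.merge(mock[["unit", "value"]], on="unit")
    if len(merged) < 4:
        raise PGRScanError("trade-off test needs >= 4 units")
    return spearman(merged["value"].to_numpy(), merged["pgr"].to_numpy())
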