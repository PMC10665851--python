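"""Synthetic data generator for the growth-response GWAS pipeline.

Emulates the study conditions end to end: a split-plot in-vitro design
(2 treatments nested within 2 blocks, 24 forty-eight-well plates per
block x treatment cell, a Col-0 control column on every plate, 12
replicates per accession per treatment), ordinal growth scores 1-7 with
block / treatment / genotype / germination-date effects, per-SNP
population allele frequencies sharing an across-population covariance
structure, and injected QTLs whose frequencies track a latent population
growth-response value, a configurable fraction of which are also
high-differentiation (XtX) outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    CapacityError,
    CovModel,
    DESIGN_COLUMNS,
    DAIS,
    INOCULATED,
    MOCK,
    PGRScanError,
    PopFreqPanel,
    SCORE_COLUMNS,
    TREATMENTS,
)

WELLS_PER_PLATE = 48
COLUMNS_PER_PLATE = 8
ROWS_PER_COLUMN = 6
CONTROL_COLUMN = COLUMNS_PER_PLATE  # the last column of every plate
CONTROL_ACCESSION = "Col-0"
CONTROL_POPULATION = "control"

#: frequencies are truncated (not resampled) to this range
FREQ_CLIP = (0.001, 0.999)

#: fixed equidistant thresholds mapping the latent growth scale to scores 1..7
SCORE_THRESHOLDS = np.array([1.5, 2.5, 3.5, 4.5, 5.5, 6.5])


# ---------------------------------------------------------------------------
# experimental design
# ---------------------------------------------------------------------------

def build_design(
    n_pop: int = 54,
    n_acc_per_pop: int = 3,
    n_blocks: int = 2,
    plates_per_cell: int = 24,
    seed: int = 0,
    reps_per_treatment: int = 12,
) -> pd.DataFrame:
    """Build the split-plot design table, one row per well.

    Two treatments (mock / inoculated) are nested within ``n_blocks``
    blocks; each block x treatment cell holds ``plates_per_cell``
    48-well plates.  The last column of every plate is sown with the
    Col-0 control accession; the remaining 7 columns receive the test
    accessions, each accession getting ``reps_per_treatment`` wells per
    treatment split evenly across blocks (whole columns of 6 wells).
    The column randomization is shared between the two treatments of a
    block and re-drawn between blocks.

    Wells left unsown (when accessions do not fill all columns) appear
    as rows with missing ``accession_id`` so that the table always has
    ``n_blocks * 2 * plates_per_cell * 48`` rows.
    """
    rng = np.random.default_rng(seed)
    n_acc = n_pop * n_acc_per_pop
    if reps_per_treatment % (ROWS_PER_COLUMN * n_blocks) != 0:
        raise CapacityError(
            f"reps_per_treatment={reps_per_treatment} must be a multiple of "
            f"{ROWS_PER_COLUMN} wells x {n_blocks} blocks"
        )
    cols_per_acc = reps_per_treatment // (ROWS_PER_COLUMN * n_blocks)
    avail_cols = plates_per_cell * (COLUMNS_PER_PLATE - 1)
    need_cols = n_acc * cols_per_acc
    if need_cols > avail_cols:
        raise CapacityError(
            f"{n_acc} accessions x {cols_per_acc} columns = {need_cols} columns "
            f"exceed {avail_cols} assignable columns "
            f"({plates_per_cell} plates x {COLUMNS_PER_PLATE - 1})"
        )

    accessions = [
        (f"pop{p + 1:02d}_acc{a + 1}", f"pop{p + 1:02d}")
        for p in range(n_pop)
        for a in range(n_acc_per_pop)
    ]

    rows: list[tuple] = []
    for block in range(1, n_blocks + 1):
        # one random assignment of accessions to (plate, column) slots,
        # shared by the two treatments of this block
        slots = [
            (plate, col)
            for plate in range(1, plates_per_cell + 1)
            for col in range(1, COLUMNS_PER_PLATE)
        ]
        order = rng.permutation(len(slots))
        slot_to_acc: dict[tuple[int, int], int] = {}
        k = 0
        for acc_idx in range(n_acc):
            for _ in range(cols_per_acc):
                slot_to_acc[slots[order[k]]] = acc_idx
                k += 1
        for treatment in TREATMENTS:
            for plate in range(1, plates_per_cell + 1):
                for col in range(1, COLUMNS_PER_PLATE + 1):
                    for row in range(1, ROWS_PER_COLUMN + 1):
                        well = (col - 1) * ROWS_PER_COLUMN + row
                        if col == CONTROL_COLUMN:
                            acc, popid = CONTROL_ACCESSION, CONTROL_POPULATION
                            germ = int(rng.integers(3, 8))
                            is_control = True
                        elif (plate, col) in slot_to_acc:
                            acc, popid = accessions[slot_to_acc[(plate, col)]]
                            germ = int(rng.integers(3, 8))
                            is_control = False
                        else:
                            acc, popid, germ, is_control = None, None, None, False
                        rows.append(
                            (block, treatment, plate, well, col, row,
                             acc, popid, germ, is_control)
                        )
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    design["germ_day"] = design["germ_day"].astype("Int64")
    return design


# ---------------------------------------------------------------------------
# population structure and allele frequencies
# ---------------------------------------------------------------------------

def simulate_structure(
    n_pop: int = 54,
    rho: float = 0.3,
    scale: float = 0.05,
    seed: int = 0,
    jitter_sd: float = 0.0,
) -> CovModel:
    """Compound-symmetry across-population covariance model.

    ``omega = scale * ((1 - rho) I + rho J)`` has diagonal ``scale`` and
    off-diagonals ``rho * scale``; ``rho`` in [0, 1) guarantees positive
    definiteness.  ``scale`` plays the role of a drift / differentiation
    intensity (Fst-like magnitude).  Optional ``jitter_sd`` adds a small
    random symmetric perturbation (seeded) for less regular structure;
    the result is checked for positive definiteness.
    """
    if not (0.0 <= rho < 1.0):
        raise PGRScanError(f"rho={rho} must lie in [0, 1)")
    if scale <= 0.0:
        raise PGRScanError("scale must be positive")
    omega = scale * ((1.0 - rho) * np.eye(n_pop) + rho * np.ones((n_pop, n_pop)))
    if jitter_sd > 0.0:
        rng = np.random.default_rng(seed)
        A = rng.normal(0.0, jitter_sd * scale, size=(n_pop, n_pop))
        omega = omega + (A + A.T) / 2.0
    eigvals = np.linalg.eigvalsh(omega)
    if eigvals.min() <= 0.0:
        raise PGRScanError(
            f"covariance parameters yield a non-positive-definite omega "
            f"(min eigenvalue {eigvals.min():.3g})"
        )
    pops = [f"pop{i + 1:02d}" for i in range(n_pop)]
    return CovModel(omega=omega, populations=pops)


@dataclass
class MapParams:
    """Genome map layout: SNPs per chromosome and physical spacing in bp."""

    n_chrom: int = 5
    spacing_bp: int = 50
    start_bp: int = 1


def _make_map(n_snp: int, map_params: MapParams) -> pd.DataFrame:
    counts = np.full(map_params.n_chrom, n_snp // map_params.n_chrom)
    counts[: n_snp % map_params.n_chrom] += 1
    recs = []
    i = 0
    for c, cnt in enumerate(counts, start=1):
        pos = map_params.start_bp + map_params.spacing_bp * np.arange(cnt)
        for p in pos:
            recs.append((f"snp{i + 1:07d}", c, int(p)))
            i += 1
    return pd.DataFrame(recs, columns=["snp_id", "chrom", "pos"])


def simulate_frequencies(
    cov: CovModel,
    n_snp: int = 10_000,
    map_params: MapParams | None = None,
    seed: int = 0,
    pi_range: tuple[float, float] = (0.1, 0.9),
) -> PopFreqPanel:
    """Simulate population allele frequencies under the covariance model.

    For each SNP s, a per-SNP mean pi_s is drawn uniformly from
    ``pi_range`` and frequencies follow a multivariate normal with mean
    pi_s and covariance pi_s (1 - pi_s) omega, truncated to
    ``FREQ_CLIP``.  Positions are laid out on ``map_params.n_chrom``
    chromosomes at fixed spacing (LD decays over ~50 bp in the mapping
    populations this emulates, hence the dense default spacing).
    """
    if n_snp < 1:
        raise PGRScanError("n_snp must be >= 1")
    map_params = map_params or MapParams()
    rng = np.random.default_rng(seed)
    P = cov.n_pop
    L = cov.cholesky()
    pi = rng.uniform(pi_range[0], pi_range[1], size=n_snp)
    eps = rng.standard_normal(size=(n_snp, P))
    dev = eps @ L.T * np.sqrt(pi * (1.0 - pi))[:, None]
    raw = pi[:, None] + dev
    freqs = np.clip(raw, *FREQ_CLIP)
    clipped = (raw != freqs).any(axis=1)
    snp_map = _make_map(n_snp, map_params)
    fdf = pd.DataFrame(freqs, index=snp_map["snp_id"].to_numpy(), columns=cov.populations)
    return PopFreqPanel(freqs=fdf, snp_map=snp_map, pi_true=pi, clipped=clipped)


def inject_signals(
    panel: PopFreqPanel,
    n_qtl: int = 20,
    beta: float = 0.2,
    xtx_overlap_frac: float = 0.5,
    seed: int = 0,
    snps_per_qtl: int = 5,
    qtl_noise_sd: float = 0.02,
    null_scale: float | None = None,
    outlier_inflation: float = 2.5,
    latent: np.ndarray | None = None,
) -> PopFreqPanel:
    """Inject QTL signals tied to a latent population growth-response value.

    ``n_qtl`` loci are placed at random positions, each spanning
    ``snps_per_qtl`` adjacent SNPs (mimicking a short-LD association
    peak).  For a QTL SNP the across-population frequency deviation is
    ``beta * g`` (plus noise), where g is the latent standard-normal
    growth-response value per population that the phenotype simulator
    reuses, so allele frequencies rank-correlate with genotypic values.

    A fraction ``xtx_overlap_frac`` of the QTL loci keep an inflated
    deviation amplitude (scaled by ``outlier_inflation`` relative to the
    null-typical magnitude) and therefore land in the XtX upper tail;
    the remaining loci have their deviation vector rescaled to the
    null-typical magnitude implied by the panel (``null_scale``, default
    estimated from the panel), which leaves rank correlations — hence
    scan detectability — intact while keeping XtX unremarkable.
    """
    if n_qtl * snps_per_qtl > panel.n_snp:
        raise PGRScanError("QTL SNPs exceed panel size")
    if not (0.0 <= xtx_overlap_frac <= 1.0):
        raise PGRScanError("xtx_overlap_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    P = panel.n_pop
    S = panel.n_snp
    g = latent if latent is not None else rng.standard_normal(P)
    g = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)

    freqs = panel.freqs.to_numpy().copy()
    pi_true = panel.pi_true.copy() if panel.pi_true is not None else None
    clipped = panel.clipped.copy() if panel.clipped is not None else None
    truth = pd.DataFrame(
        {
            "snp_id": panel.snp_map["snp_id"].to_numpy(),
            "is_qtl": False,
            "qtl_id": -1,
            "xtx_inflated": False,
            "beta": 0.0,
        }
    )

    if null_scale is None:
        # typical per-population scaled deviation magnitude in the panel
        pi0 = freqs.mean(axis=1)
        d0 = (freqs - pi0[:, None]) / np.sqrt(pi0 * (1 - pi0))[:, None]
        null_scale = float(np.sqrt(np.mean(d0**2)))

    if n_qtl > 0 and beta != 0.0:
        # choose non-overlapping runs of adjacent SNPs, away from chromosome ends
        starts = rng.choice(S - snps_per_qtl, size=n_qtl * 4, replace=False)
        chosen: list[int] = []
        occupied = np.zeros(S, dtype=bool)
        for s0 in starts:
            if len(chosen) == n_qtl:
                break
            sl = slice(s0, s0 + snps_per_qtl)
            if not occupied[sl].any():
                chosen.append(int(s0))
                occupied[sl] = True
        if len(chosen) < n_qtl:
            raise PGRScanError("could not place non-overlapping QTL loci; lower n_qtl")
        n_out = int(round(xtx_overlap_frac * n_qtl))
        outlier_loci = set(rng.choice(n_qtl, size=n_out, replace=False).tolist())
        for q, s0 in enumerate(chosen):
            inflate = q in outlier_loci
            for s in range(s0, s0 + snps_per_qtl):
                pi_s = 0.5
                dev = beta * g + rng.normal(0.0, qtl_noise_sd, size=P)
                dev = dev - dev.mean()
                scaled = dev / np.sqrt(pi_s * (1 - pi_s))
                norm = np.sqrt(np.mean(scaled**2))
                if norm > 0:
                    target = null_scale * (outlier_inflation if inflate else 1.0)
                    dev = dev * (target / norm)
                raw = pi_s + dev
                freqs[s] = np.clip(raw, *FREQ_CLIP)
                if pi_true is not None:
                    pi_true[s] = pi_s
                if clipped is not None:
                    clipped[s] = bool((raw != freqs[s]).any())
                truth.loc[s, ["is_qtl", "qtl_id", "xtx_inflated", "beta"]] = (
                    True, q, inflate, beta,
                )

    fdf = pd.DataFrame(freqs, index=panel.freqs.index, columns=panel.freqs.columns)
    return PopFreqPanel(
        freqs=fdf,
        snp_map=panel.snp_map.copy(),
        qtl_truth=truth,
        latent=pd.Series(g, index=panel.populations, name="latent_response"),
        pi_true=pi_true,
        clipped=clipped,
    )


# ---------------------------------------------------------------------------
# ordinal phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeEffects:
    """Variance components and fixed effects of the latent growth model.

    Latent well value =
        baseline(dai) + block + plate + population + accession(population)
        + germ_slope * (germ_day - 5)
        + [inoculated] * (treatment_effect(dai) + response)
        + residual noise,
    where the per-population inoculation response is
        response = response_intercept
                   - tradeoff_slope * (population + accession effect)
                   + qtl_coupling * g
    (g = latent value coupled to injected QTL allele frequencies), giving
    the negative growth-response trade-off and a genotype x treatment
    interaction.  The latent value is cut at fixed equidistant thresholds
    into ordinal scores 1..7.
    """

    baseline: dict = field(default_factory=lambda: {14: 3.2, 21: 4.0, 28: 4.4})
    treatment_effect: dict = field(default_factory=lambda: {14: 0.0, 21: 0.05, 28: 0.35})
    block_sd: float = 0.3
    plate_sd: float = 0.2
    population_sd: float = 0.5
    accession_sd: float = 0.4
    residual_sd: float = 0.6
    germ_slope: float = -0.35
    response_intercept: float = 0.0
    tradeoff_slope: float = 0.5
    qtl_coupling: float = 0.4
    response_noise_sd: float = 0.1


def _discretize(latent: np.ndarray) -> np.ndarray:
    return 1 + (latent[:, None] > SCORE_THRESHOLDS[None, :]).sum(axis=1)


def simulate_phenotypes(
    design: pd.DataFrame,
    panel: PopFreqPanel | None = None,
    effects: PhenotypeEffects | None = None,
    seed: int = 0,
    dais: tuple[int, ...] = DAIS,
) -> pd.DataFrame:
    """Simulate ordinal growth scores (1-7) for every sown well and dai.

    Control (Col-0) wells are never inoculated; they receive only
    baseline, block, plate, germination and residual effects and define
    the per-plate control-mean covariate.  When ``panel`` carries a
    latent growth-response value, the inoculation response of each
    population is coupled to it so that injected QTL allele frequencies
    correlate with the downstream growth-response index.
    """
    effects = effects or PhenotypeEffects()
    rng = np.random.default_rng(seed)
    sown = design[design["accession_id"].notna()].reset_index(drop=True)

    pops = sorted(sown.loc[~sown["is_control"], "population_id"].unique())
    accs = sorted(sown.loc[~sown["is_control"], "accession_id"].unique())
    block_ids = sorted(sown["block"].unique())

    block_eff = dict(zip(block_ids, rng.normal(0, effects.block_sd, len(block_ids))))
    pop_eff = dict(zip(pops, rng.normal(0, effects.population_sd, len(pops))))
    acc_eff = dict(zip(accs, rng.normal(0, effects.accession_sd, len(accs))))

    if panel is not None and panel.latent is not None:
        g = panel.latent.reindex(pops)
        if g.isna().any():
            raise PGRScanError("panel latent values missing for some populations")
        g = g.to_numpy()
    else:
        g = rng.standard_normal(len(pops))
    g_by_pop = dict(zip(pops, g))

    # per-(block, treatment, plate) micro-environment effect, shared across dai
    plate_key = sown[["block", "treatment", "plate"]].apply(tuple, axis=1)
    uniq_plates = sorted(plate_key.unique())
    plate_eff = dict(zip(uniq_plates, rng.normal(0, effects.plate_sd, len(uniq_plates))))

    acc_resp_noise = dict(zip(accs, rng.normal(0, effects.response_noise_sd, len(accs))))

    is_ctrl = sown["is_control"].to_numpy()
    inoc = (sown["treatment"] == INOCULATED).to_numpy() & ~is_ctrl
    germ_c = sown["germ_day"].astype(float).to_numpy() - 5.0
    base_common = (
        np.array([block_eff[b] for b in sown["block"]])
        + np.array([plate_eff[k] for k in plate_key])
        + effects.germ_slope * germ_c
    )
    gen_eff = np.where(
        is_ctrl,
        0.0,
        np.array([pop_eff.get(p, 0.0) + acc_eff.get(a, 0.0)
                  for p, a in zip(sown["population_id"], sown["accession_id"])]),
    )
    response = np.where(
        is_ctrl,
        0.0,
        effects.response_intercept
        - effects.tradeoff_slope * gen_eff
        + effects.qtl_coupling
        * np.array([g_by_pop.get(p, 0.0) for p in sown["population_id"]])
        + np.array([acc_resp_noise.get(a, 0.0) for a in sown["accession_id"]]),
    )

    frames = []
    for dai in dais:
        latent = (
            effects.baseline[dai]
            + base_common
            + gen_eff
            + inoc * (effects.treatment_effect[dai] + response)
            + rng.normal(0, effects.residual_sd, len(sown))
        )
        tbl = sown[["block", "treatment", "plate", "well", "accession_id",
                    "population_id", "germ_day", "is_control"]].copy()
        tbl["dai"] = dai
        tbl["score"] = _discretize(latent)
        frames.append(tbl)
    scores = pd.concat(frames, ignore_index=True)

    ctrl_mean = (
        scores[scores["is_control"]]
        .groupby(["block", "treatment", "plate", "dai"])["score"]
        .mean()
        .rename("plate_control_mean")
    )
    scores = scores.merge(
        ctrl_mean, on=["block", "treatment", "plate", "dai"], how="left"
    )
    return scores[SCORE_COLUMNS]


# ---------------------------------------------------------------------------
# synthetic annotation
# ---------------------------------------------------------------------------

def synthetic_genes(
    snp_map: pd.DataFrame,
    gene_length_bp: int = 200,
    gap_bp: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Tile synthetic genes along the genome map's chromosomes.

    Produces a gene table (gene_id, chrom, start_bp, end_bp, strand,
    description) covering each chromosome's SNP span with fixed-length
    genes separated by fixed gaps — enough structure to exercise
    QTL-to-gene overlap on synthetic panels.
    """
    rng = np.random.default_rng(seed)
    recs = []
    gid = 0
    for chrom, grp in snp_map.groupby("chrom", sort=True):
        lo, hi = int(grp["pos"].min()), int(grp["pos"].max())
        start = lo
        while start <= hi:
            end = start + gene_length_bp - 1
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            recs.append((f"GENE{gid:05d}", chrom, start, end, strand, "synthetic gene"))
            start = end + gap_bp + 1
    return pd.DataFrame(
        recs, columns=["gene_id", "chrom", "start_bp", "end_bp", "strand", "description"]
    )
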