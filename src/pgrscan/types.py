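"""Shared domain containers for the growth-response GWAS pipeline.

Tabular data (experimental designs, growth scores, genotypic values,
association scans) travels as plain :class:`pandas.DataFrame` objects with
documented column contracts; the small structured results below are
dataclasses so that invariants can be validated at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column contract of a design table: one row per well, including empty
#: (unsown) wells.  ``accession_id`` is NA for empty wells and ``"Col-0"``
#: for the control column.
DESIGN_COLUMNS = [
    "block", "treatment", "plate", "well", "column", "row",
    "accession_id", "population_id", "germ_day", "is_control",
]

#: Column contract of a score table: one row per sown well per scoring day.
SCORE_COLUMNS = [
    "block", "treatment", "plate", "well", "accession_id", "population_id",
    "germ_day", "is_control", "dai", "score", "plate_control_mean",
]

MOCK = "mock"
INOCULATED = "inoculated"
TREATMENTS = (MOCK, INOCULATED)

#: Scoring time points, in days after inoculation.
DAIS = (14, 21, 28)


class PGRScanError(Exception):
    """Base class for pipeline errors."""


class CapacityError(PGRScanError):
    """Design does not fit: accession columns exceed available plate columns."""


class RankDeficiencyError(PGRScanError):
    """A linear-model fit was rank deficient (confounded terms)."""


class ValidationError(PGRScanError):
    """An input table violated its contract."""


@dataclass
class CovModel:
    """Across-population covariance model of allele frequencies.

    ``omega`` is the P x P symmetric positive-definite covariance of
    scaled allele-frequency deviations across populations; ``pi`` holds
    per-SNP ancestral (or across-population mean) frequencies when the
    model is tied to a particular SNP panel.
    """

    omega: np.ndarray
    populations: list[str]
    pi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        P = len(self.populations)
        if self.omega.shape != (P, P):
            raise ValidationError(
                f"omega shape {self.omega.shape} does not match {P} populations"
            )
        if not np.allclose(self.omega, self.omega.T, atol=1e-10):
            raise ValidationError("omega is not symmetric")
        if self.pi is not None:
            self.pi = np.asarray(self.pi, dtype=float)
            if np.any(self.pi <= 0.0) or np.any(self.pi >= 1.0):
                raise ValidationError("pi must lie strictly inside (0, 1)")

    @property
    def n_pop(self) -> int:
        return len(self.populations)

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor; raises if omega is not positive-definite."""
        try:
            return np.linalg.cholesky(self.omega)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - message only
            raise ValidationError("omega is not positive-definite") from exc


@dataclass
class PopFreqPanel:
    """SNP x population allele frequencies with a genome map.

    ``freqs`` is indexed by snp_id with one column per population;
    ``snp_map`` has columns (snp_id, chrom, pos) sorted by (chrom, pos).
    ``qtl_truth`` (synthetic panels only) carries per-SNP injected-signal
    labels and ``latent`` the per-population latent growth-response value
    the QTL frequencies track.
    """

    freqs: pd.DataFrame
    snp_map: pd.DataFrame
    qtl_truth: pd.DataFrame | None = None
    latent: pd.Series | None = None
    #: synthetic panels only: the generator's true per-SNP mean frequency
    pi_true: np.ndarray | None = None
    #: synthetic panels only: SNPs where truncation to [0,1] bounds occurred
    clipped: np.ndarray | None = None

    def __post_init__(self) -> None:
        if list(self.freqs.index) != list(self.snp_map["snp_id"]):
            raise ValidationError("freqs index does not match snp_map snp_id order")
        vals = self.freqs.to_numpy()
        if np.any(vals < 0.0) or np.any(vals > 1.0):
            raise ValidationError("allele frequencies outside [0, 1]")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError("positions not strictly increasing within a chromosome")

    @property
    def populations(self) -> list[str]:
        return list(self.freqs.columns)

    @property
    def n_snp(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_pop(self) -> int:
        return self.freqs.shape[1]


@dataclass
class StdFreqPanel:
    """Structure-standardized allele frequencies and per-SNP XtX.

    ``z`` holds whitened frequency deviations (same shape/index as the
    source panel); ``xtx`` is the per-SNP squared norm of z, an Fst-like
    differentiation statistic corrected for shared population history.
    """

    z: pd.DataFrame
    xtx: pd.Series
    cov: CovModel
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.z.to_numpy())):
            raise ValidationError("standardized frequencies contain non-finite values")
        if np.any(self.xtx.to_numpy() < -1e-9):
            raise ValidationError("xtx must be non-negative")

    @property
    def populations(self) -> list[str]:
        return list(self.z.columns)


@dataclass
class VarianceComponents:
    """Method-of-moments variance components for broad-sense heritability.

    VF: genetic variance among accessions; VB: block variance; VR: residual.
    ``b_blocks`` is the number of blocks per treatment and ``n_blocks`` the
    number of blocks entering the replicate-averaging denominator.
    """

    VF: float
    VB: float
    VR: float
    b_blocks: int
    n_blocks: int

    def __post_init__(self) -> None:
        for name in ("VF", "VB", "VR"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0 (truncate at 0 upstream)")


@dataclass
class LindleyTrack:
    """Per-chromosome local-score track: scores, Lindley process, threshold."""

    chrom: object
    snp_ids: np.ndarray
    pos: np.ndarray
    scores: np.ndarray
    lindley: np.ndarray
    threshold: float
    xi: float
    alpha: float

    def __post_init__(self) -> None:
        if np.any(self.lindley < 0):
            raise ValidationError("Lindley process must be non-negative")
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")


@dataclass
class QTLSegment:
    """A significant Lindley excursion: QTL interval, peak and member top SNPs."""

    chrom: object
    start_bp: int
    end_bp: int
    peak_bp: int
    peak_lindley: float
    top_snps: list[str]
    trait: str = ""

    def __post_init__(self) -> None:
        if not (self.start_bp <= self.peak_bp <= self.end_bp):
            raise ValidationError("segment peak must lie within [start, end]")
        if not self.top_snps:
            raise ValidationError("segment must contain at least one top SNP")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class GeneAnnotation:
    """Gene-level annotation extracted from GFF3 (1-based closed intervals)."""

    genes: pd.DataFrame  # columns: gene_id, chrom, start_bp, end_bp, strand, description

    def __post_init__(self) -> None:
        bad = self.genes["start_bp"] > self.genes["end_bp"]
        if bad.any():
            raise ValidationError("gene start_bp > end_bp")


@dataclass
class EnrichmentResult:
    """Fold enrichment of top SNPs in the XtX upper tail + permutation p."""

    n_a: int
    n: int
    N_a: int
    N_tot: int
    fe: float
    p_perm: float
    n_perm: int
    seed: int | None = None
    trait: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.n_a <= min(self.n, self.N_a)):
            raise ValidationError("inconsistent enrichment counts")
        if not (0.0 < self.p_perm <= 1.0):
            raise ValidationError("p_perm must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a, "n": self.n, "N_a": self.N_a, "N_tot": self.N_tot,
            "fe": self.fe, "p_perm": self.p_perm, "n_perm": self.n_perm,
            "seed": self.seed, "trait": self.trait,
        }
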