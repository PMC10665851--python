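"""QTL interval statistics, gene overlap and time-point intersections.

Turns called segments into candidate-gene results: summary statistics
of QTL interval lengths, gene overlap against a GFF3 gene annotation
(1-based closed intervals, strand ignored), and the Venn-style
partition of candidate genes across scoring time points.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .types import GeneAnnotation, PGRScanError, QTLSegment

__all__ = [
    "read_genes_gff3",
    "interval_stats",
    "overlap_genes",
    "intersect_timepoints",
]


def read_genes_gff3(path) -> GeneAnnotation:
    """Read gene-type features from a GFF3 file.

    Only features with type ``gene`` are kept; the gene id is the ID
    attribute (falling back to Name, then to a positional id).
    Coordinates stay in GFF3 convention: 1-based closed intervals.
    """
    cols = ["chrom", "source", "type", "start_bp", "end_bp", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=cols,
        dtype={"chrom": str}, na_filter=False,
    )
    genes = df[df["type"] == "gene"].copy()
    if genes.empty:
        raise PGRScanError(f"no gene features in {path}")

    def gene_id(attrs: str, i: int) -> str:
        for field in attrs.split(";"):
            field = field.strip()
            for key in ("ID=", "Name="):
                if field.startswith(key):
                    return field[len(key):]
        return f"gene_{i}"

    genes["gene_id"] = [gene_id(a, i) for i, a in enumerate(genes["attributes"])]
    genes["description"] = genes["attributes"]
    out = genes[["gene_id", "chrom", "start_bp", "end_bp", "strand", "description"]]
    return GeneAnnotation(genes=out.reset_index(drop=True))


@dataclass
class IntervalStats:
    mean_bp: float
    q5_bp: float
    q95_bp: float
    count: int


def interval_stats(segments: list[QTLSegment]) -> IntervalStats:
    """Mean and 5%/95% quantiles of QTL interval lengths (bp, closed intervals)."""
    if not segments:
        raise PGRScanError("no segments")
    lengths = np.array([s.length_bp for s in segments], dtype=float)
    return IntervalStats(
        mean_bp=float(lengths.mean()),
        q5_bp=float(np.quantile(lengths, 0.05)),
        q95_bp=float(np.quantile(lengths, 0.95)),
        count=len(lengths),
    )


def overlap_genes(
    segments: list[QTLSegment],
    genes: GeneAnnotation,
    flank_bp: int = 0,
) -> pd.DataFrame:
    """Candidate genes per trait: genes whose (flanked) interval meets a segment.

    Closed-interval intersection on 1-based coordinates; a gene is a
    candidate for a trait as soon as one of that trait's segments
    intersects [start - flank, end + flank].  Output is de-duplicated
    per (trait, gene) with the total overlap in bp across segments.
    """
    if flank_bp < 0:
        raise PGRScanError("flank_bp must be >= 0")
    seg_chroms = {str(s.chrom) for s in segments}
    gene_chroms = set(genes.genes["chrom"].astype(str))
    missing = seg_chroms - gene_chroms
    if missing:
        raise PGRScanError(
            f"segment chromosomes absent from annotation: {sorted(missing)}"
        )
    rows = []
    by_chrom = {str(c): g for c, g in genes.genes.groupby(genes.genes["chrom"].astype(str))}
    for seg in segments:
        g = by_chrom[str(seg.chrom)]
        gs = g["start_bp"].to_numpy() - flank_bp
        ge = g["end_bp"].to_numpy() + flank_bp
        hit = (gs <= seg.end_bp) & (ge >= seg.start_bp)
        for _, gene in g[hit].iterrows():
            ov = min(gene["end_bp"] + flank_bp, seg.end_bp) - max(
                gene["start_bp"] - flank_bp, seg.start_bp
            ) + 1
            rows.append(
                (seg.trait, gene["gene_id"], str(seg.chrom), gene["start_bp"],
                 gene["end_bp"], seg.start_bp, seg.end_bp, int(ov))
            )
    report = pd.DataFrame(
        rows,
        columns=["trait", "gene_id", "chrom", "gene_start", "gene_end",
                 "seg_start", "seg_end", "overlap_bp"],
    )
    if report.empty:
        return report
    return (
        report.groupby(["trait", "gene_id", "chrom", "gene_start", "gene_end"], as_index=False)
        .agg(n_segments=("seg_start", "size"), overlap_bp=("overlap_bp", "sum"))
        .sort_values(["trait", "chrom", "gene_start"])
        .reset_index(drop=True)
    )


def intersect_timepoints(gene_lists: dict[str, set]) -> dict[tuple[str, ...], set]:
    """Exact Venn partition of candidate-gene lists across time points.

    Returns a mapping from a sorted tuple of time-point labels to the
    set of genes present in exactly those lists; the class sets
    partition the union of all lists.
    """
    if len(gene_lists) < 2:
        raise PGRScanError("need >= 2 gene lists to intersect")
    labels = sorted(gene_lists)
    out: dict[tuple[str, ...], set] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(set(gene_lists[l]) for l in combo))
            outside = set.union(
                *(set(gene_lists[l]) for l in labels if l not in combo), set()
            )
            out[combo] = inside - outside
    return out
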