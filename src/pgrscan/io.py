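"""Readers and writers for the pipeline's plain-text table contracts.

CSV for phenotype-side tables (design, scores, genotypic values, growth
response, ANOVA, candidate genes), TSV for genotype-side matrices
(frequencies, genome map, standardized frequencies, XtX, scan results,
segments), JSON for the run manifest and enrichment results.  Floats
are written with a fixed general format so that re-runs are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CovModel, PopFreqPanel, QTLSegment, StdFreqPanel, ValidationError

FLOAT_FMT = "%.10g"


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["germ_day"] = df["germ_day"].astype("Int64")
    return df


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_panel(panel: PopFreqPanel, freqs_path, map_path, truth_path=None) -> None:
    """Panel as a SNP x population TSV plus a genome-map TSV (+ truth labels)."""
    f = panel.freqs.copy()
    f.insert(0, "snp_id", panel.freqs.index)
    write_tsv(f, freqs_path)
    write_tsv(panel.snp_map, map_path)
    if truth_path is not None and panel.qtl_truth is not None:
        truth = panel.qtl_truth.copy()
        if panel.latent is not None:
            latent = pd.DataFrame(
                {"population": panel.latent.index, "latent_response": panel.latent.to_numpy()}
            )
            write_tsv(latent, str(truth_path).replace(".tsv", "_latent.tsv"))
        write_tsv(truth, truth_path)


def read_panel(freqs_path, map_path) -> PopFreqPanel:
    freqs = pd.read_csv(freqs_path, sep="\t").set_index("snp_id")
    snp_map = pd.read_csv(map_path, sep="\t")
    return PopFreqPanel(freqs=freqs, snp_map=snp_map)


def write_std_panel(std: StdFreqPanel, z_path, xtx_path, outlier_mask=None) -> None:
    z = std.z.copy()
    z.insert(0, "snp_id", std.z.index)
    write_tsv(z, z_path)
    xtx = pd.DataFrame({"snp_id": std.xtx.index, "xtx": std.xtx.to_numpy()})
    if outlier_mask is not None:
        xtx["outlier_flag"] = np.asarray(outlier_mask, dtype=int)
    write_tsv(xtx, xtx_path)


def read_std_panel(z_path, xtx_path, map_path, populations=None) -> StdFreqPanel:
    """Ingest precomputed standardized frequencies and XtX (bypasses estimation)."""
    z = pd.read_csv(z_path, sep="\t").set_index("snp_id")
    xtx = pd.read_csv(xtx_path, sep="\t").set_index("snp_id")["xtx"]
    snp_map = pd.read_csv(map_path, sep="\t")
    pops = populations or list(z.columns)
    cov = CovModel(omega=np.eye(len(pops)), populations=pops)
    return StdFreqPanel(z=z, xtx=xtx.reindex(z.index), cov=cov, snp_map=snp_map)


def write_segments(segments: list[QTLSegment], path, top_snp_path=None) -> None:
    """Segments as BED-like TSV plus an optional per-top-SNP detail table."""
    rows = [
        (s.chrom, s.start_bp, s.end_bp, s.peak_bp, s.peak_lindley,
         len(s.top_snps), s.trait)
        for s in segments
    ]
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "peak", "peak_lindley",
                       "n_top_snps", "trait"],
    )
    write_tsv(df, path)
    if top_snp_path is not None:
        detail = [
            (s.trait, s.chrom, s.start_bp, s.end_bp, snp)
            for s in segments for snp in s.top_snps
        ]
        write_tsv(
            pd.DataFrame(detail, columns=["trait", "chrom", "start", "end", "snp_id"]),
            top_snp_path,
        )


def read_segments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def validate_inputs(paths: dict) -> list[str]:
    """Validate pipeline input files; returns a list of issue strings.

    Checks frequency bounds and map sortedness for a panel
    (``freqs`` + ``map`` paths), score ranges for a score table
    (``scores``), and population-id agreement between the frequency
    panel and the score table.
    """
    issues: list[str] = []
    freqs = None
    if "freqs" in paths:
        try:
            freqs = pd.read_csv(paths["freqs"], sep="\t").set_index("snp_id")
        except Exception as exc:
            issues.append(f"{paths['freqs']}: unreadable ({exc})")
        else:
            vals = freqs.to_numpy()
            bad = np.argwhere((vals < 0) | (vals > 1))
            for r, c in bad[:20]:
                issues.append(
                    f"{paths['freqs']}: frequency {vals[r, c]} outside [0,1] "
                    f"at row {r + 2} ({freqs.index[r]}, {freqs.columns[c]})"
                )
    if "map" in paths:
        try:
            snp_map = pd.read_csv(paths["map"], sep="\t")
        except Exception as exc:
            issues.append(f"{paths['map']}: unreadable ({exc})")
        else:
            for chrom, grp in snp_map.groupby("chrom", sort=False):
                d = np.diff(grp["pos"].to_numpy())
                if np.any(d <= 0):
                    row = int(grp.index[int(np.argmax(d <= 0)) + 1]) + 2
                    issues.append(
                        f"{paths['map']}: positions not strictly increasing on "
                        f"chromosome {chrom} (first violation near row {row})"
                    )
            if freqs is not None and len(snp_map) != len(freqs):
                issues.append("map and frequency panel have different SNP counts")
    if "scores" in paths:
        try:
            scores = pd.read_csv(paths["scores"])
        except Exception as exc:
            issues.append(f"{paths['scores']}: unreadable ({exc})")
        else:
            bad = scores[~scores["score"].isin(range(1, 8))]
            for i in bad.index[:20]:
                issues.append(
                    f"{paths['scores']}: score {scores.loc[i, 'score']} outside 1..7 "
                    f"at row {i + 2}"
                )
            if freqs is not None:
                pops_s = set(scores.loc[~scores.get("is_control", False), "population_id"].dropna())
                pops_f = set(freqs.columns)
                only = sorted(pops_s - pops_f)
                if only:
                    issues.append(
                        f"populations in scores but not in frequency panel: {only[:10]}"
                    )
    return issues
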