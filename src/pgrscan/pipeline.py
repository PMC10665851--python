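"""End-to-end pipeline: simulate -> phenotype models -> standardize ->
scan -> local score -> annotate -> enrich, with a machine-readable run
manifest.

Every randomized stage draws its seed deterministically from the
config's master seed, so a run directory is bit-reproducible from its
manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, enrich, freqstd, io, localscore, phenomod, scan, synthgen
from .types import DAIS, MOCK, PGRScanError

log = logging.getLogger("pgrscan")


@dataclass
class PipelineConfig:
    """Full configuration of a pipeline run; round-trips to YAML losslessly."""

    seed: int = 1
    # design
    n_pop: int = 54
    n_acc_per_pop: int = 3
    n_blocks: int = 2
    plates_per_cell: int = 24
    # genotypes
    n_snp: int = 20_000
    structure_rho: float = 0.3
    structure_scale: float = 0.05
    n_qtl: int = 20
    snps_per_qtl: int = 5
    beta: float = 0.2
    xtx_overlap_frac: float = 0.5
    # analysis
    xi: float = 2.0
    alpha: float = 0.05
    threshold_method: str = "montecarlo"
    threshold_B: int = 1000
    q_tail: float = 0.01
    n_perm: int = 10_000
    flank_bp: int = 0
    dais: tuple = DAIS
    h2_n_perm: int = 0  # 0 disables the permutation p-value for H2
    # stage toggles
    run_annotate: bool = True
    run_enrich: bool = True
    make_plots: bool = False

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "dais" in data:
            data["dais"] = tuple(data["dais"])
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = 0
        for ch in stage:
            h = (h * 131 + ord(ch)) % 1_000_003
        return (self.seed * 7_919 + h) % (2**31 - 1)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full synthetic pipeline and write per-stage outputs.

    Returns the run manifest (also written to ``manifest.json``), which
    records the config, per-stage seeds and headline results.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"config": asdict(config), "stages": {}, "results": {}}

    def stage(name: str, **params):
        log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in params.items()))
        manifest["stages"][name] = dict(params)

    # --- simulate -----------------------------------------------------
    stage("simulate", seed=config.stage_seed("simulate"))
    design = synthgen.build_design(
        n_pop=config.n_pop, n_acc_per_pop=config.n_acc_per_pop,
        n_blocks=config.n_blocks, plates_per_cell=config.plates_per_cell,
        seed=config.stage_seed("design"),
    )
    cov = synthgen.simulate_structure(
        n_pop=config.n_pop, rho=config.structure_rho, scale=config.structure_scale,
        seed=config.stage_seed("structure"),
    )
    panel = synthgen.simulate_frequencies(
        cov, n_snp=config.n_snp, seed=config.stage_seed("frequencies")
    )
    panel = synthgen.inject_signals(
        panel, n_qtl=config.n_qtl, beta=config.beta,
        xtx_overlap_frac=config.xtx_overlap_frac,
        snps_per_qtl=config.snps_per_qtl, seed=config.stage_seed("inject"),
    )
    scores = synthgen.simulate_phenotypes(
        design, panel=panel, seed=config.stage_seed("phenotypes"), dais=config.dais
    )
    io.write_csv(design, out / "design.csv")
    io.write_csv(scores, out / "scores.csv")
    io.write_panel(panel, out / "freqs.tsv", out / "map.tsv", out / "qtl_truth.tsv")

    # --- phenotype models ---------------------------------------------
    stage("pheno")
    gv_frames, anova_frames = [], []
    h2 = {}
    for dai in config.dais:
        gv_frames.append(phenomod.fit_lsmeans(scores, model="model2", dai=dai))
        gv_frames.append(phenomod.fit_lsmeans(scores, model="model5", dai=dai))
        at = phenomod.splitplot_anova(scores, dai=dai)
        at.insert(0, "dai", dai)
        anova_frames.append(at)
        for trt in sorted(scores["treatment"].unique()):
            vc = phenomod.variance_components(scores, dai=dai, treatment=trt)
            entry = {
                "H2": phenomod.heritability(vc),
                "VF": vc.VF, "VB": vc.VB, "VR": vc.VR,
            }
            if config.h2_n_perm >= 99:
                _, pval = phenomod.heritability_pvalue(
                    scores, dai=dai, treatment=trt, n_perm=config.h2_n_perm,
                    seed=config.stage_seed(f"h2perm_{dai}_{trt}"),
                )
                entry["p_perm"] = pval
            h2[f"{trt}_{dai}dai"] = entry
    gv = pd.concat(gv_frames, ignore_index=True)
    pgr = phenomod.compute_pgr(gv)
    tradeoff = {
        f"{dai}dai": dict(
            zip(("rho", "p"), phenomod.tradeoff_test(pgr, gv, dai=dai))
        )
        for dai in config.dais
    }
    io.write_csv(gv, out / "genotypic_values.csv")
    io.write_csv(pgr, out / "pgr.csv")
    io.write_csv(pd.concat(anova_frames, ignore_index=True), out / "anova.csv")
    io.write_json({"heritability": h2, "tradeoff": tradeoff}, out / "pheno_summary.json")
    manifest["results"]["heritability"] = h2
    manifest["results"]["tradeoff"] = tradeoff

    # --- standardize ---------------------------------------------------
    stage("standardize", q_tail=config.q_tail)
    cov_hat = freqstd.estimate_cov(panel)
    std = freqstd.standardize(panel, cov_hat)
    outlier_mask, n_tail = freqstd.top_fraction_mask(std.xtx, q=config.q_tail)
    io.write_std_panel(std, out / "std_freqs.tsv", out / "xtx.tsv", outlier_mask)
    manifest["results"]["xtx_tail_count"] = int(n_tail)

    # --- scan + local score per dai -------------------------------------
    all_segments = []
    seg_trait_masks = {}
    scan_qq = {}
    for dai in config.dais:
        trait_label = f"PGR_{dai}dai"
        stage(f"scan_{dai}", trait=trait_label)
        trait = (
            pgr[(pgr["level"] == "population") & (pgr["dai"] == dai)]
            .set_index("unit")["pgr"]
        )
        sc = scan.genome_scan(std, trait, trait_label=trait_label)
        io.write_tsv(sc, out / f"scan_{dai}dai.tsv")
        lam, ks = scan.qq_diagnostic(sc)
        scan_qq[trait_label] = {"lambda_gc": lam, "ks": ks}
        stage(f"localscore_{dai}", xi=config.xi, alpha=config.alpha,
              seed=config.stage_seed(f"threshold_{dai}"))
        tracks, segments = localscore.lindley_scan(
            sc, xi=config.xi, alpha=config.alpha, method=config.threshold_method,
            B=config.threshold_B, seed=config.stage_seed(f"threshold_{dai}"),
            trait=trait_label,
        )
        io.write_segments(
            segments, out / f"segments_{dai}dai.tsv", out / f"top_snps_{dai}dai.tsv"
        )
        if config.make_plots:
            from . import plots

            plots.manhattan_lindley(
                tracks, out / f"lindley_{dai}dai.png", title=trait_label
            )
            plots.qq_plot(sc, out / f"qq_{dai}dai.png", title=trait_label)
        all_segments.extend(segments)
        top_ids = {s for seg in segments for s in seg.top_snps}
        mask = std.snp_map["snp_id"].isin(top_ids).to_numpy()
        seg_trait_masks[trait_label] = mask
    manifest["results"]["qq"] = scan_qq
    manifest["results"]["n_segments"] = len(all_segments)
    manifest["results"]["n_top_snps"] = int(
        sum(m.sum() for m in seg_trait_masks.values())
    )
    if all_segments:
        st = annotate.interval_stats(all_segments)
        manifest["results"]["interval_stats"] = {
            "mean_bp": st.mean_bp, "q5_bp": st.q5_bp, "q95_bp": st.q95_bp,
            "count": st.count,
        }

    # --- annotate -------------------------------------------------------
    if config.run_annotate and all_segments:
        stage("annotate", flank_bp=config.flank_bp)
        genes = synthgen.synthetic_genes(panel.snp_map, seed=config.stage_seed("genes"))
        from .types import GeneAnnotation

        report = annotate.overlap_genes(
            all_segments, GeneAnnotation(genes=genes), flank_bp=config.flank_bp
        )
        io.write_csv(report, out / "candidate_genes.csv")
        if not report.empty:
            lists = {
                t: set(g["gene_id"]) for t, g in report.groupby("trait")
            }
            if len(lists) >= 2:
                venn = annotate.intersect_timepoints(lists)
                venn_df = pd.DataFrame(
                    [("+".join(k), len(v)) for k, v in sorted(venn.items())],
                    columns=["timepoints", "n_genes"],
                )
                io.write_csv(venn_df, out / "venn_classes.csv")
                manifest["results"]["n_candidate_genes"] = len(
                    set().union(*lists.values())
                )

    # --- enrich ---------------------------------------------------------
    if config.run_enrich:
        enr = {}
        for trait_label, mask in seg_trait_masks.items():
            if mask.sum() == 0:
                continue
            stage(f"enrich_{trait_label}", n_perm=config.n_perm)
            res = enrich.circular_permutation_test(
                mask, outlier_mask, snp_map=std.snp_map, n_perm=config.n_perm,
                seed=config.stage_seed(f"enrich_{trait_label}"), trait=trait_label,
            )
            enr[trait_label] = res.to_dict()
        io.write_json(enr, out / "enrichment.json")
        manifest["results"]["enrichment"] = enr

    log.info("pipeline done in %.1fs", time.time() - t0)
    config.to_yaml(out / "config.yaml")
    io.write_json(manifest, out / "manifest.json")
    return manifest
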