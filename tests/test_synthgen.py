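"""Generator tests: design invariants, structure, frequencies, signals, scores."""

import numpy as np
import pandas as pd
import pytest

from pgrscan import freqstd, synthgen
from pgrscan.types import CapacityError, PGRScanError


class TestDesign:
    def test_study_scale_counts(self):
        d = synthgen.build_design(54, 3, 2, 24, seed=1)
        sown = d[d["accession_id"].notna()]
        assert len(d) == 2 * 2 * 24 * 48 == 4608
        assert (~sown["is_control"]).sum() == 162 * 12 * 2 == 3888
        assert sown["is_control"].sum() == 576
        assert sown.loc[~sown["is_control"], "accession_id"].nunique() == 162

    def test_minimal_design(self):
        d = synthgen.build_design(1, 1, 1, 1, seed=0)
        for (_, _, plate), grp in d.groupby(["block", "treatment", "plate"]):
            sown = grp[grp["accession_id"].notna()]
            assert (sown["is_control"]).sum() == 6
            assert (~sown["is_control"]).sum() == 12

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            synthgen.build_design(n_pop=10, n_acc_per_pop=2, n_blocks=2,
                                  plates_per_cell=1, seed=0)

    @pytest.mark.parametrize("seed", range(100))
    def test_invariants_over_seeds(self, seed):
        d = synthgen.build_design(n_pop=4, n_acc_per_pop=2, n_blocks=2,
                                  plates_per_cell=2, seed=seed)
        # each plate has 48 wells; control wells are exactly the last column
        for _, plate in d.groupby(["block", "treatment", "plate"]):
            assert len(plate) == 48
            ctrl = plate[plate["is_control"]]
            assert len(ctrl) == 6
            assert (ctrl["column"] == 8).all()
        sown = d[d["accession_id"].notna() & ~d["is_control"]]
        # 12 wells per accession per treatment; population constant in accession
        assert (sown.groupby(["accession_id", "treatment"]).size() == 12).all()
        assert (sown.groupby("accession_id")["population_id"].nunique() == 1).all()
        # randomization shared between treatments within block, redrawn between blocks
        slot_cols = ["plate", "column", "row", "accession_id"]
        layouts = {
            key: grp[slot_cols].reset_index(drop=True)
            for key, grp in sown.groupby(["block", "treatment"])
        }
        for b in (1, 2):
            pd.testing.assert_frame_equal(
                layouts[(b, "mock")], layouts[(b, "inoculated")]
            )
        assert not layouts[(1, "mock")].equals(layouts[(2, "mock")])

    def test_reproducible(self):
        a = synthgen.build_design(4, 2, 2, 2, seed=5)
        b = synthgen.build_design(4, 2, 2, 2, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestStructure:
    def test_identity_at_rho_zero(self):
        cov = synthgen.simulate_structure(n_pop=4, rho=0.0, scale=0.3)
        np.testing.assert_allclose(cov.omega, 0.3 * np.eye(4))

    def test_compound_symmetry_offdiag(self):
        cov = synthgen.simulate_structure(n_pop=3, rho=0.5, scale=0.2)
        np.testing.assert_allclose(np.diag(cov.omega), 0.2)
        off = cov.omega[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.1)

    def test_positive_definite_large(self):
        cov = synthgen.simulate_structure(n_pop=54, rho=0.3, seed=2)
        L = cov.cholesky()  # must not raise
        assert np.all(np.isfinite(L))

    def test_invalid_rho(self):
        with pytest.raises(PGRScanError):
            synthgen.simulate_structure(n_pop=3, rho=1.0)


class TestFrequencies:
    def test_small_omega_limit(self):
        cov = synthgen.simulate_structure(n_pop=5, rho=0.0, scale=1e-12)
        panel = synthgen.simulate_frequencies(cov, n_snp=50, seed=0)
        expected = np.repeat(panel.pi_true[:, None], 5, axis=1)
        np.testing.assert_allclose(panel.freqs.to_numpy(), expected, rtol=0, atol=1e-4)

    def test_one_snp_per_chromosome(self):
        cov = synthgen.simulate_structure(n_pop=3, seed=0)
        panel = synthgen.simulate_frequencies(cov, n_snp=5, seed=0)
        assert panel.snp_map.groupby("chrom").size().tolist() == [1] * 5

    def test_covariance_recovery_true_pi(self):
        """Empirical covariance of true-pi-scaled deviations converges to omega."""
        cov = synthgen.simulate_structure(n_pop=5, rho=0.0, scale=0.05, seed=1)
        panel = synthgen.simulate_frequencies(
            cov, n_snp=10_000, seed=2, pi_range=(0.25, 0.75)
        )
        keep = ~panel.clipped
        assert keep.mean() > 0.95  # clipping negligible at this drift scale
        D = freqstd.scaled_deviations(
            panel.freqs.to_numpy()[keep], panel.pi_true[keep]
        )
        omega_hat = D.T @ D / keep.sum()
        rel = np.linalg.norm(omega_hat - cov.omega) / np.linalg.norm(cov.omega)
        assert rel < 0.10

    def test_bit_reproducible(self):
        cov = synthgen.simulate_structure(n_pop=4, seed=3)
        a = synthgen.simulate_frequencies(cov, n_snp=100, seed=7)
        b = synthgen.simulate_frequencies(cov, n_snp=100, seed=7)
        assert np.array_equal(a.freqs.to_numpy(), b.freqs.to_numpy())


class TestInjectSignals:
    def test_no_qtl(self, panel54):
        cov = synthgen.simulate_structure(n_pop=6, seed=0)
        panel = synthgen.simulate_frequencies(cov, n_snp=100, seed=1)
        out = synthgen.inject_signals(panel, n_qtl=0, seed=2)
        assert not out.qtl_truth["is_qtl"].any()
        np.testing.assert_array_equal(out.freqs.to_numpy(), panel.freqs.to_numpy())

    def test_beta_zero_leaves_panel(self):
        cov = synthgen.simulate_structure(n_pop=6, seed=0)
        panel = synthgen.simulate_frequencies(cov, n_snp=100, seed=1)
        out = synthgen.inject_signals(panel, n_qtl=3, beta=0.0, seed=2)
        np.testing.assert_array_equal(out.freqs.to_numpy(), panel.freqs.to_numpy())

    def test_strong_beta_tops_scan(self, panel54, std54):
        """QTL SNPs rank in the top 1% of |rho| against the latent value."""
        from pgrscan import scan

        sc = scan.genome_scan(std54, panel54.latent, "latent")
        cutoff = np.quantile(np.abs(sc["rho"]), 0.99)
        q = panel54.qtl_truth["is_qtl"].to_numpy()
        frac = (np.abs(sc["rho"].to_numpy()[q]) >= cutoff).mean()
        assert frac > 0.9

    def test_overlap_fraction_controls_outliers(self, panel54, std54):
        mask, _ = freqstd.top_fraction_mask(std54.xtx, q=0.01)
        truth = panel54.qtl_truth
        inflated = truth["xtx_inflated"].to_numpy()
        plain = truth["is_qtl"].to_numpy() & ~inflated
        assert (mask & inflated).sum() == inflated.sum()
        assert (mask & plain).sum() == 0


class TestPhenotypes:
    def test_no_effects_baseline_score(self, small_design):
        eff = synthgen.PhenotypeEffects(
            baseline={14: 4.0, 21: 4.0, 28: 4.0},
            treatment_effect={14: 0, 21: 0, 28: 0},
            block_sd=0, plate_sd=0, population_sd=0, accession_sd=0,
            residual_sd=0, germ_slope=0, tradeoff_slope=0, qtl_coupling=0,
            response_noise_sd=0,
        )
        sc = synthgen.simulate_phenotypes(small_design, effects=eff, seed=0)
        assert (sc["score"] == 4).all()

    def test_score_range_and_control_mean(self, small_scores):
        assert small_scores["score"].between(1, 7).all()
        grp = small_scores.groupby(["block", "treatment", "plate", "dai"])
        assert (grp["plate_control_mean"].nunique() == 1).all()

    def test_reproducible(self, small_design):
        a = synthgen.simulate_phenotypes(small_design, seed=3)
        b = synthgen.simulate_phenotypes(small_design, seed=3)
        pd.testing.assert_frame_equal(a, b)


def test_synthetic_genes_tile_chromosomes(panel54):
    genes = synthgen.synthetic_genes(panel54.snp_map, seed=0)
    assert (genes["start_bp"] <= genes["end_bp"]).all()
    assert set(genes["chrom"]) == set(panel54.snp_map["chrom"])
    for _, g in genes.groupby("chrom"):
        starts = g["start_bp"].to_numpy()
        assert np.all(np.diff(starts) > 0)
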