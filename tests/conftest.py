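"""Shared fixtures: small synthetic designs, score tables and SNP panels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pgrscan import freqstd, synthgen


@pytest.fixture(scope="session")
def small_design() -> pd.DataFrame:
    # 12 accessions in 6 populations, 2 blocks x 2 treatments x 2 plates
    return synthgen.build_design(
        n_pop=6, n_acc_per_pop=2, n_blocks=2, plates_per_cell=2, seed=11
    )


@pytest.fixture(scope="session")
def small_scores(small_design) -> pd.DataFrame:
    return synthgen.simulate_phenotypes(small_design, seed=12)


@pytest.fixture(scope="session")
def panel54():
    """54-population panel with injected QTL signals (latent-coupled)."""
    cov = synthgen.simulate_structure(n_pop=54, rho=0.3, scale=0.05, seed=21)
    panel = synthgen.simulate_frequencies(cov, n_snp=3000, seed=22)
    return synthgen.inject_signals(
        panel, n_qtl=6, beta=0.2, xtx_overlap_frac=0.5, seed=23
    )


@pytest.fixture(scope="session")
def std54(panel54):
    cov = freqstd.estimate_cov(panel54)
    return freqstd.standardize(panel54, cov)
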