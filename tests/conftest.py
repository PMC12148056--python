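import numpy as np
import pandas as pd
import pytest

import dropscreen as ds
from dropscreen.synthetic_data import GeneEffectProfile, skewed_library


@pytest.fixture(scope="session")
def small_library():
    return ds.build_default_library(10, guides_per_gene=4, n_nontargeting=4, seed=42)


@pytest.fixture(scope="session")
def null_screen():
    """All-neutral simulated screen at calibration scale (2,000 genes)."""
    lib = skewed_library(ds.build_default_library(2000, 4, 100, seed=3), seed=3)
    effects = GeneEffectProfile.neutral(lib.genes)
    n_guides = len(lib)
    pos, neg = ds.simulate_screen(
        lib,
        effects,
        moi_f=0.25,
        n_cells=100 * n_guides,
        harvest_t=1.0,
        depth=500 * n_guides,
        n_samples_per_arm=3,
        seed=11,
    )
    counts = pd.concat([pos.counts_frame(), neg.counts_frame()], axis=1)
    table = ds.score_screen(counts, neg.sample_names, pos.sample_names, lib.gene_by_guide)
    return lib, pos, neg, table


@pytest.fixture(scope="session")
def planted_screen():
    """Screen with 5% of genes planted as neuroprotective (multiplier 3.0)
    and 2% as disease-promoting (multiplier 0.33)."""
    lib = skewed_library(ds.build_default_library(2000, 4, 100, seed=3), seed=3)
    effects = GeneEffectProfile.planted(
        lib.genes,
        frac_depleted=0.05,
        depleted_multiplier=3.0,
        frac_enriched=0.02,
        enriched_multiplier=0.33,
        seed=7,
    )
    n_guides = len(lib)
    pos, neg = ds.simulate_screen(
        lib,
        effects,
        moi_f=0.25,
        n_cells=100 * n_guides,
        harvest_t=1.0,
        depth=500 * n_guides,
        n_samples_per_arm=3,
        seed=12,
    )
    counts = pd.concat([pos.counts_frame(), neg.counts_frame()], axis=1)
    table = ds.score_screen(counts, neg.sample_names, pos.sample_names, lib.gene_by_guide)
    return lib, effects, table


def gini_pairwise_oracle(counts) -> float:
    """O(n^2) brute-force Gini: mean |xi - xj| over ordered pairs / (2*mean)."""
    x = np.asarray(counts, dtype=float)
    n = x.size
    diff_sum = np.abs(x[:, None] - x[None, :]).sum()
    return diff_sum / (2.0 * n * n * x.mean())
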