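"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import leafcorr as lc


@pytest.fixture(scope="session")
def planted_dataset():
    """105-sample dataset with 20 genes planted on LL at rho = 0.6 (seed 11)."""
    spec = lc.PopulationSpec(
        n_genes=600,
        seed=11,
        planted=[lc.PlantedSignal(i, "LL", 0.6, category="bin_99") for i in range(20)],
    )
    traits = lc.simulate_traits(spec)
    counts, annotation, truth = lc.simulate_counts(spec, traits)
    expr = lc.normalize_transform(counts, lc.size_factors(counts))
    return {
        "spec": spec,
        "traits": traits,
        "counts": counts,
        "annotation": annotation,
        "truth": truth,
        "expr": expr,
    }


@pytest.fixture(scope="session")
def planted_catalog(planted_dataset):
    """Gene-set catalog built from the planted dataset (200 permutations)."""
    expr, traits = planted_dataset["expr"], planted_dataset["traits"]
    pcc = lc.transcript_trait_pcc(expr, traits)
    observed = lc.tail_quantiles(pcc)
    permuted = lc.permutation_thresholds(expr, traits, n_perm=200, seed=11)
    return {
        "pcc": pcc,
        "observed": observed,
        "permuted": permuted,
        "catalog": lc.select_sets(pcc, observed, permuted),
    }


@pytest.fixture()
def toy_traits():
    """Tiny hand-built trait table (5 lines x 3 traits, no missing)."""
    values = pd.DataFrame(
        {
            "LL": [600.0, 620.0, 640.0, 660.0, 680.0],
            "FW": [30.0, 28.0, 35.0, 33.0, 38.0],
            "T_m": [410.0, 400.0, 395.0, 390.0, 385.0],
        },
        index=[f"L{i}" for i in range(5)],
    )
    traits = {
        "LL": lc.TraitInfo("mm", "leaf_size"),
        "FW": lc.TraitInfo("g", "shoot"),
        "T_m": lc.TraitInfo("h", "timing"),
    }
    roles = pd.Series("RIL", index=values.index)
    return lc.TraitTable(values, traits, roles)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
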