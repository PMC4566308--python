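"""Scoring against synthetic ground truth: recovery and null calibration."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .correlation import (
    permutation_thresholds,
    select_sets,
    tail_quantiles,
    transcript_trait_pcc,
)
from .preprocess import normalize_transform, size_factors
from .simulate import PopulationSpec, simulate_counts, simulate_traits
from .types import GeneSetCatalog, PlantedTruth


def recovery_metrics(
    catalog: GeneSetCatalog, truth: PlantedTruth, stringency: str = "q_random"
) -> pd.DataFrame:
    """Sign-matched precision/recall of planted associations per trait.

    A planted (gene, trait, rho > 0) association counts as recovered only
    if the gene sits in the *positive* set of that trait (and mirrored
    for negative rho): a sign flip is a miss.  Precision is NaN for an
    empty selected set.
    """
    if truth.empty:
        raise ValueError("planted truth is empty; nothing to score")
    rows = []
    traits_with_truth = sorted(
        {t for assoc in truth.associations.values() for t, _ in assoc}
    )
    for trait in traits_with_truth:
        if trait not in catalog.traits():
            continue
        for sign in ("positive", "negative"):
            planted = truth.genes_for(trait, sign)
            if not planted:
                continue
            if not planted <= catalog.universe:
                raise ValueError(
                    f"planted genes for {trait!r} missing from catalog universe"
                )
            gs = catalog.get(trait, sign, stringency)
            recovered = len(planted & gs.genes)
            rows.append(
                {
                    "trait": trait,
                    "sign": sign,
                    "stringency": stringency,
                    "n_planted": len(planted),
                    "n_selected": len(gs.genes),
                    "recovered": recovered,
                    "recall": recovered / len(planted),
                    "precision": (
                        recovered / len(gs.genes) if gs.genes else np.nan
                    ),
                    "fdp": (
                        (len(gs.genes) - recovered) / len(gs.genes)
                        if gs.genes
                        else np.nan
                    ),
                    "threshold": gs.threshold,
                }
            )
    return pd.DataFrame(rows)


def _catalog_from_spec(
    spec: PopulationSpec, n_perm: int, perm_seed: int, min_lines: int = 60
):
    traits = simulate_traits(spec)
    counts, _annotation, truth = simulate_counts(spec, traits)
    expr = normalize_transform(counts, size_factors(counts))
    pcc = transcript_trait_pcc(expr, traits, min_lines=min_lines)
    observed = tail_quantiles(pcc)
    permuted = permutation_thresholds(
        expr, traits, n_perm=n_perm, seed=perm_seed, min_lines=min_lines
    )
    return select_sets(pcc, observed, permuted), truth


def null_calibration(
    spec: PopulationSpec,
    n_reps: int = 3,
    seeds: list[int] | None = None,
    n_perm: int = 200,
) -> pd.DataFrame:
    """Fraction of genes entering q_random sets on signal-free replicates.

    By construction of the chance reference (mean permuted 1 % tail
    quantiles), ~2 % of genes per trait (both tails combined) should be
    selected when no signal is planted.  Returns one row per replicate
    and trait with the observed fraction and its binomial Monte-Carlo SE.
    """
    if n_reps < 3 and (seeds is None or len(seeds) < 3):
        raise ValueError("need at least 3 replicates")
    if spec.planted:
        raise ValueError("null_calibration requires a spec without planted signal")
    seeds = seeds if seeds is not None else list(range(n_reps))
    rows = []
    for rep_seed in seeds:
        rep_spec = replace(spec, seed=rep_seed)
        catalog, _truth = _catalog_from_spec(rep_spec, n_perm, perm_seed=rep_seed)
        G = len(catalog.universe)
        for trait in catalog.traits():
            pos = len(catalog.get(trait, "positive", "q_random").genes)
            neg = len(catalog.get(trait, "negative", "q_random").genes)
            frac = (pos + neg) / G
            rows.append(
                {
                    "seed": rep_seed,
                    "trait": trait,
                    "n_genes": G,
                    "n_selected": pos + neg,
                    "fraction": frac,
                    "expected": 0.02,
                    "mc_se": float(np.sqrt(0.02 * 0.98 / G)),
                }
            )
    return pd.DataFrame(rows)
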