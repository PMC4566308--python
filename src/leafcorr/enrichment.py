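"""Functional-category enrichment with optional transcript-length bias correction.

Over-representation of MapMan-bin-style categories in a selected gene
set against the filtered background, either with the central
hypergeometric test or — when selection probability depends on
transcript length, as is typical for count-based selections — with the
Wallenius noncentral hypergeometric distribution using odds derived
from a monotone length-bias weight function.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression


def enrich_hypergeom(
    gene_set: set[str],
    background: set[str],
    categories: dict[str, set[str]],
    min_cat: int = 5,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per category.

    P(X >= k) with X ~ Hypergeom(N = |background|, K = |category in
    background|, n = |gene_set|); categories with K < min_cat are
    skipped; p-values are deliberately uncorrected.
    """
    offenders = gene_set - background
    if offenders:
        raise ValueError(
            f"gene set not a subset of background: {sorted(offenders)[:10]}"
        )
    N, n = len(background), len(gene_set)
    rows = []
    for cat in sorted(categories):
        members = categories[cat] & background
        K = len(members)
        if K < min_cat:
            continue
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "category": cat,
                "set_count": k,
                "background_count": K,
                "expected": n * K / N,
                "p_value": p,
                "method": "hypergeom",
                "enriched": p < alpha,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "category", "set_count", "background_count", "expected",
            "p_value", "method", "enriched",
        ],
    ).set_index("category")


def bias_weights(
    lengths: pd.Series, selected: set[str], n_bins: int = 20
) -> pd.Series:
    """Monotone per-gene selection-probability weights from transcript length.

    Genes are split into equal-count length bins; the selected fraction
    per bin is smoothed by isotonic regression (non-decreasing in
    length) and assigned to member genes, then normalized to mean 1.
    With selection independent of length all weights are ~1.
    """
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    n_bins = min(n_bins, len(lengths))
    if n_bins < 1:
        raise ValueError("empty background")
    ranks = lengths.rank(method="first")
    bins = pd.qcut(ranks, n_bins, labels=False)
    sel = lengths.index.isin(list(selected)).astype(float)
    df = pd.DataFrame({"bin": bins, "sel": sel, "len": lengths})
    per_bin = df.groupby("bin").agg(
        frac=("sel", "mean"), center=("len", "median"), n=("sel", "size")
    )
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    smoothed = iso.fit_transform(
        per_bin["center"], per_bin["frac"], sample_weight=per_bin["n"]
    )
    if smoothed.max() == 0:
        return pd.Series(1.0, index=lengths.index, name="weight")
    # pseudocount floor (half a selection per bin): selection odds must stay
    # positive for the Wallenius model even in bins with no selections
    floor = 0.5 / (per_bin["n"].mean() + 1.0)
    per_bin["w"] = np.maximum(smoothed, floor)
    w = per_bin["w"].reindex(bins).to_numpy()
    w = pd.Series(w, index=lengths.index, name="weight")
    return w / w.mean()


def enrich_wallenius(
    gene_set: set[str],
    background: set[str],
    categories: dict[str, set[str]],
    weights: pd.Series,
    min_cat: int = 5,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Length-bias-aware over-representation via the Wallenius distribution.

    A category's odds ratio is the mean bias weight inside it divided by
    the mean weight outside; the p-value is the upper tail of the
    Wallenius noncentral hypergeometric with those odds.  With uniform
    weights the odds are 1 and the test reduces exactly to
    :func:`enrich_hypergeom`.
    """
    offenders = gene_set - background
    if offenders:
        raise ValueError(
            f"gene set not a subset of background: {sorted(offenders)[:10]}"
        )
    w = weights.reindex(sorted(background))
    if w.isna().any() or (w <= 0).any():
        raise ValueError("weights must be positive for every background gene")
    N, n = len(background), len(gene_set)
    rows = []
    for cat in sorted(categories):
        members = categories[cat] & background
        K = len(members)
        if K < min_cat:
            continue
        k = len(members & gene_set)
        inside = w.loc[sorted(members)].mean()
        outside_idx = sorted(background - members)
        outside = w.loc[outside_idx].mean() if outside_idx else 1.0
        odds = float(inside / outside)
        if abs(odds - 1.0) < 1e-12:
            # exact reduction to the central test
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            p = float(stats.nchypergeom_wallenius.sf(k - 1, N, K, n, odds))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        rows.append(
            {
                "category": cat,
                "set_count": k,
                "background_count": K,
                "expected": n * K / N,
                "odds": odds,
                "p_value": p,
                "method": "wallenius",
                "enriched": p < alpha,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "category", "set_count", "background_count", "expected",
            "odds", "p_value", "method", "enriched",
        ],
    ).set_index("category")
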