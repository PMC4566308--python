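"""Intersections, multiplicity and trait-group cross-tabulation of gene sets."""

from __future__ import annotations

from itertools import combinations

import pandas as pd

from .types import GeneSetCatalog


def venn_counts(sets: dict[str, set[str]]) -> dict[frozenset[str], int]:
    """Exact exclusive region counts of the inclusion lattice of 2-6 sets.

    Keys are the frozenset of set names a region belongs to; values are
    the number of elements exactly in those sets and no others.  Region
    counts sum to the union cardinality.
    """
    if not 2 <= len(sets) <= 6:
        raise ValueError("venn_counts supports 2 to 6 sets")
    names = list(sets)
    regions: dict[frozenset[str], int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names if n not in combo), set())
            regions[frozenset(combo)] = len(inside - outside)
    return regions


def multiplicity_profile(
    catalog: GeneSetCatalog, stringency: str = "top1pct"
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene trait multiplicity and sign pattern across the catalog.

    Returns (per-gene table, per-k histogram).  A gene is *discordant*
    when it sits in the positive set of at least one trait and the
    negative set of at least one other.
    """
    per_gene: dict[str, dict] = {}
    for trait in catalog.traits():
        for sign in ("positive", "negative"):
            gs = catalog.get(trait, sign, stringency)
            for g in gs.genes:
                rec = per_gene.setdefault(g, {"pos": set(), "neg": set()})
                rec["pos" if sign == "positive" else "neg"].add(trait)
    rows = []
    for g, rec in sorted(per_gene.items()):
        traits = rec["pos"] | rec["neg"]
        rows.append(
            {
                "gene": g,
                "n_traits": len(traits),
                "n_positive": len(rec["pos"]),
                "n_negative": len(rec["neg"]),
                "discordant": bool(rec["pos"] and rec["neg"]),
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene", "n_traits", "n_positive", "n_negative", "discordant"]
    ).set_index("gene")
    hist = (
        table["n_traits"].value_counts().sort_index()
        if len(table)
        else pd.Series(dtype=int)
    )
    hist.name = "n_genes"
    return table, hist


def group_crosstab(
    catalog: GeneSetCatalog,
    trait_groups: dict[str, str],
    stringency: str = "top1pct",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared-gene counts per trait pair and sign combination.

    ``trait_groups`` maps trait -> group name.  Returns (pairwise table,
    aggregate).  The pairwise table has one row per unordered trait pair
    and sign combination (pos-pos, neg-neg, pos-neg, neg-pos) with the
    shared gene count; the aggregate sums shared counts within-group vs
    between-group, plus the opposite-sign total, at both the pair level
    (sum over pairs) and the gene level (distinct genes).
    """
    traits = catalog.traits()
    unassigned = [t for t in traits if t not in trait_groups]
    if unassigned:
        raise ValueError(f"traits without a group: {unassigned}")
    rows = []
    agg_genes: dict[tuple[str, str], set[str]] = {}
    for a, b in combinations(traits, 2):
        scope = "within" if trait_groups[a] == trait_groups[b] else "between"
        for sa, sb in (
            ("positive", "positive"),
            ("negative", "negative"),
            ("positive", "negative"),
            ("negative", "positive"),
        ):
            shared = (
                catalog.get(a, sa, stringency).genes
                & catalog.get(b, sb, stringency).genes
            )
            concordance = "same_sign" if sa == sb else "opposite_sign"
            rows.append(
                {
                    "trait_a": a,
                    "trait_b": b,
                    "sign_a": sa,
                    "sign_b": sb,
                    "scope": scope,
                    "concordance": concordance,
                    "shared": len(shared),
                }
            )
            agg_genes.setdefault((scope, concordance), set()).update(shared)
    pairwise = pd.DataFrame(rows)
    agg_rows = []
    for (scope, concordance), genes in sorted(agg_genes.items()):
        pair_total = int(
            pairwise.query("scope == @scope and concordance == @concordance")[
                "shared"
            ].sum()
        )
        agg_rows.append(
            {
                "scope": scope,
                "concordance": concordance,
                "pair_level_total": pair_total,
                "gene_level_total": len(genes),
            }
        )
    aggregate = pd.DataFrame(
        agg_rows,
        columns=["scope", "concordance", "pair_level_total", "gene_level_total"],
    ).set_index(["scope", "concordance"])
    return pairwise, aggregate
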