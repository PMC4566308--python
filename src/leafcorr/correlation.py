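"""Transcript-trait correlation with a permutation-derived chance threshold.

For every transcript and trait, the Pearson correlation r_gt is computed
over the common RIL + parent samples.  Two families of per-trait
thresholds follow:

* observed tail quantiles q_0.01 / q_0.99 of the gene-wise PCC
  distribution, defining the "top 1 %" (anti-)correlating sets; and
* the chance reference: the trait vector is permuted (1000 times by
  default), the same two quantiles are recomputed each time, and their
  means over permutations become the thresholds for the "better than
  random" (q_random) sets.

Quantiles use linear interpolation (R/numpy type-7).  Each trait gets an
independent permutation stream seeded from the master seed plus the
trait's position, so adding a trait never perturbs another's thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, GeneSet, GeneSetCatalog, TraitTable


@dataclass
class TranscriptTraitPCC:
    """Gene x trait PCC matrix plus the sample count used per trait."""

    r: pd.DataFrame  # genes x traits; NaN for constant genes
    n_samples: pd.Series  # trait -> number of samples used
    excluded_traits: list[str] = field(default_factory=list)


@dataclass
class QuantileThresholds:
    """Observed and permuted-chance tail quantiles per trait."""

    observed: pd.DataFrame  # traits x [q_low, q_high]
    permuted: pd.DataFrame | None = None  # traits x [q_low, q_high, sd_low, sd_high]
    q_low: float = 0.01
    q_high: float = 0.99
    n_perm: int = 0
    seed: int | None = None


def analytic_null_quantile(q: float, n: int) -> float:
    """Null quantile of the sample PCC for n iid Gaussian pairs.

    From the exact t relation t = r sqrt(n-2)/sqrt(1-r^2):
    r_q = t_q / sqrt(t_q^2 + n - 2) with df = n - 2.
    """
    t = stats.t.ppf(q, df=n - 2)
    return float(t / np.sqrt(t**2 + (n - 2)))


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row z-scores (ddof=1); returns (Z, constant-row mask)."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    const = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd[const] = 1.0
    return (X - mu) / sd, const


def _common_samples(expr: ExpressionMatrix, traits: TraitTable) -> list[str]:
    common = [s for s in expr.values.columns if s in traits.values.index]
    if not common:
        raise ValueError("expression samples and trait lines do not overlap")
    return common


def transcript_trait_pcc(
    expr: ExpressionMatrix, traits: TraitTable, min_lines: int = 60
) -> TranscriptTraitPCC:
    """Per-gene Pearson correlation with every sufficiently observed trait.

    Traits with fewer than ``min_lines`` non-missing common samples are
    excluded (this is how partially phenotyped traits such as leaf number
    and V-stage, measured on 42 lines only, drop out).  Constant genes
    yield NaN.
    """
    common = _common_samples(expr, traits)
    X = expr.values[common].to_numpy(dtype=float)
    Zx_full, const_full = _standardize_rows(X)
    out = {}
    ns = {}
    excluded = []
    for trait in traits.trait_names:
        tv = traits.values.loc[common, trait].to_numpy(dtype=float)
        mask = np.isfinite(tv)
        if int(mask.sum()) < min_lines:
            excluded.append(trait)
            continue
        if mask.all():
            zx, const = Zx_full, const_full
        else:
            zx, const = _standardize_rows(X[:, mask])
        t = tv[mask]
        sd = t.std(ddof=1)
        if sd == 0:
            raise ValueError(f"trait {trait!r} is constant")
        zt = (t - t.mean()) / sd
        r = zx @ zt / (mask.sum() - 1)
        r[const] = np.nan
        out[trait] = r
        ns[trait] = int(mask.sum())
    if not out:
        raise ValueError(
            f"no trait has at least min_lines={min_lines} phenotyped samples"
        )
    rdf = pd.DataFrame(out, index=expr.values.index)
    return TranscriptTraitPCC(rdf, pd.Series(ns), excluded)


def tail_quantiles(
    pcc: TranscriptTraitPCC, q_low: float = 0.01, q_high: float = 0.99
) -> QuantileThresholds:
    """Observed type-7 tail quantiles of each trait's gene-wise PCC values."""
    rows = {}
    for trait in pcc.r.columns:
        vals = pcc.r[trait].dropna().to_numpy()
        if len(vals) == 0:
            raise ValueError(f"no finite PCC values for trait {trait!r}")
        ql, qh = np.quantile(vals, [q_low, q_high])  # linear interpolation
        rows[trait] = {"q_low": ql, "q_high": qh}
    return QuantileThresholds(
        pd.DataFrame(rows).T, q_low=q_low, q_high=q_high
    )


def permutation_thresholds(
    expr: ExpressionMatrix,
    traits: TraitTable,
    n_perm: int = 1000,
    seed: int = 0,
    q_low: float = 0.01,
    q_high: float = 0.99,
    min_lines: int = 60,
) -> QuantileThresholds:
    """Chance reference: mean tail quantiles under trait permutation.

    For each trait and permutation, one shuffled trait vector is shared
    by all genes; the q_low/q_high quantiles of the resulting gene-wise
    PCC distribution are recorded, and their means (and Monte-Carlo SDs)
    over permutations returned.
    """
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    common = _common_samples(expr, traits)
    X = expr.values[common].to_numpy(dtype=float)
    rows = {}
    for t_idx, trait in enumerate(traits.trait_names):
        tv = traits.values.loc[common, trait].to_numpy(dtype=float)
        mask = np.isfinite(tv)
        if int(mask.sum()) < min_lines:
            continue
        t = tv[mask]
        sd = t.std(ddof=1)
        if sd == 0:
            raise ValueError(f"trait {trait!r} is constant; permutation undefined")
        zt = (t - t.mean()) / sd
        Zx, const = _standardize_rows(X[:, mask])
        Zx = Zx[~const]
        n = len(t)
        rng = np.random.default_rng(np.random.SeedSequence([seed, t_idx]))
        P = np.empty((n, n_perm))
        for j in range(n_perm):
            P[:, j] = zt[rng.permutation(n)]
        R = Zx @ P / (n - 1)  # genes x permutations
        ql = np.quantile(R, q_low, axis=0)
        qh = np.quantile(R, q_high, axis=0)
        rows[trait] = {
            "q_low": ql.mean(),
            "q_high": qh.mean(),
            "sd_low": ql.std(ddof=1),
            "sd_high": qh.std(ddof=1),
        }
    if not rows:
        raise ValueError(
            f"no trait has at least min_lines={min_lines} phenotyped samples"
        )
    perm = pd.DataFrame(rows).T
    return QuantileThresholds(
        observed=perm[["q_low", "q_high"]],
        permuted=perm,
        q_low=q_low,
        q_high=q_high,
        n_perm=n_perm,
        seed=seed,
    )


def select_sets(
    pcc: TranscriptTraitPCC,
    observed: QuantileThresholds,
    permuted: QuantileThresholds,
) -> GeneSetCatalog:
    """Build the per-trait, per-sign catalog at both stringencies.

    top1pct uses the observed tail quantiles, q_random the mean permuted
    quantiles; inequalities are strict at the threshold.
    """
    universe = frozenset(pcc.r.index)
    catalog = GeneSetCatalog(universe)
    for trait in pcc.r.columns:
        if trait not in observed.observed.index:
            raise ValueError(f"no observed thresholds for trait {trait!r}")
        if permuted.permuted is None or trait not in permuted.permuted.index:
            raise ValueError(f"no permuted thresholds for trait {trait!r}")
        r = pcc.r[trait]
        pairs = [
            ("top1pct", observed.observed.loc[trait]),
            ("q_random", permuted.permuted.loc[trait]),
        ]
        for stringency, row in pairs:
            pos = frozenset(r.index[r > row["q_high"]])
            neg = frozenset(r.index[r < row["q_low"]])
            catalog.add(GeneSet(trait, "positive", stringency, pos, float(row["q_high"])))
            catalog.add(GeneSet(trait, "negative", stringency, neg, float(row["q_low"])))
    return catalog


def correlation_count_table(
    catalog: GeneSetCatalog, stringency: str = "q_random"
) -> pd.DataFrame:
    """Per trait: total / % of universe / positive / negative set sizes."""
    G = len(catalog.universe)
    rows = []
    for trait in catalog.traits():
        pos = len(catalog.get(trait, "positive", stringency).genes)
        neg = len(catalog.get(trait, "negative", stringency).genes)
        rows.append(
            {
                "trait": trait,
                "total": pos + neg,
                "pct": int(round(100.0 * (pos + neg) / G)),
                "positive": pos,
                "negative": neg,
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def heatmap_matrix(
    expr: ExpressionMatrix,
    traits: TraitTable,
    trait: str,
    catalog: GeneSetCatalog,
    stringency: str = "top1pct",
    clip: float = 3.0,
) -> pd.DataFrame:
    """Viewer-ready matrix: phenotype-ordered columns, z-scored rows.

    Columns are the common phenotyped samples sorted by ascending trait
    value (samples without a trait measurement are omitted); rows
    are the positively correlated block on top of the anti-correlated
    block.  Each row is z-scored (mean 0, SD 1) then clipped to
    [-clip, clip]; zero-variance rows become all-zero rows.
    """
    common = _common_samples(expr, traits)
    tv = traits.values.loc[common, trait].dropna()
    if tv.empty:
        raise ValueError(f"trait {trait!r} has no phenotyped samples")
    order = tv.sort_values(kind="stable").index
    pos = sorted(catalog.get(trait, "positive", stringency).genes)
    neg = sorted(catalog.get(trait, "negative", stringency).genes)
    sub = expr.values.loc[pos + neg, order]
    vals = sub.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    zero = sd[:, 0] == 0
    sd[zero] = 1.0
    z = (vals - mu) / sd
    z[zero] = 0.0
    return pd.DataFrame(np.clip(z, -clip, clip), index=pos + neg, columns=order)
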