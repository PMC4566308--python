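"""Phenotype-table statistics: summaries, parental contrasts, PCC matrix, PCA."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import TraitTable


def percentage_difference(max_val: float, min_val: float) -> float:
    """Spread statistic (max - min) / max * 100."""
    if max_val == 0:
        raise ValueError("percentage difference undefined for max = 0")
    return (max_val - min_val) / max_val * 100.0


def trait_summary(traits: TraitTable) -> pd.DataFrame:
    """Per-trait mean, SD, max, min, n and percentage difference.

    The percentage difference is reported both at full precision and
    rounded to the nearest integer (the form in which it is usually
    printed).
    """
    rows = []
    for t in traits.trait_names:
        vals = traits.values[t].dropna()
        if len(vals) < 2:
            raise ValueError(f"trait {t!r} has fewer than 2 observations")
        pct = percentage_difference(vals.max(), vals.min())
        rows.append(
            {
                "trait": t,
                "unit": traits.traits[t].unit,
                "group": traits.traits[t].group,
                "n": int(len(vals)),
                "mean": vals.mean(),
                "sd": vals.std(ddof=1),
                "max": vals.max(),
                "min": vals.min(),
                "pct_diff": pct,
                "pct_diff_rounded": int(round(pct)),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def parental_contrast(replicates: dict[str, pd.DataFrame]) -> pd.Series:
    """Welch two-sample t-test per trait between two parents' replicates.

    ``replicates`` maps parent id to a replicate x trait table.  When
    both parents have zero within-group variance the test degenerates:
    p = 1 for equal means and p = 0 for different means (documented
    limiting behaviour).
    """
    if len(replicates) != 2:
        raise ValueError("parental contrast needs exactly 2 parents")
    (pa, ta), (pb, tb) = replicates.items()
    if len(ta) < 2 or len(tb) < 2:
        raise ValueError("each parent needs at least 2 replicates")
    common = [c for c in ta.columns if c in tb.columns]
    out = {}
    for trait in common:
        a, b = ta[trait].dropna(), tb[trait].dropna()
        if len(a) < 2 or len(b) < 2:  # unphenotyped parent: no contrast
            out[trait] = float("nan")
            continue
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            out[trait] = 1.0 if a.mean() == b.mean() else 0.0
            continue
        out[trait] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return pd.Series(out, name="p_value")


def trait_correlation_matrix(
    traits: TraitTable,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with t-based p-values.

    Returns (r, p, flags) where ``flags`` marks significance at 0.05 and
    0.01 ("*", "**", "") and constant traits appear as NaN.
    """
    names = traits.trait_names
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sub = traits.values[[a, b]].dropna()
            if len(sub) < 3:
                raise ValueError(
                    f"traits {a!r}/{b!r} have fewer than 3 complete pairs"
                )
            x, y = sub[a].to_numpy(), sub[b].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            rr = float(np.corrcoef(x, y)[0, 1])
            n = len(sub)
            if abs(rr) >= 1.0:
                pp = 0.0
            else:
                t = rr * np.sqrt(n - 2) / np.sqrt(1 - rr**2)
                pp = float(2 * stats.t.sf(abs(t), df=n - 2))
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    flags = p.map(lambda v: "" if pd.isna(v) else "**" if v < 0.01 else "*" if v < 0.05 else "")
    np.fill_diagonal(flags.values, "")
    return r, p, flags


def trait_pca(traits: TraitTable) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """PCA of the centered, unit-variance-scaled phenotype matrix.

    Rows with any missing value are dropped (complete-case).  Returns
    (scores, loadings, variance explained in %); loadings columns are
    orthonormal and variance explained sums to 100 %.
    """
    complete = traits.values.dropna()
    if len(complete) < 2:
        raise ValueError("PCA needs at least 2 complete-case rows")
    X = complete.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic orientation: largest-magnitude loading positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    ncomp = Vt.shape[0]
    comp = [f"PC{k + 1}" for k in range(ncomp)]
    scores = pd.DataFrame(U * S, index=complete.index, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=complete.columns, columns=comp)
    var = S**2
    var_explained = pd.Series(100.0 * var / var.sum(), index=comp, name="pct_variance")
    return scores, loadings, var_explained
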