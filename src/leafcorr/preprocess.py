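"""Count-matrix filtering, normalization and transformation.

The canonical order is: coverage filter (data-driven presence cutoff) ->
SNP conservation filter (keep genes with at most 1.75 % exonic SNPs) ->
median-of-ratios size factors -> asinh transform -> prevalence filter
(expressed in at least 5 % of samples) -> CV filter (drop the 5 % least
variable genes).  Every removal is recorded in the expression matrix's
provenance so the full filter history can be reconstructed.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .types import CountMatrix, ExpressionMatrix, GeneAnnotation

SNP_THRESHOLD_PCT = 1.75


def _libsize_normalized(counts: CountMatrix) -> pd.DataFrame:
    """Counts scaled to a common library size (total-count normalization).

    Used only inside the coverage filter, which runs before reliable
    median-of-ratios factors are available.
    """
    tot = counts.values.sum(axis=0).astype(float)
    if (tot == 0).any():
        raise ValueError("sample with zero total count")
    return counts.values / (tot / tot.mean())


def coverage_filter(
    counts: CountMatrix,
    groups: pd.Series | None = None,
    method: str = "jaccard",
    s_grid: np.ndarray | list | None = None,
    s_fixed: float | None = None,
) -> tuple[list[str], float]:
    """Presence cutoff: keep genes exceeding a threshold somewhere.

    ``method="fixed"`` keeps genes whose library-size-normalized count
    exceeds ``s_fixed`` in at least one sample.  ``method="jaccard"``
    chooses the cutoff from ``s_grid`` by maximizing the mean Jaccard
    similarity of the binarized (normalized count > s) presence vectors
    over within-group sample pairs (replicate agreement), then applies
    the fixed rule at that cutoff.  Returns (surviving gene ids, s used).
    """
    norm = _libsize_normalized(counts)
    if method == "fixed":
        if s_fixed is None:
            raise ValueError("method='fixed' requires s_fixed")
        s_star = float(s_fixed)
    elif method == "jaccard":
        if s_grid is None or len(list(s_grid)) == 0:
            raise ValueError("method='jaccard' requires a non-empty s_grid")
        if groups is None:
            groups = pd.Series("all", index=counts.samples)
        pairs = [
            (a, b)
            for _, members in groups.groupby(groups)
            for a, b in combinations(members.index, 2)
        ]
        if not pairs:
            raise ValueError("jaccard mode needs at least 2 samples in a group")
        best = None
        for s in sorted(float(x) for x in s_grid):
            B = norm > s
            sims = []
            for a, b in pairs:
                inter = int((B[a] & B[b]).sum())
                union = int((B[a] | B[b]).sum())
                sims.append(1.0 if union == 0 else inter / union)
            mean_sim = float(np.mean(sims))
            if best is None or mean_sim > best[0]:
                best = (mean_sim, s)
        s_star = best[1]
    else:
        raise ValueError(f"unknown coverage method {method!r}")
    keep_mask = (norm > s_star).any(axis=1)
    if not keep_mask.any():
        warnings.warn("coverage filter removed every gene", stacklevel=2)
    return list(counts.values.index[keep_mask]), s_star


def snp_filter(
    genes: list[str],
    annotation: GeneAnnotation,
    threshold_pct: float = SNP_THRESHOLD_PCT,
) -> list[str]:
    """Keep conserved genes: SNP percentage at most ``threshold_pct``.

    The boundary is inclusive ("no more than"): a gene at exactly the
    threshold survives.
    """
    missing = [g for g in genes if g not in annotation.table.index]
    if missing:
        raise ValueError(f"genes without annotation: {missing[:10]}")
    snp = annotation.table["snp_pct"]
    return [g for g in genes if snp[g] <= threshold_pct]


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios library-size factors.

    Per-gene geometric means are computed over genes with all-positive
    counts; each sample's factor is the median over those genes of
    count / geometric mean.
    """
    vals = counts.values.to_numpy(dtype=float)
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; apply "
            "coverage_filter first"
        )
    ref = vals[allpos]
    log_geomean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.samples, name="size_factor")


def normalize_transform(counts: CountMatrix, factors: pd.Series) -> ExpressionMatrix:
    """asinh(count / size factor); zero counts map exactly to zero."""
    factors = factors.reindex(counts.samples)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive for every sample")
    vals = np.arcsinh(counts.values.to_numpy(dtype=float) / factors.to_numpy())
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=counts.genes, columns=counts.samples),
        raw_nonzero_frac=(counts.values > 0).mean(axis=1),
    )
    expr.record("normalize_transform", [], n_samples=len(counts.samples))
    return expr


def prevalence_filter(expr: ExpressionMatrix, min_frac: float = 0.05) -> ExpressionMatrix:
    """Remove genes expressed (raw count > 0) in fewer than ``min_frac`` of samples.

    Strict semantics: a gene present in exactly 5 % of samples survives;
    strictly fewer is removed.
    """
    if expr.raw_nonzero_frac is None:
        raise ValueError(
            "expression matrix lacks raw presence information; build it "
            "with normalize_transform"
        )
    drop = expr.raw_nonzero_frac.index[expr.raw_nonzero_frac < min_frac]
    return expr.drop_genes(drop, "prevalence_filter", min_frac=min_frac)


def cv_filter(expr: ExpressionMatrix, drop_frac: float = 0.05) -> ExpressionMatrix:
    """Remove the ``drop_frac`` least-varying genes by coefficient of variation.

    CV = SD/mean on the transformed values.  Exactly
    ``floor(drop_frac * G)`` genes are removed; genes with zero mean
    (undefined CV) sort first and are logged, ties break by gene id.
    """
    if expr.values.shape[1] < 2:
        raise ValueError("cv_filter needs at least 2 samples")
    n_drop = int(np.floor(drop_frac * expr.values.shape[0]))
    if n_drop == 0:
        out = expr.drop_genes([], "cv_filter", drop_frac=drop_frac)
        return out
    mean = expr.values.mean(axis=1)
    sd = expr.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    undefined = mean == 0
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} zero-mean genes have undefined CV and are "
            "removed first",
            stacklevel=2,
        )
    order = pd.DataFrame(
        {"undef": ~undefined, "cv": cv.where(~undefined, -np.inf)},
        index=expr.values.index,
    ).sort_values(["undef", "cv"], kind="stable").index
    drop = list(order[:n_drop])
    return expr.drop_genes(drop, "cv_filter", drop_frac=drop_frac, n_removed=n_drop)


def preprocess_counts(
    counts: CountMatrix,
    annotation: GeneAnnotation,
    snp_threshold: float = SNP_THRESHOLD_PCT,
    prevalence_min_frac: float = 0.05,
    cv_drop_frac: float = 0.05,
    coverage_method: str = "fixed",
    coverage_groups: pd.Series | None = None,
    coverage_grid: list | None = None,
    coverage_s: float = 0.0,
) -> ExpressionMatrix:
    """Run the full filter/normalize/transform chain in canonical order."""
    kept, s_star = coverage_filter(
        counts,
        groups=coverage_groups,
        method=coverage_method,
        s_grid=coverage_grid,
        s_fixed=coverage_s,
    )
    removed_cov = sorted(set(counts.genes) - set(kept))
    kept = snp_filter(kept, annotation, snp_threshold)
    removed_snp = sorted(set(counts.genes) - set(removed_cov) - set(kept))
    sub = CountMatrix(counts.values.loc[kept], counts.roles)
    factors = size_factors(sub)
    expr = normalize_transform(sub, factors)
    expr.record("coverage_filter", removed_cov, method=coverage_method, s=s_star)
    expr.record("snp_filter", removed_snp, threshold_pct=snp_threshold)
    expr = prevalence_filter(expr, prevalence_min_frac)
    expr = cv_filter(expr, cv_drop_frac)
    return expr
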