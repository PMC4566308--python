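"""End-to-end orchestration: YAML config, staged run directory, manifest.

Stages run in the canonical order (preprocess -> phenotype stats ->
trait correlation -> set analysis -> network + MCL -> enrichment ->
evaluation when planted truth is present).  Each stage writes its
outputs under the run directory; a manifest records parameters and
SHA-256 checksums so identical config + seed reproduce identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as lio
from .correlation import (
    correlation_count_table,
    heatmap_matrix,
    permutation_thresholds,
    select_sets,
    tail_quantiles,
    transcript_trait_pcc,
)
from .enrichment import bias_weights, enrich_hypergeom, enrich_wallenius
from .evaluation import recovery_metrics
from .network import build_network, cluster_summary, mcl, write_edge_list
from .phenotypes import trait_correlation_matrix, trait_pca, trait_summary
from .setanalysis import group_crosstab, multiplicity_profile
from .types import GeneSetCatalog

log = logging.getLogger("leafcorr")


@dataclass
class RunConfig:
    """All inputs and stage parameters for one pipeline run."""

    counts: str
    traits: str
    annotation: str
    truth: str | None = None
    out_dir: str = "leafcorr_run"
    snp_threshold: float = 1.75
    prevalence_min_frac: float = 0.05
    cv_drop_frac: float = 0.05
    coverage_method: str = "fixed"
    coverage_s: float = 0.0
    coverage_grid: list[float] = field(default_factory=lambda: [0.0, 1.0, 5.0, 10.0])
    min_lines: int = 60
    n_perm: int = 1000
    network_threshold: float = 0.6
    inflation: float = 2.0
    min_cluster_size: int = 15
    enrichment_method: str = "wallenius"
    enrichment_alpha: float = 0.01
    min_cat: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.snp_threshold <= 100, "snp_threshold in [0, 100]"),
            (0 <= self.prevalence_min_frac <= 1, "prevalence_min_frac in [0, 1]"),
            (0 <= self.cv_drop_frac < 1, "cv_drop_frac in [0, 1)"),
            (self.n_perm >= 2, "n_perm >= 2"),
            (0 < self.network_threshold <= 1, "network_threshold in (0, 1]"),
            (self.inflation > 1, "inflation > 1"),
            (self.min_cluster_size >= 1, "min_cluster_size >= 1"),
            (0 < self.enrichment_alpha < 1, "enrichment_alpha in (0, 1)"),
            (self.min_cat >= 1, "min_cat >= 1"),
            (self.enrichment_method in ("wallenius", "hypergeom"), "enrichment_method"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: require {msg}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Missing inputs fail immediately naming the path; a stage failure
    halts with the stage name and cause, retaining earlier outputs.
    """
    for name in ("counts", "traits", "annotation"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise FileNotFoundError(f"{name} file does not exist: {p}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        traits = lio.read_traits(Path(config.traits))
        roles = traits.roles
        if str(config.counts).endswith(".mtx"):
            counts = lio.read_counts_mtx(Path(config.counts), roles=roles)
        else:
            counts = lio.read_counts_tsv(Path(config.counts), roles=roles)
        annotation = lio.read_annotation(Path(config.annotation))
        truth = lio.read_truth(Path(config.truth)) if config.truth else None

        stage = "preprocess"
        from .preprocess import preprocess_counts

        expr = preprocess_counts(
            counts,
            annotation,
            snp_threshold=config.snp_threshold,
            prevalence_min_frac=config.prevalence_min_frac,
            cv_drop_frac=config.cv_drop_frac,
            coverage_method=config.coverage_method,
            coverage_grid=config.coverage_grid,
            coverage_s=config.coverage_s,
        )
        lio.write_expression(expr, out / "expression.tsv")

        stage = "phenotype_stats"
        trait_summary(traits).to_csv(out / "trait_summary.tsv", sep="\t")
        r, p, flags = trait_correlation_matrix(traits)
        r.to_csv(out / "trait_pcc.tsv", sep="\t")
        p.to_csv(out / "trait_pcc_pvalues.tsv", sep="\t")
        flags.to_csv(out / "trait_pcc_flags.tsv", sep="\t")
        scores, loadings, varexp = trait_pca(traits)
        varexp.to_csv(out / "trait_pca_variance.tsv", sep="\t")
        loadings.to_csv(out / "trait_pca_loadings.tsv", sep="\t")

        stage = "trait_correlation"
        pcc = transcript_trait_pcc(expr, traits, min_lines=config.min_lines)
        pcc.r.to_csv(out / "transcript_trait_pcc.tsv", sep="\t", float_format="%.6g")
        observed = tail_quantiles(pcc)
        permuted = permutation_thresholds(
            expr, traits, n_perm=config.n_perm, seed=config.seed,
            min_lines=config.min_lines,
        )
        thr = observed.observed.join(
            permuted.permuted, lsuffix="_observed", rsuffix="_permuted"
        )
        thr.to_csv(out / "thresholds.tsv", sep="\t")
        catalog = select_sets(pcc, observed, permuted)
        sets_dir = out / "gene_sets"
        sets_dir.mkdir(exist_ok=True)
        for key, gs in sorted(catalog.sets.items()):
            name = "__".join(key)
            pd.Series(sorted(gs.genes), name="gene_id").to_csv(
                sets_dir / f"{name}.tsv", sep="\t", index=False
            )
        correlation_count_table(catalog, "q_random").to_csv(
            out / "count_table_q_random.tsv", sep="\t"
        )
        correlation_count_table(catalog, "top1pct").to_csv(
            out / "count_table_top1pct.tsv", sep="\t"
        )
        for trait in catalog.traits():
            hm = heatmap_matrix(expr, traits, trait, catalog)
            hm.to_csv(
                out / f"heatmap_{trait}.tsv", sep="\t", float_format="%.4g"
            )

        stage = "set_analysis"
        table, hist = multiplicity_profile(catalog, "top1pct")
        table.to_csv(out / "multiplicity.tsv", sep="\t")
        hist.to_csv(out / "multiplicity_hist.tsv", sep="\t")
        groups = {t: traits.group_of(t) for t in catalog.traits()}
        pairwise, aggregate = group_crosstab(catalog, groups, "top1pct")
        pairwise.to_csv(out / "crosstab_pairwise.tsv", sep="\t", index=False)
        aggregate.to_csv(out / "crosstab_aggregate.tsv", sep="\t")

        stage = "network"
        union = catalog.union("top1pct")
        clusters_df = pd.DataFrame(columns=["cluster", "size", "large", "genes"])
        if len(union) >= 2:
            net = build_network(expr, union, threshold=config.network_threshold)
            write_edge_list(net, out / "network_edges.tsv")
            assignment = mcl(net, inflation=config.inflation)
            assignment.labels.to_csv(out / "clusters.tsv", sep="\t")
            clusters_df = cluster_summary(assignment, config.min_cluster_size)
            clusters_df.drop(columns="genes").to_csv(
                out / "cluster_summary.tsv", sep="\t", index=False
            )

        stage = "enrichment"
        background = set(catalog.universe)
        categories = {
            c: g & background
            for c, g in annotation.category_map().items()
        }
        lengths = annotation.table.loc[sorted(background), "length_bp"]
        enr_frames = []
        targets = [("set", "__".join(k), gs.genes)
                   for k, gs in sorted(catalog.sets.items()) if k[2] == "top1pct"]
        targets += [
            ("cluster", f"cluster_{row.cluster}", set(row.genes))
            for row in clusters_df.itertuples()
            if row.large
        ]
        for kind, name, genes in targets:
            genes = set(genes) & background
            if not genes:
                continue
            if config.enrichment_method == "wallenius":
                w = bias_weights(lengths, genes)
                res = enrich_wallenius(
                    genes, background, categories, w,
                    min_cat=config.min_cat, alpha=config.enrichment_alpha,
                )
            else:
                res = enrich_hypergeom(
                    genes, background, categories,
                    min_cat=config.min_cat, alpha=config.enrichment_alpha,
                )
            res = res.reset_index()
            res.insert(0, "target", name)
            res.insert(0, "kind", kind)
            enr_frames.append(res)
        if enr_frames:
            pd.concat(enr_frames, ignore_index=True).to_csv(
                out / "enrichment.tsv", sep="\t", index=False
            )

        if truth is not None and not truth.empty:
            stage = "evaluation"
            recovery_metrics(catalog, truth, "q_random").to_csv(
                out / "recovery_q_random.tsv", sep="\t", index=False
            )
            recovery_metrics(catalog, truth, "top1pct").to_csv(
                out / "recovery_top1pct.tsv", sep="\t", index=False
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": {k: v for k, v in vars(config).items()},
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
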