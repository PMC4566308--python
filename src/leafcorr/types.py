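"""Shared in-memory containers for the pipeline.

Everything is a thin, validated wrapper over pandas objects so that each
stage has an explicit contract (gene/sample alignment, integrality,
provenance) while staying trivially interoperable with the scientific
Python stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID_GROUPS = ("leaf_size", "timing", "shoot")


@dataclass(frozen=True)
class TraitInfo:
    """Metadata for one trait: measurement unit and trait group."""

    unit: str
    group: str

    def __post_init__(self) -> None:
        if not self.unit:
            raise ValueError("trait unit must be non-empty")
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"trait group {self.group!r} not one of {VALID_GROUPS}"
            )


@dataclass
class TraitTable:
    """Line x trait phenotype matrix with per-trait metadata.

    ``values`` is indexed by line id (RILs and parents); ``roles`` flags
    each line as ``"RIL"`` or ``"parent"``.  Missing phenotypes are NaN.
    """

    values: pd.DataFrame
    traits: dict[str, TraitInfo]
    roles: pd.Series  # line id -> "RIL" | "parent"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate line ids in trait table")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate trait names in trait table")
        missing = set(self.values.columns) - set(self.traits)
        if missing:
            raise ValueError(f"traits without metadata: {sorted(missing)}")
        self.roles = self.roles.reindex(self.values.index)
        bad = self.roles[~self.roles.isin(["RIL", "parent"])]
        if len(bad):
            raise ValueError(f"invalid line roles for {list(bad.index[:5])}")

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    def group_of(self, trait: str) -> str:
        return self.traits[trait].group


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts."""

    values: pd.DataFrame  # genes x samples, integer dtype
    roles: pd.Series  # sample id -> "RIL" | "parent"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.values = self.values.astype(np.int64)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.roles = self.roles.reindex(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneAnnotation:
    """Per-gene transcript length (bp), SNP percentage and category labels."""

    table: pd.DataFrame  # index gene_id; columns length_bp, snp_pct, categories

    def __post_init__(self) -> None:
        required = {"length_bp", "snp_pct", "categories"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if (self.table["length_bp"] <= 0).any():
            raise ValueError("transcript lengths must be positive")
        snp = self.table["snp_pct"]
        if ((snp < 0) | (snp > 100)).any():
            raise ValueError("snp_pct must lie in [0, 100]")

    def categories_of(self, gene: str) -> list[str]:
        raw = self.table.loc[gene, "categories"]
        if isinstance(raw, str):
            return [c for c in raw.split("|") if c]
        return list(raw)

    def category_map(self) -> dict[str, set[str]]:
        """Invert the annotation into category -> gene-id set."""
        out: dict[str, set[str]] = {}
        for gene in self.table.index:
            for cat in self.categories_of(gene):
                out.setdefault(cat, set()).add(gene)
        return out


@dataclass
class ExpressionMatrix:
    """Normalized, asinh-transformed expression with filter provenance.

    ``raw_nonzero_frac`` records, per surviving gene, the fraction of
    samples with a nonzero raw count (the prevalence filter operates on
    raw-count presence, which is invariant to library-size scaling).
    """

    values: pd.DataFrame  # genes x samples, float
    provenance: list[dict] = field(default_factory=list)
    raw_nonzero_frac: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    def record(self, step: str, removed: Iterable[str], **params) -> None:
        self.provenance.append(
            {"step": step, "params": dict(params), "removed": sorted(removed)}
        )

    def drop_genes(self, genes: Iterable[str], step: str, **params) -> "ExpressionMatrix":
        genes = list(genes)
        out = ExpressionMatrix(
            self.values.drop(index=genes),
            provenance=list(self.provenance),
            raw_nonzero_frac=(
                None
                if self.raw_nonzero_frac is None
                else self.raw_nonzero_frac.drop(index=genes)
            ),
        )
        out.record(step, genes, **params)
        return out


@dataclass(frozen=True)
class GeneSet:
    """A selected gene set with the selection threshold that produced it."""

    trait: str
    sign: str  # "positive" | "negative"
    stringency: str  # "top1pct" | "q_random"
    genes: frozenset[str]
    threshold: float


@dataclass
class GeneSetCatalog:
    """All selected gene sets over a common gene universe."""

    universe: frozenset[str]
    sets: dict[tuple[str, str, str], GeneSet] = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        if not gs.genes <= self.universe:
            raise ValueError(
                f"gene set ({gs.trait},{gs.sign},{gs.stringency}) "
                "not a subset of the catalog universe"
            )
        self.sets[(gs.trait, gs.sign, gs.stringency)] = gs

    def get(self, trait: str, sign: str, stringency: str) -> GeneSet:
        return self.sets[(trait, sign, stringency)]

    def traits(self) -> list[str]:
        return sorted({k[0] for k in self.sets})

    def union(self, stringency: str, traits: Iterable[str] | None = None) -> set[str]:
        traits = set(traits) if traits is not None else None
        out: set[str] = set()
        for (trait, _sign, strg), gs in self.sets.items():
            if strg == stringency and (traits is None or trait in traits):
                out |= gs.genes
        return out


@dataclass
class PlantedTruth:
    """Ground truth of the generator: which gene was coupled to which trait."""

    associations: dict[str, list[tuple[str, float]]]  # gene -> [(trait, rho)]
    enriched_categories: dict[str, bool] = field(default_factory=dict)

    def genes_for(self, trait: str, sign: str | None = None) -> set[str]:
        out = set()
        for gene, assoc in self.associations.items():
            for t, rho in assoc:
                if t != trait:
                    continue
                if sign is None or (sign == "positive") == (rho > 0):
                    out.add(gene)
        return out

    @property
    def empty(self) -> bool:
        return not self.associations


@dataclass
class ClusterAssignment:
    """MCL output: a partition of network nodes into clusters."""

    labels: pd.Series  # node -> cluster id (int)
    converged: bool = True

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def singletons(self) -> list[str]:
        counts = self.labels.value_counts()
        single = counts[counts == 1].index
        return sorted(self.labels[self.labels.isin(single)].index)
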