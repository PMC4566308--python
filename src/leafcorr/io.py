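"""Readers and writers for the pipeline's plain-text interchange formats.

Counts travel as TSV (gene rows, sample columns) or MatrixMarket (MTX
plus two sidecar index files); traits, annotation and planted truth as
TSV with ``NA`` for missing; population specs as YAML.  Every writer
round-trips losslessly through its reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .simulate import PopulationSpec, simulate_counts, simulate_traits, spec_from_dict, spec_to_dict
from .types import CountMatrix, ExpressionMatrix, GeneAnnotation, PlantedTruth, TraitInfo, TraitTable


def _require_dir(path: Path) -> Path:
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path}")
    return path


# -- traits -----------------------------------------------------------------

def write_traits(traits: TraitTable, path: Path) -> None:
    df = traits.values.copy()
    df.insert(0, "role", traits.roles)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="line_id")
    meta = {
        t: {"unit": info.unit, "group": info.group}
        for t, info in traits.traits.items()
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_traits(path: Path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col="line_id", na_values=["NA"])
    roles = df.pop("role") if "role" in df.columns else pd.Series(
        "RIL", index=df.index
    )
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        traits = {t: TraitInfo(m["unit"], m["group"]) for t, m in meta.items()}
    else:  # fall back to the canonical grouping for known trait names
        from .datasets import TRAIT_REFERENCE

        traits = {}
        for t in df.columns:
            ref = TRAIT_REFERENCE.get(t)
            if ref is None:
                raise ValueError(
                    f"no metadata sidecar and unknown trait {t!r}; "
                    "write traits with write_traits()"
                )
            traits[t] = TraitInfo(ref.unit, ref.group)
    return TraitTable(df, traits, roles)


# -- counts -----------------------------------------------------------------

def write_counts_tsv(counts: CountMatrix, path: Path) -> None:
    counts.values.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: Path, roles: pd.Series | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if roles is None:
        roles = pd.Series("RIL", index=df.columns)
    return CountMatrix(df, roles)


def write_counts_mtx(counts: CountMatrix, path: Path) -> None:
    """MatrixMarket triplet plus ``<path>.rows`` / ``<path>.cols`` indices."""
    sp = scipy.sparse.csr_matrix(counts.values.to_numpy())
    scipy.io.mmwrite(str(path), sp, field="integer")
    Path(str(path) + ".rows").write_text("\n".join(counts.genes) + "\n")
    Path(str(path) + ".cols").write_text("\n".join(counts.samples) + "\n")


def read_counts_mtx(path: Path, roles: pd.Series | None = None) -> CountMatrix:
    mat = scipy.io.mmread(str(path)).toarray().astype(np.int64)
    genes = Path(str(path) + ".rows").read_text().splitlines()
    samples = Path(str(path) + ".cols").read_text().splitlines()
    df = pd.DataFrame(mat, index=genes, columns=samples)
    if roles is None:
        roles = pd.Series("RIL", index=df.columns)
    return CountMatrix(df, roles)


# -- annotation & truth -----------------------------------------------------

def write_annotation(annotation: GeneAnnotation, path: Path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path: Path) -> GeneAnnotation:
    return GeneAnnotation(pd.read_csv(path, sep="\t", index_col="gene_id"))


def write_truth(truth: PlantedTruth, path: Path) -> None:
    rows = [
        {"gene_id": g, "trait": t, "rho": rho}
        for g, assoc in sorted(truth.associations.items())
        for t, rho in assoc
    ]
    pd.DataFrame(rows, columns=["gene_id", "trait", "rho"]).to_csv(
        path, sep="\t", index=False
    )
    cats = Path(str(path) + ".categories.json")
    cats.write_text(json.dumps(truth.enriched_categories, indent=1))


def read_truth(path: Path) -> PlantedTruth:
    df = pd.read_csv(path, sep="\t")
    assoc: dict[str, list[tuple[str, float]]] = {}
    for row in df.itertuples(index=False):
        assoc.setdefault(row.gene_id, []).append((row.trait, float(row.rho)))
    cats_path = Path(str(path) + ".categories.json")
    cats = json.loads(cats_path.read_text()) if cats_path.exists() else {}
    return PlantedTruth(assoc, cats)


# -- expression -------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, path: Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
    Path(str(path) + ".provenance.json").write_text(
        json.dumps(expr.provenance, indent=1)
    )


def read_expression(path: Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    prov_path = Path(str(path) + ".provenance.json")
    prov = json.loads(prov_path.read_text()) if prov_path.exists() else []
    return ExpressionMatrix(df, provenance=prov)


# -- fixtures ---------------------------------------------------------------

def write_fixture(directory: Path, spec: PopulationSpec) -> dict[str, Path]:
    """Simulate a full dataset and write every artifact to ``directory``.

    Emits counts (TSV + MTX), traits (TSV + metadata), annotation, truth
    and the generating spec (YAML).  Identical spec and seed produce
    byte-identical files.
    """
    directory = _require_dir(directory)
    traits = simulate_traits(spec)
    counts, annotation, truth = simulate_counts(spec, traits)
    paths = {
        "traits": directory / "traits.tsv",
        "counts_tsv": directory / "counts.tsv",
        "counts_mtx": directory / "counts.mtx",
        "annotation": directory / "annotation.tsv",
        "truth": directory / "truth.tsv",
        "spec": directory / "spec.yaml",
    }
    try:
        write_traits(traits, paths["traits"])
        write_counts_tsv(counts, paths["counts_tsv"])
        write_counts_mtx(counts, paths["counts_mtx"])
        write_annotation(annotation, paths["annotation"])
        write_truth(truth, paths["truth"])
        paths["spec"].write_text(
            yaml.safe_dump(spec_to_dict(spec), sort_keys=True)
        )
    except OSError as exc:  # surface path and cause, per contract
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return paths


def read_spec(path: Path) -> PopulationSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))
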