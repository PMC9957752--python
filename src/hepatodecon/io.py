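"""Plain-text readers/writers, run configuration and the run manifest.

All formats are columnar text with headers: genes x libraries TSV (first
column gene id), a gene annotation TSV (gene_id, length_kb, biotype),
marker-set files (one gene per line, file name = cell type), a sample sheet
TSV (sample_id, stage, group) and MatrixMarket sparse matrices with
row/column name sidecars.  Missing values are disallowed (fail fast) and
gene identifiers are opaque case-sensitive strings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from . import __version__
from .containers import CohortMatrix, ExpressionLibrary
from .errors import FormatError
from .markers import MarkerSet


# ---------------------------------------------------------------------------
# expression tables

def read_expression_table(
    path, annotation_path, default_length_kb: Optional[float] = None
) -> List[ExpressionLibrary]:
    """Read a genes x libraries TSV plus its gene annotation.

    The annotation TSV must carry ``length_kb`` and ``biotype`` for every
    gene unless ``default_length_kb`` declares a fallback (fallback biotype
    is ``protein_coding``).  Duplicate gene ids or non-numeric cells are
    format errors naming the offender.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    gene_col = df.columns[0]
    genes = df[gene_col]
    dup = genes[genes.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate gene id {dup.iloc[0]!r} in {path}")
    df = df.set_index(gene_col)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise FormatError(f"non-numeric cell at gene {bad[0]!r}, column {col!r} in {path}")
        if df[col].isna().any():
            missing = df[col].index[df[col].isna()][0]
            raise FormatError(f"missing value at gene {missing!r}, column {col!r} in {path}")
        df[col] = coerced

    ann = pd.read_csv(annotation_path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    unannotated = df.index.difference(ann.index)
    if len(unannotated) and default_length_kb is None:
        raise FormatError(
            f"{len(unannotated)} genes lack annotation, e.g. {list(unannotated[:5])}"
        )
    length = ann["length_kb"].reindex(df.index)
    biotype = ann["biotype"].reindex(df.index)
    if default_length_kb is not None:
        length = length.fillna(default_length_kb)
        biotype = biotype.fillna("protein_coding")
    iso = ann["isoform_group"].reindex(df.index) if "isoform_group" in ann.columns else None
    return [
        ExpressionLibrary(
            library_id=col,
            counts=df[col],
            length_kb=length,
            biotype=biotype,
            isoform_group=iso,
        )
        for col in df.columns
    ]


def write_expression_table(libs: Sequence[ExpressionLibrary], path) -> None:
    table = pd.concat({lib.library_id: lib.counts for lib in libs}, axis=1)
    table.index.name = "gene_id"
    table.to_csv(path, sep="\t")


def write_annotation(lib_or_lengths, path, biotype: Optional[pd.Series] = None) -> None:
    """Write gene_id / length_kb / biotype TSV from a library or two Series."""
    if isinstance(lib_or_lengths, ExpressionLibrary):
        length, biotype = lib_or_lengths.length_kb, lib_or_lengths.biotype
    else:
        length = lib_or_lengths
    ann = pd.DataFrame({"length_kb": length, "biotype": biotype})
    ann.index.name = "gene_id"
    ann.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# marker sets

def write_marker_sets(markers: Dict[str, MarkerSet], out_dir) -> None:
    """One file per cell type, one gene id per line, file name = cell type."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for ct, ms in markers.items():
        (out_dir / f"{ct}.txt").write_text("\n".join(ms.genes) + "\n")


def read_marker_sets(dir_path) -> Dict[str, List[str]]:
    out: Dict[str, List[str]] = {}
    for f in sorted(Path(dir_path).glob("*.txt")):
        genes = [line.strip() for line in f.read_text().splitlines() if line.strip()]
        out[f.stem] = genes
    if not out:
        raise FormatError(f"no marker-set files (*.txt) in {dir_path}")
    return out


# ---------------------------------------------------------------------------
# sample sheets and cohort matrices

def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    return df


def read_cohort_matrix(matrix_path, sample_sheet_path) -> CohortMatrix:
    df = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    samples = read_sample_sheet(sample_sheet_path)
    return CohortMatrix(values=df, samples=samples.loc[df.columns])


def write_cohort_matrix(matrix: CohortMatrix, matrix_path, sample_sheet_path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t")
    write_sample_sheet(matrix.samples, sample_sheet_path)


# ---------------------------------------------------------------------------
# sparse matrices (MatrixMarket + name sidecars)

def read_sparse_matrix(mtx_path, rownames_path, colnames_path) -> CohortMatrix:
    """Read a MatrixMarket coordinate matrix with gene/sample name sidecars.

    Name files are one id per line; their lengths must match the MTX header
    dimensions.
    """
    mat = scipy.io.mmread(mtx_path)
    rows = [line.strip() for line in Path(rownames_path).read_text().splitlines() if line.strip()]
    cols = [line.strip() for line in Path(colnames_path).read_text().splitlines() if line.strip()]
    if mat.shape != (len(rows), len(cols)):
        raise FormatError(
            f"MTX dimensions {mat.shape} do not match name files ({len(rows)}, {len(cols)})"
        )
    dense = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
    values = pd.DataFrame(dense, index=pd.Index(rows, name="gene_id"),
                          columns=pd.Index(cols, name="sample_id"))
    samples = pd.DataFrame(index=values.columns)
    return CohortMatrix(values=values, samples=samples)


def write_sparse_matrix(matrix: CohortMatrix, mtx_path, rownames_path, colnames_path) -> None:
    sparse = scipy.sparse.coo_matrix(matrix.values.to_numpy())
    scipy.io.mmwrite(str(mtx_path), sparse)
    Path(rownames_path).write_text("\n".join(map(str, matrix.gene_ids)) + "\n")
    Path(colnames_path).write_text("\n".join(map(str, matrix.sample_ids)) + "\n")


# ---------------------------------------------------------------------------
# run configuration and manifest

@dataclass
class RunConfig:
    """Serializable run parameters; every seed is explicit."""

    inputs: Dict[str, str] = field(default_factory=dict)
    normalization_mode: str = "total"
    excluded_biotypes: List[str] = field(
        default_factory=lambda: ["rRNA", "Mt_rRNA", "Mt_tRNA", "miRNA", "snoRNA", "snRNA"]
    )
    min_own_fraction: float = 1e-5
    max_other_relative: float = 0.05
    min_markers: int = 5
    average: str = "mean"
    scoring_method: str = "zmean"
    train_fraction: float = 0.25
    seed: int = 0
    out_dir: str = "."

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, config: RunConfig, input_paths: Sequence[str]) -> Path:
    """Record everything needed to re-run bit-identically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {str(p): file_sha256(p) for p in input_paths if Path(p).exists()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
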