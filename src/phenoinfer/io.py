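"""Readers and writers for the formats the workflow touches.

Expression matrices travel as TSV (region ID column + one column per
sample) or MatrixMarket coordinate files with sidecar region/sample lists.
Phenotypes travel as TSV with one row per sample. Fitted predictors are
archived as a directory holding ``model.json`` (metadata, level order or
knots) plus ``coefficients.tsv``.

Expression TSV values are written with 10 significant digits; predictor
coefficients are written with 17 significant digits so that a deserialized
model reproduces predictions bit-identically.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .matrix import ExpressionMatrix
from .phenotypes import ColumnSchema, PhenotypeTable
from .regions import parse_region_id

ARCHIVE_FORMAT_VERSION = 1

EXPR_FLOAT_FMT = "%.10g"
COEF_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _infer_format(path) -> str:
    suffix = Path(path).suffix.lower()
    return "mtx" if suffix == ".mtx" else "tsv"


def read_expression(path, format: str | None = None, transformed: bool = False) -> ExpressionMatrix:
    """Read a regions x samples expression matrix.

    Parameters
    ----------
    path : path-like
        TSV (first column region IDs ``chrom:start-end``, header = sample
        IDs) or MatrixMarket ``.mtx`` with ``<path>.regions.txt`` and
        ``<path>.samples.txt`` sidecars.
    format : {"tsv", "mtx"}, optional
        Inferred from the extension when omitted.
    transformed : bool
        Whether the stored values are already log2(1 + coverage).
    """
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        regions = []
        for lineno, rid in enumerate(df.index, start=2):
            try:
                regions.append(parse_region_id(str(rid)))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        values = df.to_numpy(dtype=float)
        samples = [str(c) for c in df.columns]
    elif fmt == "mtx":
        mat = scipy.io.mmread(os.fspath(path))
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        regions = [parse_region_id(line) for line in _read_lines(f"{path}.regions.txt")]
        samples = _read_lines(f"{path}.samples.txt")
        if values.shape != (len(regions), len(samples)):
            raise ValueError(
                f"{path}: matrix shape {values.shape} does not match sidecars "
                f"({len(regions)} regions, {len(samples)} samples)"
            )
    else:
        raise ValueError(f"unknown expression format {fmt!r}")
    return ExpressionMatrix(regions, samples, values, transformed=transformed)


def write_expression(m: ExpressionMatrix, path, format: str | None = None) -> None:
    """Write an expression matrix as TSV or MatrixMarket (+ sidecars)."""
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("region_id\t" + "\t".join(m.samples) + "\n")
            for region, row in zip(m.regions, m.values):
                fh.write(
                    region.id + "\t" + "\t".join(EXPR_FLOAT_FMT % v for v in row) + "\n"
                )
    elif fmt == "mtx":
        coo = scipy.sparse.coo_matrix(m.values)
        scipy.io.mmwrite(os.fspath(path), coo, precision=10)
        _write_lines(f"{path}.regions.txt", m.region_ids)
        _write_lines(f"{path}.samples.txt", m.samples)
    else:
        raise ValueError(f"unknown expression format {fmt!r}")


def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_lines(path, lines) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(f"{line}\n")


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

def read_phenotypes(path, schema: dict[str, ColumnSchema]) -> PhenotypeTable:
    """Read a phenotype TSV (first column = sample ID) under ``schema``.

    Raw strings are canonicalized against each column's synonym map;
    non-meaningful and missing values are flagged, not dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: empty phenotype table")
    sample_col = df.columns[0]
    samples = df[sample_col].tolist()
    missing_cols = [c for c in schema if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: schema columns absent: {missing_cols}")
    return PhenotypeTable(samples, schema, df.drop(columns=[sample_col]))


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    out = pheno.raw.copy()
    out.insert(0, "sample_id", pheno.samples)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# predictor archives
# ---------------------------------------------------------------------------

def serialize_predictor(model, path) -> None:
    """Archive a fitted categorical or continuous model to directory ``path``.

    Layout: ``model.json`` (kind, phenotype, level order or knot
    specification, provenance) + ``coefficients.tsv``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    from .categorical import CategoricalModel
    from .continuous import ContinuousModel

    if isinstance(model, CategoricalModel):
        meta = {
            "format_version": ARCHIVE_FORMAT_VERSION,
            "kind": "categorical",
            "phenotype": model.phenotype,
            "levels": list(model.levels),
            "projection": "nnls",
            "tie_tol": model.tie_tol,
            "provenance": dict(model.provenance),
        }
        header = ["region_id"] + [f"beta_{lev}" for lev in model.levels]
        rows = [
            [region.id] + [COEF_FLOAT_FMT % v for v in coef_row]
            for region, coef_row in zip(model.regions, model.coef)
        ]
    elif isinstance(model, ContinuousModel):
        meta = {
            "format_version": ARCHIVE_FORMAT_VERSION,
            "kind": "continuous",
            "phenotype": model.phenotype,
            "n_basis": model.n_basis,
            "knots": {r.id: list(map(float, k)) for r, k in zip(model.regions, model.knots)},
            "pruned_columns": [int(i) for i in model.pruned_columns],
            "training_rmse": model.training_rmse,
            "training_r2": model.training_r2,
            "provenance": dict(model.provenance),
        }
        header = ["region_id"] + [f"s{j + 1}" for j in range(model.n_basis)]
        coefs = model.coef.reshape(len(model.regions), model.n_basis)
        rows = [
            [region.id] + [COEF_FLOAT_FMT % v for v in coef_row]
            for region, coef_row in zip(model.regions, coefs)
        ]
    else:
        raise TypeError(f"cannot serialize object of type {type(model).__name__}")

    with open(path / "model.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(path / "coefficients.tsv", "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def deserialize_predictor(path, expect_kind: str | None = None):
    """Load a predictor archive written by :func:`serialize_predictor`.

    Raises an explicit error on format-version mismatch, on a missing
    coefficient table, and when ``expect_kind`` disagrees with the archive.
    """
    path = Path(path)
    meta_path = path / "model.json"
    coef_path = path / "coefficients.tsv"
    if not meta_path.exists():
        raise FileNotFoundError(f"{path}: no model.json — not a predictor archive")
    with open(meta_path) as fh:
        meta = json.load(fh)
    version = meta.get("format_version")
    if version != ARCHIVE_FORMAT_VERSION:
        raise ValueError(
            f"archive format version {version!r} does not match supported "
            f"version {ARCHIVE_FORMAT_VERSION}"
        )
    if not coef_path.exists():
        raise FileNotFoundError(f"{path}: archive missing coefficients.tsv")
    kind = meta.get("kind")
    if expect_kind is not None and kind != expect_kind:
        raise ValueError(f"archive holds a {kind!r} model, expected {expect_kind!r}")
    table = pd.read_csv(coef_path, sep="\t", float_precision="round_trip")
    regions = [parse_region_id(rid) for rid in table["region_id"]]

    if kind == "categorical":
        from .categorical import CategoricalModel

        levels = list(meta["levels"])
        coef = table[[f"beta_{lev}" for lev in levels]].to_numpy(dtype=float)
        return CategoricalModel(
            phenotype=meta["phenotype"],
            levels=levels,
            regions=regions,
            coef=coef,
            tie_tol=float(meta.get("tie_tol", 1e-8)),
            provenance=dict(meta.get("provenance", {})),
        )
    if kind == "continuous":
        from .continuous import ContinuousModel

        n_basis = int(meta["n_basis"])
        knots = [np.asarray(meta["knots"][r.id], dtype=float) for r in regions]
        coef = table[[f"s{j + 1}" for j in range(n_basis)]].to_numpy(dtype=float).ravel()
        return ContinuousModel(
            phenotype=meta["phenotype"],
            regions=regions,
            n_basis=n_basis,
            knots=knots,
            coef=coef,
            pruned_columns=list(meta.get("pruned_columns", [])),
            training_rmse=meta.get("training_rmse"),
            training_r2=meta.get("training_r2"),
            provenance=dict(meta.get("provenance", {})),
        )
    raise ValueError(f"unknown model kind {kind!r} in archive")
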