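"""Reading, writing and assembling the pipeline's core objects.

Expression data live in an :class:`anndata.AnnData` (cells x genes) whose
``.obs`` carries the three per-cell labels the pipeline needs: ``sample_id``,
``condition`` and ``cell_type``.  Two on-disk layouts are supported: Matrix
Market triplets with sidecar ``genes.tsv``/``cells.tsv`` tables, and a dense
delimited matrix with the same sidecar metadata.  The ligand-target
regulatory-potential matrix is a delimited numeric table with targets as rows
and ligands as columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .exceptions import LoadError, SchemaError

OBS_COLUMNS = ("sample_id", "condition", "cell_type")


# ---------------------------------------------------------------------------
# expression


def validate_expression(expr: ad.AnnData) -> None:
    """Check the AnnData invariants the pipeline relies on.

    Raises :class:`SchemaError` on a missing/NaN label column and
    :class:`LoadError` on duplicated genes or negative / non-finite values.
    """
    for col in OBS_COLUMNS:
        if col not in expr.obs.columns:
            raise SchemaError(f"cell metadata is missing required column {col!r}")
        if expr.obs[col].isna().any():
            raise SchemaError(f"cell metadata column {col!r} contains missing values")
    if expr.var_names.duplicated().any():
        dupes = expr.var_names[expr.var_names.duplicated()].unique().tolist()[:5]
        raise LoadError(f"duplicated gene ids: {dupes}")
    x = expr.X
    data = x.data if sp.issparse(x) else np.asarray(x)
    if not np.all(np.isfinite(data)):
        raise LoadError("expression matrix contains non-finite values")
    if data.size and data.min() < 0:
        raise LoadError("expression matrix contains negative values")


def _read_table(path: Path, **kw) -> pd.DataFrame:
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, comment="#", **kw)


def load_expression(
    matrix_path: str | Path,
    genes_path: str | Path | None,
    cells_path: str | Path,
    rename_map: str | Path | dict | None = None,
) -> ad.AnnData:
    """Assemble an AnnData from a matrix file plus gene and cell tables.

    ``matrix_path`` may be Matrix Market coordinate format (cells x genes;
    ``genes_path`` required, one gene id per line) or a dense delimited table
    whose header row holds the gene ids (``genes_path`` then optional).  The
    cells table needs columns ``sample_id``, ``condition``, ``cell_type`` and
    optionally ``barcode`` (used as the cell index).  ``rename_map`` is an
    optional cell-type rename table (two columns: from, to) or dict, applied
    after loading — this is how cross-dataset cell-type vocabularies are
    harmonized before a merged analysis.
    """
    matrix_path, cells_path = Path(matrix_path), Path(cells_path)
    cells = _read_table(cells_path)
    for col in OBS_COLUMNS:
        if col not in cells.columns:
            raise SchemaError(
                f"cells table {cells_path.name} is missing required column {col!r}"
            )

    if matrix_path.suffix == ".mtx":
        if genes_path is None:
            raise LoadError("Matrix Market input requires a genes table")
        matrix = sp.csr_matrix(scipy.io.mmread(matrix_path))
        genes = pd.read_csv(genes_path, header=None, sep="\t", comment="#")[0].astype(str)
    else:
        dense = _read_table(matrix_path)
        genes = pd.Series(dense.columns.astype(str))
        matrix = dense.to_numpy(dtype=float)
        if genes_path is not None:
            listed = pd.read_csv(genes_path, header=None, sep="\t", comment="#")[0].astype(str)
            if list(listed) != list(genes):
                raise LoadError("genes table disagrees with dense matrix header")

    if matrix.shape[0] != len(cells):
        raise LoadError(
            f"cell axis mismatch: matrix has {matrix.shape[0]} rows but the "
            f"cells table has {len(cells)} records"
        )
    if matrix.shape[1] != len(genes):
        raise LoadError(
            f"gene axis mismatch: matrix has {matrix.shape[1]} columns but the "
            f"genes table has {len(genes)} entries"
        )

    obs = cells.copy()
    if "barcode" in obs.columns:
        obs.index = obs.pop("barcode").astype(str)
    else:
        obs.index = [f"cell{i}" for i in range(len(obs))]
    obs.index.name = None
    for col in OBS_COLUMNS:
        obs[col] = obs[col].astype(str)

    expr = ad.AnnData(X=matrix, obs=obs, var=pd.DataFrame(index=genes.tolist()))
    if rename_map is not None:
        expr = apply_rename_map(expr, rename_map)
    validate_expression(expr)
    return expr


def apply_rename_map(expr: ad.AnnData, rename_map: str | Path | dict) -> ad.AnnData:
    """Rename cell types according to a two-column (from, to) table or dict."""
    if not isinstance(rename_map, dict):
        table = pd.read_csv(rename_map, sep="\t", header=None, comment="#")
        rename_map = dict(zip(table[0].astype(str), table[1].astype(str)))
    expr = expr.copy()
    expr.obs["cell_type"] = (
        expr.obs["cell_type"].astype(str).map(lambda t: rename_map.get(t, t))
    )
    return expr


def write_expression(expr: ad.AnnData, outdir: str | Path, layout: str = "mtx") -> None:
    """Write the MTX+TSV (or dense CSV) layout that :func:`load_expression` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells = expr.obs[list(OBS_COLUMNS)].copy()
    cells.insert(0, "barcode", expr.obs_names)
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    if layout == "mtx":
        x = sp.coo_matrix(expr.X)
        scipy.io.mmwrite(str(outdir / "matrix.mtx"), x)
        pd.Series(expr.var_names).to_csv(
            outdir / "genes.tsv", sep="\t", index=False, header=False
        )
    elif layout == "dense":
        dense = np.asarray(expr.X.todense() if sp.issparse(expr.X) else expr.X)
        pd.DataFrame(dense, columns=expr.var_names).to_csv(
            outdir / "expression.csv", index=False
        )
    else:
        raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# ligand-target regulatory potential


@dataclass(frozen=True)
class LigandTargetMatrix:
    """Regulatory-potential prior: how strongly each ligand is expected to
    regulate each target gene. Rows are targets, columns ligands."""

    table: pd.DataFrame

    @property
    def ligands(self) -> list[str]:
        return list(self.table.columns)

    @property
    def targets(self) -> list[str]:
        return list(self.table.index)

    @property
    def potential(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    @classmethod
    def from_frame(cls, table: pd.DataFrame) -> "LigandTargetMatrix":
        if table.columns.duplicated().any():
            raise LoadError(
                f"duplicated ligand names: "
                f"{table.columns[table.columns.duplicated()].unique().tolist()}"
            )
        if table.index.duplicated().any():
            raise LoadError(
                f"duplicated target names: "
                f"{table.index[table.index.duplicated()].unique().tolist()}"
            )
        values = table.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise LoadError("ligand-target matrix contains non-finite values")
        dead = (values != 0).sum(axis=0) == 0
        if dead.any():
            dropped = table.columns[dead].tolist()
            warnings.warn(f"dropping all-zero ligand columns: {dropped}")
            table = table.loc[:, ~dead]
        return cls(table=table)


def load_ligand_target_matrix(path: str | Path) -> LigandTargetMatrix:
    """Read a delimited targets-by-ligands table; first column = target names."""
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dupes = pd.Index(header)[pd.Index(header).duplicated()].unique().tolist()
    if dupes:  # pandas would silently mangle duplicated header names
        raise LoadError(f"duplicated ligand names: {dupes}")
    raw = _read_table(path, index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise LoadError(
            f"non-numeric entry {raw.iat[r, c]!r} at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r} of {path.name}"
        )
    if numeric.isna().to_numpy().any():
        raise LoadError(f"missing entries in {path.name}")
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return LigandTargetMatrix.from_frame(numeric)


# ---------------------------------------------------------------------------
# cell-type fractions


@dataclass
class FractionTable:
    """Samples x cell-types composition fractions plus per-sample condition."""

    values: pd.DataFrame  # samples x cell_types, entries in [0, 1]
    conditions: pd.Series  # indexed like values.index

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)) or v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("fractions must be finite and within [0, 1]")
        if len(self.values) < 2:
            raise ValueError("a fraction table needs at least 2 samples")
        if not self.conditions.index.equals(self.values.index):
            raise ValueError("conditions index must match the sample axis")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, condition: str) -> "FractionTable":
        keep = self.conditions == condition
        return FractionTable(self.values.loc[keep], self.conditions.loc[keep])

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "condition", self.conditions)
        out.to_csv(path, sep="\t")


def compute_fractions(
    expr: ad.AnnData,
    min_cells: int = 100,
    expected_samples: list[str] | None = None,
) -> FractionTable:
    """Per-sample cell-type composition fractions.

    The denominator is the total number of annotated cells in the sample,
    counted *before* the ``min_cells`` filter, so dropping rare types does not
    inflate the retained types' fractions.  Cell types with fewer than
    ``min_cells`` cells pooled across all samples are dropped.
    ``expected_samples`` (if given) lists samples that must be present; an
    expected sample with zero cells raises.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    obs = expr.obs
    counts = (
        obs.groupby(["sample_id", "cell_type"], observed=True)
        .size()
        .unstack(fill_value=0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    if expected_samples is not None:
        missing = sorted(set(expected_samples) - set(counts.index))
        if missing:
            raise ValueError(f"samples with zero cells: {missing}")
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero cells: {empty}")
    retained = counts.columns[counts.sum(axis=0) >= min_cells]
    fractions = counts[retained].div(totals, axis=0)

    cond = obs.groupby("sample_id", observed=True)["condition"].agg("unique")
    multi = cond[cond.map(len) > 1]
    if len(multi):
        raise ValueError(f"samples with conflicting condition labels: {list(multi.index)}")
    conditions = cond.map(lambda u: u[0]).reindex(fractions.index).astype(str)
    conditions.name = "condition"
    return FractionTable(values=fractions, conditions=conditions)
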