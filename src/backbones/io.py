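"""Readers and writers for biadjacency matrices, constraint masks and attribute tables.

Supported biadjacency dialects:

``csv``
    Labeled dense CSV: header row carries artifact labels, first column
    carries agent labels, cells are 0/1.
``mtx``
    Matrix Market coordinate format (1-based indices, handled by scipy).
    MTX carries no labels; they are synthesized as ``A1..`` / ``B1..``.
``edgelist``
    Two-column TSV of (agent_label, artifact_label) pairs, one present edge
    per line.  Writers prepend ``#row``/``#col`` comment lines so isolated
    nodes and label order survive a round trip; readers fall back to
    first-appearance order for plain files without comments.

The constraint-mask dialect is the same labeled dense CSV with cell values
0 = FREE, 1 = REQUIRED, -1 = PROHIBITED.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core import FREE, PROHIBITED, REQUIRED, BipartiteGraph, ConstraintMask, FormatError

__all__ = [
    "read_biadjacency",
    "write_biadjacency",
    "read_mask",
    "write_mask",
    "read_child_attributes",
    "read_group_attributes",
]

_FORMATS = ("csv", "mtx", "edgelist")


def read_biadjacency(path: str | os.PathLike, format: str = "csv") -> BipartiteGraph:
    """Read a binary bipartite network from ``path`` in the named dialect."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    try:
        if format == "csv":
            df = pd.read_csv(path, index_col=0)
            return BipartiteGraph(
                df.to_numpy(), [str(x) for x in df.index], [str(x) for x in df.columns]
            )
        if format == "mtx":
            mat = scipy.io.mmread(path)
            if scipy.sparse.issparse(mat):
                mat = mat.toarray()
            return BipartiteGraph(np.asarray(mat))
        return _read_edgelist(path)
    except FormatError:
        raise
    except Exception as exc:  # surface parse errors with path context
        raise FormatError(f"cannot read {format} biadjacency from {path}: {exc}") from exc


def write_biadjacency(g: BipartiteGraph, path: str | os.PathLike, format: str = "csv") -> None:
    """Write ``g`` so that :func:`read_biadjacency` reproduces it exactly."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    try:
        if format == "csv":
            pd.DataFrame(g.B, index=g.row_labels, columns=g.col_labels).to_csv(path)
        elif format == "mtx":
            scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(g.B), field="integer")
        else:
            _write_edgelist(g, path)
    except OSError as exc:
        raise OSError(f"cannot write biadjacency to {path}: {exc}") from exc


def _write_edgelist(g: BipartiteGraph, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for lab in g.row_labels:
            fh.write(f"#row\t{lab}\n")
        for lab in g.col_labels:
            fh.write(f"#col\t{lab}\n")
        rows, cols = np.nonzero(g.B)
        for i, k in zip(rows, cols):
            fh.write(f"{g.row_labels[i]}\t{g.col_labels[k]}\n")


def _read_edgelist(path: str | os.PathLike) -> BipartiteGraph:
    row_labels: list[str] = []
    col_labels: list[str] = []
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if line.startswith("#"):
                if parts[0] == "#row":
                    row_labels.append(parts[1])
                elif parts[0] == "#col":
                    col_labels.append(parts[1])
                continue
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            edges.append((parts[0], parts[1]))
    # plain files: node order is first appearance
    if not row_labels:
        seen = set()
        for a, _ in edges:
            if a not in seen:
                seen.add(a)
                row_labels.append(a)
    if not col_labels:
        seen = set()
        for _, b in edges:
            if b not in seen:
                seen.add(b)
                col_labels.append(b)
    ridx = {lab: i for i, lab in enumerate(row_labels)}
    cidx = {lab: k for k, lab in enumerate(col_labels)}
    B = np.zeros((len(row_labels), len(col_labels)), dtype=np.int8)
    for a, b in edges:
        if a not in ridx or b not in cidx:
            raise FormatError(f"edge ({a!r}, {b!r}) references an undeclared node")
        B[ridx[a], cidx[b]] = 1
    return BipartiteGraph(B, row_labels, col_labels)


def read_mask(path: str | os.PathLike, g: BipartiteGraph | None = None) -> ConstraintMask:
    """Read a constraint mask (labeled dense CSV of {-1, 0, 1}).

    When ``g`` is given, labels and shape are checked against the graph.
    """
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy()
    if not np.isin(vals, (FREE, REQUIRED, PROHIBITED)).all():
        raise FormatError(f"mask {path} contains values outside {{-1, 0, 1}}")
    if g is not None:
        if [str(x) for x in df.index] != g.row_labels or [str(x) for x in df.columns] != g.col_labels:
            raise FormatError(f"mask {path} labels do not match the biadjacency matrix")
    return ConstraintMask(vals)


def write_mask(m: ConstraintMask, g: BipartiteGraph, path: str | os.PathLike) -> None:
    pd.DataFrame(m.M, index=g.row_labels, columns=g.col_labels).to_csv(path)


_CLASSROOMS = ("3yo", "4yo")
_SCHEDULES = ("AM", "PM", "FULL")
_SESSIONS = ("AM", "PM")


def read_child_attributes(path: str | os.PathLike) -> pd.DataFrame:
    """Read the per-child attribute table (child_id, classroom, schedule)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ("child_id", "classroom", "schedule"), path)
    if not df["classroom"].isin(_CLASSROOMS).all():
        raise FormatError(f"{path}: classroom must be one of {_CLASSROOMS}")
    if not df["schedule"].isin(_SCHEDULES).all():
        raise FormatError(f"{path}: schedule must be one of {_SCHEDULES}")
    return df


def read_group_attributes(path: str | os.PathLike) -> pd.DataFrame:
    """Read the per-group attribute table (group_id, classroom, session, focal_child_id)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ("group_id", "classroom", "session", "focal_child_id"), path)
    if not df["classroom"].isin(_CLASSROOMS).all():
        raise FormatError(f"{path}: classroom must be one of {_CLASSROOMS}")
    if not df["session"].isin(_SESSIONS).all():
        raise FormatError(f"{path}: session must be one of {_SESSIONS}")
    return df


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
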