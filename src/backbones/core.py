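"""Core data model for binary bipartite networks and edge-constraint masks.

A bipartite network connects *agents* (type-A nodes, rows) to *artifacts*
(type-B nodes, columns) and is stored as a binary biadjacency matrix ``B``
with ``B[i, k] = 1`` iff agent ``i`` is incident to artifact ``k``.  The
weighted unipartite projection ``P = B @ B.T`` counts, for every pair of
agents, the number of artifacts they share.

Some cells of ``B`` may be *constrained*: a REQUIRED cell is logically
necessary (it must be 1 in the observed data and in every null-model draw),
a PROHIBITED cell is logically impossible (it must be 0 everywhere).  The
:class:`ConstraintMask` records this per-cell classification and
:func:`validate_or_coerce_mask` enforces consistency between a mask and the
observed matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FREE",
    "REQUIRED",
    "PROHIBITED",
    "BipartiteGraph",
    "ConstraintMask",
    "WeightedProjection",
    "DegreeSequences",
    "FormatError",
    "ConstraintViolationError",
    "project",
    "degree_sequences",
    "validate_or_coerce_mask",
]

# Cell classifications; the integer values double as the mask CSV dialect.
FREE: int = 0
REQUIRED: int = 1
PROHIBITED: int = -1


class FormatError(ValueError):
    """Raised when an input file or matrix violates the binary bipartite contract."""


class ConstraintViolationError(ValueError):
    """Raised when observed cells contradict REQUIRED/PROHIBITED constraints.

    Carries ``violations``, a list of ``(i, k, kind)`` tuples with matrix
    indices of the offending cells.
    """

    def __init__(self, message: str, violations: list[tuple[int, int, str]]):
        super().__init__(message)
        self.violations = violations


def _check_unique(labels: list[str], mode: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise FormatError(f"duplicate {mode} label: {lab!r}")
        seen.add(lab)


@dataclass
class BipartiteGraph:
    """A binary bipartite network with labeled node modes.

    Parameters
    ----------
    B : ndarray of shape (nA, nB)
        Binary biadjacency matrix; entries strictly in {0, 1}.
    row_labels, col_labels : list of str, optional
        Agent / artifact identifiers.  Synthesized as ``A1..AnA`` /
        ``B1..BnB`` when omitted.  Must be unique within each mode.
    """

    B: np.ndarray
    row_labels: list[str] = field(default=None)  # type: ignore[assignment]
    col_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        B = np.asarray(self.B)
        if B.ndim != 2 or B.shape[0] < 1 or B.shape[1] < 1:
            raise FormatError(f"biadjacency matrix must be 2-d and non-empty, got shape {B.shape}")
        bad = ~np.isin(B, (0, 1))
        if bad.any():
            i, k = np.argwhere(bad)[0]
            raise FormatError(f"non-binary entry {B[i, k]!r} at cell ({i}, {k})")
        self.B = B.astype(np.int8)
        nA, nB = B.shape
        if self.row_labels is None:
            self.row_labels = [f"A{i + 1}" for i in range(nA)]
        if self.col_labels is None:
            self.col_labels = [f"B{k + 1}" for k in range(nB)]
        self.row_labels = [str(x) for x in self.row_labels]
        self.col_labels = [str(x) for x in self.col_labels]
        if len(self.row_labels) != nA or len(self.col_labels) != nB:
            raise FormatError("label lengths do not match matrix shape")
        _check_unique(self.row_labels, "row")
        _check_unique(self.col_labels, "column")

    @property
    def shape(self) -> tuple[int, int]:
        return self.B.shape

    @property
    def n_agents(self) -> int:
        return self.B.shape[0]

    @property
    def n_artifacts(self) -> int:
        return self.B.shape[1]

    @property
    def n_edges(self) -> int:
        return int(self.B.sum())

    def copy(self) -> "BipartiteGraph":
        return BipartiteGraph(self.B.copy(), list(self.row_labels), list(self.col_labels))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteGraph):
            return NotImplemented
        return (
            np.array_equal(self.B, other.B)
            and self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
        )


@dataclass
class ConstraintMask:
    """Per-cell classification {FREE, REQUIRED, PROHIBITED} aligned with a biadjacency matrix."""

    M: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.M)
        if M.ndim != 2:
            raise FormatError("constraint mask must be 2-d")
        if not np.isin(M, (FREE, REQUIRED, PROHIBITED)).all():
            raise FormatError("constraint mask entries must be in {-1, 0, 1}")
        self.M = M.astype(np.int8)

    @classmethod
    def all_free(cls, nA: int, nB: int) -> "ConstraintMask":
        return cls(np.zeros((nA, nB), dtype=np.int8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.M.shape

    @property
    def n_required(self) -> int:
        return int((self.M == REQUIRED).sum())

    @property
    def n_prohibited(self) -> int:
        return int((self.M == PROHIBITED).sum())

    def union(self, other: "ConstraintMask") -> "ConstraintMask":
        """Cell-wise union of two masks, REQUIRED taking precedence over PROHIBITED."""
        if self.shape != other.shape:
            raise FormatError("mask shapes differ")
        M = np.where(self.M == REQUIRED, REQUIRED, np.where(other.M == REQUIRED, REQUIRED, 0))
        proh = ((self.M == PROHIBITED) | (other.M == PROHIBITED)) & (M != REQUIRED)
        M = np.where(proh, PROHIBITED, M)
        return ConstraintMask(M.astype(np.int8))


@dataclass
class WeightedProjection:
    """Weighted co-membership matrix P = B Bᵀ; the diagonal holds agent degrees."""

    P: np.ndarray
    row_labels: list[str]

    def weight(self, i: int, j: int) -> int:
        return int(self.P[i, j])


@dataclass
class DegreeSequences:
    row_degrees: np.ndarray
    col_degrees: np.ndarray


def degree_sequences(g: BipartiteGraph) -> DegreeSequences:
    """Row (agent) and column (artifact) degree sequences of ``g``."""
    B = g.B
    return DegreeSequences(
        row_degrees=B.sum(axis=1).astype(np.int64),
        col_degrees=B.sum(axis=0).astype(np.int64),
    )


def project(g: BipartiteGraph) -> WeightedProjection:
    """Weighted unipartite projection ``P = B Bᵀ``.

    ``P[i, j]`` counts the artifacts shared by agents ``i`` and ``j``; the
    diagonal equals the agents' bipartite degrees.
    """
    B = g.B.astype(np.int64)
    return WeightedProjection(P=B @ B.T, row_labels=list(g.row_labels))


def validate_or_coerce_mask(
    g: BipartiteGraph,
    m: ConstraintMask,
    mode: str = "strict",
) -> tuple[BipartiteGraph, ConstraintMask, list[tuple[int, int, str]]]:
    """Check (or repair) consistency between observed cells and a constraint mask.

    In ``strict`` mode any PROHIBITED cell observed present or REQUIRED cell
    observed absent raises :class:`ConstraintViolationError`.  In ``coerce``
    mode present-but-prohibited cells are set to 0 (the constraint outranks
    the observation, e.g. an impossible recorded membership), each coercion
    is recorded in the returned report as ``(i, k, "prohibited_present")``;
    absent-but-required cells are never repaired silently and always raise.

    Returns
    -------
    (graph, mask, report)
        The (possibly modified copy of the) graph, the mask unchanged, and
        the list of coerced cells.
    """
    if mode not in ("strict", "coerce"):
        raise ValueError(f"mode must be 'strict' or 'coerce', got {mode!r}")
    if g.shape != m.shape:
        raise FormatError(f"graph shape {g.shape} != mask shape {m.shape}")
    B, M = g.B, m.M
    proh_present = np.argwhere((M == PROHIBITED) & (B == 1))
    req_absent = np.argwhere((M == REQUIRED) & (B == 0))
    if req_absent.size:
        viol = [(int(i), int(k), "required_absent") for i, k in req_absent]
        raise ConstraintViolationError(
            f"{len(viol)} REQUIRED cells are absent in the observed matrix "
            f"(first: {viol[0][:2]})",
            viol,
        )
    report = [(int(i), int(k), "prohibited_present") for i, k in proh_present]
    if not report:
        return g, m, []
    if mode == "strict":
        raise ConstraintViolationError(
            f"{len(report)} PROHIBITED cells are present in the observed matrix "
            f"(first: {report[0][:2]})",
            report,
        )
    g2 = g.copy()
    rows = proh_present[:, 0]
    cols = proh_present[:, 1]
    g2.B[rows, cols] = 0
    return g2, m, report
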