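"""Degree-matched Bernoulli null models for bipartite networks (SDSM / SDSM-EC).

The stochastic degree sequence model (SDSM) draws random bipartite networks
``B*`` whose cells are independent Bernoulli variables with probabilities
``q_ik`` chosen so that the *expected* row and column degree sequences of
``B*`` equal the observed ones.  We use the maximum-entropy solution — the
bipartite configuration model — in which ``q_ik = x_i y_k / (1 + x_i y_k)``
for positive row/column multipliers ``x_i``, ``y_k`` fitted to the margins.

The edge-constrained variant (SDSM-EC) additionally fixes REQUIRED cells at
``q = 1`` and PROHIBITED cells at ``q = 0`` in every draw.  The free cells
are then fitted to *adjusted* margins: each row must supply its observed
degree minus the number of REQUIRED cells it contains, and likewise for
columns.  With an all-FREE mask the two models coincide, so SDSM is the
zero-constraint special case of SDSM-EC and both run through the same code
path here.

Fitting uses a multiplicative fixed-point iteration on the multipliers
(x_i <- r_i / sum_k y_k / (1 + x_i y_k), and symmetrically for y), with
geometric damping engaged if the degree residual ever increases.  Rows or
columns whose adjusted margin is 0 (all free cells must be absent) or equal
to their free-cell count (all must be present) are resolved exactly before
iteration and removed from the problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    FREE,
    PROHIBITED,
    REQUIRED,
    BipartiteGraph,
    ConstraintMask,
    DegreeSequences,
    degree_sequences,
    validate_or_coerce_mask,
)

__all__ = [
    "ProbabilityMatrix",
    "InfeasibleMarginsError",
    "ConvergenceError",
    "fit_probabilities",
    "expected_degree_residual",
]

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 10_000


class InfeasibleMarginsError(ValueError):
    """The constrained degree-matching problem has no solution."""


class ConvergenceError(RuntimeError):
    """The multiplier iteration did not reach the residual tolerance."""


@dataclass
class ProbabilityMatrix:
    """Per-cell Bernoulli probabilities of a fitted null model."""

    Q: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    fit_meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.Q.shape

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one random biadjacency matrix ``B*`` from the null model."""
        return (rng.random(self.Q.shape) < self.Q).astype(np.int8)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.Q, index=self.row_labels, columns=self.col_labels).to_csv(path)


def fit_probabilities(
    g: BipartiteGraph,
    mask: ConstraintMask | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ProbabilityMatrix:
    """Fit the maximum-entropy degree-matched cell probabilities for ``g``.

    Parameters
    ----------
    g : BipartiteGraph
        Observed binary bipartite network.
    mask : ConstraintMask, optional
        Edge constraints; ``None`` means all cells FREE (plain SDSM).  The
        mask must be consistent with ``g`` (REQUIRED cells present,
        PROHIBITED cells absent) — coerce beforehand if necessary.
    tol : float
        Convergence bound on the maximum absolute degree residual.
    max_iter : int
        Iteration cap; exceeded -> :class:`ConvergenceError`.

    Returns
    -------
    ProbabilityMatrix
        ``Q`` with REQUIRED cells exactly 1, PROHIBITED cells exactly 0, and
        every expected row/column degree within ``tol`` of the observed one.
    """
    if mask is None:
        mask = ConstraintMask.all_free(*g.shape)
    validate_or_coerce_mask(g, mask, mode="strict")

    B = g.B
    M = mask.M
    free = M == FREE
    req = M == REQUIRED
    nA, nB = B.shape

    # Adjusted margins: free cells must supply degree minus required cells.
    r = B.sum(axis=1).astype(np.float64) - req.sum(axis=1)
    c = B.sum(axis=0).astype(np.float64) - req.sum(axis=0)
    free_work = free.copy()
    _check_feasible(r, c, free_work)

    Q = np.zeros((nA, nB), dtype=np.float64)
    Q[req] = 1.0

    r, c = _resolve_degenerate(Q, free_work, r, c)

    rows = r > 0  # rows still carrying mass over free cells
    cols = c > 0
    iterations = 0
    if rows.any() and cols.any():
        A = free_work[np.ix_(rows, cols)]
        rr = r[rows]
        cc = c[cols]
        x, y, iterations, residual = _fit_multipliers(A, rr, cc, tol, max_iter)
        Qsub = np.outer(x, y)
        Qsub = Qsub / (1.0 + Qsub)
        Qsub[~A] = 0.0
        block = Q[np.ix_(rows, cols)]
        block[A] = Qsub[A]
        Q[np.ix_(rows, cols)] = block
    else:
        residual = 0.0

    pm = ProbabilityMatrix(
        Q=Q,
        row_labels=list(g.row_labels),
        col_labels=list(g.col_labels),
        fit_meta={"iterations": iterations, "residual": float(residual), "tol": tol},
    )
    # Report the residual against the *original* margins (fixed cells included).
    final = expected_degree_residual(pm, degree_sequences(g))
    pm.fit_meta["residual"] = float(final)
    if final > max(tol, 1e-7):  # small slack: fixed-cell sums are exact
        raise ConvergenceError(
            f"degree residual {final:.3e} exceeds tolerance {tol:.1e} after {iterations} iterations"
        )
    return pm


def _check_feasible(r: np.ndarray, c: np.ndarray, free: np.ndarray) -> None:
    nfree_row = free.sum(axis=1)
    nfree_col = free.sum(axis=0)
    bad_r = np.where((r < 0) | (r > nfree_row))[0]
    if bad_r.size:
        i = int(bad_r[0])
        raise InfeasibleMarginsError(
            f"row {i}: adjusted degree {r[i]:.0f} outside [0, {nfree_row[i]}] free cells"
        )
    bad_c = np.where((c < 0) | (c > nfree_col))[0]
    if bad_c.size:
        k = int(bad_c[0])
        raise InfeasibleMarginsError(
            f"column {k}: adjusted degree {c[k]:.0f} outside [0, {nfree_col[k]}] free cells"
        )


def _resolve_degenerate(
    Q: np.ndarray, free: np.ndarray, r: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fix rows/columns whose margin forces all free cells to 0 or 1.

    Mutates ``Q`` and ``free`` in place; returns the reduced margins.
    Repeats until stable because fixing one mode can degenerate the other.
    """
    r = r.copy()
    c = c.copy()
    while True:
        changed = False
        nfree_row = free.sum(axis=1)
        for i in np.where((r == 0) & (nfree_row > 0))[0]:
            free[i, :] = False
            changed = True
        nfree_row = free.sum(axis=1)
        for i in np.where((r > 0) & (r == nfree_row))[0]:
            ks = np.where(free[i])[0]
            Q[i, ks] = 1.0
            c[ks] -= 1.0
            r[i] = 0.0
            free[i, ks] = False
            changed = True
        nfree_col = free.sum(axis=0)
        for k in np.where((c == 0) & (nfree_col > 0))[0]:
            free[:, k] = False
            changed = True
        nfree_col = free.sum(axis=0)
        for k in np.where((c > 0) & (c == nfree_col))[0]:
            is_ = np.where(free[:, k])[0]
            Q[is_, k] = 1.0
            r[is_] -= 1.0
            c[k] = 0.0
            free[is_, k] = False
            changed = True
        if not changed:
            return r, c


_FIXED_POINT_ITERS = 500


def _free_probs(A: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    Qf = np.outer(x, y)
    return np.where(A, Qf / (1.0 + Qf), 0.0)


def _residual(A, x, y, r, c) -> float:
    Qf = _free_probs(A, x, y)
    return max(np.abs(Qf.sum(axis=1) - r).max(), np.abs(Qf.sum(axis=0) - c).max())


def _fit_multipliers(
    A: np.ndarray, r: np.ndarray, c: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Solve for the row/column multipliers on the free cells ``A``.

    Phase 1 is the classic multiplicative fixed point
    ``x_i <- r_i / sum_k y_k / (1 + x_i y_k)`` (with geometric damping once
    the residual stops decreasing); near-degenerate margins can make it
    crawl, so phase 2 finishes with a damped Newton iteration on the
    log-multipliers, which is locally quadratic and insensitive to the
    conditioning that stalls the fixed point.
    """
    nfree = A.sum()
    rho = min(max(float(r.sum()) / nfree, 1e-9), 1 - 1e-9)
    x0 = np.sqrt(rho / (1.0 - rho))
    x = np.full(r.shape, x0)
    y = np.full(c.shape, x0)
    prev_res = np.inf
    damping = False
    fp_iters = min(_FIXED_POINT_ITERS, max_iter)
    res = np.inf
    for it in range(1, fp_iters + 1):
        denom = 1.0 + np.outer(x, y)
        s = np.where(A, y[None, :] / denom, 0.0).sum(axis=1)
        x_new = r / s
        x = np.sqrt(x * x_new) if damping else x_new
        denom = 1.0 + np.outer(x, y)
        s = np.where(A, x[:, None] / denom, 0.0).sum(axis=0)
        y_new = c / s
        y = np.sqrt(y * y_new) if damping else y_new
        res = _residual(A, x, y, r, c)
        if res <= tol:
            return x, y, it, res
        if res > prev_res * (1 + 1e-12):
            damping = True
        prev_res = res
    x, y, newton_iters, res = _newton_polish(A, x, y, r, c, tol, max_iter - fp_iters)
    total = fp_iters + newton_iters
    if res > tol:
        raise ConvergenceError(
            f"no convergence after {total} iterations; residual {res:.3e} > tol {tol:.1e}"
        )
    return x, y, total, res


def _newton_polish(
    A: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    r: np.ndarray,
    c: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Damped Newton on theta = log x, eta = log y with backtracking line search.

    The margin system is gauge-invariant under theta += t, eta -= t, so the
    Jacobian has a null direction; a tiny ridge keeps the solve stable.
    """
    theta = np.log(np.clip(x, 1e-300, None))
    eta = np.log(np.clip(y, 1e-300, None))
    nR, nC = theta.size, eta.size
    res = _residual(A, np.exp(theta), np.exp(eta), r, c)
    it = 0
    while res > tol and it < max_iter:
        it += 1
        Qf = _free_probs(A, np.exp(theta), np.exp(eta))
        f = np.concatenate([Qf.sum(axis=1) - r, Qf.sum(axis=0) - c])
        V = Qf * (1.0 - Qf)
        J = np.zeros((nR + nC, nR + nC))
        J[:nR, :nR] = np.diag(V.sum(axis=1))
        J[nR:, nR:] = np.diag(V.sum(axis=0))
        J[:nR, nR:] = V
        J[nR:, :nR] = V.T
        J[np.diag_indices_from(J)] += 1e-12
        try:
            step = np.linalg.solve(J, f)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, f, rcond=None)[0]
        step = np.clip(step, -50.0, 50.0)
        lam = 1.0
        for _ in range(40):
            th = np.clip(theta - lam * step[:nR], -700, 700)
            et = np.clip(eta - lam * step[nR:], -700, 700)
            new_res = _residual(A, np.exp(th), np.exp(et), r, c)
            if new_res < res:
                theta, eta, res = th, et, new_res
                break
            lam *= 0.5
        else:  # no improving step found
            break
    return np.exp(theta), np.exp(eta), it, res


def expected_degree_residual(q: ProbabilityMatrix, d: DegreeSequences) -> float:
    """Maximum absolute difference between expected and observed degrees."""
    Q = q.Q
    if Q.shape != (len(d.row_degrees), len(d.col_degrees)):
        raise ValueError("probability matrix and degree sequences have mismatched shapes")
    row_res = np.abs(Q.sum(axis=1) - d.row_degrees).max()
    col_res = np.abs(Q.sum(axis=0) - d.col_degrees).max()
    return float(max(row_res, col_res))
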