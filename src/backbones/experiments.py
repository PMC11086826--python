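"""The two study pipelines: the synthetic constraint sweep and the
eight-condition empirical-style comparison.

The sweep quantifies how far a constraint-ignoring backbone (SDSM) drifts
from a constraint-aware one (SDSM-EC) as the prevalence of required and
prohibited cells grows: for each grid cell (X% of present cells required,
Y% of absent cells prohibited) it generates random bipartite networks,
extracts both backbones and averages their agreement indices over
replicates.

The empirical-style comparison takes a membership matrix plus child/group
attribute tables, builds the constraint mask for every subset of the three
rule families {focal, age, time}, extracts the SDSM-EC backbone of each,
and scores every backbone against the maximally-constrained one (the
condition that models all known constraints, used as the reference).  It
also reports the Pearson correlation, across the seven less-constrained
conditions, between backbone accuracy (phi vs the reference) and the
number of constrained cells the condition imposes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compare import ComparisonResult, confusion
from .core import (
    FREE,
    PROHIBITED,
    REQUIRED,
    BipartiteGraph,
    ConstraintMask,
    validate_or_coerce_mask,
)
from .significance import Backbone, extract_backbone
from .synth import PreschoolWorld, build_constraint_mask, sweep_instance

__all__ = [
    "SweepResult",
    "ConditionReport",
    "EmpiricalResult",
    "run_constraint_sweep",
    "constraint_counts",
    "run_empirical_comparison",
    "CONDITION_ORDER",
]

DEFAULT_GRID = tuple(range(0, 100, 10))

# Table order: no constraints, single families, pairs, all three.
CONDITION_ORDER: tuple[tuple[str, ...], ...] = (
    (),
    ("focal",),
    ("age",),
    ("time",),
    ("focal", "age"),
    ("focal", "time"),
    ("age", "time"),
    ("focal", "age", "time"),
)

_INDEX_NAMES = ("correlation", "kappa", "jaccard")


@dataclass
class SweepResult:
    """Aggregated backbone-agreement surface over the (X, Y) constraint grid."""

    table: pd.DataFrame  # one row per (X, Y) cell
    reps: int
    alpha: float
    seed: int

    def cell(self, x: int, y: int) -> pd.Series:
        t = self.table
        row = t[(t["x_required_pct"] == x) & (t["y_prohibited_pct"] == y)]
        if row.empty:
            raise KeyError(f"cell ({x}, {y}) not in sweep grid")
        return row.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_constraint_sweep(
    nA: int = 20,
    nB: int = 100,
    density: float = 0.5,
    x_values=DEFAULT_GRID,
    y_values=DEFAULT_GRID,
    reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "auto",
) -> SweepResult:
    """Run the synthetic constraint sweep.

    For every (X, Y) cell and replicate: draw a Bernoulli(``density``)
    bipartite network, mark X% of present cells REQUIRED and Y% of absent
    cells PROHIBITED, extract the SDSM backbone (mask ignored) and the
    SDSM-EC backbone (mask imposed) at level ``alpha``, and compare them.
    Replicates with an undefined index (degenerate backbones) are dropped
    from that index's mean/SD and counted in ``n_dropped_<index>``.

    Fully deterministic for a fixed ``seed``: replicate ``r`` of cell
    (X, Y) uses an RNG seeded from ``(seed, X, Y, r)``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    for x, y in itertools.product(x_values, y_values):
        vals = {name: [] for name in _INDEX_NAMES}
        for r in range(reps):
            rng = np.random.default_rng(np.random.SeedSequence([seed, int(x), int(y), r]))
            inst = sweep_instance(nA, nB, density, x, y, rng)
            bb_sdsm = extract_backbone(inst.graph, None, alpha=alpha, method=method)
            bb_ec = extract_backbone(inst.graph, inst.mask, alpha=alpha, method=method)
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                c = confusion(bb_sdsm, bb_ec)
            vals["correlation"].append(c.correlation)
            vals["kappa"].append(c.kappa)
            vals["jaccard"].append(c.jaccard)
        row: dict = {"x_required_pct": x, "y_prohibited_pct": y, "reps": reps}
        for name in _INDEX_NAMES:
            arr = np.asarray(vals[name], dtype=float)
            ok = ~np.isnan(arr)
            row[f"mean_{name}"] = float(arr[ok].mean()) if ok.any() else np.nan
            row[f"sd_{name}"] = float(arr[ok].std(ddof=1)) if ok.sum() > 1 else np.nan
            row[f"n_effective_{name}"] = int(ok.sum())
            row[f"n_dropped_{name}"] = int((~ok).sum())
        rows.append(row)
    return SweepResult(table=pd.DataFrame(rows), reps=reps, alpha=alpha, seed=seed)


def constraint_counts(g: BipartiteGraph, mask: ConstraintMask) -> dict[str, int]:
    """Edge accounting of a (coerced) graph/mask pair.

    Returns counts of unconstrained missing, prohibited, unconstrained
    present and required cells; the four always sum to nA * nB.
    """
    if g.shape != mask.shape:
        raise ValueError("graph and mask shapes differ")
    B, M = g.B, mask.M
    return {
        "unconstrained_missing": int(((M == FREE) & (B == 0)).sum()),
        "prohibited": int((M == PROHIBITED).sum()),
        "unconstrained_present": int(((M == FREE) & (B == 1)).sum()),
        "required": int((M == REQUIRED).sum()),
    }


@dataclass
class ConditionReport:
    """One row of the empirical comparison: a constraint condition end to end."""

    which: tuple[str, ...]
    counts: dict[str, int]
    n_coerced: int
    backbone: Backbone = field(repr=False)
    comparison: ComparisonResult | None = None  # vs the all-constraints reference

    @property
    def n_constrained(self) -> int:
        return self.counts["prohibited"] + self.counts["required"]


@dataclass
class EmpiricalResult:
    """All eight condition reports plus the accuracy-vs-constraints correlation."""

    reports: list[ConditionReport]
    accuracy_constraints_correlation: float

    @property
    def reference(self) -> ConditionReport:
        return self.reports[-1]

    def table_characteristics(self) -> pd.DataFrame:
        """Edge accounting per condition (unconstrained/prohibited missing,
        unconstrained/required present)."""
        rows = []
        for rep in self.reports:
            rows.append(
                {
                    "focal": "X" if "focal" in rep.which else "",
                    "age": "X" if "age" in rep.which else "",
                    "time": "X" if "time" in rep.which else "",
                    **rep.counts,
                }
            )
        return pd.DataFrame(rows)

    def table_comparisons(self) -> pd.DataFrame:
        """Agreement with the all-constraints backbone per condition."""
        rows = []
        for rep in self.reports:
            row = {
                "focal": "X" if "focal" in rep.which else "",
                "age": "X" if "age" in rep.which else "",
                "time": "X" if "time" in rep.which else "",
            }
            if rep.comparison is not None:
                row.update(rep.comparison.to_row())
            rows.append(row)
        return pd.DataFrame(rows)


def run_empirical_comparison(
    g: BipartiteGraph,
    children: pd.DataFrame,
    groups: pd.DataFrame,
    alpha: float = 0.13,
    method: str = "auto",
    tol: float = 1e-8,
) -> EmpiricalResult:
    """Extract and compare backbones under all eight constraint conditions.

    For each subset of {focal, age, time}: build the mask from the attribute
    tables, coerce present-but-prohibited cells to missing (the time rule
    can reclassify observed memberships), account the edges, and extract
    the SDSM-EC backbone at level ``alpha``.  Every backbone is scored
    against the maximally-constrained one; the comparison of the reference
    with itself is included for completeness (all indices 1, no errors).

    ``accuracy_constraints_correlation`` is the Pearson correlation between
    phi-vs-reference and the number of constrained cells over the seven
    non-reference conditions.
    """
    prelim: list[ConditionReport] = []
    for which in CONDITION_ORDER:
        mask = build_constraint_mask(children, groups, which=which)
        g_c, _, coercions = validate_or_coerce_mask(g, mask, mode="coerce")
        counts = constraint_counts(g_c, mask)
        bb = extract_backbone(g_c, mask, alpha=alpha, method=method, tol=tol)
        prelim.append(
            ConditionReport(which=which, counts=counts, n_coerced=len(coercions), backbone=bb)
        )
    ref = prelim[-1].backbone
    import warnings as _w

    for rep in prelim:
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            rep.comparison = confusion(rep.backbone, ref)
    phis = np.array([rep.comparison.correlation for rep in prelim[:-1]])
    ncon = np.array([rep.n_constrained for rep in prelim[:-1]], dtype=float)
    ok = ~np.isnan(phis)
    if ok.sum() >= 2 and np.std(ncon[ok]) > 0 and np.std(phis[ok]) > 0:
        rho = float(np.corrcoef(phis[ok], ncon[ok])[0, 1])
    else:
        rho = float("nan")
    return EmpiricalResult(reports=prelim, accuracy_constraints_correlation=rho)


def run_empirical_comparison_world(
    world: PreschoolWorld, alpha: float = 0.13, method: str = "auto"
) -> EmpiricalResult:
    """Convenience wrapper running the eight-condition comparison on a world bundle."""
    return run_empirical_comparison(world.graph, world.children, world.groups, alpha=alpha, method=method)
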