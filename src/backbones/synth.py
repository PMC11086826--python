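"""Synthetic data generators.

Two generators are provided:

* random Bernoulli bipartite networks with randomly placed edge constraints,
  the raw material of the constraint sweep (a share of the *present* cells
  is marked REQUIRED, a share of the *absent* cells PROHIBITED — so a mask
  is always consistent with its graph by construction);

* a scan-sampled "preschool world" emulating observational play-group data:
  children split over two age-segregated classrooms, attending in the
  morning (AM), afternoon (PM) or all day (FULL); play groups each observed
  in one classroom and one session around a randomly chosen *focal* child
  who is necessarily a member.  A planted within-classroom friendship
  network ("truth") can bias group membership through an assortativity
  multiplier, giving a known ground truth to score backbones against.

:func:`build_constraint_mask` derives the three empirical constraint
families from the attribute tables: the focal child's membership edge is
REQUIRED; cross-classroom edges are PROHIBITED (age); AM-child/PM-group and
PM-child/AM-group edges are PROHIBITED (time).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    FREE,
    PROHIBITED,
    REQUIRED,
    BipartiteGraph,
    ConstraintMask,
)
from . import io as bio

__all__ = [
    "SweepInstance",
    "PreschoolWorld",
    "generate_random_bipartite",
    "assign_constraints",
    "sweep_instance",
    "generate_preschool",
    "build_constraint_mask",
    "save_world",
    "load_world",
]

CONSTRAINT_FAMILIES = ("focal", "age", "time")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class SweepInstance:
    """One replicate of the synthetic sweep: a random graph plus a random mask."""

    graph: BipartiteGraph
    mask: ConstraintMask
    x_required_pct: float
    y_prohibited_pct: float
    seed: int | None


@dataclass
class PreschoolWorld:
    """A synthetic scan-sampled play-group dataset with planted ground truth."""

    children: pd.DataFrame  # child_id, classroom, schedule
    groups: pd.DataFrame  # group_id, classroom, session, focal_child_id
    truth: np.ndarray  # symmetric binary friendship matrix on children
    graph: BipartiteGraph  # memberships, children x groups


def generate_random_bipartite(
    nA: int, nB: int, density: float, seed=None
) -> BipartiteGraph:
    """Bernoulli random bipartite network: each cell present independently with ``density``."""
    if not 0.0 < density < 1.0:
        raise ValueError(f"density must be strictly between 0 and 1, got {density}")
    rng = _rng(seed)
    B = (rng.random((nA, nB)) < density).astype(np.int8)
    return BipartiteGraph(B)


def assign_constraints(
    g: BipartiteGraph, x_pct: float, y_pct: float, seed=None
) -> ConstraintMask:
    """Mark a random X% of present cells REQUIRED and Y% of absent cells PROHIBITED.

    Sampling is uniform without replacement; counts are rounded half-up.
    The result is consistent with ``g`` by construction (REQUIRED only at
    observed-present cells, PROHIBITED only at observed-absent cells).
    """
    if not (0 <= x_pct <= 100 and 0 <= y_pct <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    rng = _rng(seed)
    M = np.zeros(g.shape, dtype=np.int8)
    present = np.flatnonzero(g.B == 1)
    absent = np.flatnonzero(g.B == 0)
    n_req = _round_half_up(x_pct / 100.0 * present.size)
    n_pro = _round_half_up(y_pct / 100.0 * absent.size)
    if n_req:
        M.flat[rng.choice(present, size=n_req, replace=False)] = REQUIRED
    if n_pro:
        M.flat[rng.choice(absent, size=n_pro, replace=False)] = PROHIBITED
    return ConstraintMask(M)


def sweep_instance(
    nA: int, nB: int, density: float, x_pct: float, y_pct: float, seed=None
) -> SweepInstance:
    """Generate one sweep replicate (graph + constraint mask) from a single seed."""
    rng = _rng(seed)
    g = generate_random_bipartite(nA, nB, density, rng)
    m = assign_constraints(g, x_pct, y_pct, rng)
    return SweepInstance(g, m, x_pct, y_pct, seed if isinstance(seed, int) else None)


def generate_preschool(
    n_children: int = 53,
    n_groups: int = 1829,
    classroom_split: tuple[int, int] = (26, 27),
    schedule_probs: tuple[float, float, float] = (0.3, 0.2, 0.5),
    group_size_range: tuple[int, int] = (2, 6),
    truth_density: float = 0.15,
    assortativity: float = 1.0,
    seed=None,
) -> PreschoolWorld:
    """Generate a scan-sampled play-group world with a planted friendship truth.

    Parameters
    ----------
    classroom_split : (int, int)
        Sizes of the younger (3yo) and older (4yo) classrooms; must sum to
        ``n_children``.
    schedule_probs : (float, float, float)
        Probabilities of the AM, PM and FULL attendance schedules.
    group_size_range : (int, int)
        Inclusive bounds of the uniform group-size draw (truncated to the
        eligible pool).
    truth_density : float
        Probability of a friendship edge between two same-classroom children.
    assortativity : float
        Odds multiplier applied once per already-chosen friend when sampling
        additional members; 1.0 means membership ignores the truth network.

    Each group is observed in one classroom (chosen proportionally to
    classroom size) and one session (AM or PM, equiprobable); its focal
    child is uniform among schedule-eligible children of that classroom and
    is always a member.
    """
    if sum(classroom_split) != n_children:
        raise ValueError("classroom_split must sum to n_children")
    if assortativity <= 0:
        raise ValueError("assortativity must be positive")
    rng = _rng(seed)
    n3, n4 = classroom_split
    classrooms = np.array(["3yo"] * n3 + ["4yo"] * n4)
    schedules = rng.choice(["AM", "PM", "FULL"], size=n_children, p=schedule_probs)
    child_ids = [f"C{i + 1:02d}" for i in range(n_children)]
    children = pd.DataFrame(
        {"child_id": child_ids, "classroom": classrooms, "schedule": schedules}
    )

    # planted within-classroom friendship truth
    truth = np.zeros((n_children, n_children), dtype=np.int8)
    same_class = classrooms[:, None] == classrooms[None, :]
    iu = np.triu_indices(n_children, k=1)
    draw = (rng.random(len(iu[0])) < truth_density) & same_class[iu]
    truth[iu[0][draw], iu[1][draw]] = 1
    truth += truth.T

    # eligibility: AM session admits AM+FULL children, PM session PM+FULL
    eligible = {
        (cls, ses): np.where(
            (classrooms == cls) & np.isin(schedules, [ses, "FULL"])
        )[0]
        for cls in ("3yo", "4yo")
        for ses in ("AM", "PM")
    }
    for (cls, ses), pool in eligible.items():
        if pool.size == 0:
            raise ValueError(f"no eligible focal child for classroom {cls}, session {ses}")

    lo, hi = group_size_range
    B = np.zeros((n_children, n_groups), dtype=np.int8)
    rows = []
    p_class = np.array([n3, n4]) / n_children
    for k in range(n_groups):
        cls = rng.choice(["3yo", "4yo"], p=p_class)
        ses = rng.choice(["AM", "PM"])
        pool = eligible[(cls, ses)]
        focal = int(rng.choice(pool))
        size = min(int(rng.integers(lo, hi + 1)), pool.size)
        members = [focal]
        remaining = [c for c in pool if c != focal]
        while len(members) < size and remaining:
            w = np.array(
                [assortativity ** sum(truth[c, m] for m in members) for c in remaining],
                dtype=np.float64,
            )
            pick = int(rng.choice(len(remaining), p=w / w.sum()))
            members.append(remaining.pop(pick))
        B[members, k] = 1
        rows.append(
            {
                "group_id": f"G{k + 1:04d}",
                "classroom": cls,
                "session": ses,
                "focal_child_id": child_ids[focal],
            }
        )
    groups = pd.DataFrame(rows)
    graph = BipartiteGraph(B, child_ids, groups["group_id"].tolist())
    return PreschoolWorld(children=children, groups=groups, truth=truth, graph=graph)


def build_constraint_mask(
    world_or_children: "PreschoolWorld | pd.DataFrame",
    groups: pd.DataFrame | None = None,
    which=("focal", "age", "time"),
) -> ConstraintMask:
    """Derive the constraint mask implied by attribute tables and rule families.

    ``which`` is any subset of ``{"focal", "age", "time"}``:

    * ``focal`` — REQUIRED at (focal child, its group) for every group;
    * ``age`` — PROHIBITED at every cross-classroom (child, group) cell;
    * ``time`` — PROHIBITED at (AM child, PM group) and (PM child, AM group).

    REQUIRED takes precedence; a focal child prohibited for its own group
    (inconsistent attribute data) raises ``ValueError``.
    """
    if isinstance(world_or_children, PreschoolWorld):
        children = world_or_children.children
        groups = world_or_children.groups
    else:
        children = world_or_children
        if groups is None:
            raise ValueError("groups table required when not passing a PreschoolWorld")
    bad = set(which) - set(CONSTRAINT_FAMILIES)
    if bad:
        raise ValueError(f"unknown constraint families: {sorted(bad)}")

    child_class = children["classroom"].to_numpy()
    child_sched = children["schedule"].to_numpy()
    group_class = groups["classroom"].to_numpy()
    group_ses = groups["session"].to_numpy()
    child_index = {cid: i for i, cid in enumerate(children["child_id"])}
    focal_idx = np.array([child_index[c] for c in groups["focal_child_id"]])

    nA, nB = len(children), len(groups)
    prohibited = np.zeros((nA, nB), dtype=bool)
    if "age" in which:
        prohibited |= child_class[:, None] != group_class[None, :]
    if "time" in which:
        prohibited |= (child_sched == "AM")[:, None] & (group_ses == "PM")[None, :]
        prohibited |= (child_sched == "PM")[:, None] & (group_ses == "AM")[None, :]
    M = np.where(prohibited, PROHIBITED, FREE).astype(np.int8)
    if "focal" in which:
        if prohibited[focal_idx, np.arange(nB)].any():
            k = int(np.where(prohibited[focal_idx, np.arange(nB)])[0][0])
            raise ValueError(
                f"inconsistent attributes: focal child of group {groups['group_id'].iloc[k]} "
                "is prohibited for its own group"
            )
        M[focal_idx, np.arange(nB)] = REQUIRED
    return ConstraintMask(M)


def save_world(world: PreschoolWorld, directory: str | os.PathLike) -> None:
    """Export a world bundle: labeled edge-list biadjacency + attribute CSVs + truth."""
    os.makedirs(directory, exist_ok=True)
    d = str(directory)
    bio.write_biadjacency(world.graph, os.path.join(d, "biadjacency.tsv"), format="edgelist")
    world.children.to_csv(os.path.join(d, "children.csv"), index=False)
    world.groups.to_csv(os.path.join(d, "groups.csv"), index=False)
    pd.DataFrame(
        world.truth, index=world.graph.row_labels, columns=world.graph.row_labels
    ).to_csv(os.path.join(d, "truth.csv"))


def load_world(directory: str | os.PathLike) -> PreschoolWorld:
    """Load a world bundle written by :func:`save_world` (truth.csv optional)."""
    d = str(directory)
    graph = bio.read_biadjacency(os.path.join(d, "biadjacency.tsv"), format="edgelist")
    children = bio.read_child_attributes(os.path.join(d, "children.csv"))
    groups = bio.read_group_attributes(os.path.join(d, "groups.csv"))
    truth_path = os.path.join(d, "truth.csv")
    if os.path.exists(truth_path):
        truth = pd.read_csv(truth_path, index_col=0).to_numpy().astype(np.int8)
    else:
        truth = np.zeros((len(children), len(children)), dtype=np.int8)
    return PreschoolWorld(children=children, groups=groups, truth=truth, graph=graph)
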