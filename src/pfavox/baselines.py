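"""Comparator voxel selectors: univariate t-statistic and searchlight.

Also hosts the top-N selection rule and the per-category/union protocol
shared by all selectors (each stimulus category contributes a subset
from its own localizer contrast; the union is the final voxel set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import DesignTable, VoxelTimeSeries
from .pfa import PFAConfig, SelectedFeatures, pfa_select

__all__ = [
    "ScoreMap",
    "SphereOffsets",
    "tstat_scores",
    "sphere_offsets",
    "searchlight_scores",
    "top_n_select",
    "per_category_union",
]

CONTROL_LABEL = "control"
BLANK_LABEL = "blank"


@dataclass
class ScoreMap:
    """Per-voxel scores aligned with VoxelTimeSeries row order."""

    scores: np.ndarray
    method: str
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


@dataclass
class SphereOffsets:
    """Integer displacements within a sphere of the given voxel radius."""

    radius: float
    offsets: np.ndarray

    def __len__(self) -> int:
        return self.offsets.shape[0]


def tstat_scores(
    ts: VoxelTimeSeries,
    design: DesignTable,
    category: str,
    lag_observations: int = 1,
) -> ScoreMap:
    """Absolute two-sample pooled-variance t per voxel (task vs control).

    Observations are labelled from the design table with block intervals
    shifted forward by ``lag_observations`` to crudely absorb the
    hemodynamic delay.  Only runs containing the category's task blocks
    contribute.  A voxel with zero pooled variance scores 0 (a constant
    voxel carries no contrast) with a logged warning.
    """
    runs = design.runs_with_condition(category)
    if not runs:
        raise ValueError(f"no run contains condition {category!r}")
    labels = design.observation_labels(ts.run_id, lag_observations=lag_observations)
    in_run = np.isin(ts.run_id, runs)
    task = in_run & (labels == category)
    control = in_run & (labels == CONTROL_LABEL)
    n1, n0 = int(task.sum()), int(control.sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(
            f"need >= 2 task and >= 2 control observations after lag shift, "
            f"got {n1} task / {n0} control"
        )
    a = ts.values[:, task]
    b = ts.values[:, control]
    m1, m0 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v0 = b.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0))
    t = np.zeros(ts.n_voxels)
    ok = se > 0
    t[ok] = (m1[ok] - m0[ok]) / se[ok]
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} voxel(s) with zero pooled variance scored 0",
            stacklevel=2,
        )
    return ScoreMap(scores=np.abs(t), method=f"tstat[{category}]")


def sphere_offsets(radius: float) -> SphereOffsets:
    """All integer displacements with squared norm <= radius**2.

    Lexicographic order; radius 2 yields the 33-voxel searchlight.
    """
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    r = int(np.floor(radius))
    r2 = radius * radius + 1e-9
    offs = [
        (dx, dy, dz)
        for dx in range(-r, r + 1)
        for dy in range(-r, r + 1)
        for dz in range(-r, r + 1)
        if dx * dx + dy * dy + dz * dz <= r2
    ]
    return SphereOffsets(radius=float(radius), offsets=np.array(sorted(offs), dtype=int).reshape(-1, 3))


def searchlight_scores(
    tmap: ScoreMap,
    voxel_index: np.ndarray,
    mask_shape: tuple,
    radius: float = 2.0,
) -> ScoreMap:
    """Mean |t| over the in-mask sphere centered on each voxel.

    Sphere positions falling outside the mask or the volume are dropped
    from both numerator and denominator, so edge voxels average over a
    truncated neighborhood.  Radius 0 reduces to |t| itself.
    """
    voxel_index = np.asarray(voxel_index, dtype=int)
    n = voxel_index.shape[0]
    t = np.abs(np.asarray(tmap.scores, dtype=float))
    if t.shape[0] != n:
        raise ValueError("tmap is not aligned with voxel_index")
    shape = tuple(int(s) for s in mask_shape)

    # map coordinates -> row id for O(1) in-mask neighbor lookup
    row_of = np.full(shape, -1, dtype=int)
    row_of[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = np.arange(n)

    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for off in sphere_offsets(radius).offsets:
        nb = voxel_index + off
        inside = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
        rows = np.flatnonzero(inside)
        nb_rows = row_of[nb[rows, 0], nb[rows, 1], nb[rows, 2]]
        hit = nb_rows >= 0
        sums[rows[hit]] += t[nb_rows[hit]]
        counts[rows[hit]] += 1
    # (0,0,0) is always in the sphere, so counts >= 1 everywhere
    return ScoreMap(scores=sums / counts, method=f"searchlight[r={radius}]({tmap.method})")


def top_n_select(scores: ScoreMap, n: int) -> SelectedFeatures:
    """The n highest-scoring voxels, descending score, ties -> lowest index."""
    s = scores.scores
    if n <= 0:
        raise ValueError("n must be positive")
    if n > s.size:
        raise ValueError(f"n={n} exceeds the {s.size} available voxels")
    order = np.lexsort((np.arange(s.size), -s))
    top = order[:n]
    return SelectedFeatures(indices=top, scores=s[top], method=scores.method)


def _category_view(ts: VoxelTimeSeries, design: DesignTable, category: str) -> VoxelTimeSeries:
    """Observations of the runs that contain the category's task blocks."""
    runs = design.runs_with_condition(category)
    if not runs:
        raise ValueError(f"no run contains condition {category!r}")
    return ts.subset_observations(np.isin(ts.run_id, runs))


def _run_selector(
    selector,
    ts: VoxelTimeSeries,
    design: DesignTable,
    category: str,
    budget: int,
    *,
    lag_observations: int = 1,
    radius: float = 2.0,
    mask_shape: tuple | None = None,
    pfa_config: PFAConfig | None = None,
) -> SelectedFeatures:
    if callable(selector):
        return selector(ts, design, category, budget)
    if selector == "tstat":
        return top_n_select(tstat_scores(ts, design, category, lag_observations), budget)
    if selector == "searchlight":
        if mask_shape is None:
            mask_shape = tuple(ts.voxel_index.max(axis=0) + 1)
        tmap = tstat_scores(ts, design, category, lag_observations)
        return top_n_select(
            searchlight_scores(tmap, ts.voxel_index, mask_shape, radius), budget
        )
    if selector == "pfa":
        view = _category_view(ts, design, category)
        return pfa_select(view, budget, pfa_config)
    raise ValueError(f"unknown selector {selector!r}")


def per_category_union(
    ts: VoxelTimeSeries,
    design: DesignTable,
    categories,
    selector,
    per_category_budget: int,
    total_budget: int | None = None,
    **selector_kwargs,
) -> SelectedFeatures:
    """Run a selector per category and take the union of the subsets.

    ``selector`` is one of ``{"pfa", "tstat", "searchlight"}`` or a
    callable ``f(ts, design, category, budget) -> SelectedFeatures``.
    Each voxel in the union is scored by its maximum score over the
    categories that picked it; if the union exceeds ``total_budget``,
    the lowest-scoring voxels are dropped (ties -> lowest index kept).
    """
    if per_category_budget <= 0 or (total_budget is not None and total_budget <= 0):
        raise ValueError("budgets must be positive")
    best_score: dict[int, float] = {}
    picked_by: dict[int, list] = {}
    for category in categories:
        sel = _run_selector(selector, ts, design, category, per_category_budget,
                            **selector_kwargs)
        sel.category = category
        for i, s in zip(sel.indices.tolist(), sel.scores.tolist()):
            picked_by.setdefault(i, []).append(category)
            if i not in best_score or s > best_score[i]:
                best_score[i] = s
    idx = np.array(sorted(best_score), dtype=int)
    scores = np.array([best_score[i] for i in idx])
    if total_budget is not None and idx.size > total_budget:
        order = np.lexsort((idx, -scores))[:total_budget]
        keep = np.sort(order)
        idx, scores = idx[keep], scores[keep]
    method = selector if isinstance(selector, str) else getattr(selector, "__name__", "custom")
    return SelectedFeatures(
        indices=idx,
        scores=scores,
        method=f"{method}-union",
        provenance={int(i): picked_by[int(i)] for i in idx},
    )
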