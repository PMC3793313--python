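"""Synthetic multi-run fMRI generation with planted ground truth.

Emulates a block-design localizer (alternating task/control blocks, one
stimulus category per run) and event-related task runs (short stimulus
trials with interspersed blanks), planting four kinds of voxels on a
3-D grid: strongly activated, weakly activated, redundant (correlated
duplicates of strong voxels), and pure noise.  Ground truth is returned
alongside, so selector recovery and decoding behaviour can be tested
without any external data.

Responses use a lag-shifted boxcar/impulse rather than a hemodynamic
convolution, keeping expected statistics analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .baselines import BLANK_LABEL, CONTROL_LABEL
from .io import DesignTable, VoxelTimeSeries

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SubjectDataset",
    "generate_localizer_run",
    "generate_task_runs",
    "generate_subject",
    "generate_subject_cohort",
]

DEFAULT_CATEGORIES = ("animal", "building", "car", "face")


@dataclass
class SyntheticSpec:
    """Generator parameters.

    Effect sizes are response amplitudes in units of the noise SD.
    ``seed`` fixes the voxel layout (which rows are strong/weak/
    duplicate/noise and where they sit on the grid); per-run noise uses
    the seed passed to each generate call, so one subject's runs share a
    layout but have independent noise.
    """

    n_voxels: int = 120
    grid_shape: tuple = (8, 8, 8)
    n_categories: int = 4
    n_stimuli_per_category: int = 50
    blocks_per_run: int = 12
    block_observations: int = 15
    strong_fraction: float = 0.1
    weak_fraction: float = 0.1
    redundancy_copies: int = 1
    effect_size_strong: float = 1.5
    effect_size_weak: float = 0.5
    cross_response: float = 0.25
    hemodynamic_lag_observations: int = 1
    noise_sd: float = 1.0
    duplicate_jitter: float = 0.05
    trend_slope_range: tuple = (0.0, 0.0)
    n_task_runs: int = 2
    trial_observations: int = 2
    blank_every: int = 5
    ar_phi: float = 0.0
    tr_seconds: float = 2.0
    seed: int = 0
    categories: tuple = ()

    def __post_init__(self) -> None:
        if not self.categories:
            base = DEFAULT_CATEGORIES
            self.categories = tuple(
                base[i] if i < len(base) else f"cat{i}" for i in range(self.n_categories)
            )
        if len(self.categories) != self.n_categories:
            raise ValueError("categories must match n_categories")
        for name, val in [
            ("n_voxels", self.n_voxels),
            ("n_categories", self.n_categories),
            ("n_stimuli_per_category", self.n_stimuli_per_category),
            ("blocks_per_run", self.blocks_per_run),
            ("block_observations", self.block_observations),
            ("n_task_runs", self.n_task_runs),
            ("trial_observations", self.trial_observations),
        ]:
            if val < 1:
                raise ValueError(f"{name} must be positive")
        if self.blocks_per_run % 2 != 0:
            raise ValueError("blocks_per_run must be even (alternating task/control)")
        if self.strong_fraction < 0 or self.weak_fraction < 0:
            raise ValueError("fractions must be nonnegative")
        if int(np.prod(self.grid_shape)) < self.n_voxels:
            raise ValueError("grid capacity smaller than n_voxels")
        n_strong = self.n_strong
        n_inform = n_strong * (1 + self.redundancy_copies) + self.n_weak
        if n_inform > self.n_voxels:
            raise ValueError(
                f"{n_inform} informative voxels exceed n_voxels={self.n_voxels}"
            )

    @property
    def n_strong(self) -> int:
        return int(round(self.strong_fraction * self.n_voxels))

    @property
    def n_weak(self) -> int:
        return int(round(self.weak_fraction * self.n_voxels))


@dataclass
class GroundTruth:
    """Which voxels were planted with what."""

    strong_indices: np.ndarray
    weak_indices: np.ndarray
    duplicate_groups: list
    category_of_voxel: dict

    @property
    def informative_indices(self) -> np.ndarray:
        dups = [i for g in self.duplicate_groups for i in g[1:]]
        return np.array(
            sorted(set(self.strong_indices.tolist()) | set(self.weak_indices.tolist()) | set(dups)),
            dtype=int,
        )


@dataclass
class SubjectDataset:
    """One synthetic subject: localizer runs, task runs, ground truth."""

    localizer: VoxelTimeSeries
    localizer_design: DesignTable
    task: VoxelTimeSeries
    task_design: DesignTable
    ground_truth: GroundTruth
    categories: tuple
    subject_id: str = "sim"


def _grid_coordinates(spec: SyntheticSpec) -> np.ndarray:
    """First n_voxels grid positions in x-fastest linearized order."""
    nx, ny, nz = spec.grid_shape
    lin = np.arange(spec.n_voxels)
    x = lin % nx
    y = (lin // nx) % ny
    z = lin // (nx * ny)
    if np.any(z >= nz):
        raise ValueError("grid capacity smaller than n_voxels")
    return np.stack([x, y, z], axis=1)


def plan_layout(spec: SyntheticSpec) -> GroundTruth:
    """Assign voxel roles deterministically from ``spec.seed``.

    Half of the strong sources form a contiguous clump at the start of
    the row order (adjacent grid positions, exercising searchlight's
    neighborhood averaging); the rest are scattered singletons, as are
    duplicates and weak voxels.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xFACE)))
    n = spec.n_voxels
    n_strong, n_weak = spec.n_strong, spec.n_weak
    clump = (n_strong + 1) // 2
    scattered = rng.permutation(np.arange(clump, n))
    cursor = 0

    def take(count):
        nonlocal cursor
        out = scattered[cursor : cursor + count]
        cursor += count
        return out

    strong = np.concatenate([np.arange(clump), take(n_strong - clump)]).astype(int)
    duplicate_groups = []
    category_of_voxel: dict[int, str] = {}
    for i, src in enumerate(strong):
        cat = spec.categories[i % spec.n_categories]
        category_of_voxel[int(src)] = cat
        group = [int(src)]
        for dup in take(spec.redundancy_copies):
            group.append(int(dup))
            category_of_voxel[int(dup)] = cat
        duplicate_groups.append(group)
    weak = np.sort(take(n_weak)).astype(int)
    for i, w in enumerate(weak):
        category_of_voxel[int(w)] = spec.categories[i % spec.n_categories]
    return GroundTruth(
        strong_indices=np.sort(strong),
        weak_indices=weak,
        duplicate_groups=duplicate_groups,
        category_of_voxel=category_of_voxel,
    )


def _noise(rng: np.random.Generator, spec: SyntheticSpec, n: int, L: int) -> np.ndarray:
    white = rng.normal(0.0, spec.noise_sd, size=(n, L))
    if spec.ar_phi:
        # innovations scaled to keep the stationary SD at noise_sd
        white *= np.sqrt(1.0 - spec.ar_phi**2)
        return lfilter([1.0], [1.0, -spec.ar_phi], white, axis=1)
    return white


def _amplitude(
    spec: SyntheticSpec, gt: GroundTruth, voxel: int, voxel_cat: str, stimulus_cat: str
) -> float:
    """Response amplitude of an informative voxel to a stimulus category.

    Preferred-category stimuli evoke the full effect size; other
    categories evoke ``cross_response`` times it (visual voxels respond
    to any image, just more weakly to non-preferred ones).
    """
    base = (
        spec.effect_size_strong
        if voxel in gt.strong_indices
        else spec.effect_size_weak
    ) * spec.noise_sd
    return base if voxel_cat == stimulus_cat else base * spec.cross_response


def _shift_forward(x: np.ndarray, lag: int) -> np.ndarray:
    if lag <= 0:
        return x
    out = np.zeros_like(x)
    out[lag:] = x[:-lag]
    return out


def _apply_duplicates_and_trend(
    values: np.ndarray, gt: GroundTruth, spec: SyntheticSpec, rng: np.random.Generator
) -> None:
    L = values.shape[1]
    for group in gt.duplicate_groups:
        src = group[0]
        for dup in group[1:]:
            values[dup] = values[src] + rng.normal(
                0.0, spec.duplicate_jitter * spec.noise_sd, size=L
            )
    lo, hi = spec.trend_slope_range
    if lo != 0.0 or hi != 0.0:
        slopes = rng.uniform(lo, hi, size=values.shape[0])
        values += slopes[:, None] * np.arange(L)


def generate_localizer_run(
    spec: SyntheticSpec, category: str, seed: int, run: int = 0
) -> tuple[VoxelTimeSeries, DesignTable, GroundTruth]:
    """One block-design localizer run for a single stimulus category.

    Blocks alternate task/control starting with task; strong and weak
    voxels of the matching category respond with a lag-shifted boxcar.
    """
    if category not in spec.categories:
        raise ValueError(f"unknown category {category!r}")
    gt = plan_layout(spec)
    coords = _grid_coordinates(spec)
    L = spec.blocks_per_run * spec.block_observations
    bo = spec.block_observations

    rows = []
    boxcar = np.zeros(L)
    for b in range(spec.blocks_per_run):
        cond = category if b % 2 == 0 else CONTROL_LABEL
        rows.append((run, b * bo, bo, cond))
        if cond == category:
            boxcar[b * bo : (b + 1) * bo] = 1.0
    design = DesignTable.from_rows(rows)
    response = _shift_forward(boxcar, spec.hemodynamic_lag_observations)

    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, seed, 1)))
    values = _noise(rng, spec, spec.n_voxels, L)
    dup_members = {v for g in gt.duplicate_groups for v in g[1:]}
    for v, cat in gt.category_of_voxel.items():
        if v in dup_members:
            continue
        amp = _amplitude(spec, gt, v, cat, category)
        if amp:
            values[v] += amp * response
    _apply_duplicates_and_trend(values, gt, spec, rng)

    run_id = np.full(L, run, dtype=int)
    ts = VoxelTimeSeries(
        values=values,
        voxel_index=coords,
        run_id=run_id,
        condition=design.observation_labels(run_id),
        tr_seconds=spec.tr_seconds,
    )
    return ts, design, gt


def _task_run_schedule(spec: SyntheticSpec, labels: list, rng) -> list:
    """Shuffle stimulus labels and insert a blank after every 5 trials."""
    labels = list(labels)
    rng.shuffle(labels)
    out = []
    for i, lab in enumerate(labels):
        out.append(lab)
        if (i + 1) % spec.blank_every == 0 and i + 1 < len(labels):
            out.append(BLANK_LABEL)
    return out


def generate_task_runs(
    spec: SyntheticSpec, seed: int
) -> tuple[VoxelTimeSeries, DesignTable, GroundTruth]:
    """Event-related task runs covering all stimuli of all categories.

    Each stimulus occupies one short trial; category voxels respond with
    a lag-shifted impulse of the same amplitude as in the localizer.
    Stimuli are split evenly across ``n_task_runs`` runs and shuffled
    per run with the seeded generator.
    """
    gt = plan_layout(spec)
    dup_members = {v for g in gt.duplicate_groups for v in g[1:]}
    coords = _grid_coordinates(spec)
    to = spec.trial_observations
    ss = np.random.SeedSequence((spec.seed, seed, 2))
    rngs = [np.random.default_rng(c) for c in ss.spawn(spec.n_task_runs + 1)]

    # even per-category split across runs; leftovers go to the first runs
    per_run_labels: list[list] = [[] for _ in range(spec.n_task_runs)]
    for cat in spec.categories:
        base, extra = divmod(spec.n_stimuli_per_category, spec.n_task_runs)
        for r in range(spec.n_task_runs):
            per_run_labels[r].extend([cat] * (base + (1 if r < extra else 0)))

    all_values, all_run_id, rows = [], [], []
    for r in range(spec.n_task_runs):
        schedule = _task_run_schedule(spec, per_run_labels[r], rngs[r])
        # lag-length tail keeps the last trial's shifted window inside the run
        L = len(schedule) * to + spec.hemodynamic_lag_observations
        values = _noise(rngs[-1], spec, spec.n_voxels, L)
        for slot, lab in enumerate(schedule):
            onset = slot * to
            rows.append((r, onset, to, lab))
            if lab == BLANK_LABEL:
                continue
            lo = onset + spec.hemodynamic_lag_observations
            hi = min(lo + to, L)
            if lo >= L:
                continue
            for v, cat in gt.category_of_voxel.items():
                if v in dup_members:
                    continue
                amp = _amplitude(spec, gt, v, cat, lab)
                if amp:
                    values[v, lo:hi] += amp
        _apply_duplicates_and_trend(values, gt, spec, rngs[-1])
        all_values.append(values)
        all_run_id.append(np.full(L, r, dtype=int))

    design = DesignTable.from_rows(rows)
    run_id = np.concatenate(all_run_id)
    ts = VoxelTimeSeries(
        values=np.concatenate(all_values, axis=1),
        voxel_index=coords,
        run_id=run_id,
        condition=design.observation_labels(run_id),
        tr_seconds=spec.tr_seconds,
    )
    return ts, design, gt


def generate_subject(
    spec: SyntheticSpec, seed: int, subject_id: str = "sim"
) -> SubjectDataset:
    """One localizer run per category plus the task runs, under one layout."""
    loc_parts = []
    designs = []
    gt = plan_layout(spec)
    for ci, cat in enumerate(spec.categories):
        ts, design, _ = generate_localizer_run(spec, cat, seed=seed * 1000 + ci, run=ci)
        loc_parts.append(ts)
        designs.append(design.table)
    loc_design = DesignTable(pd.concat(designs, ignore_index=True))
    localizer = VoxelTimeSeries(
        values=np.concatenate([p.values for p in loc_parts], axis=1),
        voxel_index=loc_parts[0].voxel_index,
        run_id=np.concatenate([p.run_id for p in loc_parts]),
        condition=np.concatenate([p.condition for p in loc_parts]),
        tr_seconds=spec.tr_seconds,
    )
    task, task_design, _ = generate_task_runs(spec, seed=seed * 1000 + 99)
    return SubjectDataset(
        localizer=localizer,
        localizer_design=loc_design,
        task=task,
        task_design=task_design,
        ground_truth=gt,
        categories=spec.categories,
        subject_id=subject_id,
    )


def generate_subject_cohort(
    spec: SyntheticSpec,
    n_subjects: int,
    master_seed: int,
    effect_jitter: float = 0.2,
) -> list[SubjectDataset]:
    """Independent subjects with per-subject effect-size jitter.

    Each subject gets a deterministic child seed of ``master_seed`` and
    effect sizes jittered by a uniform factor in ``1 ± effect_jitter``,
    creating between-subject variability for paired comparisons.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    subjects = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        js = float(rng.uniform(1 - effect_jitter, 1 + effect_jitter))
        jw = float(rng.uniform(1 - effect_jitter, 1 + effect_jitter))
        sub_spec = replace(
            spec,
            effect_size_strong=spec.effect_size_strong * js,
            effect_size_weak=spec.effect_size_weak * jw,
            seed=int(rng.integers(2**31)),
            categories=spec.categories,
        )
        subjects.append(
            generate_subject(sub_spec, seed=int(rng.integers(2**31)), subject_id=f"sub{i:02d}")
        )
    return subjects
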