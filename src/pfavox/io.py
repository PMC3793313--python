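"""Volumetric I/O, voxel-matrix flattening, design tables, and detrending.

The central container is :class:`VoxelTimeSeries`: an ``n voxels x L
observations`` matrix with a reversible mapping back to 3-D voxel
coordinates.  Voxel rows are always ordered by ascending linearized
coordinate with x varying fastest, which makes row order (and therefore
all downstream tie-breaking) deterministic for a given mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "VoxelTimeSeries",
    "DesignTable",
    "read_volume_series",
    "read_matrix_series",
    "write_selection_mask",
    "detrend_linear",
    "mask_voxel_coordinates",
    "flatten_volume",
    "unflatten_to_volume",
]


@dataclass
class VoxelTimeSeries:
    """An ``n x L`` voxel-by-observation signal matrix with annotations.

    Parameters
    ----------
    values
        Array of shape ``(n, L)`` of signal intensities (arbitrary units).
    voxel_index
        Integer array of shape ``(n, 3)``; 0-based voxel coordinates of
        each row in the source grid.
    run_id
        Integer array of shape ``(L,)`` labelling the run of each
        observation.  Observations of a run must be contiguous.
    condition
        Optional per-observation condition labels (length ``L``).
    tr_seconds
        Repetition time in seconds.
    """

    values: np.ndarray
    voxel_index: np.ndarray
    run_id: np.ndarray | None = None
    condition: np.ndarray | None = None
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (voxels x observations) array")
        n, L = self.values.shape
        if n < 1 or L < 2:
            raise ValueError(f"need n >= 1 voxels and L >= 2 observations, got {n} x {L}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.voxel_index.shape != (n, 3):
            raise ValueError(f"voxel_index must have shape ({n}, 3)")
        if len({tuple(c) for c in self.voxel_index}) != n:
            raise ValueError("voxel_index entries must be unique")
        if self.run_id is None:
            self.run_id = np.zeros(L, dtype=int)
        self.run_id = np.asarray(self.run_id, dtype=int)
        if self.run_id.shape != (L,):
            raise ValueError(f"run_id must have shape ({L},)")
        if self.condition is None:
            self.condition = np.full(L, "unlabeled", dtype=object)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.condition.shape != (L,):
            raise ValueError(f"condition must have shape ({L},)")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_observations(self) -> int:
        return self.values.shape[1]

    @property
    def runs(self) -> np.ndarray:
        """Unique run ids in order of first appearance."""
        _, first = np.unique(self.run_id, return_index=True)
        return self.run_id[np.sort(first)]

    def run_slice(self, run: int) -> slice:
        """Contiguous observation slice of one run."""
        where = np.flatnonzero(self.run_id == run)
        if where.size == 0:
            raise ValueError(f"run {run} not present")
        lo, hi = int(where[0]), int(where[-1])
        if hi - lo + 1 != where.size:
            raise ValueError(f"observations of run {run} are not contiguous")
        return slice(lo, hi + 1)

    def subset_observations(self, obs_mask: np.ndarray) -> "VoxelTimeSeries":
        obs_mask = np.asarray(obs_mask)
        return replace(
            self,
            values=self.values[:, obs_mask],
            run_id=self.run_id[obs_mask],
            condition=self.condition[obs_mask],
        )

    def subset_voxels(self, rows: np.ndarray) -> "VoxelTimeSeries":
        rows = np.asarray(rows, dtype=int)
        return replace(self, values=self.values[rows], voxel_index=self.voxel_index[rows])


@dataclass
class DesignTable:
    """Run/onset/duration/condition intervals, in observation units.

    Stored as a data frame with columns ``run onset duration condition``.
    Intervals within one run must not overlap.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("run", "onset", "duration", "condition")

    def __post_init__(self) -> None:
        if len(self.table) == 0 and list(self.table.columns) != list(self.COLUMNS):
            self.table = pd.DataFrame(columns=list(self.COLUMNS))
        if list(self.table.columns) != list(self.COLUMNS):
            raise ValueError(f"design table must have columns {self.COLUMNS}")
        t = self.table
        if len(t):
            if (t["onset"] < 0).any() or (t["duration"] < 1).any():
                raise ValueError("onsets must be >= 0 and durations >= 1")
            for run, grp in t.groupby("run"):
                iv = sorted(zip(grp["onset"], grp["onset"] + grp["duration"]))
                for (s0, e0), (s1, _) in zip(iv, iv[1:]):
                    if s1 < e0:
                        raise ValueError(f"overlapping intervals in run {run}")

    @classmethod
    def from_rows(cls, rows) -> "DesignTable":
        """Build from an iterable of (run, onset, duration, condition)."""
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @classmethod
    def from_tsv(cls, path) -> "DesignTable":
        t = pd.read_csv(path, sep="\t")
        return cls(t[list(cls.COLUMNS)])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.table)

    def rows_for(self, condition=None, run=None) -> pd.DataFrame:
        t = self.table
        if condition is not None:
            t = t[t["condition"] == condition]
        if run is not None:
            t = t[t["run"] == run]
        return t

    def runs_with_condition(self, condition) -> list:
        return sorted(self.table.loc[self.table["condition"] == condition, "run"].unique())

    def observation_labels(
        self, run_id: np.ndarray, lag_observations: int = 0, fill: str = "rest"
    ) -> np.ndarray:
        """Per-observation condition labels, intervals shifted by a lag.

        Observations not covered by any (shifted) interval get ``fill``.
        Shifted intervals are clipped at the end of their run.
        """
        run_id = np.asarray(run_id, dtype=int)
        labels = np.full(run_id.shape[0], fill, dtype=object)
        for run in np.unique(run_id):
            where = np.flatnonzero(run_id == run)
            start, length = int(where[0]), where.size
            for _, row in self.rows_for(run=run).iterrows():
                lo = int(row["onset"]) + lag_observations
                hi = lo + int(row["duration"])
                lo, hi = max(lo, 0), min(hi, length)
                if lo < hi:
                    labels[start + lo : start + hi] = row["condition"]
        return labels


def mask_voxel_coordinates(mask: np.ndarray) -> np.ndarray:
    """Coordinates of nonzero mask voxels, ascending with x fastest.

    Returns an ``(n, 3)`` integer array.  The ordering key is the
    linearized coordinate ``x + nx*(y + ny*z)``, i.e. Fortran order.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    coords = np.argwhere(mask != 0)
    if coords.shape[0] == 0:
        raise ValueError("mask is empty (no nonzero voxels)")
    nx, ny, _ = mask.shape
    lin = coords[:, 0] + nx * (coords[:, 1] + ny * coords[:, 2])
    return coords[np.argsort(lin, kind="stable")]


def flatten_volume(data: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a 3-D or 4-D volume to (values, voxel_index) under a mask."""
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask)
    if data.shape[:3] != mask.shape:
        raise ValueError(
            f"grid mismatch: data grid {data.shape[:3]} vs mask {mask.shape}"
        )
    coords = mask_voxel_coordinates(mask)
    values = data[coords[:, 0], coords[:, 1], coords[:, 2]]
    if values.ndim == 1:
        values = values[:, None]
    return values, coords


def unflatten_to_volume(
    values: np.ndarray, voxel_index: np.ndarray, shape: tuple, fill: float = 0.0
) -> np.ndarray:
    """Inverse of :func:`flatten_volume` on the masked voxels."""
    values = np.asarray(values)
    voxel_index = np.asarray(voxel_index, dtype=int)
    out_shape = tuple(shape) + tuple(values.shape[1:])
    out = np.full(out_shape, fill, dtype=float)
    out[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = values
    return out


def read_volume_series(series_path, mask_path, tr_seconds: float | None = None) -> VoxelTimeSeries:
    """Load a 4-D NIfTI series and a 3-D mask into a :class:`VoxelTimeSeries`.

    One row per nonzero mask voxel; rows ordered by ascending linearized
    coordinate with x fastest; ``L`` = number of volumes.
    """
    img = nib.load(str(series_path))
    mask_img = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"series must be 4-D, got {data.ndim}-D")
    mask = np.asarray(mask_img.dataobj)
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3-D, got {mask.ndim}-D")
    if data.shape[:3] != mask.shape:
        raise ValueError(f"grid mismatch: series {data.shape[:3]} vs mask {mask.shape}")
    values, coords = flatten_volume(data, mask)
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return VoxelTimeSeries(values=values, voxel_index=coords, tr_seconds=tr_seconds)


def read_matrix_series(path, delimiter: str = "\t", tr_seconds: float = 2.0) -> VoxelTimeSeries:
    """Read a delimited text matrix (voxels in rows, observations in columns).

    Synthetic coordinates ``(i, 0, 0)`` are assigned, so spatial
    operations (searchlight, mask output) are not meaningful for data
    loaded this way.
    """
    values = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    coords = np.stack(
        [np.arange(values.shape[0]), np.zeros(values.shape[0], int), np.zeros(values.shape[0], int)],
        axis=1,
    )
    return VoxelTimeSeries(values=values, voxel_index=coords, tr_seconds=tr_seconds)


def write_selection_mask(selection, reference_mask_path, out_path) -> None:
    """Write selected voxels as a binary NIfTI mask on the reference grid.

    ``selection`` may be a SelectedFeatures-like object with ``.indices``
    or a plain index sequence; indices refer to rows of the flattened
    reference mask (same ordering as :func:`read_volume_series`).
    """
    indices = np.asarray(getattr(selection, "indices", selection), dtype=int)
    ref = nib.load(str(reference_mask_path))
    mask = np.asarray(ref.dataobj)
    coords = mask_voxel_coordinates(mask)
    if indices.size and (indices.min() < 0 or indices.max() >= coords.shape[0]):
        raise ValueError(
            f"selection index out of mask range [0, {coords.shape[0] - 1}]"
        )
    out = np.zeros(mask.shape, dtype=np.uint8)
    sel = coords[indices]
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = 1
    nib.save(nib.Nifti1Image(out, ref.affine, ref.header), str(out_path))


def detrend_linear(ts: VoxelTimeSeries) -> VoxelTimeSeries:
    """Remove the per-run least-squares line (intercept + slope) per voxel.

    Each run is detrended independently; the residual of every voxel has
    zero mean and zero linear trend within each run.  Idempotent.
    """
    out = ts.values.copy()
    for run in ts.runs:
        sl = ts.run_slice(int(run))
        if sl.stop - sl.start < 3:
            raise ValueError(f"run {run} has fewer than 3 observations; cannot detrend")
        out[:, sl] = signal.detrend(out[:, sl], axis=1, type="linear")
    return replace(ts, values=out)
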