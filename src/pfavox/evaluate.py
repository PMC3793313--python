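"""Decoding evaluation: trial patterns, cross-validated SVM, similarity
matrices, and the paired Wilcoxon signed-rank comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .baselines import BLANK_LABEL, CONTROL_LABEL
from .io import DesignTable, VoxelTimeSeries

__all__ = [
    "PatternSet",
    "CVResult",
    "SimilarityMatrix",
    "extract_patterns",
    "cv_svm_accuracy",
    "similarity_matrix",
    "within_between_contrast",
    "wilcoxon_signed_rank",
]

_NON_STIMULUS = {CONTROL_LABEL, BLANK_LABEL, "rest", "unlabeled"}


@dataclass
class PatternSet:
    """m stimulus patterns over p selected voxels, with category labels."""

    patterns: np.ndarray
    labels: np.ndarray
    subject_id: str | None = None
    run_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.patterns.ndim != 2 or self.patterns.shape[0] != self.labels.shape[0]:
            raise ValueError("patterns and labels misaligned")
        if not np.all(np.isfinite(self.patterns)):
            raise ValueError("patterns contain non-finite values")
        if self.run_id is not None:
            self.run_id = np.asarray(self.run_id, dtype=int)

    @property
    def m(self) -> int:
        return self.patterns.shape[0]


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    mean_accuracy: float
    n_folds: int
    seed: int


@dataclass
class SimilarityMatrix:
    """m x m pairwise linear-correlation matrix of centered patterns."""

    values: np.ndarray
    labels: np.ndarray


def extract_patterns(
    ts: VoxelTimeSeries,
    design: DesignTable,
    selection,
    window_observations: int = 2,
    lag_observations: int = 1,
    subject_id: str | None = None,
) -> PatternSet:
    """One pattern per stimulus trial: the mean signal of the selected
    voxels over the trial's lag-shifted window.

    Control/blank intervals are skipped.  The window starts
    ``lag_observations`` after trial onset and spans
    ``window_observations`` observations; a window running past the end
    of its run is an error.
    """
    if window_observations < 1:
        raise ValueError("window_observations must be >= 1")
    indices = np.asarray(getattr(selection, "indices", selection), dtype=int)
    if indices.size and (indices.min() < 0 or indices.max() >= ts.n_voxels):
        raise ValueError("selection index out of range")
    patterns, labels, runs = [], [], []
    for _, row in design.table.iterrows():
        cond = row["condition"]
        if cond in _NON_STIMULUS:
            continue
        run = int(row["run"])
        sl = ts.run_slice(run)
        run_len = sl.stop - sl.start
        lo = int(row["onset"]) + lag_observations
        hi = lo + window_observations
        if lo < 0 or hi > run_len:
            raise ValueError(
                f"trial window [{lo}, {hi}) exceeds run {run} length {run_len}"
            )
        seg = ts.values[np.ix_(indices, np.arange(sl.start + lo, sl.start + hi))]
        patterns.append(seg.mean(axis=1))
        labels.append(cond)
        runs.append(run)
    if not patterns:
        raise ValueError("design contains no stimulus trials")
    return PatternSet(
        patterns=np.array(patterns),
        labels=np.array(labels, dtype=object),
        subject_id=subject_id,
        run_id=np.array(runs),
    )


def cv_svm_accuracy(ps: PatternSet, n_folds: int = 5, seed: int = 0) -> CVResult:
    """Stratified k-fold linear-SVM classification accuracy.

    Per fold, a linear soft-margin SVM (one-vs-rest, C=1) is trained on
    the remaining portions with features standardized by the training
    split's mean/SD and scored on the held-out portion.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = np.asarray([str(v) for v in ps.labels])
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(ps.patterns, y):
        if np.unique(y[train]).size != classes.size:
            raise ValueError(
                "a class is absent from a training split; "
                "use a different seed or fewer folds"
            )
        scaler = StandardScaler().fit(ps.patterns[train])
        clf = LinearSVC(C=1.0, max_iter=10000)
        clf.fit(scaler.transform(ps.patterns[train]), y[train])
        accs.append(float(np.mean(clf.predict(scaler.transform(ps.patterns[test])) == y[test])))
    accs = np.array(accs)
    return CVResult(fold_accuracies=accs, mean_accuracy=float(accs.mean()),
                    n_folds=n_folds, seed=seed)


def similarity_matrix(ps: PatternSet) -> SimilarityMatrix:
    """Pairwise correlation of patterns after per-voxel mean-centering.

    Every voxel's mean response across all patterns is subtracted before
    correlating, so similarities reflect deviations from the grand mean
    pattern rather than shared baseline activation.
    """
    if ps.m < 2:
        raise ValueError("need at least 2 patterns")
    centered = ps.patterns - ps.patterns.mean(axis=0, keepdims=True)
    sd = centered.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance centered pattern(s): stimuli {dead.tolist()}")
    values = np.corrcoef(centered)
    values = np.clip(0.5 * (values + values.T), -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values=values, labels=ps.labels.copy())


def within_between_contrast(sm: SimilarityMatrix) -> float:
    """Mean within-category correlation (off-diagonal) minus mean
    between-category correlation."""
    labels = np.asarray(sm.labels)
    cats, counts = np.unique(labels.astype(str), return_counts=True)
    if cats.size < 2:
        raise ValueError("need at least 2 categories")
    if (counts < 2).any():
        bad = cats[counts < 2].tolist()
        raise ValueError(f"categories with a single pattern: {bad}")
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(labels.size, dtype=bool)
    within = sm.values[same & off].mean()
    between = sm.values[~same].mean()
    return float(within - between)


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = stats.rankdata(np.abs(d))  # average ranks on ties
    return float(ranks[d > 0].sum()), ranks


def _exact_sf_table(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Distribution of W+ over all sign assignments.

    Returns (counts over achievable 2*W+ values, total 2**m).  Ranks are
    doubled so tied average ranks (halves) become integers.
    """
    scaled = np.round(2 * ranks).astype(int)
    total = scaled.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled:  # scaled ranks are always >= 2
        counts[r:] = counts[r:] + counts[:-r]
    return counts, 2 ** len(scaled)


def wilcoxon_signed_rank(
    paired_a, paired_b, alternative: str = "greater"
) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; tied absolute differences get average
    ranks.  The statistic is W+, the rank sum of positive differences.
    For up to 25 nonzero differences the p-value comes from the exact
    distribution over all sign assignments; beyond that, a normal
    approximation with tie correction and continuity correction is used.
    ``alternative='greater'`` tests whether ``a`` tends to exceed ``b``.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = a - b
    d = d[d != 0]
    m = d.size
    if m == 0:
        raise ValueError("all differences are zero")
    w, ranks = _signed_rank_statistic(d)

    if m <= 25:
        counts, total = _exact_sf_table(ranks)
        w2 = int(round(2 * w))
        p_greater = counts[w2:].sum() / total
        p_less = counts[: w2 + 1].sum() / total
    else:
        mean = m * (m + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = m * (m + 1) * (2 * m + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        sd = np.sqrt(var)
        p_greater = float(stats.norm.sf((w - mean - 0.5) / sd))
        p_less = float(stats.norm.cdf((w - mean + 0.5) / sd))

    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return w, float(min(p, 1.0))
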