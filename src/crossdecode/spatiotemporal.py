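"""Searchlight decoding, temporal generalization and peak-to-diagonal statistics.

Searchlights repeat the cross-decoding analysis in a small neighborhood
around every measurement site: a sphere of grid radius 4 around each voxel
(257 voxels when complete), or the 5 channels closest to each EEG channel.

Temporal generalization trains at one time point and tests at every other,
across background conditions (train no-clutter, test high-clutter), on a
10 ms grid over the -100...600 ms peri-stimulus window.  The signed
peak-to-diagonal distance quantifies whether the matrix peak lies below the
diagonal (test later than train: positive) — evidence for a shared but
delayed processing stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Literal, Optional, Tuple

import numpy as np

from .decoding import (
    ClassifierSpec,
    IncompleteDesignError,
    TimecourseResult,
    _acc,
    _balance,
    _bin_indices,
    _cell_conditions,
    _fit,
    _group_by_condition,
    cross_decode_roi,
    cross_decode_timecourse,
)
from .design import PairScheme, classification_cells
from .simulate import EEGEpochSet, FMRIPatternSet

__all__ = [
    "GeneralizationMatrix",
    "PeakShift",
    "SearchlightVolume",
    "SearchlightChannelMap",
    "sphere_offsets",
    "searchlight_volume",
    "searchlight_channels",
    "downsample_time",
    "temporal_generalization",
    "peak_to_diagonal",
    "diagonal_difference",
    "find_peak_latency",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class GeneralizationMatrix:
    """Train-time x test-time accuracy matrix (percent, chance 50)."""

    accuracy: np.ndarray  # (n_train_times, n_test_times)
    train_axis_ms: np.ndarray
    test_axis_ms: np.ndarray
    train_condition: str
    test_condition: str
    n_cells_averaged: int = 0


@dataclass
class PeakShift:
    """Signed perpendicular distance of a matrix peak from the diagonal.

    p_x is the test-axis peak time, p_y the train-axis peak time;
    b_x = (p_x + p_y) / 2 is the diagonal foot; d_euclidean is negative
    when p_x < p_y (peak above the diagonal).
    """

    p_x: float
    p_y: float
    b_x: float
    d_euclidean: float
    tied: bool = False


@dataclass
class SearchlightVolume:
    """Per-voxel decoding accuracy on the input grid (NaN where unevaluated)."""

    accuracy: np.ndarray  # 3-D grid
    sphere_radius: int
    clutter: str
    target: str


@dataclass
class SearchlightChannelMap:
    """Per-channel x down-sampled-time decoding accuracy."""

    accuracy: np.ndarray  # (n_channels, n_timebins)
    time_ms: np.ndarray
    neighborhood_size: int
    clutter: str
    target: str


# --------------------------------------------------------------------------
# voxel-space searchlight
# --------------------------------------------------------------------------

def sphere_offsets(radius: int) -> np.ndarray:
    """Integer offsets with squared norm <= radius^2 (257 at radius 4)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius)
    grid = np.arange(-r, r + 1)
    xx, yy, zz = np.meshgrid(grid, grid, grid, indexing="ij")
    keep = xx**2 + yy**2 + zz**2 <= r**2
    return np.stack([xx[keep], yy[keep], zz[keep]], axis=1)


def searchlight_volume(
    patterns: FMRIPatternSet,
    target: Literal["location", "category"],
    clutter: str,
    scheme: PairScheme,
    radius: int = 4,
    seed: int = 0,
    classifier: ClassifierSpec = ClassifierSpec(),
    n_pseudo_runs: int = 5,
) -> SearchlightVolume:
    """Sphere searchlight: cross-decoding on the voxels within grid distance
    ``radius`` of each voxel, stored at the sphere centre.

    The pseudo-run binning is fixed by ``seed`` and therefore identical for
    every sphere of one subject.
    """
    coords = np.asarray(patterns.voxel_coords, dtype=int)
    shape = tuple(coords.max(axis=0) + 1)
    index_of: Dict[Tuple[int, int, int], int] = {
        tuple(c): i for i, c in enumerate(coords)
    }
    offsets = sphere_offsets(radius)
    accuracy = np.full(shape, np.nan)
    for center in coords:
        neighbors = center[None, :] + offsets
        vox = [
            index_of[t]
            for t in map(tuple, neighbors)
            if t in index_of
        ]
        result = cross_decode_roi(
            patterns,
            roi=None,
            target=target,
            clutter=clutter,
            scheme=scheme,
            seed=seed,
            n_pseudo_runs=n_pseudo_runs,
            classifier=classifier,
            voxel_indices=np.asarray(vox),
        )
        accuracy[tuple(center)] = result.accuracy
    return SearchlightVolume(
        accuracy=accuracy, sphere_radius=radius, clutter=clutter, target=target
    )


# --------------------------------------------------------------------------
# channel-space searchlight
# --------------------------------------------------------------------------

def searchlight_channels(
    epochs: EEGEpochSet,
    target: Literal["location", "category"],
    clutter: str,
    scheme: PairScheme,
    k: int = 5,
    seed: int = 0,
    n_iterations: int = 100,
    step_ms: float = 10.0,
    include_center: bool = False,
    classifier: ClassifierSpec = ClassifierSpec(),
) -> SearchlightChannelMap:
    """Channel searchlight: time-resolved cross-decoding on the k channels
    closest to each channel c (excluding c itself by default, reading
    "surrounding" literally; set ``include_center`` to add c), stored at c,
    with the time axis down-sampled to ``step_ms`` bins.
    """
    layout = np.asarray(epochs.channel_layout, dtype=float)
    n_channels = layout.shape[0]
    if k >= n_channels:
        raise ValueError("k must be smaller than the channel count")
    d = np.linalg.norm(layout[:, None, :] - layout[None, :, :], axis=-1)
    off_diag = d[~np.eye(n_channels, dtype=bool)]
    if np.any(off_diag == 0):
        raise ValueError("duplicate channel positions make neighborhoods ambiguous")
    maps = []
    time_ds = None
    for c in range(n_channels):
        order = np.argsort(d[c], kind="stable")
        neighbors = [i for i in order if i != c][:k]
        if include_center:
            neighbors = [c] + neighbors
        nbr = np.asarray(neighbors)
        sub = EEGEpochSet(
            data=epochs.data[:, nbr, :],
            labels=list(epochs.labels),
            time_ms=epochs.time_ms,
            channel_layout=layout[nbr],
        )
        course = cross_decode_timecourse(
            sub,
            target=target,
            clutter=clutter,
            scheme=scheme,
            n_iterations=n_iterations,
            seed=seed,
            classifier=classifier,
        )
        acc_ds, time_ds = downsample_time(course.accuracy, course.index, step_ms)
        maps.append(acc_ds)
    return SearchlightChannelMap(
        accuracy=np.stack(maps),
        time_ms=time_ds,
        neighborhood_size=k,
        clutter=clutter,
        target=target,
    )


# --------------------------------------------------------------------------
# time-axis resampling
# --------------------------------------------------------------------------

def downsample_time(
    values: np.ndarray, time_ms: np.ndarray, step_ms: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Down-sample the trailing time axis to ``step_ms`` by non-overlapping
    bin means; the returned axis holds bin centres.  A trailing remainder
    shorter than one bin is dropped.
    """
    values = np.asarray(values)
    time_ms = np.asarray(time_ms, dtype=float)
    dt = float(time_ms[1] - time_ms[0])
    factor = step_ms / dt
    if factor < 1 or abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"step {step_ms} ms must be an integer multiple of the native "
            f"resolution {dt} ms"
        )
    factor = int(round(factor))
    n_bins = values.shape[-1] // factor
    if n_bins == 0:
        raise ValueError("fewer samples than one bin")
    trimmed = values[..., : n_bins * factor]
    binned = trimmed.reshape(*values.shape[:-1], n_bins, factor).mean(axis=-1)
    centers = time_ms[: n_bins * factor].reshape(n_bins, factor).mean(axis=-1)
    return binned, centers


def _grid_resample(
    data: np.ndarray, time_ms: np.ndarray, grid: np.ndarray, step_ms: float
) -> np.ndarray:
    """Average samples into bins of width ``step_ms`` centred on grid points."""
    out = np.empty(data.shape[:-1] + (len(grid),), dtype=float)
    half = step_ms / 2.0
    for i, g in enumerate(grid):
        sel = (time_ms >= g - half) & (time_ms < g + half)
        if not np.any(sel):
            raise ValueError(f"no samples within {step_ms} ms of grid point {g} ms")
        out[..., i] = data[..., sel].mean(axis=-1)
    return out


# --------------------------------------------------------------------------
# temporal generalization
# --------------------------------------------------------------------------

def temporal_generalization(
    epochs_train: EEGEpochSet,
    epochs_test: EEGEpochSet,
    target: Literal["location", "category"],
    scheme: PairScheme,
    train_clutter: str = "no",
    test_clutter: str = "high",
    window: Tuple[float, float] = (-100.0, 600.0),
    step_ms: float = 10.0,
    n_iterations: int = 100,
    seed: int = 0,
    n_bins: int = 4,
    classifier: ClassifierSpec = ClassifierSpec(),
) -> GeneralizationMatrix:
    """Cross-condition temporal generalization.

    Trains on ``n_bins - 1`` pseudo-trials from the train condition at every
    train-time on the grid and tests the held-out pseudo-trial from the test
    condition at every test-time, averaging the full scheme x iterations per
    matrix entry.  The default -100...600 ms window at 10 ms steps yields a
    71 x 71 matrix.
    """
    if epochs_train.n_channels != epochs_test.n_channels:
        raise ValueError("train and test sets must share the channel space")
    if not np.allclose(epochs_train.time_ms, epochs_test.time_ms):
        raise ValueError("train and test sets must share the time axis")
    t0, t1 = window
    tmin, tmax = float(epochs_train.time_ms[0]), float(epochs_train.time_ms[-1])
    if t0 < tmin - epochs_train.dt_ms / 2 or t1 > tmax + epochs_train.dt_ms / 2:
        raise ValueError(f"window {window} outside epoch range ({tmin}, {tmax})")
    grid = np.arange(t0, t1 + step_ms / 2, step_ms)

    rng = np.random.default_rng(seed)
    groups_tr = _balance(
        _group_by_condition(epochs_train.labels, train_clutter), rng
    )
    groups_te = _balance(_group_by_condition(epochs_test.labels, test_clutter), rng)
    if not groups_tr or not groups_te:
        raise IncompleteDesignError("missing clutter level in train or test epochs")
    cells = classification_cells(scheme, target)
    for cell in cells:
        tr_a, tr_b, te_a, te_b = _cell_conditions(cell, target)
        for key, grp in ((tr_a, groups_tr), (tr_b, groups_tr)):
            if key not in grp:
                raise IncompleteDesignError(f"missing train condition {key}")
        for key, grp in ((te_a, groups_te), (te_b, groups_te)):
            if key not in grp:
                raise IncompleteDesignError(f"missing test condition {key}")

    data_tr = _grid_resample(
        np.asarray(epochs_train.data, dtype=np.float64), epochs_train.time_ms, grid, step_ms
    )
    data_te = _grid_resample(
        np.asarray(epochs_test.data, dtype=np.float64), epochs_test.time_ms, grid, step_ms
    )

    used_tr: list = []
    used_te: list = []
    for cell in cells:
        conds = _cell_conditions(cell, target)
        for k in conds[:2]:
            if k not in used_tr:
                used_tr.append(k)
        for k in conds[2:]:
            if k not in used_te:
                used_te.append(k)
    n_grid = len(grid)
    acc_sum = np.zeros((n_grid, n_grid))
    truth = np.repeat([0, 1], n_grid)  # test pairs stacked per class
    for _ in range(n_iterations):
        pseudo_tr = {}
        for key in used_tr:
            bins = _bin_indices(rng, groups_tr[key], n_bins)
            pseudo_tr[key] = np.stack([data_tr[b].mean(axis=0) for b in bins])
        pseudo_te = {}
        for key in used_te:
            bins = _bin_indices(rng, groups_te[key], n_bins)
            pseudo_te[key] = np.stack([data_te[b].mean(axis=0) for b in bins])
        for cell in cells:
            tr_a, tr_b, te_a, te_b = _cell_conditions(cell, target)
            # held-out pseudo-trials from the test condition, all test times
            test_X = np.concatenate(
                [
                    pseudo_te[te_a][n_bins - 1].T,  # (n_grid, channels)
                    pseudo_te[te_b][n_bins - 1].T,
                ]
            )
            for ti in range(n_grid):
                train_X = np.concatenate(
                    [
                        pseudo_tr[tr_a][: n_bins - 1, :, ti],
                        pseudo_tr[tr_b][: n_bins - 1, :, ti],
                    ]
                )
                pred = _fit(train_X, classifier).predict(test_X)
                correct = (pred == truth).reshape(2, n_grid)
                acc_sum[ti] += correct.mean(axis=0) * 100.0
    accuracy = acc_sum / (len(cells) * n_iterations)
    return GeneralizationMatrix(
        accuracy=accuracy,
        train_axis_ms=grid,
        test_axis_ms=grid.copy(),
        train_condition=train_clutter,
        test_condition=test_clutter,
        n_cells_averaged=len(cells) * n_iterations,
    )


# --------------------------------------------------------------------------
# peak statistics
# --------------------------------------------------------------------------

def peak_to_diagonal(
    matrix: GeneralizationMatrix,
    peak_window: Tuple[float, float] = (0.0, 600.0),
) -> PeakShift:
    """Locate the post-stimulus matrix maximum and its signed perpendicular
    distance from the train-time = test-time diagonal.

    b_x = (p_x + p_y) / 2; d = sqrt((p_x - b_x)^2 + (p_y - b_x)^2), negated
    when p_x < p_y (peak above the diagonal).  Exact ties are broken to the
    entry closest to the diagonal, then to the earliest train time, and
    flagged in the output.
    """
    lo, hi = peak_window
    tr_sel = (matrix.train_axis_ms >= lo) & (matrix.train_axis_ms <= hi)
    te_sel = (matrix.test_axis_ms >= lo) & (matrix.test_axis_ms <= hi)
    if not np.any(tr_sel) or not np.any(te_sel):
        raise ValueError(f"peak window {peak_window} outside matrix axes")
    sub = matrix.accuracy[np.ix_(tr_sel, te_sel)]
    tr_times = matrix.train_axis_ms[tr_sel]
    te_times = matrix.test_axis_ms[te_sel]
    peak_val = np.max(sub)
    ii, jj = np.nonzero(sub == peak_val)
    tied = len(ii) > 1
    if tied:
        dist = np.abs(te_times[jj] - tr_times[ii])
        order = np.lexsort((te_times[jj], tr_times[ii], dist))
        best = order[0]
    else:
        best = 0
    p_y = float(tr_times[ii[best]])
    p_x = float(te_times[jj[best]])
    b_x = (p_x + p_y) / 2.0
    d = float(np.hypot(p_x - b_x, p_y - b_x))
    if p_x < p_y:
        d = -d
    return PeakShift(p_x=p_x, p_y=p_y, b_x=b_x, d_euclidean=d, tied=tied)


def diagonal_difference(matrix: GeneralizationMatrix) -> np.ndarray:
    """Below-minus-above-diagonal accuracy: out[i, j] = acc[i, j] - acc[j, i].

    The output is exactly antisymmetric with a zero diagonal; e.g. the entry
    at (train 100 ms, test 300 ms) holds that point's accuracy minus the
    accuracy of its mirror (train 300 ms, test 100 ms).
    """
    acc = np.asarray(matrix.accuracy)
    if acc.shape[0] != acc.shape[1]:
        raise ValueError("diagonal difference requires a square matrix")
    return acc - acc.T


def find_peak_latency(
    accuracy: np.ndarray, time_ms: np.ndarray, window: Tuple[float, float]
) -> float:
    """Time of the accuracy maximum within the window; ties go to the
    earliest time point."""
    time_ms = np.asarray(time_ms, dtype=float)
    lo, hi = window
    sel = (time_ms >= lo) & (time_ms <= hi)
    if not np.any(sel):
        raise ValueError(f"window {window} contains no time points")
    sub = np.asarray(accuracy, dtype=float)[sel]
    return float(time_ms[sel][int(np.argmax(sub))])
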