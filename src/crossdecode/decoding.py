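"""Pseudo-trial construction, noise normalization and the cross-decoding schemes.

All classification is binary c-support-vector classification with a linear
kernel (libsvm via scikit-learn), regularization constant 1, no feature
scaling — decoding operates on whitened channel vectors (EEG), t-value
patterns (fMRI) or unit activations (features) as-is.

The cross-decoding logic is shared across modalities: the classified factor
(e.g. location) is decoded pairwise while the training and testing sets come
from *different* levels of a transfer factor (e.g. category), so above-chance
accuracy indicates representations tolerant to the transfer factor.  Chance
level is 50% throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from sklearn.covariance import LedoitWolf
from sklearn.svm import SVC

from .design import DesignSpec, PairScheme, classification_cells
from .simulate import EEGEpochSet, FMRIPatternSet, FeatureActivationSet

__all__ = [
    "ClassifierSpec",
    "PseudoTrialSet",
    "DecodingResult",
    "TimecourseResult",
    "DegenerateTrainingError",
    "InfeasibleBinningError",
    "IncompleteDesignError",
    "noise_normalize",
    "bin_pseudotrials",
    "train_test_linear",
    "cross_decode_roi",
    "cross_decode_timecourse",
    "cross_decode_features",
    "select_top_k_voxels",
]

CHANCE = 50.0


class DegenerateTrainingError(ValueError):
    """Training set contains fewer than two classes."""


class InfeasibleBinningError(ValueError):
    """Fewer raw trials than requested bins."""


class IncompleteDesignError(ValueError):
    """A condition cell required by the scheme is missing from the data."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Linear maximum-margin binary classifier; deterministic given its inputs."""

    regularization_constant: float = 1.0

    def make(self) -> SVC:
        return SVC(kernel="linear", C=self.regularization_constant)


@dataclass
class DecodingResult:
    """One averaged cross-decoding accuracy (percent, chance 50)."""

    accuracy: float
    index: object  # ROI name, time in ms, or layer name
    clutter: str
    target: str
    n_cells_averaged: int
    chance: float = CHANCE
    cell_accuracy: Optional[Dict] = None  # per scheme cell, if requested


@dataclass
class TimecourseResult:
    """Accuracy resolved over an ordered index axis (time points or layers)."""

    accuracy: np.ndarray
    index: np.ndarray  # time in ms, or layer names
    clutter: str
    target: str
    n_cells_averaged: int
    chance: float = CHANCE
    cell_accuracy: Optional[np.ndarray] = None  # index x cells, if requested
    cell_index: Optional[list] = None

    def at(self, i: int) -> DecodingResult:
        return DecodingResult(
            accuracy=float(self.accuracy[i]),
            index=self.index[i],
            clutter=self.clutter,
            target=self.target,
            n_cells_averaged=self.n_cells_averaged,
        )


# --------------------------------------------------------------------------
# noise normalization
# --------------------------------------------------------------------------

def noise_normalize(
    epochs: EEGEpochSet, max_samples: int = 200_000
) -> EEGEpochSet:
    """Multivariate noise normalization: whiten channels by the inverse
    square root of the shrinkage-regularized noise covariance.

    The noise covariance is estimated from within-condition residuals
    (trial minus condition mean, per time point), pooled over time points and
    conditions, with Ledoit-Wolf analytic shrinkage toward the scaled
    identity.  Shapes are preserved.
    """
    data = np.asarray(epochs.data, dtype=np.float64)
    n_trials, n_channels, n_time = data.shape
    keys = [
        (lab.category, lab.location, lab.clutter, lab.exemplar)
        for lab in epochs.labels
    ]
    residuals = np.empty_like(data)
    for key in set(keys):
        idx = [i for i, k in enumerate(keys) if k == key]
        if len(idx) < 2:
            raise ValueError("noise normalization needs >= 2 trials per condition")
        residuals[idx] = data[idx] - data[idx].mean(axis=0, keepdims=True)
    samples = residuals.transpose(0, 2, 1).reshape(-1, n_channels)
    if samples.shape[0] > max_samples:
        stride = int(np.ceil(samples.shape[0] / max_samples))
        samples = samples[::stride]
    lw = LedoitWolf(assume_centered=True).fit(samples)
    evals, evecs = np.linalg.eigh(lw.covariance_)
    evals = np.maximum(evals, 1e-12)
    whitener = evecs @ np.diag(evals**-0.5) @ evecs.T
    out = np.einsum("ij,tjk->tik", whitener, data).astype(epochs.data.dtype)
    return EEGEpochSet(
        data=out,
        labels=list(epochs.labels),
        time_ms=epochs.time_ms,
        channel_layout=epochs.channel_layout,
    )


# --------------------------------------------------------------------------
# pseudo-trials
# --------------------------------------------------------------------------

@dataclass
class PseudoTrialSet:
    """Averaged pseudo-trials plus the raw-trial -> pseudo-trial assignment."""

    data: np.ndarray  # pseudo-trials x features (or x ... feature dims)
    labels: list
    bin_assignment: np.ndarray  # per raw trial, index of its pseudo-trial row
    seed: int


def _bin_indices(
    rng: np.random.Generator, indices: np.ndarray, n_bins: int
) -> List[np.ndarray]:
    """Random disjoint, exhaustive split of trial indices into near-equal bins."""
    if len(indices) < n_bins:
        raise InfeasibleBinningError(
            f"cannot split {len(indices)} trials into {n_bins} bins"
        )
    perm = rng.permutation(indices)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_bins)]


def bin_pseudotrials(
    data: np.ndarray, labels: Sequence, n_bins: int, seed: int
) -> PseudoTrialSet:
    """Average randomly assigned raw trials into pseudo-trials, per condition.

    The canonical EEG use averages 60 raw trials into four pseudo-trials of
    15 trials each; the fMRI variant averages 10 runs into five pseudo-runs
    of two runs.  Bins within a condition are disjoint and exhaustive.
    """
    data = np.asarray(data)
    rng = np.random.default_rng(seed)
    order: List = []
    for lab in labels:
        if lab not in order:
            order.append(lab)
    pseudo_rows = []
    pseudo_labels = []
    assignment = np.full(len(labels), -1, dtype=int)
    for lab in order:
        idx = np.array([i for i, l in enumerate(labels) if l == lab])
        for bin_idx in _bin_indices(rng, idx, n_bins):
            assignment[bin_idx] = len(pseudo_rows)
            pseudo_rows.append(data[bin_idx].mean(axis=0))
            pseudo_labels.append(lab)
    return PseudoTrialSet(
        data=np.stack(pseudo_rows),
        labels=pseudo_labels,
        bin_assignment=assignment,
        seed=int(seed),
    )


# --------------------------------------------------------------------------
# classifier contract
# --------------------------------------------------------------------------

def train_test_linear(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
) -> float:
    """Train the linear SVM and return percent correct on the test set."""
    train_y = np.asarray(train_y)
    test_y = np.asarray(test_y)
    classes = np.unique(train_y)
    if len(classes) != 2:
        raise DegenerateTrainingError(
            f"binary classification requires 2 training classes, got {len(classes)}"
        )
    clf = spec.make()
    clf.fit(np.asarray(train_X), train_y)
    pred = clf.predict(np.asarray(test_X))
    return float(np.mean(pred == test_y) * 100.0)


def _fit(train_X: np.ndarray, spec: ClassifierSpec) -> SVC:
    n = train_X.shape[0] // 2
    clf = spec.make()
    clf.fit(train_X, np.repeat([0, 1], n))
    return clf


def _acc(clf: SVC, test_X: np.ndarray) -> float:
    pred = clf.predict(test_X)
    half = test_X.shape[0] // 2
    truth = np.repeat([0, 1], half)
    return float(np.mean(pred == truth) * 100.0)


# --------------------------------------------------------------------------
# scheme plumbing shared by the modalities
# --------------------------------------------------------------------------

def _cell_conditions(
    cell: Tuple[Tuple[str, str], Tuple[str, str]], target: str
) -> Tuple[Tuple, Tuple, Tuple, Tuple]:
    """Map one scheme cell to its four (category, location) condition keys:
    (train_a, train_b, test_a, test_b)."""
    (a, b), (lvl_train, lvl_test) = cell
    if target == "location":
        return ((lvl_train, a), (lvl_train, b), (lvl_test, a), (lvl_test, b))
    return ((a, lvl_train), (b, lvl_train), (a, lvl_test), (b, lvl_test))


def _group_by_condition(
    labels: Sequence, clutter: str
) -> Dict[Tuple[str, str], np.ndarray]:
    groups: Dict[Tuple[str, str], list] = {}
    for i, lab in enumerate(labels):
        if lab.clutter == clutter:
            groups.setdefault((lab.category, lab.location), []).append(i)
    return {k: np.asarray(v) for k, v in groups.items()}


def _balance(groups: Dict, rng: np.random.Generator) -> Dict:
    """Subsample every condition to the common minimum trial count."""
    n_min = min(len(v) for v in groups.values())
    out = {}
    for k, v in groups.items():
        if len(v) > n_min:
            out[k] = np.sort(rng.choice(v, size=n_min, replace=False))
        else:
            out[k] = v
    return out


def _decode_pointwise(
    get_features,
    n_points: int,
    groups: Dict[Tuple[str, str], np.ndarray],
    cells: list,
    target: str,
    n_iterations: int,
    n_bins: int,
    rng: np.random.Generator,
    spec: ClassifierSpec,
    collect_cells: bool,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Shared engine: bin pseudo-trials per iteration, train on ``n_bins - 1``
    pseudo-trials per class from the train level of the transfer factor, test
    on the held-out pseudo-trial from the test level, for every cell and
    point on the index axis (time points or layers).

    ``get_features(cond_trial_indices)`` must return an array
    (trials, features, n_points).
    """
    for cell in cells:
        for key in _cell_conditions(cell, target):
            if key not in groups:
                raise IncompleteDesignError(f"missing condition {key}")
    acc_sum = np.zeros(n_points)
    cell_sum = np.zeros((n_points, len(cells))) if collect_cells else None
    # ordered, deduplicated condition list: RNG consumption order must not
    # depend on set-hash order or results would vary across processes
    used: List = []
    for cell in cells:
        for key in _cell_conditions(cell, target):
            if key not in used:
                used.append(key)
    feats = {key: get_features(groups[key]) for key in used}
    for _ in range(n_iterations):
        pseudo = {}
        for key in used:
            bins = _bin_indices(rng, np.arange(feats[key].shape[0]), n_bins)
            pseudo[key] = np.stack(
                [feats[key][b].mean(axis=0) for b in bins]
            )  # (n_bins, features, n_points)
        for ci, cell in enumerate(cells):
            tr_a, tr_b, te_a, te_b = _cell_conditions(cell, target)
            for p in range(n_points):
                train_X = np.concatenate(
                    [pseudo[tr_a][: n_bins - 1, :, p], pseudo[tr_b][: n_bins - 1, :, p]]
                )
                test_X = np.stack(
                    [pseudo[te_a][n_bins - 1, :, p], pseudo[te_b][n_bins - 1, :, p]]
                )
                a = _acc(_fit(train_X, spec), test_X)
                acc_sum[p] += a
                if cell_sum is not None:
                    cell_sum[p, ci] += a
    acc = acc_sum / (len(cells) * n_iterations)
    if cell_sum is not None:
        cell_sum /= n_iterations
    return acc, cell_sum


# --------------------------------------------------------------------------
# the three cross-decoding schemes
# --------------------------------------------------------------------------

def cross_decode_timecourse(
    epochs: EEGEpochSet,
    target: Literal["location", "category"],
    clutter: str,
    scheme: PairScheme,
    n_iterations: int = 100,
    seed: int = 0,
    n_bins: int = 4,
    classifier: ClassifierSpec = ClassifierSpec(),
    return_cells: bool = False,
) -> TimecourseResult:
    """Time-resolved cross-decoding of ``target`` across the other factor.

    Per time point and iteration, raw trials of each condition are averaged
    into ``n_bins`` pseudo-trials; the SVM trains on ``n_bins - 1``
    pseudo-trials per class from the train level and tests on the held-out
    pseudo-trial from the test level.  Under the defaults this averages
    6 x 12 x 100 = 7,200 accuracies per time point.
    """
    rng = np.random.default_rng(seed)
    groups = _balance(_group_by_condition(epochs.labels, clutter), rng)
    if not groups:
        raise IncompleteDesignError(f"no trials with clutter level {clutter!r}")
    cells = classification_cells(scheme, target)
    data = np.asarray(epochs.data, dtype=np.float64)
    acc, cell_acc = _decode_pointwise(
        get_features=lambda idx: data[idx],
        n_points=data.shape[2],
        groups=groups,
        cells=cells,
        target=target,
        n_iterations=n_iterations,
        n_bins=n_bins,
        rng=rng,
        spec=classifier,
        collect_cells=return_cells,
    )
    return TimecourseResult(
        accuracy=acc,
        index=np.asarray(epochs.time_ms),
        clutter=clutter,
        target=target,
        n_cells_averaged=len(cells) * n_iterations,
        cell_accuracy=cell_acc,
        cell_index=cells if return_cells else None,
    )


def cross_decode_features(
    features: FeatureActivationSet,
    target: Literal["location", "category"],
    clutter: str,
    scheme: PairScheme,
    n_iterations: int = 100,
    seed: int = 0,
    n_bins: int = 4,
    classifier: ClassifierSpec = ClassifierSpec(),
    return_cells: bool = False,
) -> TimecourseResult:
    """Layer-wise cross-decoding; identical to the time-resolved scheme with
    layers in place of time points."""
    rng = np.random.default_rng(seed)
    groups = _balance(_group_by_condition(features.labels, clutter), rng)
    if not groups:
        raise IncompleteDesignError(f"no trials with clutter level {clutter!r}")
    cells = classification_cells(scheme, target)
    stacked = np.stack(
        [np.asarray(features.data[layer], dtype=np.float64) for layer in features.layer_names],
        axis=-1,
    )  # trials x units x layers
    acc, cell_acc = _decode_pointwise(
        get_features=lambda idx: stacked[idx],
        n_points=stacked.shape[2],
        groups=groups,
        cells=cells,
        target=target,
        n_iterations=n_iterations,
        n_bins=n_bins,
        rng=rng,
        spec=classifier,
        collect_cells=return_cells,
    )
    return TimecourseResult(
        accuracy=acc,
        index=np.asarray(features.layer_names, dtype=object),
        clutter=clutter,
        target=target,
        n_cells_averaged=len(cells) * n_iterations,
        cell_accuracy=cell_acc,
        cell_index=cells if return_cells else None,
    )


def cross_decode_roi(
    patterns: FMRIPatternSet,
    roi: Optional[str],
    target: Literal["location", "category"],
    clutter: str,
    scheme: PairScheme,
    seed: int = 0,
    n_pseudo_runs: int = 5,
    classifier: ClassifierSpec = ClassifierSpec(),
    voxel_indices: Optional[np.ndarray] = None,
    return_cells: bool = False,
) -> DecodingResult:
    """ROI cross-decoding with leave-one-pseudo-run-out cross-validation.

    Runs are randomly binned into ``n_pseudo_runs`` pseudo-runs (five bins of
    two runs under the defaults).  Per fold the SVM trains on the remaining
    pseudo-runs at the train level of the transfer factor and tests on the
    held-out pseudo-run at the test level.  Under the defaults this averages
    6 x 12 x 5 = 360 accuracies.
    """
    if voxel_indices is None:
        voxel_indices = patterns.roi_voxels(roi)
    rng = np.random.default_rng(seed)
    run_bins = _bin_indices(rng, np.arange(patterns.n_runs), n_pseudo_runs)
    cond_index: Dict[Tuple[str, str], int] = {}
    for ci, lab in enumerate(patterns.condition_labels):
        if lab.clutter == clutter:
            cond_index[(lab.category, lab.location)] = ci
    if not cond_index:
        raise IncompleteDesignError(f"no conditions with clutter level {clutter!r}")
    cells = classification_cells(scheme, target)
    for cell in cells:
        for key in _cell_conditions(cell, target):
            if key not in cond_index:
                raise IncompleteDesignError(f"missing condition {key}")
    data = np.asarray(patterns.data, dtype=np.float64)[:, :, voxel_indices]
    # pseudo-run patterns: (n_pseudo_runs, conditions, voxels)
    pseudo = np.stack([data[b].mean(axis=0) for b in run_bins])
    acc_sum = 0.0
    cell_sums: Dict = {cell: 0.0 for cell in cells} if return_cells else {}
    n_folds = n_pseudo_runs
    for fold in range(n_folds):
        train_runs = [r for r in range(n_pseudo_runs) if r != fold]
        for cell in cells:
            tr_a, tr_b, te_a, te_b = (
                cond_index[k] for k in _cell_conditions(cell, target)
            )
            train_X = np.concatenate(
                [pseudo[train_runs, tr_a, :], pseudo[train_runs, tr_b, :]]
            )
            test_X = np.stack([pseudo[fold, te_a, :], pseudo[fold, te_b, :]])
            a = _acc(_fit(train_X, classifier), test_X)
            acc_sum += a
            if return_cells:
                cell_sums[cell] += a
    result = DecodingResult(
        accuracy=acc_sum / (len(cells) * n_folds),
        index=roi,
        clutter=clutter,
        target=target,
        n_cells_averaged=len(cells) * n_folds,
    )
    if return_cells:
        result.cell_accuracy = {c: v / n_folds for c, v in cell_sums.items()}
    return result


# --------------------------------------------------------------------------
# voxel selection
# --------------------------------------------------------------------------

def select_top_k_voxels(
    statistic_map: np.ndarray, mask: np.ndarray, k: int
) -> np.ndarray:
    """Indices (k x 3) of the k largest statistic values within the mask.

    Ties are broken deterministically by ascending grid coordinate
    (C-order flat index).
    """
    statistic_map = np.asarray(statistic_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    flat_idx = np.flatnonzero(mask.ravel())
    if flat_idx.size == 0:
        raise ValueError("mask is empty")
    if k > flat_idx.size:
        raise ValueError(f"k={k} exceeds masked voxel count {flat_idx.size}")
    values = statistic_map.ravel()[flat_idx]
    order = np.lexsort((flat_idx, -values))
    chosen = flat_idx[order[:k]]
    return np.stack(np.unravel_index(chosen, statistic_map.shape), axis=1)
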