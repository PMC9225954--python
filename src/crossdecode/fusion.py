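"""RDV construction, EEG-fMRI representational fusion and group inference.

The representational dissimilarity vector (RDV) collects the pairwise
cross-decoding accuracies of every scheme cell — all location pairs crossed
with all ordered category train/test directions, 72 entries under the
default design — in one canonical order shared across modalities.  Higher
accuracy is read directly as higher dissimilarity (no distance transform).
Fusion correlates an EEG RDV (averaged over the time points inside the peak
latency's confidence interval, then over subjects) with subject-specific
fMRI ROI RDVs using Spearman's rank correlation.

Group inference: two-tailed Wilcoxon signed-rank tests against chance with
Benjamini-Hochberg FDR at q = 0.05; percentile bootstraps over subjects
(10,000 resamples) for peak-latency confidence intervals and latency
differences (one-tailed p = proportion of resampled differences <= 0); a
label-shuffle bootstrap null for searchlight peak distances; and the effect
sizes partial eta^2 = SS_effect / (SS_effect + SS_residual) and r = Z / sqrt(N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import PairScheme
from .spatiotemporal import find_peak_latency

__all__ = [
    "RDV",
    "BootstrapResult",
    "TestResult",
    "build_rdv",
    "canonical_rdv_index",
    "eeg_peak_rdv",
    "fuse_rdvs",
    "wilcoxon_vs_chance",
    "fdr_correct",
    "bootstrap_peak_ci",
    "bootstrap_difference",
    "bootstrap_searchlight_peak_distance",
    "partial_eta_squared",
    "signed_rank_effect_size",
    "UndefinedCorrelationError",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a rank correlation is undefined (constant input vector)."""


# --------------------------------------------------------------------------
# RDVs and fusion
# --------------------------------------------------------------------------

@dataclass
class RDV:
    """Representational dissimilarity vector of pairwise cross-decoding
    accuracies in canonical scheme-cell order."""

    values: np.ndarray
    entry_index: List[Tuple[Tuple[str, str], Tuple[str, str]]]
    modality: str = ""
    clutter: str = ""
    tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.entry_index):
            raise ValueError("values and entry_index must have equal length")


def canonical_rdv_index(
    scheme: PairScheme,
) -> List[Tuple[Tuple[str, str], Tuple[str, str]]]:
    """Canonical (location pair, category train->test pair) entry order.

    Location pairs vary slowest, ordered category pairs fastest, both in
    design order; 6 x 12 = 72 entries under the defaults.  The ordered
    category pairs enumerate each unordered pair in both transfer
    directions, so this equals the "six unordered pairs x two directions"
    count.
    """
    return [
        (lp, cp)
        for lp in scheme.location_pairs
        for cp in scheme.category_train_test_pairs
    ]


def build_rdv(
    pairwise_accuracies: Mapping[Tuple[Tuple[str, str], Tuple[str, str]], float],
    scheme: PairScheme,
    modality: str = "",
    clutter: str = "",
    tag: str = "",
) -> RDV:
    """Assemble an RDV from per-cell accuracies, without averaging entries."""
    index = canonical_rdv_index(scheme)
    values = []
    for cell in index:
        if cell not in pairwise_accuracies:
            raise KeyError(f"missing accuracy for scheme cell {cell}")
        values.append(float(pairwise_accuracies[cell]))
    return RDV(
        values=np.asarray(values),
        entry_index=index,
        modality=modality,
        clutter=clutter,
        tag=tag,
    )


def eeg_peak_rdv(
    time_resolved_rdvs: np.ndarray,
    time_ms: np.ndarray,
    peak_ci: Tuple[float, float],
    entry_index: List,
    clutter: str = "",
) -> RDV:
    """Group EEG RDV: mean over the time points inside the peak's 95% CI,
    then over subjects.

    ``time_resolved_rdvs`` has shape (subjects, time points, entries).
    """
    arr = np.asarray(time_resolved_rdvs, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    lo, hi = peak_ci
    sel = (time_ms >= lo) & (time_ms <= hi)
    if not np.any(sel):
        raise ValueError(f"peak CI window {peak_ci} contains no time points")
    group = arr[:, sel, :].mean(axis=1).mean(axis=0)
    return RDV(
        values=group,
        entry_index=list(entry_index),
        modality="eeg",
        clutter=clutter,
        tag="group",
    )


def fuse_rdvs(eeg_rdv: RDV, fmri_rdv: RDV) -> float:
    """Spearman rank correlation between two RDVs with identical entry order."""
    if eeg_rdv.entry_index != fmri_rdv.entry_index:
        raise ValueError("RDV entry orders differ; fusion requires identical order")
    for rdv in (eeg_rdv, fmri_rdv):
        if np.ptp(rdv.values) == 0:
            raise UndefinedCorrelationError(
                f"constant RDV ({rdv.modality or 'unnamed'}): rank correlation undefined"
            )
    rho = stats.spearmanr(eeg_rdv.values, fmri_rdv.values).statistic
    return float(rho)


# --------------------------------------------------------------------------
# group tests
# --------------------------------------------------------------------------

@dataclass
class TestResult:
    """One Wilcoxon signed-rank test against a null value."""

    p: float
    statistic: float
    n: int
    z: float
    degenerate: bool = False
    rejected: Optional[bool] = None
    p_adjusted: Optional[float] = None


def wilcoxon_vs_chance(values: Sequence[float], null_value: float) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test that the median of
    ``values - null_value`` is zero.

    Zero differences are dropped; the exact null distribution is used for
    small samples without ties, the normal approximation with continuity
    correction otherwise.  The normal-approximation Z is always reported for
    the r = Z / sqrt(N) effect size.
    """
    diffs = np.asarray(values, dtype=float) - float(null_value)
    n_total = len(diffs)
    if n_total < 5:
        raise ValueError("Wilcoxon test requires at least 5 subjects")
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        return TestResult(p=1.0, statistic=0.0, n=n_total, z=0.0, degenerate=True)
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", correction=True, method="auto"
    )
    n = len(nonzero)
    mu = n * (n + 1) / 4.0
    ranks = stats.rankdata(np.abs(nonzero))
    tie_counts = np.unique(ranks, return_counts=True)[1]
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    w_plus = float(np.sum(ranks[nonzero > 0]))
    z = (w_plus - mu) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    return TestResult(
        p=float(res.pvalue), statistic=float(res.statistic), n=n_total, z=float(z)
    )


def fdr_correct(
    p_values: Sequence[float], q: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up decisions at level q.

    Returns (reject flags, adjusted p-values); decisions are monotone in the
    raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# --------------------------------------------------------------------------
# bootstraps
# --------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    statistic: str
    estimate: float
    n_boot: int
    ci_low: float
    ci_high: float
    p: Optional[float] = None
    seed: int = 0
    samples: Optional[np.ndarray] = field(default=None, repr=False)


def _resample_indices(
    rng: np.random.Generator, n_subjects: int, n_boot: int
) -> np.ndarray:
    return rng.integers(0, n_subjects, size=(n_boot, n_subjects))


def bootstrap_peak_ci(
    subject_timecourses: np.ndarray,
    time_ms: np.ndarray,
    window: Tuple[float, float],
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile bootstrap CI for the group peak latency.

    Subjects are resampled with replacement; each resample's group-mean time
    course is peak-picked inside ``window``; the CI is the 2.5/97.5
    percentile of the resulting latency distribution.
    """
    courses = np.asarray(subject_timecourses, dtype=float)
    if courses.ndim != 2 or courses.shape[0] < 2:
        raise ValueError("need a (subjects x time) array with >= 2 subjects")
    rng = np.random.default_rng(seed)
    estimate = find_peak_latency(courses.mean(axis=0), time_ms, window)
    idx = _resample_indices(rng, courses.shape[0], n_boot)
    samples = np.array(
        [
            find_peak_latency(courses[row].mean(axis=0), time_ms, window)
            for row in idx
        ]
    )
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return BootstrapResult(
        statistic="peak_latency_ms",
        estimate=estimate,
        n_boot=n_boot,
        ci_low=float(lo),
        ci_high=float(hi),
        seed=int(seed),
        samples=samples,
    )


def bootstrap_difference(
    subject_courses_a: np.ndarray,
    subject_courses_b: np.ndarray,
    time_ms: np.ndarray,
    window: Tuple[float, float],
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Paired bootstrap of the peak-latency difference B - A.

    The same resampled subjects enter both group means; the one-tailed p is
    the proportion of resampled differences <= 0 (FDR correction across
    condition pairs is the caller's responsibility).
    """
    a = np.asarray(subject_courses_a, dtype=float)
    b = np.asarray(subject_courses_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired bootstrap requires equally shaped course arrays")
    rng = np.random.default_rng(seed)
    estimate = find_peak_latency(b.mean(axis=0), time_ms, window) - find_peak_latency(
        a.mean(axis=0), time_ms, window
    )
    idx = _resample_indices(rng, a.shape[0], n_boot)
    samples = np.array(
        [
            find_peak_latency(b[row].mean(axis=0), time_ms, window)
            - find_peak_latency(a[row].mean(axis=0), time_ms, window)
            for row in idx
        ]
    )
    lo, hi = np.percentile(samples, [2.5, 97.5])
    p = float(np.mean(samples <= 0))
    return BootstrapResult(
        statistic="peak_latency_difference_ms",
        estimate=float(estimate),
        n_boot=n_boot,
        ci_low=float(lo),
        ci_high=float(hi),
        p=p,
        seed=int(seed),
        samples=samples,
    )


def _group_peak_coords(maps: np.ndarray) -> np.ndarray:
    """Coordinates of the maximum of the subject-mean map (first in C order
    on exact ties)."""
    mean_map = maps.mean(axis=0)
    flat = int(np.argmax(mean_map))
    return np.asarray(np.unravel_index(flat, mean_map.shape), dtype=float)


def bootstrap_searchlight_peak_distance(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Label-shuffle null for the distance between two conditions' group
    searchlight peaks.

    The observed statistic is the Euclidean distance between the peak
    coordinates of the two subject-mean maps.  The null swaps the A/B labels
    of each subject at random and recomputes the distance; the one-tailed p
    is the proportion of null distances >= the observed one (Bonferroni
    correction across condition pairs is the caller's responsibility).
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share subjects and grid")
    if np.ptp(a.mean(axis=0)) == 0 or np.ptp(b.mean(axis=0)) == 0:
        raise ValueError("flat group map: peak undefined")
    rng = np.random.default_rng(seed)
    observed = float(np.linalg.norm(_group_peak_coords(a) - _group_peak_coords(b)))
    n_subjects = a.shape[0]
    samples = np.empty(n_boot)
    for i in range(n_boot):
        swap = rng.integers(0, 2, size=n_subjects).astype(bool)
        a_null = np.where(swap[(...,) + (None,) * (a.ndim - 1)], b, a)
        b_null = np.where(swap[(...,) + (None,) * (a.ndim - 1)], a, b)
        samples[i] = np.linalg.norm(
            _group_peak_coords(a_null) - _group_peak_coords(b_null)
        )
    p = float(np.mean(samples >= observed))
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return BootstrapResult(
        statistic="searchlight_peak_distance",
        estimate=observed,
        n_boot=n_boot,
        ci_low=float(lo),
        ci_high=float(hi),
        p=p,
        seed=int(seed),
        samples=samples,
    )


# --------------------------------------------------------------------------
# effect sizes
# --------------------------------------------------------------------------

def partial_eta_squared(ss_effect: float, ss_residual: float) -> float:
    """partial eta^2 = SS_effect / (SS_effect + SS_residual), in [0, 1]."""
    if ss_effect < 0 or ss_residual < 0:
        raise ValueError("sums of squares must be non-negative")
    total = ss_effect + ss_residual
    if total == 0:
        raise ValueError("partial eta^2 undefined when both sums of squares are zero")
    return float(ss_effect / total)


def signed_rank_effect_size(z: float, n: int) -> float:
    """Effect size r = Z / sqrt(N) for a signed-rank normal statistic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(z / np.sqrt(n))
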