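"""Synthetic EEG epochs, fMRI t-value patterns and layer-wise feature activations.

Every downstream stage of the pipeline is exercised on data from this module,
with planted, configurable location and category signals so that parameter
recovery can be checked against ground truth.

The generative model, per trial of condition (category, location, clutter):

``signal(t) = A_loc * topo(loc, cat) * g(t; lat_loc, w_loc)
            + A_cat * topo(cat, loc) * g(t; lat_cat, w_cat) + noise``

where ``g`` is a Gaussian bump (latency = mean, width = FWHM) and
``topo(loc, cat)`` mixes a *category-invariant* location topography with a
category-specific one according to ``invariant_fraction`` — the invariant part
is what cross-decoding across categories can transfer on.  Location
topographies embed the quadrant offsets through a (shared) random orthonormal
map, so pairwise pattern distances inherit the quadrant geometry; this gives
EEG, fMRI and feature data a common representational structure for the
fusion analyses to recover.  Noise is Gaussian with exponential spatial-decay
correlation over the 2-D channel layout and optional temporal smoothing.

fMRI patterns are simulated directly on the t-value scale (runs x conditions
x voxels), with a per-ROI x per-clutter SNR map so tests can plant, e.g.,
location information that survives clutter only in higher-level ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .design import (
    ConditionLabel,
    DesignSpec,
    InvalidDesignError,
    enumerate_conditions,
)

__all__ = [
    "SignalSpec",
    "NoiseSpec",
    "FMRIConfig",
    "FeatureConfig",
    "GeneratorConfig",
    "EEGEpochSet",
    "FMRIPatternSet",
    "FeatureActivationSet",
    "generate_eeg",
    "generate_fmri",
    "generate_features",
    "subject_seeds",
    "default_channel_layout",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalSpec:
    """One planted signal component: a Gaussian bump in time.

    latency_ms is the bump centre, width_ms its FWHM, amplitude its peak
    channel-space norm, and invariant_fraction the share of the topography
    that is common across levels of the *other* factor (what cross-decoding
    transfers on).
    """

    latency_ms: float
    width_ms: float = 80.0
    amplitude: float = 1.0
    invariant_fraction: float = 0.7

    def validate(self) -> None:
        if self.amplitude < 0:
            raise InvalidDesignError("signal amplitude must be >= 0")
        if not 0.0 <= self.invariant_fraction <= 1.0:
            raise InvalidDesignError("invariant_fraction must be in [0, 1]")
        if self.width_ms <= 0:
            raise InvalidDesignError("width_ms must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    channel_correlation: float = 0.3  # nearest-neighbour noise correlation
    temporal_smoothing_ms: float = 5.0
    sd: float = 1.0

    def validate(self) -> None:
        if not 0.0 <= self.channel_correlation < 1.0:
            raise InvalidDesignError("channel_correlation must be in [0, 1)")
        if self.sd < 0:
            raise InvalidDesignError("noise sd must be >= 0")


def _default_location_signal() -> Dict[str, SignalSpec]:
    # Planted location-signal latencies per clutter level: early for uncluttered
    # backgrounds, delayed when the object is embedded in high clutter.
    return {
        "no": SignalSpec(latency_ms=140.0),
        "low": SignalSpec(latency_ms=133.0),
        "high": SignalSpec(latency_ms=317.0),
    }


def _default_category_signal() -> Dict[str, SignalSpec]:
    return {
        "no": SignalSpec(latency_ms=150.0, invariant_fraction=0.7),
        "low": SignalSpec(latency_ms=160.0, invariant_fraction=0.7),
        "high": SignalSpec(latency_ms=250.0, invariant_fraction=0.7),
    }


def _default_fmri_location_snr() -> Dict[str, Dict[str, float]]:
    # Early visual ROIs carry location information only without clutter;
    # object-selective cortex retains it under clutter.
    return {
        "V1": {"no": 1.2, "low": 0.5, "high": 0.1},
        "V2": {"no": 1.1, "low": 0.5, "high": 0.15},
        "V3": {"no": 1.0, "low": 0.6, "high": 0.2},
        "V4": {"no": 0.9, "low": 0.7, "high": 0.4},
        "LOC": {"no": 0.8, "low": 0.8, "high": 0.8},
    }


def _default_fmri_category_snr() -> Dict[str, Dict[str, float]]:
    return {
        "V1": {"no": 0.3, "low": 0.2, "high": 0.1},
        "V2": {"no": 0.3, "low": 0.2, "high": 0.1},
        "V3": {"no": 0.4, "low": 0.3, "high": 0.2},
        "V4": {"no": 0.6, "low": 0.5, "high": 0.4},
        "LOC": {"no": 0.9, "low": 0.8, "high": 0.7},
    }


@dataclass(frozen=True)
class FMRIConfig:
    n_runs: int = 10
    n_voxels_per_roi: int = 325
    grid_shape: Tuple[int, int, int] = (18, 18, 12)
    location_snr: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_fmri_location_snr
    )
    category_snr: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_fmri_category_snr
    )
    invariant_fraction: float = 0.8


def _default_layer_separability() -> Dict[str, Dict[str, float]]:
    # Location separability along a 4-block feedforward hierarchy: present
    # everywhere without clutter, emerging gradually under high clutter.
    return {
        "block1": {"no": 1.0, "low": 0.5, "high": 0.1},
        "block2": {"no": 1.0, "low": 0.6, "high": 0.3},
        "block3": {"no": 1.0, "low": 0.8, "high": 0.6},
        "block4": {"no": 1.0, "low": 1.0, "high": 1.2},
    }


@dataclass(frozen=True)
class FeatureConfig:
    layer_separability: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_layer_separability
    )
    n_units: int = 128
    invariant_fraction: float = 0.8


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the generators need; ``seed`` fixes all randomness.

    ``geometry_seed`` fixes the shared location-geometry embedding so that
    independently seeded subjects (and modalities) share representational
    structure, as real participants viewing the same stimuli would.
    """

    design: DesignSpec = field(default_factory=DesignSpec)
    n_channels: int = 63
    sampling_rate: float = 1000.0
    epoch_window: Tuple[float, float] = (-100.0, 999.0)
    location_signal: Mapping[str, SignalSpec] = field(
        default_factory=_default_location_signal
    )
    category_signal: Mapping[str, SignalSpec] = field(
        default_factory=_default_category_signal
    )
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    fmri: FMRIConfig = field(default_factory=FMRIConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    seed: int = 0
    geometry_seed: int = 12345

    def validate(self) -> None:
        t0, t1 = self.epoch_window
        if t1 <= t0:
            raise InvalidDesignError("epoch_window must be increasing")
        for mapping in (self.location_signal, self.category_signal):
            # keys for clutter levels absent from the design are ignored
            for clutter, sig in mapping.items():
                sig.validate()
                if not (t0 <= sig.latency_ms <= t1):
                    raise InvalidDesignError(
                        f"signal latency {sig.latency_ms} ms outside epoch window"
                    )
        missing = set(self.design.clutter_levels) - set(self.location_signal)
        if missing:
            raise InvalidDesignError(f"location_signal missing clutter levels {missing}")
        self.noise.validate()
        if self.n_channels < 2:
            raise InvalidDesignError("need at least 2 channels")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))

    # -- JSON config round trip -----------------------------------------------
    def to_dict(self) -> dict:
        import json as _json

        def sig(m: Mapping[str, SignalSpec]) -> dict:
            return {
                k: {
                    "latency_ms": v.latency_ms,
                    "width_ms": v.width_ms,
                    "amplitude": v.amplitude,
                    "invariant_fraction": v.invariant_fraction,
                }
                for k, v in m.items()
            }

        return {
            "design": _json.loads(self.design.to_json()),
            "n_channels": self.n_channels,
            "sampling_rate": self.sampling_rate,
            "epoch_window": list(self.epoch_window),
            "location_signal": sig(self.location_signal),
            "category_signal": sig(self.category_signal),
            "noise": {
                "channel_correlation": self.noise.channel_correlation,
                "temporal_smoothing_ms": self.noise.temporal_smoothing_ms,
                "sd": self.noise.sd,
            },
            "fmri": {
                "n_runs": self.fmri.n_runs,
                "n_voxels_per_roi": self.fmri.n_voxels_per_roi,
                "grid_shape": list(self.fmri.grid_shape),
                "location_snr": {k: dict(v) for k, v in self.fmri.location_snr.items()},
                "category_snr": {k: dict(v) for k, v in self.fmri.category_snr.items()},
                "invariant_fraction": self.fmri.invariant_fraction,
            },
            "features": {
                "layer_separability": {
                    k: dict(v) for k, v in self.features.layer_separability.items()
                },
                "n_units": self.features.n_units,
                "invariant_fraction": self.features.invariant_fraction,
            },
            "seed": self.seed,
            "geometry_seed": self.geometry_seed,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "GeneratorConfig":
        import json as _json

        def sig(m: dict) -> Dict[str, SignalSpec]:
            return {k: SignalSpec(**v) for k, v in m.items()}

        design = DesignSpec.from_json(_json.dumps(obj["design"]))
        fm = obj.get("fmri", {})
        ft = obj.get("features", {})
        return cls(
            design=design,
            n_channels=int(obj.get("n_channels", 63)),
            sampling_rate=float(obj.get("sampling_rate", 1000.0)),
            epoch_window=tuple(obj.get("epoch_window", (-100.0, 999.0))),
            location_signal=sig(obj["location_signal"]),
            category_signal=sig(obj.get("category_signal", {})),
            noise=NoiseSpec(**obj.get("noise", {})),
            fmri=FMRIConfig(
                n_runs=int(fm.get("n_runs", 10)),
                n_voxels_per_roi=int(fm.get("n_voxels_per_roi", 325)),
                grid_shape=tuple(fm.get("grid_shape", (18, 18, 12))),
                location_snr=fm.get("location_snr", _default_fmri_location_snr()),
                category_snr=fm.get("category_snr", _default_fmri_category_snr()),
                invariant_fraction=float(fm.get("invariant_fraction", 0.8)),
            ),
            features=FeatureConfig(
                layer_separability=ft.get(
                    "layer_separability", _default_layer_separability()
                ),
                n_units=int(ft.get("n_units", 128)),
                invariant_fraction=float(ft.get("invariant_fraction", 0.8)),
            ),
            seed=int(obj.get("seed", 0)),
            geometry_seed=int(obj.get("geometry_seed", 12345)),
        )


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class EEGEpochSet:
    """Epoched multichannel data: trials x channels x time points."""

    data: np.ndarray
    labels: list  # ConditionLabel per trial
    time_ms: np.ndarray
    channel_layout: np.ndarray  # n_channels x 2 positions, arbitrary units

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.labels):
            raise ValueError("label count must equal trial count")
        if self.data.shape[1] != self.channel_layout.shape[0]:
            raise ValueError("layout rows must equal channel count")
        dt = np.diff(self.time_ms)
        if len(dt) and not (np.all(dt > 0) and np.allclose(dt, dt[0])):
            raise ValueError("time axis must be strictly increasing and uniform")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    def select_clutter(self, clutter: str) -> "EEGEpochSet":
        idx = [i for i, lab in enumerate(self.labels) if lab.clutter == clutter]
        return EEGEpochSet(
            data=self.data[idx],
            labels=[self.labels[i] for i in idx],
            time_ms=self.time_ms,
            channel_layout=self.channel_layout,
        )


@dataclass
class FMRIPatternSet:
    """Run-wise condition patterns on the t-value scale: runs x conditions x voxels."""

    data: np.ndarray
    condition_labels: list  # ConditionLabel per condition axis entry
    voxel_coords: np.ndarray  # n_voxels x 3 integer grid coordinates
    roi_labels: np.ndarray  # n_voxels, dtype str

    def __post_init__(self) -> None:
        if self.data.shape[1] != len(self.condition_labels):
            raise ValueError("condition axis must match label count")
        if self.data.shape[2] != self.voxel_coords.shape[0]:
            raise ValueError("voxel axis must match coordinate count")
        coords = [tuple(c) for c in np.asarray(self.voxel_coords)]
        if len(set(coords)) != len(coords):
            raise ValueError("voxel coordinates must be unique")

    @property
    def n_runs(self) -> int:
        return self.data.shape[0]

    def roi_voxels(self, roi: str) -> np.ndarray:
        idx = np.flatnonzero(self.roi_labels == roi)
        if idx.size == 0:
            raise KeyError(f"unknown ROI {roi!r}")
        return idx

    @property
    def rois(self) -> list:
        seen: Dict[str, None] = {}
        for r in self.roi_labels:
            seen.setdefault(str(r), None)
        return list(seen)


@dataclass
class FeatureActivationSet:
    """Per-layer unit activations: {layer: trials x units}, shared trial labels."""

    data: Dict[str, np.ndarray]
    labels: list
    layer_names: list

    def __post_init__(self) -> None:
        n = len(self.labels)
        for name in self.layer_names:
            if name not in self.data:
                raise ValueError(f"missing layer {name!r}")
            if self.data[name].shape[0] != n:
                raise ValueError("all layers must share the trial labelling")


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def subject_seeds(root_seed: int, n_subjects: int) -> list:
    """Deterministic per-subject seeds spawned from a root seed (each < 2^31)."""
    ss = np.random.SeedSequence(int(root_seed))
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subjects)]


def default_channel_layout(n_channels: int) -> np.ndarray:
    """Deterministic 2-D cap layout: concentric rings on the unit disc."""
    pos = [(0.0, 0.0)]
    ring = 1
    while len(pos) < n_channels:
        k = 6 * ring
        r = ring
        for i in range(k):
            a = 2 * np.pi * i / k
            pos.append((r * np.cos(a), r * np.sin(a)))
            if len(pos) == n_channels:
                break
        ring += 1
    out = np.asarray(pos[:n_channels], dtype=float)
    return out / max(1.0, out[:, 0].max())


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _geometry_embedding(
    rng: np.random.Generator, design: DesignSpec, dim: int
) -> Dict[str, np.ndarray]:
    """Embed quadrant offsets through a random orthonormal map; unit-norm output.

    Pairwise distances between the resulting location topographies are
    proportional to the distances between quadrant centres, so every modality
    drawn with the same geometry seed shares the same representational
    structure over locations.
    """
    a = rng.standard_normal((dim, 2))
    q, _ = np.linalg.qr(a)
    out = {}
    for loc in design.locations:
        off = np.asarray(design.location_offsets_deg[loc], dtype=float)
        out[loc] = q @ off
    scale = max(np.linalg.norm(v) for v in out.values())
    return {loc: v / scale for loc, v in out.items()}


def _mixed_topography(
    shared: np.ndarray, specific: np.ndarray, invariant_fraction: float
) -> np.ndarray:
    f = invariant_fraction
    return np.sqrt(f) * shared + np.sqrt(1.0 - f) * specific


def _noise_chol(layout: np.ndarray, spec: NoiseSpec) -> Optional[np.ndarray]:
    """Cholesky factor of the channel noise covariance (None for iid noise)."""
    rho = spec.channel_correlation
    if rho == 0.0:
        return None
    d = np.linalg.norm(layout[:, None, :] - layout[None, :, :], axis=-1)
    nn = np.min(d + np.eye(len(layout)) * 1e9, axis=1).mean()
    cov = rho ** (d / max(nn, 1e-12))
    cov += 1e-8 * np.eye(len(layout))
    return np.linalg.cholesky(cov)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def generate_eeg(config: GeneratorConfig, seed: Optional[int] = None) -> EEGEpochSet:
    """Simulate one subject's epoched EEG under the crossed design.

    Under the default design each category-level condition receives
    ``n_runs * trials_per_condition_per_run * exemplars`` = 60 trials,
    giving a (2880, 63, 1100) tensor over the 48 conditions.
    """
    config.validate()
    design = config.design
    rng = np.random.default_rng(config.seed if seed is None else int(seed))
    geom_rng = np.random.default_rng(config.geometry_seed)

    dt = 1000.0 / config.sampling_rate
    t0, t1 = config.epoch_window
    time_ms = np.arange(t0, t1 + 0.5 * dt, dt)
    n_time = len(time_ms)
    layout = default_channel_layout(config.n_channels)

    loc_shared = _geometry_embedding(geom_rng, design, config.n_channels)
    cat_shared = {
        c: _unit(geom_rng.standard_normal(config.n_channels))
        for c in design.categories
    }
    # subject-specific, factor-crossed topography components
    loc_specific = {
        (loc, cat): _unit(rng.standard_normal(config.n_channels))
        for loc in design.locations
        for cat in design.categories
    }
    cat_specific = {
        (cat, loc): _unit(rng.standard_normal(config.n_channels))
        for cat in design.categories
        for loc in design.locations
    }

    conditions = enumerate_conditions(design, level="category")
    n_per_cond = design.trials_per_condition()
    n_trials = len(conditions) * n_per_cond

    data = np.empty((n_trials, config.n_channels, n_time), dtype=np.float32)
    labels = []
    chol = _noise_chol(layout, config.noise)
    smooth = max(1, int(round(config.noise.temporal_smoothing_ms / dt)))

    def bump(sig: SignalSpec) -> np.ndarray:
        sigma = sig.width_ms / 2.3548200450309493  # FWHM -> sd
        return np.exp(-0.5 * ((time_ms - sig.latency_ms) / sigma) ** 2)

    row = 0
    for cond in conditions:
        loc_sig = config.location_signal[cond.clutter]
        cat_sig = config.category_signal.get(cond.clutter)
        topo_loc = _mixed_topography(
            loc_shared[cond.location],
            loc_specific[(cond.location, cond.category)],
            loc_sig.invariant_fraction,
        )
        mean = loc_sig.amplitude * np.outer(topo_loc, bump(loc_sig))
        if cat_sig is not None and cat_sig.amplitude > 0:
            topo_cat = _mixed_topography(
                cat_shared[cond.category],
                cat_specific[(cond.category, cond.location)],
                cat_sig.invariant_fraction,
            )
            mean = mean + cat_sig.amplitude * np.outer(topo_cat, bump(cat_sig))
        for _ in range(n_per_cond):
            noise = rng.standard_normal((config.n_channels, n_time))
            if smooth > 1:
                kernel = np.ones(smooth) / np.sqrt(smooth)
                noise = np.apply_along_axis(
                    lambda x: np.convolve(x, kernel, mode="same"), 1, noise
                )
            if chol is not None:
                noise = chol @ noise
            data[row] = mean + config.noise.sd * noise
            labels.append(cond)
            row += 1
    return EEGEpochSet(data=data, labels=labels, time_ms=time_ms, channel_layout=layout)


def generate_fmri(config: GeneratorConfig, seed: Optional[int] = None) -> FMRIPatternSet:
    """Simulate run-wise condition t-value patterns on a labelled voxel grid.

    Per run and condition the voxel pattern is a location pattern scaled by
    the ROI x clutter location SNR, plus a category pattern scaled by the
    category SNR, plus unit-variance noise.  ROIs occupy disjoint compact
    blocks of the integer grid.
    """
    config.validate()
    design = config.design
    fmri = config.fmri
    rng = np.random.default_rng(config.seed if seed is None else int(seed))
    geom_rng = np.random.default_rng(config.geometry_seed + 1)

    rois = list(fmri.location_snr)
    for roi in rois:
        if roi not in fmri.category_snr:
            raise InvalidDesignError(f"category_snr missing ROI {roi!r}")

    # carve each ROI out of the grid as a compact slab along x
    nx, ny, nz = fmri.grid_shape
    all_coords = np.array(
        [(x, y, z) for x in range(nx) for y in range(ny) for z in range(nz)], dtype=int
    )
    needed = fmri.n_voxels_per_roi * len(rois)
    if needed > len(all_coords):
        raise InvalidDesignError(
            f"grid {fmri.grid_shape} too small for {needed} voxels"
        )
    voxel_coords = all_coords[:needed]
    roi_labels = np.repeat(np.asarray(rois, dtype=object), fmri.n_voxels_per_roi)
    roi_labels = roi_labels.astype(str)

    conditions = enumerate_conditions(design, level="category")
    n_vox = len(voxel_coords)
    data = np.empty((fmri.n_runs, len(conditions), n_vox), dtype=np.float32)

    means = np.zeros((len(conditions), n_vox))
    for roi in rois:
        vox = np.flatnonzero(roi_labels == roi)
        dim = len(vox)
        loc_shared = _geometry_embedding(geom_rng, design, dim)
        cat_shared = {
            c: _unit(geom_rng.standard_normal(dim)) for c in design.categories
        }
        loc_specific = {
            (loc, cat): _unit(rng.standard_normal(dim))
            for loc in design.locations
            for cat in design.categories
        }
        cat_specific = {
            (cat, loc): _unit(rng.standard_normal(dim))
            for cat in design.categories
            for loc in design.locations
        }
        for ci, cond in enumerate(conditions):
            snr_loc = float(fmri.location_snr[roi].get(cond.clutter, 0.0))
            snr_cat = float(fmri.category_snr[roi].get(cond.clutter, 0.0))
            pattern = snr_loc * _mixed_topography(
                loc_shared[cond.location],
                loc_specific[(cond.location, cond.category)],
                fmri.invariant_fraction,
            )
            pattern = pattern + snr_cat * _mixed_topography(
                cat_shared[cond.category],
                cat_specific[(cond.category, cond.location)],
                fmri.invariant_fraction,
            )
            means[ci, vox] = pattern
    for run in range(fmri.n_runs):
        data[run] = means + rng.standard_normal((len(conditions), n_vox))
    return FMRIPatternSet(
        data=data,
        condition_labels=conditions,
        voxel_coords=voxel_coords,
        roi_labels=roi_labels,
    )


def generate_features(
    config: GeneratorConfig, seed: Optional[int] = None
) -> FeatureActivationSet:
    """Simulate layer-wise unit activations with planted location separability.

    The per-layer x clutter separability map scales the location pattern,
    supporting hierarchies in which location information under clutter
    emerges only in later layers.
    """
    config.validate()
    design = config.design
    feat = config.features
    rng = np.random.default_rng(config.seed if seed is None else int(seed))
    geom_rng = np.random.default_rng(config.geometry_seed + 2)

    layers = list(feat.layer_separability)
    conditions = enumerate_conditions(design, level="category")
    n_per_cond = design.trials_per_condition()
    labels = [c for c in conditions for _ in range(n_per_cond)]

    data: Dict[str, np.ndarray] = {}
    for layer in layers:
        dim = feat.n_units
        loc_shared = _geometry_embedding(geom_rng, design, dim)
        loc_specific = {
            (loc, cat): _unit(rng.standard_normal(dim))
            for loc in design.locations
            for cat in design.categories
        }
        rows = np.empty((len(labels), dim), dtype=np.float32)
        row = 0
        for cond in conditions:
            sep = float(feat.layer_separability[layer].get(cond.clutter, 0.0))
            mean = sep * _mixed_topography(
                loc_shared[cond.location],
                loc_specific[(cond.location, cond.category)],
                feat.invariant_fraction,
            )
            for _ in range(n_per_cond):
                rows[row] = mean + rng.standard_normal(dim)
                row += 1
        data[layer] = rows
    return FeatureActivationSet(data=data, labels=labels, layer_names=layers)
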