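"""Shared fixtures: small designs and synthetic datasets generated at test time."""

import numpy as np
import pytest

from crossdecode import (
    DesignSpec,
    GeneratorConfig,
    NoiseSpec,
    SignalSpec,
    build_pair_scheme,
    generate_eeg,
)
from crossdecode.simulate import FMRIConfig


@pytest.fixture(scope="session")
def default_design():
    return DesignSpec()


@pytest.fixture(scope="session")
def small_design():
    """2 categories x 2 locations x 2 clutter levels, 12 trials/condition."""
    return DesignSpec(
        categories=("animals", "faces"),
        exemplars_per_category=1,
        locations=("left-up", "right-bottom"),
        clutter_levels=("no", "high"),
        n_runs=4,
        trials_per_condition_per_run=3,
    )


@pytest.fixture(scope="session")
def small_scheme(small_design):
    return build_pair_scheme(small_design)


def make_eeg_config(
    design,
    amplitude=1.5,
    latency_no=150.0,
    latency_high=300.0,
    invariant_fraction=0.8,
    n_channels=12,
    sampling_rate=100.0,
    epoch_window=(-100.0, 400.0),
    noise=None,
    seed=0,
    **kwargs,
):
    """Small EEG generator config with one planted location signal per clutter."""
    latencies = {"no": latency_no, "low": latency_no, "high": latency_high}
    latencies = {c: latencies.get(c, latency_no) for c in design.clutter_levels}
    loc = {
        c: SignalSpec(
            latency_ms=latencies[c],
            amplitude=amplitude,
            invariant_fraction=invariant_fraction,
        )
        for c in design.clutter_levels
    }
    return GeneratorConfig(
        design=design,
        n_channels=n_channels,
        sampling_rate=sampling_rate,
        epoch_window=epoch_window,
        location_signal=loc,
        category_signal={},
        noise=noise or NoiseSpec(channel_correlation=0.0, temporal_smoothing_ms=0.0),
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_eeg(small_design):
    return generate_eeg(make_eeg_config(small_design, seed=7))


def make_fmri_config(design, location_snr, category_snr=None, n_voxels=40, seed=0):
    rois = list(location_snr)
    if category_snr is None:
        category_snr = {
            roi: {c: 0.0 for c in design.clutter_levels} for roi in rois
        }
    n_total = n_voxels * len(rois)
    side = int(np.ceil(n_total ** (1 / 3))) + 1
    return GeneratorConfig(
        design=design,
        fmri=FMRIConfig(
            n_runs=10,
            n_voxels_per_roi=n_voxels,
            grid_shape=(side, side, side),
            location_snr=location_snr,
            category_snr=category_snr,
        ),
        seed=seed,
    )
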