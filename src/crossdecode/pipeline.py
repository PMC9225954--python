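"""End-to-end replicate-on-synthetic driver.

Chains every stage on simulated subjects: generation, time-resolved and ROI
cross-decoding, layer-wise feature decoding, voxel- and channel-space
searchlights, cross-condition temporal generalization with the
peak-to-diagonal statistic, EEG-fMRI RDV fusion, and the group inference
stack (Wilcoxon vs. chance with BH-FDR, bootstrap peak CIs and latency
differences, label-shuffle searchlight peak nulls).

Every stochastic stage derives its seed deterministically from the run's
root seed and the stage name, and every output file is listed in a
machine-readable manifest together with the seed that produced it.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as cdio
from .decoding import (
    cross_decode_features,
    cross_decode_roi,
    cross_decode_timecourse,
    noise_normalize,
)
from .design import DesignSpec, build_pair_scheme
from .fusion import (
    UndefinedCorrelationError,
    bootstrap_difference,
    bootstrap_peak_ci,
    bootstrap_searchlight_peak_distance,
    build_rdv,
    canonical_rdv_index,
    eeg_peak_rdv,
    fdr_correct,
    fuse_rdvs,
    signed_rank_effect_size,
    wilcoxon_vs_chance,
)
from .simulate import (
    FMRIConfig,
    FeatureConfig,
    GeneratorConfig,
    NoiseSpec,
    SignalSpec,
    generate_eeg,
    generate_features,
    generate_fmri,
    subject_seeds,
)
from .spatiotemporal import (
    peak_to_diagonal,
    searchlight_channels,
    searchlight_volume,
    temporal_generalization,
)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline", "stage_seed"]

log = logging.getLogger("crossdecode")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and its parameters."""

    def __init__(self, stage: str, params: dict, cause: BaseException):
        super().__init__(f"stage {stage!r} failed with parameters {params}: {cause}")
        self.stage = stage
        self.params = params


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    return (int(root_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Full parameterization of one synthetic replication run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_subjects: int = 20
    decode_iterations: int = 100
    n_bins: int = 4
    apply_noise_normalization: bool = True
    rois: Optional[Tuple[str, ...]] = None
    tempgen_train: str = "no"
    tempgen_test: str = "high"
    tempgen_window: Tuple[float, float] = (-100.0, 600.0)
    tempgen_step_ms: float = 10.0
    peak_window: Tuple[float, float] = (0.0, 600.0)
    searchlight_radius: int = 4
    channel_k: int = 5
    run_searchlights: bool = True
    n_boot: int = 10_000
    fdr_q: float = 0.05
    root_seed: int = 0
    out_dir: str = "crossdecode_run"
    verbosity: int = 1

    @classmethod
    def small(cls, out_dir: str = "crossdecode_run", root_seed: int = 0) -> "RunConfig":
        """A desk-scale configuration that exercises every stage in seconds:
        a 2 x 2 x 2 design, 12 channels at 100 Hz, 10 simulated subjects.
        Ten subjects keep the exact signed-rank floor (2/2^10 ~ 0.002) low
        enough for BH-FDR across the ~50 time points to have power."""
        design = DesignSpec(
            categories=("animals", "faces"),
            exemplars_per_category=1,
            locations=("left-up", "right-bottom"),
            clutter_levels=("no", "high"),
            n_runs=4,
            trials_per_condition_per_run=3,
        )
        gen = GeneratorConfig(
            design=design,
            n_channels=12,
            sampling_rate=100.0,
            epoch_window=(-100.0, 400.0),
            location_signal={
                "no": SignalSpec(latency_ms=140.0, amplitude=1.5),
                "high": SignalSpec(latency_ms=300.0, amplitude=1.0),
            },
            category_signal={
                "no": SignalSpec(latency_ms=160.0, amplitude=0.8),
                "high": SignalSpec(latency_ms=260.0, amplitude=0.6),
            },
            noise=NoiseSpec(channel_correlation=0.2, temporal_smoothing_ms=10.0),
            fmri=FMRIConfig(
                n_runs=10,
                n_voxels_per_roi=30,
                grid_shape=(5, 4, 4),
                location_snr={
                    "V1": {"no": 1.5, "high": 0.0},
                    "LOC": {"no": 1.0, "high": 1.0},
                },
                category_snr={
                    "V1": {"no": 0.2, "high": 0.1},
                    "LOC": {"no": 0.8, "high": 0.6},
                },
            ),
            features=FeatureConfig(
                layer_separability={
                    "block1": {"no": 1.0, "high": 0.1},
                    "block4": {"no": 1.0, "high": 1.0},
                },
                n_units=32,
            ),
        )
        return cls(
            generator=gen,
            n_subjects=10,
            decode_iterations=2,
            tempgen_window=(-100.0, 400.0),
            tempgen_step_ms=50.0,
            peak_window=(0.0, 400.0),
            searchlight_radius=2,
            channel_k=3,
            n_boot=200,
            root_seed=root_seed,
            out_dir=out_dir,
        )

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict(),
            "n_subjects": self.n_subjects,
            "decode_iterations": self.decode_iterations,
            "n_bins": self.n_bins,
            "apply_noise_normalization": self.apply_noise_normalization,
            "rois": list(self.rois) if self.rois else None,
            "tempgen_train": self.tempgen_train,
            "tempgen_test": self.tempgen_test,
            "tempgen_window": list(self.tempgen_window),
            "tempgen_step_ms": self.tempgen_step_ms,
            "peak_window": list(self.peak_window),
            "searchlight_radius": self.searchlight_radius,
            "channel_k": self.channel_k,
            "run_searchlights": self.run_searchlights,
            "n_boot": self.n_boot,
            "fdr_q": self.fdr_q,
            "root_seed": self.root_seed,
            "out_dir": self.out_dir,
            "verbosity": self.verbosity,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        kwargs = dict(obj)
        kwargs["generator"] = GeneratorConfig.from_dict(obj["generator"])
        if kwargs.get("rois"):
            kwargs["rois"] = tuple(kwargs["rois"])
        for key in ("tempgen_window", "peak_window"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


# --------------------------------------------------------------------------
# the driver
# --------------------------------------------------------------------------

class _Manifest:
    def __init__(self, out_dir: Path, root_seed: int):
        self.out_dir = out_dir
        self.doc = {
            "root_seed": int(root_seed),
            "versions": _versions(),
            "stages": {},
        }

    def record(self, stage: str, seed: int, outputs: List[Path], t0: float) -> None:
        self.doc["stages"][stage] = {
            "seed": int(seed),
            "outputs": [str(p.relative_to(self.out_dir)) for p in outputs],
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
        log.info(
            "stage=%s seed=%d wall=%.2fs outputs=%s",
            stage,
            seed,
            time.perf_counter() - t0,
            [str(p) for p in outputs],
        )

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.doc, indent=2, sort_keys=True))
        return path


def _versions() -> dict:
    import importlib.metadata as im

    out = {}
    for pkg in ("crossdecode", "numpy", "scipy", "scikit-learn", "pandas"):
        try:
            out[pkg] = im.version(pkg)
        except im.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def _stage(manifest: _Manifest, name: str, params: dict):
    """Context-free stage wrapper: call fn, record outputs, map errors."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineStageError(name, params, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run the full synthetic replication and write all outputs.

    Returns a bundle of in-memory results keyed by stage; all tables are
    also written as TSV under ``config.out_dir`` together with a manifest
    of seeds, versions and output files.  Re-running with the same config
    yields byte-identical TSV outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.verbosity and not log.handlers:
        logging.basicConfig(level=logging.INFO)
    manifest = _Manifest(out_dir, config.root_seed)
    bundle: Dict[str, object] = {}
    design = config.generator.design
    scheme = build_pair_scheme(design)
    clutters = list(design.clutter_levels)
    seeds = subject_seeds(stage_seed(config.root_seed, "subjects"), config.n_subjects)

    # ---- simulate -----------------------------------------------------------
    with _stage(manifest, "simulate", {"n_subjects": config.n_subjects}) as ctx:
        eeg_sets, fmri_sets, feat_sets = [], [], []
        for s in seeds:
            eeg = generate_eeg(config.generator, seed=s)
            if config.apply_noise_normalization:
                eeg = noise_normalize(eeg)
            eeg_sets.append(eeg)
            fmri_sets.append(generate_fmri(config.generator, seed=s + 1))
            feat_sets.append(generate_features(config.generator, seed=s + 2))
        manifest.record("simulate", stage_seed(config.root_seed, "subjects"), [], ctx.t0)

    # ---- time-resolved EEG decoding ----------------------------------------
    with _stage(manifest, "decode_time", {"clutters": clutters}) as ctx:
        seed0 = stage_seed(config.root_seed, "decode_time")
        rows = []
        courses: Dict[str, np.ndarray] = {}
        cell_courses: Dict[str, np.ndarray] = {}
        for clutter in clutters:
            per_subj, per_subj_cells = [], []
            for si, eeg in enumerate(eeg_sets):
                res = cross_decode_timecourse(
                    eeg,
                    target="location",
                    clutter=clutter,
                    scheme=scheme,
                    n_iterations=config.decode_iterations,
                    seed=seed0 + si,
                    n_bins=config.n_bins,
                    return_cells=True,
                )
                per_subj.append(res.accuracy)
                per_subj_cells.append(res.cell_accuracy)
                for t, acc in zip(res.index, res.accuracy):
                    rows.append(
                        dict(
                            subject=si,
                            modality="eeg",
                            target="location",
                            clutter=clutter,
                            index=float(t),
                            accuracy=acc,
                            n_cells=res.n_cells_averaged,
                            seed=seed0 + si,
                        )
                    )
            courses[clutter] = np.stack(per_subj)
            cell_courses[clutter] = np.stack(per_subj_cells)
        frame = pd.DataFrame(rows, columns=cdio.RESULT_COLUMNS)
        path = out_dir / "eeg_timecourse.tsv"
        cdio.results_to_tsv(frame, path)
        bundle["eeg_timecourse"] = frame
        bundle["eeg_courses"] = courses
        time_axis = np.asarray(eeg_sets[0].time_ms, dtype=float)
        manifest.record("decode_time", seed0, [path], ctx.t0)

    # ---- group stats on the EEG time courses -------------------------------
    with _stage(manifest, "eeg_group_stats", {"q": config.fdr_q}) as ctx:
        seed0 = stage_seed(config.root_seed, "eeg_group_stats")
        stat_rows = []
        for clutter in clutters:
            arr = courses[clutter]
            tests = [wilcoxon_vs_chance(arr[:, t], 50.0) for t in range(arr.shape[1])]
            reject, p_adj = fdr_correct([t.p for t in tests], q=config.fdr_q)
            for ti, test in enumerate(tests):
                stat_rows.append(
                    dict(
                        clutter=clutter,
                        index=float(time_axis[ti]),
                        mean_accuracy=float(arr[:, ti].mean()),
                        p=test.p,
                        p_adjusted=float(p_adj[ti]),
                        significant=bool(reject[ti]),
                    )
                )
        stats_frame = pd.DataFrame(stat_rows)
        path = out_dir / "eeg_group_stats.tsv"
        cdio.results_to_tsv(stats_frame, path)
        bundle["eeg_group_stats"] = stats_frame
        manifest.record("eeg_group_stats", seed0, [path], ctx.t0)

    # ---- bootstrap peak latencies and differences --------------------------
    with _stage(manifest, "eeg_peaks", {"n_boot": config.n_boot}) as ctx:
        seed0 = stage_seed(config.root_seed, "eeg_peaks")
        peak_rows, peak_results = [], {}
        for ci, clutter in enumerate(clutters):
            boot = bootstrap_peak_ci(
                courses[clutter],
                time_axis,
                config.peak_window,
                n_boot=config.n_boot,
                seed=seed0 + ci,
            )
            peak_results[clutter] = boot
            peak_rows.append(
                dict(
                    statistic=boot.statistic,
                    clutter=clutter,
                    estimate=boot.estimate,
                    ci_low=boot.ci_low,
                    ci_high=boot.ci_high,
                    p=np.nan,
                    p_adjusted=np.nan,
                    n=config.n_subjects,
                    n_boot=boot.n_boot,
                    seed=boot.seed,
                )
            )
        diff_rows = []
        pairs = list(itertools.combinations(clutters, 2))
        diffs = []
        for pi, (a, b) in enumerate(pairs):
            boot = bootstrap_difference(
                courses[a],
                courses[b],
                time_axis,
                config.peak_window,
                n_boot=config.n_boot,
                seed=seed0 + 100 + pi,
            )
            diffs.append(boot)
        if pairs:
            reject, p_adj = fdr_correct([d.p for d in diffs], q=config.fdr_q)
            for (a, b), boot, r, pa in zip(pairs, diffs, reject, p_adj):
                diff_rows.append(
                    dict(
                        statistic=boot.statistic,
                        pair=f"{b}-{a}",
                        estimate=boot.estimate,
                        ci_low=boot.ci_low,
                        ci_high=boot.ci_high,
                        p=boot.p,
                        p_adjusted=float(pa),
                        significant=bool(r),
                        n_boot=boot.n_boot,
                        seed=boot.seed,
                    )
                )
        peaks_frame = pd.DataFrame(peak_rows)
        diffs_frame = pd.DataFrame(diff_rows)
        p1 = out_dir / "eeg_peaks.tsv"
        p2 = out_dir / "eeg_peak_differences.tsv"
        cdio.results_to_tsv(peaks_frame, p1)
        cdio.results_to_tsv(diffs_frame, p2)
        bundle["eeg_peaks"] = peak_results
        bundle["eeg_peak_differences"] = diffs_frame
        manifest.record("eeg_peaks", seed0, [p1, p2], ctx.t0)

    # ---- fMRI ROI decoding --------------------------------------------------
    with _stage(manifest, "decode_roi", {}) as ctx:
        seed0 = stage_seed(config.root_seed, "decode_roi")
        rois = list(config.rois) if config.rois else fmri_sets[0].rois
        rows = []
        roi_cells: Dict[Tuple[int, str, str], dict] = {}
        for si, patterns in enumerate(fmri_sets):
            for roi in rois:
                for clutter in clutters:
                    res = cross_decode_roi(
                        patterns,
                        roi=roi,
                        target="location",
                        clutter=clutter,
                        scheme=scheme,
                        seed=seed0 + si,
                        return_cells=True,
                    )
                    roi_cells[(si, roi, clutter)] = res.cell_accuracy
                    rows.append(
                        dict(
                            subject=si,
                            modality="fmri",
                            target="location",
                            clutter=clutter,
                            index=roi,
                            accuracy=res.accuracy,
                            n_cells=res.n_cells_averaged,
                            seed=seed0 + si,
                        )
                    )
        roi_frame = pd.DataFrame(rows, columns=cdio.RESULT_COLUMNS)
        path = out_dir / "fmri_roi.tsv"
        cdio.results_to_tsv(roi_frame, path)
        # group tests per roi x clutter
        stat_rows = []
        tests = []
        keys = [(roi, clutter) for roi in rois for clutter in clutters]
        for roi, clutter in keys:
            sel = (roi_frame["index"] == roi) & (roi_frame["clutter"] == clutter)
            tests.append(wilcoxon_vs_chance(roi_frame.loc[sel, "accuracy"].to_numpy(), 50.0))
        reject, p_adj = fdr_correct([t.p for t in tests], q=config.fdr_q)
        for (roi, clutter), test, r, pa in zip(keys, tests, reject, p_adj):
            sel = (roi_frame["index"] == roi) & (roi_frame["clutter"] == clutter)
            vals = roi_frame.loc[sel, "accuracy"]
            stat_rows.append(
                dict(
                    roi=roi,
                    clutter=clutter,
                    mean_accuracy=float(vals.mean()),
                    p=test.p,
                    p_adjusted=float(pa),
                    significant=bool(r),
                )
            )
        roi_stats = pd.DataFrame(stat_rows)
        path2 = out_dir / "fmri_roi_stats.tsv"
        cdio.results_to_tsv(roi_stats, path2)
        bundle["fmri_roi"] = roi_frame
        bundle["fmri_roi_stats"] = roi_stats
        manifest.record("decode_roi", seed0, [path, path2], ctx.t0)

    # ---- feature decoding ---------------------------------------------------
    with _stage(manifest, "decode_features", {}) as ctx:
        seed0 = stage_seed(config.root_seed, "decode_features")
        rows = []
        for si, feats in enumerate(feat_sets):
            for clutter in clutters:
                res = cross_decode_features(
                    feats,
                    target="location",
                    clutter=clutter,
                    scheme=scheme,
                    n_iterations=config.decode_iterations,
                    seed=seed0 + si,
                    n_bins=config.n_bins,
                )
                for layer, acc in zip(res.index, res.accuracy):
                    rows.append(
                        dict(
                            subject=si,
                            modality="features",
                            target="location",
                            clutter=clutter,
                            index=layer,
                            accuracy=float(acc),
                            n_cells=res.n_cells_averaged,
                            seed=seed0 + si,
                        )
                    )
        feat_frame = pd.DataFrame(rows, columns=cdio.RESULT_COLUMNS)
        path = out_dir / "features.tsv"
        cdio.results_to_tsv(feat_frame, path)
        bundle["features"] = feat_frame
        manifest.record("decode_features", seed0, [path], ctx.t0)

    # ---- searchlights -------------------------------------------------------
    if config.run_searchlights:
        with _stage(manifest, "searchlight", {"radius": config.searchlight_radius}) as ctx:
            seed0 = stage_seed(config.root_seed, "searchlight")
            outputs = []
            vol_maps: Dict[str, np.ndarray] = {}
            for clutter in clutters:
                maps = []
                for si, patterns in enumerate(fmri_sets):
                    vol = searchlight_volume(
                        patterns,
                        target="location",
                        clutter=clutter,
                        scheme=scheme,
                        radius=config.searchlight_radius,
                        seed=seed0 + si,
                    )
                    maps.append(vol.accuracy)
                stack = np.stack(maps)
                vol_maps[clutter] = stack
                from .spatiotemporal import SearchlightVolume

                with np.errstate(invalid="ignore"):
                    import warnings

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        group_mean = np.nanmean(stack, axis=0)
                group = SearchlightVolume(
                    accuracy=group_mean,
                    sphere_radius=config.searchlight_radius,
                    clutter=clutter,
                    target="location",
                )
                path = out_dir / f"searchlight_volume_{clutter}.nii.gz"
                cdio.save_searchlight_nifti(path, group)
                outputs.append(path)
            # peak distance null between first/last clutter levels
            a, b = clutters[0], clutters[-1]
            dist = bootstrap_searchlight_peak_distance(
                np.nan_to_num(vol_maps[a], nan=50.0),
                np.nan_to_num(vol_maps[b], nan=50.0),
                n_boot=config.n_boot,
                seed=seed0 + 999,
            )
            dist_frame = pd.DataFrame(
                [
                    dict(
                        statistic=dist.statistic,
                        pair=f"{a}-{b}",
                        estimate=dist.estimate,
                        ci_low=dist.ci_low,
                        ci_high=dist.ci_high,
                        p=dist.p,
                        n_boot=dist.n_boot,
                        seed=dist.seed,
                    )
                ]
            )
            path = out_dir / "searchlight_peak_distance.tsv"
            cdio.results_to_tsv(dist_frame, path)
            outputs.append(path)
            # channel searchlight, first subject per clutter (illustrative map)
            rows = []
            for clutter in clutters:
                cmap = searchlight_channels(
                    eeg_sets[0],
                    target="location",
                    clutter=clutter,
                    scheme=scheme,
                    k=config.channel_k,
                    seed=seed0,
                    n_iterations=max(1, config.decode_iterations // 2),
                )
                for ch in range(cmap.accuracy.shape[0]):
                    for ti, t in enumerate(cmap.time_ms):
                        rows.append(
                            dict(
                                clutter=clutter,
                                channel=ch,
                                time_ms=float(t),
                                accuracy=float(cmap.accuracy[ch, ti]),
                            )
                        )
            chan_frame = pd.DataFrame(rows)
            path = out_dir / "searchlight_channels.tsv"
            cdio.results_to_tsv(chan_frame, path)
            outputs.append(path)
            bundle["searchlight_volume"] = vol_maps
            bundle["searchlight_peak_distance"] = dist
            bundle["searchlight_channels"] = chan_frame
            manifest.record("searchlight", seed0, outputs, ctx.t0)

    # ---- temporal generalization -------------------------------------------
    with _stage(
        manifest,
        "tempgen",
        {"train": config.tempgen_train, "test": config.tempgen_test},
    ) as ctx:
        seed0 = stage_seed(config.root_seed, "tempgen")
        matrices, shifts = [], []
        for si, eeg in enumerate(eeg_sets):
            mat = temporal_generalization(
                eeg,
                eeg,
                target="location",
                scheme=scheme,
                train_clutter=config.tempgen_train,
                test_clutter=config.tempgen_test,
                window=config.tempgen_window,
                step_ms=config.tempgen_step_ms,
                n_iterations=config.decode_iterations,
                seed=seed0 + si,
                n_bins=config.n_bins,
            )
            matrices.append(mat)
            shifts.append(peak_to_diagonal(mat, config.peak_window))
        group_acc = np.mean([m.accuracy for m in matrices], axis=0)
        rows = []
        for i, tr in enumerate(matrices[0].train_axis_ms):
            for j, te in enumerate(matrices[0].test_axis_ms):
                rows.append(
                    dict(train_ms=float(tr), test_ms=float(te), accuracy=float(group_acc[i, j]))
                )
        tg_frame = pd.DataFrame(rows)
        p1 = out_dir / "tempgen_group.tsv"
        cdio.results_to_tsv(tg_frame, p1)
        d_values = np.array([s.d_euclidean for s in shifts])
        test = wilcoxon_vs_chance(d_values, 0.0)
        shift_frame = pd.DataFrame(
            [
                dict(
                    statistic="peak_to_diagonal_ms",
                    mean_d=float(d_values.mean()),
                    p=test.p,
                    z=test.z,
                    r=signed_rank_effect_size(test.z, test.n),
                    n=test.n,
                )
            ]
        )
        p2 = out_dir / "peak_shift.tsv"
        cdio.results_to_tsv(shift_frame, p2)
        bundle["tempgen_matrices"] = matrices
        bundle["tempgen_group"] = group_acc
        bundle["peak_shifts"] = shifts
        bundle["peak_shift_test"] = test
        manifest.record("tempgen", seed0, [p1, p2], ctx.t0)

    # ---- EEG-fMRI fusion ----------------------------------------------------
    with _stage(manifest, "fusion", {}) as ctx:
        seed0 = stage_seed(config.root_seed, "fusion")
        entry_index = canonical_rdv_index(scheme)
        rows = []
        for clutter in clutters:
            boot = bundle["eeg_peaks"][clutter]
            group_rdv = eeg_peak_rdv(
                cell_courses[clutter],
                time_axis,
                (boot.ci_low, boot.ci_high),
                entry_index,
                clutter=clutter,
            )
            for si in range(config.n_subjects):
                for roi in rois:
                    fmri_rdv = build_rdv(
                        roi_cells[(si, roi, clutter)],
                        scheme,
                        modality="fmri",
                        clutter=clutter,
                        tag=f"sub-{si}",
                    )
                    try:
                        rho = fuse_rdvs(group_rdv, fmri_rdv)
                    except UndefinedCorrelationError:
                        rho = np.nan
                    rows.append(
                        dict(subject=si, roi=roi, clutter=clutter, rho=rho, seed=seed0)
                    )
        fusion_frame = pd.DataFrame(rows)
        # group test per roi x clutter
        stat_rows, tests, keys = [], [], []
        for roi in rois:
            for clutter in clutters:
                sel = (fusion_frame["roi"] == roi) & (fusion_frame["clutter"] == clutter)
                vals = fusion_frame.loc[sel, "rho"].dropna()
                if len(vals) >= 5:
                    keys.append((roi, clutter))
                    tests.append(wilcoxon_vs_chance(vals.to_numpy(), 0.0))
        if tests:
            reject, p_adj = fdr_correct([t.p for t in tests], q=config.fdr_q)
            for (roi, clutter), test, r, pa in zip(keys, tests, reject, p_adj):
                stat_rows.append(
                    dict(
                        roi=roi,
                        clutter=clutter,
                        p=test.p,
                        p_adjusted=float(pa),
                        significant=bool(r),
                    )
                )
        fusion_stats = pd.DataFrame(stat_rows)
        p1 = out_dir / "fusion.tsv"
        p2 = out_dir / "fusion_stats.tsv"
        cdio.results_to_tsv(fusion_frame, p1)
        cdio.results_to_tsv(fusion_stats, p2)
        bundle["fusion"] = fusion_frame
        bundle["fusion_stats"] = fusion_stats
        manifest.record("fusion", seed0, [p1, p2], ctx.t0)

    # ---- summary ------------------------------------------------------------
    summary = {
        "n_subjects": config.n_subjects,
        "n_significant_eeg_timepoints": int(
            bundle["eeg_group_stats"]["significant"].sum()
        ),
        "n_significant_roi_cells": int(bundle["fmri_roi_stats"]["significant"].sum()),
        "n_significant_fusion_cells": int(
            bundle["fusion_stats"]["significant"].sum()
        )
        if len(bundle["fusion_stats"])
        else 0,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out_dir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    manifest_path = manifest.write()
    bundle["summary"] = summary
    bundle["manifest"] = manifest.doc
    bundle["manifest_path"] = manifest_path
    return bundle
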