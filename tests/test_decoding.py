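"""Pseudo-trials, noise normalization, the classifier contract and the
cross-decoding schemes, including an exhaustive hand-enumerated oracle."""

import itertools

import numpy as np
import pytest

from crossdecode import (
    ClassifierSpec,
    ConditionLabel,
    DesignSpec,
    bin_pseudotrials,
    build_pair_scheme,
    cross_decode_roi,
    cross_decode_timecourse,
    generate_eeg,
    noise_normalize,
    select_top_k_voxels,
    train_test_linear,
)
from crossdecode.decoding import (
    DegenerateTrainingError,
    InfeasibleBinningError,
    _bin_indices,
)
from crossdecode.simulate import EEGEpochSet, FMRIPatternSet, default_channel_layout

from conftest import make_eeg_config, make_fmri_config


# --------------------------------------------------------------------------
# pseudo-trials
# --------------------------------------------------------------------------

class TestBinPseudotrials:
    def test_sixty_trials_into_four_bins_of_fifteen(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((60, 5))
        pt = bin_pseudotrials(data, ["c"] * 60, n_bins=4, seed=1)
        assert pt.data.shape == (4, 5)
        sizes = np.bincount(pt.bin_assignment)
        assert list(sizes) == [15, 15, 15, 15]
        # each pseudo-trial is the mean of its bin
        for b in range(4):
            members = np.flatnonzero(pt.bin_assignment == b)
            assert np.allclose(pt.data[b], data[members].mean(axis=0))

    def test_ten_runs_into_five_bins_of_two(self):
        data = np.arange(20, dtype=float).reshape(10, 2)
        pt = bin_pseudotrials(data, ["r"] * 10, n_bins=5, seed=0)
        assert pt.data.shape == (5, 2)
        assert sorted(np.bincount(pt.bin_assignment)) == [2] * 5

    def test_identity_binning(self):
        data = np.arange(8, dtype=float).reshape(4, 2)
        pt = bin_pseudotrials(data, ["c"] * 4, n_bins=4, seed=3)
        assert sorted(map(tuple, pt.data)) == sorted(map(tuple, data))

    def test_bins_disjoint_and_exhaustive_within_condition(self):
        data = np.zeros((30, 2))
        labels = ["a"] * 14 + ["b"] * 16
        pt = bin_pseudotrials(data, labels, n_bins=4, seed=2)
        assert np.all(pt.bin_assignment >= 0)
        # trials of one condition map only to that condition's pseudo-trials
        for lab in ("a", "b"):
            rows = {pt.bin_assignment[i] for i, l in enumerate(labels) if l == lab}
            assert all(pt.labels[r] == lab for r in rows)

    def test_too_few_trials_rejected(self):
        with pytest.raises(InfeasibleBinningError):
            bin_pseudotrials(np.zeros((3, 2)), ["c"] * 3, n_bins=4, seed=0)


# --------------------------------------------------------------------------
# classifier contract
# --------------------------------------------------------------------------

class TestTrainTestLinear:
    def test_separable_clusters_perfect(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, (20, 4))
        b = rng.normal(5, 0.1, (20, 4))
        acc = train_test_linear(
            np.vstack([a[:10], b[:10]]),
            [0] * 10 + [1] * 10,
            np.vstack([a[10:], b[10:]]),
            [0] * 10 + [1] * 10,
        )
        assert acc == 100.0

    def test_permuted_labels_are_chance_on_average(self):
        rng = np.random.default_rng(1)
        accs = []
        for _ in range(300):
            X = rng.standard_normal((12, 4))
            y = rng.permutation([0] * 6 + [1] * 6)
            X_test = rng.standard_normal((8, 4))
            y_test = rng.permutation([0] * 4 + [1] * 4)
            accs.append(train_test_linear(X[:8], y[:8], X_test, y_test))
        assert abs(np.mean(accs) - 50.0) < 3.0

    def test_cross_decoding_geometry(self):
        """Transfer succeeds along a shared discriminant direction and stays
        at chance along an orthogonal one — the geometric core of
        cross-decoding."""
        rng = np.random.default_rng(2)
        d = np.zeros(6)
        d[0] = 4.0  # discriminant along axis 0
        y = [0] * 10 + [1] * 10
        base = rng.normal(0, 0.2, (40, 6))
        train_X = np.vstack([base[:10] - d / 2, base[10:20] + d / 2])
        offset = np.zeros(6)
        offset[3] = 7.0  # test pair displaced along an unrelated axis
        test_same = np.vstack(
            [base[20:30] - d / 2 + offset, base[30:] + d / 2 + offset]
        )
        assert train_test_linear(train_X, y, test_same, y) == 100.0
        # orthogonal discriminant: redraw training noise each repetition so
        # the chance-level average is over independent classifiers
        d_orth = np.zeros(6)
        d_orth[1] = 4.0
        accs = []
        for _ in range(100):
            b1 = rng.normal(0, 0.2, (20, 6))
            b2 = rng.normal(0, 0.2, (20, 6))
            tr = np.vstack([b1[:10] - d / 2, b1[10:] + d / 2])
            test_orth = np.vstack([b2[:10] - d_orth / 2, b2[10:] + d_orth / 2])
            accs.append(train_test_linear(tr, y, test_orth, y))
        assert abs(np.mean(accs) - 50.0) < 12.0

    def test_one_class_training_rejected(self):
        with pytest.raises(DegenerateTrainingError):
            train_test_linear(np.zeros((4, 2)), [0, 0, 0, 0], np.zeros((2, 2)), [0, 1])


# --------------------------------------------------------------------------
# noise normalization
# --------------------------------------------------------------------------

def _epochs_with_noise_cov(cov, n_trials=200, n_time=50, seed=0):
    rng = np.random.default_rng(seed)
    n_ch = cov.shape[0]
    chol = np.linalg.cholesky(cov)
    data = np.einsum(
        "ij,tjk->tik", chol, rng.standard_normal((n_trials, n_ch, n_time))
    )
    labels = [
        ConditionLabel("animals", "left-up", "no") for _ in range(n_trials)
    ]
    return EEGEpochSet(
        data=data,
        labels=labels,
        time_ms=np.arange(n_time, dtype=float),
        channel_layout=default_channel_layout(n_ch),
    )


class TestNoiseNormalize:
    def test_identity_noise_roughly_preserved(self):
        eeg = _epochs_with_noise_cov(np.eye(4), seed=1)
        out = noise_normalize(eeg)
        assert out.data.shape == eeg.data.shape
        # whitening identity noise is close to a rescaling
        ratio = out.data.std() / eeg.data.std()
        assert 0.8 < ratio < 1.25
        corr = np.corrcoef(
            eeg.data.transpose(1, 0, 2).reshape(4, -1),
            out.data.transpose(1, 0, 2).reshape(4, -1),
        )[:4, 4:]
        assert np.all(np.diag(corr) > 0.99)

    def test_correlated_noise_whitened(self):
        cov = np.full((4, 4), 0.8) + 0.2 * np.eye(4)
        eeg = _epochs_with_noise_cov(cov, n_trials=300, n_time=40, seed=2)
        out = noise_normalize(eeg)
        resid = out.data - out.data.mean(axis=0, keepdims=True)
        samples = resid.transpose(0, 2, 1).reshape(-1, 4)
        emp = samples.T @ samples / len(samples)
        off = emp - np.diag(np.diag(emp))
        assert np.max(np.abs(off)) < 0.1

    def test_whitening_helps_decoding_with_correlated_noise(self, small_design):
        """Replicates the recommendation the normalization implements: with
        spatially correlated noise, decoding after whitening is at least as
        accurate as before (averaged over seeds)."""
        from crossdecode import NoiseSpec

        scheme = build_pair_scheme(small_design)
        before, after = [], []
        for seed in range(5):
            cfg = make_eeg_config(
                small_design,
                amplitude=0.7,
                noise=NoiseSpec(channel_correlation=0.85, temporal_smoothing_ms=0.0),
                epoch_window=(100.0, 200.0),
                latency_high=150.0,
                seed=seed,
            )
            eeg = generate_eeg(cfg)
            white = noise_normalize(eeg)
            r0 = cross_decode_timecourse(
                eeg, "location", "no", scheme, n_iterations=2, seed=seed
            )
            r1 = cross_decode_timecourse(
                white, "location", "no", scheme, n_iterations=2, seed=seed
            )
            before.append(r0.accuracy.mean())
            after.append(r1.accuracy.mean())
        assert np.mean(after) >= np.mean(before) - 1.0


# --------------------------------------------------------------------------
# scheme-level decoding
# --------------------------------------------------------------------------

class TestCrossDecodeROI:
    def test_default_cell_count_is_360(self, default_design):
        cfg = make_fmri_config(
            default_design, {"V1": {"no": 0.5, "low": 0.0, "high": 0.0}}, n_voxels=12
        )
        from crossdecode import generate_fmri

        pat = generate_fmri(cfg)
        scheme = build_pair_scheme(default_design)
        res = cross_decode_roi(pat, "V1", "location", "no", scheme, seed=0)
        assert res.n_cells_averaged == 360
        assert 0.0 <= res.accuracy <= 100.0

    def test_null_snr_is_chance(self, small_design):
        from crossdecode import generate_fmri

        accs = []
        for seed in range(10):
            cfg = make_fmri_config(
                small_design, {"V1": {"no": 0.0, "high": 0.0}}, n_voxels=25, seed=seed
            )
            pat = generate_fmri(cfg)
            scheme = build_pair_scheme(small_design)
            accs.append(
                cross_decode_roi(pat, "V1", "location", "no", scheme, seed=seed).accuracy
            )
        assert abs(np.mean(accs) - 50.0) < 5.0

    def test_planted_snr_gradient_recovered(self, default_design):
        """Location decodable in the V1-like ROI only without clutter and in
        the LOC-like ROI regardless — the planted ordering is recovered."""
        from crossdecode import generate_fmri

        cfg = make_fmri_config(
            default_design,
            {
                "V1like": {"no": 2.0, "low": 1.0, "high": 0.0},
                "LOClike": {"no": 1.0, "low": 1.0, "high": 1.0},
            },
            n_voxels=40,
        )
        pat = generate_fmri(cfg)
        scheme = build_pair_scheme(default_design)
        acc = {
            (roi, cl): cross_decode_roi(pat, roi, "location", cl, scheme, seed=1).accuracy
            for roi in ("V1like", "LOClike")
            for cl in ("no", "high")
        }
        assert acc[("V1like", "no")] > 60.0
        assert abs(acc[("V1like", "high")] - 50.0) < 8.0
        assert acc[("LOClike", "high")] > 55.0

    def test_swapped_factor_roles_for_category(self, small_design):
        """With a strong planted category signal, decoding category across
        locations is above chance (mean over seeds)."""
        from crossdecode import generate_fmri

        scheme = build_pair_scheme(small_design)
        accs = []
        for seed in range(8):
            cfg = make_fmri_config(
                small_design,
                {"V1": {"no": 0.5, "high": 0.5}},
                category_snr={"V1": {"no": 2.0, "high": 2.0}},
                n_voxels=30,
                seed=seed,
            )
            pat = generate_fmri(cfg)
            res = cross_decode_roi(pat, "V1", "category", "no", scheme, seed=seed)
            assert res.target == "category"
            accs.append(res.accuracy)
        assert np.mean(accs) > 60.0


class TestOracleEquivalence:
    def test_toy_scheme_matches_hand_enumeration(self):
        """On a 2-location, 2-category, 8-trial toy set with deterministic
        binning (bins of one trial), the full scheme's averaged accuracy
        equals an exhaustive hand enumeration with an independently coded
        nearest-margin rule replaced by explicit SVM calls per cell."""
        design = DesignSpec(
            categories=("catA", "catB"),
            exemplars_per_category=1,
            locations=("left-up", "right-bottom"),
            clutter_levels=("no",),
            n_runs=2,
            trials_per_condition_per_run=1,
        )
        scheme = build_pair_scheme(design)
        rng = np.random.default_rng(5)
        conds = [
            (cat, loc)
            for cat in design.categories
            for loc in design.locations
        ]
        # two trials per condition, 2-D features
        data = {c: rng.standard_normal((2, 2)) * 2 for c in conds}
        trials, labels = [], []
        for c in conds:
            for t in range(2):
                trials.append(data[c][t])
                labels.append(ConditionLabel(c[0], c[1], "no"))
        eeg = EEGEpochSet(
            data=np.asarray(trials)[:, :, None],
            labels=labels,
            time_ms=np.array([0.0]),
            channel_layout=default_channel_layout(2),
        )
        res = cross_decode_timecourse(
            eeg, "location", "no", scheme, n_iterations=1, seed=9, n_bins=2
        )
        # oracle: enumerate the same cells by hand; with 2 bins of one trial
        # each, pseudo-trials are raw trials selected by the same RNG stream
        rng2 = np.random.default_rng(9)
        groups = {}
        for i, lab in enumerate(labels):
            groups.setdefault((lab.category, lab.location), []).append(i)
        # reproduce the engine's RNG consumption order: _balance draws nothing
        # (already balanced), then per condition two bins
        order = [
            ("catA", "left-up"),
            ("catA", "right-bottom"),
            ("catB", "left-up"),
            ("catB", "right-bottom"),
        ]
        bins = {}
        for key in order:
            perm = rng2.permutation(np.asarray(groups[key]))
            bins[key] = [np.sort(p) for p in np.array_split(perm, 2)]
        accs = []
        X = np.asarray(trials)
        for (l1, l2) in scheme.location_pairs:
            for (ca, cb) in scheme.category_train_test_pairs:
                train_X = np.vstack(
                    [
                        X[bins[(ca, l1)][0]].mean(axis=0),
                        X[bins[(ca, l2)][0]].mean(axis=0),
                    ]
                )
                test_X = np.vstack(
                    [
                        X[bins[(cb, l1)][1]].mean(axis=0),
                        X[bins[(cb, l2)][1]].mean(axis=0),
                    ]
                )
                accs.append(
                    train_test_linear(train_X, [0, 1], test_X, [0, 1])
                )
        assert res.accuracy[0] == pytest.approx(np.mean(accs))

    def test_mean_over_cells_equals_reported_accuracy(self, small_eeg, small_scheme):
        res = cross_decode_timecourse(
            small_eeg, "location", "no", small_scheme,
            n_iterations=2, seed=4, return_cells=True,
        )
        assert np.allclose(res.cell_accuracy.mean(axis=1), res.accuracy)
        assert np.all((res.accuracy >= 0) & (res.accuracy <= 100))


class TestTrainTestSeparation:
    def test_no_raw_trial_in_both_train_and_test_bins(self):
        """Structural check on the bin assignment: the held-out pseudo-trial
        shares no raw trials with the training pseudo-trials."""
        data = np.zeros((20, 3))
        pt = bin_pseudotrials(data, ["c"] * 20, n_bins=4, seed=11)
        train_rows = {0, 1, 2}
        test_rows = {3}
        train_trials = {
            i for i, b in enumerate(pt.bin_assignment) if b in train_rows
        }
        test_trials = {i for i, b in enumerate(pt.bin_assignment) if b in test_rows}
        assert train_trials.isdisjoint(test_trials)
        assert train_trials | test_trials == set(range(20))

    def test_label_swap_symmetry(self):
        """Swapping the two class labels leaves the accuracy unchanged
        (binary classification symmetry)."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            train_X = rng.standard_normal((6, 5))
            test_X = rng.standard_normal((4, 5))
            y_tr = [0, 0, 0, 1, 1, 1]
            y_te = [0, 0, 1, 1]
            a = train_test_linear(train_X, y_tr, test_X, y_te)
            b = train_test_linear(
                train_X, [1 - y for y in y_tr], test_X, [1 - y for y in y_te]
            )
            assert a == pytest.approx(b)


# --------------------------------------------------------------------------
# voxel selection
# --------------------------------------------------------------------------

class TestSelectTopK:
    def test_top_k_dominates_excluded(self):
        rng = np.random.default_rng(0)
        vol = rng.standard_normal((10, 10, 10))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.ravel()[:1000] = True
        sel = select_top_k_voxels(vol, mask, 325)
        assert sel.shape == (325, 3)
        chosen = {tuple(c) for c in sel}
        vals_in = [vol[c] for c in chosen]
        vals_out = [
            vol[tuple(c)]
            for c in np.argwhere(mask)
            if tuple(c) not in chosen
        ]
        assert min(vals_in) >= max(vals_out)

    def test_k_equals_mask_size(self):
        vol = np.zeros((3, 3, 3))
        mask = np.ones((3, 3, 3), dtype=bool)
        sel = select_top_k_voxels(vol, mask, 27)
        assert sel.shape == (27, 3)

    def test_constant_map_tie_break_by_coordinate(self):
        vol = np.ones((2, 2, 2))
        mask = np.ones((2, 2, 2), dtype=bool)
        sel = select_top_k_voxels(vol, mask, 3)
        assert [tuple(c) for c in sel] == [(0, 0, 0), (0, 0, 1), (0, 1, 0)]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            select_top_k_voxels(np.zeros((2, 2, 2)), np.ones((2, 2, 2), bool), 9)
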