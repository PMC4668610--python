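"""CSP: covariance estimation, simultaneous diagonalization, multiclass
decompositions, feature transform, and spatial patterns."""

import numpy as np
import pytest
import scipy.linalg

from emgshift import (
    DataError,
    InvalidArgumentError,
    WindowSet,
    class_covariance,
    csp_transform,
    fit_multiclass,
    fit_two_class_csp,
    spatial_patterns,
)
from emgshift.csp import ClassCovariance, load_model, save_model
from emgshift.features import VARIANCE_FLOOR

from conftest import random_spd


def make_windowset(windows, labels):
    windows = np.asarray(windows, dtype=float)
    n = windows.shape[0]
    return WindowSet(windows=windows, labels=np.asarray(labels),
                     trial_ids=np.arange(n), fs=1000.0,
                     channels=tuple(range(windows.shape[1])))


class TestClassCovariance:
    def test_hand_computed_single_window(self):
        w = np.array([[[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]]])
        cov = class_covariance(make_windowset(w, [0]), 0)
        assert np.allclose(cov.sigma, (4.0 / 3.0) * np.eye(2))

    def test_duplicating_windows_leaves_average_unchanged(self, rng):
        w = rng.standard_normal((3, 4, 50))
        ws1 = make_windowset(w, [0, 0, 0])
        ws2 = make_windowset(np.concatenate([w, w]), [0] * 6)
        c1 = class_covariance(ws1, 0)
        c2 = class_covariance(ws2, 0)
        assert np.allclose(c1.sigma, c2.sigma)

    def test_ridge_scales_with_trace(self):
        w = np.array([[[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]]])
        base = class_covariance(make_windowset(w, [0]), 0).sigma
        ridged = class_covariance(make_windowset(w, [0]), 0, ridge=0.1).sigma
        expected = base + 0.1 * (np.trace(base) / 2) * np.eye(2)
        assert np.allclose(ridged, expected)

    def test_missing_motion_raises(self, rng):
        ws = make_windowset(rng.standard_normal((2, 3, 20)), [0, 0])
        with pytest.raises(DataError):
            class_covariance(ws, 5)


class TestTwoClassCSP:
    def test_diagonal_toy_case(self):
        bank = fit_two_class_csp(
            ClassCovariance(0, np.diag([4.0, 1.0]), 1),
            ClassCovariance(1, np.diag([1.0, 4.0]), 1),
        )
        assert np.allclose(bank.d_j, [0.8, 0.2])
        assert np.allclose(bank.d_k, [0.2, 0.8])
        # filters are axis-aligned up to scale
        assert abs(bank.W[0, 1]) < 1e-12
        assert abs(bank.W[1, 0]) < 1e-12
        assert bank.selected == (0, 1)

    def test_equal_covariances_give_half_eigenvalues(self, rng):
        sigma = random_spd(rng, 5)
        bank = fit_two_class_csp(ClassCovariance(0, sigma, 1),
                                 ClassCovariance(1, sigma.copy(), 1))
        assert np.allclose(bank.d_j, 0.5)
        assert np.allclose(bank.d_k, 0.5)

    def test_selected_filter_attains_max_rayleigh_quotient(self, rng):
        a = random_spd(rng, 6)
        b = random_spd(rng, 6)
        bank = fit_two_class_csp(ClassCovariance(0, a, 1),
                                 ClassCovariance(1, b, 1))
        w = bank.W[bank.selected[0]]
        rq = (w @ a @ w) / (w @ b @ w)
        # brute-force random-direction oracle
        dirs = rng.standard_normal((100_000, 6))
        brute = np.max(np.einsum("nd,de,ne->n", dirs, a, dirs)
                       / np.einsum("nd,de,ne->n", dirs, b, dirs))
        assert rq >= brute - 1e-6 * abs(brute)
        # and matches the generalized-eigenvalue solution
        top = scipy.linalg.eigh(a, b, eigvals_only=True)[-1]
        assert rq == pytest.approx(top, rel=1e-8)

    def test_diagonalization_contract_random_pairs(self, rng):
        for dim in (2, 5, 17, 96):
            a, b = random_spd(rng, dim), random_spd(rng, dim)
            bank = fit_two_class_csp(ClassCovariance(0, a, 1),
                                     ClassCovariance(1, b, 1))
            dj = bank.W @ a @ bank.W.T
            dk = bank.W @ b @ bank.W.T
            scale = np.abs(np.diag(dj)).max()
            assert np.abs(dj - np.diag(np.diag(dj))).max() < 1e-8 * scale
            assert np.abs(dk - np.diag(np.diag(dk))).max() < 1e-8
            assert np.allclose(np.diag(dj) + np.diag(dk), 1.0, atol=1e-8)

    def test_eigenvalue_orderings_are_reversed(self, rng):
        a, b = random_spd(rng, 8), random_spd(rng, 8)
        bank = fit_two_class_csp(ClassCovariance(0, a, 1),
                                 ClassCovariance(1, b, 1))
        assert np.all(np.diff(bank.d_j) <= 1e-12)   # descending
        assert np.all(np.diff(bank.d_k) >= -1e-12)  # ascending
        assert np.argmax(bank.d_j) == np.argmin(bank.d_k)

    def test_scale_invariance_of_filters_and_eigenvalues(self, rng):
        a, b = random_spd(rng, 5), random_spd(rng, 5)
        b1 = fit_two_class_csp(ClassCovariance(0, a, 1),
                               ClassCovariance(1, b, 1))
        b2 = fit_two_class_csp(ClassCovariance(0, 7.0 * a, 1),
                               ClassCovariance(1, 7.0 * b, 1))
        assert np.allclose(b1.d_j, b2.d_j)
        # filter directions identical; scale differs by 1/sqrt(7)
        norm1 = b1.W / np.linalg.norm(b1.W, axis=1, keepdims=True)
        norm2 = b2.W / np.linalg.norm(b2.W, axis=1, keepdims=True)
        assert np.allclose(norm1, norm2, atol=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            fit_two_class_csp(ClassCovariance(0, random_spd(rng, 3), 1),
                              ClassCovariance(1, random_spd(rng, 4), 1))


class TestMulticlass:
    def test_ovo_bank_and_feature_counts_for_11_classes(self, rng):
        covs = [ClassCovariance(m, random_spd(rng, 4), 1) for m in range(11)]
        model = fit_multiclass(covs, "OvO")
        assert len(model.banks) == 55
        assert model.n_features == 110

    def test_ovr_bank_and_feature_counts_for_11_classes(self, rng):
        covs = [ClassCovariance(m, random_spd(rng, 4), 1) for m in range(11)]
        model = fit_multiclass(covs, "OvR")
        assert len(model.banks) == 11
        assert model.n_features == 22

    def test_two_classes_ovr_rest_equals_other_class(self, rng):
        a, b = random_spd(rng, 4), random_spd(rng, 4)
        covs = [ClassCovariance(0, a, 1), ClassCovariance(1, b, 1)]
        ovo = fit_multiclass(covs, "OvO")
        ovr = fit_multiclass(covs, "OvR")
        # the first OvR bank (class 0 vs rest=class 1) solves the same
        # problem as the single OvO bank
        assert np.allclose(ovo.banks[0].W, ovr.banks[0].W)
        assert np.allclose(ovo.banks[0].d_j, ovr.banks[0].d_j)

    def test_single_class_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            fit_multiclass([ClassCovariance(0, random_spd(rng, 3), 1)], "OvO")


class TestTransform:
    def test_pure_class_signals_recover_toy_variances(self, rng):
        # two channels carrying independent sources with variances (4, 1)
        # for class 0 and (1, 4) for class 1
        l = 40960
        src = rng.standard_normal((2, l))
        src = (src - src.mean(axis=1, keepdims=True))
        src /= src.std(axis=1, ddof=1, keepdims=True)
        w0 = (np.diag([2.0, 1.0]) @ src)[None]
        w1 = (np.diag([1.0, 2.0]) @ src)[None]
        ws = make_windowset(np.concatenate([w0, w1]), [0, 1])
        covs = [class_covariance(ws, 0), class_covariance(ws, 1)]
        model = fit_multiclass(covs, "OvO")
        fm = csp_transform(model, ws)
        # class-0 window: the underlying component variances are 4:1, and
        # with the W (S_j + S_k) W' = I scaling the filters carry 1/sqrt(5),
        # so the log-variances are log 0.8 and log 0.2 (difference log 4)
        assert fm.values[0, 0] - fm.values[0, 1] == pytest.approx(
            np.log(4.0), abs=0.05)
        assert fm.values[0, 0] == pytest.approx(np.log(0.8), abs=0.05)
        assert fm.values[0, 1] == pytest.approx(np.log(0.2), abs=0.05)

    def test_zero_window_maps_to_log_floor(self, rng):
        w = rng.standard_normal((4, 3, 50))
        ws = make_windowset(w, [0, 0, 1, 1])
        covs = [class_covariance(ws, 0, ridge=1e-6),
                class_covariance(ws, 1, ridge=1e-6)]
        model = fit_multiclass(covs, "OvO")
        zero_ws = make_windowset(np.zeros((1, 3, 50)), [0])
        with pytest.warns(UserWarning):
            fm = csp_transform(model, zero_ws)
        assert np.allclose(fm.values, np.log(VARIANCE_FLOOR))

    def test_channel_permutation_invariance(self, rng):
        w = rng.standard_normal((6, 4, 80))
        labels = [0, 0, 0, 1, 1, 1]
        perm = [2, 0, 3, 1]
        ws = make_windowset(w, labels)
        ws_p = make_windowset(w[:, perm], labels)
        covs = [class_covariance(ws, m) for m in (0, 1)]
        covs_p = [class_covariance(ws_p, m) for m in (0, 1)]
        fm = csp_transform(fit_multiclass(covs, "OvO"), ws)
        fm_p = csp_transform(fit_multiclass(covs_p, "OvO"), ws_p)
        assert np.allclose(fm.values, fm_p.values, atol=1e-8)

    def test_channel_count_mismatch_rejected(self, rng):
        w = rng.standard_normal((4, 3, 50))
        ws = make_windowset(w, [0, 0, 1, 1])
        covs = [class_covariance(ws, m) for m in (0, 1)]
        model = fit_multiclass(covs, "OvO")
        bad = make_windowset(rng.standard_normal((2, 5, 50)), [0, 1])
        with pytest.raises(InvalidArgumentError):
            csp_transform(model, bad)


class TestPatterns:
    def test_patterns_invert_filters(self, rng):
        a, b = random_spd(rng, 5), random_spd(rng, 5)
        bank = fit_two_class_csp(ClassCovariance(0, a, 1),
                                 ClassCovariance(1, b, 1))
        assert np.allclose(bank.patterns @ bank.W, np.eye(5), atol=1e-8) or \
            np.allclose(bank.W @ bank.patterns, np.eye(5), atol=1e-8)

    def test_diagonal_toy_pattern_is_coordinate_axis(self):
        bank = fit_two_class_csp(
            ClassCovariance(0, np.diag([4.0, 1.0]), 1),
            ClassCovariance(1, np.diag([1.0, 4.0]), 1),
        )
        pats = spatial_patterns(bank)
        assert pats.shape == (2, 2)
        assert np.allclose(np.abs(pats[:, 0]), [1.0, 0.0], atol=1e-12)

    def test_pattern_reshapes_to_grid(self, rng):
        dim = 12  # 3 x 4 grid
        a, b = random_spd(rng, dim), random_spd(rng, dim)
        bank = fit_two_class_csp(ClassCovariance(0, a, 1),
                                 ClassCovariance(1, b, 1))
        pats = spatial_patterns(bank)
        assert pats[:, 0].reshape(3, 4).shape == (3, 4)
        assert np.abs(pats).max() == pytest.approx(1.0)


def test_model_serialization_round_trip(tmp_path, rng):
    covs = [ClassCovariance(m, random_spd(rng, 4), 7) for m in range(3)]
    model = fit_multiclass(covs, "OvR")
    path = save_model(tmp_path / "model.h5", model, channels=(0, 1, 2, 3))
    back = load_model(path)
    assert back.scheme == model.scheme
    assert back.n_classes == model.n_classes
    assert back.feature_names == model.feature_names
    for b1, b2 in zip(model.banks, back.banks):
        assert b1.class_pair == b2.class_pair
        assert b1.selected == b2.selected
        assert np.array_equal(b1.W, b2.W)
        assert np.array_equal(b1.d_j, b2.d_j)
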