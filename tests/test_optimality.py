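"""Prewhitened-GLM detection power and estimation efficiency."""

import numpy as np
import pytest

from fmridesign import (
    DesignSpec,
    DegenerateDesignError,
    Event,
    EventSequence,
    GLMSetup,
    build_detection_matrix,
    build_fir_matrix,
    canonical_hrf,
    detection_power,
    estimate_ar1,
    estimation_efficiency,
    generate_alternating_sequence,
    whitening_matrix,
)
from fmridesign.optimality import _whiten


def make_sequence(onsets_and_types, n_scans=294, tr=1.5):
    events = tuple(
        Event(s, t, 0.0 if null else 1.0, is_null=null)
        for s, t, null in onsets_and_types
    )
    return EventSequence(events=events, n_scans=n_scans, tr=tr)


class TestDetectionMatrix:
    def test_single_event_column_is_shifted_hrf(self, hrf_tr):
        seq = make_sequence([(10, "cue", False), (60, "target", False)], n_scans=100)
        setup = build_detection_matrix(seq, hrf_tr)
        cue = setup.X[:, setup.columns.index("cue")]
        np.testing.assert_allclose(cue[10:31], hrf_tr.samples)
        assert not cue[:10].any()

    def test_cue_and_target_are_distinct_regressors(self, default_sequence, hrf_tr):
        setup = build_detection_matrix(default_sequence, hrf_tr)
        assert setup.columns == ["intercept", "cue", "target"]
        cue = setup.X[:, 1]
        target = setup.X[:, 2]
        assert np.abs(cue - target).max() > 0.1

    def test_default_contrast_is_differential(self, default_sequence, hrf_tr):
        setup = build_detection_matrix(default_sequence, hrf_tr)
        np.testing.assert_array_equal(setup.contrast, [[0.0, 1.0, -1.0]])

    def test_cue_only_contrast_available(self, default_sequence, hrf_tr):
        setup = build_detection_matrix(default_sequence, hrf_tr, contrast="cue")
        np.testing.assert_array_equal(setup.contrast, [[0.0, 1.0, 0.0]])

    def test_all_null_type_raises_rank_deficiency(self, hrf_tr):
        seq = make_sequence(
            [(10, "cue", False), (20, "target", True), (40, "cue", False)]
        )
        with pytest.raises(DegenerateDesignError, match="target"):
            build_detection_matrix(seq, hrf_tr)

    def test_empty_sequence_rejected(self, hrf_tr):
        seq = EventSequence(events=(), n_scans=100, tr=1.5)
        with pytest.raises(DegenerateDesignError):
            build_detection_matrix(seq, hrf_tr)


class TestFirMatrix:
    def test_impulse_fills_lag_diagonal(self):
        seq = make_sequence([(10, "cue", False), (80, "target", False)], n_scans=120)
        setup = build_fir_matrix(seq, n_lags=5)
        for k in range(5):
            col = setup.X[:, setup.columns.index(f"cue_lag{k}")]
            assert col[10 + k] == 1.0
            assert col.sum() == 1.0

    def test_noiseless_fir_recovers_hrf(self, hrf_tr):
        # well-separated events: FIR least squares = exact deconvolution
        onsets = [(s, "cue", False) for s in range(5, 280, 35)]
        seq = make_sequence(onsets)
        train = np.zeros(294)
        train[[s for s, _, _ in onsets]] = 1.0
        y = np.convolve(train, hrf_tr.samples)[:294]
        # window spans the whole 21-sample kernel so recovery is exact
        setup = build_fir_matrix(seq, n_lags=21)
        beta, *_ = np.linalg.lstsq(setup.X, y, rcond=None)
        fir = beta[1:22]
        np.testing.assert_allclose(fir, hrf_tr.samples, atol=1e-8)

    def test_overlap_worsens_conditioning(self):
        sep = make_sequence([(10, "cue", False), (100, "cue", False)], n_scans=200)
        close = make_sequence([(10, "cue", False), (11, "cue", False)], n_scans=200)
        cond_sep = np.linalg.cond(build_fir_matrix(sep, 10).X.T @ build_fir_matrix(sep, 10).X)
        cond_close = np.linalg.cond(build_fir_matrix(close, 10).X.T @ build_fir_matrix(close, 10).X)
        assert cond_close > cond_sep

    def test_contrast_selects_cue_lags(self, default_sequence):
        setup = build_fir_matrix(default_sequence, n_lags=20)
        assert setup.contrast.shape == (20, len(setup.columns))
        picked = [setup.columns[j] for j in np.flatnonzero(setup.contrast.sum(0))]
        assert picked == [f"cue_lag{k}" for k in range(20)]

    def test_too_many_lags_rejected(self, default_sequence):
        from fmridesign import InvalidDesignError

        with pytest.raises(InvalidDesignError):
            build_fir_matrix(default_sequence, n_lags=294)


class TestWhitening:
    def test_identity_at_zero_rho(self):
        np.testing.assert_array_equal(whitening_matrix(0.0, 5), np.eye(5))

    def test_whitening_identity(self):
        rho, n = 0.5, 50
        K = whitening_matrix(rho, n)
        V = rho ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        np.testing.assert_allclose(K @ V @ K.T, np.eye(n), atol=1e-8)

    def test_fast_transform_matches_matrix(self, rng):
        rho, n = 0.7, 40
        a = rng.standard_normal((n, 3))
        np.testing.assert_allclose(
            _whiten(rho, a), whitening_matrix(rho, n) @ a, atol=1e-12
        )

    def test_ar1_estimate_recovers_rho(self):
        # Monte-Carlo: AR(1) with rho = 0.3 at the default run length
        from scipy import signal

        rhos = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            e = rng.standard_normal(394)
            x = signal.lfilter([1.0], [1.0, -0.3], e)[100:]
            rhos.append(estimate_ar1(x))
        assert np.mean(rhos) == pytest.approx(0.3, abs=0.1)

    def test_estimate_stays_stationary(self, rng):
        # smooth, trending and constant-ish series all map inside (-1, 1)
        for x in (np.cumsum(np.ones(200)), np.sin(np.arange(200) / 3),
                  rng.standard_normal(200)):
            assert abs(estimate_ar1(x)) < 1.0
        assert estimate_ar1(np.zeros(50)) == 0.0


class TestEfficiencyMeasures:
    def test_unit_case_closed_form(self):
        # orthonormal single task column, V = I, C = [1], sigma2 = 1 -> D = 1
        n = 16
        x = np.zeros(n)
        x[3] = 1.0
        setup = GLMSetup(X=x[:, None], columns=["task"], contrast=[1.0])
        d = detection_power(setup, np.zeros(n), scale_by_fit=False, rho=0.0)
        assert d == pytest.approx(1.0)

    def test_matches_dense_oracle_on_toy_design(self, rng):
        # 8x2 design: formula path vs explicit inversion and trace
        X = np.array(
            [
                [1.0, 0.2],
                [1.0, 0.9],
                [0.5, 0.1],
                [0.3, 0.8],
                [1.2, 0.0],
                [0.0, 1.1],
                [0.7, 0.7],
                [0.4, 0.3],
            ]
        )
        y = rng.standard_normal(8)
        C = np.array([[1.0, 0.0]])
        rho = 0.3
        setup = GLMSetup(X=X, columns=["a", "b"], contrast=C)
        d = detection_power(setup, y, rho=rho)
        K = whitening_matrix(rho, 8)
        Xw, yw = K @ X, K @ y
        beta = np.linalg.inv(Xw.T @ Xw) @ Xw.T @ yw
        resid = yw - Xw @ beta
        sigma2 = max(resid @ resid / 6, 1e-12)
        oracle = 1.0 / (sigma2 * np.trace(C @ np.linalg.inv(Xw.T @ Xw) @ C.T))
        assert d == pytest.approx(oracle, abs=1e-10 * oracle)

    def test_whitening_invariance_with_known_covariance(self, default_sequence, hrf_tr, rng):
        # D on raw (X, V) equals D on premultiplied (KX, I)
        setup = build_detection_matrix(default_sequence, hrf_tr)
        y = rng.standard_normal(default_sequence.n_scans)
        rho = 0.4
        d_raw = detection_power(setup, y, rho=rho)
        K = whitening_matrix(rho, default_sequence.n_scans)
        setup_w = GLMSetup(
            X=K @ setup.X, columns=setup.columns, contrast=setup.contrast
        )
        d_white = detection_power(setup_w, K @ y, rho=0.0)
        assert d_raw == pytest.approx(d_white, rel=1e-8)

    def test_fir_closed_form_for_isolated_events(self):
        # isolated events, V = I, no overlap: X'X diagonal with event count
        # m per lag, so E = m / n_lags at sigma2 = 1
        n_lags, m = 4, 6
        onsets = [(s, "cue", False) for s in range(5, 5 + 30 * m, 30)]
        seq = make_sequence(onsets)
        setup = build_fir_matrix(seq, n_lags=n_lags)
        setup.X = setup.X[:, 1:]  # drop intercept for the pure closed form
        setup.columns = setup.columns[1:]
        setup.contrast = setup.contrast[:, 1:]
        e = estimation_efficiency(
            setup, np.zeros(294), scale_by_fit=False, rho=0.0
        )
        assert e == pytest.approx(m / n_lags)

    def test_relabelling_symmetry(self, hrf_tr, rng):
        # swapping cue and target labels leaves the FIR efficiency of the
        # contrasted type's lags unchanged in a symmetric design
        onsets = [(10 + 8 * i, "cue" if i % 2 == 0 else "target", False) for i in range(20)]
        seq = make_sequence(onsets)
        swapped = make_sequence(
            [(s, "target" if t == "cue" else "cue", n) for s, t, n in onsets]
        )
        y = rng.standard_normal(294)
        e1 = estimation_efficiency(build_fir_matrix(seq, 10), y, rho=0.0)
        e2 = estimation_efficiency(
            build_fir_matrix(swapped, 10, contrast_type="target"), y, rho=0.0
        )
        assert e1 == pytest.approx(e2, rel=1e-10)

    def test_noiseless_model_data_is_maximal(self, hrf_tr):
        # data generated exactly by X: sigma2 floors out, D is maximal
        # among same-design comparisons with noisy data
        seq = make_sequence([(10 + 12 * i, "cue" if i % 2 == 0 else "target", False) for i in range(20)])
        setup = build_detection_matrix(seq, hrf_tr)
        beta = np.array([0.0, 1.0, 1.0])
        clean = setup.X @ beta
        d_clean = detection_power(setup, clean)
        noisy = clean + np.random.default_rng(0).standard_normal(len(clean))
        d_noisy = detection_power(setup, noisy)
        assert d_clean > d_noisy * 100

    def test_efficiency_increases_with_upper_bound(self):
        # fixed l = 2: more jitter resolves the response shape better
        from scipy import stats
        from fmridesign import evaluate_design

        means = []
        u_values = range(2, 21, 3)
        for u in u_values:
            vals = []
            for rep in range(20):
                rng = np.random.default_rng(rep)
                res = evaluate_design(DesignSpec(l_isi=2, u_isi=u), rng)
                vals.append(res.estimation_efficiency)
            means.append(np.mean(vals))
        assert stats.spearmanr(list(u_values), means).statistic > 0
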