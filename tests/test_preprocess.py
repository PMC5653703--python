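import numpy as np
import pytest

from bayesconn.cohort import CohortSpec, ConfoundSet, simulate_confounds, simulate_subject, template_model
from bayesconn.errors import DesignMatrixError, ParameterError
from bayesconn.preprocess import (
    DCT_PROJECTION,
    GAUSSIAN_RUNNING_LINE,
    CohortLedger,
    apply_exclusions,
    highpass_filter,
    preprocess_subject,
    regress_confounds,
)

from .oracles import fitted_amplitude, projection_residual

TR = 2.38


def _toy_confounds(T, seed=0, k=4):
    rng = np.random.default_rng(seed)
    return ConfoundSet(regressors=rng.standard_normal((T, k)),
                       names=tuple(f"c{i}" for i in range(k)))


class TestRegressConfounds:
    def test_series_equal_to_confound_column_residualizes_to_zero(self):
        conf = _toy_confounds(80, seed=1)
        series = np.tile(conf.regressors[:, [0]], (1, 3))
        out = regress_confounds(series, conf)
        assert np.max(np.abs(out.values)) < 1e-10

    def test_orthogonal_confounds_leave_centered_input(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 2))
        # build confounds orthogonal to X and to the intercept
        C = rng.standard_normal((200, 3))
        C = projection_residual(C, X)  # orthogonal to X and mean
        out = regress_confounds(X, ConfoundSet(regressors=C, names=("a", "b", "c")))
        np.testing.assert_allclose(out.values, X - X.mean(axis=0), atol=1e-8)

    def test_known_mixing_recovered_matches_projection_oracle(self):
        rng = np.random.default_rng(3)
        conf = _toy_confounds(150, seed=3)
        signal = rng.standard_normal((150, 5))
        mixed = signal + 2.0 * conf.regressors[:, [1]] @ np.ones((1, 5))
        out = regress_confounds(mixed, conf)
        oracle = projection_residual(mixed, conf.regressors)
        np.testing.assert_allclose(out.values, oracle, atol=1e-8)
        # correlation with the raw signal is capped near sqrt(1 - k/T)
        for col in range(5):
            assert np.corrcoef(out.values[:, col], signal[:, col])[0, 1] > 0.95

    def test_residuals_orthogonal_to_design(self):
        conf = _toy_confounds(120, seed=4)
        rng = np.random.default_rng(5)
        X = rng.standard_normal((120, 3)) + conf.regressors[:, :3]
        out = regress_confounds(X, conf)
        proj = conf.regressors.T @ out.values
        assert np.max(np.abs(proj)) < 1e-8 * np.linalg.norm(X)

    def test_idempotent(self):
        conf = _toy_confounds(100, seed=6)
        rng = np.random.default_rng(7)
        X = rng.standard_normal((100, 4))
        once = regress_confounds(X, conf)
        twice = regress_confounds(once, conf)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)

    def test_duplicate_columns_dropped_silently(self):
        base = _toy_confounds(90, seed=8, k=2)
        dup = ConfoundSet(
            regressors=np.column_stack([base.regressors, base.regressors[:, 0]]),
            names=("c0", "c1", "c0_copy"),
        )
        rng = np.random.default_rng(9)
        X = rng.standard_normal((90, 2))
        out = regress_confounds(X, dup)
        assert "c0_copy" not in out.provenance[-1]["regressors"]

    def test_collinear_columns_raise_naming_them(self):
        base = _toy_confounds(90, seed=10, k=2)
        coll = ConfoundSet(
            regressors=np.column_stack([base.regressors,
                                        base.regressors @ np.array([1.0, -2.0])]),
            names=("c0", "c1", "combo"),
        )
        with pytest.raises(DesignMatrixError) as err:
            regress_confounds(np.zeros((90, 2)), coll)
        assert "combo" in err.value.collinear

    def test_row_mismatch_rejected(self):
        conf = _toy_confounds(50)
        with pytest.raises(Exception):
            regress_confounds(np.zeros((60, 2)), conf)


class TestHighpassFilter:
    def test_constant_column_removed(self):
        X = np.full((110, 2), 3.7)
        out = highpass_filter(X, 100.0, TR)
        assert np.max(np.abs(out.values)) < 1e-10

    @pytest.mark.parametrize("method", [DCT_PROJECTION, GAUSSIAN_RUNNING_LINE])
    def test_fast_oscillation_preserved(self, method):
        """A 20 s sinusoid passes a 100 s high-pass within 5% amplitude."""
        t = np.arange(110) * TR
        y = np.sin(2 * np.pi * t / 20.0)
        out = highpass_filter(y[:, None], 100.0, TR, method=method).values[:, 0]
        assert fitted_amplitude(out, 20.0, TR) == pytest.approx(1.0, abs=0.05)

    def test_slow_oscillation_attenuated(self):
        """Components slower than the cutoff lose > 90% amplitude under the
        default (cosine-basis) filter."""
        t = np.arange(110) * TR
        for period in (120.0, 150.0, 300.0):
            y = np.sin(2 * np.pi * t / period)
            out = highpass_filter(y[:, None], 100.0, TR).values[:, 0]
            assert fitted_amplitude(out, period, TR) < 0.10

    @pytest.mark.parametrize("method", [DCT_PROJECTION, GAUSSIAN_RUNNING_LINE])
    def test_linear_drift_removed(self, method):
        t = np.arange(110) * TR
        y = 0.5 * (t / t[-1]) - 0.25
        out = highpass_filter(y[:, None], 100.0, TR, method=method).values[:, 0]
        assert np.var(out) < 0.10 * np.var(y)

    def test_output_zero_mean(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((110, 4)) + 5.0
        out = highpass_filter(X, 100.0, TR)
        assert np.max(np.abs(out.values.mean(axis=0))) < 1e-10

    def test_cutoff_at_or_below_resolution_rejected(self):
        with pytest.raises(ParameterError):
            highpass_filter(np.zeros((110, 1)), 2 * TR, TR)

    def test_shape_preserved(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((110, 14))
        assert highpass_filter(X, 100.0, TR).values.shape == X.shape


class TestPreprocessOrders:
    def test_orders_commute_for_prefiltered_confounds(self, roi14):
        """When the confound columns carry no sub-cutoff power, regressing
        then filtering equals filtering then regressing (both reduce to the
        projection off the joint span)."""
        model = template_model(roi14, seed=1)
        spec = CohortSpec(T=110, seed=0)
        series, confounds = simulate_subject(model, spec, seed=21,
                                             labels=roi14.labels)
        pref = highpass_filter(confounds.regressors, 100.0, TR,
                               method=DCT_PROJECTION)
        conf_hp = ConfoundSet(regressors=pref.values, names=confounds.names)
        a = preprocess_subject(series, conf_hp, order="regress-first",
                               method=DCT_PROJECTION)
        b = preprocess_subject(series, conf_hp, order="filter-first",
                               method=DCT_PROJECTION)
        np.testing.assert_allclose(a.values, b.values, atol=1e-6)

    def test_provenance_records_both_steps(self, roi14):
        model = template_model(roi14, seed=1)
        series, confounds = simulate_subject(model, CohortSpec(T=110, seed=0),
                                             seed=22, labels=roi14.labels)
        out = preprocess_subject(series, confounds)
        steps = [p["step"] for p in out.provenance]
        assert steps == ["regress_confounds", "highpass_filter"]


class TestSimulatedConfounds:
    def test_derivatives_are_backward_differences(self):
        conf = simulate_confounds(110, seed=0)
        base = conf.regressors[:, :8]
        deriv = conf.regressors[:, 8:]
        assert np.all(deriv[0] == 0.0)
        np.testing.assert_allclose(deriv[1:], np.diff(base, axis=0), atol=1e-12)

    def test_names_cover_motion_wm_csf_and_derivatives(self):
        conf = simulate_confounds(110, seed=0)
        assert len(conf.names) == 16
        assert "wm_mean" in conf.names and "csf_mean_derivative" in conf.names


class TestExclusionAccounting:
    def test_study_sized_ledger(self):
        """87 acquired minus 15 excluded and 42 minus 3 give 72 and 39."""
        ledger = CohortLedger(
            acquired_a=87, acquired_b=42,
            excluded_a=tuple((f"p{i}", "image quality") for i in range(15)),
            excluded_b=tuple((f"c{i}", "scanner artifact") for i in range(3)),
        )
        assert apply_exclusions(ledger) == (72, 39)

    def test_zero_exclusions_retain_everyone(self):
        assert apply_exclusions(CohortLedger(acquired_a=10, acquired_b=5)) == (10, 5)

    def test_over_exclusion_rejected(self):
        with pytest.raises(ParameterError):
            CohortLedger(acquired_a=1, acquired_b=0,
                         excluded_a=(("s1", "x"), ("s2", "y")))

    def test_empty_reason_rejected(self):
        with pytest.raises(ParameterError):
            CohortLedger(acquired_a=2, acquired_b=2, excluded_a=(("s1", ""),))
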