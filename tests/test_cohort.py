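import numpy as np
import pytest

from bayesconn.cohort import (
    CohortSpec,
    build_template_graph,
    default_homotopic_targets,
    generate_precision,
    shrink_model,
    simulate_cohort,
    simulate_subject,
    template_model,
)
from bayesconn.errors import ConvergenceError, ParameterError
from bayesconn.gwishart import partial_from_precision
from bayesconn.preprocess import regress_confounds
from bayesconn.rois import default_roi_set
from bayesconn.studies import reduced_roi_set


class TestTemplateGraph:
    def test_zero_extra_probability_leaves_only_homotopic_edges(self, roi14):
        G = build_template_graph(roi14, extra_edge_prob=0.0, seed=1)
        assert G.sum() == 2 * 7
        for i, j in roi14.homotopic_pairs:
            assert G[i, j] == 1

    def test_probability_one_gives_complete_graph(self, roi14):
        G = build_template_graph(roi14, extra_edge_prob=1.0, seed=1)
        assert np.triu(G, 1).sum() == 91

    def test_same_seed_reproduces_graph(self, roi14):
        a = build_template_graph(roi14, 0.3, seed=5)
        b = build_template_graph(roi14, 0.3, seed=5)
        assert np.array_equal(a, b)

    def test_invalid_probability_rejected(self, roi14):
        with pytest.raises(ParameterError):
            build_template_graph(roi14, extra_edge_prob=1.5, seed=0)


class TestGeneratePrecision:
    def test_empty_graph_gives_diagonal_precision(self):
        G = np.zeros((4, 4), dtype=int)
        model = generate_precision(G, seed=0)
        off = ~np.eye(4, dtype=bool)
        assert np.all(model.precision[off] == 0)
        assert np.all(model.partials[off] == 0)

    def test_two_node_target_matches_closed_form(self):
        G = np.array([[0, 1], [1, 0]])
        model = generate_precision(G, {(0, 1): 0.5}, seed=0)
        K = model.precision
        assert K[0, 1] == pytest.approx(-0.5 * np.sqrt(K[0, 0] * K[1, 1]))
        assert model.partials[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_default_template_hits_strongest_homotopic_targets(self, roi14):
        """Thalamus (0.55) and caudate (0.41) pairs are realized within 0.02."""
        model = template_model(roi14, seed=0)
        targets = default_homotopic_targets(roi14)
        for (i, j), want in targets.items():
            assert model.partials[i, j] == pytest.approx(want, abs=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_generated_precision_is_spd_on_graph(self, roi14, seed):
        G = build_template_graph(roi14, 0.3, seed=seed)
        model = generate_precision(G, default_homotopic_targets(roi14), seed=seed)
        assert np.min(np.linalg.eigvalsh(model.precision)) > 0
        off = ~np.eye(14, dtype=bool)
        assert np.all(model.precision[(G == 0) & off] == 0)
        # implied partials self-consistent
        np.testing.assert_allclose(
            model.partials, partial_from_precision(model.precision), atol=1e-10
        )

    def test_infeasible_targets_raise_naming_edges(self):
        # three mutually incompatible strong positive partials on a triangle
        # (the implied I - R has eigenvalue 1 - 2*0.9 < 0)
        G = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        targets = {(0, 1): 0.9, (0, 2): 0.9, (1, 2): 0.9}
        with pytest.raises(ConvergenceError) as err:
            generate_precision(G, targets, seed=0)
        assert err.value.offending_edges

    def test_target_on_missing_edge_rejected(self):
        G = np.zeros((3, 3), dtype=int)
        with pytest.raises(ParameterError):
            generate_precision(G, {(0, 1): 0.3}, seed=0)


class TestSimulateSubject:
    def test_clean_signal_partials_converge_to_model(self, roi14):
        """Law of large numbers: with drift and coupling off, sample partial
        correlations at T=1e5 match the generating model within 0.02."""
        model = template_model(roi14, seed=2)
        spec = CohortSpec(T=100_000, drift_amplitude=0.0, confound_coupling=0.0,
                          seed=0)
        series, _ = simulate_subject(model, spec, seed=11, labels=roi14.labels)
        X = series.values - series.values.mean(axis=0)
        sample_partials = partial_from_precision(np.linalg.inv(X.T @ X / (len(X) - 1)))
        assert np.max(np.abs(sample_partials - model.partials)) < 0.02

    def test_sample_covariance_matches_model_covariance(self, roi14):
        model = template_model(roi14, seed=2)
        spec = CohortSpec(T=100_000, drift_amplitude=0.0, confound_coupling=0.0,
                          seed=0)
        series, _ = simulate_subject(model, spec, seed=11, labels=roi14.labels)
        X = series.values - series.values.mean(axis=0)
        cov = X.T @ X / (len(X) - 1)
        assert np.max(np.abs(cov - model.covariance)) < 0.01

    def test_same_seed_bit_identical(self, roi14):
        model = template_model(roi14, seed=2)
        spec = CohortSpec(T=110, seed=0)
        s1, c1 = simulate_subject(model, spec, seed=7, labels=roi14.labels)
        s2, c2 = simulate_subject(model, spec, seed=7, labels=roi14.labels)
        assert np.array_equal(s1.values, s2.values)
        assert np.array_equal(c1.regressors, c2.regressors)

    def test_confound_regression_recovers_clean_signal(self, roi14):
        """With strong confound coupling, residualizing against the true
        confounds restores the projection of the clean signal off the
        confound span (correlation > 0.99 with that projection; correlation
        with the raw clean signal is bounded by the unavoidable
        sqrt(1 - k/T) projection loss, ~0.92 here)."""
        model = template_model(roi14, seed=2)
        clean_spec = CohortSpec(T=110, drift_amplitude=0.0, confound_coupling=0.0,
                                seed=0)
        noisy_spec = CohortSpec(T=110, drift_amplitude=0.0, confound_coupling=5.0,
                                seed=0)
        clean, _ = simulate_subject(model, clean_spec, seed=13, labels=roi14.labels)
        noisy, confounds = simulate_subject(model, noisy_spec, seed=13,
                                            labels=roi14.labels)
        recovered = regress_confounds(noisy, confounds).values
        ref = regress_confounds(clean, confounds).values
        for col in range(14):
            assert np.corrcoef(recovered[:, col], ref[:, col])[0, 1] > 0.99
        raw = clean.values - clean.values.mean(axis=0)
        for col in range(14):
            assert np.corrcoef(recovered[:, col], raw[:, col])[0, 1] > 0.85

    def test_too_short_series_rejected(self, roi14):
        model = template_model(roi14, seed=2)
        with pytest.raises(ParameterError):
            CohortSpec(T=1, seed=0)


class TestSimulateCohort:
    def test_default_design_point(self, roi14):
        """Defaults give 72 + 39 subjects, each a 110 x 14 series."""
        cohort = simulate_cohort(CohortSpec(seed=0), roi14)
        groups = [s.group for s in cohort.subjects]
        assert groups.count("a") == 72
        assert groups.count("b") == 39
        for rec in cohort.subjects:
            assert rec.series.values.shape == (110, 14)
            assert rec.confounds.regressors.shape[0] == 110

    def test_zero_group_effect_shares_generating_model(self, roi6):
        spec = CohortSpec(n_group_a=2, n_group_b=2, group_effect=0.0, seed=1)
        cohort = simulate_cohort(spec, roi6)
        np.testing.assert_array_equal(cohort.model_a.precision,
                                      cohort.model_b.precision)

    def test_full_group_effect_zeroes_group_b_partials(self, roi6):
        spec = CohortSpec(n_group_a=2, n_group_b=2, group_effect=1.0, seed=1)
        cohort = simulate_cohort(spec, roi6)
        off = ~np.eye(6, dtype=bool)
        assert np.all(cohort.model_b.partials[off] == 0)
        np.testing.assert_array_equal(cohort.model_b.graph, cohort.model_a.graph)

    def test_shrinkage_scales_partials_uniformly(self, roi6):
        spec = CohortSpec(n_group_a=1, n_group_b=1, group_effect=0.25, seed=3)
        cohort = simulate_cohort(spec, roi6)
        np.testing.assert_allclose(
            cohort.model_b.partials - np.eye(6),
            0.75 * (cohort.model_a.partials - np.eye(6)),
            atol=1e-12,
        )

    def test_cohort_is_pure_function_of_spec(self, roi6):
        spec = CohortSpec(n_group_a=3, n_group_b=2, seed=9)
        c1 = simulate_cohort(spec, roi6)
        c2 = simulate_cohort(spec, roi6)
        for r1, r2 in zip(c1.subjects, c2.subjects):
            assert r1.seed == r2.seed
            assert np.array_equal(r1.series.values, r2.series.values)
            assert np.array_equal(r1.confounds.regressors, r2.confounds.regressors)


class TestShrinkModel:
    def test_shrunk_model_stays_spd(self, roi14):
        model = template_model(roi14, seed=4)
        for effect in (0.0, 0.3, 1.0):
            shrunk = shrink_model(model, effect)
            assert np.min(np.linalg.eigvalsh(shrunk.precision)) > 0
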