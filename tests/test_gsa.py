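"""Sobol sampling, total-effect estimation, freezing errors, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import qmc

from sixmp.errors import ConfigError, DomainError
from sixmp.gsa import (
    GsaSpec,
    SensitivityReport,
    SobolDesign,
    SobolIndices,
    classify_sensitive,
    freezing_error,
    sample_parameter_space,
    total_sobol_indices,
)


def _unit_design(d: int, n: int, seed: int) -> SobolDesign:
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
    u = sampler.random_base2(int(np.log2(n)))
    return SobolDesign(A=u[:, :d].copy(), B=u[:, d:].copy(),
                       names=tuple(f"z{i}" for i in range(d)))


class TestSampleParameterSpace:
    def test_samples_stay_inside_the_box(self):
        spec = GsaSpec(output="x_t", n=128, seed=4)
        design = sample_parameter_space(spec)
        lo, hi = spec.box()
        for mat in (design.A, design.B):
            assert np.all(mat >= lo) and np.all(mat <= hi)

    def test_box_is_half_to_double_nominal(self):
        spec = GsaSpec(output="x_t", nominal={"k_pt": 10.0}, n=64, seed=0)
        lo, hi = spec.box()
        assert lo[0] == 5.0 and hi[0] == 20.0

    def test_marginal_means_hit_box_midpoints(self):
        spec = GsaSpec(output="x_t", n=1024, seed=9)
        design = sample_parameter_space(spec)
        lo, hi = spec.box()
        mid = 0.5 * (lo + hi)
        se = (hi - lo) / np.sqrt(12.0 * design.n_base)
        assert np.all(np.abs(design.A.mean(axis=0) - mid) < 3 * se)

    def test_deterministic_given_seed(self):
        a = sample_parameter_space(GsaSpec(output="x_t", n=64, seed=5))
        b = sample_parameter_space(GsaSpec(output="x_t", n=64, seed=5))
        assert np.array_equal(a.A, b.A) and np.array_equal(a.B, b.B)


class TestTotalSobolIndices:
    def test_additive_linear_model_analytic_indices(self):
        """Y = 2 Z1 + Z2 with independent uniform inputs has total indices
        4/5 and 1/5 (variance decomposition 4/12 vs 1/12)."""
        design = _unit_design(2, 1024, seed=3)
        idx = total_sobol_indices(lambda X: 2 * X[:, 0] + X[:, 1], design)
        assert idx.S_T[0, 0] == pytest.approx(0.8, abs=0.03)
        assert idx.S_T[1, 0] == pytest.approx(0.2, abs=0.03)

    def test_constant_output_flagged_degenerate(self):
        design = _unit_design(2, 256, seed=1)
        idx = total_sobol_indices(lambda X: np.full(X.shape[0], 7.0), design)
        assert idx.degenerate.all()
        assert np.isnan(idx.S_T).all()

    def test_pure_interaction_is_symmetric(self):
        design = _unit_design(2, 2048, seed=8)
        idx = total_sobol_indices(lambda X: X[:, 0] * X[:, 1], design)
        assert idx.S_T[0, 0] == pytest.approx(idx.S_T[1, 0], abs=0.05)

    def test_estimator_consistent_as_n_grows(self):
        """Median absolute error on the analytic linear test function shrinks
        with the base sample size."""
        errors = {}
        for n in (256, 1024, 4096):
            errs = []
            for seed in range(10):
                design = _unit_design(2, n, seed=seed)
                idx = total_sobol_indices(lambda X: 2 * X[:, 0] + X[:, 1], design)
                errs.append(abs(idx.S_T[0, 0] - 0.8) + abs(idx.S_T[1, 0] - 0.2))
            errors[n] = float(np.median(errs))
        assert errors[4096] < errors[1024] < errors[256]


class TestFreezingError:
    def _indices(self, st_matrix, variance):
        st_matrix = np.asarray(st_matrix, dtype=float)
        return SobolIndices(S_T=st_matrix, variance=np.asarray(variance, dtype=float),
                            names=tuple(f"p{i}" for i in range(st_matrix.shape[0])),
                            time_points=tuple(range(st_matrix.shape[1])),
                            degenerate=np.zeros(st_matrix.shape[1], dtype=bool))

    def test_zero_index_gives_zero_error(self):
        idx = self._indices([[0.0, 0.0], [0.5, 0.5]], [1.0, 2.0])
        errors = freezing_error(idx, p=0.05)
        assert errors[0] == 0.0 and errors[1] > 0.0

    def test_identical_profiles_give_identical_errors(self):
        idx = self._indices([[0.3, 0.1], [0.3, 0.1]], [1.0, 4.0])
        errors = freezing_error(idx)
        assert errors[0] == errors[1]

    def test_rss_aggregation_over_time_points(self):
        idx = self._indices([[0.4, 0.9]], [2.0, 1.0])
        expected = np.sqrt(0.4 * 2.0 / 0.05 + 0.9 * 1.0 / 0.05)
        assert freezing_error(idx, p=0.05)[0] == pytest.approx(expected)

    def test_invalid_probability_rejected(self):
        idx = self._indices([[0.4]], [1.0])
        with pytest.raises(ConfigError):
            freezing_error(idx, p=1.5)

    def test_bound_covers_realized_freezing_deviation(self):
        """Empirical check of the probabilistic bound: for the linear test
        function, freezing one input at nominal perturbs the output by less
        than sqrt(S_T * Var / p) in at least 1-p of random draws."""
        rng = np.random.default_rng(12)
        z = rng.uniform(size=(4000, 2))
        y = 2 * z[:, 0] + z[:, 1]
        y_frozen = 2 * 0.5 + z[:, 1]  # z1 fixed at nominal midpoint
        var = y.var()
        p = 0.05
        bound = np.sqrt(0.8 * var / p)
        coverage = np.mean(np.abs(y - y_frozen) <= bound)
        assert coverage >= 1 - p


class TestClassification:
    def test_threshold_edge(self):
        sensitive, redundant = classify_sensitive([100.0, 4.9, 5.1],
                                                  names=("a", "b", "c"), threshold=0.05)
        assert set(sensitive) == {"a", "c"} and redundant == ("b",)

    def test_single_parameter_is_sensitive(self):
        sensitive, redundant = classify_sensitive([0.123], names=("only",))
        assert sensitive == ("only",) and redundant == ()

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            classify_sensitive([])

    @given(st.floats(1e-6, 1e6))
    @settings(max_examples=30, derandomize=True)
    def test_classification_invariant_to_common_rescaling(self, scale):
        errors = np.array([10.0, 0.4, 3.0, 0.6])
        base = classify_sensitive(errors, names=("a", "b", "c", "d"))
        scaled = classify_sensitive(errors * scale, names=("a", "b", "c", "d"))
        assert base == scaled


class TestSensitivityReport:
    def test_percent_of_max_column(self):
        report = SensitivityReport.from_errors(("k_pt", "k_te"), [84.61, 46.36])
        pct = dict(zip(report.table["parameter"], report.table["pct_of_max"]))
        assert pct["k_pt"] == 100.0
        assert pct["k_te"] == pytest.approx(54.8, abs=0.05)

    def test_exactly_one_parameter_at_hundred_percent(self):
        report = SensitivityReport.from_errors(("a", "b", "c"), [3.0, 7.0, 1.0])
        pct = report.table["pct_of_max"].to_numpy()
        assert np.sum(pct == 100.0) == 1
        assert np.all((pct >= 0) & (pct <= 100))

    def test_json_layout(self):
        spec = GsaSpec(output="x_t", n=64, seed=2)
        report = SensitivityReport.from_errors(spec.names, np.arange(1.0, 9.0), spec=spec)
        payload = report.to_json_dict()
        assert {"parameter", "error", "pct_of_max", "classification"} <= set(payload["parameters"][0])
        assert payload["metadata"]["n"] == 64


class TestGsaSpecValidation:
    def test_defaults_cover_model_parameters(self):
        spec = GsaSpec(output="x_t")
        assert set(spec.names) == {"k_a", "k_e", "k_pt", "K_t", "k_pm", "K_m", "k_te", "k_me"}
        assert len(spec.time_points) == 6

    @pytest.mark.parametrize("kwargs", [
        {"output": "bogus"}, {"p": 0.0}, {"p": 1.0}, {"n": 32},
        {"time_points": (10.0, 200.0)},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            GsaSpec(**{"output": "x_t", **kwargs})
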