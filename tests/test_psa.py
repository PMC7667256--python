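"""Probabilistic sensitivity analysis: distributions, propagation, planes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imrcea.psa import (
    ParamDistribution,
    PSAConfig,
    PSAModel,
    default_distributions,
    deterministic_base,
    export_ce_plane,
    fit_beta,
    fit_beta_moments,
    fit_gamma,
    quadrant_proportions,
    run_psa,
)


class TestGammaFit:
    def test_published_or_time_parameters(self):
        shape, scale = fit_gamma(368.0, 75.0)
        assert shape == pytest.approx((368 / 75) ** 2)
        assert shape == pytest.approx(24.076, abs=0.001)
        assert scale == pytest.approx(75**2 / 368)

    @given(mean=st.floats(0.01, 1e6), sd=st.floats(0.001, 1e4))
    @settings(max_examples=100, derandomize=True)
    def test_moment_matching_identity(self, mean, sd):
        shape, scale = fit_gamma(mean, sd)
        assert shape * scale == pytest.approx(mean, rel=1e-9)
        assert math.sqrt(shape) * scale == pytest.approx(sd, rel=1e-9)

    @pytest.mark.parametrize("mean,sd", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_nonpositive_inputs_rejected(self, mean, sd):
        with pytest.raises(ValueError):
            fit_gamma(mean, sd)

    def test_zero_sd_collapses_to_fixed_family(self):
        d = ParamDistribution.gamma("x", 5.0, 0.0)
        assert d.family == "fixed" and d.base_value == 5.0


class TestBetaFit:
    def test_icu_counts(self):
        alpha, beta = fit_beta(98, 48)
        assert alpha / (alpha + beta) == pytest.approx(98 / 146)

    def test_uniform_case_draws_in_unit_interval(self):
        d = ParamDistribution.beta_counts("u", 1, 1)
        draws = d.draw(np.random.default_rng(0), 5000)
        assert np.all((draws >= 0) & (draws <= 1))
        assert draws.mean() == pytest.approx(0.5, abs=0.05)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_beta(0, 48)

    def test_draw_mean_converges_to_count_mean(self):
        d = ParamDistribution.beta_counts("icu", 98, 48)
        draws = d.draw(np.random.default_rng(1), 10_000)
        p = 98 / 146
        mc_se = draws.std() / math.sqrt(10_000)
        assert abs(draws.mean() - p) < 3 * mc_se

    @given(mean=st.floats(0.05, 0.95), cv=st.floats(0.05, 0.3))
    @settings(max_examples=50, derandomize=True)
    def test_beta_moments_round_trip(self, mean, cv):
        sd = cv * mean
        if sd**2 >= mean * (1 - mean):
            return
        a, b = fit_beta_moments(mean, sd)
        m = a / (a + b)
        v = a * b / ((a + b) ** 2 * (a + b + 1))
        assert m == pytest.approx(mean, rel=1e-9)
        assert math.sqrt(v) == pytest.approx(sd, rel=1e-9)


class TestQuadrants:
    def test_all_dominant_draws(self):
        q = quadrant_proportions([1.0, 2.0], [-1.0, -3.0])
        assert q == {"NE": 0.0, "SE": 1.0, "SW": 0.0, "NW": 0.0}

    def test_one_draw_per_quadrant(self):
        q = quadrant_proportions([1, 1, -1, -1], [1, -1, -1, 1])
        assert q == {"NE": 0.25, "SE": 0.25, "SW": 0.25, "NW": 0.25}

    def test_negation_symmetry(self):
        rng = np.random.default_rng(0)
        de = rng.normal(size=400)
        dc = rng.normal(size=400)
        de_full = np.concatenate([de, -de])
        dc_full = np.concatenate([dc, -dc])
        q = quadrant_proportions(de_full, dc_full)
        assert q["NE"] == pytest.approx(q["SW"])
        assert q["SE"] == pytest.approx(q["NW"])

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(2)
        q = quadrant_proportions(rng.normal(size=999), rng.normal(size=999))
        assert sum(q.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quadrant_proportions([], [])


class TestRunPsa:
    def test_reproducible_given_config(self):
        model = PSAModel.default()
        a = run_psa(model, PSAConfig(n_draws=500, seed=42))
        b = run_psa(model, PSAConfig(n_draws=500, seed=42))
        assert a == b

    def test_seed_changes_draws(self):
        model = PSAModel.default()
        a = run_psa(model, PSAConfig(n_draws=500, seed=1))
        b = run_psa(model, PSAConfig(n_draws=500, seed=2))
        assert not np.array_equal(a.delta_cost, b.delta_cost)

    def test_zero_variance_collapses_to_base_case(self):
        """All families fixed: every draw equals the deterministic model."""
        model = PSAModel.default()
        dists = {k: d.as_fixed() for k, d in default_distributions(model).items()}
        result = run_psa(model, PSAConfig(n_draws=50, seed=7, distributions=dists))
        base = deterministic_base(model)
        assert np.allclose(result.delta_cost, base.delta_cost[0])
        for ep in result.delta_effect:
            assert np.allclose(result.delta_effect[ep], base.delta_effect[ep][0])

    def test_deterministic_base_recovers_printed_deltas(self):
        """At parameter means the effect deltas are the published 7.1/17/38."""
        base = deterministic_base(PSAModel.default())
        assert base.delta_effect["post_kps"][0] == pytest.approx(7.1)
        assert base.delta_effect["rkps"][0] == pytest.approx(17.0)
        assert base.delta_effect["pfs_1y"][0] == pytest.approx(38.0)

    def test_monte_carlo_means_unbiased(self):
        """LLN: draw means converge to the deterministic base case (3 MC SE)."""
        model = PSAModel.default()
        result = run_psa(model, PSAConfig(n_draws=10_000, seed=3))
        base = deterministic_base(model)
        n = result.n_draws
        se_c = result.delta_cost.std() / math.sqrt(n)
        assert abs(result.delta_cost.mean() - base.delta_cost[0]) < 3 * se_c
        for ep in result.delta_effect:
            se_e = result.delta_effect[ep].std() / math.sqrt(n)
            assert (
                abs(result.delta_effect[ep].mean() - base.delta_effect[ep][0])
                < 3 * se_e
            )

    def test_draw_validity(self):
        model = PSAModel.default()
        result = run_psa(model, PSAConfig(n_draws=2000, seed=9))
        for ep, q in result.quadrants.items():
            assert sum(q.values()) == pytest.approx(1.0, abs=1e-9)
        assert result.delta_cost.shape == (2000,)

    def test_beta_and_gamma_draw_supports(self):
        model = PSAModel.default()
        dists = default_distributions(model)
        rng = np.random.default_rng(5)
        for d in dists.values():
            draws = d.draw(rng, 1000)
            if d.family == "beta":
                assert np.all((draws >= 0) & (draws <= 1))
            elif d.family == "gamma":
                assert np.all(draws > 0)

    def test_missing_distribution_rejected(self):
        model = PSAModel.default()
        dists = default_distributions(model)
        dists.pop("lf_imr.los")
        with pytest.raises(ValueError, match="lf_imr.los"):
            run_psa(model, PSAConfig(n_draws=10, seed=0, distributions=dists))

    def test_device_cost_inflation_shifts_delta_cost_up(self):
        """Coupled draws: scaling the device price distribution by k scales
        its gamma draws exactly, so delta cost rises draw-wise."""
        model = PSAModel.default()
        base_dists = default_distributions(model)
        inflated = dict(base_dists)
        d = base_dists["device_total"]
        inflated["device_total"] = ParamDistribution.gamma(
            "device_total", 1.5 * d.mean, 1.5 * d.sd
        )
        cfg_a = PSAConfig(n_draws=1000, seed=13, distributions=base_dists)
        cfg_b = PSAConfig(n_draws=1000, seed=13, distributions=inflated)
        a = run_psa(model, cfg_a)
        b = run_psa(model, cfg_b)
        assert np.all(b.delta_cost >= a.delta_cost)
        assert np.any(b.delta_cost > a.delta_cost)


class TestExport:
    def test_csv_row_count_and_determinism(self, tmp_path):
        model = PSAModel.default()
        result = run_psa(model, PSAConfig(n_draws=100, seed=4))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        export_ce_plane(result, "rkps", p1)
        export_ce_plane(result, "rkps", p2)
        lines = p1.read_text().splitlines()
        assert len(lines) == 101
        assert p1.read_bytes() == p2.read_bytes()

    def test_plot_written_when_requested(self, tmp_path):
        model = PSAModel.default()
        result = run_psa(model, PSAConfig(n_draws=50, seed=4))
        plot = tmp_path / "plane.png"
        export_ce_plane(result, "post_kps", tmp_path / "c.csv", plot_path=plot)
        assert plot.exists() and plot.stat().st_size > 0

    def test_unknown_endpoint_rejected(self, tmp_path):
        model = PSAModel.default()
        result = run_psa(model, PSAConfig(n_draws=10, seed=4))
        with pytest.raises(ValueError):
            export_ce_plane(result, "qaly", tmp_path / "x.csv")
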