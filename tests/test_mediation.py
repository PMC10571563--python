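"""Hazard-ratio effect decomposition: identities, worked examples, null behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depmed import summarize_effects, total_effect
from depmed.jointmodel import PosteriorDraws
from depmed.mediation import (
    direct_effect,
    indirect_effect,
    mediation_summary,
    mediator_probability_shift,
)

from test_jointmodel import make_data


def fixed_draws(data, *, beta_x=0.0, beta_m=None, alpha0=None, alpha_x=None,
                lambda_m=0.0, n_draws=4):
    """Degenerate draws at a single parameter point."""
    n_med = data.n_levels - 1
    beta_m = np.zeros(n_med) if beta_m is None else np.asarray(beta_m, float)
    alpha0 = np.zeros(n_med) if alpha0 is None else np.asarray(alpha0, float)
    alpha_x = np.zeros(n_med) if alpha_x is None else np.asarray(alpha_x, float)

    def tile(a):
        a = np.asarray(a, dtype=float)
        return np.tile(a, (1, n_draws) + (1,) * a.ndim)

    params = {
        "beta_x": np.full((1, n_draws), beta_x),
        "beta_m": tile(beta_m),
        "alpha0": tile(alpha0),
        "alpha_x": tile(alpha_x),
        "alpha_c": tile(np.zeros((n_med, data.p))),
        "lambda_m": np.full((1, n_draws), lambda_m),
        "u": tile(np.zeros(data.n_tracts)),
    }
    return PosteriorDraws(params=params, levels=data.levels,
                          columns=data.columns, mediator=data.mediator,
                          n_tracts=data.n_tracts)


@pytest.fixture(scope="module")
def stage_data():
    data, _ = make_data(n=60, seed=31)
    return data


class TestDirectEffect:
    def test_zero_coefficient_gives_unit_hr(self, stage_data):
        hr = direct_effect(fixed_draws(stage_data, beta_x=0.0))
        assert np.all(hr == 1.0)

    def test_published_point_value(self, stage_data):
        hr = direct_effect(fixed_draws(stage_data, beta_x=math.log(0.731)))
        assert hr.mean() == pytest.approx(0.731)

    def test_lognormal_mean_closed_form(self, stage_data):
        rng = np.random.default_rng(32)
        n = 200_000
        draws = fixed_draws(stage_data, n_draws=n)
        draws.params["beta_x"] = rng.normal(size=(1, n))
        hr = direct_effect(draws)
        assert hr.mean() == pytest.approx(math.exp(0.5), rel=0.02)


class TestIndirectEffect:
    def test_no_exposure_mediator_path_gives_unit_hr(self, stage_data):
        draws = fixed_draws(stage_data, beta_m=[0.5, 1.0], alpha_x=[0.0, 0.0])
        for level in stage_data.levels:
            hr = indirect_effect(draws, stage_data, level)
            assert np.allclose(hr, 1.0)

    def test_zero_outcome_coefficient_gives_unit_hr(self, stage_data):
        draws = fixed_draws(stage_data, beta_m=[0.0, 0.0], alpha_x=[-0.3, -0.6])
        for level in stage_data.levels:
            assert np.allclose(indirect_effect(draws, stage_data, level), 1.0)

    def test_reference_level_unit_by_coding(self, stage_data):
        draws = fixed_draws(stage_data, beta_m=[0.5, 1.0], alpha_x=[-0.3, -0.6])
        assert np.all(indirect_effect(draws, stage_data, "localized") == 1.0)
        assert not np.allclose(indirect_effect(draws, stage_data, "distant"), 1.0)

    def test_unknown_level_rejected(self, stage_data):
        with pytest.raises(ValueError, match="unknown mediator level"):
            indirect_effect(fixed_draws(stage_data), stage_data, "metastatic")

    def test_probability_shifts_sum_to_zero(self, stage_data):
        draws = fixed_draws(stage_data, alpha_x=[-0.3, -0.6], lambda_m=0.4)
        dp = mediator_probability_shift(draws, stage_data)
        assert np.allclose(dp.sum(axis=1), 0.0, atol=1e-12)


class TestTotalEffect:
    @pytest.mark.parametrize("direct,indirect,expected", [
        (0.736, 0.971, 0.715),  # stage-mediated SES-index worked example
        (0.816, 0.978, 0.798),  # debulking-mediated worked example
    ])
    def test_published_products(self, direct, indirect, expected):
        d = np.full(5, direct)
        out = total_effect(d, {"level": np.full(5, indirect)})
        assert round(float(out["level"].mean()), 3) == expected

    def test_unit_indirect_returns_direct(self):
        d = np.array([0.7, 0.9, 1.2])
        out = total_effect(d, {"a": np.ones(3)})
        assert np.array_equal(out["a"], d)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            total_effect(np.ones(3), {"a": np.ones(4)})

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None)
    def test_drawwise_identity_exact(self, seed):
        rng = np.random.default_rng(seed)
        direct = np.exp(rng.normal(size=50))
        indirect = {"k1": np.exp(rng.normal(size=50)),
                    "k2": np.exp(rng.normal(size=50))}
        total = total_effect(direct, indirect)
        for k in indirect:
            assert np.array_equal(total[k], direct * indirect[k])
            assert np.all(total[k] > 0)


class TestNullCalibration:
    def test_null_config_intervals_contain_one(self):
        # all exposure paths zero: 95% intervals for the direct effect should
        # contain HR=1 in nearly all of a handful of replicates
        from depmed import GeneratorConfig, JointModelSpec, build_model_data, \
            exposure_spec, generate_cohort, run_mcmc
        from depmed.mediation import direct_effect as de

        hits = 0
        for r in range(5):
            cfg = GeneratorConfig(n=250, n_tracts=85, seed=900 + r,
                                  beta_x=0.0, stage_alpha_x=(0.0, 0.0))
            truth = generate_cohort(cfg, truth_draws=500)
            data = build_model_data(truth.cohort, exposure_spec("URB"),
                                    "stage3", modifiers=())
            spec = JointModelSpec(exposure=exposure_spec("URB"), chains=2,
                                  iterations=500, burn_in=200, seed=901 + r,
                                  candidate_modifiers=())
            draws, _ = run_mcmc(data, spec)
            lo, hi = np.quantile(de(draws), [0.025, 0.975])
            hits += bool(lo <= 1.0 <= hi)
        assert hits >= 4


class TestSummaries:
    def test_degenerate_draws(self):
        out = summarize_effects({"direct": np.full(10, 0.7)}).iloc[0]
        assert out["mean"] == pytest.approx(0.7)
        assert out["lo"] == out["hi"] == pytest.approx(0.7)

    def test_well_estimated_flag(self):
        rng = np.random.default_rng(33)
        below = np.exp(rng.normal(math.log(0.731), 0.11, 4000))  # CI ~ (0.59, 0.91)
        crossing = np.exp(rng.normal(math.log(1.149), 0.115, 4000))
        out = summarize_effects({"b": below, "c": crossing}).set_index("effect")
        assert bool(out.loc["b", "well_estimated"])
        assert not bool(out.loc["c", "well_estimated"])

    def test_formatting_three_decimals(self):
        out = summarize_effects({"d": np.full(4, 0.7305)}).iloc[0]
        assert out["formatted"] == "0.731 (0.731, 0.731)"

    def test_mediation_summary_table_rows(self, stage_data):
        draws = fixed_draws(stage_data, beta_x=math.log(0.8),
                            beta_m=[0.5, 1.0], alpha_x=[-0.2, -0.4])
        summary = mediation_summary(draws, stage_data)
        effects = list(summary.table["effect"])
        assert effects[0] == "direct"
        assert sum(e.startswith("indirect") for e in effects) == 3
        assert sum(e.startswith("total") for e in effects) == 3
        tbl = summary.table.set_index("effect")
        for i, lvl in enumerate(stage_data.levels, start=1):
            assert tbl.loc[f"total_{i}_{lvl}", "mean"] == pytest.approx(
                tbl.loc["direct", "mean"] * tbl.loc[f"indirect_{i}_{lvl}", "mean"])
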