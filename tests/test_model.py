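import numpy as np
import pandas as pd
import pytest

from turnalign.design import USER_SIDE, build_observation_table
from turnalign.model import (
    DissociationModel,
    compute_icc,
    cumulative_progressive_d,
    fit_dissociation_model,
    per_conversation_slopes,
    static_effect_size,
    within_similarity_series,
)


def gaussian_table(
    n_conversations,
    n_turns,
    rng,
    beta0=0.5,
    beta1=0.0,
    beta2=0.0,
    beta3=0.0,
    sigma_u=0.0,
    sigma_e=0.1,
):
    """Directly simulate the multilevel model (oracle for estimator checks)."""
    rows = []
    turns = np.arange(1, n_turns + 1, dtype=float)
    centered = turns - turns.mean()
    for j in range(n_conversations):
        u = rng.normal(0, sigma_u)
        for t, ct in zip(turns, centered):
            for w in (1, 0):
                mu = beta0 + beta1 * w + beta2 * ct + beta3 * w * ct + u
                rows.append(
                    {
                        "conversation_id": f"g{j}",
                        "direction": "user_side",
                        "N": t,
                        "centered_turn": ct,
                        "is_within": w,
                        "similarity": mu + rng.normal(0, sigma_e),
                    }
                )
    return pd.DataFrame(rows)


class TestComputeIcc:
    @pytest.mark.parametrize(
        "su,se,expected",
        [(0.048, 0.088, 0.35), (0.003, 0.095, 0.03), (0.045, 0.089, 0.34), (0.0, 0.5, 0.0)],
    )
    def test_variance_component_ratios(self, su, se, expected):
        assert round(compute_icc(su, se), 2) == expected

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            compute_icc(0.0, 0.0)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            compute_icc(-0.1, 0.2)


class TestDissociationModel:
    def test_constant_data_recovers_constant(self, rng):
        table = gaussian_table(10, 5, rng, beta0=0.37, sigma_e=0.0)
        fit = fit_dissociation_model(table)
        assert fit.beta0 == pytest.approx(0.37, abs=1e-6)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-6)
        assert fit.beta3 == pytest.approx(0.0, abs=1e-6)
        assert fit.sigma_e2 == pytest.approx(0.0, abs=1e-8)

    def test_recovers_within_offset_and_variance_components(self, rng):
        # ground truth: beta1=0.05, sigma_u^2=0.04, sigma_e^2=0.09
        reps = 25
        est = [
            fit_dissociation_model(
                gaussian_table(300, 10, rng, beta1=0.05, sigma_u=0.2, sigma_e=0.3)
            )
            for _ in range(reps)
        ]
        b1 = np.array([f.beta1 for f in est])
        # analytic SE of beta1 at this design is ~0.0077; the mean over 25
        # replicates should sit within ~3 SE/sqrt(25) of truth
        assert abs(b1.mean() - 0.05) < 0.005
        assert np.mean([f.sigma_u2 for f in est]) == pytest.approx(0.04, rel=0.15)
        assert np.mean([f.sigma_e2 for f in est]) == pytest.approx(0.09, rel=0.1)
        iccs = [f.icc for f in est]
        assert np.mean(iccs) == pytest.approx(0.04 / 0.13, rel=0.15)

    def test_interaction_recovery(self, rng):
        table = gaussian_table(300, 10, rng, beta1=0.03, beta3=0.01, sigma_u=0.2, sigma_e=0.1)
        fit = fit_dissociation_model(table)
        assert fit.beta3 == pytest.approx(0.01, abs=0.003)
        assert fit.pvalues["is_within:centered_turn"] < 0.001

    def test_icc_identity_exact(self, rng):
        table = gaussian_table(50, 6, rng, beta1=0.02, sigma_u=0.1, sigma_e=0.2)
        fit = fit_dissociation_model(table)
        assert fit.icc == pytest.approx(fit.sigma_u2 / (fit.sigma_u2 + fit.sigma_e2), abs=1e-12)

    def test_requires_both_within_levels(self, rng):
        table = gaussian_table(5, 4, rng)
        with pytest.raises(ValueError):
            DissociationModel(table[table["is_within"] == 1])

    def test_requires_two_conversations(self, rng):
        table = gaussian_table(1, 6, rng)
        with pytest.raises(ValueError):
            DissociationModel(table)

    def test_summary_carries_components(self, rng):
        table = gaussian_table(30, 6, rng, sigma_u=0.1, sigma_e=0.2)
        fit = fit_dissociation_model(table)
        summ = fit.summary()
        assert list(summ.index) == [
            "intercept", "is_within", "centered_turn", "is_within:centered_turn",
        ]
        assert summ.attrs["n_conversations"] == 30
        assert 0 <= summ.attrs["icc"] <= 1

    def test_from_conversations_end_to_end(self, small_corpus):
        convs, rates, _ = small_corpus
        fit = DissociationModel.from_conversations(convs, USER_SIDE, seed=1, rates=rates).fit()
        assert fit.n_conversations == len(convs)
        assert fit.direction == "user_side"
        assert np.isfinite(fit.beta3)

    def test_random_slope_refit_leaves_beta3_close(self, small_corpus):
        convs, rates, _ = small_corpus
        model = DissociationModel.from_conversations(convs, USER_SIDE, seed=1, rates=rates)
        base = model.fit()
        slopes = model.fit(random_slopes=("is_within",))
        assert "var_is_within" in slopes.random_effects
        assert slopes.beta3 == pytest.approx(base.beta3, abs=5e-3)


class TestPerConversationSlopes:
    def test_closed_form_slope(self):
        summary = per_conversation_slopes({"c": [(1, 0.2), (2, 0.3), (3, 0.4)]})
        assert summary.slopes[0] == pytest.approx(0.1, abs=1e-12)

    def test_constant_series_zero_slope(self):
        summary = per_conversation_slopes({"c": [(1, 0.5), (2, 0.5), (3, 0.5)]})
        assert summary.slopes[0] == pytest.approx(0.0, abs=1e-15)

    def test_identical_positive_slopes(self):
        series = {f"c{i}": [(1, 0.1 + 0.01), (2, 0.1 + 0.02), (3, 0.1 + 0.03)] for i in range(5)}
        summary = per_conversation_slopes(series)
        assert summary.mean_slope == pytest.approx(0.01, abs=1e-12)
        assert summary.pct_positive == 100.0
        assert summary.df == 4

    def test_short_series_excluded_with_count(self):
        summary = per_conversation_slopes({"a": [(1, 0.2), (2, 0.4)], "b": [(1, 0.3)]})
        assert summary.n_excluded == 1
        assert summary.df == 0

    def test_t_test_detects_negative_drift(self, rng):
        series = {
            f"c{i}": [(t, 0.5 - 0.01 * t + rng.normal(0, 0.005)) for t in range(1, 8)]
            for i in range(40)
        }
        summary = per_conversation_slopes(series)
        assert summary.mean_slope < 0
        assert summary.p_value < 0.001
        assert summary.pct_positive < 50

    def test_series_extraction_from_table(self, small_corpus):
        convs, rates, _ = small_corpus
        table = build_observation_table(convs, USER_SIDE, (1, 10), seed=1, rates=rates)
        series = within_similarity_series(table)
        assert set(series) == set(table["conversation_id"].unique())
        n_within = (table["is_within"] == 1).sum()
        assert sum(len(v) for v in series.values()) == n_within


class TestEffectSizes:
    def test_identical_groups_zero_d(self, rng):
        vals = rng.normal(0.5, 0.1, 200)
        table = pd.DataFrame(
            {
                "is_within": np.r_[np.ones(200), np.zeros(200)],
                "similarity": np.r_[vals, vals],
            }
        )
        assert static_effect_size(table).d == pytest.approx(0.0, abs=1e-12)

    def test_simulation_matches_closed_form(self, rng):
        n = 100_000
        table = pd.DataFrame(
            {
                "is_within": np.r_[np.ones(n), np.zeros(n)],
                "similarity": np.r_[rng.normal(0.6, 0.1, n), rng.normal(0.5, 0.1, n)],
            }
        )
        assert static_effect_size(table).d == pytest.approx(1.0, abs=0.02)

    def test_shift_over_pooled_sd_arithmetic(self, rng):
        n = 200_000
        table = pd.DataFrame(
            {
                "is_within": np.r_[np.ones(n), np.zeros(n)],
                "similarity": np.r_[rng.normal(0.509, 0.1, n), rng.normal(0.5, 0.1, n)],
            }
        )
        assert static_effect_size(table).d == pytest.approx(0.09, abs=0.01)

    def test_zero_pooled_sd_errors(self):
        table = pd.DataFrame(
            {"is_within": [1, 1, 0, 0], "similarity": [0.5, 0.5, 0.5, 0.5]}
        )
        with pytest.raises(ValueError):
            static_effect_size(table)

    @pytest.mark.parametrize(
        "beta3,span,sd,expected",
        [(0.0, 9, 0.09, 0.0), (0.001, 9, 0.09, 0.1), (-0.002, 9, 0.09, -0.2)],
    )
    def test_cumulative_progressive_arithmetic(self, beta3, span, sd, expected):
        assert cumulative_progressive_d(beta3, span, sd).d == pytest.approx(expected)

    def test_cumulative_progressive_invalid_inputs(self):
        with pytest.raises(ValueError):
            cumulative_progressive_d(0.1, 0, 0.1)
        with pytest.raises(ValueError):
            cumulative_progressive_d(0.1, 9, 0.0)
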