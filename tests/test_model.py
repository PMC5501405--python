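import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logsumexp

from inhalerdce.errors import DataError, EstimationError
from inhalerdce.model import (
    ModelSpec,
    encode,
    exploded_ranking_logprob,
    fit_mle,
    odds_ratios,
    ranking_loglik,
    wald_tests,
)
from inhalerdce.params import ASTHMA_ESTIMATES, COPD_ESTIMATES
from inhalerdce.cohort import cohort_to_frame, default_cohort_config, generate_respondents
from inhalerdce.design import search_design
from inhalerdce.simulate import TrueModel, simulate_study_frame

utilities_3 = st.lists(
    st.floats(-8, 8, allow_nan=False), min_size=3, max_size=3
).map(np.array)


def brute_force_ranking_prob(utilities, ranking):
    """Permutation mass by explicit stagewise arithmetic (loops only)."""
    u = list(utilities)
    prob = 1.0
    remaining = list(ranking)
    while len(remaining) > 1:
        denom = sum(np.exp(u[j]) for j in remaining)
        prob *= np.exp(u[remaining[0]]) / denom
        remaining.pop(0)
    return prob


class TestExplodedLogprob:
    @pytest.mark.parametrize("n_alts", [2, 3, 4])
    def test_matches_permutation_oracle(self, n_alts):
        rng = np.random.default_rng(n_alts)
        for _ in range(20):
            u = rng.normal(0, 1.5, n_alts)
            for perm in itertools.permutations(range(n_alts)):
                assert np.exp(
                    exploded_ranking_logprob(u, perm)
                ) == pytest.approx(brute_force_ranking_prob(u, perm), abs=1e-12)

    @pytest.mark.parametrize("n_alts", [3, 4])
    def test_probabilities_sum_to_one_over_all_rankings(self, n_alts):
        rng = np.random.default_rng(10 + n_alts)
        for _ in range(20):
            u = rng.normal(0, 2, n_alts)
            total = sum(
                np.exp(exploded_ranking_logprob(u, p))
                for p in itertools.permutations(range(n_alts))
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    @given(utilities_3, st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_location_invariance(self, u, shift):
        base = exploded_ranking_logprob(u, (2, 0, 1))
        shifted = exploded_ranking_logprob(u + shift, (2, 0, 1))
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_two_stage_closed_form(self):
        # utilities (ln 2, 0, 0), ranking (A, B, current):
        # P = 2/(2+1+1) * 1/(1+1) = 0.25
        lp = exploded_ranking_logprob(np.array([np.log(2), 0, 0]), (0, 1, 2))
        assert np.exp(lp) == pytest.approx(0.25, abs=1e-12)

    def test_bad_permutation_rejected(self):
        with pytest.raises(DataError):
            exploded_ranking_logprob(np.zeros(3), (0, 0, 1))


@pytest.fixture(scope="module")
def small_data(attrs):
    design = search_design(attrs, 6, 1, seed=3, n_restarts=2)
    everyone = generate_respondents(default_cohort_config(), seed=8)
    cohort = everyone[:30] + everyone[201:211]  # 30 asthma + 10 COPD
    for r in cohort:
        r.block_id = 0
    model = TrueModel.asthma_defaults(sigma_re=0.4)
    frame = simulate_study_frame(cohort, design, model, seed=13)
    return frame, cohort_to_frame(cohort)


class TestEncode:
    def test_column_values_match_profile_levels(self, small_data, attrs):
        frame, cohort_df = small_data
        spec = ModelSpec(attributes=attrs)
        enc = encode(frame, cohort_df, spec)
        df = frame.sort_values(
            ["respondent_id", "set_id", "rank"], kind="mergesort"
        ).reset_index(drop=True)
        j = enc.names.index("ease_of_use[1 step]")
        expected = (df["ease_of_use"] == "1 step").to_numpy(float)
        assert np.array_equal(enc.X[:, j], expected)
        j2 = enc.names.index("ease_of_use[2 to 3 steps]")
        expected2 = (df["ease_of_use"] == "2 to 3 steps").to_numpy(float)
        assert np.array_equal(enc.X[:, j2], expected2)
        assert np.array_equal(enc.X[:, enc.names.index("cost")], df["cost"])

    def test_status_quo_rows_flagged(self, small_data, attrs):
        frame, cohort_df = small_data
        enc = encode(frame, cohort_df, ModelSpec(attributes=attrs))
        df = frame.sort_values(
            ["respondent_id", "set_id", "rank"], kind="mergesort"
        )
        assert np.array_equal(enc.sq, (df["alt_id"] == "current").to_numpy(float))

    def test_disease_interaction_is_product_column(self, small_data, attrs):
        frame, cohort_df = small_data
        spec = ModelSpec(
            attributes=attrs, interactions=[("flexibility", "disease")]
        )
        enc = encode(frame, cohort_df, spec)
        base = enc.X[:, enc.names.index("flexibility[any position]")]
        inter = enc.X[:, enc.names.index("flexibility[any position]:COPD")]
        copd_ids = set(
            cohort_df.loc[cohort_df["disease"] == "COPD", "respondent_id"]
        )
        df = frame.sort_values(
            ["respondent_id", "set_id", "rank"], kind="mergesort"
        )
        is_copd = df["respondent_id"].isin(copd_ids).to_numpy(float)
        assert np.array_equal(inter, base * is_copd)

    def test_unknown_level_named_in_error(self, small_data, attrs):
        frame, cohort_df = small_data
        bad = frame.copy()
        bad.loc[bad.index[4], "hygiene"] = "sterilized"
        with pytest.raises(DataError, match="hygiene"):
            encode(bad, cohort_df, ModelSpec(attributes=attrs))

    def test_broken_rank_permutation_rejected(self, small_data, attrs):
        frame, cohort_df = small_data
        bad = frame.copy()
        bad.loc[bad.index[0], "rank"] = 2
        with pytest.raises(DataError, match="permutation"):
            encode(bad, cohort_df, ModelSpec(attributes=attrs))


class TestRankingLoglik:
    def test_all_zero_utilities_give_uniform_ranking_probability(
        self, small_data, attrs
    ):
        frame, cohort_df = small_data
        spec = ModelSpec(attributes=attrs, random_effect="none")
        enc = encode(frame, cohort_df, spec)
        ll = ranking_loglik(np.zeros(len(enc.names)), enc, spec)
        assert ll == pytest.approx(enc.n_sets * np.log(1 / 6), rel=1e-12)

    def test_vectorized_path_matches_scalar_oracle(self, small_data, attrs):
        frame, cohort_df = small_data
        spec = ModelSpec(attributes=attrs, random_effect="none")
        enc = encode(frame, cohort_df, spec)
        rng = np.random.default_rng(5)
        beta = rng.normal(0, 0.4, len(enc.names))
        ll = ranking_loglik(beta, enc, spec)
        V = enc.X @ beta
        expected = sum(
            exploded_ranking_logprob(V[3 * s : 3 * s + 3], (0, 1, 2))
            for s in range(enc.n_sets)
        )
        assert ll == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("nodes", [1, 7, 15, 25])
    def test_sigma_zero_reduces_to_plain_exploded_logit(
        self, small_data, attrs, nodes
    ):
        frame, cohort_df = small_data
        plain = ModelSpec(attributes=attrs, random_effect="none")
        enc0 = encode(frame, cohort_df, plain)
        rng = np.random.default_rng(6)
        beta = rng.normal(0, 0.3, len(enc0.names))
        ll_plain = ranking_loglik(beta, enc0, plain)
        mixed = ModelSpec(attributes=attrs, quadrature_nodes=nodes)
        enc1 = encode(frame, cohort_df, mixed)
        ll_mixed = ranking_loglik(
            np.concatenate([beta, [np.log(1e-13)]]), enc1, mixed
        )
        assert ll_mixed == pytest.approx(ll_plain, abs=1e-10)

    def test_gradient_matches_finite_differences(self, small_data, attrs):
        frame, cohort_df = small_data
        spec = ModelSpec(attributes=attrs, quadrature_nodes=9)
        enc = encode(frame, cohort_df, spec)
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.3, len(enc.names) + 1)
        _, g = ranking_loglik(x, enc, spec, with_grad=True)
        for i in range(len(x)):
            e = np.zeros_like(x)
            e[i] = 1e-6
            fd = (
                ranking_loglik(x + e, enc, spec)
                - ranking_loglik(x - e, enc, spec)
            ) / 2e-6
            assert g[i] == pytest.approx(fd, abs=1e-5)


class TestFit:
    def test_null_data_recovers_zero_coefficients(self, attrs):
        design = search_design(attrs, 8, 1, seed=4, n_restarts=2)
        cohort = generate_respondents(default_cohort_config(), seed=30)[:150]
        for r in cohort:
            r.block_id = 0
        null = TrueModel(beta={}, beta_cost=0.0, delta_sq=0.0, sigma_re=0.0)
        frame = simulate_study_frame(cohort, design, null, seed=31)
        fit = fit_mle(
            frame, cohort_to_frame(cohort),
            ModelSpec(attributes=attrs, random_effect="none"),
        )
        assert fit.converged
        z = fit.estimates / fit.std_errors
        assert np.all(np.abs(z) < 3.5)

    def test_sigma_free_on_sigma_zero_data_stays_near_boundary(
        self, small_data, attrs
    ):
        design = search_design(attrs, 6, 1, seed=3, n_restarts=2)
        cohort = generate_respondents(default_cohort_config(), seed=40)[:60]
        for r in cohort:
            r.block_id = 0
        model = TrueModel.asthma_defaults(sigma_re=0.0)
        frame = simulate_study_frame(cohort, design, model, seed=41)
        cdf = cohort_to_frame(cohort)
        free = fit_mle(frame, cdf, ModelSpec(attributes=attrs, quadrature_nodes=9))
        fixed = fit_mle(
            frame, cdf, ModelSpec(attributes=attrs, random_effect="none")
        )
        assert free.estimates["sigma_re"] < 0.15
        assert abs(free.log_likelihood - fixed.log_likelihood) < 0.5


class TestWaldAndOddsRatios:
    def test_published_estimates_reproduce_published_odds_ratios(self):
        from inhalerdce.params import ASTHMA_ODDS_RATIOS, COPD_ODDS_RATIOS

        for table, printed in (
            (ASTHMA_ESTIMATES, ASTHMA_ODDS_RATIOS),
            (COPD_ESTIMATES, COPD_ODDS_RATIOS),
        ):
            for term, (est, _se) in table.items():
                assert np.exp(est) == pytest.approx(printed[term], abs=2e-3)

    def test_known_transform_values(self):
        assert np.exp(0.55) == pytest.approx(1.733, abs=5e-4)
        assert np.exp(0.419) == pytest.approx(1.52, abs=5e-3)

    def test_wald_p_values(self, small_data, attrs):
        frame, cohort_df = small_data
        fit = fit_mle(
            frame, cohort_df, ModelSpec(attributes=attrs, random_effect="none")
        )
        p = wald_tests(fit)
        orr = odds_ratios(fit)
        z = fit.estimates[p.index] / fit.std_errors[p.index]
        # estimate 1.96 SE away → p = 0.05; 0 → p = 1
        from scipy import stats

        assert p.to_numpy() == pytest.approx(2 * stats.norm.sf(np.abs(z.to_numpy())))
        assert orr.to_numpy() == pytest.approx(
            np.exp(fit.estimates[p.index].to_numpy())
        )

    def test_zero_standard_error_rejected(self, small_data, attrs):
        frame, cohort_df = small_data
        fit = fit_mle(
            frame, cohort_df, ModelSpec(attributes=attrs, random_effect="none")
        )
        fit.std_errors.iloc[0] = 0.0
        with pytest.raises(EstimationError, match="zero standard error"):
            wald_tests(fit)


def test_wald_normal_quantile_identities():
    from scipy import stats

    assert 2 * stats.norm.sf(abs(0.0 / 1.0)) == pytest.approx(1.0)
    assert 2 * stats.norm.sf(abs(1.959963985 / 1.0)) == pytest.approx(0.05, abs=1e-9)
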