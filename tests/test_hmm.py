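"""ZIP-HMM: observed-state transform, emissions, exact-inference oracles,
EM behaviour, pretraining, BIC and chunked fitting."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import poisson

from tnscape import hmm
from tnscape.genome import Track

from conftest import random_model, random_series


# ---------------------------------------------------------------- brute force

def brute_force_pathsums(model, series):
    """Enumerate all n^T paths: total likelihood, posterior marginals and
    the argmax path. Independent of the forward-backward code path."""
    n, T = model.n, len(series)
    X = series.X
    emis = np.zeros((T, n))
    for s, e in enumerate(model.emissions):
        lam = np.exp(X @ e.beta)
        for t in range(T):
            y = series.y[t]
            p = (1 - e.omega) * poisson.pmf(y, lam[t])
            if y == 0:
                p += e.omega
            emis[t, s] = p
    total = 0.0
    marginals = np.zeros((T, n))
    best_prob, best_path = -1.0, None
    for path in itertools.product(range(n), repeat=T):
        p = model.pi_init[path[0]] * emis[0, path[0]]
        for t in range(1, T):
            p *= model.A[path[t - 1], path[t]] * emis[t, path[t]]
        total += p
        for t in range(T):
            marginals[t, path[t]] += p
        if p > best_prob:
            best_prob, best_path = p, path
    return total, marginals / total, np.array(best_path)


class TestObservedStates:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, 0), (1, 0), (2, 1), (5, 2), (6, 3), (8, 3), (100, 7)],
    )
    def test_rounded_log2_with_low_count_collapse(self, count, expected):
        # log2(5)=2.32 -> 2; log2(6)=2.585 -> 3; 0 and 1 share state 0
        assert hmm.observed_states(np.array([count]))[0] == expected

    def test_negative_count_errors(self):
        with pytest.raises(ValueError):
            hmm.observed_states(np.array([-1]))

    def test_plus_one_variant_separates_zero_and_one(self):
        y = hmm.observed_states(np.array([0, 1]), plus_one=True)
        assert y.tolist() == [0, 1]

    def test_half_up_rounding_switch(self):
        # log2(x)=2.5 never happens exactly; engineer the difference via
        # plus_one: log2(2+1)=1.585 rounds the same; use 0.5 cases directly
        assert hmm.observed_states(np.array([6]), rounding="half_up")[0] == 3


class TestZipLogpmf:
    def test_omega_zero_is_plain_poisson(self):
        y = np.arange(6)
        lam = np.full(6, 2.3)
        np.testing.assert_allclose(
            hmm.zip_logpmf(y, lam, 0.0), poisson.logpmf(y, 2.3), rtol=1e-12
        )

    def test_omega_one_limits(self):
        assert hmm.zip_logpmf(np.array([0]), np.array([2.0]), 1.0)[0] == 0.0
        assert hmm.zip_logpmf(np.array([3]), np.array([2.0]), 1.0)[0] == -np.inf

    def test_hand_computed_mixture_value(self):
        # log(0.3 + 0.7 e^-2) = log(0.39467...) = -0.92965
        val = hmm.zip_logpmf(np.array([0]), np.array([2.0]), 0.3)[0]
        assert val == pytest.approx(math.log(0.3 + 0.7 * math.exp(-2)), abs=1e-12)
        assert val == pytest.approx(-0.9297, abs=2e-4)


class TestNucleosomeNormalization:
    def test_normal_scores_have_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        raw = Track({"chrI": rng.gamma(2.0, 1.0, size=5000)})
        out = hmm.normalize_nucleosome(raw)
        assert abs(out["chrI"].mean()) < 0.01
        assert abs(out["chrI"].std() - 1.0) < 0.01

    def test_monotone_in_ranks(self):
        raw = np.array([5.0, 1.0, 3.0, 2.0, 4.0])
        out = hmm.normalize_nucleosome(Track({"chrI": raw}))["chrI"]
        assert np.argsort(out).tolist() == np.argsort(raw).tolist()

    def test_missing_imputed_with_transformed_median(self):
        raw = Track({"chrI": np.array([1.0, 2.0, np.nan, 3.0, 4.0, np.nan])})
        out = hmm.normalize_nucleosome(raw)["chrI"]
        finite_median = np.median(out[[0, 1, 3, 4]])
        assert out[2] == finite_median and out[5] == finite_median

    def test_constant_input_warns_and_zeroes(self, caplog):
        raw = Track({"chrI": np.full(10, 3.0)})
        with caplog.at_level("WARNING", logger="tnscape"):
            out = hmm.normalize_nucleosome(raw)["chrI"]
        assert (out == 0).all()
        assert "constant" in caplog.text


class TestExactInferenceOracles:
    @pytest.mark.parametrize("seed", range(6))
    def test_forward_posterior_viterbi_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 4))
        T = int(rng.integers(5, 13))
        model = random_model(rng, n)
        series = random_series(rng, T)
        total, marginals, best = brute_force_pathsums(model, series)
        ll = hmm.loglikelihood(model, series)
        assert ll == pytest.approx(math.log(total), rel=1e-10)
        post = hmm.posterior_probabilities(model, series)
        np.testing.assert_allclose(post, marginals, rtol=1e-8, atol=1e-12)
        path = hmm.viterbi_decode(model, series)
        np.testing.assert_array_equal(path - 1, best)

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(42)
        model = random_model(rng, 3)
        series = random_series(rng, 200)
        post = hmm.posterior_probabilities(model, series)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_near_deterministic_emissions_give_one_hot_posterior(self):
        # state 1 emits ~0, state 2 emits ~8: posteriors collapse
        emissions = [
            hmm.ZIPEmission(beta0=-6.0, omega=0.0),
            hmm.ZIPEmission(beta0=math.log(8.0), omega=0.0),
        ]
        model = hmm.initial_model(emissions, self_prob=0.5)
        series = hmm.ObservedSeries(
            "c", np.arange(6), np.array([0, 0, 8, 8, 0, 8]),
            np.zeros(6), np.zeros(6),
        )
        post = hmm.posterior_probabilities(model, series)
        np.testing.assert_allclose(
            post.argmax(axis=1), [0, 0, 1, 1, 0, 1]
        )
        assert post.max(axis=1).min() > 0.99

    def test_viterbi_beats_random_paths(self):
        rng = np.random.default_rng(3)
        model = random_model(rng, 3)
        series = random_series(rng, 60)
        logB = model.log_emission_matrix(series)
        with np.errstate(divide="ignore"):
            logpi, logA = np.log(model.pi_init), np.log(model.A)

        def path_logprob(p):
            lp = logpi[p[0]] + logB[0, p[0]]
            for t in range(1, len(p)):
                lp += logA[p[t - 1], p[t]] + logB[t, p[t]]
            return lp

        best = path_logprob(hmm.viterbi_decode(model, series) - 1)
        for _ in range(1000):
            rand = rng.integers(0, 3, size=60)
            assert path_logprob(rand) <= best + 1e-9

    def test_constant_emissions_near_diagonal_A_constant_path(self):
        emissions = [hmm.ZIPEmission(beta0=0.0), hmm.ZIPEmission(beta0=0.0)]
        model = hmm.CovariateHMM(
            2, np.array([0.9, 0.1]),
            np.array([[0.99, 0.01], [0.01, 0.99]]), emissions,
        )
        series = hmm.ObservedSeries(
            "c", np.arange(30), np.ones(30, dtype=int), np.zeros(30), np.zeros(30)
        )
        path = hmm.viterbi_decode(model, series)
        assert (path == path[0]).all()

    def test_single_position_is_argmax_of_init_times_emission(self):
        rng = np.random.default_rng(9)
        model = random_model(rng, 3)
        series = random_series(rng, 1)
        logB = model.log_emission_matrix(series)
        expected = int(np.argmax(np.log(model.pi_init) + logB[0])) + 1
        assert hmm.viterbi_decode(model, series)[0] == expected


class TestPretraining:
    def test_no_covariate_mle_matches_truncated_poisson_closed_form(self):
        # ZIP MLE stationarity: mean of positives = lambda/(1-exp(-lambda))
        rng = np.random.default_rng(1)
        lam_true, om_true = 1.8, 0.35
        n = 20_000
        y = np.where(rng.random(n) < om_true, 0, rng.poisson(lam_true, n)).astype(float)
        X = np.column_stack([np.ones(n), np.zeros(n), np.zeros(n)])
        fit = hmm.fit_weighted_zip(y, X, np.ones(n))
        m_pos = y[y > 0].mean()
        lam_hat = brentq(lambda l: l / (1 - math.exp(-l)) - m_pos, 1e-6, 100)
        assert fit.beta0 == pytest.approx(math.log(lam_hat), abs=1e-3)
        assert fit.omega == pytest.approx(om_true, abs=0.02)

    def test_all_zero_subset_degenerates_flagged(self):
        y = np.zeros(50)
        X = np.column_stack([np.ones(50), np.zeros(50), np.zeros(50)])
        fit = hmm.fit_weighted_zip(y, X, np.ones(50))
        assert fit.flagged
        assert fit.omega == 1.0
        assert fit.beta0 == -12.0  # lower bound

    def test_parameter_recovery_with_covariates(self):
        rng = np.random.default_rng(2)
        n = 30_000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        lam = np.exp(0.5 - 0.4 * x1 + 0.3 * x2)
        y = np.where(rng.random(n) < 0.3, 0, rng.poisson(lam)).astype(float)
        X = np.column_stack([np.ones(n), x1, x2])
        fit = hmm.fit_weighted_zip(y, X, np.ones(n))
        series = hmm.ObservedSeries("c", np.arange(n), y.astype(int), x1, x2)
        se = hmm.emission_standard_errors(series, fit)
        for value, truth, s in zip(fit.beta, [0.5, -0.4, 0.3], se[:3]):
            assert abs(value - truth) < 3 * s

    def test_poisson_family_forces_omega_zero(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(2.0, 500).astype(float)
        X = np.column_stack([np.ones(500), np.zeros(500), np.zeros(500)])
        fit = hmm.fit_weighted_zip(y, X, np.ones(500), family="poisson")
        assert fit.omega == 0.0 and fit.n_params() == 3
        assert fit.beta0 == pytest.approx(math.log(y.mean()), abs=0.02)


class TestPartitions:
    def test_annotation_scheme_five_states_disjoint_nonempty(self, small_series):
        part = hmm.build_training_partition(small_series, "annotation", 5)
        assert set(part.sets) == {1, 2, 3, 4, 5}
        assert part.families[5] == "poisson"
        all_idx = np.concatenate(list(part.sets.values()))
        assert len(np.unique(all_idx)) == len(all_idx)

    def test_s5_takes_precedence_over_annotation(self):
        # 5 windows of 100 nt; the first (essential CDS) is the densest, so
        # its positions go to S5, not S1
        classes = np.repeat([0, 0, 1, 2, 4], 100).astype(np.int8)
        unique = np.zeros(500)
        unique[:100] = 1.0
        series = hmm.ObservedSeries(
            "c", np.arange(500), np.zeros(500, int), np.zeros(500), np.zeros(500),
            unique=unique, classes=classes,
        )
        part = hmm.build_training_partition(series, "annotation", 5)
        assert np.array_equal(part.sets[5], np.arange(0, 100))
        assert np.array_equal(part.sets[1], np.arange(100, 200))
        for s in (1, 2, 3, 4):
            assert not np.intersect1d(part.sets[5], part.sets[s]).size

    def test_quantile_tertiles_on_designed_densities(self):
        # 100-nt windows with 0, 1 and 2 unique insertions -> three tiers
        unique = np.concatenate([np.zeros(100), np.r_[np.ones(1), np.zeros(99)],
                                 np.r_[np.ones(2), np.zeros(98)]])
        series = hmm.ObservedSeries(
            "c", np.arange(300), np.zeros(300, int), np.zeros(300), np.zeros(300),
            unique=unique,
        )
        part = hmm.build_training_partition(series, "quantile", 3)
        assert np.array_equal(part.sets[1], np.arange(0, 100))
        assert np.array_equal(part.sets[2], np.arange(100, 200))
        assert np.array_equal(part.sets[3], np.arange(200, 300))

    def test_empty_state_set_errors_naming_state(self):
        series = hmm.ObservedSeries(
            "c", np.arange(50), np.zeros(50, int), np.zeros(50), np.zeros(50),
            unique=np.zeros(50), classes=np.full(50, 4, dtype=np.int8),
        )
        with pytest.raises(ValueError, match="state 1"):
            hmm.build_training_partition(series, "annotation", 4)


class TestEM:
    def test_one_state_converges_immediately(self):
        rng = np.random.default_rng(4)
        series = random_series(rng, 300)
        init = hmm.initial_model([hmm.ZIPEmission(beta0=0.0, omega=0.2)])
        model = hmm.em_fit(series, init, max_iter=20)
        assert model.converged
        trace = np.array(model.loglik_trace)
        assert (np.diff(trace) >= -1e-6 * np.abs(trace[:-1])).all()

    def test_infinite_tolerance_returns_after_one_iteration(self):
        rng = np.random.default_rng(5)
        series = random_series(rng, 100)
        init = random_model(rng, 2)
        model = hmm.em_fit(series, init, tol=np.inf)
        assert len(model.loglik_trace) == 2

    def test_loglik_trace_nondecreasing_on_twin_data(self, small_series):
        model = hmm.fit_hmm(small_series.slice_positions(0, 20_000),
                            "annotation", 4)
        trace = np.array(model.loglik_trace)
        assert (np.diff(trace) >= -1e-6 * np.maximum(np.abs(trace[:-1]), 1)).all()

    def test_series_shorter_than_states_errors(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="shorter"):
            hmm.em_fit(random_series(rng, 2), random_model(rng, 3))


class TestBICAndRelabel:
    def test_parameter_count_identity_one_state(self):
        rng = np.random.default_rng(7)
        series = random_series(rng, 150)
        init = hmm.initial_model([hmm.ZIPEmission(beta0=0.0, omega=0.2)])
        model = hmm.em_fit(series, init, max_iter=5)
        L = model.loglik_trace[-1]
        # k = (n-1) + n(n-1) + 4 = 4 for a single ZIP state
        assert hmm.bic_score(model, series) == pytest.approx(
            -2 * L + 4 * math.log(150)
        )

    def test_adding_states_never_decreases_k(self):
        rng = np.random.default_rng(8)
        series = random_series(rng, 150)
        ks = []
        for n in (1, 2, 3):
            model = random_model(rng, n)
            model.loglik_trace = [0.0]  # isolate the penalty term
            ks.append(hmm.bic_score(model, series))
        assert ks == sorted(ks)

    def test_relabel_orders_states_by_expected_count(self):
        rng = np.random.default_rng(9)
        series = random_series(rng, 50)
        emissions = [
            hmm.ZIPEmission(beta0=2.0, omega=0.0),
            hmm.ZIPEmission(beta0=-1.0, omega=0.5),
        ]
        model = hmm.initial_model(emissions)
        relabelled, order = hmm.relabel_by_depletion(model, series)
        assert order.tolist() == [1, 0]
        assert relabelled.emissions[0].beta0 == -1.0
        counts = hmm.expected_counts(relabelled, series)
        assert counts[0] < counts[1]


class TestChunkedFitting:
    def test_chunks_must_tile(self, small_series):
        with pytest.raises(ValueError, match="tile"):
            hmm.fit_chunked(small_series, [(0, 10_000), (20_000, 50_000)])

    def test_small_chunk_rejected(self, small_series):
        with pytest.raises(ValueError, match="mappable positions"):
            hmm.fit_chunked(small_series, [(0, 30), (30, 50_000)], n=5)

    def test_split_fits_agree_within_error(self, ident_series):
        """Independent fits of two halves of one homogeneous chromosome give
        per-state intercepts compatible within 3 combined SEs."""
        path, models = hmm.fit_chunked(
            ident_series, [(0, 30_000), (30_000, 60_000)], scheme="annotation",
            n=5, s5_poisson=False,
        )
        assert len(models) == 2
        assert (path > 0).all()
        sub_a = ident_series.slice_positions(0, 30_000)
        sub_b = ident_series.slice_positions(30_000, 60_000)
        gam_a = hmm.posterior_probabilities(models[0], sub_a)
        gam_b = hmm.posterior_probabilities(models[1], sub_b)
        for s in range(5):
            se_a = hmm.emission_standard_errors(sub_a, models[0].emissions[s], gam_a[:, s])[0]
            se_b = hmm.emission_standard_errors(sub_b, models[1].emissions[s], gam_b[:, s])[0]
            diff = models[0].emissions[s].beta0 - models[1].emissions[s].beta0
            assert abs(diff) < 3 * math.hypot(se_a, se_b) + 1e-6


class TestStateAgreement:
    def test_identical_paths(self):
        a = np.array([1, 2, 3])
        frac, per = hmm.state_agreement(a, a.copy())
        assert frac == 1.0 and per == {1: 1.0, 2: 1.0, 3: 1.0}

    def test_complementary_paths(self):
        frac, _ = hmm.state_agreement(np.ones(5, int), np.full(5, 2))
        assert frac == 0.0

    def test_alignment_by_positions_and_interval(self):
        frac, _ = hmm.state_agreement(
            np.array([1, 2, 2]), np.array([2, 9, 9]),
            positions_a=np.array([10, 20, 30]),
            positions_b=np.array([20, 30, 40]),
            interval=(15, 35),
        )
        assert frac == 0.5  # positions 20 (2==2) and 30 (2!=9)

    def test_empty_overlap_errors(self):
        with pytest.raises(ValueError, match="overlap"):
            hmm.state_agreement(
                np.array([1]), np.array([1]),
                positions_a=np.array([0]), positions_b=np.array([5]),
            )


def test_model_serialization_round_trip():
    rng = np.random.default_rng(10)
    model = random_model(rng, 3)
    model.loglik_trace = [-10.0, -9.0]
    again = hmm.CovariateHMM.from_dict(model.to_dict())
    np.testing.assert_allclose(again.A, model.A)
    assert [e.beta0 for e in again.emissions] == [e.beta0 for e in model.emissions]
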