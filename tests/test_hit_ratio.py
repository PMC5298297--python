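"""Beta-binomial hit-ratio model: prior moments, conjugacy, mixtures, labels."""

import numpy as np
import pytest
from scipy import integrate, stats

from bioprofile import (BetaPrior, HitRatioModel, SelectivityProfile,
                        estimate_prior, ks_distance,
                        label_sensitivity_specificity, mixture_samples,
                        posterior, prior_from_moments, promiscuity_probability)


def profile(cid, n, N):
    return SelectivityProfile(compound_id=cid, n_screened=N,
                              target_selectivity=n, cluster_selectivity=n,
                              domain_selectivity=n)


class TestPrior:
    def test_uniform_moments_give_flat_prior(self):
        prior = prior_from_moments(0.5, np.sqrt(1.0 / 12.0))
        assert prior.alpha == pytest.approx(1.0, abs=1e-12)
        assert prior.beta == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_moment_equations(self):
        prior = prior_from_moments(0.2, 0.1)
        assert prior.alpha == pytest.approx(3.0, abs=1e-12)
        assert prior.beta == pytest.approx(12.0, abs=1e-12)

    def test_moment_identities_hold(self):
        prior = prior_from_moments(0.31, 0.09)
        mean = prior.alpha / (prior.alpha + prior.beta)
        var = (prior.alpha * prior.beta
               / ((prior.alpha + prior.beta) ** 2
                  * (prior.alpha + prior.beta + 1)))
        assert mean == pytest.approx(0.31, abs=1e-9)
        assert np.sqrt(var) == pytest.approx(0.09, abs=1e-9)

    def test_recovers_beta_shape_from_samples(self):
        rng = np.random.default_rng(5)
        thetas = rng.beta(2.0, 5.0, size=100_000)
        # exact hit ratios at large N so the empirical ratio equals theta
        profs = [profile(f"c{i}", round(t * 10_000), 10_000)
                 for i, t in enumerate(thetas)]
        prior = estimate_prior(profs, min_screened=20)
        assert prior.alpha == pytest.approx(2.0, rel=0.05)
        assert prior.beta == pytest.approx(5.0, rel=0.05)

    def test_invalid_moments_rejected(self):
        with pytest.raises(ValueError):
            prior_from_moments(0.5, 0.6)  # sigma^2 >= mu(1-mu)


class TestPosterior:
    def test_no_data_returns_prior(self):
        prior = BetaPrior(alpha=2.5, beta=7.5, mu=0.25, sigma=0.1)
        post = posterior(0, 0, prior)
        assert (post.alpha_post, post.beta_post) == (2.5, 7.5)

    def test_conjugate_update(self):
        prior = BetaPrior(alpha=1.0, beta=1.0, mu=0.5, sigma=0.28)
        post = posterior(3, 10, prior)
        assert (post.alpha_post, post.beta_post) == (4.0, 8.0)

    def test_density_matches_quadrature_of_bayes_rule(self, rng):
        """Posterior pdf equals the grid-normalised prior x likelihood."""
        grid = np.linspace(0.0, 1.0, 1_000_001)
        for _ in range(20):
            # shapes >= 1.5 keep the integrand's boundary derivatives finite,
            # so the quadrature oracle itself is accurate to < 1e-6
            a = float(rng.uniform(1.5, 8.0))
            b = float(rng.uniform(1.5, 8.0))
            N = int(rng.integers(1, 40))
            n = int(rng.integers(0, N + 1))
            prior = BetaPrior(alpha=a, beta=b, mu=a / (a + b), sigma=0.1)
            post = posterior(n, N, prior)
            unnorm = stats.beta.pdf(grid, a, b) * stats.binom.pmf(n, N, grid)
            dens = unnorm / integrate.simpson(unnorm, x=grid)
            assert np.max(np.abs(dens - post.dist.pdf(grid))) < 1e-6

    def test_n_exceeding_N_rejected(self):
        prior = BetaPrior(alpha=1.0, beta=1.0, mu=0.5, sigma=0.28)
        with pytest.raises(ValueError):
            posterior(5, 3, prior)


class TestPromiscuityProbability:
    def test_uniform_tail(self):
        prior = BetaPrior(alpha=1.0, beta=1.0, mu=0.5, sigma=0.28)
        assert promiscuity_probability(posterior(0, 0, prior), 0.25) \
            == pytest.approx(0.75, abs=1e-12)

    def test_zero_threshold_is_certainty(self):
        prior = BetaPrior(alpha=2.0, beta=3.0, mu=0.4, sigma=0.2)
        assert promiscuity_probability(posterior(1, 4, prior), 0.0) == 1.0

    def test_matches_numerical_tail_integral(self):
        prior = BetaPrior(alpha=1.0, beta=1.0, mu=0.5, sigma=0.28)
        post = posterior(3, 10, prior)  # Beta(4, 8)
        val, _ = integrate.quad(post.dist.pdf, 0.25, 1.0, epsabs=1e-12)
        assert promiscuity_probability(post, 0.25) == pytest.approx(
            val, abs=1e-10)

    def test_monotone_in_actives_at_fixed_screening(self):
        prior = BetaPrior(alpha=2.0, beta=8.0, mu=0.2, sigma=0.1)
        probs = [promiscuity_probability(posterior(n, 30, prior))
                 for n in range(31)]
        assert all(b > a for a, b in zip(probs, probs[1:]))


class TestMixtureSamples:
    def test_degenerate_mixture_matches_component(self):
        prior = BetaPrior(alpha=1.0, beta=1.0, mu=0.5, sigma=0.28)
        post = posterior(5, 20, prior)
        mix = mixture_samples([post], per_compound=100_000,
                              pool_size=100_000, seed=1)
        direct = np.random.default_rng(2).beta(
            post.alpha_post, post.beta_post, 100_000)
        assert ks_distance(mix.values, direct) < 0.01

    def test_symmetric_two_component_mean(self):
        prior = BetaPrior(alpha=1.0, beta=1.0, mu=0.5, sigma=0.28)
        lo = posterior(0, 8, prior)   # Beta(1, 9)
        hi = posterior(8, 8, prior)   # Beta(9, 1)
        mix = mixture_samples([lo, hi], per_compound=50_000,
                              pool_size=100_000, seed=3)
        se = np.std(mix.values) / np.sqrt(mix.values.size)
        assert abs(mix.values.mean() - 0.5) < 3 * se

    def test_seed_determinism_and_pool_guard(self):
        prior = BetaPrior(alpha=1.0, beta=1.0, mu=0.5, sigma=0.28)
        post = posterior(2, 10, prior)
        m1 = mixture_samples([post], 1000, pool_size=1000, seed=7)
        m2 = mixture_samples([post], 1000, pool_size=1000, seed=7)
        assert np.array_equal(m1.values, m2.values)
        with pytest.raises(ValueError):
            mixture_samples([post], 10, pool_size=100, seed=7)


class TestKSDistance:
    def test_identical_samples(self):
        assert ks_distance([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports(self):
        assert ks_distance([1, 2, 3], [4, 5, 6]) == 1.0

    def test_matches_breakpoint_sweep_oracle(self, rng):
        for _ in range(50):
            a = rng.integers(0, 10, size=int(rng.integers(1, 9)))
            b = rng.integers(0, 10, size=int(rng.integers(1, 9)))
            breakpoints = np.concatenate([a, b])
            oracle = max(abs((a <= t).mean() - (b <= t).mean())
                         for t in breakpoints)
            assert ks_distance(a, b) == pytest.approx(oracle)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ks_distance([], [1.0])


class TestModelAndLabels:
    def test_separation_of_generated_classes(self, small_world,
                                             small_world_maps):
        from bioprofile import build_matrix, selectivity_profiles
        cmap, dmap = small_world_maps
        matrix = build_matrix(small_world.activity_records)
        profiles = selectivity_profiles(matrix, cmap, dmap)
        model = HitRatioModel().fit(profiles)
        scores = model.score_compounds(profiles)
        cls = dict(zip(small_world.truth["cid"],
                       small_world.truth["compound_class"]))
        by_class = scores.assign(cls=[cls[c] for c in scores["cid"]])
        med = by_class.groupby("cls")["prom_prob"].median()
        assert med["promiscuous"] > med["selective"]

    def test_scores_sorted_most_promiscuous_first(self):
        profs = [profile("c1", 1, 30), profile("c2", 25, 30),
                 profile("c3", 10, 30), profile("c4", 12, 25)]
        model = HitRatioModel(min_screened_prior=20).fit(profs)
        scores = model.score_compounds(profs)
        assert list(scores["prom_prob"]) == sorted(scores["prom_prob"],
                                                   reverse=True)

    def test_low_participation_compounds_not_scored(self):
        profs = [profile("c1", 5, 30), profile("c2", 10, 25),
                 profile("c3", 2, 5)]
        model = HitRatioModel().fit(profs)
        assert "c3" not in set(model.score_compounds(profs)["cid"])

    def test_all_positive_labels_give_unit_sensitivity(self):
        probs = {"c1": 0.9, "c2": 0.6, "c3": 0.1}
        labels = {c: True for c in probs}
        table = label_sensitivity_specificity(probs, labels,
                                              cutoffs=(0.3, 0.5))
        assert (table["sensitivity"] == 1.0).all()

    def test_empty_promiscuous_class_reports_missing(self):
        probs = {"c1": 0.1, "c2": 0.2}
        table = label_sensitivity_specificity(
            probs, {"c1": True, "c2": False}, cutoffs=(0.9,))
        assert np.isnan(table.loc[0, "sensitivity"])
        assert table.loc[0, "specificity"] == 0.5

    def test_matches_hand_computed_confusion_fractions(self):
        probs = {f"c{i}": p for i, p in enumerate(
            [0.95, 0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1, 0.05])}
        labels = {f"c{i}": flag for i, flag in enumerate(
            [True, True, False, True, False, False, False, True, False, False])}
        table = label_sensitivity_specificity(probs, labels, cutoffs=(0.5,))
        # promiscuous at 0.5: c0..c4 -> 3 of 5 labelled; non-promiscuous
        # c5..c9 -> 4 of 5 unlabelled
        assert table.loc[0, "sensitivity"] == pytest.approx(3 / 5)
        assert table.loc[0, "specificity"] == pytest.approx(4 / 5)
        assert table.loc[0, "n_promiscuous"] == 5

    def test_unlabelled_scored_compound_rejected(self):
        with pytest.raises(KeyError):
            label_sensitivity_specificity({"c1": 0.5}, {}, cutoffs=(0.5,))
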