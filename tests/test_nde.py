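"""Empirical-Bayes NDE/DE classifier: factors, marginals, posteriors, FDR."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom

import devscreen as ds
from devscreen import nde as N


def make_comparison(n_a, n_b, factors=None):
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    if factors is None:
        factors = pd.Series(1.0, index=samples)
    else:
        factors = pd.Series(factors, index=samples)
    return N.Comparison(
        group_a=tuple(samples[:n_a]),
        group_b=tuple(samples[n_a:]),
        library_factors=factors,
    )


def make_particles(model, class_means, phi, weights, coupled):
    p = len(phi)
    return N.ModelParticles(
        model=model,
        class_means=tuple(np.asarray(m, dtype=float) for m in class_means),
        dispersion=np.asarray(phi, dtype=float),
        class_weights=tuple(np.asarray(w, dtype=float) for w in weights),
        source_genes=np.arange(p),
        coupled=coupled,
    )


def oracle_log_marginal(row, comparison, particles):
    """Direct enumeration with scipy's NB pmf (independent of the
    log-space chunked implementation)."""
    masks = comparison.class_masks(particles.model)
    f = comparison.factors
    x = np.asarray(row, dtype=float)
    size = 1.0 / particles.dispersion

    def class_pmf(i, c, mask):
        mu = particles.class_means[c][i] * f[mask]
        prob = size[i] / (size[i] + mu)
        return float(np.prod(nbinom.pmf(x[mask], size[i], prob)))

    if particles.coupled:
        total = sum(
            particles.class_weights[0][i]
            * math.prod(class_pmf(i, c, m) for c, m in enumerate(masks))
            for i in range(particles.n_particles)
        )
        return math.log(total)
    total = 1.0
    for c, m in enumerate(masks):
        total *= sum(
            particles.class_weights[c][i] * class_pmf(i, c, m)
            for i in range(particles.n_particles)
        )
    return math.log(total)


class TestLibraryFactors:
    def test_equal_sums_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20], "b": [15, 15]})
        np.testing.assert_allclose(N.estimate_library_factors(counts), 1.0)

    def test_two_to_one_ratio(self):
        counts = pd.DataFrame({"a": [1_000_000], "b": [2_000_000]})
        f = N.estimate_library_factors(counts)
        assert f["a"] == pytest.approx(1 / math.sqrt(2))
        assert f["b"] == pytest.approx(math.sqrt(2))

    def test_single_sample_is_unit(self):
        counts = pd.DataFrame({"a": [5, 7]})
        assert N.estimate_library_factors(counts)["a"] == pytest.approx(1.0)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            N.estimate_library_factors(pd.DataFrame({"a": [0, 0]}))


class TestMarginalLikelihood:
    def test_single_particle_single_sample_is_the_pmf(self):
        comp = make_comparison(1, 1)
        mu, phi = 50.0, 0.1
        particles = make_particles("NDE", [[mu]], [phi], [[1.0]], coupled=True)
        priors = N.PriorParticleSet(nde=particles, de=particles, bootstrap_rounds=1)
        x = pd.Series([42, 55], index=comp.samples)
        got = N.marginal_likelihood(x, comp, priors, "NDE")
        size = 1 / phi
        expected = nbinom.logpmf(42, size, size / (size + mu)) + nbinom.logpmf(
            55, size, size / (size + mu)
        )
        assert got == pytest.approx(float(expected), abs=1e-10)

    def test_two_equal_weight_particles_average(self):
        comp = make_comparison(1, 1)
        particles = make_particles(
            "NDE", [[30.0, 80.0]], [0.1, 0.2], [[0.5, 0.5]], coupled=True
        )
        priors = N.PriorParticleSet(nde=particles, de=particles, bootstrap_rounds=1)
        x = pd.Series([42, 55], index=comp.samples)
        got = N.marginal_likelihood(x, comp, priors, "NDE")

        def one(mu, phi):
            size = 1 / phi
            return math.exp(
                nbinom.logpmf(42, size, size / (size + mu))
                + nbinom.logpmf(55, size, size / (size + mu))
            )

        assert got == pytest.approx(
            math.log(0.5 * one(30.0, 0.1) + 0.5 * one(80.0, 0.2)), abs=1e-10
        )

    @pytest.mark.parametrize("coupled", [True, False])
    @pytest.mark.parametrize("model", ["NDE", "DE"])
    def test_matches_enumeration_oracle(self, model, coupled):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n_a = int(rng.integers(1, 3))
            n_b = int(rng.integers(1, 3))
            if n_a + n_b > 3:
                continue
            p = int(rng.integers(1, 4))
            comp = make_comparison(n_a, n_b, factors=rng.uniform(0.5, 2.0, n_a + n_b))
            means_a = rng.uniform(5, 200, p)
            means_b = rng.uniform(5, 200, p)
            phi = rng.uniform(0.01, 0.5, p)
            w = rng.dirichlet(np.ones(p))
            if model == "NDE":
                particles = make_particles("NDE", [means_a], phi, [w], coupled)
            else:
                particles = make_particles(
                    "DE", [means_a, means_b], phi, [w, w], coupled
                )
            priors = N.PriorParticleSet(
                nde=particles, de=particles, bootstrap_rounds=1
            )
            x = pd.Series(rng.integers(0, 300, n_a + n_b), index=comp.samples)
            got = N.marginal_likelihood(x, comp, priors, model)
            want = oracle_log_marginal(x.to_numpy(), comp, particles)
            assert got == pytest.approx(want, abs=1e-10)


class TestPosteriorRankFdr:
    def test_perfect_posteriors_have_zero_fdr(self):
        post = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        np.testing.assert_allclose(N.posterior_rank_fdr(post), 0.0)

    def test_hand_cumulative_mean(self):
        post = pd.Series([0.9, 0.8], index=["a", "b"])
        fdr = N.posterior_rank_fdr(post)
        assert fdr["a"] == pytest.approx(0.1)
        assert fdr["b"] == pytest.approx(0.15)

    def test_single_gene(self):
        assert N.posterior_rank_fdr(pd.Series([0.7], index=["a"]))["a"] == pytest.approx(0.3)

    def test_monotone_along_ranking(self):
        rng = np.random.default_rng(3)
        post = pd.Series(rng.random(500))
        fdr = N.posterior_rank_fdr(post)
        order = post.sort_values(ascending=False).index
        assert (np.diff(fdr.loc[order]) >= -1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            N.posterior_rank_fdr(pd.Series(dtype=float))


class TestPosteriorLikelihoods:
    def test_frozen_priors_reproduce_bayes_arithmetic(self):
        # one gene, hand-checkable: posterior = L_N / (L_N + L_D) at equal
        # model priors
        comp = make_comparison(1, 1)
        nde = make_particles("NDE", [[50.0]], [0.1], [[1.0]], coupled=True)
        de = make_particles("DE", [[20.0], [90.0]], [0.1], [[1.0], [1.0]], coupled=True)
        priors = N.PriorParticleSet(nde=nde, de=de, bootstrap_rounds=1)
        counts = pd.DataFrame([[48, 52]], index=["g0"], columns=comp.samples)
        table = N.posterior_likelihoods(counts, comp, priors, freeze_priors=True)
        l_n = math.exp(oracle_log_marginal([48, 52], comp, nde))
        l_d = math.exp(oracle_log_marginal([48, 52], comp, de))
        assert table.table.loc["g0", "likelihood_NDE"] == pytest.approx(
            l_n / (l_n + l_d), abs=1e-10
        )

    def test_nine_to_one_ratio_gives_point_nine(self):
        # frozen equal priors and a marginal-likelihood ratio of 9:1 in
        # favour of NDE yield posterior 0.9 exactly; engineer the ratio by
        # weighting one particle mixture 9x richer at the observed count
        comp = make_comparison(1, 1)
        mu, phi = 50.0, 0.1
        size = 1 / phi
        pmf = float(
            np.exp(
                nbinom.logpmf(50, size, size / (size + mu)) * 2
            )
        )
        nde = make_particles("NDE", [[mu]], [phi], [[1.0]], coupled=True)
        # DE marginal forced to 1/9 of the NDE marginal via a pseudo-count
        # particle with the same fit but weight 1/9 plus a far-off particle
        far = 1e6
        de = make_particles(
            "DE",
            [[mu, far], [mu, far]],
            [phi, phi],
            [[1 / 9, 8 / 9], [1 / 9, 8 / 9]],
            coupled=True,
        )
        priors = N.PriorParticleSet(nde=nde, de=de, bootstrap_rounds=1)
        counts = pd.DataFrame([[50, 50]], index=["g0"], columns=comp.samples)
        table = N.posterior_likelihoods(counts, comp, priors, freeze_priors=True)
        assert table.table.loc["g0", "likelihood_NDE"] == pytest.approx(0.9, abs=1e-6)

    def test_identical_marginals_stay_at_half(self):
        comp = make_comparison(1, 1)
        particles = make_particles("NDE", [[50.0]], [0.1], [[1.0]], coupled=True)
        priors = N.PriorParticleSet(nde=particles, de=particles, bootstrap_rounds=1)
        counts = pd.DataFrame(
            [[40, 60], [55, 45]], index=["g0", "g1"], columns=comp.samples
        )
        table = N.posterior_likelihoods(counts, comp, priors)
        np.testing.assert_allclose(table.table["likelihood_NDE"], 0.5, atol=1e-9)
        assert table.model_prior_nde == pytest.approx(0.5, abs=1e-4)

    def test_posteriors_sum_to_one(self, calibration_classification):
        _, _, table = calibration_classification
        s = table.table["likelihood_NDE"] + table.table["likelihood_DE"]
        np.testing.assert_allclose(s, 1.0, atol=1e-12)

    def test_null_panel_prefers_nde(self):
        panel, catalog, truth = ds.calibration_panel(
            n_genes=2000, de_fraction=0.0, seed=3
        )
        comp = N.make_category_comparison(panel, "normal", 12.0)
        table = N.run_comparison(panel, comp, seed=3)
        assert table.table["likelihood_DE"].mean() < 0.5


class TestPriors:
    def test_same_seed_gives_identical_particles(self, small_panel):
        panel, _, _ = small_panel
        comp = N.make_category_comparison(panel, "normal", 12.0)
        a = N.sample_priors(panel.counts, comp, n_particles=20, seed=5)
        b = N.sample_priors(panel.counts, comp, n_particles=20, seed=5)
        np.testing.assert_array_equal(a.nde.source_genes, b.nde.source_genes)
        np.testing.assert_allclose(a.de.class_means[0], b.de.class_means[0])
        np.testing.assert_allclose(a.de.class_weights[0], b.de.class_weights[0])

    def test_single_round_keeps_uniform_weights(self, small_panel):
        panel, _, _ = small_panel
        comp = N.make_category_comparison(panel, "normal", 12.0)
        priors = N.sample_priors(
            panel.counts, comp, n_particles=20, bootstrap_rounds=1, seed=5
        )
        np.testing.assert_allclose(priors.nde.class_weights[0], 1 / 20)
        assert not priors.coupled_evaluation

    def test_null_data_gives_matching_group_means(self):
        panel, catalog, truth = ds.calibration_panel(
            n_genes=1000, de_fraction=0.0, seed=4
        )
        comp = N.make_category_comparison(panel, "normal", 12.0)
        priors = N.sample_priors(panel.counts, comp, n_particles=50, seed=4)
        de = priors.de
        # under the null every sampled gene's two group means agree within
        # sampling error, so their log ratios centre on zero
        log_ratio = np.log(de.class_means[0] + 1) - np.log(de.class_means[1] + 1)
        assert abs(np.median(log_ratio)) < 0.5

    def test_too_few_particles_rejected(self, small_panel):
        panel, _, _ = small_panel
        comp = N.make_category_comparison(panel, "normal", 12.0)
        with pytest.raises(ValueError, match=">= 10"):
            N.sample_priors(panel.counts, comp, n_particles=5)

    def test_panel_dispersions_recover_simulated_value(self, acceptance_panel):
        panel, _, _ = acceptance_panel
        phi = N.estimate_panel_dispersions(panel)
        # generator uses NB size 10 => phi = 0.1 for well-expressed genes
        expressed = panel.counts.mean(axis=1) > 50
        assert np.median(phi[expressed]) == pytest.approx(0.1, abs=0.03)


class TestClassification:
    def make_table(self, liks, fdrs):
        df = pd.DataFrame(
            {
                "likelihood_NDE": liks,
                "likelihood_DE": [1 - l for l in liks],
                "fdr_NDE": fdrs,
                "fdr_DE": [0.5] * len(liks),
            },
            index=[f"g{i}" for i in range(len(liks))],
        )
        return N.PosteriorTable(table=df, model_prior_nde=0.5, n_iterations=1)

    def test_both_thresholds_required(self):
        table = self.make_table([0.95, 0.95, 0.5], [0.001, 0.01, 0.001])
        assert N.classify_nde(table) == frozenset({"g0"})

    def test_empty_table_gives_empty_set(self):
        table = N.PosteriorTable(
            table=pd.DataFrame(
                columns=["likelihood_NDE", "likelihood_DE", "fdr_NDE", "fdr_DE"]
            ),
            model_prior_nde=0.5,
            n_iterations=1,
        )
        assert N.classify_nde(table) == frozenset()

    def test_null_sensitivity_at_unit_effect(self):
        # planted invariant genes are recovered as NDE with sensitivity
        # >= 0.8 even when the perturbed minority changes only e-fold
        panel, catalog, truth = ds.calibration_panel(
            n_genes=5000, effect_size_logfc=1.0, seed=1
        )
        comp = N.make_category_comparison(panel, "normal", 12.0)
        table = N.run_comparison(panel, comp, seed=1)
        nde_set = N.classify_nde(table)
        planted = truth.perturbed_genes_of("N01")
        nulls = set(panel.gene_ids) - planted
        sensitivity = len(nde_set & nulls) / len(nulls)
        assert sensitivity >= 0.8
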