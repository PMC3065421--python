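"""Gene models, likelihood measures, cross-testing and model-free diagnostics."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

from hybcal import measures
from hybcal.datamodel_io import ValidationError
from hybcal.measures import (
    CrossTestResult,
    GeneModel,
    cross_test,
    fit_gene_models,
    generalization_accuracy,
    loglik_linear,
    loglik_nb,
    mutual_information,
    nb_posterior,
    roc_summary,
    score_protocol,
)

from conftest import make_es, make_obs, planted_two_group_es


class TestFitGeneModels:
    def test_hand_computed_ml_estimates(self):
        # group0 {1,3}, group1 {2,4}: means 2/3, pooled ML variance (1+1+1+1)/4 = 1
        es = make_es(np.array([[1.0, 2.0, 4.0, 3.0]]))  # y = 0,1,1,0
        (m,) = fit_gene_models(es)
        assert (m.mu0, m.mu1, m.sigma, m.prior1) == (2.0, 3.0, 1.0, 0.5)

    def test_identical_groups_give_zero_weight(self):
        # y order is (0, 1, 1, 0), so both classes observe {1, 2}
        es = make_es(np.array([[5.0, 5.0, 5.0, 5.0], [1, 2, 1, 2.0]]))
        models = fit_gene_models(es)
        assert models[1].w == 0.0
        assert models[1].b == pytest.approx(np.log(models[1].prior1 / (1 - models[1].prior1)))

    def test_constant_gene_hits_sigma_floor(self):
        es = make_es(np.full((1, 4), 7.0))
        (m,) = fit_gene_models(es)
        assert m.sigma == measures.SIGMA_FLOOR

    def test_empty_subset_rejected(self, toy_es):
        with pytest.raises(ValidationError):
            fit_gene_models(toy_es, subset=[])


class TestLoglikLinear:
    def test_closed_form_at_zero_residuals(self):
        es = make_es(np.array([[1.0, 2.0, 2.0, 1.0]]))
        models = [GeneModel("g0", 1.0, 2.0, 1.0, 0.5)]
        assert loglik_linear(es, models) == pytest.approx(4 * np.log(1 / np.sqrt(2 * np.pi)))

    def test_additivity_over_observations(self, rng):
        import pandas as pd

        from hybcal.datamodel_io import ExpressionSet

        es = planted_two_group_es(rng, n_genes=10, n_slides=4)
        models = fit_gene_models(es)
        dup_obs = es.obs.copy()
        dup_obs["slide"] = dup_obs["slide"] + "_dup"
        big = ExpressionSet(
            gene_ids=es.gene_ids,
            values=np.hstack([es.values, es.values]),
            obs=pd.concat([es.obs, dup_obs], ignore_index=True),
        )
        assert loglik_linear(big, models) == pytest.approx(2 * loglik_linear(es, models))

    def test_ml_fit_maximizes_likelihood(self, rng):
        es = planted_two_group_es(rng, n_genes=8, n_slides=4)
        models = fit_gene_models(es)
        best = loglik_linear(es, models)
        for _ in range(50):
            perturbed = [
                GeneModel(
                    m.gene_id,
                    m.mu0 + rng.normal(0, 0.2),
                    m.mu1 + rng.normal(0, 0.2),
                    m.sigma * np.exp(rng.normal(0, 0.2)),
                    m.prior1,
                )
                for m in models
            ]
            assert loglik_linear(es, perturbed) <= best + 1e-9


class TestPosteriorDual:
    def test_midpoint_with_equal_priors_is_half(self):
        m = GeneModel("g", 0.0, 2.0, 1.0, 0.5)
        assert nb_posterior(1.0, m) == pytest.approx(0.5)

    def test_bayes_rule_value_at_class_mean(self):
        # mu0=0, mu1=2, sigma=1, equal priors, x=2 -> logistic(2)
        m = GeneModel("g", 0.0, 2.0, 1.0, 0.5)
        assert nb_posterior(2.0, m) == pytest.approx(expit(2.0), abs=1e-9)
        assert nb_posterior(2.0, m) == pytest.approx(0.880797, abs=1e-6)

    def test_zero_weight_returns_prior(self):
        m = GeneModel("g", 3.0, 3.0, 0.7, 0.3)
        for x in (-10.0, 0.0, 42.0):
            assert nb_posterior(x, m) == pytest.approx(0.3)

    def test_dual_representation_identity(self, rng):
        """logistic(w x + b) equals the Bayes-rule posterior of the two Gaussians."""
        for _ in range(2000):
            m = GeneModel(
                "g",
                rng.normal(0, 2),
                rng.normal(0, 2),
                rng.uniform(0.5, 3.0),
                rng.uniform(0.05, 0.95),
            )
            x = rng.normal(0, 3)
            f1 = m.prior1 * norm.pdf(x, m.mu1, m.sigma)
            f0 = (1 - m.prior1) * norm.pdf(x, m.mu0, m.sigma)
            bayes = f1 / (f0 + f1)
            assert abs(expit(m.w * x + m.b) - bayes) < 1e-10


class TestLoglikNB:
    def test_equals_direct_posterior_sum(self, rng):
        es = planted_two_group_es(rng, n_genes=12, n_slides=4)
        models = fit_gene_models(es)
        direct = sum(
            float(
                np.log(
                    nb_posterior(x, m) if y == 1 else 1 - nb_posterior(x, m)
                )
            )
            for m, row in zip(models, es.values)
            for x, y in zip(row, es.y)
        )
        assert loglik_nb(es, models) == pytest.approx(direct)

    def test_never_positive(self, rng):
        es = planted_two_group_es(rng, n_genes=20, n_slides=4, effect=3.0)
        assert loglik_nb(es, fit_gene_models(es)) <= 0.0

    def test_uninformative_genes_near_half_per_observation(self, rng):
        es = planted_two_group_es(rng, n_genes=200, n_slides=6, effect=0.0, noise_sd=1.0)
        ll = loglik_nb(es, fit_gene_models(es))
        per_term = ll / (es.n_genes * es.n_obs)
        assert per_term == pytest.approx(np.log(0.5), abs=0.12)

    def test_separated_genes_approach_zero(self, rng):
        es = planted_two_group_es(
            rng, n_genes=10, n_slides=4, effect=10.0, noise_sd=0.05,
            informative_fraction=1.0,
        )
        ll = loglik_nb(es, fit_gene_models(es))
        assert ll > es.n_genes * es.n_obs * np.log(1 - 1e-4)


class TestCrossTest:
    def test_loo_gives_one_fold_per_slide(self, rng):
        es = planted_two_group_es(rng, n_genes=5, n_slides=6)
        ct = cross_test(es, "loo")
        assert ct.n_folds == 6
        assert sorted(ct.fold_of_slide) == sorted(es.slides)
        assert len(set(ct.fold_of_slide.values())) == 6

    def test_equals_hand_rolled_leave_one_slide_out(self, rng):
        es = planted_two_group_es(rng, n_genes=7, n_slides=5)
        ct = cross_test(es, "loo")
        slide_arr = es.obs["slide"].to_numpy()
        for s in es.slides:
            test = slide_arr == s
            sub = make_es(
                es.values[:, ~test],
                n_slides=None,
                gene_ids=es.gene_ids,
            )
            # rebuild training set with original metadata to keep labels aligned
            from hybcal.datamodel_io import ExpressionSet

            train = ExpressionSet(
                gene_ids=es.gene_ids,
                values=es.values[:, ~test],
                obs=es.obs[~test],
            )
            models = fit_gene_models(train)
            for g, m in enumerate(models):
                expected = nb_posterior(es.values[g, test], m)
                np.testing.assert_allclose(ct.posteriors[g, test], expected)

    def test_separable_data_predicts_correct_side(self, rng):
        es = planted_two_group_es(
            rng, n_genes=10, n_slides=6, effect=5.0, noise_sd=0.1,
            informative_fraction=1.0,
        )
        ct = cross_test(es)
        correct = (ct.posteriors > 0.5) == (ct.y[None, :] == 1)
        assert correct.all()

    def test_too_few_training_slides_rejected(self, rng):
        es = planted_two_group_es(rng, n_genes=3, n_slides=2)
        with pytest.raises(ValidationError):
            cross_test(es, "loo")


def _manual_ct(posteriors, y, prior=0.5):
    posteriors = np.atleast_2d(np.asarray(posteriors, dtype=float))
    y = np.asarray(y)
    return CrossTestResult(
        gene_ids=[f"g{i}" for i in range(posteriors.shape[0])],
        posteriors=posteriors,
        y=y,
        priors=np.full(y.size, prior),
        fold_of_slide={},
    )


class TestAccuracy:
    def test_perfect_separation_is_100(self):
        ct = _manual_ct([[0.9, 0.95, 0.1, 0.05]], [1, 1, 0, 0])
        assert generalization_accuracy(ct) == 100.0

    def test_tie_rule_gives_majority_rate_in_balanced_design(self):
        ct = _manual_ct([[0.5, 0.5, 0.5, 0.5]], [1, 1, 0, 0])
        assert generalization_accuracy(ct) == 50.0

    def test_matches_brute_force_counting(self, rng):
        post = rng.uniform(size=(6, 10))
        y = np.tile([0, 1], 5)
        ct = _manual_ct(post, y)
        n_correct = 0
        for g in range(6):
            for n in range(10):
                pred = 1 if post[g, n] > 0.5 else 0
                n_correct += pred == y[n]
        assert generalization_accuracy(ct) == pytest.approx(100 * n_correct / 60)


class TestRoc:
    def test_perfect_gene_has_auc_one(self):
        ct = _manual_ct([[0.9, 0.8, 0.2, 0.1]], [1, 1, 0, 0])
        curve, mean_auc = roc_summary(ct)
        assert mean_auc == 1.0
        assert curve["tpr"].iloc[0] >= 0.0 and curve["tpr"].iloc[-1] == 1.0

    def test_constant_posteriors_give_half(self):
        ct = _manual_ct([[0.4, 0.4, 0.4, 0.4]], [1, 0, 1, 0])
        _, mean_auc = roc_summary(ct)
        assert mean_auc == pytest.approx(0.5)

    def test_matches_exhaustive_threshold_oracle(self, rng):
        scores = rng.uniform(size=8)
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        ct = _manual_ct(scores[None, :], y)
        # oracle: P(score_pos > score_neg) + 0.5 P(tie) over all pairs
        pos, neg = scores[y == 1], scores[y == 0]
        pairs = [(p, n) for p in pos for n in neg]
        auc = np.mean([1.0 if p > n else 0.5 if p == n else 0.0 for p, n in pairs])
        _, mean_auc = roc_summary(ct)
        assert mean_auc == pytest.approx(auc)

    def test_single_class_rejected(self):
        ct = _manual_ct([[0.5, 0.6, 0.7, 0.8]], [1, 1, 1, 1])
        with pytest.raises(ValidationError):
            roc_summary(ct)


class TestMutualInformation:
    def test_perfect_predictor_with_equal_priors_is_one_bit(self):
        eps = measures.POSTERIOR_EPS
        ct = _manual_ct([[1 - eps, 1 - eps, eps, eps]], [1, 1, 0, 0])
        assert mutual_information(ct) == pytest.approx(1.0, abs=1e-5)

    def test_posterior_equal_prior_is_zero_bits(self):
        ct = _manual_ct([[0.5] * 6, [0.5] * 6], [1, 0, 1, 0, 1, 0])
        assert mutual_information(ct) == 0.0

    def test_matches_numeric_integration_for_known_gaussians(self, rng):
        """Plug-in bit rate at a large test sample approaches the integral
        I = E_x[ sum_y P(y|x) log2(P(y|x)/P(y)) ] under the fitted model."""
        mu0, mu1, sigma = 0.0, 1.2, 1.0
        m = GeneModel("g", mu0, mu1, sigma, 0.5)
        n = 100_000
        y = np.tile([0, 1], n // 2)
        x = np.where(y == 1, rng.normal(mu1, sigma, n), rng.normal(mu0, sigma, n))
        post = nb_posterior(x, m)
        ct = _manual_ct(post[None, :], y)
        grid = np.linspace(-8, 9, 4001)
        p1 = nb_posterior(grid, m)
        px = 0.5 * (norm.pdf(grid, mu0, sigma) + norm.pdf(grid, mu1, sigma))
        integrand = px * (
            p1 * np.log2(p1 / 0.5) + (1 - p1) * np.log2((1 - p1) / 0.5)
        )
        expected = np.trapezoid(integrand, grid)
        assert mutual_information(ct) == pytest.approx(expected, abs=0.01)

    def test_label_shuffled_data_slightly_negative(self, rng):
        """Held-out MI of shuffled labels is near zero but biased slightly
        negative (cross-validation pessimism), far below real-signal MI."""
        from hybcal import hybsim

        es, _ = hybsim.gaussian_group_dataset(
            n_per_group=15, effect_sizes=(0, 0, 0, 0), rng=rng
        )
        vals = []
        for _ in range(30):
            y = es.obs["sample"].to_numpy().copy()
            for s in es.slides:
                if rng.random() < 0.5:
                    mask = (es.obs["slide"] == s).to_numpy()
                    y[mask] = 1 - y[mask]
            shuffled = es.copy(obs=es.obs.assign(sample=y))
            vals.append(mutual_information(cross_test(shuffled)))
        mean = float(np.mean(vals))
        assert -0.5 < mean < 0.01

    def test_noise_genes_degrade_mean_bitrate(self, rng):
        es = planted_two_group_es(
            rng, n_genes=40, n_slides=6, effect=2.0, informative_fraction=1.0
        )
        mi_signal = mutual_information(cross_test(es))
        noise = planted_two_group_es(
            rng, n_genes=40, n_slides=6, effect=0.0,
            informative_fraction=0.0,
        )
        combined = make_es(
            np.vstack([es.values, noise.values]),
            n_slides=6,
            gene_ids=[f"g{i}" for i in range(80)],
        )
        assert mutual_information(cross_test(combined)) < mi_signal


class TestScoreProtocol:
    def test_all_measures_rank_low_noise_first(self, rng):
        low = planted_two_group_es(rng, n_genes=60, n_slides=6, noise_sd=0.2, effect=0.8)
        high = make_es(
            low.values + rng.normal(0, 0.4, size=low.values.shape),
            n_slides=6,
            gene_ids=low.gene_ids,
        )
        scores = {s.protocol: s for s in score_protocol({"low": low, "high": high})}
        a, b = scores["low"], scores["high"]
        assert a.loglik_nb > b.loglik_nb
        assert a.loglik_linear > b.loglik_linear
        assert a.accuracy_pct > b.accuracy_pct
        assert a.mean_auc > b.mean_auc
        assert a.bitrate > b.bitrate

    def test_identical_inputs_give_identical_scores(self, rng):
        es = planted_two_group_es(rng, n_genes=20, n_slides=4)
        s1, s2 = score_protocol({"a": es, "b": es.copy()})
        assert (
            s1.loglik_nb == s2.loglik_nb
            and s1.accuracy_pct == s2.accuracy_pct
            and s1.bitrate == s2.bitrate
        )

    def test_subset_descriptor_bookkeeping(self, rng):
        es = planted_two_group_es(rng, n_genes=20, n_slides=4)
        all_scores = score_protocol({"a": es})
        sub = score_protocol({"a": es}, subset=es.gene_ids[:5], subset_name="spikes")
        assert all_scores[0].subset == "all" and sub[0].subset == "spikes"

    def test_gene_mismatch_rejected(self, rng):
        es = planted_two_group_es(rng, n_genes=10, n_slides=4)
        other = make_es(es.values, gene_ids=[f"x{i}" for i in range(10)])
        with pytest.raises(ValidationError):
            score_protocol({"a": es, "b": other})
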