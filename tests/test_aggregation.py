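"""Pooling, Gaussian demographic models, age priors and group tests."""


import numpy as np
import pytest
from scipy import integrate, stats

from metaphen import reference
from metaphen.aggregation import (
    GaussianModel,
    age_prior,
    build_profile,
    fit_gaussian,
    group_tests,
    pooled_mean_sd,
    survival_probability,
)
from metaphen.aggregation import TestConfig as SignificanceConfig
from metaphen.annotations import AgeSummary
from metaphen.synth import clopper_pearson, default_config, simulate_corpus


def summaries_from_groups(groups):
    return [AgeSummary.from_values(g, keep_values=False) for g in groups]


class TestPooling:
    def test_single_summary_is_identity(self):
        out = pooled_mean_sd([AgeSummary(mean=10, sd=2, n=5)])
        assert (out.mean, out.sd, out.n_total) == (10, 2, 5)

    def test_weighted_mean_of_two_degenerate_groups(self):
        out = pooled_mean_sd([AgeSummary(mean=10, sd=0, n=5), AgeSummary(mean=20, sd=0, n=5)])
        assert out.mean == 15

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_concatenated_raw_samples(self, seed):
        rng = np.random.default_rng(seed)
        groups = [
            rng.normal(rng.uniform(50, 80), rng.uniform(1, 15), rng.integers(2, 60))
            for _ in range(20)
        ]
        pooled = pooled_mean_sd(summaries_from_groups(groups))
        concat = np.concatenate(groups)
        assert pooled.mean == pytest.approx(concat.mean(), abs=1e-9)
        assert pooled.sd == pytest.approx(concat.std(ddof=1), abs=1e-9)
        assert pooled.n_total == concat.size
        assert sum(pooled.weights) == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_ordering_and_splitting(self):
        rng = np.random.default_rng(42)
        groups = [rng.normal(60, 8, 30), rng.normal(70, 5, 21)]
        base = pooled_mean_sd(summaries_from_groups(groups))
        shuffled = pooled_mean_sd(summaries_from_groups(groups[::-1]))
        split = pooled_mean_sd(
            summaries_from_groups([groups[0][:11], groups[0][11:], groups[1]])
        )
        for other in (shuffled, split):
            assert other.mean == pytest.approx(base.mean, abs=1e-9)
            assert other.sd == pytest.approx(base.sd, abs=1e-9)

    def test_empty_and_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            pooled_mean_sd([])
        with pytest.raises(Exception):
            pooled_mean_sd([AgeSummary(mean=1, sd=-1, n=2)])


class TestGaussianModels:
    def test_fit_uses_pooled_moments(self):
        mu, sd = reference.ONSET_MEAN_SD["MSA"]
        summary = pooled_mean_sd([AgeSummary(mean=mu, sd=sd, n=100)])
        model = fit_gaussian(summary, reference.ONSET_SUPPORT)
        assert model.mu == pytest.approx(59.19)
        assert model.ml_age == pytest.approx(model.mu)

    def test_degenerate_sd_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian(pooled_mean_sd([AgeSummary(mean=10, sd=0, n=5)]), (0, 30))

    def test_density_mass_on_four_sigma_support(self):
        model = GaussianModel(mu=60, sigma=8, support=(60 - 32, 60 + 32))
        mass, _ = integrate.quad(model.pdf, *model.support)
        assert mass >= 0.99

    def test_density_zero_outside_support(self):
        model = GaussianModel(mu=15, sigma=5, support=(0, 30))
        assert model.pdf(-1) == 0 and model.pdf(31) == 0

    def test_survival_half_at_mean(self):
        mu, sd = reference.DURATION_MEAN_SD["MSA"]
        model = GaussianModel(mu=mu, sigma=sd, support=reference.SURVIVAL_SUPPORT)
        assert survival_probability(model, mu) == pytest.approx(0.5)

    def test_survival_monotone_and_boundary(self):
        model = GaussianModel(mu=7.19, sigma=2.60, support=(0, 30))
        ts = np.linspace(0, 30, 50)
        vals = [survival_probability(model, t) for t in ts]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[0] > 0.99 and vals[-1] < 1e-6

    def test_survival_matches_monte_carlo(self):
        model = GaussianModel(mu=7.19, sigma=2.60, support=(0, 30))
        draws = np.random.default_rng(0).normal(model.mu, model.sigma, 10**6)
        for t in (3.0, 7.19, 12.0):
            assert survival_probability(model, t) == pytest.approx(
                (draws > t).mean(), abs=3e-3
            )

    def test_survival_outside_support_rejected(self):
        model = GaussianModel(mu=7, sigma=2, support=(0, 30))
        with pytest.raises(ValueError):
            survival_probability(model, 31)


class TestAgePrior:
    @staticmethod
    def onset_models():
        return {
            d: GaussianModel(mu=mu, sigma=sd, support=reference.ONSET_SUPPORT)
            for d, (mu, sd) in reference.ONSET_MEAN_SD.items()
        }

    def test_symmetric_models_give_half(self):
        m = GaussianModel(mu=60, sigma=10, support=(30, 100))
        out = age_prior(55, {"A": m, "B": m})
        assert out == {"A": pytest.approx(0.5), "B": pytest.approx(0.5)}

    def test_msa_most_likely_at_45(self):
        out = age_prior(45, self.onset_models())
        assert max(out, key=out.get) == "MSA"
        assert sum(out.values()) == pytest.approx(1.0)

    def test_scale_invariance_of_weights(self):
        models = self.onset_models()
        w = {d: i + 1.0 for i, d in enumerate(models)}
        a = age_prior(50, models, w)
        b = age_prior(50, models, {d: 17.3 * v for d, v in w.items()})
        for d in models:
            assert a[d] == pytest.approx(b[d], abs=1e-12)

    def test_zero_weights_rejected(self):
        models = self.onset_models()
        with pytest.raises(ValueError):
            age_prior(50, models, {d: 0.0 for d in models})


class TestGroupTests:
    def test_identical_groups_uninformative(self):
        g = list(range(30))
        res = group_tests({"a": g, "b": g}, SignificanceConfig())
        pw = res.pairwise_p.loc["a", "b"]
        assert res.pvalue > 0.9
        assert np.isnan(pw) or pw > 0.99

    def test_small_separated_groups_exact_permutation_p(self):
        # all 20 assignments of {1,2,3}|{101,102,103}: the observed split is
        # one of the two extremes, so the exact two-sided p is 2/20 = 0.1
        res = group_tests({"lo": [1, 2, 3], "hi": [101, 102, 103]},
                          SignificanceConfig(alpha_omnibus=0.2))
        assert res.pairwise_p.loc["lo", "hi"] == pytest.approx(0.1)
        assert not res.significant.loc["lo", "hi"]

    def test_omnibus_matches_bruteforce_ranks(self):
        groups = {"a": [1.0, 5.0, 8.0], "b": [2.0, 9.0, 11.0], "c": [12.0, 14.0, 3.0]}
        values = np.concatenate(list(groups.values()))
        ranks = stats.rankdata(values)
        n = values.size
        idx = 0
        h = 0.0
        for g in groups.values():
            r = ranks[idx : idx + len(g)]
            idx += len(g)
            h += r.sum() ** 2 / len(g)
        h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
        res = group_tests(groups)
        assert res.statistic == pytest.approx(h, abs=1e-9)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            group_tests({"a": [1.0], "b": [1.0, 2.0]})


class TestBuildProfile:
    def test_counts_sum_over_cohorts(self):
        from tests.test_annotations import make_annotation

        anns = [
            make_annotation(source_id="a",
                            phenotypes=[{"term_id": "HP:0001337", "n_present": 10,
                                         "n_assessed": 20}]),
            make_annotation(source_id="b", n_cases=40,
                            phenotypes=[{"term_id": "HP:0001337", "n_present": 5,
                                         "n_assessed": 30}]),
        ]
        profile = build_profile(anns, "PD")
        assert profile.phenotype_table["HP:0001337"] == (15, 50)

    def test_unassessed_cohort_contributes_nothing(self):
        from tests.test_annotations import make_annotation

        anns = [
            make_annotation(source_id="a",
                            phenotypes=[{"term_id": "HP:0001337", "n_present": 10,
                                         "n_assessed": 20}]),
            make_annotation(source_id="b", phenotypes=[]),
        ]
        assert build_profile(anns, "PD").phenotype_table["HP:0001337"] == (10, 20)

    def test_no_cohorts_for_disease(self):
        from tests.test_annotations import make_annotation

        with pytest.raises(ValueError):
            build_profile([make_annotation()], "MSA")

    def test_propagation_aggregates_to_ancestors(self, graph):
        from tests.test_annotations import make_annotation

        anns = [make_annotation(phenotypes=[
            {"term_id": "HP:0002322", "n_present": 30, "n_assessed": 80},
            {"term_id": "HP:0002174", "n_present": 10, "n_assessed": 80},
        ])]
        profile = build_profile(anns, "PD", graph=graph, propagate=True)
        # conservative max mode: parent "tremor" gets the larger child count
        assert profile.phenotype_table["HP:0001337"] == (30, 80)

    def test_frequency_recovery_within_binomial_ci(self, graph):
        cfg = default_config(seed=5, n_studies=60)
        annotations, _ = simulate_corpus(cfg)
        profile = build_profile(annotations, "PD", graph=graph)
        truth = cfg.diseases["PD"].phenotype_freqs["HP:0002322"]
        k, n = profile.phenotype_table["HP:0002322"]
        lo, hi = clopper_pearson(k, n, 0.99)
        assert lo <= truth <= hi
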