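"""The diagnostic calculator: odds machinery, posteriors, screening, inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaphen.aggregation import DiseaseProfile
from metaphen.bayes import (
    DiagnosticQuery,
    ExternalTest,
    Finding,
    next_best_observation,
    odds_to_prob,
    posterior,
    prob_to_odds,
    screening_projection,
    sequential_update,
)
from metaphen.likelihood import LrConfig


def world(freqs, n=10**6):
    """Profiles with exact phenotype frequencies (huge denominators)."""
    return {
        d: DiseaseProfile(
            disease=d,
            phenotype_table={t: (int(round(f * n)), n) for t, f in terms.items()},
            n_cases=n,
        )
        for d, terms in freqs.items()
    }


def enumeration_bayes(priors, freqs, findings):
    """Exact posterior over diseases for a set of binary findings,
    by direct evaluation of the joint Bernoulli likelihood."""
    scores = {}
    for d, prior in priors.items():
        like = prior
        for term, status in findings:
            p = freqs[d][term]
            like *= p if status == "present" else 1 - p
        scores[d] = like
    total = sum(scores.values())
    return {d: s / total for d, s in scores.items()}


class TestOddsConversions:
    def test_worked_example_anchors(self):
        assert round(odds_to_prob(29.19), 2) == 0.97
        assert round(odds_to_prob(1.36), 2) == 0.58
        assert round(odds_to_prob(2.76), 2) == 0.73

    def test_even_odds(self):
        assert odds_to_prob(1) == 0.5
        assert prob_to_odds(0.5) == 1

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=1e-9, max_value=1 - 1e-9))
    def test_round_trip_identity(self, p):
        assert odds_to_prob(prob_to_odds(p)) == pytest.approx(p, abs=1e-12)

    def test_degenerate_probabilities_rejected(self):
        for p in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                prob_to_odds(p)
        with pytest.raises(ValueError):
            odds_to_prob(-0.5)


class TestPosterior:
    two_disease = {
        "PD": {"T:a": 0.7, "T:b": 0.2, "T:c": 0.5},
        "MSA": {"T:a": 0.3, "T:b": 0.6, "T:c": 0.5},
    }

    def test_uninformative_findings_return_prior(self):
        freqs = {"PD": {"T:a": 0.4}, "MSA": {"T:a": 0.4}}
        q = DiagnosticQuery(findings=(Finding("T:a"),), differential=("PD", "MSA"),
                            prior_override={"PD": 0.7, "MSA": 0.3})
        r = posterior(q, world(freqs))
        assert r.probability["PD"] == pytest.approx(0.7, abs=1e-9)
        assert r.posterior["PD"] == pytest.approx(0.7, abs=1e-9)

    def test_invariant_to_finding_order(self):
        q1 = DiagnosticQuery(findings=(Finding("T:a"), Finding("T:b", "absent")),
                             differential=("PD", "MSA"))
        q2 = DiagnosticQuery(findings=q1.findings[::-1], differential=("PD", "MSA"))
        w = world(self.two_disease)
        r1, r2 = posterior(q1, w), posterior(q2, w)
        assert r1.post_test_odds == pytest.approx(r2.post_test_odds)
        assert r1.posterior == pytest.approx(r2.posterior)

    def test_two_disease_world_equals_enumeration_bayes(self):
        priors = {"PD": 0.6, "MSA": 0.4}
        findings = [("T:a", "present"), ("T:b", "absent"), ("T:c", "present")]
        q = DiagnosticQuery(
            findings=tuple(Finding(t, s) for t, s in findings),
            differential=("PD", "MSA"), prior_override=priors,
        )
        r = posterior(q, world(self.two_disease))
        expected = enumeration_bayes(priors, self.two_disease, findings)
        for d in priors:
            assert r.posterior[d] == pytest.approx(expected[d], abs=1e-9)
            # with two diseases the one-vs-rest odds view is exact Bayes too
            assert r.probability[d] == pytest.approx(expected[d], abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_three_disease_world_equals_enumeration_bayes(self, seed):
        rng = np.random.default_rng(seed)
        terms = [f"T:{i}" for i in range(6)]
        freqs = {
            d: {t: float(np.round(rng.uniform(0.05, 0.95), 6)) for t in terms}
            for d in ("PD", "MSA", "DLB")
        }
        priors = {"PD": 0.5, "MSA": 0.3, "DLB": 0.2}
        findings = [
            (t, "present" if rng.random() < 0.5 else "absent") for t in terms
        ]
        q = DiagnosticQuery(
            findings=tuple(Finding(t, s) for t, s in findings),
            differential=("PD", "MSA", "DLB"), prior_override=priors,
        )
        r = posterior(q, world(freqs))
        expected = enumeration_bayes(priors, freqs, findings)
        for d in priors:
            assert r.posterior[d] == pytest.approx(expected[d], abs=1e-9)

    def test_normalised_posterior_sums_to_one_but_odds_view_need_not(self):
        q = DiagnosticQuery(findings=(Finding("T:a"),),
                            differential=("PD", "MSA"))
        r = posterior(q, world(self.two_disease))
        assert sum(r.posterior.values()) == pytest.approx(1.0)

    def test_monotone_in_finding_frequency(self):
        base = 0.3
        probs = []
        for f_pd in (0.3, 0.5, 0.7, 0.9):
            freqs = {"PD": {"T:a": f_pd}, "MSA": {"T:a": base}}
            q = DiagnosticQuery(findings=(Finding("T:a"),), differential=("PD", "MSA"))
            probs.append(posterior(q, world(freqs)).probability["PD"])
        assert probs == sorted(probs)

    def test_disease_missing_assessment_is_dropped_with_reason(self, profiles):
        # RBD has never been assessed in the generated CBD literature
        q = DiagnosticQuery(findings=(Finding("HP:0033696"),))
        r = posterior(q, profiles)
        assert "CBD" not in r.differential
        assert "HP:0033696" in r.dropped["CBD"]

    def test_external_test_shifts_towards_validated_side(self, profiles):
        q0 = DiagnosticQuery(findings=(Finding("HP:0002322"),))
        nflc = ExternalTest("NFLC", 0.86, 0.85, result="positive",
                            applies_to=frozenset({"MSA", "PSP"}))
        q1 = DiagnosticQuery(findings=(Finding("HP:0002322"),),
                             external_tests=(nflc,))
        r0, r1 = posterior(q0, profiles), posterior(q1, profiles)
        assert r1.probability["MSA"] > r0.probability["MSA"]
        assert r1.probability["PD"] < r0.probability["PD"]

    def test_pathognomonic_finding_excluded_and_flagged(self):
        freqs = {"PD": {"T:a": 0.5}, "MSA": {"T:a": 0.0}}
        q = DiagnosticQuery(findings=(Finding("T:a"),), differential=("PD", "MSA"))
        r = posterior(q, world(freqs))
        assert any(d == "PD" for d, _, _ in r.excluded)
        capped = posterior(q, world(freqs), pathognomonic_policy="cap")
        assert capped.lr_product["PD"] == pytest.approx(1e3)

    def test_pairwise_mode_reports_contrast_products(self):
        q = DiagnosticQuery(findings=(Finding("T:a"),), differential=("PD", "MSA"))
        r = posterior(q, world(self.two_disease), mode="pairwise")
        pw = r.pairwise[("PD", "MSA")]
        assert pw["per_finding"]["T:a"] == pytest.approx(0.7 / 0.3)
        assert pw["product"] == pytest.approx(0.7 / 0.3)

    def test_duplicate_finding_rejected(self):
        with pytest.raises(ValueError):
            DiagnosticQuery(findings=(Finding("T:a"), Finding("T:a", "absent")))


class TestSequentialUpdate:
    def test_update_equals_recomputation(self):
        w = world(TestPosterior.two_disease)
        q = DiagnosticQuery(findings=(Finding("T:a"),), differential=("PD", "MSA"))
        r = posterior(q, w)
        updated = sequential_update(r, finding=Finding("T:b", "absent"))
        full = posterior(
            DiagnosticQuery(findings=(Finding("T:a"), Finding("T:b", "absent")),
                            differential=("PD", "MSA")), w)
        assert updated.post_test_odds == pytest.approx(full.post_test_odds)
        assert updated.posterior == pytest.approx(full.posterior)

    def test_uninformative_update_leaves_result_unchanged(self):
        freqs = {"PD": {"T:a": 0.7, "T:e": 0.4}, "MSA": {"T:a": 0.3, "T:e": 0.4}}
        w = world(freqs)
        q = DiagnosticQuery(findings=(Finding("T:a"),), differential=("PD", "MSA"))
        r = posterior(q, w)
        updated = sequential_update(r, finding=Finding("T:e"))
        for d in ("PD", "MSA"):
            assert updated.post_test_odds[d] == pytest.approx(
                r.post_test_odds[d], rel=1e-9)

    def test_adding_then_dividing_out_restores_odds(self):
        w = world(TestPosterior.two_disease)
        q = DiagnosticQuery(findings=(Finding("T:a"),), differential=("PD", "MSA"))
        r = posterior(q, w)
        updated = sequential_update(r, finding=Finding("T:b"))
        for d in ("PD", "MSA"):
            lr = dict(updated.lr_details[d])["T:b"]
            assert updated.post_test_odds[d] / lr == pytest.approx(
                r.post_test_odds[d], abs=1e-12)

    def test_duplicate_evidence_rejected(self):
        w = world(TestPosterior.two_disease)
        r = posterior(DiagnosticQuery(findings=(Finding("T:a"),),
                                      differential=("PD", "MSA")), w)
        with pytest.raises(ValueError):
            sequential_update(r, finding=Finding("T:a"))


class TestScreening:
    def test_anosmia_rtquic_worked_example(self):
        proj = screening_projection(10000, 0.1, 0.98, 0.953)
        assert proj.TP == pytest.approx(980)
        assert proj.FP == pytest.approx(423)
        assert proj.ppv == pytest.approx(980 / (980 + 423))

    def test_margins_conserved(self):
        proj = screening_projection(5000, 0.2, 0.9, 0.8)
        assert proj.TP + proj.FN == pytest.approx(5000 * 0.2)
        assert proj.TN + proj.FP == pytest.approx(5000 * 0.8)

    def test_ppv_approaches_one_at_high_prevalence(self):
        proj = screening_projection(10000, 1 - 1e-9, 0.9, 0.6)
        assert proj.ppv == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            screening_projection(10000, 0.0, 0.9, 0.9)
        with pytest.raises(ValueError):
            screening_projection(0, 0.1, 0.9, 0.9)


class TestNextBestObservation:
    def test_larger_lr_ranks_first(self):
        freqs = {"PD": {"T:a": 0.8, "T:b": 0.5}, "MSA": {"T:a": 0.2, "T:b": 0.4}}
        out = next_best_observation(world(freqs), "PD", "MSA", ["T:a", "T:b"])
        assert [t for t, _ in out] == ["T:a", "T:b"]

    def test_negative_discriminators_rank_by_distance_from_one(self):
        freqs = {"PD": {"T:a": 0.2, "T:b": 0.6}, "MSA": {"T:a": 0.8, "T:b": 0.4}}
        # LR(T:a) = 0.25, LR(T:b) = 1.5: |log| 0.602 > 0.176
        out = next_best_observation(world(freqs), "PD", "MSA", ["T:a", "T:b"])
        assert out[0][0] == "T:a"
        assert out[0][1] == pytest.approx(abs(math.log10(0.25)))

    def test_planted_discriminator_ranks_first(self, profiles):
        # by generator truth the most informative PD-vs-MSA term is stridor
        # (0.01 vs 0.30, |log10 LR| ≈ 1.5 — a strong *negative* discriminator,
        # ahead of pill-rolling tremor's 0.40 vs 0.05, |log10 LR| ≈ 0.9)
        candidates = list(profiles["PD"].phenotype_table)
        out = next_best_observation(profiles, "PD", "MSA", candidates)
        assert out[0][0] == "HP:0010307"

    def test_ineligible_candidates_skipped(self):
        freqs = {"PD": {"T:a": 0.5}, "MSA": {"T:a": 0.0}}
        assert next_best_observation(world(freqs), "PD", "MSA", ["T:a", "T:z"]) == []
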