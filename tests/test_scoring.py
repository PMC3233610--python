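"""Likelihood scoring, argmax selection, accuracy and ROC diagnostics."""

import numpy as np
import pytest
from scipy import integrate, stats

from scfia.ground_truth import GroundTruthEntry
from scfia.scoring import (
    evaluate_accuracy,
    identify_corresponding,
    roc_curves,
    roc_table,
    score_pair,
)
from scfia.stat_models import ARModel, ATModel, CorrespondencePair, ar_density, at_density
from scfia.warp import identity_warp

from conftest import make_interval

AT_MODEL = ATModel(mu=0.0, sigma=4.0)
AR_MODEL = ARModel(k=2.0, theta=0.05)


def _feature(apex, shape=None, width=6.0):
    t = np.arange(apex - width, apex + width + 1.0)
    if shape is None:
        y = 10.0 * np.exp(-0.5 * ((t - apex) / 2.0) ** 2)
    else:
        y = shape(t - apex)
    return make_interval(t, y)


class TestScorePair:
    def test_factorizes_into_the_two_densities(self):
        for at, ar in [(0.0, 0.9), (3.0, 0.5), (-7.0, 0.99)]:
            expected = at_density(AT_MODEL, at) * ar_density(AR_MODEL, ar)
            assert score_pair(at, ar, AT_MODEL, AR_MODEL) == pytest.approx(expected, rel=1e-12)

    def test_maximal_at_mu_and_gamma_mode(self):
        best = score_pair(0.0, 1.0 - (AR_MODEL.k - 1) * AR_MODEL.theta, AT_MODEL, AR_MODEL)
        for at in (-5.0, 2.0, 8.0):
            for ar in (0.2, 0.7, 0.99):
                assert score_pair(at, ar, AT_MODEL, AR_MODEL) <= best + 1e-12

    def test_decreases_away_from_mu(self):
        scores = [score_pair(d, 0.9, AT_MODEL, AR_MODEL) for d in (0.0, 1.0, 3.0, 8.0)]
        assert scores == sorted(scores, reverse=True)

    def test_disabled_ar_model_reduces_to_at_density(self):
        assert score_pair(2.0, 0.3, AT_MODEL, None) == pytest.approx(at_density(AT_MODEL, 2.0))


class TestIdentifyCorresponding:
    def test_single_candidate_always_chosen(self):
        q1 = _feature(100.0)
        cand = _feature(160.0)  # terrible time shift, still the only option
        pair = identify_corresponding(q1, [cand], identity_warp(), AT_MODEL, AR_MODEL)
        assert pair.q2_feature is cand
        assert pair.n_candidates == 1

    def test_dominant_candidate_wins(self):
        q1 = _feature(100.0)
        good = _feature(100.0)
        bad = _feature(100.0 + 5 * AT_MODEL.sigma,
                       shape=lambda d: 10.0 / (1.0 + np.abs(d)))
        pair = identify_corresponding(q1, [bad, good], identity_warp(), AT_MODEL, AR_MODEL)
        assert pair.q2_feature is good

    def test_no_candidates_is_unmatched(self):
        assert identify_corresponding(_feature(100.0), [], identity_warp(),
                                      AT_MODEL, AR_MODEL) is None

    def test_argmax_invariant_under_log_transform(self):
        rng = np.random.default_rng(8)
        q1 = _feature(100.0)
        cands = [_feature(100.0 + rng.normal(0, 6),
                          shape=lambda d, w=rng.uniform(1.5, 3.5): 10 * np.exp(-0.5 * (d / w) ** 2))
                 for _ in range(6)]
        pair = identify_corresponding(q1, cands, identity_warp(), AT_MODEL, AR_MODEL)
        # manual log-score ranking must select the same candidate
        def log_score(c):
            from scfia.stat_models import compute_ar, compute_at
            at = compute_at(q1, c, identity_warp())
            ar = compute_ar(q1, c)
            return np.log(at_density(AT_MODEL, at)) + np.log(ar_density(AR_MODEL, ar))
        best = max(cands, key=log_score)
        assert pair.q2_feature is best


def _entry(rt_q2):
    return GroundTruthEntry(sequence="AK", charge=2, mz_mono=500.0,
                            rt_q1=100.0, rt_q2=rt_q2, probability=0.99)


def _pred(apex, n_candidates=1):
    f = _feature(apex)
    return CorrespondencePair(sequence="AK", charge=2, q1_run="Q1", q2_run="Q2",
                              q1_feature=f, q2_feature=f, at=0.0, ar=1.0,
                              score=1.0, n_candidates=n_candidates)


class TestEvaluateAccuracy:
    def test_all_containing_predictions_give_one(self):
        truth = [_entry(100.0), _entry(200.0)]
        preds = [_pred(100.0), _pred(199.0)]
        assert evaluate_accuracy(preds, truth) == 1.0

    def test_ninety_five_of_one_forty_four(self):
        truth = [_entry(100.0)] * 144
        preds = [_pred(100.0)] * 95 + [_pred(500.0)] * 49
        assert evaluate_accuracy(preds, truth) == pytest.approx(95 / 144)

    def test_unmatched_counts_as_error(self):
        truth = [_entry(100.0), _entry(100.0)]
        assert evaluate_accuracy([_pred(100.0), None], truth) == 0.5

    def test_empty_testing_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate_accuracy([], [])

    def test_random_choice_hits_chance_level(self):
        # picking a uniformly random candidate is correct with prob 1/n_i;
        # the exact expectation is mean(1/n_i) over the testing set
        rng = np.random.default_rng(0)
        n_entries = 4000
        correct = 0
        inv_n = []
        for _ in range(n_entries):
            n = int(rng.integers(2, 6))
            inv_n.append(1.0 / n)
            correct += rng.integers(n) == 0  # the true candidate is one of n
        acc = correct / n_entries
        expected = float(np.mean(inv_n))
        se = np.sqrt(expected * (1 - expected) / n_entries)
        assert abs(acc - expected) < 4 * se


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        _, auc = roc_table([10.0, 11.0, 12.0] * 5, [1.0, 2.0, 3.0] * 5)
        assert auc == 1.0

    def test_identical_distributions_give_half(self):
        vals = list(np.random.default_rng(0).normal(size=200))
        _, auc = roc_table(vals, vals)
        assert auc == pytest.approx(0.5, abs=0.01)

    def test_table_sorted_by_fpr(self):
        rng = np.random.default_rng(1)
        df, _ = roc_table(rng.normal(1, 1, 50), rng.normal(0, 1, 50))
        assert (np.diff(df.fpr) >= 0).all()

    def test_three_statistics_produced(self):
        rng = np.random.default_rng(2)
        curves = roc_curves(rng.normal(0, 4, 100), rng.uniform(0.8, 1.0, 100),
                            rng.normal(15, 4, 100), rng.uniform(0.0, 0.9, 100),
                            AT_MODEL, AR_MODEL)
        assert set(curves) == {"at", "ar", "combined"}
        for _, auc in curves.values():
            assert 0.0 <= auc <= 1.0

    def test_empirical_auc_matches_quadrature_oracle(self):
        # positives AT ~ N(0, 5), negatives AT ~ N(15, 5); ranking by the
        # N(0,5) density is equivalent to ranking by -|at|, so
        # AUC = P(|X+| < |X-|), computable by numeric integration
        mu_n, sigma = 15.0, 5.0
        model = ATModel(mu=0.0, sigma=sigma)
        rng = np.random.default_rng(3)
        n = 2000
        pos = at_density(model, rng.normal(0.0, sigma, n))
        neg = at_density(model, rng.normal(mu_n, sigma, n))
        _, auc = roc_table(pos, neg)

        def p_neg_further(x):
            # P(|X-| > |x|) for X- ~ N(mu_n, sigma)
            a = abs(x)
            return 1.0 - (stats.norm.cdf(a, mu_n, sigma) - stats.norm.cdf(-a, mu_n, sigma))

        oracle, _ = integrate.quad(
            lambda x: p_neg_further(x) * stats.norm.pdf(x, 0.0, sigma), -np.inf, np.inf)
        assert auc == pytest.approx(oracle, abs=0.02)
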