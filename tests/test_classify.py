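"""Naive-Bayes training, scoring, evaluation schemes, independence tests."""

import numpy as np
import pytest

from chronosig.classify import (
    AccountFeatures,
    ClassModel,
    account_score,
    classify_account,
    correlation_pair,
    independence_tests,
    loocv,
    shuffled_baseline,
    split_evaluate,
    train,
)
from chronosig.density import HourDensity
from chronosig.events import EventStream, TweetEvent


def _account(aid, label, delays, hours):
    delays = np.asarray(delays, float)
    hours = np.asarray(hours)
    return AccountFeatures(aid, label, delays, hours[: len(delays)], hours)


def _stream(aid, label, gap, n=30, start=0):
    events = [TweetEvent(aid, start + int(i * gap), 0) for i in range(n)]
    return EventStream(aid, label, events)


class TestTraining:
    def test_disjoint_delay_ranges_give_disjoint_mass(self):
        a = [_account(f"a{i}", "personal", [10 + j for j in range(20)],
                      list(range(21))) for i in range(2)]
        b = [_account(f"b{i}", "managed", [100_000 + 50 * j for j in range(20)],
                      list(range(21))) for i in range(2)]
        model = train(a + b, mode="itd")
        da = model.delay_densities["personal"]
        db = model.delay_densities["managed"]
        assert np.sum((da.raw_density > 0) & (db.raw_density > 0)) == 0

    def test_tt_mode_ignores_delays(self, rng):
        hours = list(rng.integers(0, 24, 30))
        a1 = _account("a", "personal", rng.uniform(10, 100, 29), hours)
        a2 = _account("a", "personal", rng.uniform(1000, 5000, 29), hours)
        b = _account("b", "managed", rng.uniform(10, 100, 29),
                     list(rng.integers(0, 24, 30)))
        m1 = train([a1, b], mode="tt")
        m2 = train([a2, b], mode="tt")
        probe = _account("p", "unlabelled", rng.uniform(10, 100, 10),
                         list(rng.integers(0, 24, 11)))
        assert account_score(m1, probe) == account_score(m2, probe)

    def test_ji_scores_sum_marginal_logs(self, rng):
        cohort = [_account(f"{c}{i}", c, rng.uniform(lo, hi, 40),
                           rng.integers(0, 24, 41))
                  for c, lo, hi in (("personal", 10, 100), ("managed", 500, 5000))
                  for i in range(2)]
        model = train(cohort, mode="ji")
        probe = cohort[0]
        from chronosig.density import density_at
        for cls in model.classes:
            expected = np.sum(
                np.log(density_at(model.delay_densities[cls], probe.delays))
                + np.log(model.hour_densities[cls].mass[probe.preceding_hours])
            )
            assert account_score(model, probe)[cls] == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            train([_account("a", "personal", [10.0], [1, 2])])


class TestDecisionRule:
    def _tt_model(self, mass_a, mass_b, priors=(0.5, 0.5)):
        mk = lambda m: HourDensity(mass=np.asarray(m), n_samples=100)
        return ClassModel(
            classes=("personal", "managed"), mode="tt",
            priors=np.asarray(priors),
            hour_densities={"personal": mk(mass_a), "managed": mk(mass_b)},
        )

    @staticmethod
    def _masses(p0):
        m = np.full(24, (1 - p0) / 23)
        m[0] = p0
        return m

    def test_equal_scores_tie_break_to_first_class(self):
        model = self._tt_model(self._masses(0.5), self._masses(0.5))
        out = classify_account(model, _account("x", "unlabelled", [], [0]))
        assert out.predicted == "personal"

    def test_prior_flips_decision_when_gap_below_log_odds(self):
        # single event at hour 0: score gap = ln(0.6/0.3) = ln 2 < ln 9
        probe = _account("x", "unlabelled", [], [0])
        flat = self._tt_model(self._masses(0.6), self._masses(0.3))
        assert classify_account(flat, probe).predicted == "personal"
        tilted = self._tt_model(self._masses(0.6), self._masses(0.3),
                                priors=(0.1, 0.9))
        assert classify_account(tilted, probe).predicted == "managed"
        # gap ln(0.9/0.05) = ln 18 > ln 9: prior cannot flip it
        wide = self._tt_model(self._masses(0.9), self._masses(0.05),
                              priors=(0.1, 0.9))
        assert classify_account(wide, probe).predicted == "personal"

    def test_floor_region_scores_below_dense_region(self, rng):
        a = [_account(f"a{i}", "personal", rng.uniform(10, 100, 30),
                      rng.integers(0, 24, 31)) for i in range(2)]
        b = [_account(f"b{i}", "managed", rng.uniform(10_000, 100_000, 30),
                      rng.integers(0, 24, 31)) for i in range(2)]
        model = train(a + b, mode="itd")
        probe = _account("p", "unlabelled", rng.uniform(10_000, 100_000, 10),
                         rng.integers(0, 24, 11))
        scores = account_score(model, probe)
        assert scores["managed"] > scores["personal"]

    def test_well_separated_account_recovered(self, default_specs, small_cohort):
        model = train(small_cohort[1:], mode="ji")
        out = classify_account(model, small_cohort[0])
        assert out.predicted == small_cohort[0].label


class TestEvaluation:
    def test_loocv_on_identical_accounts_is_deterministic(self):
        # same event stream under two labels: every score ties, every
        # prediction falls to the first class in model order
        streams = [_stream(f"p{i}", "personal", 60) for i in range(3)]
        streams += [_stream(f"m{i}", "managed", 60) for i in range(3)]
        report = loocv(streams, mode="itd")
        assert report.accuracy == pytest.approx(0.5)
        assert report.confusion[:, 0].sum() == 6  # everything -> personal

    def test_loocv_requires_two_accounts_per_class(self):
        streams = [_stream("p0", "personal", 60), _stream("p1", "personal", 61),
                   _stream("m0", "managed", 60)]
        with pytest.raises(ValueError, match="2 accounts"):
            loocv(streams, mode="itd")

    def test_split_reproducible_and_balanced(self, small_cohort):
        r1 = split_evaluate(small_cohort, mode="tt", train_fraction=0.5,
                            n_repeats=1, seed=9)
        r2 = split_evaluate(small_cohort, mode="tt", train_fraction=0.5,
                            n_repeats=1, seed=9)
        assert r1.per_repeat_accuracy == r2.per_repeat_accuracy

    def test_split_two_accounts_gives_one_each(self):
        streams = [_stream("p0", "personal", 60), _stream("p1", "personal", 3600),
                   _stream("m0", "managed", 120), _stream("m1", "managed", 7200)]
        report = split_evaluate(streams, mode="itd", train_fraction=0.5,
                                n_repeats=2, seed=0)
        # one test account per class per repeat
        assert report.confusion.sum() == 2 * 2

    def test_invalid_fraction_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            split_evaluate(small_cohort, train_fraction=1.0, seed=0)

    def test_identity_shuffle_equals_resubstitution(self, small_cohort):
        baseline = shuffled_baseline(small_cohort, mode="ji", n_repeats=1,
                                     seed=0, _identity=True)
        model = train(small_cohort, mode="ji")
        resub = np.mean([classify_account(model, s).predicted == s.label
                         for s in small_cohort])
        assert baseline.mean_accuracy == pytest.approx(resub)


class TestIndependence:
    def test_independent_pairs_have_near_zero_correlation(self, rng):
        delays = 10 ** rng.uniform(0.5, 5, 10_000)
        hours = rng.integers(0, 24, 10_000)
        res = correlation_pair(delays, hours)
        assert abs(res["pearson_r"]) < 0.05
        assert abs(res["kendall_tau"]) < 0.05

    def test_monotone_coupling_gives_unit_tau(self):
        hours = np.arange(24)
        res = correlation_pair(10.0 * 2 ** hours, hours)
        assert res["kendall_tau"] == pytest.approx(1.0)

    def test_linear_anticorrelation(self):
        hours = np.arange(24, dtype=float)
        res = correlation_pair(-hours, hours)
        assert res["pearson_r"] == pytest.approx(-1.0)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_pair([5.0] * 10, list(range(10)))

    def test_per_class_report(self, small_cohort):
        res = independence_tests(small_cohort)
        assert set(res) == {"personal", "managed", "bot"}
        for stats in res.values():
            assert set(stats) == {"pearson_r", "pearson_p", "kendall_tau",
                                  "kendall_p"}
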