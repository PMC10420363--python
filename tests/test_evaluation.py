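import numpy as np
import pytest
from dataclasses import replace

from gaitevents.evaluation import (
    EvaluationConfig,
    MatchResult,
    compare_methods,
    cumulative_detection_curve,
    detection_rate,
    frames_to_ms,
    match_events,
    seed_sensitivity,
    temporal_error_summary,
)
from gaitevents.detector import ModelConfig
from gaitevents.features import make_training_batches
from gaitevents.gait_core import EventType, GaitEvent, Side, Source
from gaitevents.synthetic_gait import PRESET_PROFILES, CohortSpec, simulate_cohort


def ev(frame, etype="IC", side="L", source="TRUTH"):
    return GaitEvent(etype, side, frame, source)


def events(frames, source="MODEL"):
    return [ev(f, source=source) for f in frames]


def brute_force_match(truth, preds, fp_window):
    """All one-to-one matchings within the window: max cardinality, then min
    total |error| (exhaustive recursion oracle)."""

    def rec(ti, used):
        if ti == len(truth):
            return (0, 0.0)
        best = rec(ti + 1, used)  # leave this truth event unmatched
        for pi, p in enumerate(preds):
            err = abs(p - truth[ti])
            if pi not in used and err <= fp_window:
                card, tot = rec(ti + 1, used | {pi})
                cand = (card + 1, tot + err)
                if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                    best = cand
        return best

    return rec(0, frozenset())


class TestFramesToMs:
    @pytest.mark.parametrize(
        "frames,expected", [(1, 6.7), (4, 26.7), (50, 333.3), (0, 0.0)]
    )
    def test_conversions_at_150hz(self, frames, expected):
        assert round(frames_to_ms(frames, 150.0), 1) == expected

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            frames_to_ms(1, 0)


class TestMatchEvents:
    def test_true_positive_with_signed_error(self):
        res = match_events(events([103]), events([100], "TRUTH"))
        (m,) = res.matches
        assert m.outcome == "TP"
        assert m.error_ms == pytest.approx(20.0)
        assert (res.n_tp, res.n_fp, res.n_fn) == (1, 0, 0)

    def test_false_positive_beyond_tolerance(self):
        res = match_events(events([110]), events([100], "TRUTH"))
        (m,) = res.matches
        assert m.outcome == "FP"
        assert abs(m.error_ms) == pytest.approx(66.7, abs=0.05)

    def test_false_negative_when_unpredicted(self):
        res = match_events([], events([100], "TRUTH"))
        assert res.matches[0].outcome == "FN"
        assert (res.n_tp, res.n_fp, res.n_fn) == (0, 0, 1)

    def test_nearest_prediction_wins_other_reported_spurious(self):
        res = match_events(events([97, 104]), events([100], "TRUTH"))
        (m,) = res.matches
        assert m.outcome == "TP" and m.pred_frame == 97
        assert res.spurious == [104]

    def test_far_prediction_is_spurious_not_fp(self):
        res = match_events(events([400]), events([100], "TRUTH"))
        assert res.matches[0].outcome == "FN"
        assert res.spurious == [400]
        assert res.n_fp == 0
        counted = replace_count(res)
        assert counted.n_fp == 1

    def test_mixed_streams_rejected(self):
        with pytest.raises(ValueError, match="streams"):
            match_events([ev(1, side="L"), ev(5, side="R")], [])

    def test_unsorted_stream_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            match_events([], [ev(9), ev(2)])

    def test_matches_brute_force_assignment_on_random_instances(self):
        rng = np.random.default_rng(6)
        cfg = EvaluationConfig()
        for _ in range(300):
            truth = sorted(rng.choice(120, size=int(rng.integers(0, 9)), replace=False))
            preds = sorted(rng.choice(120, size=int(rng.integers(0, 9)), replace=False))
            res = match_events(events(list(preds)), events(list(truth), "TRUTH"), cfg)
            card, total = brute_force_match(list(truth), list(preds), cfg.fp_window)
            assert res.n_matched == card
            assert sum(abs(m.error_frames) for m in res.matches
                       if m.error_frames is not None) == pytest.approx(total)
            assert res.n_tp + res.n_fn + res.n_fp == len(truth)
            assert res.n_matched + len(res.spurious) == len(preds)


def replace_count(res):
    out = MatchResult(res.matches, res.spurious, res.fs, count_spurious_as_fp=True)
    return out


class TestSummaries:
    def test_mae_arithmetic(self):
        res = _result_from_errors([0.0, 6.7, 13.3])
        mae, lo, hi, n = temporal_error_summary(res, n_boot=0)
        assert round(mae, 2) == 6.67
        assert n == 3

    def test_single_error_degenerate_ci(self):
        mae, lo, hi, n = temporal_error_summary(_result_from_errors([5.0]))
        assert (mae, lo, hi, n) == (5.0, 5.0, 5.0, 1)

    def test_bootstrap_ci_contains_mae(self, rng):
        errors = rng.exponential(8.0, size=100)
        mae, lo, hi, _ = temporal_error_summary(_result_from_errors(errors), seed=1)
        assert lo <= mae <= hi
        assert lo < hi

    def test_no_matches_rejected(self):
        with pytest.raises(ValueError):
            temporal_error_summary(MatchResult())

    @pytest.mark.parametrize(
        "tp,fp,fn,expected", [(3, 1, 0, 0.75), (4, 0, 0, 1.0), (0, 0, 5, 0.0)]
    )
    def test_detection_rate(self, tp, fp, fn, expected):
        res = MatchResult(
            matches=[_match("TP", 0.0)] * tp + [_match("FP", 60.0)] * fp
            + [_match("FN")] * fn
        )
        assert detection_rate(res) == expected

    def test_cumulative_curve_from_frame_errors(self):
        res = MatchResult(
            matches=[_match("TP", e * 1000 / 150, e) for e in [0, 1, 1, 3]]
        )
        curve = cumulative_detection_curve(res)
        assert curve == {0: 0.25, 1: 0.75, 2: 0.75, 3: 1.0, 4: 1.0}

    def test_curve_nondecreasing_and_consistent_with_rate(self, rng):
        for _ in range(20):
            matches = []
            for _ in range(int(rng.integers(1, 30))):
                kind = rng.choice(["TP", "FP", "FN"])
                if kind == "FN":
                    matches.append(_match("FN"))
                else:
                    e = int(rng.integers(0, 5)) if kind == "TP" else int(rng.integers(5, 50))
                    matches.append(_match(kind, e * 1000 / 150, e))
            res = MatchResult(matches=matches)
            curve = cumulative_detection_curve(res)
            vals = [curve[w] for w in sorted(curve)]
            assert vals == sorted(vals)
            assert curve[4] == pytest.approx(detection_rate(res))


def _match(outcome, error_ms=None, error_frames=None):
    from gaitevents.evaluation import EventMatch

    if outcome == "FN":
        return EventMatch(truth_frame=0, outcome="FN")
    ef = error_frames if error_frames is not None else error_ms / (1000 / 150)
    return EventMatch(0, outcome, int(ef), float(ef), float(error_ms))


def _result_from_errors(errors):
    return MatchResult(
        matches=[_match("TP" if e <= 26.7 else "FP", float(e)) for e in errors]
    )


class TestCompareMethods:
    def test_identical_samples_report_no_difference(self):
        a = np.arange(1.0, 13.0)
        out = compare_methods(a, a.copy())
        assert out["r"] == 0.0
        assert out["p_corrected"] == 1.0
        assert out["note"] == "no difference"

    def test_bonferroni_triples_p(self, rng):
        a = rng.exponential(5.0, 30)
        b = a + rng.normal(1.0, 0.3, 30)
        out = compare_methods(a, b)
        assert out["p_corrected"] == pytest.approx(min(1.0, out["p"] * 3))

    def test_twelve_pair_sample_matches_rank_arithmetic(self):
        # hand-built paired sample, no ties among |differences|
        a = np.array([3.1, 7.4, 2.2, 9.8, 5.5, 4.1, 8.8, 6.6, 1.9, 10.5, 12.0, 0.7])
        b = np.array([2.0, 9.0, 2.9, 6.0, 5.0, 6.3, 7.1, 6.2, 4.0, 9.1, 8.5, 2.5])
        d = a - b
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        t_plus = ranks[d > 0].sum()
        n = len(d)
        mu = n * (n + 1) / 4
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        z = (t_plus - mu) / sigma
        from scipy.stats import norm

        p = 2 * norm.sf(abs(z))
        out = compare_methods(a, b)
        assert abs(out["z"]) == pytest.approx(abs(z), abs=1e-8)
        assert out["p"] == pytest.approx(p, abs=1e-8)
        assert out["r"] == pytest.approx(abs(z) / np.sqrt(12), abs=1e-8)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_methods(np.arange(6.0), np.arange(7.0))


class TestSeedSensitivity:
    def test_identical_seed_reproduces_and_single_seed_std_zero(self):
        profile = replace(PRESET_PROFILES["HC-heel"], duration_s=3.0)
        ds = simulate_cohort(CohortSpec(profiles=((profile, 3, 2),), seed=5))
        cfg = ModelConfig(etype="IC", n_layers=1, hidden_units=8, dropout=0.0,
                          epochs=2, seed=0)
        batches = make_training_batches(
            ds.trials[:4], EventType.IC, 10, np.random.default_rng(0), 4
        )
        out = seed_sensitivity(cfg, batches, None, ds.trials[4:], seeds=[3])
        assert out["std_ms"] == 0.0
        again = seed_sensitivity(cfg, batches, None, ds.trials[4:], seeds=[3, 3])
        vals = list(again["per_seed_mae_ms"].values())
        assert len(again["per_seed_mae_ms"]) == 1 or vals[0] == vals[1]

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValueError):
            seed_sensitivity(None, [], None, [], seeds=[])
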