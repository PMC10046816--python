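"""SI/VAS trigger detection, window scoring, and feature accumulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gazedys.core import CleanTrial, downsample
from gazedys.features import (
    detect_si_triggers,
    detect_vas_triggers,
    extract_feature,
    score_window,
    segments_intersect,
    y_direction_changes,
)
from gazedys.simulate import ReaderProfile, generate_trial

from .oracles import direction_changes_oracle

STEP_60 = 1000.0 / 60.0


def make_clean(y, x=None, t=None, rate_hz=60.0, group="control"):
    y = np.asarray(y, float)
    n = y.size
    return CleanTrial(
        trial_id="t1", subject_id="s1", group=group, cc="white", rate_hz=rate_hz,
        t=np.arange(n) * (1000.0 / rate_hz) if t is None else np.asarray(t, float),
        x=np.arange(n, dtype=float) if x is None else np.asarray(x, float),
        y=y,
    )


class TestDirectionChanges:
    @pytest.mark.parametrize("y,carry,expected", [
        ([0, 1, 0, 1], 0, (2, 1)),        # up, down, up
        ([0, 1, 2, 3], 0, (0, 1)),        # monotone
        ([0, 1, 1, 0], 0, (1, -1)),       # zero delta inherits "up", then one flip
        ([0, 0, 0], 0, (0, 0)),           # no movement at all
        ([0, 1, 0, 1, 0], 1, (3, -1)),    # entering carry "+": +,-,+,- flips 3x
        ([0, 1, 0, 1, 0], -1, (4, -1)),   # entering carry "-": one more flip
        ([], 0, (0, 0)),
        ([5.0], 1, (0, 1)),               # too short: carry passes through
    ])
    def test_examples(self, y, carry, expected):
        assert y_direction_changes(y, carry) == expected

    def test_bad_carry_rejected(self):
        with pytest.raises(ValueError):
            y_direction_changes([0, 1], 2)

    @given(st.lists(st.integers(-3, 3), max_size=12),
           st.sampled_from([-1, 0, 1]))
    def test_matches_run_length_oracle(self, y, carry):
        assert y_direction_changes(y, carry) == direction_changes_oracle(y, carry)


class TestTriggers:
    def test_monotone_scan_has_no_triggers(self):
        c = make_clean(y=np.linspace(0, 5, 40), x=np.linspace(0, 400, 40))
        assert detect_si_triggers(c).size == 0
        assert detect_vas_triggers(c).size == 0

    def test_short_trial_yields_empty_result(self):
        c = make_clean(y=[0, 1, 2])
        assert detect_si_triggers(c).size == 0
        assert detect_vas_triggers(c).size == 0

    def test_vas_quadruple_examples(self):
        assert detect_vas_triggers(make_clean([0, 1, 0, 1])).tolist() == [3]
        assert detect_vas_triggers(make_clean([0, 1, 2, 1])).size == 0

    def test_planted_crossing_fires_expected_quadruples(self):
        # monotone ramp, then a bow-tie crossing, then monotone again
        x = [0, 1, 2, 10, 20, 15, 15, 30, 31, 32]
        y = [0, 0, 0, 0, 5, 5, -5, 0, 0, 0]
        c = make_clean(y=y, x=x)
        hits = detect_si_triggers(c)
        # brute-force enumeration with the scalar predicate
        expected = [
            i for i in range(3, c.n_points)
            if segments_intersect(
                (x[i - 3], y[i - 3]), (x[i - 2], y[i - 2]),
                (x[i - 1], y[i - 1]), (x[i], y[i]))
        ]
        assert hits.tolist() == expected
        assert len(expected) >= 1

    def test_dyslexic_profile_fires_more_than_control(self):
        """Median trigger counts over 50 seeds separate the group profiles,
        and VAS fires much more often than SI on the same trials."""
        si = {"dyslexic": [], "control": []}
        vas = {"dyslexic": [], "control": []}
        for seed in range(50):
            for group in ("dyslexic", "control"):
                prof = (ReaderProfile(group="dyslexic", p_regress=0.28, y_jitter_px=3.5,
                                      x_jitter_px=2.5, wander_smooth=1.0, p_dropout=0.0)
                        if group == "dyslexic" else
                        ReaderProfile(group="control", p_dropout=0.0))
                rng = np.random.default_rng(1000 + seed)
                tr = generate_trial(prof, "white", rng, lines_per_segment=2, words_per_line=5)
                from gazedys.core import clean_trial
                c = clean_trial(tr)
                si[group].append(detect_si_triggers(c).size)
                vas[group].append(detect_vas_triggers(c).size)
        assert np.median(si["dyslexic"]) > np.median(si["control"])
        assert np.median(vas["dyslexic"]) > np.median(vas["control"])
        assert np.median(vas["dyslexic"]) > np.median(si["dyslexic"])


class TestScoreWindow:
    def test_flat_window_scores_zero(self):
        y = [0, 1, 0, 1] + [1] * 16   # trigger at index 3, then flat
        c = make_clean(y)
        assert score_window(c, 3) == 0

    def test_carry_rule_frozen_values(self):
        # quadruple rises monotonically (carry +1 at its end); the window
        # after the anchor oscillates: deltas +,-,+,- -> 3 flips with carry +.
        y = [0, 2, 4, 6, 7, 6, 7, 6]
        t = np.arange(8) * 60.0      # 60 ms spacing: 4 points fall in 250 ms
        c = make_clean(y, t=t)
        assert score_window(c, 3) == 3
        # same window entered from a falling quadruple (carry -1): one more flip
        y2 = [12, 10, 8, 6, 7, 6, 7, 6]
        c2 = make_clean(y2, t=t)
        assert score_window(c2, 3) == 4

    @pytest.mark.parametrize("rate,expected_span", [(60.0, 15), (30.0, 7)])
    def test_window_spans_quarter_second_of_samples(self, rate, expected_span):
        n = 40
        c = make_clean(np.zeros(n), rate_hz=rate)
        i = 3
        end = np.searchsorted(c.t, c.t[i] + 250.0 + 1e-6, side="right")
        assert end - 1 - i == expected_span

    def test_truncated_window_scores_available_points(self):
        # trigger at index 3, only one point follows before the trial ends;
        # the quadruple [0,1,0,1] ends rising, and the final 1->0 delta flips.
        c = make_clean([0, 1, 0, 1, 0])
        assert score_window(c, 3) == 1

    def test_out_of_range_index(self):
        c = make_clean([0, 1, 0, 1, 0])
        with pytest.raises(ValueError):
            score_window(c, 2)


class TestExtractFeature:
    def test_monotone_trial_totals_zero(self):
        c = make_clean(y=np.linspace(0, 50, 60), x=np.linspace(0, 600, 60))
        for kind in ("SI", "VAS"):
            res = extract_feature(c, kind)
            assert res.total == 0
            assert res.events == ()

    def test_conservation_and_event_order(self):
        rng = np.random.default_rng(3)
        c = make_clean(y=rng.normal(0, 3, 300).cumsum(), x=rng.normal(0, 2, 300).cumsum())
        for kind in ("SI", "VAS"):
            res = extract_feature(c, kind)
            assert res.total == sum(e.contribution for e in res.events)
            idx = [e.index for e in res.events]
            assert idx == sorted(idx)
            for e in res.events:
                assert e.anchor == (c.x[e.index], c.y[e.index])

    def test_suppress_overlap_spaces_windows(self):
        rng = np.random.default_rng(4)
        c = make_clean(y=rng.normal(0, 3, 400).cumsum())
        full = extract_feature(c, "VAS", suppress_overlap=False)
        sparse = extract_feature(c, "VAS", suppress_overlap=True)
        assert 0 < len(sparse.events) < len(full.events)
        times = [e.t for e in sparse.events]
        assert all(b - a > 250.0 for a, b in zip(times, times[1:]))
        assert sparse.total <= full.total

    def test_monotone_growth_under_extension(self):
        rng = np.random.default_rng(6)
        y = rng.normal(0, 3, 500).cumsum()
        x = rng.normal(0, 2, 500).cumsum()
        c_full = make_clean(y=y, x=x)
        for kind in ("SI", "VAS"):
            prev = -1
            for n in (100, 250, 400, 500):
                c = make_clean(y=y[:n], x=x[:n])
                total = extract_feature(c, kind).total
                assert total >= prev
                prev = total
            assert prev == extract_feature(c_full, kind).total

    def test_downsampled_extraction_runs_on_same_trial(self):
        rng = np.random.default_rng(8)
        c = make_clean(y=rng.normal(0, 3, 240).cumsum())
        low = downsample(c, 2)
        res = extract_feature(low, "VAS")
        assert res.rate_hz == 30.0
        assert res.total == sum(e.contribution for e in res.events)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            extract_feature(make_clean([0, 1, 0, 1]), "XYZ")


class TestInvariances:
    @staticmethod
    def _random_trials(n=8):
        out = []
        for seed in range(n):
            rng = np.random.default_rng(2000 + seed)
            prof = ReaderProfile(group="dyslexic", p_regress=0.2, y_jitter_px=3.0,
                                 x_jitter_px=2.0, wander_smooth=1.5, p_dropout=0.01)
            tr = generate_trial(prof, "white", rng, lines_per_segment=2, words_per_line=5)
            from gazedys.core import clean_trial
            out.append(clean_trial(tr))
        return out

    def test_si_triggers_invariant_under_similarity_maps(self):
        rng = np.random.default_rng(99)
        for c in self._random_trials():
            ref = detect_si_triggers(c).tolist()
            theta = rng.uniform(0, 2 * np.pi)
            s = rng.uniform(0.5, 3.0)
            R = s * np.array([[np.cos(theta), -np.sin(theta)],
                              [np.sin(theta), np.cos(theta)]])
            shift = rng.uniform(-500, 500, size=2)
            xy = np.column_stack([c.x, c.y]) @ R.T + shift
            mapped = make_clean(y=xy[:, 1], x=xy[:, 0], t=c.t)
            assert detect_si_triggers(mapped).tolist() == ref

    def test_vas_invariant_under_increasing_y_maps_and_any_x(self):
        rng = np.random.default_rng(100)
        for c in self._random_trials():
            ref_triggers = detect_vas_triggers(c).tolist()
            ref_total = extract_feature(c, "VAS").total
            for f in (lambda y: 2.5 * y - 40.0, lambda y: (y + 50.0) ** 3 / 1e4):
                mapped = make_clean(y=f(c.y), x=rng.uniform(0, 1000, c.n_points), t=c.t)
                assert detect_vas_triggers(mapped).tolist() == ref_triggers
                assert extract_feature(mapped, "VAS").total == ref_total
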