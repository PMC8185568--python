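import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wristfog import (
    AnnotationTrack,
    ImuRecording,
    LABELS,
    WindowConfig,
    build_dataset,
    compute_cohort_scales,
    count_windows,
    label_window,
    normalize,
    segment,
)
from wristfog.windowing import NormalizationScale, load_dataset, save_dataset


def _rec(data, sid="S01", fs=128):
    return ImuRecording(sid, np.asarray(data, dtype=float), fs=fs)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_count(n, window_n, step_n):
    """Enumerate valid start indices."""
    return sum(1 for s in range(0, n + 1, step_n) if s + window_n <= n)


def brute_force_label(window_span, track, config):
    """Sample-level labeling oracle for grid-aligned annotations.

    Labels every sample of the window by the interval containing it,
    then applies the containment / half-window rule on sample counts.
    """
    fs = config.fs
    w0, w1 = window_span
    i0, i1 = int(round(w0 * fs)), int(round(w1 * fs))
    counts = dict.fromkeys(LABELS, 0)
    for i in range(i0, i1):
        t = i / fs
        for s, e, lab in track.intervals:
            if s <= t < e:
                counts[lab] += 1
                break
    full_episode_inside = any(
        lab == "FOG" and s >= w0 and e <= w1 and e > s
        for s, e, lab in track.intervals
    )
    if full_episode_inside or counts["FOG"] >= config.window_n // 2:
        return "FOG"
    return "STOP" if counts["STOP"] > counts["WALK"] else "WALK"


def random_grid_track(rng, total_s, fs=128):
    """Random annotation track with boundaries on the sample grid."""
    n_cuts = rng.integers(1, 8)
    cuts = np.sort(rng.choice(
        np.arange(1, int(total_s * fs)), size=n_cuts, replace=False
    )) / fs
    bounds = [0.0, *cuts.tolist(), float(total_s)]
    labels = rng.choice(LABELS, size=len(bounds) - 1)
    return AnnotationTrack("S01", [
        (bounds[i], bounds[i + 1], labels[i]) for i in range(len(bounds) - 1)
    ])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


class TestCohortScales:
    def test_max_over_recordings(self):
        r1 = _rec(np.full((10, 6), 2.0))
        r2 = _rec(np.full((10, 6), 5.0), "S02")
        scales = compute_cohort_scales([r1, r2])
        np.testing.assert_allclose(scales.scales, 5.0)

    def test_negative_extreme_uses_absolute_value(self, rng):
        data = rng.uniform(-1, 1, (50, 6))
        data[17, 3] = -7.5
        scales = compute_cohort_scales([_rec(data)])
        expected = np.abs(data).max(axis=0)  # max-abs oracle over all samples
        np.testing.assert_allclose(scales.scales, expected)
        assert scales.scales[3] == 7.5

    def test_all_zero_channel_is_error(self, rng):
        data = rng.standard_normal((20, 6))
        data[:, 5] = 0.0
        with pytest.raises(ValueError, match="gz"):
            compute_cohort_scales([_rec(data)])

    def test_empty_cohort_is_error(self):
        with pytest.raises(ValueError):
            compute_cohort_scales([])


class TestNormalize:
    def test_cohort_max_maps_to_one(self, rng):
        data = rng.uniform(-1, 1, (30, 6))
        data[4, 0] = 9.81
        rec = _rec(data)
        scales = compute_cohort_scales([rec])
        out = normalize(rec, scales)
        assert out.samples[4, 0] == 1.0
        assert np.abs(out.samples).max() <= 1.0 + 1e-12

    def test_half_to_even_rounding_at_4_decimals(self):
        scales = NormalizationScale(np.ones(6))
        rec = _rec(np.full((1, 6), 0.123456))
        out = normalize(rec, scales)
        assert out.samples[0, 0] == 0.1235

    def test_sign_preserved(self):
        scales = NormalizationScale(np.full(6, 2.0))
        out = normalize(_rec(np.full((1, 6), -1.0)), scales)
        np.testing.assert_allclose(out.samples, -0.5)

    def test_idempotent_up_to_rounding(self, rng):
        recs = [_rec(rng.standard_normal((200, 6)) * 10, f"S{i}") for i in range(3)]
        scales = compute_cohort_scales(recs)
        once = [normalize(r, scales) for r in recs]
        scales2 = compute_cohort_scales(once)
        twice = [normalize(r, scales2) for r in once]
        for a, b in zip(once, twice):
            assert np.abs(a.samples - b.samples).max() <= 1e-4


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


class TestCountWindows:
    @pytest.mark.parametrize("n,expected", [(384, 1), (383, 0), (1280, 29)])
    def test_known_counts(self, n, expected):
        assert count_windows(n, WindowConfig()) == expected

    @given(
        n=st.integers(0, 5000),
        window_n=st.integers(1, 600),
        step_n=st.integers(1, 600),
    )
    @settings(max_examples=300, derandomize=True)
    def test_matches_enumeration(self, n, window_n, step_n):
        if step_n > window_n:
            return
        cfg = WindowConfig(window_s=window_n, step_s=step_n, fs=1.0)
        assert count_windows(n, cfg) == brute_force_count(n, window_n, step_n)


class TestSegment:
    def test_starts_and_contents(self, rng):
        data = rng.standard_normal((448, 6))
        rec = _rec(data)
        parts = segment(rec, WindowConfig())
        assert [s for s, _ in parts] == [0, 32, 64]
        for start, w in parts:
            np.testing.assert_array_equal(w, data[start:start + 384])

    def test_single_exact_window(self, rng):
        data = rng.standard_normal((384, 6))
        parts = segment(_rec(data), WindowConfig())
        assert len(parts) == 1
        np.testing.assert_array_equal(parts[0][1], data)


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------


class TestLabelWindow:
    CFG = WindowConfig()

    def _track(self, intervals):
        return AnnotationTrack("S01", intervals)

    def test_short_episode_fully_inside_is_fog(self):
        track = self._track([(0, 10.2, "WALK"), (10.2, 10.7, "FOG"),
                             (10.7, 20, "WALK")])
        assert label_window((9.0, 12.0), track, self.CFG) == "FOG"

    def test_partial_overlap_below_half_window_is_not_fog(self):
        track = self._track([(0, 7, "WALK"), (7, 10, "FOG"), (10, 20, "WALK")])
        # overlap 1.0 s < 1.5 s, episode not contained -> majority WALK
        assert label_window((9.0, 12.0), track, self.CFG) == "WALK"

    def test_partial_overlap_at_or_above_half_window_is_fog(self):
        track = self._track([(0, 7, "WALK"), (7, 10.7, "FOG"), (10.7, 20, "WALK")])
        assert label_window((9.0, 12.0), track, self.CFG) == "FOG"  # 1.7 s

    def test_window_inside_stop_is_stop(self):
        track = self._track([(0, 5, "WALK"), (5, 15, "STOP"), (15, 20, "WALK")])
        assert label_window((6.0, 9.0), track, self.CFG) == "STOP"

    def test_stop_walk_tie_breaks_walk(self):
        track = self._track([(0, 10, "STOP"), (10, 20, "WALK")])
        assert label_window((8.5, 11.5), track, self.CFG) == "WALK"

    def test_multiple_short_episodes_sum_to_fog(self):
        # two 0.8 s episodes each crossing a window edge: neither contained,
        # summed in-window overlap 1.6 s >= 1.5 s
        track = self._track([
            (0, 8.2, "WALK"), (8.2, 9.8, "FOG"), (9.8, 11.2, "WALK"),
            (11.2, 12.8, "FOG"), (12.8, 20, "WALK"),
        ])
        assert label_window((9.0, 12.0), track, self.CFG) == "FOG"

    def test_window_outside_coverage_is_error(self):
        track = self._track([(0, 10, "WALK")])
        with pytest.raises(ValueError, match="coverage"):
            label_window((8.0, 11.0), track, self.CFG)

    def test_episode_duration_rule_variant(self):
        cfg = WindowConfig(fog_rule="episode_duration")
        # long episode barely touching the window: episode duration >= 1.5 s
        track = self._track([(0, 11.5, "FOG"), (11.5, 30, "WALK")])
        assert label_window((11.0, 14.0), track, cfg) == "FOG"
        # same geometry under the default in-window rule: overlap 0.5 s -> WALK
        assert label_window((11.0, 14.0), track, self.CFG) == "WALK"

    def test_agrees_with_sample_level_oracle(self):
        cfg = self.CFG
        rng = np.random.default_rng(99)
        total_s = 30.0
        for _ in range(300):
            track = random_grid_track(rng, total_s)
            k = count_windows(int(total_s * cfg.fs), cfg)
            start = int(rng.integers(0, k)) * cfg.step_n
            span = (start / cfg.fs, (start + cfg.window_n) / cfg.fs)
            assert label_window(span, track, cfg) == brute_force_label(
                span, track, cfg
            )


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


class TestBuildDataset:
    def _session(self, rng):
        fs = 128
        track = AnnotationTrack("S01", [
            (0, 12, "WALK"), (12, 14, "FOG"), (14, 22, "WALK"), (22, 30, "STOP"),
        ])
        rec = _rec(rng.standard_normal((30 * fs, 6)), "S01")
        return rec, track

    def test_window_count_and_fog_labels_match_brute_force(self, rng):
        rec, track = self._session(rng)
        cfg = WindowConfig()
        windows, _ = build_dataset([rec], [track], cfg)
        assert len(windows) == 109  # K for N=3840
        for w in windows:
            span = (w.start_index / cfg.fs, (w.start_index + cfg.window_n) / cfg.fs)
            assert w.label == brute_force_label(span, track, cfg)
        assert sum(w.label == "FOG" for w in windows) > 0

    def test_no_fog_intervals_gives_no_fog_windows(self, rng):
        track = AnnotationTrack("S01", [(0, 20, "WALK"), (20, 30, "STOP")])
        rec = _rec(rng.standard_normal((30 * 128, 6)), "S01")
        windows, _ = build_dataset([rec], [track])
        assert all(w.label != "FOG" for w in windows)

    def test_subject_partition(self, rng):
        recs = [_rec(rng.standard_normal((10 * 128, 6)), s) for s in ("A", "B")]
        tracks = [AnnotationTrack(s, [(0, 10, "WALK")]) for s in ("A", "B")]
        windows, _ = build_dataset(recs, tracks)
        per_sub = {s: sum(w.subject_id == s for w in windows) for s in ("A", "B")}
        assert per_sub["A"] == per_sub["B"] == count_windows(1280, WindowConfig())

    def test_subject_mismatch_is_error(self, rng):
        rec = _rec(rng.standard_normal((1280, 6)), "A")
        track = AnnotationTrack("B", [(0, 10, "WALK")])
        with pytest.raises(ValueError, match="A"):
            build_dataset([rec], [track])

    def test_values_normalized_into_unit_interval(self, rng):
        rec, track = self._session(rng)
        windows, _ = build_dataset([rec], [track])
        stacked = np.stack([w.data for w in windows])
        assert np.abs(stacked).max() <= 1.0 + 1e-12

    def test_save_load_round_trip(self, rng, tmp_path):
        rec, track = self._session(rng)
        windows, _ = build_dataset([rec], [track])
        save_dataset(windows, tmp_path / "m.csv", tmp_path / "w.npz")
        back = load_dataset(tmp_path / "m.csv", tmp_path / "w.npz")
        assert len(back) == len(windows)
        assert [w.label for w in back] == [w.label for w in windows]
        np.testing.assert_array_equal(back[0].data, windows[0].data)
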