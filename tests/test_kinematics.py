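"""Landmark QC, midline reconstruction and kinematic variable extraction."""

import numpy as np
import pytest

from wakekin import SwimmerSpec, generate_swimmer
from wakekin.kinematics import (
    InsufficientBeatsError,
    WavelengthUndeterminedError,
    analyze_landmarks,
    body_wavelength,
    lateral_excursion,
    qc_landmarks,
    reconstruct_midline,
    segment_tailbeats,
    tailbeat_frequency,
)
from wakekin.landmarks import BODY_PARTS

from tests.conftest import straight_fish_midline, table_from_midline

L = 0.074


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class TestQC:
    def _table_with_bad(self, frac, seed=0, n_frames=200):
        """Steadily translating fish with a chosen fraction of dropouts."""
        rng = np.random.default_rng(seed)
        table = table_from_midline(
            straight_fish_midline(offset_fn=lambda t: (0.05 * t, 0.0)),
            n_frames=n_frames,
        )
        n_bad = int(round(frac * len(BODY_PARTS) * n_frames))
        flat = [(p, j) for p in BODY_PARTS for j in range(n_frames)]
        for k in rng.choice(len(flat), n_bad, replace=False):
            p, j = flat[k]
            table.data.iloc[j, table.data.columns.get_loc(("wakekin", p, "likelihood"))] = 0.2
        return table

    def test_below_threshold_not_flagged(self):
        _, report = qc_landmarks(self._table_with_bad(0.08))
        assert report.overall_bad_fraction == pytest.approx(0.08, abs=0.01)
        assert not report.needs_manual_review

    def test_above_ten_percent_flagged(self):
        clean, report = qc_landmarks(self._table_with_bad(0.12))
        assert report.needs_manual_review
        assert clean.meta["needs_manual_review"]

    def test_single_bad_frame_interpolated_to_midpoint(self):
        # linear motion: the interpolated point must be the midpoint
        table = table_from_midline(
            straight_fish_midline(offset_fn=lambda t: (0.05 * t, 0.03 * t)),
            n_frames=60,
        )
        col = table.data.columns.get_loc(("wakekin", "snout", "likelihood"))
        table.data.iloc[30, col] = 0.1
        before = table.xy("snout")
        clean, report = qc_landmarks(table)
        after = clean.xy("snout")
        expected = 0.5 * (before[29] + before[31])
        assert np.allclose(after[30], expected, atol=1e-12)
        assert report.interpolated["snout"] == 1

    def test_isolated_jump_detected_and_repaired(self):
        table = table_from_midline(
            straight_fish_midline(offset_fn=lambda t: (0.05 * t, 0.0)), n_frames=60
        )
        xcol = table.data.columns.get_loc(("wakekin", "tail_tip", "x"))
        good = table.data.iloc[25, xcol]
        table.data.iloc[25, xcol] = good + 0.5 * L          # gross outlier
        clean, report = qc_landmarks(table)
        assert report.bad_fraction["tail_tip"] > 0
        assert abs(clean.data.iloc[25, xcol] - good) < 1e-6

    def test_all_bad_part_refused(self):
        table = table_from_midline(straight_fish_midline(), n_frames=30)
        col = table.data.columns.get_loc(("wakekin", "left_3", "likelihood"))
        table.data.iloc[:, col] = 0.0
        with pytest.raises(ValueError, match="left_3"):
            qc_landmarks(table)


# ---------------------------------------------------------------------------
# midline
# ---------------------------------------------------------------------------

class TestMidline:
    def test_symmetric_outline_gives_straight_midline(self):
        table = table_from_midline(straight_fish_midline(), n_frames=120)
        series = reconstruct_midline(table)
        dev = np.abs(series.points[..., 1])
        assert dev.max() < 1e-6 * series.body_length

    def test_equal_arc_spacing(self):
        spec = SwimmerSpec(tailbeat_frequency=3.0, amplitude_tail=0.15, seed=0)
        table, _ = generate_swimmer(spec, 1.5)
        clean, _ = qc_landmarks(table)
        series = reconstruct_midline(clean)
        seg = np.linalg.norm(np.diff(series.points, axis=1), axis=2)
        cv = seg.std(axis=1) / seg.mean(axis=1)
        assert cv.max() < 0.01

    def test_matches_generator_ground_truth(self):
        spec = SwimmerSpec(tailbeat_frequency=3.0, amplitude_tail=0.15, seed=1)
        table, truth = generate_swimmer(spec, 1.5)
        series = reconstruct_midline(table)
        rms = np.sqrt(
            np.mean((series.points - truth.midline[series.frame_indices]) ** 2)
        )
        assert rms < 0.005 * truth.body_length

    def test_crossed_pairs_drop_frame(self):
        table = table_from_midline(straight_fish_midline(), n_frames=40)
        # swap left_2/right_2 with left_5/right_5 in one frame: midpoint
        # order along the body axis becomes non-monotonic
        for side in ("left", "right"):
            a = table.data[("wakekin", f"{side}_2", "x")].copy()
            b = table.data[("wakekin", f"{side}_5", "x")].copy()
            table.data.loc[20, ("wakekin", f"{side}_2", "x")] = b[20]
            table.data.loc[20, ("wakekin", f"{side}_5", "x")] = a[20]
        series = reconstruct_midline(table)
        assert 20 in series.dropped_frames
        assert series.points.shape[0] == 39


# ---------------------------------------------------------------------------
# excursion
# ---------------------------------------------------------------------------

class TestLateralExcursion:
    def test_steady_axial_translation_near_zero(self):
        table = table_from_midline(
            straight_fish_midline(offset_fn=lambda t: (0.08 * t, 0.0)), n_frames=150
        )
        series = reconstruct_midline(table)
        for s in (0.0, 0.5, 1.0):
            exc = lateral_excursion(series, s)
            assert np.abs(exc).max() < 1e-9

    def test_rigid_lateral_oscillation_amplitude(self):
        table = table_from_midline(
            straight_fish_midline(
                offset_fn=lambda t: (0.0, 0.1 * L * np.sin(2 * np.pi * 2 * t))
            ),
            n_frames=150,
        )
        series = reconstruct_midline(table)
        for s in (0.0, 0.35, 1.0):
            exc = lateral_excursion(series, s)
            amp = 0.5 * (exc.max() - exc.min())
            assert amp == pytest.approx(0.1, rel=0.01)

    def test_rotation_invariance(self):
        spec = SwimmerSpec(tailbeat_frequency=3.0, seed=3)
        table, _ = generate_swimmer(spec, 1.5)
        exc0 = lateral_excursion(reconstruct_midline(table), 1.0)
        theta = np.deg2rad(30)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        rotated = table.copy()
        for part in BODY_PARTS:
            xy = table.xy(part) @ rot.T
            rotated.data[("wakekin", part, "x")] = xy[:, 0]
            rotated.data[("wakekin", part, "y")] = xy[:, 1]
        exc1 = lateral_excursion(reconstruct_midline(rotated), 1.0)
        assert np.allclose(exc1, exc0, atol=1e-9)

    def test_short_window_refused(self):
        table = table_from_midline(straight_fish_midline(), n_frames=50)
        series = reconstruct_midline(table)
        with pytest.raises(ValueError, match="1 s"):
            lateral_excursion(series, 0.5)


class TestGlobalInvariance:
    def test_translation_rotation_scale_leave_outputs(self):
        spec = SwimmerSpec(tailbeat_frequency=3.0, amplitude_tail=0.15, seed=5)
        table, _ = generate_swimmer(spec, 2.0)
        base, _, _ = analyze_landmarks(table)
        theta = np.deg2rad(73.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        scale = 250.0                     # e.g. meters -> pixels
        moved = table.copy()
        moved.scale = table.scale / scale
        for part in BODY_PARTS:
            xy = (table.xy(part) @ rot.T + np.array([1.7, -2.2])) * scale
            moved.data[("wakekin", part, "x")] = xy[:, 0]
            moved.data[("wakekin", part, "y")] = xy[:, 1]
        transformed, _, _ = analyze_landmarks(moved)
        for a, b in zip(base, transformed):
            assert b.tailbeat_frequency == pytest.approx(
                a.tailbeat_frequency, rel=1e-9
            )
            assert b.body_wavelength == pytest.approx(a.body_wavelength, rel=1e-6)
            assert b.amplitude_tail == pytest.approx(a.amplitude_tail, rel=1e-6)
            assert b.amplitude_snout == pytest.approx(a.amplitude_snout, rel=1e-6)


# ---------------------------------------------------------------------------
# frequency, segmentation, wavelength, amplitudes
# ---------------------------------------------------------------------------

class TestTailbeatFrequency:
    def test_pure_tone(self):
        t = np.arange(0, 2, 0.01)
        res = tailbeat_frequency(np.sin(2 * np.pi * 3 * t), 100.0)
        assert res.frequency == pytest.approx(3.0, rel=0.02)

    def test_noisy_tone_across_seeds(self):
        t = np.arange(0, 3, 0.01)
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sig = 0.9 * np.sin(2 * np.pi * 2 * t) + 0.05 * rng.normal(size=t.size)
            res = tailbeat_frequency(sig, 100.0)
            errs.append(abs(res.frequency - 2.0) / 2.0)
        assert np.median(errs) < 0.05

    def test_monotone_series_refused(self):
        with pytest.raises(InsufficientBeatsError):
            tailbeat_frequency(np.linspace(0, 1, 300), 100.0)


class TestSegmentTailbeats:
    def _extrema_times(self, n_beats, f=2.0):
        # alternating extrema at half-period spacing: n_beats full beats
        return np.arange(2 * n_beats + 1) * (0.5 / f)

    def test_sixteen_beats_four_windows(self):
        windows = segment_tailbeats(self._extrema_times(16))
        assert len(windows) == 4
        starts = [w[0] for w in windows]
        ends = [w[1] for w in windows]
        assert starts[1:] == ends[:-1]                 # non-overlapping, abutting

    def test_trailing_beats_dropped(self):
        assert len(segment_tailbeats(self._extrema_times(18))) == 4

    def test_too_few_beats_refused(self):
        with pytest.raises(InsufficientBeatsError):
            segment_tailbeats(self._extrema_times(3))


class TestBodyWavelength:
    def test_traveling_wave_recovered(self):
        spec = SwimmerSpec(
            tailbeat_frequency=3.0, body_wavelength=1.2, amplitude_tail=0.15, seed=0
        )
        table, _ = generate_swimmer(spec, 2.0)
        series = reconstruct_midline(table)
        lam = body_wavelength(series, 3.0)
        assert lam == pytest.approx(1.2, rel=0.03)

    def test_standing_wave_undetermined(self):
        def standing(s, t):
            s = np.asarray(s)
            y = 0.1 * L * np.sin(np.pi * s) * np.sin(2 * np.pi * 3 * t)
            return np.column_stack([s * L, y])

        table = table_from_midline(standing, n_frames=200)
        series = reconstruct_midline(table)
        with pytest.raises(WavelengthUndeterminedError):
            body_wavelength(series, 3.0)

    def test_noisy_wavelength_across_seeds(self):
        errs = []
        for seed in range(10):
            spec = SwimmerSpec(
                tailbeat_frequency=3.0, body_wavelength=0.9, amplitude_tail=0.15,
                landmark_noise_sd=0.002, seed=seed,
            )
            table, _ = generate_swimmer(spec, 2.0)
            series = reconstruct_midline(qc_landmarks(table)[0])
            lam = body_wavelength(series, 3.0)
            errs.append(abs(lam - 0.9) / 0.9)
        assert np.median(errs) < 0.07


class TestAmplitudes:
    def test_rigid_oscillation_all_equal(self):
        table = table_from_midline(
            straight_fish_midline(
                offset_fn=lambda t: (0.0, 0.1 * L * np.sin(2 * np.pi * 2 * t))
            ),
            n_frames=450,
        )
        results, _, _ = analyze_landmarks(table)
        r = results[0]
        for amp in (r.amplitude_snout, r.amplitude_com, r.amplitude_tail):
            assert amp == pytest.approx(0.1, rel=0.01)

    def test_envelope_recovered(self):
        spec = SwimmerSpec(
            tailbeat_frequency=3.0, amplitude_snout=0.02, amplitude_tail=0.15, seed=1
        )
        table, truth = generate_swimmer(spec, 2.0)
        results, _, _ = analyze_landmarks(table)
        r = results[0]
        assert r.amplitude_tail == pytest.approx(truth.amplitude_tail, rel=0.05)
        assert r.amplitude_snout == pytest.approx(truth.amplitude_snout, rel=0.05)
        assert r.amplitude_com == pytest.approx(truth.amplitude_com, rel=0.05)
        # monotone envelope implies tail amplitude >= snout amplitude
        assert r.amplitude_tail >= r.amplitude_snout

    def test_straight_steady_swimmer_tiny_amplitudes(self):
        table = table_from_midline(
            straight_fish_midline(offset_fn=lambda t: (0.05 * t, 0.0)), n_frames=200
        )
        series = reconstruct_midline(table)
        from wakekin.kinematics import _window_amplitude

        exc = lateral_excursion(series, 1.0)
        amp = _window_amplitude(exc, series.times, (0.0, series.times[-1]))
        assert amp < 0.005


class TestFullRecovery:
    def test_parameter_recovery_across_specs(self):
        """Median relative error <= 5% for f, <= 10% for wavelength and
        amplitudes, over randomized swimmer specs with tracking noise."""
        rng = np.random.default_rng(2024)
        errs = {k: [] for k in ("f", "lam", "snout", "com", "tail")}
        for i in range(8):
            f = rng.uniform(2, 8)
            lam = rng.uniform(0.8, 1.4)
            amp_t = rng.uniform(0.05, 0.2)
            spec = SwimmerSpec(
                tailbeat_frequency=f, body_wavelength=lam, amplitude_tail=amp_t,
                landmark_noise_sd=0.002, seed=300 + i,
            )
            table, truth = generate_swimmer(spec, max(2.0, 6.5 / f))
            results, _, _ = analyze_landmarks(table)
            r = results[0]
            errs["f"].append(abs(r.tailbeat_frequency - f) / f)
            errs["lam"].append(
                abs(r.body_wavelength - lam) / lam if r.body_wavelength else 1.0
            )
            errs["snout"].append(
                abs(r.amplitude_snout - truth.amplitude_snout) / truth.amplitude_snout
            )
            errs["com"].append(
                abs(r.amplitude_com - truth.amplitude_com) / truth.amplitude_com
            )
            errs["tail"].append(
                abs(r.amplitude_tail - truth.amplitude_tail) / truth.amplitude_tail
            )
        assert np.median(errs["f"]) <= 0.05
        for key in ("lam", "snout", "com", "tail"):
            assert np.median(errs[key]) <= 0.10, key
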