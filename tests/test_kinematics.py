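"""Kinematic estimators against closed-form fixtures (sines, circles,
straight lines) and against the synthetic generator's ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from undulokin import SyntheticSpec, generate_trial, tracking_io
from undulokin import kinematics as K
from undulokin.errors import (DegenerateInputError, NoCompleteCycleError,
                              NoTravelingWaveError)
from undulokin.types import CycleWindow, MidlineSequence, N_MIDLINE_POINTS


def _sequence_from_xy(x, y, body_length=1.0, fps=100.0):
    pts = np.stack([x, y], axis=-1)[None, :, :]
    return MidlineSequence(trial_id="fix", fps=fps, times=np.array([0.0]),
                           points=pts, body_length=body_length)


class TestCycleDetection:
    def test_pure_sine_period(self):
        t = np.arange(0, 1.0, 0.001)
        cycle = K.detect_cycle(0.08 * np.sin(2 * np.pi * 2.5 * t), fps=1000.0)
        assert cycle.period == pytest.approx(0.400, abs=0.001)

    def test_linear_drift_does_not_bias_period(self):
        t = np.arange(0, 1.0, 0.001)
        y = 0.08 * np.sin(2 * np.pi * 2.5 * t) + 0.01 * t
        cycle = K.detect_cycle(y, fps=1000.0)
        assert cycle.period == pytest.approx(0.400, abs=0.001)

    def test_monotone_ramp_has_no_cycle(self):
        with pytest.raises(NoCompleteCycleError):
            K.detect_cycle(np.linspace(0, 1, 500), fps=1000.0)

    def test_flat_trace_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            K.detect_cycle(np.full(500, 0.123), fps=1000.0)


class TestTipKinematics:
    @pytest.mark.parametrize("T, expected", [(0.4, 2.5), (1.0, 1.0)])
    def test_tbf_is_reciprocal_period(self, T, expected):
        cycle = CycleWindow(start_frame=0, end_frame=int(T * 1000), fps=1000.0)
        assert K.tail_beat_frequency(cycle) == pytest.approx(expected)

    def test_amplitude_is_peak_to_peak(self):
        t = np.arange(0, 1.0, 0.001)
        y = 0.08 * np.sin(2 * np.pi * 2.5 * t)
        cycle = K.detect_cycle(y, fps=1000.0)
        assert K.tail_amplitude(y, cycle) == pytest.approx(0.16, rel=1e-3)

    def test_window_outside_trace_is_bounds_error(self):
        with pytest.raises(IndexError):
            K.tail_amplitude(np.zeros(10),
                             CycleWindow(start_frame=0, end_frame=50, fps=100.0))


class TestTravelingWave:
    def _trial(self, **kw):
        kw.setdefault("duration", 1.0)
        spec = SyntheticSpec(noise_sd=0.0, **kw)
        seq, _, _ = generate_trial(spec)
        cycle = K.detect_cycle(seq.tip_trace(), seq.fps)
        tbf = K.tail_beat_frequency(cycle)
        return seq, cycle, tbf

    def test_unit_wavelength_gives_2pi_phase_gradient(self):
        seq, cycle, tbf = self._trial(tbf=2.5, wavelength=1.0)
        u, phi = K.wave_phase_profile(seq, cycle, tbf)
        slope = np.polynomial.polynomial.polyfit(u, phi, 1)[1]
        assert slope == pytest.approx(-2 * np.pi, rel=0.01)

    @pytest.mark.parametrize("lam, f", [(1.0, 2.5), (0.8, 2.0)])
    def test_wave_speed_identity(self, lam, f):
        seq, cycle, tbf = self._trial(tbf=f, wavelength=lam,
                                      duration=2.5 / f)
        u, phi = K.wave_phase_profile(seq, cycle, tbf)
        c, lam_hat = K.wave_speed_and_wavelength(u, phi, tbf)
        assert c == pytest.approx(lam * f, rel=0.01)
        assert lam_hat == pytest.approx(lam, rel=0.01)
        assert c == pytest.approx(lam_hat * tbf, rel=1e-12)  # same slope

    def test_standing_wave_has_no_speed(self):
        # y(u, t) = envelope(u) * sin(wt): no phase propagation
        seq, cycle, tbf = self._trial(tbf=2.5, wavelength=0.6)
        t = seq.times[:, None]
        u = np.linspace(0, 1, N_MIDLINE_POINTS)[None, :]
        seq.points[..., 1] = 0.05 * seq.body_length * u ** 2 \
            * np.sin(2 * np.pi * 2.5 * t)
        u_p, phi = K.wave_phase_profile(seq, cycle, 2.5)
        with pytest.raises(NoTravelingWaveError):
            K.wave_speed_and_wavelength(u_p, phi, 2.5)


class TestCurvature:
    @pytest.mark.parametrize("radius", [0.25, 0.5, 1.0, 2.0])
    def test_circle_curvature_is_reciprocal_radius(self, radius):
        theta = np.linspace(0, np.pi / 2, N_MIDLINE_POINTS)
        x, y = radius * np.cos(theta), radius * np.sin(theta)
        seq = _sequence_from_xy(x, y, body_length=1.0)
        kappa = K.curvature_field(seq)[0]
        interior = kappa[10:-10]
        assert np.max(np.abs(interior - 1.0 / radius)) * radius < 0.02

    def test_straight_line_has_zero_curvature(self):
        x = np.linspace(0, 1, N_MIDLINE_POINTS)
        seq = _sequence_from_xy(x, np.zeros_like(x))
        assert np.allclose(K.curvature_field(seq), 0.0, atol=1e-8)

    def test_sine_midline_max_curvature_closed_form(self):
        # y = a sin(2 pi x / lam): kappa_max = a (2 pi / lam)^2 at the peaks
        a, lam = 0.1, 1.0
        x_dense = np.linspace(0, 1, 5000)
        y_dense = a * np.sin(2 * np.pi * x_dense / lam)
        s = np.concatenate([[0], np.cumsum(np.hypot(np.diff(x_dense),
                                                    np.diff(y_dense)))])
        s_grid = np.linspace(0, s[-1], N_MIDLINE_POINTS)
        x = np.interp(s_grid, s, x_dense)
        y = np.interp(s_grid, s, y_dense)
        seq = _sequence_from_xy(x, y, body_length=1.0)
        k_max, _ = K.max_curvature(K.curvature_field(seq))
        assert k_max == pytest.approx(a * (2 * np.pi / lam) ** 2, rel=0.02)

    def test_duplicate_points_are_degenerate(self):
        x = np.linspace(0, 1, N_MIDLINE_POINTS)
        x[5] = x[4]
        seq = _sequence_from_xy(x, np.zeros_like(x))
        with pytest.raises(DegenerateInputError):
            K.curvature_field(seq)


class TestAngles:
    def _ba_tracks(self, snout_xz, pelvic_xz, n=4):
        from undulokin.types import LandmarkTracks
        lateral = np.zeros((n, 4, 2))
        lateral[:, 0] = snout_xz
        lateral[:, 3] = pelvic_xz
        return LandmarkTracks(lateral_2d=lateral, dorsal_2d=np.zeros((n, 3, 2)))

    def _cycle(self, n=4):
        return CycleWindow(start_frame=0, end_frame=n - 1, fps=100.0)

    @pytest.mark.parametrize("snout, pelvic, expected", [
        ((0.0, 1.0), (-1.0, 0.0), 45.0),
        ((1.0, 0.0), (0.0, 0.0), 0.0),
        ((0.0, -1.0), (-1.0, 0.0), -45.0),
    ])
    def test_body_angle_sign_convention(self, snout, pelvic, expected):
        tracks = self._ba_tracks(snout, pelvic)
        assert K.body_angle(tracks, self._cycle()) == pytest.approx(expected)

    def test_coincident_landmarks_degenerate(self):
        tracks = self._ba_tracks((0.5, 0.5), (0.5, 0.5))
        with pytest.raises(DegenerateInputError):
            K.body_angle(tracks, self._cycle())

    @pytest.mark.parametrize("chord, expected", [
        ((1.0, 0.0, 0.0), 0.0), ((0.0, 0.0, 1.0), 90.0),
        ((1.0, 0.0, 1.0), 45.0),
    ])
    def test_angle_of_attack_from_chord(self, chord, expected):
        from undulokin.types import LandmarkTracks
        n = 3
        tracks = LandmarkTracks(lateral_2d=np.zeros((n, 4, 2)),
                                dorsal_2d=np.zeros((n, 3, 2)))
        merged = np.zeros((n, 3, 3))
        merged[:, 2, :] = chord     # pelvic insertion; pectoral tip at origin
        tracks.merged_3d = merged
        assert K.angle_of_attack(tracks, self._cycle(n)) == pytest.approx(expected)


class TestDimensionless:
    @pytest.mark.parametrize("U, BL, nu, expected", [
        (1.0, 1.0, 1.0, 1.0), (0.0, 1.0, 1e-6, 0.0),
        (0.158, 0.158, 1e-6, 24964.0),
    ])
    def test_reynolds(self, U, BL, nu, expected):
        assert K.reynolds(U, BL, nu) == pytest.approx(expected)

    def test_strouhal_and_fin_effort(self):
        assert K.strouhal(2.0, 0.1, 1.0) == pytest.approx(0.2)
        assert K.strouhal(2.0, 0.0, 1.0) == 0.0
        assert K.fin_effort(2.0, 0.1) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            K.strouhal(2.0, 0.1, 0.0)

    def test_published_fin_effort_at_unit_speed_is_optimal(self):
        # fin effort 0.37 BL/s at 1 BL/s -> St = 0.37, inside [0.2, 0.4]
        from undulokin import PUBLISHED_SPEED_MEANS, STUDY_SPEEDS
        i = STUDY_SPEEDS.index(1.0)
        st = PUBLISHED_SPEED_MEANS["fin_effort"][i] / 1.0
        assert st == pytest.approx(0.37)
        assert 0.2 <= st <= 0.4


class TestSummarizeTrial:
    def test_noise_free_recovery_within_1pct(self, clean_trial):
        spec, seq, tracks, meta = clean_trial
        s = K.summarize_trial(seq, tracks, meta)
        assert s.tbf == pytest.approx(spec.tbf, rel=0.01)
        assert s.amplitude == pytest.approx(spec.tip_amplitude_pp, rel=0.01)
        assert s.wavelength == pytest.approx(spec.wavelength, rel=0.01)
        assert s.wave_speed == pytest.approx(spec.wave_speed, rel=0.01)
        assert s.body_angle == pytest.approx(spec.body_angle, abs=0.1)
        assert s.angle_of_attack == pytest.approx(spec.aa_chord_pitch, abs=0.1)

    def test_identities_hold_exactly(self, noisy_trial):
        _, seq, tracks, meta = noisy_trial
        s = K.summarize_trial(seq, tracks, meta)
        assert s.fin_effort == pytest.approx(s.tbf * s.amplitude, rel=1e-12)
        assert s.strouhal == pytest.approx(s.fin_effort / meta.speed_bl, rel=1e-12)
        assert s.reynolds == pytest.approx(
            meta.speed_ms * meta.body_length / meta.kinematic_viscosity, rel=1e-12)

    def test_missing_merge_leaves_aa_nan_only(self, noisy_trial):
        _, seq, tracks, meta = noisy_trial
        import copy
        tr = copy.copy(tracks)
        tr.merged_3d = None
        s = K.summarize_trial(seq, tr, meta)
        assert np.isnan(s.angle_of_attack)
        assert np.isfinite(s.tbf) and np.isfinite(s.body_angle)

    def test_noisy_recovery_median_error_small(self):
        """Over 12 random specs at 0.002 BL noise, median relative error
        stays below 2% for TBF, amplitude, wavelength and wave speed."""
        rng = np.random.default_rng(1)
        errs = {k: [] for k in ("tbf", "amplitude", "wavelength", "wave_speed")}
        for seed in range(12):
            spec = SyntheticSpec(
                tbf=rng.uniform(1.8, 3.8), wavelength=rng.uniform(0.45, 0.8),
                tip_amplitude_pp=rng.uniform(0.1, 0.25),
                body_angle=rng.uniform(10, 45),
                aa_chord_pitch=rng.uniform(2, 20), noise_sd=0.002,
                duration=1.25, seed=seed,
                phase0=rng.uniform(0, 2 * np.pi))
            seq, tracks, meta = generate_trial(spec)
            tracking_io.merge_views(tracks, meta.body_length)
            s = K.summarize_trial(seq, tracks, meta)
            for k in errs:
                truth = {"tbf": spec.tbf, "amplitude": spec.tip_amplitude_pp,
                         "wavelength": spec.wavelength,
                         "wave_speed": spec.wave_speed}[k]
                errs[k].append(abs(getattr(s, k) - truth) / truth)
        for k, v in errs.items():
            assert np.median(v) < 0.02, k

    @settings(max_examples=10, deadline=None)
    @given(k=st.floats(min_value=0.2, max_value=5.0))
    def test_scale_invariance(self, k):
        """Multiplying all coordinates and BL by k leaves every
        BL-normalized variable unchanged."""
        spec = SyntheticSpec(noise_sd=0.0, fps=200.0, duration=1.0, seed=2)
        seq, tracks, meta = generate_trial(spec)
        tracking_io.merge_views(tracks, meta.body_length)
        base = K.summarize_trial(seq, tracks, meta)

        seq2 = MidlineSequence(trial_id=seq.trial_id, fps=seq.fps,
                               times=seq.times, points=seq.points * k,
                               body_length=seq.body_length * k)
        from undulokin.types import LandmarkTracks, TrialMeta
        tracks2 = LandmarkTracks(lateral_2d=tracks.lateral_2d * k,
                                 dorsal_2d=tracks.dorsal_2d * k,
                                 merged_3d=tracks.merged_3d * k)
        meta2 = TrialMeta(individual_id=meta.individual_id,
                          body_length=meta.body_length * k,
                          speed_bl=meta.speed_bl)
        scaled = K.summarize_trial(seq2, tracks2, meta2)
        for name in ("tbf", "amplitude", "wave_speed", "wavelength", "k_max",
                     "k_max_loc", "fin_effort", "body_angle",
                     "angle_of_attack", "strouhal"):
            assert getattr(scaled, name) == pytest.approx(
                getattr(base, name), rel=1e-6), name
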