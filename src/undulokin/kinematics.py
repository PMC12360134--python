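"""Per-trial swimming kinematics from midline and landmark coordinates.

Implements the standard variable set for steady undulatory swimming:

* tail beat frequency (TBF) from same-direction zero crossings of the
  mean-centred tail-tip trace (one complete cycle per trial);
* tail amplitude A as the peak-to-peak tip excursion over that cycle (BL);
* body-wave speed c and wavelength lambda from the phase gradient of the
  single-frequency Fourier component of each midline station's lateral
  motion (c = 2*pi*TBF/|dphi/du|, lambda = c/TBF);
* maximum midline curvature and its arc-length location, from a
  Savitzky-Golay-smoothed parametric curvature field (1/BL);
* body angle (snout vs. pelvic-fin insertion, lateral view) and the 3-D
  angle of attack of the pectoral-tip -> pelvic-insertion chord (degrees);
* Reynolds number Re = U*BL/nu and Strouhal number St = TBF*A/U. With A in
  BL and U in BL/s, St equals fin effort (TBF*A) divided by speed, and that
  identity is enforced exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import (DegenerateInputError, InsufficientDataError,
                     NoCompleteCycleError, NoTravelingWaveError)
from .types import (CycleWindow, KinematicSummary, LandmarkTracks,
                    MidlineSequence, TrialMeta, N_MIDLINE_POINTS)

__all__ = [
    "detect_cycle", "tail_beat_frequency", "tail_amplitude",
    "wave_phase_profile", "wave_speed_and_wavelength", "curvature_field",
    "max_curvature", "body_angle", "angle_of_attack", "reynolds",
    "strouhal", "fin_effort", "summarize_trial", "KinematicsOptions",
]


@dataclass
class KinematicsOptions:
    """Tunables for the per-trial extraction.

    fit_region: arc-length fraction interval used for the phase-slope fit
    (default posterior half of the body, excluding the final 5% where tip
    digitizing noise dominates). smooth_window/smooth_order: Savitzky-Golay
    parameters for the curvature field, in stations (of 200).
    min_phase_slope: |dphi/du| below this (rad per BL) is treated as a
    standing wave. station_power_frac: stations whose oscillation power is
    below this fraction of the tip's are excluded from the phase profile.
    """

    fit_region: tuple[float, float] = (0.50, 0.95)
    smooth_window: int = 15
    smooth_order: int = 3
    min_phase_slope: float = 0.5
    station_power_frac: float = 0.01
    min_landmark_frac: float = 0.5


# ---------------------------------------------------------------------------
# cycle detection and tip kinematics
# ---------------------------------------------------------------------------

def _moving_average(y: np.ndarray, win: int) -> np.ndarray:
    """Zero-phase centred moving average with reflected edges.

    Even windows are widened to the next odd size to keep the filter
    symmetric (no phase shift).
    """
    if win <= 1:
        return y.copy()
    if win % 2 == 0:
        win += 1
    half = win // 2
    ypad = np.pad(y, half, mode="reflect")
    return np.convolve(ypad, np.ones(win) / win, mode="valid")


def _dominant_frequency(y: np.ndarray, fps: float, pad: int = 16) -> float:
    """Dominant oscillation frequency via a zero-padded periodogram.

    Zero padding interpolates the spectrum so short traces (a few cycles)
    still localize the peak to a few percent.
    """
    yc = y - y.mean()
    nfft = pad * y.size
    spec = np.abs(np.fft.rfft(yc, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fps)
    k = int(np.argmax(spec[1:])) + 1
    return max(float(freqs[k]), fps / nfft)


def detect_cycle(tip_trace: np.ndarray, fps: float,
                 nominal_tbf: float | None = None) -> CycleWindow:
    """Locate the first complete tail-beat cycle in a tip trace.

    The trace is linearly detrended (steady swimming can still drift slowly
    across the working section) and low-pass filtered with a zero-phase
    moving average before the upward zero crossings are found; the window
    runs from the first crossing to the third (one full oscillation).
    """
    y = np.asarray(tip_trace, dtype=float)
    n = y.size
    if n < 4:
        raise NoCompleteCycleError("trace too short")
    if np.ptp(y) < 1e-6:
        raise DegenerateInputError("flat tip trace (range < 1e-6 BL)")

    if nominal_tbf is None:
        nominal_tbf = _dominant_frequency(y, fps)

    # Mean-centre by harmonic regression: fit offset + linear drift +
    # a sinusoid at the nominal frequency and subtract the offset/drift
    # part. Unlike a plain linear detrend over a non-integer number of
    # cycles, this leaves the zero crossings of the oscillation unbiased.
    t = np.arange(n) / fps
    design = np.column_stack([np.ones(n), t,
                              np.cos(2 * np.pi * nominal_tbf * t),
                              np.sin(2 * np.pi * nominal_tbf * t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    y = y - design[:, :2] @ coef[:2]
    # light zero-phase low-pass against digitizing noise
    win = max(int(round(fps / (10.0 * nominal_tbf))), 1)
    if win > 1:
        y = _moving_average(y, win)

    sign = np.signbit(y)
    cross = np.nonzero(sign[1:] != sign[:-1])[0]   # y changes sign between i, i+1
    crossings = []
    for i in cross:
        if y[i + 1] == y[i]:
            continue
        frac = -y[i] / (y[i + 1] - y[i])
        crossings.append(i + frac)
    # crossings i and i+2 share a direction and bracket one full oscillation
    if len(crossings) < 3:
        raise NoCompleteCycleError(
            f"only {len(crossings)} zero crossings; need 3 for a full cycle")
    start = int(round(crossings[0]))
    end = int(round(crossings[2]))
    if end <= start:
        raise NoCompleteCycleError("degenerate cycle window")
    return CycleWindow(start_frame=start, end_frame=min(end, n - 1), fps=fps)


def tail_beat_frequency(cycle: CycleWindow) -> float:
    """TBF in Hz: the reciprocal of the cycle period."""
    return 1.0 / cycle.period


def tail_amplitude(tip_trace: np.ndarray, cycle: CycleWindow,
                   smooth_window: int | None = None) -> float:
    """Peak-to-peak tail-tip excursion over the cycle, in the trace's units
    (BL when the trace is BL-normalized).

    ``smooth_window`` (odd, in frames) applies a cubic Savitzky-Golay filter
    before taking max - min; a local polynomial preserves the excursion peaks
    while suppressing digitizing noise, which would otherwise inflate the
    extrema.
    """
    y = np.asarray(tip_trace, dtype=float)
    if cycle.end_frame >= y.size or cycle.start_frame < 0:
        raise IndexError("cycle window outside trace bounds")
    if smooth_window is not None and smooth_window > 4:
        if smooth_window % 2 == 0:
            smooth_window += 1
        y = savgol_filter(y, min(smooth_window, y.size - (y.size + 1) % 2), 3)
    seg = y[cycle.frames]
    return float(np.ptp(seg))


# ---------------------------------------------------------------------------
# traveling-wave phase profile -> wave speed, wavelength
# ---------------------------------------------------------------------------

def wave_phase_profile(midlines: MidlineSequence, cycle: CycleWindow,
                       tbf: float, power_frac: float = 0.01
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Phase of the TBF-frequency component of each station's lateral motion.

    Fits y_s(t) = a_s cos(2 pi f t) + b_s sin(2 pi f t) per station by least
    squares over the cycle frames and returns (u, phi) for the stations whose
    oscillation power reaches ``power_frac`` of the tail tip's. phi is
    unwrapped from the tail toward the head, so a head-to-tail traveling wave
    has negative slope dphi/du.
    """
    frames = cycle.frames
    t = midlines.times[frames]
    Y = midlines.points[frames, :, 1]                 # (n_t, 200)
    Y = Y - Y.mean(axis=0, keepdims=True)
    w = 2 * np.pi * tbf
    design = np.column_stack([np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)  # (2, 200)
    a, b = coef
    power = a ** 2 + b ** 2
    keep = power >= power_frac * power[-1]
    if keep.sum() < 2:
        raise NoTravelingWaveError("fewer than 2 stations with oscillation power")
    u = np.linspace(0.0, 1.0, N_MIDLINE_POINTS)[keep]
    phi = np.arctan2(a, b)[keep]
    phi = np.unwrap(phi[::-1])[::-1]                  # anchor at the tail
    return u, phi


def wave_speed_and_wavelength(u: np.ndarray, phi: np.ndarray, tbf: float,
                              fit_region: tuple[float, float] = (0.50, 0.95),
                              min_slope: float = 0.5
                              ) -> tuple[float, float]:
    """Wave speed c (BL/s) and wavelength lambda (BL) from the phase slope.

    Least-squares slope s = dphi/du over the fit region; c = 2 pi TBF / |s|
    and lambda = c / TBF. The slope must be negative (head-to-tail
    propagation under this phase convention) and clearly nonzero.
    """
    lo, hi = fit_region
    m = (u >= lo) & (u <= hi)
    if m.sum() < 10:
        raise InsufficientDataError(
            f"only {int(m.sum())} phase stations in fit region [{lo}, {hi}]")
    slope = np.polynomial.polynomial.polyfit(u[m], phi[m], 1)[1]
    if abs(slope) < min_slope:
        raise NoTravelingWaveError(f"|dphi/du| = {abs(slope):.3g} rad/BL: standing wave")
    if slope > 0:
        raise NoTravelingWaveError("phase slope positive: wave travels tail to head")
    c = 2 * np.pi * tbf / abs(slope)
    return float(c), float(c / tbf)


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def curvature_field(midlines: MidlineSequence, window: int = 15,
                    order: int = 3) -> np.ndarray:
    """Unsigned curvature kappa(u, t) in 1/BL, shape (n_frames, 200).

    Each frame's polyline is smoothed with a least-squares local polynomial
    (Savitzky-Golay) along arc length; derivatives come from the same filter.
    The parametric formula |x'y'' - y'x''| / (x'^2 + y'^2)^(3/2) is invariant
    to the (uniform) station spacing, so index-space derivatives suffice.
    """
    pts = midlines.points
    seg = np.linalg.norm(np.diff(pts, axis=1), axis=2)
    if np.any(seg < 1e-12 * midlines.body_length):
        raise DegenerateInputError("duplicate consecutive midline points")
    x, y = pts[..., 0], pts[..., 1]
    d = {}
    for deriv in (1, 2):
        d[("x", deriv)] = savgol_filter(x, window, order, deriv=deriv, axis=1)
        d[("y", deriv)] = savgol_filter(y, window, order, deriv=deriv, axis=1)
    num = np.abs(d[("x", 1)] * d[("y", 2)] - d[("y", 1)] * d[("x", 2)])
    den = (d[("x", 1)] ** 2 + d[("y", 1)] ** 2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(den > 0, num / den, 0.0)
    return kappa * midlines.body_length


def max_curvature(field: np.ndarray, cycle: CycleWindow | None = None
                  ) -> tuple[float, float]:
    """(k_max, arc-length fraction of k_max) over the cycle frames."""
    k = field[cycle.frames] if cycle is not None else field
    flat = int(np.argmax(k))
    _, station = np.unravel_index(flat, k.shape)
    return float(k.flat[flat]), float(station / (k.shape[1] - 1))


# ---------------------------------------------------------------------------
# posture angles
# ---------------------------------------------------------------------------

def body_angle(tracks: LandmarkTracks, cycle: CycleWindow,
               min_frac: float = 0.5) -> float:
    """Mean body pitch over the cycle, degrees; positive = snout up.

    Per frame: atan2(z_snout - z_pelvic, |x_snout - x_pelvic|) from the
    lateral-view snout (landmark 1) and pelvic-insertion (landmark 4) tracks.
    """
    lat = tracks.lateral_2d[cycle.frames]
    snout, pelv = lat[:, 0, :], lat[:, 3, :]
    ok = np.all(np.isfinite(snout), axis=1) & np.all(np.isfinite(pelv), axis=1)
    if ok.mean() < min_frac:
        raise InsufficientDataError(
            f"snout/pelvic landmarks present in only {ok.mean():.0%} of cycle frames")
    dz = snout[ok, 1] - pelv[ok, 1]
    dx = np.abs(snout[ok, 0] - pelv[ok, 0])
    if np.any(np.hypot(dx, dz) < 1e-12):
        raise DegenerateInputError("snout and pelvic landmarks coincide")
    return float(np.degrees(np.arctan2(dz, dx)).mean())


def angle_of_attack(tracks: LandmarkTracks, cycle: CycleWindow,
                    min_frac: float = 0.5) -> float:
    """Mean 3-D pitch of the pectoral-tip -> pelvic-insertion chord, degrees.

    Per frame: asin(|dz| / ||chord||), signed by dz (positive when the pelvic
    insertion sits above the pectoral tip). Requires merged 3-D tracks.
    """
    if tracks.merged_3d is None:
        raise InsufficientDataError("merged 3-D landmark tracks required")
    m = tracks.merged_3d[cycle.frames]
    tip, pelv = m[:, 1, :], m[:, 2, :]        # landmarks 3 and 4
    ok = np.all(np.isfinite(tip), axis=1) & np.all(np.isfinite(pelv), axis=1)
    if ok.mean() < min_frac:
        raise InsufficientDataError(
            f"3-D chord present in only {ok.mean():.0%} of cycle frames")
    delta = pelv[ok] - tip[ok]
    norm = np.linalg.norm(delta, axis=1)
    if np.any(norm < 1e-12):
        raise DegenerateInputError("zero-length pectoral-pelvic chord")
    angle = np.degrees(np.arcsin(np.abs(delta[:, 2]) / norm))
    return float((np.sign(delta[:, 2]) * angle).mean())


# ---------------------------------------------------------------------------
# dimensionless numbers
# ---------------------------------------------------------------------------

def reynolds(speed_ms: float, body_length: float, nu: float = 1e-6) -> float:
    """Re = U * BL / nu (U in m/s, BL in m, nu in m^2/s)."""
    if not nu > 0:
        raise ValueError("kinematic viscosity must be positive")
    return speed_ms * body_length / nu


def strouhal(tbf: float, amplitude_m: float, speed_ms: float) -> float:
    """St = TBF * A / U with A and U in consistent units (here metres)."""
    if not speed_ms > 0:
        raise ValueError("speed must be positive for the Strouhal number")
    return tbf * amplitude_m / speed_ms


def fin_effort(tbf: float, amplitude_bl: float) -> float:
    """Fin effort TBF * A (BL/s), a kinematic proxy for locomotor cost."""
    return tbf * amplitude_bl


# ---------------------------------------------------------------------------
# per-trial driver
# ---------------------------------------------------------------------------

def summarize_trial(midlines: MidlineSequence, tracks: LandmarkTracks,
                    meta: TrialMeta,
                    options: KinematicsOptions | None = None
                    ) -> KinematicSummary:
    """Compute the full variable set for one trial.

    The angle of attack is reported NaN (not an error) when merged 3-D
    landmark tracks are unavailable; every other variable is still computed.
    Strouhal is derived through the fin-effort identity St = (TBF*A)/U with
    both sides in BL units, which equals TBF*A[m]/U[m/s] exactly.
    """
    opt = options or KinematicsOptions()
    try:
        tip = midlines.tip_trace()
        cycle = detect_cycle(tip, midlines.fps)
        tbf = tail_beat_frequency(cycle)
        amp = tail_amplitude(tip, cycle,
                             smooth_window=int(round(midlines.fps / (10 * tbf))))
        u, phi = wave_phase_profile(midlines, cycle, tbf,
                                    power_frac=opt.station_power_frac)
        c, lam = wave_speed_and_wavelength(u, phi, tbf,
                                           fit_region=opt.fit_region,
                                           min_slope=opt.min_phase_slope)
        kfield = curvature_field(midlines, window=opt.smooth_window,
                                 order=opt.smooth_order)
        k_max, k_loc = max_curvature(kfield, cycle)
        ba = body_angle(tracks, cycle, min_frac=opt.min_landmark_frac)
    except Exception as err:
        raise type(err)(f"trial {meta.trial_id}: {err}") from err

    try:
        aa = angle_of_attack(tracks, cycle, min_frac=opt.min_landmark_frac)
    except InsufficientDataError:
        aa = math.nan

    effort = fin_effort(tbf, amp)
    st = effort / meta.speed_bl if meta.speed_bl > 0 else math.nan
    re = reynolds(meta.speed_ms, meta.body_length, meta.kinematic_viscosity)
    return KinematicSummary(
        trial_id=meta.trial_id, individual_id=meta.individual_id,
        speed_bl=meta.speed_bl, tbf=tbf, amplitude=amp, wave_speed=c,
        wavelength=lam, k_max=k_max, k_max_loc=k_loc, fin_effort=effort,
        body_angle=ba, angle_of_attack=aa, reynolds=re, strouhal=st)
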