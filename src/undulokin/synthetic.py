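"""Synthetic traveling-wave swimmer: trials with known ground-truth kinematics.

The generator emulates what the pipeline would receive from digitized video
of a steadily swimming elongate fish: a 200-point dorsal-view midline per
frame plus four anatomical landmarks (snout, pectoral insertion, pectoral
tip, pelvic insertion) seen in orthogonal lateral and dorsal views.

The dorsal-view lateral displacement at arc-length fraction u in [0, 1] and
time t is

    y(u, t) = (A_pp / 2) * u**p * sin(2*pi*(u / lambda_bl - f*t) + phi0) + eps

with A_pp the peak-to-peak tail-tip excursion (BL), p >= 0 the amplitude
envelope exponent, lambda_bl the body wavelength in BL, f the tail beat
frequency and eps i.i.d. Gaussian digitizing noise per coordinate. The
streamwise coordinate is reconstructed so the 200 sample points are equally
spaced in arc length, which is how midline-tracking tools parameterize the
body. The wave travels head to tail with speed c = lambda * f by
construction, so every downstream estimator has an exact target.

The lateral view applies a rigid pitch (body angle) to the anterior body
axis, and the pectoral-tip landmark is placed so the 3-D pectoral-tip ->
pelvic-insertion chord has a prescribed pitch (the ground-truth angle of
attack). The generator is a test harness for estimator verification, not a
hydrodynamic or anatomical model of the animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import LandmarkTracks, MidlineSequence, TrialMeta, N_MIDLINE_POINTS

__all__ = ["SyntheticSpec", "CohortDesign", "generate_trial", "generate_cohort",
           "STUDY_SPEEDS", "PUBLISHED_SPEED_MEANS"]

# Arc-length fractions of the landmarks along the body and the sweep geometry
# of the pectoral-tip chord. The pelvic-insertion fraction (0.45) is the
# module default; anatomy varies and it is configurable per trial.
PELVIC_U = 0.45
PECTORAL_INSERTION_U = 0.25
CHORD_LENGTH_BL = 0.20        # pectoral tip -> pelvic insertion chord, BL
CHORD_SWEEP_DEG = 20.0        # lateral sweep of that chord in the horizontal plane


@dataclass
class SyntheticSpec:
    """Ground-truth parameters of one simulated steady-swimming trial.

    Lengths are in BL units unless stated; ``body_length`` is in metres.
    """

    body_length: float = 0.158          # m (snout to tail tip)
    tbf: float = 2.5                    # Hz
    tip_amplitude_pp: float = 0.18      # peak-to-peak tail-tip excursion, BL
    wavelength: float = 0.6             # body wavelength, BL
    envelope_power: float = 2.0         # p >= 0; amplitude grows as u**p
    body_angle: float = 30.0            # pitch, degrees, positive = snout up
    aa_chord_pitch: float = 11.0        # pectoral-tip->pelvic chord pitch, degrees
    fps: float = 1000.0
    duration: float = 1.0               # seconds
    noise_sd: float = 0.0               # per-coordinate Gaussian SD, BL
    phase0: float = 0.0                 # radians
    seed: int = 0
    pelvic_u: float = PELVIC_U

    def __post_init__(self) -> None:
        if not self.body_length > 0:
            raise ValidationError("body_length: must be positive")
        if not self.tbf > 0:
            raise ValidationError("tbf: must be positive")
        if not 0 < self.tip_amplitude_pp < 1:
            raise ValidationError("tip_amplitude_pp: must lie in (0, 1) BL")
        if not self.wavelength > 0:
            raise ValidationError("wavelength: must be positive")
        if self.envelope_power < 0:
            raise ValidationError("envelope_power: must be >= 0")
        if self.fps < 2 * self.tbf * 10:
            raise ValidationError(
                "fps: need >= 10 samples per half-cycle (fps >= 20*tbf)")
        if self.duration < 2.0 / self.tbf:
            raise ValidationError("duration: need >= 2 full cycles (>= 2/tbf)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd: must be >= 0")
        if not 0 < self.pelvic_u < 1:
            raise ValidationError("pelvic_u: must lie in (0, 1)")

    @property
    def wave_speed(self) -> float:
        """Ground-truth wave speed c = lambda * f, BL/s."""
        return self.wavelength * self.tbf


def _midline_frames(spec: SyntheticSpec, times: np.ndarray) -> np.ndarray:
    """Noise-free midline coordinates, shape (n_frames, 200, 2), metres.

    Points are equally spaced in arc length: the streamwise increment of each
    segment is chosen so that its total length equals BL/199 given the lateral
    increment, i.e. the midline is inextensible.
    """
    bl = spec.body_length
    u = np.linspace(0.0, 1.0, N_MIDLINE_POINTS)
    phase = (2 * np.pi * (u[None, :] / spec.wavelength - spec.tbf * times[:, None])
             + spec.phase0)
    y = (spec.tip_amplitude_pp / 2.0) * u[None, :] ** spec.envelope_power \
        * np.sin(phase) * bl
    ds = bl / (N_MIDLINE_POINTS - 1)
    dy = np.diff(y, axis=1)
    dx = np.sqrt(np.clip(ds ** 2 - dy ** 2, 0.0, None))
    x = np.concatenate([np.zeros((len(times), 1)), np.cumsum(dx, axis=1)], axis=1)
    return np.stack([x, y], axis=2)


def _landmarks(spec: SyntheticSpec, midline: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free landmark tracks from the noise-free midline.

    Returns (lateral_2d (n,4,2) as (x,z), dorsal_2d (n,3,2) as (x,y)).
    The anterior body axis (snout -> pelvic insertion) carries a rigid pitch
    of ``body_angle``; streamwise landmark positions match the dorsal view so
    an orthogonal merge recovers the ground truth exactly.
    """
    bl = spec.body_length
    n = midline.shape[0]
    ba = np.deg2rad(spec.body_angle)
    aa = np.deg2rad(spec.aa_chord_pitch)
    sweep = np.deg2rad(CHORD_SWEEP_DEG)

    idx = [int(round(f * (N_MIDLINE_POINTS - 1)))
           for f in (0.0, PECTORAL_INSERTION_U, spec.pelvic_u)]
    i_snout, i_pect, i_pelv = idx

    snout = midline[:, i_snout, :]        # (n, 2): (x, y)
    pect = midline[:, i_pect, :]
    pelv = midline[:, i_pelv, :]

    # Rigid pitch of the anterior body axis, pelvic insertion at z = 0: each
    # anterior landmark sits above the pelvic insertion by its streamwise
    # distance times tan(body angle). Both views then share the same
    # (foreshortened) streamwise coordinate, so the orthogonal merge is
    # exact and the lateral-view snout-pelvic angle equals the body angle.
    z_snout = (pelv[:, 0] - snout[:, 0]) * np.tan(ba)
    z_pect = (pelv[:, 0] - pect[:, 0]) * np.tan(ba)

    # pectoral tip: displaced from the pelvic insertion by the 3-D chord
    chord = CHORD_LENGTH_BL * bl
    dz = chord * np.sin(aa)
    dh = chord * np.cos(aa)
    dx, dy = dh * np.cos(sweep), dh * np.sin(sweep)
    tip_x = pelv[:, 0] - dx
    tip_y = pelv[:, 1] - dy
    tip_z = np.full(n, -dz)               # z_pelv - dz with z_pelv = 0

    lateral = np.empty((n, 4, 2))
    lateral[:, 0] = np.column_stack([snout[:, 0], z_snout])
    lateral[:, 1] = np.column_stack([pect[:, 0], z_pect])
    lateral[:, 2] = np.column_stack([tip_x, tip_z])
    lateral[:, 3] = np.column_stack([pelv[:, 0], np.zeros(n)])

    dorsal = np.empty((n, 3, 2))
    dorsal[:, 0] = pect
    dorsal[:, 1] = np.column_stack([tip_x, tip_y])
    dorsal[:, 2] = pelv
    return lateral, dorsal


def generate_trial(spec: SyntheticSpec,
                   individual_id: str = "sim",
                   speed_bl: float = 1.0,
                   ) -> tuple[MidlineSequence, LandmarkTracks, TrialMeta]:
    """Simulate one trial: midline sequence, landmark tracks and metadata.

    Identical seeds give bit-identical output. Noise is i.i.d. Gaussian per
    coordinate with SD ``noise_sd`` (in BL), applied to midline points and
    landmarks alike.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration * spec.fps)) + 1
    times = np.arange(n_frames) / spec.fps

    midline = _midline_frames(spec, times)
    lateral, dorsal = _landmarks(spec, midline)

    if spec.noise_sd > 0:
        sd = spec.noise_sd * spec.body_length
        midline = midline + rng.normal(0.0, sd, midline.shape)
        lateral = lateral + rng.normal(0.0, sd, lateral.shape)
        dorsal = dorsal + rng.normal(0.0, sd, dorsal.shape)

    meta = TrialMeta(individual_id=individual_id, body_length=spec.body_length,
                     speed_bl=speed_bl)
    seq = MidlineSequence(trial_id=meta.trial_id, fps=spec.fps, times=times,
                          points=midline, body_length=spec.body_length)
    tracks = LandmarkTracks(lateral_2d=lateral, dorsal_2d=dorsal)
    return seq, tracks, meta


# ---------------------------------------------------------------------------
# Cohort design: the study layout of 5 individuals x 11 speeds with 4
# missing trials (51 sequences), with speed trends interpolating the
# published per-speed means so that end-to-end statistics see a realistic
# signal structure.
# ---------------------------------------------------------------------------

STUDY_SPEEDS = (0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 3.0, 4.0, 5.0, 6.0)

#: Published per-speed cohort means: TBF (Hz), wave speed (BL/s),
#: fin effort (BL/s), body angle (deg).
PUBLISHED_SPEED_MEANS = {
    "tbf":        (2.17, 2.04, 2.32, 2.20, 2.20, 2.49, 2.44, 3.00, 3.24, 3.77, 3.66),
    "wave_speed": (1.12, 1.11, 1.21, 1.25, 1.24, 1.33, 1.37, 1.71, 1.74, 2.32, 2.52),
    "fin_effort": (0.44, 0.41, 0.37, 0.41, 0.44, 0.48, 0.46, 0.50, 0.57, 0.63, 0.57),
    "body_angle": (39.4, 44.6, 39.6, 41.9, 39.0, 39.0, 34.8, 28.5, 23.5, 19.2, 14.0),
}


def _interp_trend(var: str) -> Callable[[float], float]:
    xs = np.asarray(STUDY_SPEEDS)
    ys = np.asarray(PUBLISHED_SPEED_MEANS[var])
    return lambda s: float(np.interp(s, xs, ys))


def default_trends() -> dict[str, Callable[[float], float]]:
    """Speed -> expected value, linear interpolation of the cohort means."""
    trends = {v: _interp_trend(v) for v in PUBLISHED_SPEED_MEANS}
    trends["angle_of_attack"] = lambda s: 11.0   # no published speed trend
    return trends


#: Between-individual SDs, matched in magnitude to the published per-speed
#: SDs (which mix individual and trial variation).
DEFAULT_BETWEEN_SD = {
    "tbf": 0.30, "wave_speed": 0.20, "fin_effort": 0.06,
    "body_angle": 4.0, "angle_of_attack": 2.0,
}


@dataclass
class CohortDesign:
    """The cohort layout and generative trends for a synthetic study.

    Defaults reproduce the study design: 5 individuals swum at 11 flow
    speeds, with one individual missing 4 speeds, giving 51 trials.
    """

    n_individuals: int = 5
    speeds: Sequence[float] = STUDY_SPEEDS
    missing: Sequence[tuple[int, float]] = (
        (4, 0.5), (4, 0.75), (4, 1.75), (4, 6.0))
    trends: dict[str, Callable[[float], float]] = field(default_factory=default_trends)
    between_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_SD))
    within_sd_frac: float = 0.5          # trial-level SD as fraction of between SD
    body_length_mean: float = 0.158      # m
    body_length_sd: float = 0.008        # m
    fps: float = 1000.0
    n_cycles: float = 2.5                # trial duration in tail-beat cycles
    noise_sd: float = 0.002              # digitizing noise, BL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError("n_individuals: must be >= 1")
        if len(set(self.speeds)) != len(self.speeds):
            raise ValidationError("speeds: must be unique")
        for ind, spd in self.missing:
            if not (0 <= ind < self.n_individuals) or spd not in self.speeds:
                raise ValidationError(f"missing: unknown cell ({ind}, {spd})")

    @property
    def n_trials(self) -> int:
        return self.n_individuals * len(self.speeds) - len(self.missing)


def generate_cohort(design: CohortDesign
                    ) -> tuple[list[tuple[MidlineSequence, LandmarkTracks, TrialMeta]],
                               pd.DataFrame]:
    """Simulate every non-missing (individual, speed) cell of the design.

    Returns the trials and a ground-truth table recording every generative
    parameter; the table satisfies wave_speed = wavelength * tbf exactly.
    Two cohorts built from the same design (same seed) are identical.
    """
    rng = np.random.default_rng(design.seed)
    bls = np.clip(rng.normal(design.body_length_mean, design.body_length_sd,
                             design.n_individuals), 0.10, None)
    offsets = {v: rng.normal(0.0, sd, design.n_individuals)
               for v, sd in design.between_sd.items()}
    # all per-cell randomness is drawn on the full grid up front, so the
    # trial generated for a cell does not depend on which other cells exist
    grid = (design.n_individuals, len(design.speeds))
    trial_seeds = rng.integers(0, 2 ** 31 - 1, grid)
    phase0 = rng.uniform(0, 2 * np.pi, grid)
    variables = ("tbf", "wave_speed", "fin_effort", "body_angle",
                 "angle_of_attack")
    jitter = {v: rng.normal(0.0, design.within_sd_frac
                            * design.between_sd.get(v, 0.0), grid)
              for v in variables}

    missing = set(design.missing)
    trials, truth = [], []
    for i in range(design.n_individuals):
        for j, speed in enumerate(design.speeds):
            if (i, speed) in missing:
                continue
            zero = np.zeros(design.n_individuals)
            # per-trial jitter on top of the stable individual offsets: a
            # single tail beat is itself a noisy sample of the fish's state
            val = {v: design.trends[v](speed) + offsets.get(v, zero)[i]
                   + jitter[v][i, j] for v in variables}
            if val["tbf"] <= 0:
                raise ValidationError(
                    f"trends: non-positive TBF at speed {speed} for ind{i}")
            val["wave_speed"] = max(val["wave_speed"], 0.1)
            val["fin_effort"] = float(np.clip(val["fin_effort"], 0.05, 0.9 * val["tbf"]))
            wavelength = val["wave_speed"] / val["tbf"]
            amplitude = val["fin_effort"] / val["tbf"]
            spec = SyntheticSpec(
                body_length=float(bls[i]), tbf=float(val["tbf"]),
                tip_amplitude_pp=float(amplitude), wavelength=float(wavelength),
                body_angle=float(val["body_angle"]),
                aa_chord_pitch=float(val["angle_of_attack"]),
                fps=design.fps, duration=design.n_cycles / float(val["tbf"]),
                noise_sd=design.noise_sd,
                phase0=float(phase0[i, j]),
                seed=int(trial_seeds[i, j]))
            trial = generate_trial(spec, individual_id=f"ind{i}", speed_bl=speed)
            trials.append(trial)
            truth.append({
                "trial_id": trial[2].trial_id, "individual_id": f"ind{i}",
                "speed_bl": speed, "body_length": spec.body_length,
                "tbf": spec.tbf, "amplitude": spec.tip_amplitude_pp,
                "wavelength": spec.wavelength, "wave_speed": spec.wave_speed,
                "fin_effort": spec.tbf * spec.tip_amplitude_pp,
                "body_angle": spec.body_angle,
                "angle_of_attack": spec.aa_chord_pitch,
                "seed": spec.seed,
            })
    return trials, pd.DataFrame(truth)
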