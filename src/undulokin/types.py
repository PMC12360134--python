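"""Core data containers for one swimming trial.

Coordinate convention (dorsal view): x streamwise, positive toward the tail
at rest; y lateral. Lateral view: x streamwise, z vertical (positive up).
Midline origin is the snout in every frame. All coordinates are stored in
metres after calibration; kinematic outputs are normalized by body length
(BL) where the field convention does so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

N_MIDLINE_POINTS = 200

#: Landmark semantics (lateral view indices 0..3):
#: 0 snout tip, 1 pectoral-fin insertion, 2 pectoral-fin tip,
#: 3 pelvic-fin insertion. The dorsal view tracks landmarks 1..3 only.
LANDMARK_NAMES = ("snout", "pectoral_insertion", "pectoral_tip", "pelvic_insertion")


@dataclass
class MidlineSequence:
    """Time-indexed dorsal-view body midlines for one trial.

    ``points`` has shape (n_frames, 200, 2) in metres, each frame's points
    equally spaced in arc length from snout (index 0) to tail tip (index 199).
    """

    trial_id: str
    fps: float
    times: np.ndarray          # (n_frames,) seconds, strictly increasing
    points: np.ndarray         # (n_frames, 200, 2) metres
    body_length: float         # metres

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[1] != N_MIDLINE_POINTS \
                or self.points.shape[2] != 2:
            raise ValidationError(
                f"points: expected (n_frames, {N_MIDLINE_POINTS}, 2), "
                f"got {self.points.shape}")
        if self.points.shape[0] != self.times.shape[0]:
            raise ValidationError("times: length does not match points")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValidationError("times: not strictly increasing")
            if not np.allclose(dt, 1.0 / self.fps, rtol=1e-6, atol=1e-9):
                raise ValidationError("times: spacing differs from 1/fps")
        if not self.body_length > 0:
            raise ValidationError("body_length: must be positive")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    def arc_lengths(self) -> np.ndarray:
        """Per-frame total polyline arc length (m)."""
        seg = np.linalg.norm(np.diff(self.points, axis=1), axis=2)
        return seg.sum(axis=1)

    def tip_trace(self) -> np.ndarray:
        """Lateral (y) displacement of the tail tip, in BL."""
        return self.points[:, -1, 1] / self.body_length


@dataclass
class LandmarkTracks:
    """2-D lateral + dorsal (and optionally merged 3-D) landmark tracks.

    Missing detections are NaN; they are masked, never interpolated, unless
    the caller explicitly asks :func:`undulokin.tracking_io.interpolate_gaps`.
    """

    lateral_2d: np.ndarray            # (n_frames, 4, 2): (x, z), metres
    dorsal_2d: np.ndarray             # (n_frames, 3, 2): (x, y), landmarks 2-4
    merged_3d: np.ndarray | None = None   # (n_frames, 3, 3): (x, y, z)
    frame_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lateral_2d = np.asarray(self.lateral_2d, dtype=float)
        self.dorsal_2d = np.asarray(self.dorsal_2d, dtype=float)
        if self.lateral_2d.ndim != 3 or self.lateral_2d.shape[1:] != (4, 2):
            raise ValidationError(
                f"lateral_2d: expected (n_frames, 4, 2), got {self.lateral_2d.shape}")
        if self.dorsal_2d.ndim != 3 or self.dorsal_2d.shape[1:] != (3, 2):
            raise ValidationError(
                f"dorsal_2d: expected (n_frames, 3, 2), got {self.dorsal_2d.shape}")
        if self.lateral_2d.shape[0] != self.dorsal_2d.shape[0]:
            raise ValidationError("dorsal_2d: frame count differs from lateral_2d")

    @property
    def n_frames(self) -> int:
        return self.lateral_2d.shape[0]


@dataclass
class TrialMeta:
    """Per-trial metadata: identity, scale, flow condition, water properties."""

    individual_id: str
    body_length: float                 # metres
    speed_bl: float                    # flow speed, BL/s
    sex: str = "unknown"
    temperature: float = 18.0          # deg C
    kinematic_viscosity: float = 1e-6  # m^2/s
    trial_id: str = ""

    def __post_init__(self) -> None:
        if not self.body_length > 0:
            raise ValidationError("body_length: must be positive")
        if not self.kinematic_viscosity > 0:
            raise ValidationError("kinematic_viscosity: must be positive")
        if self.speed_bl < 0:
            raise ValidationError("speed_bl: must be non-negative")
        if not self.trial_id:
            self.trial_id = f"{self.individual_id}_U{self.speed_bl:g}"

    @property
    def speed_ms(self) -> float:
        """Flow speed U in m/s (= speed_bl x body_length)."""
        return self.speed_bl * self.body_length


@dataclass
class CycleWindow:
    """One complete tail-beat cycle, located by same-direction zero crossings
    of the mean-centred tail-tip trace."""

    start_frame: int
    end_frame: int          # inclusive
    fps: float
    method: str = "zero-crossing"

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValidationError("end_frame: must exceed start_frame")

    @property
    def period(self) -> float:
        """Cycle period T in seconds: (end - start) / fps."""
        return (self.end_frame - self.start_frame) / self.fps

    @property
    def frames(self) -> slice:
        return slice(self.start_frame, self.end_frame + 1)


@dataclass
class KinematicSummary:
    """The per-trial swimming variables (one row of the cross-speed table).

    Units: tbf Hz; amplitude BL (peak-to-peak tail-tip excursion);
    wave_speed BL/s; wavelength BL; k_max 1/BL; k_max_loc arc-length
    fraction in [0, 1]; fin_effort BL/s (tbf x amplitude); body_angle and
    angle_of_attack degrees; reynolds and strouhal dimensionless.
    """

    trial_id: str
    individual_id: str
    speed_bl: float
    tbf: float
    amplitude: float
    wave_speed: float
    wavelength: float
    k_max: float
    k_max_loc: float
    fin_effort: float
    body_angle: float
    angle_of_attack: float
    reynolds: float
    strouhal: float

    def __post_init__(self) -> None:
        for name in ("tbf", "amplitude", "wave_speed", "wavelength", "reynolds"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValidationError(f"{name}: must be non-negative")
        if np.isfinite(self.k_max_loc) and not 0 <= self.k_max_loc <= 1:
            raise ValidationError("k_max_loc: must lie in [0, 1]")

    FIELDS = ("tbf", "amplitude", "wave_speed", "wavelength", "k_max",
              "k_max_loc", "fin_effort", "body_angle", "angle_of_attack",
              "reynolds", "strouhal")

    def as_dict(self) -> dict:
        d = {"trial_id": self.trial_id, "individual_id": self.individual_id,
             "speed_bl": self.speed_bl}
        d.update({k: getattr(self, k) for k in self.FIELDS})
        return d
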