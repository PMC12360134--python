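"""Read/write digitized-coordinate files and merge orthogonal camera views.

Two tabular text formats are supported, mirroring what midline-tracking and
landmark-digitizing tools export:

* midline files: one row per frame, ``frame_index`` followed by 400
  alternating x,y pixel values (200 points);
* landmark files: one row per frame, ``frame_index`` followed by x,y pixel
  pairs per landmark (4 landmarks lateral, 3 dorsal); missing detections are
  blank or NaN.

The delimiter (comma or tab) is auto-detected. Calibration is a linear
length-per-pixel scale; all in-memory coordinates are metres. A trial is
bundled on disk as ``<stem>_midline.csv``, ``<stem>_lateral.csv``,
``<stem>_dorsal.csv`` and a ``<stem>_meta.json`` sidecar.

Missing landmark frames stay masked (NaN); optional gap interpolation is
available but never applied implicitly, to avoid manufacturing kinematics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .errors import InsufficientDataError, ParseError, SchemaError
from .types import (LandmarkTracks, MidlineSequence, TrialMeta,
                    N_MIDLINE_POINTS)

__all__ = [
    "read_midlines", "write_midlines", "read_landmarks", "write_landmarks",
    "merge_views", "interpolate_gaps", "write_trial_bundle",
    "read_trial_bundle",
]

#: default x-consistency tolerance for the orthogonal merge, as a fraction
#: of body length
MERGE_TOLERANCE_BL = 0.02


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def _read_table(path: Path, n_fields: int, what: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse a delimited frame-indexed table -> (frame_indices, values).

    Every row must have exactly ``n_fields`` fields (frame index included);
    blank coordinate fields become NaN. Malformed rows raise ParseError
    naming the 1-based row number.
    """
    lines = Path(path).read_text().splitlines()
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not rows:
        raise ParseError(f"{path}: empty {what} file")
    delim = _sniff_delimiter(rows[0][1])
    idx, vals = [], []
    for rowno, ln in rows:
        fields = ln.split(delim)
        if rowno == rows[0][0] and not _is_number(fields[0]):
            continue  # header row
        if len(fields) != n_fields:
            raise ParseError(
                f"{path} row {rowno}: expected {n_fields} fields, got {len(fields)}")
        try:
            idx.append(int(float(fields[0])))
        except ValueError as e:
            raise ParseError(f"{path} row {rowno}: bad frame index {fields[0]!r}") from e
        vals.append([float(f) if f.strip() not in ("", "NaN", "nan", "NA")
                     else np.nan for f in fields[1:]])
    frame_idx = np.asarray(idx)
    if np.any(np.diff(frame_idx) <= 0):
        raise ParseError(f"{path}: frame indices not strictly increasing")
    return frame_idx, np.asarray(vals, dtype=float)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _fmt(v: float) -> str:
    """Shortest round-trip decimal representation (bit-exact read-back)."""
    return "" if np.isnan(v) else repr(float(v))


# ---------------------------------------------------------------------------
# midlines
# ---------------------------------------------------------------------------

def read_midlines(path, calibration: float, fps: float,
                  body_length: float | None = None,
                  trial_id: str | None = None) -> MidlineSequence:
    """Read a midline file; pixel coordinates are scaled by ``calibration``
    (metres per pixel). If ``body_length`` is omitted it is taken as the
    mean per-frame arc length."""
    path = Path(path)
    frame_idx, vals = _read_table(path, 1 + 2 * N_MIDLINE_POINTS, "midline")
    pts = vals.reshape(len(frame_idx), N_MIDLINE_POINTS, 2) * calibration
    if body_length is None:
        body_length = float(_smoothed_arc_lengths(pts).mean())
    times = (frame_idx - frame_idx[0]) / fps
    seq = MidlineSequence(trial_id=trial_id or path.stem, fps=fps, times=times,
                          points=pts, body_length=body_length)
    arcs = _smoothed_arc_lengths(pts)
    if np.any(np.abs(arcs - body_length) > 0.10 * body_length):
        warnings.warn(f"{path}: frame arc length departs >10% from body length")
    return seq


def _smoothed_arc_lengths(pts: np.ndarray, window: int = 9) -> np.ndarray:
    """Per-frame polyline length after light smoothing.

    Raw polyline length over ~200 points is biased upward by independent
    digitizing noise on every point; a short local-quadratic smooth removes
    that inflation so the body-length sanity check compares like with like.
    """
    from scipy.signal import savgol_filter

    smoothed = savgol_filter(pts, window, 2, axis=1)
    seg = np.linalg.norm(np.diff(smoothed, axis=1), axis=2)
    return seg.sum(axis=1)


def write_midlines(path, seq: MidlineSequence, calibration: float = 1.0,
                   delimiter: str = ",") -> None:
    """Inverse of :func:`read_midlines` (bit-exact round trip)."""
    with open(path, "w") as fh:
        for i in range(seq.n_frames):
            row = [str(i)]
            row += [_fmt(v) for v in (seq.points[i] / calibration).ravel()]
            fh.write(delimiter.join(row) + "\n")


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path_lateral, path_dorsal, calibration: float = 1.0
                   ) -> LandmarkTracks:
    """Read lateral (4-landmark) and dorsal (3-landmark) tracks.

    Views with different frame sets are intersected (with a warning); the
    merged 3-D tracks are left unset until :func:`merge_views` is called.
    """
    lat_idx, lat = _read_table(Path(path_lateral), 1 + 8, "lateral landmark")
    dor_idx, dor = _read_table(Path(path_dorsal), 1 + 6, "dorsal landmark")
    if lat.shape[1] != 8:
        raise SchemaError(f"{path_lateral}: expected 4 landmarks (8 columns)")
    if dor.shape[1] != 6:
        raise SchemaError(f"{path_dorsal}: expected 3 landmarks (6 columns)")
    common, ia, ib = np.intersect1d(lat_idx, dor_idx, return_indices=True)
    if common.size == 0:
        raise InsufficientDataError("no overlapping frames between views")
    if common.size != lat_idx.size or common.size != dor_idx.size:
        warnings.warn("landmark views cover different frames; "
                      f"keeping the {common.size}-frame intersection")
    lateral = lat[ia].reshape(-1, 4, 2) * calibration
    dorsal = dor[ib].reshape(-1, 3, 2) * calibration
    return LandmarkTracks(lateral_2d=lateral, dorsal_2d=dorsal,
                          frame_labels=common)


def write_landmarks(path_lateral, path_dorsal, tracks: LandmarkTracks,
                    calibration: float = 1.0, delimiter: str = ",") -> None:
    """Inverse of :func:`read_landmarks` (bit-exact round trip)."""
    labels = (tracks.frame_labels if tracks.frame_labels is not None
              else np.arange(tracks.n_frames))
    for path, arr in ((path_lateral, tracks.lateral_2d),
                      (path_dorsal, tracks.dorsal_2d)):
        with open(path, "w") as fh:
            for i, lab in enumerate(labels):
                row = [str(int(lab))]
                row += [_fmt(v) for v in (arr[i] / calibration).ravel()]
                fh.write(delimiter.join(row) + "\n")


def merge_views(tracks: LandmarkTracks, body_length: float,
                tolerance: float | None = None) -> LandmarkTracks:
    """Merge the orthogonal views into 3-D tracks for landmarks 2-4.

    Both views share the streamwise axis: the 3-D point is (mean of the two
    views' x, dorsal y, lateral z). Frames where the views' x estimates
    disagree by more than ``tolerance`` (default 2% of body length) are
    flagged and excluded (NaN). Sets ``tracks.merged_3d`` in place and
    returns the tracks.
    """
    if tolerance is None:
        tolerance = MERGE_TOLERANCE_BL * body_length
    lat = tracks.lateral_2d[:, 1:, :]          # landmarks 2-4: (x, z)
    dor = tracks.dorsal_2d                      # landmarks 2-4: (x, y)
    both = np.isfinite(lat[..., 0]) & np.isfinite(dor[..., 0])
    if not both.any():
        raise InsufficientDataError("no frames with both views present")
    dx = np.abs(lat[..., 0] - dor[..., 0])
    ok = both & (dx <= tolerance)
    n_flagged = int((both & ~ok).sum())
    if n_flagged:
        warnings.warn(f"merge_views: {n_flagged} landmark-frames exceed the "
                      f"x-consistency tolerance ({tolerance:.4g} m); excluded")
    merged = np.full(lat.shape[:2] + (3,), np.nan)
    merged[..., 0] = np.where(ok, (lat[..., 0] + dor[..., 0]) / 2, np.nan)
    merged[..., 1] = np.where(ok, dor[..., 1], np.nan)
    merged[..., 2] = np.where(ok, lat[..., 1], np.nan)
    tracks.merged_3d = merged
    return tracks


def interpolate_gaps(track: np.ndarray, max_gap: int = 3) -> np.ndarray:
    """Linearly fill NaN runs of length <= max_gap in a (n_frames, d) track.

    Opt-in only; longer gaps and edge gaps stay masked.
    """
    out = np.array(track, dtype=float)
    for col in range(out.shape[1]):
        y = out[:, col]
        isnan = np.isnan(y)
        if not isnan.any() or isnan.all():
            continue
        idx = np.arange(y.size)
        runs = np.split(idx[isnan], np.where(np.diff(idx[isnan]) > 1)[0] + 1)
        for run in runs:
            lo, hi = run[0] - 1, run[-1] + 1
            if run.size <= max_gap and lo >= 0 and hi < y.size:
                y[run] = np.interp(run, [lo, hi], [y[lo], y[hi]])
    return out


# ---------------------------------------------------------------------------
# trial bundles
# ---------------------------------------------------------------------------

def write_trial_bundle(directory, stem: str, seq: MidlineSequence,
                       tracks: LandmarkTracks, meta: TrialMeta,
                       calibration: float = 1.0) -> None:
    """Write one trial as midline + lateral + dorsal CSVs with a JSON
    metadata sidecar (calibration, fps, body length, flow condition)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_midlines(d / f"{stem}_midline.csv", seq, calibration)
    write_landmarks(d / f"{stem}_lateral.csv", d / f"{stem}_dorsal.csv",
                    tracks, calibration)
    sidecar = {"calibration": calibration, "fps": seq.fps,
               "meta": asdict(meta)}
    (d / f"{stem}_meta.json").write_text(json.dumps(sidecar, indent=2))


def read_trial_bundle(directory, stem: str
                      ) -> tuple[MidlineSequence, LandmarkTracks, TrialMeta]:
    d = Path(directory)
    sidecar = json.loads((d / f"{stem}_meta.json").read_text())
    meta = TrialMeta(**sidecar["meta"])
    cal, fps = sidecar["calibration"], sidecar["fps"]
    seq = read_midlines(d / f"{stem}_midline.csv", cal, fps,
                        body_length=meta.body_length, trial_id=meta.trial_id)
    tracks = read_landmarks(d / f"{stem}_lateral.csv",
                            d / f"{stem}_dorsal.csv", calibration=cal)
    return seq, tracks, meta


def list_bundles(directory) -> list[str]:
    """Stems of all trial bundles in a directory, sorted."""
    return sorted(p.name[:-len("_meta.json")]
                  for p in Path(directory).glob("*_meta.json"))
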