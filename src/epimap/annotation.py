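"""Unipolar electrogram annotation.

Each recording is segmented into beats (anchored to pacing stimuli when
available, otherwise to peaks of the cross-channel signal envelope) and
every electrode/beat deflection is annotated with:

* LAT — local activation time at the steepest negative deflection, i.e.
  the minimum of the central-difference first derivative in the beat
  window (ties broken by the earlier time);
* voltage — peak-to-peak amplitude within the window (mV);
* slope — the central-difference derivative at the LAT sample (V/s,
  signed, non-positive for accepted potentials).

A 10 ms post-stimulus blanking interval excludes the pacing artifact from
the LAT search. Channels with peak-to-peak amplitude below the noise floor
are flagged ``excluded_flat``; saturated or positive-slope annotations are
flagged ``excluded_artifact``. Flagged potentials are retained, not
dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import AnnotationError
from .recording import MappingPosition, Recording

#: LAT search exclusion after each pacing stimulus (ms)
BLANKING_MS = 10.0
#: guard before each stimulus (ms): the artifact's leading lobe
BLANK_PRE_MS = 5.0
#: beat window relative to its anchor (ms); post chosen to hold the widest
#: (flattest-slope) deflections this pipeline analyses
WINDOW_PRE_MS = 50.0
WINDOW_POST_MS = 250.0
#: absolute peak-to-peak floor below which a channel/beat is surely flat (mV)
FLAT_FLOOR_MV = 0.05


@dataclass(frozen=True)
class BeatWindow:
    """One beat's analysis window [start_ms, end_ms) anchored at ``anchor_ms``."""

    beat_index: int
    start_ms: float
    end_ms: float
    anchor_ms: float

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise AnnotationError("window start must precede end")


@dataclass(frozen=True)
class UnipolarPotential:
    """One annotated deflection at one electrode in one beat."""

    heart_id: str
    position: MappingPosition
    electrode: tuple[int, int]
    beat_index: int
    lat_ms: float
    voltage_mv: float
    slope_v_s: float
    quality_flag: str = "ok"  # ok | excluded_flat | excluded_artifact


def detect_beats(
    rec: Recording,
    pre_ms: float = WINDOW_PRE_MS,
    post_ms: float = WINDOW_POST_MS,
) -> list[BeatWindow]:
    """Segment a recording into per-beat windows.

    With pacing times present, each stimulus with a complete response
    window (``anchor + post_ms`` inside the recording) anchors one beat.
    Otherwise anchors are peaks of the smoothed cross-channel mean absolute
    signal. Adjacent windows are clipped at the midpoint between anchors so
    they never overlap. Returns ``[]`` (with a warning) when nothing
    beat-like is found.
    """
    dur = rec.duration_ms
    if rec.pacing_times_ms is not None and len(rec.pacing_times_ms):
        anchors = [float(a) for a in rec.pacing_times_ms if a + post_ms <= dur]
    else:
        centered = rec.samples - np.median(rec.samples, axis=1, keepdims=True)
        env = np.mean(np.abs(centered), axis=0)
        width = max(1, int(0.02 * rec.fs_hz))  # 20 ms smoothing
        kernel = np.ones(width) / width
        env = np.convolve(env, kernel, mode="same")
        floor = np.median(env)
        if env.max() <= max(1e-9, 5.0 * floor):
            warnings.warn("no detectable beats in recording", stacklevel=2)
            return []
        min_dist = int(0.3 * rec.fs_hz)  # >= 200 bpm guard
        peaks, _ = find_peaks(env, height=0.5 * env.max(), distance=min_dist)
        anchors = [1000.0 * p / rec.fs_hz for p in peaks]
        anchors = [a for a in anchors if a + post_ms <= dur]
    if not anchors:
        warnings.warn("no complete beats in recording", stacklevel=2)
        return []
    windows = []
    for i, a in enumerate(anchors):
        start = max(0.0, a - pre_ms)
        end = min(dur, a + post_ms)
        if i > 0:
            start = max(start, 0.5 * (anchors[i - 1] + a))
        if i + 1 < len(anchors):
            end = min(end, 0.5 * (a + anchors[i + 1]))
        windows.append(BeatWindow(i, start, end, a))
    return windows


def _window_slice(window: BeatWindow, n: int, fs_hz: float) -> tuple[int, int]:
    i0 = max(0, int(np.ceil(window.start_ms * fs_hz / 1000.0)))
    i1 = min(n, int(np.floor(window.end_ms * fs_hz / 1000.0)) + 1)
    return i0, i1


def _blank_mask(
    times_ms: np.ndarray,
    pacing_times_ms: Optional[np.ndarray],
    blank_ms: float,
) -> np.ndarray:
    """True where the LAT search is allowed."""
    ok = np.ones(times_ms.shape, bool)
    if pacing_times_ms is not None:
        for ts in np.atleast_1d(pacing_times_ms):
            ok &= ~((times_ms >= ts - BLANK_PRE_MS) & (times_ms <= ts + blank_ms))
    return ok


def annotate_lat(
    trace: np.ndarray,
    window: BeatWindow,
    fs_hz: float,
    pacing_times_ms: Optional[np.ndarray] = None,
    blank_ms: float = BLANKING_MS,
) -> float:
    """LAT (ms) of the steepest negative deflection inside a beat window.

    The derivative is the central difference at the native sampling rate;
    the first admissible minimum wins on ties. Samples within ``blank_ms``
    after a pacing stimulus are excluded from the search.
    """
    trace = np.asarray(trace, float)
    i0, i1 = _window_slice(window, trace.size, fs_hz)
    if i1 - i0 < 3:
        raise AnnotationError("window shorter than 3 samples")
    lo, hi = max(i0, 1), min(i1, trace.size - 1)
    idx = np.arange(lo, hi)
    deriv = (trace[idx + 1] - trace[idx - 1]) * fs_hz / 2000.0  # mV/ms = V/s
    t = idx * 1000.0 / fs_hz
    admissible = _blank_mask(t, pacing_times_ms, blank_ms)
    if not admissible.any():
        raise AnnotationError("window fully blanked")
    deriv = np.where(admissible, deriv, np.inf)
    return float(t[int(np.argmin(deriv))])


def measure_voltage(trace: np.ndarray, window: BeatWindow, fs_hz: float) -> float:
    """Peak-to-peak amplitude (mV) inside a beat window."""
    trace = np.asarray(trace, float)
    i0, i1 = _window_slice(window, trace.size, fs_hz)
    if i1 <= i0:
        raise AnnotationError("empty window")
    seg = trace[i0:i1]
    return float(seg.max() - seg.min())


def measure_slope(trace: np.ndarray, lat_ms: float, fs_hz: float) -> float:
    """Central-difference derivative (V/s) at the LAT sample.

    Falls back to a one-sided difference at the trace boundary.
    """
    trace = np.asarray(trace, float)
    i = int(round(lat_ms * fs_hz / 1000.0))
    if not (0 <= i < trace.size):
        raise AnnotationError(f"lat_ms {lat_ms} outside trace")
    if 0 < i < trace.size - 1:
        return float((trace[i + 1] - trace[i - 1]) * fs_hz / 2000.0)
    warnings.warn("LAT at trace boundary; one-sided slope", stacklevel=2)
    if i == 0:
        return float((trace[1] - trace[0]) * fs_hz / 1000.0)
    return float((trace[i] - trace[i - 1]) * fs_hz / 1000.0)


def annotate_recording(
    rec: Recording,
    windows: Optional[Sequence[BeatWindow]] = None,
    blank_ms: float = BLANKING_MS,
    flat_floor_mv: float = FLAT_FLOOR_MV,
    saturation_fraction: float = 0.01,
) -> list[UnipolarPotential]:
    """Annotate every electrode/beat deflection of a recording.

    Vectorized across channels per beat; the per-channel results match
    :func:`annotate_lat` / :func:`measure_voltage` / :func:`measure_slope`
    exactly. Exclusion rules (flagged, not dropped):

    * ``excluded_flat`` — window peak-to-peak below ``max(3 * noise SD,
      flat_floor_mv)``, with the noise SD estimated per channel from the
      median absolute first difference;
    * ``excluded_artifact`` — more than ``saturation_fraction`` of window
      samples at the ADC rails, or a non-negative slope at the annotated
      LAT.
    """
    if windows is None:
        windows = detect_beats(rec)
    fs = rec.fs_hz
    n = rec.n_samples
    x = rec.samples
    # robust per-channel noise SD from first differences
    dx = np.abs(np.diff(x, axis=1))
    noise_sd = 1.4826 * np.median(dx, axis=1) / np.sqrt(2.0)
    rail = np.float64((2 ** 15 - 1)) * rec.scale_mv_per_count
    out: list[UnipolarPotential] = []
    for w in windows:
        i0, i1 = _window_slice(w, n, fs)
        if i1 - i0 < 3:
            continue
        seg = x[:, i0:i1]
        # pacing artifact is excluded from the peak-to-peak measurement as
        # well as from the LAT search
        seg_ok = _blank_mask(np.arange(i0, i1) * 1000.0 / fs,
                             rec.pacing_times_ms, blank_ms)
        if not seg_ok.any():
            continue
        seg = seg[:, seg_ok]
        vpp = seg.max(axis=1) - seg.min(axis=1)
        lo, hi = max(i0, 1), min(i1, n - 1)
        deriv = (x[:, lo + 1:hi + 1] - x[:, lo - 1:hi - 1]) * fs / 2000.0
        t = np.arange(lo, hi) * 1000.0 / fs
        admissible = _blank_mask(t, rec.pacing_times_ms, blank_ms)
        masked = np.where(admissible[None, :], deriv, np.inf)
        lat_idx = np.argmin(masked, axis=1)
        lat_ms = t[lat_idx]
        slope = masked[np.arange(masked.shape[0]), lat_idx]
        saturated = np.mean(np.abs(seg) >= rail - 1e-12, axis=1) > saturation_fraction
        flat = vpp < np.maximum(3.0 * noise_sd, flat_floor_mv)
        for ch in range(x.shape[0]):
            if flat[ch]:
                flag = "excluded_flat"
            elif saturated[ch] or not np.isfinite(slope[ch]) or slope[ch] > 0:
                flag = "excluded_artifact"
            else:
                flag = "ok"
            out.append(
                UnipolarPotential(
                    heart_id=rec.heart_id,
                    position=rec.position,
                    electrode=rec.grid.electrode(ch),
                    beat_index=w.beat_index,
                    lat_ms=float(lat_ms[ch]),
                    voltage_mv=float(vpp[ch]),
                    slope_v_s=float(slope[ch]) if np.isfinite(slope[ch]) else np.nan,
                    quality_flag=flag,
                )
            )
    return out


def potentials_to_frame(potentials: Sequence[UnipolarPotential]):
    """Tabulate annotated potentials (one row per electrode/beat)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "heart_id": p.heart_id,
            "ventricle": p.position.ventricle,
            "region": p.position.region,
            "position_index": p.position.position_index,
            "row": p.electrode[0],
            "col": p.electrode[1],
            "beat_index": p.beat_index,
            "lat_ms": p.lat_ms,
            "voltage_mv": p.voltage_mv,
            "slope_v_s": p.slope_v_s,
            "quality_flag": p.quality_flag,
        }
        for p in potentials
    )
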