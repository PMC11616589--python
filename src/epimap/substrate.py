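"""Voltage/slope substrate quantification and per-heart summaries.

The low-voltage threshold is the 5th percentile of all peak-to-peak
amplitudes pooled per ventricle across the cohort, rounded to the nearest
integer (half away from zero); a potential is low-voltage when its
amplitude is strictly below that threshold. Per-heart, per-ventricle
summaries are medians over all accepted potentials (all positions, all
beats) plus the pooled conduction products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError
from .annotation import UnipolarPotential
from .recording import ElectrodeGrid

MAP_UNITS = {"voltage": "mV", "slope": "V/s", "lat": "ms"}


@dataclass
class ElectrodeMap:
    """Per-electrode scalar map (voltage, slope, or LAT) for rendering."""

    kind: str
    values: np.ndarray
    units: str = ""
    title: str = ""

    def __post_init__(self) -> None:
        if self.kind not in MAP_UNITS:
            raise ParameterError(f"kind must be one of {sorted(MAP_UNITS)}")
        if not self.units:
            self.units = MAP_UNITS[self.kind]


@dataclass(frozen=True)
class LowVoltageThreshold:
    """Integer low-voltage cutoff for one ventricle (mV)."""

    ventricle: str
    threshold_mv: int
    percentile: float = 5.0
    raw_percentile_mv: float = float("nan")


@dataclass
class HeartSummary:
    """Per-heart, per-ventricle electrophysiological summary row."""

    heart_id: str
    ventricle: str
    n_potentials: int
    median_voltage_mv: float
    pct_low_voltage: float
    median_slope_v_s: float
    median_cv_cm_s: float
    pct_block: float


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def low_voltage_threshold(
    amplitudes: Sequence[float], ventricle: str, percentile: float = 5.0
) -> LowVoltageThreshold:
    """5th-percentile low-voltage cutoff over cohort-pooled amplitudes.

    Percentile by linear interpolation between order statistics (position
    ``(n - 1) q``), rounded half away from zero to an integer mV. Requires
    at least 20 values for the tail percentile to be meaningful.
    """
    values = np.asarray(list(amplitudes), float)
    if values.size == 0:
        raise ParameterError("no amplitudes supplied")
    if values.size < 20:
        raise ParameterError("need >= 20 amplitudes for a 5th percentile")
    raw = float(np.percentile(values, percentile))
    return LowVoltageThreshold(
        ventricle=ventricle,
        threshold_mv=_round_half_away(raw),
        percentile=percentile,
        raw_percentile_mv=raw,
    )


def _voltages(potentials_or_values) -> np.ndarray:
    seq = list(potentials_or_values)
    if seq and isinstance(seq[0], UnipolarPotential):
        return np.array([p.voltage_mv for p in seq if p.quality_flag == "ok"], float)
    return np.asarray(seq, float)


def pct_low_voltage(potentials_or_values, thr: LowVoltageThreshold) -> float:
    """Percentage of accepted potentials strictly below the threshold."""
    v = _voltages(potentials_or_values)
    if v.size == 0:
        return float("nan")
    return 100.0 * float(np.count_nonzero(v < thr.threshold_mv)) / v.size


def heart_summary(
    heart_id: str,
    ventricle: str,
    potentials: Sequence[UnipolarPotential],
    thr: Optional[LowVoltageThreshold] = None,
    cv_values: Optional[Sequence[float]] = None,
    block_flags: Optional[Sequence[bool]] = None,
) -> HeartSummary:
    """Summarize one heart/ventricle over its pooled accepted potentials.

    ``cv_values`` and ``block_flags`` are the conduction products pooled
    over all positions and beats of that ventricle.
    """
    ok = [p for p in potentials
          if p.quality_flag == "ok" and p.position.ventricle == ventricle]
    voltages = np.array([p.voltage_mv for p in ok], float)
    slopes = np.array([p.slope_v_s for p in ok], float)
    nan = float("nan")
    cv = np.asarray([] if cv_values is None else list(cv_values), float)
    cv = cv[np.isfinite(cv)]
    flags = np.asarray([] if block_flags is None else list(block_flags), bool)
    return HeartSummary(
        heart_id=heart_id,
        ventricle=ventricle,
        n_potentials=len(ok),
        median_voltage_mv=float(np.median(voltages)) if len(ok) else nan,
        pct_low_voltage=pct_low_voltage(voltages, thr) if (thr and len(ok)) else nan,
        median_slope_v_s=float(np.median(slopes)) if len(ok) else nan,
        median_cv_cm_s=float(np.median(cv)) if cv.size else nan,
        pct_block=100.0 * int(flags.sum()) / flags.size if flags.size else nan,
    )


def voltage_histogram(
    voltages: Sequence[float], bin_width_mv: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of deflection amplitudes with fixed-width bins from zero."""
    if bin_width_mv <= 0:
        raise ParameterError("bin_width_mv must be > 0")
    v = np.asarray(list(voltages), float)
    upper = max(bin_width_mv, float(v.max()) if v.size else bin_width_mv)
    n_bins = int(math.ceil(upper / bin_width_mv)) + 1
    edges = np.arange(n_bins + 1) * bin_width_mv
    counts, edges = np.histogram(v, bins=edges)
    return edges, counts


def electrode_map_from_potentials(
    potentials: Sequence[UnipolarPotential],
    grid: ElectrodeGrid,
    kind: str = "voltage",
    title: str = "",
) -> ElectrodeMap:
    """Per-electrode median (across beats) of voltage, slope, or LAT."""
    attr = {"voltage": "voltage_mv", "slope": "slope_v_s", "lat": "lat_ms"}[kind]
    acc: dict[tuple[int, int], list[float]] = {}
    for p in potentials:
        if p.quality_flag != "ok":
            continue
        acc.setdefault(p.electrode, []).append(getattr(p, attr))
    values = np.full((grid.rows, grid.cols), np.nan)
    for (r, c), vals in acc.items():
        values[r, c] = float(np.median(vals))
    return ElectrodeMap(kind=kind, values=values, title=title)


def render_maps(maps: Sequence[ElectrodeMap], out_dir: str | Path) -> list[Path]:
    """Render each electrode map to a PNG with a colorbar.

    Missing (excluded) electrodes are drawn in a distinct grey.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cmaps = {"voltage": "turbo_r", "slope": "viridis", "lat": "plasma"}
    paths = []
    for i, m in enumerate(maps):
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        cmap = plt.get_cmap(cmaps.get(m.kind, "viridis")).copy()
        cmap.set_bad("0.75")
        im = ax.imshow(np.ma.masked_invalid(m.values), cmap=cmap, origin="upper")
        fig.colorbar(im, ax=ax, label=f"{m.kind} ({m.units})")
        ax.set_title(m.title or f"{m.kind} map")
        ax.set_xlabel("electrode column")
        ax.set_ylabel("electrode row")
        path = out_dir / f"map_{i:03d}_{m.kind}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
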