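"""Domain types and file I/O for multielectrode epicardial recordings.

A recording is one mapping-array position: a [channels x time] matrix of
unipolar electrogram voltages (mV) acquired with a rectangular electrode
grid, together with position metadata (heart, group, ventricle, region) and
acquisition constants (sampling rate, ADC scale, pacing stimulus times).

On disk a recording is a plain-text CSV matrix of integer ADC counts
(rows = samples, columns = channels, row-major channel order by electrode
(row, col)) plus a JSON metadata sidecar holding the mV-per-count scale, so
round-trips are bit exact for quantized data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ManifestError, ValidationError

#: ADC characteristics: 16-bit conversion over a +/- full-scale span.
ADC_BITS = 16
FULL_SCALE_MV = 32.0

VENTRICLES = ("RV", "LV")
REGIONS = ("anterior", "lateral", "posterior")
GROUP_LABELS = ("group1", "group2", "unknown")


def adc_scale_mv(full_scale_mv: float = FULL_SCALE_MV, bits: int = ADC_BITS) -> float:
    """mV per ADC count for a symmetric converter of the given depth."""
    return 2.0 * full_scale_mv / (2 ** bits)


def quantize_mv(
    samples_mv: np.ndarray,
    full_scale_mv: float = FULL_SCALE_MV,
    bits: int = ADC_BITS,
) -> tuple[np.ndarray, float]:
    """Round a mV signal onto the ADC grid; returns (counts, scale).

    Counts are clipped to the converter range, so inputs beyond
    ``full_scale_mv`` saturate exactly as the hardware would.
    """
    scale = adc_scale_mv(full_scale_mv, bits)
    lo, hi = -(2 ** (bits - 1)), 2 ** (bits - 1) - 1
    counts = np.clip(np.rint(np.asarray(samples_mv) / scale), lo, hi).astype(np.int32)
    return counts, scale


@dataclass(frozen=True)
class ElectrodeGrid:
    """Rectangular mapping-electrode array (default 10 x 12 = 120 electrodes)."""

    rows: int = 10
    cols: int = 12
    pitch_mm: float = 2.0
    diameter_mm: float = 0.6

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValidationError("grid rows and cols must be positive")
        if self.pitch_mm <= 0:
            raise ValidationError("pitch_mm must be > 0")

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols

    def channel_index(self, row: int, col: int) -> int:
        """Row-major electrode (row, col) -> channel index."""
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValidationError(f"electrode ({row}, {col}) outside grid")
        return row * self.cols + col

    def electrode(self, channel: int) -> tuple[int, int]:
        """Channel index -> electrode (row, col)."""
        if not (0 <= channel < self.n_channels):
            raise ValidationError(f"channel {channel} outside grid")
        return divmod(channel, self.cols)


@dataclass(frozen=True)
class MappingPosition:
    """Where on the epicardium the array sat for one 5-s acquisition."""

    ventricle: str
    region: str
    position_index: int = 0

    def __post_init__(self) -> None:
        if self.ventricle not in VENTRICLES:
            raise ValidationError(f"ventricle must be one of {VENTRICLES}")
        if self.region not in REGIONS:
            raise ValidationError(f"region must be one of {REGIONS}")
        if self.position_index < 0:
            raise ValidationError("position_index must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.ventricle}-{self.region}-{self.position_index}"


@dataclass
class Recording:
    """One multielectrode acquisition: [channels x time] unipolar signals in mV."""

    heart_id: str
    group_label: str
    position: MappingPosition
    grid: ElectrodeGrid
    samples: np.ndarray
    fs_hz: float = 2000.0
    duration_s: float = 5.0
    pacing_times_ms: Optional[np.ndarray] = None
    scale_mv_per_count: float = field(default_factory=adc_scale_mv)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.pacing_times_ms is not None:
            self.pacing_times_ms = np.asarray(self.pacing_times_ms, dtype=float)
        issues = validate_recording(self, warnings_too=False)
        if issues:
            raise ValidationError("; ".join(issues))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.fs_hz

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.fs_hz

    def channel(self, row: int, col: int) -> np.ndarray:
        return self.samples[self.grid.channel_index(row, col)]


def validate_recording(rec: Recording, warnings_too: bool = True) -> list[str]:
    """Check a Recording against its invariants; returns issue strings.

    Structural violations (wrong channel/sample counts, out-of-range pacing
    times) are always reported; data-quality warnings (flat channels) only
    when ``warnings_too``.
    """
    issues: list[str] = []
    if rec.group_label not in GROUP_LABELS:
        issues.append(f"group_label must be one of {GROUP_LABELS}")
    if rec.samples.ndim != 2:
        issues.append("samples must be a 2-D [channels x time] matrix")
        return issues
    if rec.samples.shape[0] != rec.grid.n_channels:
        issues.append(
            f"channel count {rec.samples.shape[0]} != grid size {rec.grid.n_channels}"
        )
    expected = round(rec.fs_hz * rec.duration_s)
    if rec.samples.shape[1] != expected:
        issues.append(
            f"sample count {rec.samples.shape[1]} != round(fs * duration) = {expected}"
        )
    if rec.pacing_times_ms is not None and len(rec.pacing_times_ms):
        p = np.asarray(rec.pacing_times_ms, dtype=float)
        if np.any(np.diff(p) <= 0):
            issues.append("pacing times not strictly increasing")
        if p[0] < 0 or p[-1] > 1000.0 * rec.duration_s:
            issues.append("pacing time outside duration")
    if warnings_too and rec.samples.size:
        flat = np.flatnonzero(np.ptp(rec.samples, axis=1) == 0.0)
        for k in flat:
            issues.append(f"flat channel {k}")
    return issues


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as CSV ADC counts + JSON sidecar; returns CSV path.

    The mV samples are mapped to integer counts with the recording's
    ``scale_mv_per_count``; signals already on the ADC grid survive a
    write/read cycle bit exactly.
    """
    path = Path(path).with_suffix(".csv")
    counts = np.rint(rec.samples / rec.scale_mv_per_count).astype(np.int32)
    # rows = samples, cols = channels: one time point per text line
    pd.DataFrame(counts.T).to_csv(path, header=False, index=False)
    meta = {
        "heart_id": rec.heart_id,
        "group": rec.group_label,
        "ventricle": rec.position.ventricle,
        "region": rec.position.region,
        "position_index": rec.position.position_index,
        "rows": rec.grid.rows,
        "cols": rec.grid.cols,
        "pitch_mm": rec.grid.pitch_mm,
        "diameter_mm": rec.grid.diameter_mm,
        "fs_hz": rec.fs_hz,
        "duration_s": rec.duration_s,
        "scale_mv_per_count": rec.scale_mv_per_count,
        "pacing_times_ms": (
            None if rec.pacing_times_ms is None else list(map(float, rec.pacing_times_ms))
        ),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path: str | Path) -> Recording:
    """Load a CSV + JSON-sidecar recording written by :func:`write_recording`."""
    path = Path(path).with_suffix(".csv")
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise FormatError(f"recording matrix not found: {path}")
    if not sidecar.exists():
        raise FormatError(f"metadata sidecar not found: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed sidecar {sidecar}: {exc}") from exc
    required = {"heart_id", "group", "ventricle", "region", "rows", "cols",
                "fs_hz", "scale_mv_per_count"}
    missing = required - meta.keys()
    if missing:
        raise FormatError(f"sidecar {sidecar} missing fields: {sorted(missing)}")
    counts = pd.read_csv(path, header=None, dtype=np.int32).to_numpy()
    grid = ElectrodeGrid(
        rows=int(meta["rows"]),
        cols=int(meta["cols"]),
        pitch_mm=float(meta.get("pitch_mm", 2.0)),
        diameter_mm=float(meta.get("diameter_mm", 0.6)),
    )
    position = MappingPosition(
        ventricle=meta["ventricle"],
        region=meta["region"],
        position_index=int(meta.get("position_index", 0)),
    )
    pacing = meta.get("pacing_times_ms")
    return Recording(
        heart_id=str(meta["heart_id"]),
        group_label=str(meta["group"]),
        position=position,
        grid=grid,
        samples=counts.T * float(meta["scale_mv_per_count"]),
        fs_hz=float(meta["fs_hz"]),
        duration_s=float(meta.get("duration_s", counts.shape[0] / float(meta["fs_hz"]))),
        pacing_times_ms=None if pacing is None else np.asarray(pacing, dtype=float),
        scale_mv_per_count=float(meta["scale_mv_per_count"]),
    )


@dataclass(frozen=True)
class PerfusateSample:
    """One perfusate chemistry measurement during ex-situ perfusion."""

    heart_id: str
    time_min: float
    site: str  # arterial | venous
    lactate_mmol_l: float
    potassium_mmol_l: float = 4.5
    sodium_mmol_l: float = 140.0
    calcium_mmol_l: float = 1.1
    glucose_mmol_l: float = 7.0
    ph: float = 7.38

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValidationError("time_min must be >= 0")
        if self.lactate_mmol_l < 0:
            raise ValidationError("lactate must be >= 0")
        if self.site not in ("arterial", "venous"):
            raise ValidationError("site must be 'arterial' or 'venous'")


@dataclass(frozen=True)
class ContractilityScore:
    """One blinded rater's visual contractility assessment (1-5 per chamber)."""

    heart_id: str
    rater_id: str
    score_whole: int
    score_lv: int
    score_rv: int
    transplantable: bool

    def __post_init__(self) -> None:
        for name in ("score_whole", "score_lv", "score_rv"):
            v = getattr(self, name)
            if not (1 <= int(v) <= 5):
                raise ValidationError(f"{name} must be within 1-5, got {v}")


def perfusate_to_frame(samples: Sequence[PerfusateSample]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in samples])


def scores_to_frame(scores: Sequence[ContractilityScore]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in scores])


def write_perfusate(samples: Sequence[PerfusateSample], path: str | Path) -> Path:
    path = Path(path)
    perfusate_to_frame(samples).to_csv(path, index=False)
    return path


def read_perfusate(path: str | Path) -> list[PerfusateSample]:
    df = pd.read_csv(path)
    return [PerfusateSample(**{k: row[k] for k in df.columns}) for _, row in df.iterrows()]


def write_scores(scores: Sequence[ContractilityScore], path: str | Path) -> Path:
    path = Path(path)
    scores_to_frame(scores).to_csv(path, index=False)
    return path


def read_scores(path: str | Path) -> list[ContractilityScore]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            ContractilityScore(
                heart_id=str(row["heart_id"]),
                rater_id=str(row["rater_id"]),
                score_whole=int(row["score_whole"]),
                score_lv=int(row["score_lv"]),
                score_rv=int(row["score_rv"]),
                transplantable=bool(row["transplantable"]),
            )
        )
    return out


MANIFEST_COLUMNS = [
    "heart_id", "group", "ventricle", "region", "position_index",
    "recording", "perfusate", "contractility",
]


def read_cohort_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV and aggregate it to one row per heart.

    The manifest has one row per recording (columns
    ``heart_id, group, ventricle, region, position_index, recording,
    perfusate, contractility``); paths are resolved relative to the manifest
    location. Returns a DataFrame indexed 0..n_hearts-1 with columns
    ``heart_id, group, recordings`` (list of paths), ``perfusate`` and
    ``contractility``.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        return pd.DataFrame(columns=["heart_id", "group", "recordings",
                                     "perfusate", "contractility"])
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ManifestError(f"manifest missing columns: {sorted(missing_cols)}")
    dup_key = ["heart_id", "ventricle", "region", "position_index"]
    dups = df[df.duplicated(dup_key, keep=False)]
    if not dups.empty:
        raise ManifestError(
            "duplicate (heart, position) entries: "
            + ", ".join(map(str, dups[dup_key].drop_duplicates().values.tolist()))
        )
    base = path.parent
    for col in ("recording", "perfusate", "contractility"):
        for p in df[col].dropna().unique():
            if not (base / p).exists():
                raise ManifestError(f"dangling path in manifest: {p}")
    rows = []
    for heart_id, sub in df.groupby("heart_id", sort=False):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ManifestError(f"heart {heart_id} listed with multiple groups")
        rows.append(
            {
                "heart_id": heart_id,
                "group": groups[0],
                "recordings": [str(base / p) for p in sub["recording"]],
                "perfusate": str(base / sub["perfusate"].iloc[0]),
                "contractility": str(base / sub["contractility"].iloc[0]),
            }
        )
    return pd.DataFrame(rows)
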