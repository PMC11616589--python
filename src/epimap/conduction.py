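"""Per-beat conduction analysis: LAT maps, conduction times, block, CV.

Conduction time differences (ΔCT) are absolute LAT differences over the
4-neighbour adjacency of the electrode grid (2 mm pitch). Conduction block
is a ΔCT of at least 12 ms between adjacent electrodes; its prevalence is
the flagged percentage of all evaluable conduction times. Local effective
conduction velocity is obtained by inverting the central-difference time
gradient of the LAT surface (discrete velocity vectors on a regular grid):
at an interior electrode with all four neighbours,

    g = (dT/dx, dT/dy)   [ms/mm],    speed = 1/|g|  -> cm/s,

with the direction of propagation along +g (towards later activation).
Electrodes adjacent to a flagged block pair are excluded from the velocity
field so lines of block do not contaminate the "effective" velocity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DataError
from .recording import ElectrodeGrid
from .annotation import UnipolarPotential

BLOCK_THRESHOLD_MS = 12.0

Pair = tuple[tuple[int, int], tuple[int, int]]


@dataclass
class LATMap:
    """Per-beat LAT matrix (ms); NaN where the electrode was excluded."""

    beat_index: int
    lat_ms: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat_ms.shape


@dataclass
class ConductionTimeSet:
    """Absolute LAT differences over adjacent electrode pairs."""

    pairs: list  # of (electrode_a, electrode_b, delta_ct_ms)

    def deltas(self) -> np.ndarray:
        return np.array([d for _, _, d in self.pairs], float)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class BlockResult:
    """Block flags per conduction-time pair and their prevalence (%)."""

    block_flags: np.ndarray
    prevalence_pct: float
    threshold_ms: float = BLOCK_THRESHOLD_MS
    pairs: Optional[list] = None

    def blocked_pairs(self) -> set:
        if self.pairs is None:
            return set()
        return {
            _norm_pair(a, b)
            for (a, b, _), f in zip(self.pairs, self.block_flags) if f
        }


@dataclass
class CVField:
    """Local effective conduction velocity magnitudes and directions."""

    magnitude_cm_s: np.ndarray  # NaN where not evaluable
    direction_deg: np.ndarray

    def magnitudes(self) -> np.ndarray:
        m = self.magnitude_cm_s
        return m[np.isfinite(m)]


def _norm_pair(a: tuple[int, int], b: tuple[int, int]) -> Pair:
    return (a, b) if a <= b else (b, a)


def build_lat_map(
    potentials: Sequence[UnipolarPotential],
    beat_index: int,
    grid: ElectrodeGrid,
) -> LATMap:
    """Arrange one beat's ok-potential LATs on the electrode grid."""
    lat = np.full((grid.rows, grid.cols), np.nan)
    seen = set()
    for p in potentials:
        if p.beat_index != beat_index:
            continue
        if p.electrode in seen:
            raise DataError(f"duplicate potential at electrode {p.electrode}, beat {beat_index}")
        seen.add(p.electrode)
        if p.quality_flag == "ok":
            lat[p.electrode] = p.lat_ms
    return LATMap(beat_index=beat_index, lat_ms=lat)


def conduction_times(latmap: LATMap) -> ConductionTimeSet:
    """ΔCT over all 4-neighbour pairs where both LATs are present."""
    lat = latmap.lat_ms
    rows, cols = lat.shape
    pairs = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                d = abs(lat[r, c + 1] - lat[r, c])
                if np.isfinite(d):
                    pairs.append(((r, c), (r, c + 1), float(d)))
            if r + 1 < rows:
                d = abs(lat[r + 1, c] - lat[r, c])
                if np.isfinite(d):
                    pairs.append(((r, c), (r + 1, c), float(d)))
    return ConductionTimeSet(pairs=pairs)


def detect_block(
    cts: ConductionTimeSet, threshold_ms: float = BLOCK_THRESHOLD_MS
) -> BlockResult:
    """Flag conduction block (ΔCT >= threshold, inclusive) and its prevalence."""
    deltas = cts.deltas()
    if deltas.size == 0:
        return BlockResult(block_flags=np.zeros(0, bool), prevalence_pct=float("nan"),
                           threshold_ms=threshold_ms, pairs=[])
    flags = deltas >= threshold_ms
    prevalence = 100.0 * int(flags.sum()) / deltas.size
    return BlockResult(block_flags=flags, prevalence_pct=prevalence,
                       threshold_ms=threshold_ms, pairs=cts.pairs)


def estimate_cv(
    latmap: LATMap,
    pitch_mm: float,
    block: Optional[BlockResult] = None,
    exclude_block: bool = True,
) -> CVField:
    """Discrete-velocity-vector CV from the LAT time gradient.

    Evaluated at interior electrodes whose four neighbours are all present
    and, when ``exclude_block``, whose incident pairs are all unblocked.
    """
    lat = latmap.lat_ms
    rows, cols = lat.shape
    mag = np.full((rows, cols), np.nan)
    direction = np.full((rows, cols), np.nan)
    blocked = block.blocked_pairs() if (block is not None and exclude_block) else set()
    for r in range(1, rows - 1):
        for c in range(1, cols - 1):
            neighbours = [(r, c - 1), (r, c + 1), (r - 1, c), (r + 1, c)]
            if not all(np.isfinite(lat[n]) for n in neighbours) or not np.isfinite(lat[r, c]):
                continue
            if blocked and any(_norm_pair((r, c), n) in blocked for n in neighbours):
                continue
            gx = (lat[r, c + 1] - lat[r, c - 1]) / (2.0 * pitch_mm)  # ms/mm
            gy = (lat[r + 1, c] - lat[r - 1, c]) / (2.0 * pitch_mm)
            g2 = gx * gx + gy * gy
            if g2 <= 0:
                continue
            speed_mm_ms = 1.0 / np.sqrt(g2)
            mag[r, c] = 100.0 * speed_mm_ms  # mm/ms -> cm/s
            direction[r, c] = np.degrees(np.arctan2(gy, gx))
    return CVField(magnitude_cm_s=mag, direction_deg=direction)


def summarize_conduction(
    cv: CVField, block: BlockResult
) -> tuple[float, float]:
    """(median CV over present magnitudes, block prevalence %)."""
    mags = cv.magnitudes()
    median_cv = float(np.median(mags)) if mags.size else float("nan")
    return median_cv, block.prevalence_pct
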