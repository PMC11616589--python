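"""Synthetic cohort generator with full ground truth.

Emulates paced epicardial mapping of ex-situ perfused porcine hearts:
planar or focal activation wavefronts sweep a rectangular electrode grid;
each electrode sees a biphasic (RS-shaped) unipolar deflection per beat
whose peak-to-peak amplitude and steepest negative slope are controlled in
closed form; severely ischemic hearts additionally carry low-amplitude
patches and lines of conduction block. Perfusate lactate series and
blinded contractility scores are generated alongside, so the entire
analysis pipeline can be exercised and checked against known truth.

The deflection is a derivative-of-Gaussian,

    w(t) = -k (t - t0) exp(-(t - t0)^2 / (2 sigma^2)),

with extrema +/- k sigma e^{-1/2} at t0 -/+ sigma, peak-to-peak amplitude
A = 2 k sigma e^{-1/2}, and steepest (most negative) slope -k at t0. Given
target amplitude A and slope magnitude S, sigma = A e^{1/2} / (2 S) and
k = S, so amplitude and slope can be dialled independently per electrode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ParameterError
from .recording import (
    ContractilityScore,
    ElectrodeGrid,
    MappingPosition,
    PerfusateSample,
    Recording,
    quantize_mv,
)

#: fixed conduction latency from pacing stimulus to earliest epicardial
#: activation under the array (ms); clears the 10 ms post-stimulus blanking.
ACTIVATION_LATENCY_MS = 15.0


def deflection_scale(app_mv: float, sigma_ms: float) -> float:
    """Steepest-slope magnitude (mV/ms == V/s) of a deflection with
    peak-to-peak amplitude ``app_mv`` and width ``sigma_ms``."""
    return app_mv * math.exp(0.5) / (2.0 * sigma_ms)


def sigma_for(app_mv: float, slope_v_s: float) -> float:
    """Deflection width (ms) giving amplitude ``app_mv`` at slope magnitude
    ``slope_v_s``."""
    return app_mv * math.exp(0.5) / (2.0 * abs(slope_v_s))


@dataclass(frozen=True)
class BlockLine:
    """A straight line of conduction block between two grid lines.

    ``axis='col'`` places the line between columns ``index - 1`` and
    ``index``; ``axis='row'`` likewise between rows. Electrodes at or beyond
    ``index`` on the later-activated side receive ``delay_ms`` extra
    activation delay.
    """

    axis: str  # 'row' | 'col'
    index: int
    delay_ms: float = 18.0

    def __post_init__(self) -> None:
        if self.axis not in ("row", "col"):
            raise ParameterError("axis must be 'row' or 'col'")
        if self.delay_ms < 12.0:
            raise ParameterError("a declared block line must delay >= 12 ms")

    def crossing_pairs(self, grid: ElectrodeGrid) -> frozenset:
        """Unordered adjacent electrode pairs crossing the line."""
        pairs = set()
        if self.axis == "col":
            for r in range(grid.rows):
                pairs.add(((r, self.index - 1), (r, self.index)))
        else:
            for c in range(grid.cols):
                pairs.add(((self.index - 1, c), (self.index, c)))
        return frozenset(pairs)


@dataclass(frozen=True)
class ActivationModel:
    """Wavefront geometry: planar sweep or focal spread at fixed velocity."""

    mode: str = "planar"  # 'planar' | 'focal'
    cv_cm_s: float = 80.0
    direction_deg: float = 0.0  # planar: propagation direction, 0 = +col axis
    origin_electrode: tuple[int, int] = (0, 0)  # focal

    def __post_init__(self) -> None:
        if self.mode not in ("planar", "focal"):
            raise ParameterError("mode must be 'planar' or 'focal'")
        if self.cv_cm_s <= 0:
            raise ParameterError("cv_cm_s must be > 0")


@dataclass(frozen=True)
class IschemiaModel:
    """Local substrate pathology: a low-amplitude patch plus block lines."""

    patch_mask: Optional[np.ndarray] = None
    amplitude_factor: float = 1.0
    slope_factor: float = 1.0
    block_lines: tuple[BlockLine, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.amplitude_factor <= 1.0):
            raise ParameterError("amplitude_factor must be in (0, 1]")
        if not (0.0 < self.slope_factor <= 1.0):
            raise ParameterError("slope_factor must be in (0, 1]")


@dataclass(frozen=True)
class WaveformParams:
    """Per-position electrogram synthesis parameters."""

    app_mv: float = 15.0
    sigma_ms: float = 10.0
    noise_sd_mv: float = 0.05
    baseline_amp_mv: float = 0.2
    baseline_freq_hz: float = 0.5
    pacing_bpm: float = 84.0
    pacing_artifact_mv: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.app_mv <= 0:
            raise ParameterError("app_mv must be > 0")
        if self.sigma_ms <= 0:
            raise ParameterError("sigma_ms must be > 0")
        if self.pacing_bpm < 70:
            raise ParameterError("pacing_bpm must be >= 70 (pacing floor)")


def ground_truth_lat(grid: ElectrodeGrid, act: ActivationModel) -> np.ndarray:
    """Ground-truth relative activation times (ms), earliest electrode at 0.

    Planar mode yields an affine surface with gradient magnitude 1/cv along
    ``direction_deg``; focal mode yields Euclidean distance from the origin
    electrode divided by cv. Block-line delays are applied separately by
    :func:`apply_block_lines`.
    """
    v_mm_ms = act.cv_cm_s * 0.01  # cm/s -> mm/ms
    r = np.arange(grid.rows)[:, None] * grid.pitch_mm
    c = np.arange(grid.cols)[None, :] * grid.pitch_mm
    if act.mode == "planar":
        theta = math.radians(act.direction_deg)
        proj = c * math.cos(theta) + r * math.sin(theta)
        lat = (proj - proj.min()) / v_mm_ms
        lat = lat + np.zeros((grid.rows, grid.cols))
    else:
        r0, c0 = act.origin_electrode
        dist = np.hypot(r - r0 * grid.pitch_mm, c - c0 * grid.pitch_mm)
        lat = dist / v_mm_ms
    return lat


def apply_block_lines(
    lat: np.ndarray, grid: ElectrodeGrid, lines: Sequence[BlockLine]
) -> tuple[np.ndarray, frozenset]:
    """Add each line's delay to its later-activated side.

    Returns the delayed LAT matrix and the set of ground-truth block pairs
    (all adjacent pairs crossing any line).
    """
    lat = lat.copy()
    pairs: set = set()
    for line in lines:
        if line.axis == "col":
            near, far = lat[:, : line.index], lat[:, line.index:]
        else:
            near, far = lat[: line.index, :], lat[line.index:, :]
        # delay accrues to whichever side the wavefront reaches second
        if far.min() >= near.min():
            far += line.delay_ms
        else:
            near += line.delay_ms
        pairs |= line.crossing_pairs(grid)
    return lat, frozenset(pairs)


def _deflection(t_ms: np.ndarray, t0_ms, k_mv_ms, sigma_ms) -> np.ndarray:
    u = t_ms - t0_ms
    return -k_mv_ms * u * np.exp(-(u * u) / (2.0 * sigma_ms * sigma_ms))


def synth_potential(
    wf: WaveformParams, lat_ms: float, n_samples: int, fs_hz: float
) -> np.ndarray:
    """One single-channel trace (mV) with a deflection centred at ``lat_ms``.

    The noise-free, wander-free trace has peak-to-peak amplitude ``app_mv``
    up to ADC quantization and its steepest negative first difference within
    one sample of ``lat_ms``.
    """
    duration_ms = 1000.0 * n_samples / fs_hz
    if not (0.0 <= lat_ms < duration_ms):
        raise ParameterError(f"lat_ms {lat_ms} outside trace span [0, {duration_ms})")
    t = np.arange(n_samples) * 1000.0 / fs_hz
    rng = np.random.default_rng(wf.seed)
    y = _deflection(t, lat_ms, deflection_scale(wf.app_mv, wf.sigma_ms), wf.sigma_ms)
    if wf.baseline_amp_mv > 0:
        phase = rng.uniform(0, 2 * math.pi)
        y = y + wf.baseline_amp_mv * np.sin(2 * math.pi * wf.baseline_freq_hz * t / 1000.0 + phase)
    if wf.noise_sd_mv > 0:
        y = y + rng.normal(0.0, wf.noise_sd_mv, n_samples)
    counts, scale = quantize_mv(y)
    return counts * scale


@dataclass
class GroundTruth:
    """Per-recording truth bundle used by recovery and consistency tests."""

    lat_rel_ms: np.ndarray           # [rows x cols], relative to beat onset
    amplitude_mv: np.ndarray         # [rows x cols] true peak-to-peak
    slope_v_s: np.ndarray            # [rows x cols] true steepest slope (<= 0)
    block_pairs: frozenset           # adjacent pairs crossing a block line
    cv_cm_s: float
    direction_deg: float
    stim_times_ms: np.ndarray
    beat_onsets_ms: np.ndarray       # stimulus + conduction latency

    def lat_abs_ms(self, beat_index: int) -> np.ndarray:
        return self.beat_onsets_ms[beat_index] + self.lat_rel_ms


def synth_recording(
    grid: ElectrodeGrid,
    act: ActivationModel,
    isch: IschemiaModel,
    wf: WaveformParams,
    *,
    heart_id: str = "H000",
    group_label: str = "unknown",
    position: Optional[MappingPosition] = None,
    duration_s: float = 5.0,
    fs_hz: float = 2000.0,
    amplitude_multipliers: Optional[np.ndarray] = None,
    activation_latency_ms: float = ACTIVATION_LATENCY_MS,
) -> tuple[Recording, GroundTruth]:
    """Synthesize one paced mapping-position recording plus its ground truth.

    ``amplitude_multipliers`` (default all ones) models per-electrode
    contact/substrate heterogeneity; it scales amplitude and slope jointly,
    leaving the deflection width unchanged. The ischemic patch scales
    amplitude by ``amplitude_factor`` and slope by
    ``amplitude_factor * slope_factor`` (widening the deflection by
    1/slope_factor).
    """
    shape = (grid.rows, grid.cols)
    mult = np.ones(shape) if amplitude_multipliers is None else np.asarray(amplitude_multipliers, float)
    if mult.shape != shape:
        raise ParameterError(f"amplitude_multipliers shape {mult.shape} != grid {shape}")
    mask = isch.patch_mask
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != shape:
            raise ParameterError(f"patch_mask shape {mask.shape} != grid {shape}")
    else:
        mask = np.zeros(shape, bool)

    lat_rel, block_pairs = apply_block_lines(ground_truth_lat(grid, act), grid, isch.block_lines)

    amp = wf.app_mv * mult * np.where(mask, isch.amplitude_factor, 1.0)
    slope_mag = deflection_scale(wf.app_mv, wf.sigma_ms) * mult * np.where(
        mask, isch.amplitude_factor * isch.slope_factor, 1.0
    )
    sigma = amp * math.exp(0.5) / (2.0 * slope_mag)  # = sigma_ms / slope_factor in patch

    n_samples = round(fs_hz * duration_s)
    duration_ms = 1000.0 * n_samples / fs_hz
    t = np.arange(n_samples) * 1000.0 / fs_hz
    dt_ms = 1000.0 / fs_hz
    interval_ms = 60000.0 / wf.pacing_bpm
    stim = np.arange(0.0, duration_ms - 1e-9, interval_ms)
    # onset clears the post-stimulus blanking plus one deflection width so
    # neither extremum of any deflection falls inside the blanked interval
    latency = activation_latency_ms + float(sigma.max())
    onsets = stim + latency

    rng = np.random.default_rng(wf.seed)
    n_ch = grid.n_channels
    y = np.zeros((n_ch, n_samples))
    if wf.baseline_amp_mv > 0:
        phases = rng.uniform(0, 2 * math.pi, n_ch)
        y += wf.baseline_amp_mv * np.sin(
            2 * math.pi * wf.baseline_freq_hz * t[None, :] / 1000.0 + phases[:, None]
        )
    if wf.pacing_artifact_mv > 0:
        tau = 1.0  # ms
        for ts in stim:
            i0 = max(0, int((ts - 5 * tau) / dt_ms))
            i1 = min(n_samples, int((ts + 5 * tau) / dt_ms) + 1)
            u = (t[i0:i1] - ts) / tau
            y[:, i0:i1] += wf.pacing_artifact_mv * math.exp(0.5) * u * np.exp(-u * u / 2.0)

    k_flat = slope_mag.ravel()[:, None]
    sig_flat = sigma.ravel()[:, None]
    lat_flat = lat_rel.ravel()
    sig_max = float(sigma.max())
    for onset in onsets:
        t0 = onset + lat_flat
        i0 = max(0, int((t0.min() - 6 * sig_max) / dt_ms))
        i1 = min(n_samples, int((t0.max() + 6 * sig_max) / dt_ms) + 1)
        if i1 <= i0:
            continue
        u = t[None, i0:i1] - t0[:, None]
        y[:, i0:i1] += -k_flat * u * np.exp(-(u * u) / (2.0 * sig_flat * sig_flat))

    if wf.noise_sd_mv > 0:
        y += rng.normal(0.0, wf.noise_sd_mv, y.shape)

    counts, scale = quantize_mv(y)
    rec = Recording(
        heart_id=heart_id,
        group_label=group_label,
        position=position or MappingPosition("RV", "anterior", 0),
        grid=grid,
        samples=counts * scale,
        fs_hz=fs_hz,
        duration_s=duration_s,
        pacing_times_ms=stim,
        scale_mv_per_count=scale,
    )
    gt = GroundTruth(
        lat_rel_ms=lat_rel,
        amplitude_mv=amp,
        slope_v_s=-slope_mag,
        block_pairs=block_pairs,
        cv_cm_s=act.cv_cm_s,
        direction_deg=act.direction_deg,
        stim_times_ms=stim,
        beat_onsets_ms=onsets,
    )
    return rec, gt


def simulate_perfusate(
    start_mmol_l: float,
    trend_um_min: float,
    times_min: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    heart_id: str = "H000",
    site: str = "arterial",
    potassium_mmol_l: float = 4.5,
) -> list[PerfusateSample]:
    """Linear lactate series: ``start`` at the first time, slope in uM/min.

    With ``noise_sd == 0`` the series is exactly linear. Electrolytes and pH
    are physiological constants with the same noise scale applied.
    """
    times = np.asarray(times_min, dtype=float)
    if times.size == 0:
        raise ParameterError("times_min must be non-empty")
    if np.any(np.diff(times) <= 0):
        raise ParameterError("times_min must be strictly increasing")
    rng = np.random.default_rng(seed)
    lact = start_mmol_l + trend_um_min / 1000.0 * (times - times[0])
    if noise_sd > 0:
        lact = lact + rng.normal(0.0, noise_sd, times.size)
    lact = np.maximum(lact, 0.0)
    out = []
    for t, c in zip(times, lact):
        jitter = (lambda s: rng.normal(0.0, s)) if noise_sd > 0 else (lambda s: 0.0)
        out.append(
            PerfusateSample(
                heart_id=heart_id,
                time_min=float(t),
                site=site,
                lactate_mmol_l=float(c),
                potassium_mmol_l=potassium_mmol_l + jitter(0.2),
                sodium_mmol_l=140.0 + jitter(1.5),
                calcium_mmol_l=1.1 + jitter(0.05),
                glucose_mmol_l=7.0 + jitter(0.3),
                ph=7.38 + jitter(0.02),
            )
        )
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the simulated two-group cohort.

    Defaults encode the severe- vs. mild-ischemia contrast: per-ventricle
    group voltage and slope medians, conduction-velocity range, lactate
    kinetics, and the per-heart/per-electrode dispersion model.
    """

    n_per_group: int = 4
    # per-ventricle group medians (mV, V/s magnitude)
    group1_rv_voltage_mv: float = 3.6
    group1_lv_voltage_mv: float = 10.8
    group2_rv_voltage_mv: float = 15.3
    group2_lv_voltage_mv: float = 23.6
    group1_rv_slope_v_s: float = 0.2
    group1_lv_slope_v_s: float = 0.3
    group2_rv_slope_v_s: float = 1.2
    group2_lv_slope_v_s: float = 1.1
    cv_range_cm_s: tuple[float, float] = (60.0, 100.0)
    # arterial lactate kinetics (first sample 20 min after reperfusion)
    group1_lactate_start_mmol_l: float = 9.0
    group2_lactate_start_mmol_l: float = 8.0
    lactate_start_sd_mmol_l: float = 1.5
    group1_lactate_trend_um_min: float = -24.0
    group2_lactate_trend_um_min: float = -36.0
    group1_lactate_trend_sd: float = 6.0
    group2_lactate_trend_sd: float = 14.0
    lactate_noise_sd_mmol_l: float = 0.1
    # sampling design
    positions_per_ventricle: int = 3
    duration_s: float = 5.0
    fs_hz: float = 2000.0
    pacing_bpm: float = 84.0
    noise_sd_mv: float = 0.05
    baseline_amp_mv: float = 0.2
    # dispersion: symmetric per-heart severity factors + per-electrode
    # log-normal contact heterogeneity (median-normalized)
    heart_factors: tuple[float, ...] = (0.75, 0.95, 1.05, 1.3)
    electrode_sigma_ln: float = 0.25
    # Group 1 pathology
    patch_amplitude_factor: float = 0.25
    patch_slope_factor: float = 0.5
    block_delay_ms: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ParameterError("n_per_group must be >= 1")
        for name in ("group1_rv_voltage_mv", "group1_lv_voltage_mv",
                     "group2_rv_voltage_mv", "group2_lv_voltage_mv",
                     "group1_rv_slope_v_s", "group1_lv_slope_v_s",
                     "group2_rv_slope_v_s", "group2_lv_slope_v_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if len(self.heart_factors) < self.n_per_group:
            raise ParameterError("need at least n_per_group heart_factors")

    def voltage_median(self, group: str, ventricle: str) -> float:
        return getattr(self, f"{group}_{ventricle.lower()}_voltage_mv")

    def slope_median(self, group: str, ventricle: str) -> float:
        return getattr(self, f"{group}_{ventricle.lower()}_slope_v_s")


@dataclass
class HeartData:
    """All simulated data for one heart."""

    heart_id: str
    group: str
    recordings: list  # list of (Recording, GroundTruth)
    perfusate: list   # PerfusateSample (arterial + venous)
    contractility: list  # ContractilityScore
    target_voltage_mv: dict  # ventricle -> per-heart target median


@dataclass
class CohortBundle:
    spec: CohortSpec
    hearts: list

    def iter_recordings(self) -> Iterable:
        for h in self.hearts:
            for rec, gt in h.recordings:
                yield h, rec, gt


REGION_CYCLE = ("anterior", "lateral", "posterior")


def _contractility_score(voltage_mv: float) -> float:
    """Monotone map from per-ventricle median voltage to a 1-5 visual score."""
    return float(np.clip(1.0 + 3.5 * (voltage_mv - 2.0) / 23.0, 1.0, 5.0))


def simulate_cohort(spec: CohortSpec) -> CohortBundle:
    """Simulate the full two-group cohort with ground truth.

    Per-heart voltage targets are the group median times a symmetric factor
    set (median factor product = 1), so each group's median-of-heart-medians
    equals the configured group median by construction. Group 1 hearts carry an ischemic
    patch and one block line per position; Group 2 hearts conduct cleanly.
    Deterministic for a fixed spec (all randomness derives from
    ``spec.seed``).
    """
    root = np.random.SeedSequence(spec.seed)
    hearts: list[HeartData] = []
    times_min = np.arange(20.0, 121.0, 20.0)

    # one child sequence per heart, plus one for group-factor assignment
    children = root.spawn(2 * spec.n_per_group + 2)
    factor_rng = np.random.default_rng(children[-2])
    hearts_idx = 0
    for group in ("group1", "group2"):
        factors = factor_rng.permutation(np.asarray(spec.heart_factors[: spec.n_per_group]))
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(children[hearts_idx])
            heart_id = f"{'G1' if group == 'group1' else 'G2'}H{i + 1}"
            factor = float(factors[i])
            recordings = []
            targets = {}
            for ventricle in ("RV", "LV"):
                target_v = spec.voltage_median(group, ventricle) * factor
                target_s = spec.slope_median(group, ventricle) * factor
                targets[ventricle] = target_v
                sigma_ms = sigma_for(target_v, target_s)
                for p in range(spec.positions_per_ventricle):
                    region = REGION_CYCLE[p % len(REGION_CYCLE)]
                    act = ActivationModel(
                        mode="planar",
                        cv_cm_s=float(rng.uniform(*spec.cv_range_cm_s)),
                        direction_deg=float(rng.uniform(0.0, 360.0)),
                    )
                    grid = ElectrodeGrid()
                    if group == "group1":
                        # 4x5 ischemic patch (~17% of electrodes): large enough
                        # to dominate the low-voltage tail, small enough to
                        # leave the pooled group median at its target
                        mask = np.zeros((grid.rows, grid.cols), bool)
                        r0 = int(rng.integers(0, grid.rows - 3))
                        c0 = int(rng.integers(0, grid.cols - 4))
                        mask[r0:r0 + 4, c0:c0 + 5] = True
                        isch = IschemiaModel(
                            patch_mask=mask,
                            amplitude_factor=spec.patch_amplitude_factor,
                            slope_factor=spec.patch_slope_factor,
                            block_lines=(
                                BlockLine("col", int(rng.integers(3, grid.cols - 2)),
                                          spec.block_delay_ms),
                            ),
                        )
                    else:
                        isch = IschemiaModel()
                    mult = np.exp(rng.normal(0.0, spec.electrode_sigma_ln,
                                             (grid.rows, grid.cols)))
                    # calibrate so the median *true* amplitude (patch included)
                    # equals the per-heart target
                    eff = mult * np.where(
                        isch.patch_mask if isch.patch_mask is not None else False,
                        isch.amplitude_factor, 1.0,
                    )
                    mult = mult / np.median(eff)
                    wf = WaveformParams(
                        app_mv=target_v,
                        sigma_ms=sigma_ms,
                        noise_sd_mv=spec.noise_sd_mv,
                        baseline_amp_mv=spec.baseline_amp_mv,
                        pacing_bpm=spec.pacing_bpm,
                        seed=int(rng.integers(0, 2 ** 31)),
                    )
                    rec, gt = synth_recording(
                        grid, act, isch, wf,
                        heart_id=heart_id,
                        group_label=group,
                        position=MappingPosition(ventricle, region, p),
                        duration_s=spec.duration_s,
                        fs_hz=spec.fs_hz,
                        amplitude_multipliers=mult,
                    )
                    recordings.append((rec, gt))

            # perfusate: arterial linear lactate + venous with uptake offset
            start = max(5.0, float(rng.normal(
                spec.group1_lactate_start_mmol_l if group == "group1"
                else spec.group2_lactate_start_mmol_l,
                spec.lactate_start_sd_mmol_l)))
            trend = min(-5.0, float(rng.normal(
                spec.group1_lactate_trend_um_min if group == "group1"
                else spec.group2_lactate_trend_um_min,
                spec.group1_lactate_trend_sd if group == "group1"
                else spec.group2_lactate_trend_sd)))
            potassium = 6.5 if group == "group1" else 4.5
            arterial = simulate_perfusate(
                start, trend, times_min, spec.lactate_noise_sd_mmol_l,
                seed=int(rng.integers(0, 2 ** 31)), heart_id=heart_id,
                site="arterial", potassium_mmol_l=potassium)
            venous = [
                replace(s, site="venous",
                        lactate_mmol_l=max(0.0, s.lactate_mmol_l - 0.2))
                for s in arterial
            ]

            # contractility: monotone in the heart's voltage targets + rater jitter
            score_rv = _contractility_score(targets["RV"])
            score_lv = _contractility_score(targets["LV"])
            score_whole = 0.5 * (score_rv + score_lv)
            contractility = []
            for rater in ("R1", "R2", "R3"):
                def draw(s: float) -> int:
                    return int(np.clip(round(s + rng.normal(0.0, 0.35)), 1, 5))
                sw = draw(score_whole)
                contractility.append(
                    ContractilityScore(
                        heart_id=heart_id, rater_id=rater,
                        score_whole=sw, score_lv=draw(score_lv),
                        score_rv=draw(score_rv), transplantable=sw >= 3,
                    )
                )
            hearts.append(HeartData(heart_id, group, recordings,
                                    arterial + venous, contractility, targets))
            hearts_idx += 1
    return CohortBundle(spec=spec, hearts=hearts)
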