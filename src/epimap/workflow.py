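"""End-to-end cohort analysis: recordings -> potentials -> summaries -> stats.

Thin orchestration over the analysis modules, used by the CLI and by batch
scripts. Each step is also usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import annotation, conduction, stats, substrate
from .recording import Recording
from .synthetic import CohortBundle


@dataclass
class PositionConduction:
    """Pooled conduction products of one recording (all beats)."""

    heart_id: str
    ventricle: str
    cv_cm_s: np.ndarray
    block_flags: np.ndarray


def analyze_position(
    rec: Recording,
    potentials: Optional[Sequence[annotation.UnipolarPotential]] = None,
    block_threshold_ms: float = conduction.BLOCK_THRESHOLD_MS,
) -> tuple[list, PositionConduction]:
    """Annotate one recording and pool its per-beat conduction products."""
    if potentials is None:
        potentials = annotation.annotate_recording(rec)
    cv_all: list[float] = []
    flags_all: list[bool] = []
    beats = sorted({p.beat_index for p in potentials})
    for b in beats:
        latmap = conduction.build_lat_map(potentials, b, rec.grid)
        cts = conduction.conduction_times(latmap)
        if not len(cts):
            continue
        block = conduction.detect_block(cts, block_threshold_ms)
        cv = conduction.estimate_cv(latmap, rec.grid.pitch_mm, block)
        cv_all.extend(cv.magnitudes().tolist())
        flags_all.extend(bool(f) for f in block.block_flags)
    return list(potentials), PositionConduction(
        heart_id=rec.heart_id,
        ventricle=rec.position.ventricle,
        cv_cm_s=np.asarray(cv_all, float),
        block_flags=np.asarray(flags_all, bool),
    )


@dataclass
class CohortAnalysis:
    potentials: list
    thresholds: dict            # ventricle -> LowVoltageThreshold
    summaries: list             # HeartSummary per heart/ventricle
    groups: dict                # heart_id -> group label
    comparisons: list
    comparison_table: pd.DataFrame
    heart_variables: pd.DataFrame
    correlations: list
    correlation_r: pd.DataFrame


def analyze_cohort(bundle: CohortBundle, correlate: bool = True) -> CohortAnalysis:
    """Run the full pipeline on a simulated cohort bundle."""
    potentials_by_heart: dict[str, list] = {}
    conduction_by_heart: dict[tuple[str, str], list[PositionConduction]] = {}
    groups: dict[str, str] = {}
    for heart in bundle.hearts:
        groups[heart.heart_id] = heart.group
        for rec, _gt in heart.recordings:
            pots, cond = analyze_position(rec)
            potentials_by_heart.setdefault(heart.heart_id, []).extend(pots)
            conduction_by_heart.setdefault((heart.heart_id, cond.ventricle), []).append(cond)

    all_potentials = [p for ps in potentials_by_heart.values() for p in ps]
    thresholds = {}
    for ventricle in ("RV", "LV"):
        amps = [p.voltage_mv for p in all_potentials
                if p.quality_flag == "ok" and p.position.ventricle == ventricle]
        if len(amps) >= 20:
            thresholds[ventricle] = substrate.low_voltage_threshold(amps, ventricle)

    summaries = []
    for heart in bundle.hearts:
        for ventricle in ("RV", "LV"):
            conds = conduction_by_heart.get((heart.heart_id, ventricle), [])
            cv = np.concatenate([c.cv_cm_s for c in conds]) if conds else None
            flags = np.concatenate([c.block_flags for c in conds]) if conds else None
            summaries.append(
                substrate.heart_summary(
                    heart.heart_id, ventricle,
                    potentials_by_heart.get(heart.heart_id, []),
                    thresholds.get(ventricle), cv, flags,
                )
            )

    comparisons, table = stats.group_compare_table(summaries, groups)

    variables = heart_variable_table(bundle, summaries)
    correlations: list = []
    rmat = pd.DataFrame()
    if correlate and len(variables) >= 3:
        correlations, rmat = stats.correlation_matrix(
            variables.drop(columns=["group"]))

    return CohortAnalysis(
        potentials=all_potentials,
        thresholds=thresholds,
        summaries=summaries,
        groups=groups,
        comparisons=comparisons,
        comparison_table=table,
        heart_variables=variables,
        correlations=correlations,
        correlation_r=rmat,
    )


def heart_variable_table(bundle: CohortBundle, summaries: Sequence) -> pd.DataFrame:
    """One row per heart: lactate levels/trend, contractility, EP summaries."""
    by_hv = {(s.heart_id, s.ventricle): s for s in summaries}
    rows = []
    for heart in bundle.hearts:
        arterial = [s for s in heart.perfusate if s.site == "arterial"]
        trend = stats.lactate_trend(arterial) if len(arterial) >= 2 else None
        lact = {round(s.time_min): s.lactate_mmol_l for s in arterial}
        contr = pd.DataFrame([vars(c) for c in heart.contractility])
        row = {
            "heart_id": heart.heart_id,
            "group": heart.group,
            "lactate_20min": lact.get(20, np.nan),
            "lactate_60min": lact.get(60, np.nan),
            "lactate_trend_um_min": trend.slope_um_min if trend else np.nan,
            "contractility_whole": contr["score_whole"].mean(),
            "contractility_rv": contr["score_rv"].mean(),
            "contractility_lv": contr["score_lv"].mean(),
        }
        for ventricle in ("RV", "LV"):
            s = by_hv.get((heart.heart_id, ventricle))
            v = ventricle.lower()
            row[f"{v}_voltage_mv"] = s.median_voltage_mv if s else np.nan
            row[f"{v}_slope_v_s"] = -s.median_slope_v_s if s else np.nan
            row[f"{v}_low_voltage_pct"] = s.pct_low_voltage if s else np.nan
            row[f"{v}_cv_cm_s"] = s.median_cv_cm_s if s else np.nan
            row[f"{v}_block_pct"] = s.pct_block if s else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("heart_id")
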