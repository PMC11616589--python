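import numpy as np
import pytest

import epimap as em
from epimap.annotation import UnipolarPotential
from epimap.recording import MappingPosition


@pytest.fixture(scope="session")
def grid():
    return em.ElectrodeGrid()


@pytest.fixture(scope="session")
def planar_recording(grid):
    """Noise-free planar wave along the column axis at 80 cm/s."""
    act = em.ActivationModel(mode="planar", cv_cm_s=80.0, direction_deg=0.0)
    wf = em.WaveformParams(app_mv=15.3, noise_sd_mv=0.0, baseline_amp_mv=0.0, seed=7)
    rec, gt = em.synth_recording(grid, act, em.IschemiaModel(), wf)
    return rec, gt


@pytest.fixture(scope="session")
def planar_potentials(planar_recording):
    rec, gt = planar_recording
    return em.annotate_recording(rec)


def make_potential(
    electrode=(0, 0),
    beat_index=0,
    lat_ms=100.0,
    voltage_mv=10.0,
    slope_v_s=-1.0,
    flag="ok",
    ventricle="RV",
    heart_id="H1",
):
    return UnipolarPotential(
        heart_id=heart_id,
        position=MappingPosition(ventricle, "anterior", 0),
        electrode=electrode,
        beat_index=beat_index,
        lat_ms=lat_ms,
        voltage_mv=voltage_mv,
        slope_v_s=slope_v_s,
        quality_flag=flag,
    )
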