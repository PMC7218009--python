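"""Shared fixtures: a desk-scale motor unit, calibrated once per session.

The study profile used throughout the suite is a 4-stem synthetic arbor
discretized at 0.2 lambda with ramp runs at dt = 0.05 ms — small enough
that the full (D_path, X_m) sweeps complete quickly, while preserving the
cat-motoneuron electrotonic range that the hot-spot grid requires.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from picloop.config import RunConfig, SyntheticMorphology, cmd_calibrate, cmd_sweep

settings.register_profile(
    "ci", max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")

DPATH_GRID = [round(0.1 * i, 1) for i in range(1, 11)]
XM_GRID = [-16.0, -8.0, 0.0]
RAMP_DT = 0.05


@pytest.fixture(scope="session")
def desk_config():
    return RunConfig(
        synthetic=SyntheticMorphology(n_stems=4, branch_depth=2, seed=1),
        max_electrotonic_segment=0.2,
        d_path=0.6,
    )


@pytest.fixture(scope="session")
def calibrated(desk_config):
    """Fully calibrated desk-scale closed-loop model (all four routines)."""
    return cmd_calibrate(desk_config)


@pytest.fixture(scope="session")
def somatic_sweep(calibrated, desk_config):
    return cmd_sweep(calibrated, desk_config, DPATH_GRID, XM_GRID,
                     "somatic_ramp", dt=RAMP_DT)


@pytest.fixture(scope="session")
def dendritic_sweep(calibrated, desk_config):
    return cmd_sweep(calibrated, desk_config, DPATH_GRID, XM_GRID,
                     "dendritic_ramp", dt=RAMP_DT)


@pytest.fixture(scope="session")
def warmup_grid(calibrated):
    """Warm-up flags for (mode, D_path, X_m) over the tested grid."""
    from picloop import analysis, morphology, protocols

    model = calibrated.model
    out = {}
    for mode in ("warmup_somatic", "warmup_dendritic"):
        for dp in (0.6, 0.8, 1.0):
            band = morphology.select_band(model.tree, dp, 0.1, model.spec.passive)
            protocols.calibrate_gcal(model, band, 22.0)
            for xm in (-16.0, -8.0, 0.0):
                proto = protocols.ProtocolSpec(mode=mode, x_m=xm, d_path=dp)
                traces, _ = protocols.run_warmup(
                    model, proto, calibrated.anchors, calibrated.muscle, dt=RAMP_DT)
                trials = analysis.split_warmup_trials(traces, proto)
                rep = analysis.warmup_metrics(trials)
                out[(mode, dp, xm)] = rep
    return out
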