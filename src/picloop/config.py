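"""Run configuration, orchestration and fixtures.

``RunConfig`` is the validated description of a study: morphology source,
discretization, hot-spot band, muscle length, protocol and calibration
targets.  ``cmd_calibrate`` runs the calibration chain in dependency order
and returns a manifest that later runs consume; ``cmd_sweep`` maps the
(D_path, X_m) grid to one ramp run + index report per cell.  All outputs
are plain CSV/JSON for diffability; every run is deterministic given the
config (morphology generation is the only seeded element).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import analysis, cable, morphology, protocols, spindle
from .biophysics import MembraneSpec
from .errors import EmptyBandError, ParameterError
from .muscle import MuscleParams


class SyntheticMorphology(BaseModel):
    n_stems: int = 10
    max_path: float = 1.8
    stem_diam: float = 13.0
    taper: float = 0.3
    branch_depth: int = 3
    seed: int = 1


class RunConfig(BaseModel):
    """Validated configuration for calibration, ramp and sweep runs."""

    swc_path: Optional[str] = None
    synthetic: SyntheticMorphology = Field(default_factory=SyntheticMorphology)
    max_electrotonic_segment: float = 0.1
    d_path: float = 0.6           # mm, band center
    halfwidth: float = 0.1        # mm
    x_m: float = -8.0             # mm
    mode: Literal["somatic_ramp", "dendritic_ramp", "warmup_somatic",
                  "warmup_dendritic"] = "somatic_ramp"
    dt: float = 0.025             # ms
    gcal_target: float = 22.0     # nA effective calcium current
    gaff_targets: tuple[float, float, float] = (0.0, 2.5, 5.0)
    gaff_lengths: tuple[float, float, float] = (-16.0, -8.0, 0.0)
    gsyn_target: float = 16.0     # nA peak I_N
    ahp_twitch_target: float = 250.0  # ms
    out_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check(self):
        if not (-16.0 <= self.x_m <= 0.0):
            raise ValueError("x_m must lie in [-16, 0] mm")
        if self.dt <= 0 or self.halfwidth <= 0:
            raise ValueError("dt and halfwidth must be positive")
        return self

    def build_tree(self) -> morphology.NeuriteTree:
        if self.swc_path:
            return morphology.load_swc(self.swc_path)
        s = self.synthetic
        return morphology.generate_synthetic_tree(
            n_stems=s.n_stems, max_path=s.max_path, stem_diam=s.stem_diam,
            taper=s.taper, branch_depth=s.branch_depth, seed=s.seed,
        )


@dataclasses.dataclass
class CalibratedModel:
    """A discretized model plus everything the protocols need."""

    model: cable.CompartmentalModel
    band: morphology.SiteSet
    anchors: list
    muscle: MuscleParams
    manifest: dict


def cmd_calibrate(config: RunConfig, spec: MembraneSpec | None = None,
                  muscle: MuscleParams | None = None,
                  calibrate_speed: bool = True) -> CalibratedModel:
    """Run the calibration chain and return the ready-to-stimulate model.

    Order: AHP/twitch speed coupling, PIC conductance for the configured
    band, spindle anchors, dendritic-drive peak.  The manifest records each
    calibrated value with its achieved target and residual.
    """
    tree = config.build_tree()
    spec = spec or MembraneSpec()
    muscle = muscle or MuscleParams()
    model = cable.discretize(tree, spec, config.max_electrotonic_segment)
    band = morphology.select_band(tree, config.d_path, config.halfwidth, spec.passive)
    spindle.place_afferents(tree, model)

    reports = []
    if calibrate_speed:
        _, muscle, speed_reports = protocols.calibrate_ahp_twitch(
            model, muscle, target=config.ahp_twitch_target)
        reports += speed_reports
    rep_cal = protocols.calibrate_gcal(model, band, target=config.gcal_target)
    reports.append(rep_cal)
    anchors, rep_aff = protocols.calibrate_gaff(
        model, config.gaff_lengths, config.gaff_targets)
    reports += rep_aff
    rep_syn = protocols.calibrate_gsyn_peak(model, band, target=config.gsyn_target)
    reports.append(rep_syn)

    from . import __version__

    manifest = {
        "version": __version__,
        "d_path": config.d_path,
        "halfwidth": config.halfwidth,
        "mean_electrotonic_length": band.mean_electrotonic_length,
        "gsyn_peak": rep_syn.value,
        "anchors": anchors,
        "muscle_tau_uptake": muscle.tau_uptake,
        "ca_pool_tau": model.spec.ca_pool.tau,
        "reports": [dataclasses.asdict(r) | {"residual": r.residual} for r in reports],
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "calibration.json").write_text(json.dumps(manifest, indent=2))
        (out / "config.json").write_text(config.model_dump_json(indent=2))
    return CalibratedModel(model=model, band=band, anchors=anchors,
                           muscle=muscle, manifest=manifest)


def run_cell(cal: CalibratedModel, config: RunConfig,
             d_path: float, x_m: float, mode: str,
             dt: float | None = None) -> dict:
    """One ramp run + index report for a (D_path, X_m, mode) grid cell."""
    model, tree = cal.model, cal.model.tree
    band = morphology.select_band(tree, d_path, config.halfwidth,
                                  model.spec.passive)
    rep = protocols.calibrate_gcal(model, band, target=config.gcal_target)
    proto = protocols.ProtocolSpec(mode=mode, x_m=x_m, d_path=d_path,
                                   halfwidth=config.halfwidth)
    rep_syn = None
    if mode == "dendritic_ramp":
        rep_syn = protocols.calibrate_gsyn_peak(model, band,
                                                target=config.gsyn_target)
        proto.peak_gsyn = rep_syn.value
    traces, force = protocols.run_ramp(model, proto, cal.anchors, cal.muscle,
                                       dt=dt or config.dt)
    io = analysis.build_io_curve(
        traces, traces.channels["force"],
        mode="somatic" if mode == "somatic_ramp" else "dendritic",
        i_n_peak=None if rep_syn is None else rep_syn.achieved,
    )
    idx = analysis.compute_indices(io)
    return {
        "d_path": d_path, "x_m": x_m, "mode": mode,
        "lambda_mean": band.mean_electrotonic_length,
        "g_cal": rep.value,
        "recruitment": idx.recruitment, "derecruitment": idx.derecruitment,
        "pic_onset": idx.pic_onset,
        "force_initiation": idx.force_initiation,
        "force_cessation": idx.force_cessation,
        "dct": idx.dct, "dci": idx.dci, "dfg": idx.dfg,
        "firing_type": idx.firing_type,
    }


def cmd_sweep(cal: CalibratedModel, config: RunConfig,
              dpath_grid: Sequence[float], xm_grid: Sequence[float],
              mode: str = "somatic_ramp", dt: float | None = None) -> pd.DataFrame:
    """Index reports over the (D_path, X_m) grid; one row per cell.

    Failed cells are flagged in the ``error`` column and the sweep
    continues.  Deterministic: repeating a sweep reproduces it exactly.
    """
    rows = []
    for d_path in dpath_grid:
        for x_m in xm_grid:
            try:
                rows.append(run_cell(cal, config, d_path, x_m, mode, dt=dt))
            except EmptyBandError as exc:
                rows.append({"d_path": d_path, "x_m": x_m, "mode": mode,
                             "error": str(exc)})
    df = pd.DataFrame(rows)
    if config.out_dir:
        import hashlib

        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"sweep_{mode}.csv", index=False)
        digest = hashlib.sha256(
            json.dumps(cal.manifest, sort_keys=True, default=str).encode()
        ).hexdigest()
        (out / "provenance.json").write_text(json.dumps({
            "config": json.loads(config.model_dump_json()),
            "calibration_manifest_sha256": digest,
            "version": cal.manifest.get("version"),
        }, indent=2))
    return df


def make_fixtures(seed: int, out_dir) -> dict:
    """Emit tiny deterministic inputs for unit tests.

    A 3-point straight-dendrite SWC, a constructed hysteretic IO curve (CSV
    with its embedded DCT/DCI labels) and a 10 Hz spike train.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    swc = out / "straight.swc"
    swc.write_text(
        "# three-point straight dendrite\n"
        "1 1 0 0 0 24.4 -1\n"
        "2 3 50 0 0 1.0 1\n"
        "3 3 100 0 0 1.0 2\n"
    )
    stim = np.round(np.arange(0.0, 12.0 + 1e-9, 0.05), 10)
    init, cess, s63 = 6.0, 2.0, 10.0
    f_asc = np.clip((stim - init) / (s63 - init) * 0.63, 0.0, 1.0)
    f_desc = np.clip((stim - cess) / (s63 - cess) * 0.8, 0.0, 1.0)
    io = pd.DataFrame({"stim": stim, "force_asc": f_asc, "force_desc": f_desc})
    io.attrs["dct"] = init - cess
    io_path = out / "hysteretic_io.csv"
    io.to_csv(io_path, index=False)
    train = np.arange(0.0, 2000.0, 100.0)
    np.savetxt(out / "spikes_10hz.txt", train, fmt="%.3f")
    return {"swc": swc, "io_curve": io_path, "spikes": out / "spikes_10hz.txt",
            "dct": init - cess, "dci": s63 - init}
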