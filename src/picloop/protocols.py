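"""Stimulation protocols and calibration routines.

Protocols (triangular somatic current, triangular dendritic conductance,
repeated somatic triangles and sinusoidal afferent drive for warm-up) are
generated as fixed-step waveforms and run on the closed-loop model: the
motoneuron is integrated, its somatic spikes are forwarded to the muscle
unit with the 10 ms efferent conduction delay, and the isometric force at
the protocol's muscle length is appended to the trace set.

Calibrations pin the model's free parameters to their physiological
constraints by monotone bracketing + bisection:

* ``calibrate_gcal``   — Cav1.3 density per hot-spot band such that the
  leak-subtracted peak inward clamp deflection during a slow somatic
  voltage ramp (-70 → -30 mV over 5 s, Cav1.3 the only active channel)
  equals the effective calcium current target of 22 nA;
* ``calibrate_gaff``   — spindle conductance density per length anchor such
  that the effective synaptic current I_N at the clamped soma equals
  0 / 2.5 / 5 nA at X_m = -16 / -8 / 0 mm;
* ``calibrate_gsyn_peak`` — peak of the triangular dendritic test
  conductance such that max I_N = 16 nA on passive dendrites;
* ``calibrate_ahp_twitch`` — somatic Ca-pool removal constant and muscle
  Ca-uptake constant such that AHP duration and twitch duration are
  speed-coupled at ~250 ms (slow motor unit) at the optimal length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from . import cable
from .biophysics import MembraneSpec
from .cable import CompartmentalModel, TraceSet
from .errors import CalibrationError, ParameterError, StateError
from .muscle import MuscleParams, simulate_muscle, twitch_metrics
from .spindle import AFFERENT_DELAY_MS, gaff_of_length

EFFERENT_DELAY_MS = 10.0

Mode = Literal["somatic_ramp", "dendritic_ramp", "warmup_somatic", "warmup_dendritic"]


@dataclass
class ProtocolSpec:
    """A stimulation protocol in one of the four standard modes.

    Defaults follow the reference protocols: somatic triangle peaking at
    20 nA at 5 s; dendritic G_syn triangle peaking at 10 s (peak amplitude
    from calibration, reference 1.2 mS/cm²); somatic warm-up triangles
    -5 → 10 nA over 2 s repeated 4× with 1 s gaps (the -5 nA floor is held
    between triangles); dendritic warm-up sinusoidal G_aff with 2 s period
    over 16 s with a -1 → -0.5 nA somatic step at 4 s under QX-314 block.
    """

    mode: Mode = "somatic_ramp"
    x_m: float = -8.0              # mm
    d_path: float = 0.6            # mm, band center
    halfwidth: float = 0.1         # mm
    peak_is: float = 20.0          # nA (somatic ramp)
    peak_time: float = 5000.0      # ms
    peak_gsyn: float = 1.2         # mS/cm² (dendritic ramp; recalibrated per cell)
    gsyn_peak_time: float = 10000.0
    tri_start: float = -5.0        # nA (somatic warm-up)
    tri_peak: float = 10.0
    tri_period: float = 2000.0     # ms
    tri_count: int = 4
    tri_gap: float = 1000.0        # ms
    sin_period: float = 2000.0     # ms (dendritic warm-up)
    sin_cycles: int = 8
    step_levels: tuple = (-1.0, -0.5)  # nA
    step_switch: float = 4000.0    # ms
    qx314: bool = False
    settle: float = 1000.0         # ms of pre-protocol settling

    def __post_init__(self):
        if self.qx314 and self.mode != "warmup_dendritic":
            raise ParameterError("QX-314 block applies only to warmup_dendritic")
        if self.mode == "warmup_dendritic":
            self.qx314 = True

    @property
    def duration(self) -> float:
        if self.mode == "somatic_ramp":
            return 2.0 * self.peak_time
        if self.mode == "dendritic_ramp":
            return 2.0 * self.gsyn_peak_time
        if self.mode == "warmup_somatic":
            return self.tri_count * self.tri_period + (self.tri_count - 1) * self.tri_gap
        return self.sin_cycles * self.sin_period

    def is_waveform(self, t: np.ndarray) -> np.ndarray:
        """Somatic current (nA) at times ``t`` (ms)."""
        if self.mode == "somatic_ramp":
            up = t / self.peak_time
            return self.peak_is * np.clip(np.where(t <= self.peak_time, up, 2.0 - up), 0.0, 1.0)
        if self.mode == "warmup_somatic":
            cyc = self.tri_period + self.tri_gap
            ph = np.mod(t, cyc)
            tri = np.where(
                ph <= self.tri_period,
                1.0 - np.abs(ph - self.tri_period / 2.0) / (self.tri_period / 2.0),
                0.0,
            )
            # last triangle has no trailing gap
            tri = np.where(t >= self.duration, 0.0, tri)
            return self.tri_start + (self.tri_peak - self.tri_start) * tri
        if self.mode == "warmup_dendritic":
            return np.where(t < self.step_switch, self.step_levels[0], self.step_levels[1])
        return np.zeros_like(t)

    def gsyn_waveform(self, t: np.ndarray) -> np.ndarray:
        """Dendritic test-synapse density (mS/cm²) at times ``t``."""
        if self.mode != "dendritic_ramp":
            return np.zeros_like(t)
        up = t / self.gsyn_peak_time
        return self.peak_gsyn * np.clip(np.where(t <= self.gsyn_peak_time, up, 2.0 - up), 0.0, 1.0)

    def gaff_waveform(self, t: np.ndarray, anchors) -> np.ndarray:
        """Afferent density (μS/cm²): constant hold, or the warm-up sinusoid.

        In ``warmup_dendritic`` mode the tendon vibrates between the held
        length and the maximal length, so G_aff swings sinusoidally between
        gaff_of_length(x_m) and gaff_of_length(0) with the given period,
        applied with the 10 ms afferent conduction delay.
        """
        g_hold = gaff_of_length(self.x_m, anchors)
        if self.mode != "warmup_dendritic":
            return np.full_like(t, g_hold)
        g_hi = gaff_of_length(0.0, anchors)
        td = np.maximum(t - AFFERENT_DELAY_MS, 0.0)
        return g_hold + (g_hi - g_hold) * 0.5 * (1.0 - np.cos(2.0 * np.pi * td / self.sin_period))


@dataclass
class CalibrationReport:
    parameter: str
    value: float
    target: float
    achieved: float
    iterations: int

    @property
    def residual(self) -> float:
        scale = abs(self.target) if self.target != 0 else 1.0
        return abs(self.achieved - self.target) / scale


def _bisect(f, lo: float, hi: float, target: float, rtol: float = 0.02,
            max_iter: int = 60, grow: float = 4.0, max_hi: float = 1e4):
    """Monotone bracket + bisection on ``f(x) = target``; returns (x, f(x), iters)."""
    it = 0
    f_hi = f(hi)
    while f_hi < target:
        lo, hi = hi, hi * grow
        if hi > max_hi:
            raise CalibrationError(f"target {target} unreachable below {max_hi}")
        f_hi = f(hi)
        it += 1
    x, fx = hi, f_hi
    f_lo = f(lo)
    if f_lo > target:
        raise CalibrationError("bracket failure: lower bound already exceeds target")
    for _ in range(max_iter):
        scale = abs(target) if target != 0 else 1.0
        if abs(fx - target) / scale <= rtol:
            break
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        it += 1
        if fm < target:
            lo = mid
        else:
            hi = mid
        x, fx = mid, fm
    else:
        raise CalibrationError(f"no convergence to {target} in {max_iter} iterations")
    return x, fx, it


# ---------------------------------------------------------------------------
# Effective-current measurements (somatic voltage clamp, passive dendrites)
# ---------------------------------------------------------------------------

CLAMP_DT = 0.1  # ms; clamp measurements carry no spikes, so a coarser step suffices


def measure_effective_synaptic_current(
    model: CompartmentalModel,
    syn_density=None,
    aff_density=None,
    duration: float = 500.0,
    dt: float = CLAMP_DT,
) -> np.ndarray:
    """I_N(t): effective synaptic current (nA) at the soma.

    The soma is clamped at rest with all membrane passive; I_N is the
    negated clamp-current deflection (sign-positive for excitation).
    """
    tr = cable.voltage_clamp(
        model, model.spec.passive.e_leak, duration, dt=dt, mode="passive",
        syn_density=syn_density, aff_density=aff_density,
    )
    return -tr.channels["i_clamp"][1:]


def measure_cal_clamp_deflection(
    model: CompartmentalModel,
    v_start: float = -70.0,
    v_stop: float = -30.0,
    ramp_ms: float = 5000.0,
    dt: float = CLAMP_DT,
) -> float:
    """Leak-subtracted peak inward clamp deflection (nA) of the Cav1.3 band.

    Runs the slow somatic voltage-clamp ramp twice — with the calibrated
    Cav1.3 density and with it removed — and returns the peak difference
    current (positive = inward calcium reaching the soma).
    """
    cmd = lambda t: v_start + (v_stop - v_start) * t / ramp_ms
    with_cal = cable.voltage_clamp(model, cmd, ramp_ms, dt=dt, mode="cal_only")
    g_save = model.cal_density
    model.set_cal_density(0.0)
    try:
        leak_only = cable.voltage_clamp(model, cmd, ramp_ms, dt=dt, mode="cal_only")
    finally:
        model.set_cal_density(g_save)
    defl = leak_only.channels["i_clamp"] - with_cal.channels["i_clamp"]
    return float(defl.max())


# ---------------------------------------------------------------------------
# Calibrations
# ---------------------------------------------------------------------------

def calibrate_gcal(model: CompartmentalModel, band, target: float = 22.0,
                   rtol: float = 0.02) -> CalibrationReport:
    """Set the band Cav1.3 density so the effective calcium current at the
    soma equals ``target`` nA under the slow clamp ramp."""
    model.set_cal_band(band, 0.0)
    if target == 0.0:
        return CalibrationReport("g_cal", 0.0, 0.0, 0.0, 0)

    def f(g):
        model.set_cal_density(g)
        return measure_cal_clamp_deflection(model)

    g, achieved, it = _bisect(f, 0.0, 1.0, target, rtol=rtol, max_hi=500.0)
    model.set_cal_density(g)
    return CalibrationReport("g_cal", g, target, achieved, it)


def calibrate_gaff(model: CompartmentalModel,
                   anchor_lengths=(-16.0, -8.0, 0.0),
                   targets=(0.0, 2.5, 5.0),
                   rtol: float = 0.02) -> tuple[list, list[CalibrationReport]]:
    """Calibrate the spindle density at each length anchor against its
    effective synaptic current; returns (anchors, reports)."""
    if model.aff_idx.size == 0:
        raise StateError("afferent map not placed")
    anchors = []
    reports = []

    def i_n_steady(dens):
        return float(measure_effective_synaptic_current(model, aff_density=dens)[-1])

    for x_m, tgt in zip(anchor_lengths, targets):
        if tgt == 0.0:
            anchors.append((x_m, 0.0))
            reports.append(CalibrationReport(f"g_aff@{x_m}mm", 0.0, 0.0, 0.0, 0))
            continue
        g, achieved, it = _bisect(i_n_steady, 0.0, 5.0, tgt, rtol=rtol, max_hi=1e3)
        anchors.append((x_m, g))
        reports.append(CalibrationReport(f"g_aff@{x_m}mm", g, tgt, achieved, it))
    return anchors, reports


def calibrate_gsyn_peak(model: CompartmentalModel, band, target: float = 16.0,
                        rtol: float = 0.02,
                        peak_time: float = 10000.0) -> CalibrationReport:
    """Scale the triangular dendritic drive so its peak I_N equals ``target``.

    Bisection runs on the quasi-static (steady-conductance) measurement;
    the report's achieved value re-measures with the full triangular ramp.
    """
    if model.band_idx.size == 0:
        model.set_cal_band(band, model.cal_density)
    if target == 0.0:
        return CalibrationReport("g_syn_peak", 0.0, 0.0, 0.0, 0)

    def i_n_steady(peak):
        return float(measure_effective_synaptic_current(model, syn_density=peak)[-1])

    g, _, it = _bisect(i_n_steady, 0.0, 0.5, target, rtol=rtol, max_hi=1e3)

    def tri(t):
        up = t / peak_time
        return g * np.clip(np.where(t <= peak_time, up, 2.0 - up), 0.0, 1.0)

    i_n = measure_effective_synaptic_current(model, syn_density=tri,
                                             duration=2.0 * peak_time)
    achieved = float(i_n.max())
    return CalibrationReport("g_syn_peak", g, target, achieved, it)


def measure_ahp_duration(model: CompartmentalModel, dt: float = 0.025,
                         settle: float = 300.0, window: float = 1500.0) -> float:
    """AHP duration (ms): somatic spike to return within 1 mV of rest.

    A 2 ms suprathreshold pulse elicits one spike from the settled model.
    The AHP is a somatic property: the dendritic Cav1.3 population is
    disabled so residual PIC activation cannot distort the measurement.
    """
    _, st = cable.run(model, settle, dt=dt, mode="no_cal")
    rest = float(st.v[0])
    nsteps = int(round(window / dt))
    t = (np.arange(nsteps) + 0.5) * dt
    tr = None
    for amp in (30.0, 60.0, 120.0, 240.0):  # escalate for low-R_N cells
        pulse = np.where(t < 2.0, amp, 0.0)
        tr, _ = cable.run(model, window, dt=dt, i_soma=pulse, state=st,
                          mode="no_cal")
        if len(tr.spikes):
            break
    if tr is None or len(tr.spikes) == 0:
        raise CalibrationError("test pulse elicited no spike")
    spike_t = tr.spikes[0]
    v = tr.channels["v_soma"]
    i0 = int(spike_t / dt)
    below = v[i0:] < rest - 1.0
    if not below.any():
        return 0.0
    start = i0 + int(np.nonzero(below)[0][0])
    back = np.nonzero(v[start:] >= rest - 1.0)[0]
    if back.size == 0:
        raise CalibrationError("membrane did not return to rest within the window")
    end = start + int(back[0])
    return (end - i0) * dt


def calibrate_ahp_twitch(
    model: CompartmentalModel,
    muscle: MuscleParams,
    target: float = 250.0,
    rtol: float = 0.02,
) -> tuple[MembraneSpec, MuscleParams, list[CalibrationReport]]:
    """Speed-couple the AHP and the twitch at ~250 ms (optimal length).

    Bisects the muscle Ca-uptake constant against the twitch duration and
    the somatic Ca-pool removal constant against the AHP duration, both to
    ``target`` within ``rtol``.  Returns the updated membrane spec, the
    updated muscle parameters and the two reports.
    """
    from .muscle import single_twitch

    def twitch_dur(tau_u):
        p = muscle.with_tau_uptake(tau_u)
        m = twitch_metrics(single_twitch(p), dt=0.5)
        if m is None:
            raise CalibrationError("no twitch produced")
        return m.duration

    tau_u, ach_tw, it_tw = _bisect(twitch_dur, 1.0, 50.0, target, rtol=rtol, max_hi=2e3)
    muscle_out = muscle.with_tau_uptake(tau_u)

    def ahp_dur(tau_ca):
        model.spec = model.spec.with_ca_tau(tau_ca)
        return measure_ahp_duration(model)

    tau_ca, ach_ahp, it_ahp = _bisect(ahp_dur, 5.0, 60.0, target, rtol=rtol, max_hi=4e3)
    model.spec = model.spec.with_ca_tau(tau_ca)
    reports = [
        CalibrationReport("muscle_tau_uptake", tau_u, target, ach_tw, it_tw),
        CalibrationReport("ca_pool_tau", tau_ca, target, ach_ahp, it_ahp),
    ]
    return model.spec, muscle_out, reports


# ---------------------------------------------------------------------------
# Closed-loop protocol runs
# ---------------------------------------------------------------------------

def _require_calibrated(model: CompartmentalModel, protocol: ProtocolSpec):
    if model.band_idx.size == 0:
        raise StateError("no PIC band placed; run calibrate_gcal first")
    if protocol.mode in ("somatic_ramp", "dendritic_ramp", "warmup_somatic",
                         "warmup_dendritic") and model.aff_idx.size == 0:
        raise StateError("afferent map not placed; run place_afferents/calibrate_gaff")


def run_ramp(
    model: CompartmentalModel,
    protocol: ProtocolSpec,
    anchors,
    muscle: MuscleParams,
    dt: float = 0.025,
    muscle_dt: float = 0.5,
) -> tuple[TraceSet, np.ndarray]:
    """Run a triangular somatic or dendritic ramp on the closed-loop model.

    The spindle drive is held at gaff_of_length(x_m); somatic spikes are
    forwarded to the muscle with the 10 ms efferent delay; returns the
    neural trace set (with the force resampled onto its time base) and the
    muscle force trace.
    """
    if protocol.mode not in ("somatic_ramp", "dendritic_ramp"):
        raise ParameterError(f"run_ramp got mode {protocol.mode!r}")
    _require_calibrated(model, protocol)
    return _run_protocol(model, protocol, anchors, muscle, dt, muscle_dt)


def run_warmup(
    model: CompartmentalModel,
    protocol: ProtocolSpec,
    anchors,
    muscle: MuscleParams,
    dt: float = 0.025,
    muscle_dt: float = 0.5,
) -> tuple[TraceSet, np.ndarray]:
    """Run a repeated-stimulation (warm-up) protocol.

    ``warmup_somatic`` repeats the -5 → 10 nA triangle with ~1 s gaps;
    ``warmup_dendritic`` applies the sinusoidal spindle drive with all
    voltage-gated channels on the soma/hillock/initial segment blocked
    (QX-314 condition) plus the small somatic step current.
    """
    if protocol.mode not in ("warmup_somatic", "warmup_dendritic"):
        raise ParameterError(f"run_warmup got mode {protocol.mode!r}")
    _require_calibrated(model, protocol)
    return _run_protocol(model, protocol, anchors, muscle, dt, muscle_dt)


def _run_protocol(model, protocol, anchors, muscle, dt, muscle_dt):
    mode = "qx314" if protocol.qx314 else "all"
    duration = protocol.duration
    nsteps = int(round(duration / dt))
    t = (np.arange(nsteps) + 0.5) * dt

    # settle to steady state under the protocol's starting drive
    g0 = float(protocol.gaff_waveform(np.zeros(1), anchors)[0])
    i0 = float(protocol.is_waveform(np.zeros(1))[0])
    _, st = cable.run(model, protocol.settle, dt=dt, i_soma=i0,
                      aff_density=g0, mode=mode)

    traces, _ = cable.run(
        model, duration, dt=dt,
        i_soma=protocol.is_waveform(t),
        aff_density=protocol.gaff_waveform(t, anchors),
        syn_density=protocol.gsyn_waveform(t),
        state=st, mode=mode,
    )
    spikes = traces.spikes
    force = simulate_muscle(spikes + EFFERENT_DELAY_MS, protocol.x_m,
                            duration, muscle_dt, muscle)
    # resample force onto the neural time base
    tf = np.arange(len(force)) * muscle_dt
    traces.channels["force"] = np.interp(traces.t, tf, force)
    return traces, force
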