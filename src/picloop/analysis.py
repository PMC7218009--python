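"""Input-output analysis: hysteresis indices and firing-pattern classes.

From a triangular-ramp run the stimulus-force relationship is resampled
separately on the ascending and descending phases, and three indices are
computed:

* DCT — difference in stimulus threshold for force between the phases
  (force-initiation current minus force-cessation current); positive DCT
  means force persists below the ascending threshold, i.e. self-sustained
  force by dendritic PIC activation (counterclockwise hysteresis);
* DCI — stimulus interval from force initiation to 63% of the ascending
  peak force; 1/DCI proxies the rate of force development;
* DFG — descending-minus-ascending force difference read at the stimulus
  where the firing rate starts to accelerate (full PIC activation); forced
  to zero when no acceleration exists or when it coincides with
  recruitment, since then there is no bistable transition to potentiate
  the force.

Warm-up is flagged when per-trial response peaks grow strictly across all
repeated stimuli by more than a 1% relative margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, StateError

STIM_GRID_NA = 0.05
FORCE_ONSET_FRAC = 0.01
PIC_SLOPE_FACTOR = 2.0
PIC_SUSTAIN_NA = 0.5
PIC_COINCIDENCE_NA = 0.5


def instantaneous_rate(spike_times) -> np.ndarray:
    """(t, rate) pairs: 1000/ISI assigned at the second spike of each pair.

    Returns an (n-1, 2) array; empty for fewer than two spikes.
    """
    s = np.asarray(spike_times, dtype=float)
    if s.size < 2:
        return np.empty((0, 2))
    isi = np.diff(s)
    return np.column_stack([s[1:], 1000.0 / isi])


@dataclass
class IOCurve:
    """Stimulus-resampled input-output relationship of one ramp run."""

    stim: np.ndarray            # shared stimulus grid (nA)
    force_asc: np.ndarray
    force_desc: np.ndarray
    rate_points_asc: np.ndarray  # (stim, rate) at ascending spikes
    rate_points_desc: np.ndarray
    peak_force: float
    recruitment: float | None
    derecruitment: float | None
    mode: str = "somatic"


@dataclass
class IndexReport:
    recruitment: float | None
    derecruitment: float | None
    pic_onset: float | None
    force_initiation: float | None
    force_cessation: float | None
    dct: float
    dci: float
    dfg: float
    firing_type: str = "other"


@dataclass
class WarmupReport:
    peak_rates: np.ndarray
    peak_forces: np.ndarray
    warmup: bool
    peak_v_soma: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_v_band: np.ndarray = field(default_factory=lambda: np.empty(0))


def _stim_of_time(traces, mode: str, i_n_peak: float | None):
    """Stimulus axis sample per trace sample: I_S, or I_N composed from the
    measured conductance→current map (linear in the passive tree)."""
    if mode == "somatic":
        return traces.channels["i_soma"]
    if i_n_peak is None:
        raise StateError("dendritic mode requires the measured I_N map")
    g = traces.channels["g_syn"]
    peak_g = g.max()
    if peak_g <= 0:
        return np.zeros_like(g)
    return i_n_peak * g / peak_g


def build_io_curve(traces, force: np.ndarray, mode: str = "somatic",
                   i_n_peak: float | None = None,
                   grid: float = STIM_GRID_NA) -> IOCurve:
    """Resample force and firing rate against the stimulus, per phase.

    ``force`` must share the trace time base.  The stimulus axis is I_S
    (somatic mode) or I_N (dendritic mode, from the calibrated peak I_N).
    Grid boundary ties resolve toward the earlier time sample.
    """
    stim_t = _stim_of_time(traces, mode, i_n_peak)
    ipk = int(np.argmax(stim_t))
    t = traces.t
    lo = float(stim_t.min())
    hi = float(stim_t.max())
    stim_grid = np.arange(np.floor(lo / grid), np.ceil(hi / grid) + 1) * grid
    stim_grid = stim_grid[(stim_grid >= lo) & (stim_grid <= hi)]

    asc_s, asc_f = stim_t[: ipk + 1], force[: ipk + 1]
    desc_s, desc_f = stim_t[ipk:][::-1], force[ipk:][::-1]
    force_asc = np.interp(stim_grid, asc_s, asc_f)
    force_desc = np.interp(stim_grid, desc_s, desc_f)

    spikes = traces.spikes
    rr = instantaneous_rate(spikes)
    t_peak = t[ipk]
    if rr.size:
        stim_at = np.interp(rr[:, 0], t, stim_t)
        asc_mask = rr[:, 0] <= t_peak
        rate_asc = np.column_stack([stim_at[asc_mask], rr[asc_mask, 1]])
        rate_desc = np.column_stack([stim_at[~asc_mask], rr[~asc_mask, 1]])
    else:
        rate_asc = np.empty((0, 2))
        rate_desc = np.empty((0, 2))

    recr = float(np.interp(spikes[0], t, stim_t)) if spikes.size else None
    derecr = float(np.interp(spikes[-1], t, stim_t)) if spikes.size else None
    return IOCurve(
        stim=stim_grid, force_asc=force_asc, force_desc=force_desc,
        rate_points_asc=rate_asc, rate_points_desc=rate_desc,
        peak_force=float(force.max()), recruitment=recr, derecruitment=derecr,
        mode=mode,
    )


@dataclass
class Thresholds:
    recruitment: float | None
    derecruitment: float | None
    force_initiation: float | None
    force_cessation: float | None


def thresholds(io: IOCurve, force_onset_frac: float = FORCE_ONSET_FRAC) -> Thresholds:
    """Recruitment/derecruitment (first/last spike) and force initiation/
    cessation (ascending/descending force crossing the onset fraction)."""
    level = force_onset_frac * io.peak_force
    init = cess = None
    if io.peak_force > 0:
        on = np.nonzero(io.force_asc > level)[0]
        if on.size:
            init = float(io.stim[on[0]])
        off = np.nonzero(io.force_desc > level)[0]
        if off.size:
            cess = float(io.stim[off[0]])
    return Thresholds(io.recruitment, io.derecruitment, init, cess)


def pic_onset_current(io: IOCurve, slope_factor: float = PIC_SLOPE_FACTOR,
                      sustain: float = PIC_SUSTAIN_NA) -> float | None:
    """Stimulus at the onset of firing-rate acceleration on the ascent.

    The primary-range slope is estimated over the first ~1 nA above
    recruitment; the onset is the first stimulus from which the local f-I
    slope exceeds ``slope_factor`` times that baseline over at least
    ``sustain`` nA of stimulus.  Returns None when never sustained (or
    fewer than 10 rate samples).
    """
    pts = io.rate_points_asc
    if len(pts) < 10:
        return None
    s, r = pts[:, 0], pts[:, 1]
    base_mask = s <= s[0] + 1.0
    if base_mask.sum() < 3:
        base_mask = np.zeros(len(s), dtype=bool)
        base_mask[:3] = True
    s0 = np.polyfit(s[base_mask], r[base_mask], 1)[0]
    s0 = max(s0, 0.1)  # floor for flat primary ranges
    for i in range(1, len(s)):
        jend = np.searchsorted(s, s[i] + sustain)
        if jend >= len(s):
            break
        span = s[jend] - s[i]
        if span <= 0:
            continue
        slope = (r[jend] - r[i]) / span
        # require the acceleration to be sustained across the window
        mid = (i + jend) // 2
        span1 = s[mid] - s[i]
        ok_mid = True
        if span1 > 0.05:
            ok_mid = (r[mid] - r[i]) / span1 > slope_factor * s0 * 0.5
        if slope > slope_factor * s0 and ok_mid:
            return float(s[i])
    return None


def compute_indices(io: IOCurve, force_onset_frac: float = FORCE_ONSET_FRAC) -> IndexReport:
    """DCT, DCI, DFG and the firing-pattern class for one ramp run."""
    th = thresholds(io, force_onset_frac)
    onset = pic_onset_current(io)
    dct = 0.0
    if th.force_initiation is not None and th.force_cessation is not None:
        dct = th.force_initiation - th.force_cessation
    dci = np.nan
    if th.force_initiation is not None and io.peak_force > 0:
        apk = io.force_asc.max()
        i63 = np.nonzero(io.force_asc >= 0.63 * apk)[0]
        if i63.size:
            # linear interpolation between grid samples
            j = i63[0]
            if j > 0:
                f0, f1 = io.force_asc[j - 1], io.force_asc[j]
                frac = (0.63 * apk - f0) / (f1 - f0) if f1 > f0 else 0.0
                s63 = io.stim[j - 1] + frac * (io.stim[j] - io.stim[j - 1])
            else:
                s63 = io.stim[j]
            dci = float(s63 - th.force_initiation)
    dfg = 0.0
    bistable = (
        onset is not None
        and th.recruitment is not None
        and onset > th.recruitment + PIC_COINCIDENCE_NA
    )
    if bistable:
        fa = float(np.interp(onset, io.stim, io.force_asc))
        fd = float(np.interp(onset, io.stim, io.force_desc))
        dfg = max(fd - fa, 0.0)
    report = IndexReport(
        recruitment=th.recruitment, derecruitment=th.derecruitment,
        pic_onset=onset, force_initiation=th.force_initiation,
        force_cessation=th.force_cessation, dct=dct, dci=dci, dfg=dfg,
    )
    report.firing_type = classify_firing_type(io, report)
    return report


def classify_firing_type(io: IOCurve, report: IndexReport,
                         dct_tol: float = 2 * STIM_GRID_NA) -> str:
    """Firing-pattern classes of the somatic ramp response.

    Type I: linear f-I, no hysteresis.  Type IV: acceleration above
    recruitment with counterclockwise hysteresis.  Type III: acceleration
    at recruitment with (expanded) hysteresis.
    """
    accel = report.pic_onset is not None
    hyst = report.dct > dct_tol
    if not accel and not hyst:
        return "I"
    if accel and hyst:
        at_recruitment = (
            report.recruitment is not None
            and report.pic_onset <= report.recruitment + PIC_COINCIDENCE_NA
        )
        return "III" if at_recruitment else "IV"
    return "other"


def warmup_metrics(trial_traces, trial_forces=None, margin: float = 0.01,
                   v_rest: float = -70.0) -> WarmupReport:
    """Per-trial peaks and the warm-up flag for repeated stimulation.

    ``trial_traces`` is a sequence of per-trial TraceSets (or per-cycle
    slices).  Peaks of firing rate and force are extracted per trial (and
    somatic/dendritic peak potentials, used in the QX-314 mode where no
    spikes occur).  The warm-up flag is true iff the relevant peak series
    (rate when spiking, somatic potential otherwise) increases strictly
    across all trials by more than ``margin`` relative per step.
    """
    if len(trial_traces) < 3:
        raise ParameterError("warm-up metrics need at least 3 trials/cycles")
    peak_rates, peak_forces, pv_soma, pv_band = [], [], [], []
    for k, tr in enumerate(trial_traces):
        rr = instantaneous_rate(tr.spikes)
        peak_rates.append(float(rr[:, 1].max()) if rr.size else 0.0)
        pv_soma.append(float(tr.channels["v_soma"].max()))
        pv_band.append(float(tr.channels["v_band"].max()))
        if trial_forces is not None:
            peak_forces.append(float(np.max(trial_forces[k])))
        elif "force" in tr.channels:
            peak_forces.append(float(tr.channels["force"].max()))
        else:
            peak_forces.append(0.0)
    peak_rates = np.asarray(peak_rates)
    peak_forces = np.asarray(peak_forces)
    pv_soma = np.asarray(pv_soma)
    pv_band = np.asarray(pv_band)

    def strictly_up(x):
        x = np.asarray(x, dtype=float)
        ref = np.maximum(np.abs(x[:-1]), 1e-9)
        return bool(np.all((x[1:] - x[:-1]) / ref > margin))

    spiking = peak_rates.max() > 0
    if spiking:
        # firing rate is the motoneuron's response series; force saturates
        # near fusion and is reported alongside
        flag = strictly_up(peak_rates)
    else:
        # QX-314: judge on peak depolarizations relative to rest
        flag = (_potentials_up(pv_soma, margin, v_rest)
                and _potentials_up(pv_band, margin, v_rest))
    return WarmupReport(
        peak_rates=peak_rates, peak_forces=peak_forces, warmup=flag,
        peak_v_soma=pv_soma, peak_v_band=pv_band,
    )


def _potentials_up(v: np.ndarray, margin: float, v_rest: float) -> bool:
    """Strict growth of per-cycle peak depolarization above resting."""
    amp = v - v_rest
    return bool(np.all(np.diff(amp) / np.maximum(amp[:-1], 1e-9) > margin))


def split_warmup_trials(traces, protocol) -> list:
    """Slice a warm-up TraceSet into per-trial (somatic) or per-cycle
    (dendritic) windows."""
    from .cable import TraceSet

    if protocol.mode == "warmup_somatic":
        cyc = protocol.tri_period + protocol.tri_gap
        n = protocol.tri_count
        win = protocol.tri_period
    elif protocol.mode == "warmup_dendritic":
        cyc = protocol.sin_period
        n = protocol.sin_cycles
        win = protocol.sin_period
    else:
        raise ParameterError("not a warm-up protocol")
    out = []
    dt = traces.dt
    for k in range(n):
        t0 = k * cyc
        i0, i1 = int(round(t0 / dt)), int(round((t0 + win) / dt))
        ch = {name: arr[i0:i1 + 1] for name, arr in traces.channels.items()}
        sl = TraceSet(dt=dt, channels=ch)
        sp = traces.spikes
        sl.spikes = sp[(sp >= t0) & (sp <= t0 + win)] - t0
        out.append(sl)
    return out
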