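"""Branched-cable engine: discretization, implicit integration, clamp.

The tree is discretized into iso-potential compartments joined by axial
conductances (a Hines-ordered tree matrix).  Each fixed time step advances
gates by exact exponential relaxation at the pre-step voltage (CNEXP
staggering) and then solves the voltage implicitly with a symmetric
Crank-Nicolson scheme via one leaf-to-root elimination and one
root-to-leaf back-substitution — unconditionally stable on passive trees
and second order in time.

Units follow the NEURON-style set: mV, ms, nA, μS, nF, μm/cm mixed as
noted.  The soma is always compartment 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import morphology as mo
from .biophysics import MembraneSpec
from .errors import ContractError, IntegrationError, ParameterError, StructuralError

# gate register: row indices into the gate-parameter table
M_NA, H_NA, N_KDR, M_NAP, M_CAN, H_CAN, M_CAL = range(7)
N_GATES = 7


def _gate_table(spec: MembraneSpec) -> np.ndarray:
    """Pack the seven gate kinetics into a (7, 6) parameter table."""
    ch = spec.channels
    rows = [
        ch["na"].gates[0],
        ch["na"].gates[1],
        ch["kdr"].gates[0],
        ch["nap"].gates[0],
        ch["can"].gates[0],
        ch["can"].gates[1],
        ch["cal"].gates[0],
    ]
    P = np.zeros((N_GATES, 6))
    for i, g in enumerate(rows):
        P[i] = (g.vhalf, g.slope, g.tau_base, g.tau_amp, g.tau_vhalf, g.tau_k)
    return P


@dataclass
class SimState:
    """Instantaneous solver state: voltages, gate fractions, somatic Ca."""

    v: np.ndarray          # (N,) mV
    gates: np.ndarray      # (7, N)
    ca: float              # μM
    t: float = 0.0         # ms


@dataclass
class TraceSet:
    """Recorded time series on a shared fixed-step time base."""

    dt: float
    channels: dict[str, np.ndarray]
    spikes: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def t(self) -> np.ndarray:
        n = len(next(iter(self.channels.values())))
        return np.arange(n) * self.dt

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t_ms": self.t, **self.channels})

    def write_csv(self, path, stride: int = 1) -> None:
        self.to_frame().iloc[::stride].to_csv(path, index=False)

    def write_spikes(self, path) -> None:
        """Spike times as a one-column text file (ms)."""
        np.savetxt(path, self.spikes, fmt="%.6f")

    def write_hdf5(self, path) -> None:
        """Binary container for long runs (one dataset per channel)."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["dt_ms"] = self.dt
            for name, arr in self.channels.items():
                fh.create_dataset(name, data=arr, compression="gzip")
            fh.create_dataset("spikes", data=self.spikes)


class CompartmentalModel:
    """Discretized cable with channel densities and synapse slots.

    Built by :func:`discretize`.  Channel conductances are stored per
    compartment in μS; ``g_aff_unit`` / ``g_syn_unit`` are the synaptic
    conductances at unit density (1 μS/cm² afferent, 1 mS/cm² test synapse)
    so a scalar density waveform scales them at run time.
    """

    def __init__(self, tree: mo.NeuriteTree, spec: MembraneSpec, arrays: dict):
        self.tree = tree
        self.spec = spec
        for k, v in arrays.items():
            setattr(self, k, v)
        self.n = len(self.parent)
        self.soma = 0
        self.band: mo.SiteSet | None = None
        self.cal_density = 0.0  # mS/cm²
        self.g_cal = np.zeros(self.n)
        self.band_idx = np.empty(0, dtype=np.int64)
        self.g_syn_unit = np.zeros(self.n)
        self.g_aff_unit = np.zeros(self.n)
        self.aff_idx = np.empty(0, dtype=np.int64)

    # -- channel/synapse placement ------------------------------------------

    def comps_in_band(self, center_mm: float, halfwidth_mm: float) -> np.ndarray:
        lo, hi = (center_mm - halfwidth_mm) * 1e3, (center_mm + halfwidth_mm) * 1e3
        mask = (self.kind == 1) & (self.path_um >= lo) & (self.path_um <= hi)
        return np.nonzero(mask)[0]

    def set_cal_band(self, band: mo.SiteSet, gbar: float) -> None:
        """Place Cav1.3 at density ``gbar`` (mS/cm²) on the band compartments."""
        idx = self.comps_in_band(band.band_center, band.band_halfwidth)
        if idx.size == 0:
            raise ContractError("band maps to no compartments")
        self.band = band
        self.band_idx = idx
        self.cal_density = gbar
        self.g_cal = np.zeros(self.n)
        self.g_cal[idx] = gbar * 1e3 * self.area[idx]  # mS/cm² → μS
        # test synapses share the PIC band sites
        self.g_syn_unit = np.zeros(self.n)
        self.g_syn_unit[idx] = 1e3 * self.area[idx]  # at 1 mS/cm²

    def set_cal_density(self, gbar: float) -> None:
        if self.band_idx.size == 0:
            raise ContractError("no band placed")
        self.cal_density = gbar
        self.g_cal = np.zeros(self.n)
        self.g_cal[self.band_idx] = gbar * 1e3 * self.area[self.band_idx]

    # -- state --------------------------------------------------------------

    def initial_state(self, v: float | None = None) -> SimState:
        v0 = self.spec.passive.e_leak if v is None else v
        V = np.full(self.n, float(v0))
        P = self.P
        gates = np.zeros((N_GATES, self.n))
        for gi in range(N_GATES):
            vh, k = P[gi, 0], P[gi, 1]
            gates[gi] = 1.0 / (1.0 + np.exp(-(V - vh) / k))
        return SimState(v=V, gates=gates, ca=self.spec.ca_pool.rest, t=0.0)

    def total_area(self) -> float:
        """Total membrane area, cm²."""
        return float(np.sum(self.area))


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

_KIND_CODE = {mo.SOMA: 0, mo.DENDRITE: 1, mo.HILLOCK: 2, mo.INITIAL_SEGMENT: 3}


def discretize(
    tree: mo.NeuriteTree,
    spec: MembraneSpec | None = None,
    max_electrotonic_segment: float = 0.1,
) -> CompartmentalModel:
    """Discretize a tree into compartments bounded in 100 Hz electrotonic size.

    Every compartment is shorter than ``max_electrotonic_segment`` of the
    local AC space constant at 100 Hz.  Somatic/axonal channels are placed
    by section kind with the densities in ``spec``; Cav1.3 and synapses are
    placed afterwards (``set_cal_band``, spindle placement).
    """
    if not (0.0 < max_electrotonic_segment <= 0.3):
        raise ParameterError("max_electrotonic_segment must be in (0, 0.3]")
    spec = spec or MembraneSpec()
    pas = spec.passive

    parent, area, gax, path_um, kind, length_um = [], [], [], [], [], []

    # compartment 0: the soma
    soma = tree.soma
    area.append(soma.area * 1e-8)  # μm² → cm²
    parent.append(-1)
    gax.append(0.0)
    path_um.append(0.0)
    kind.append(0)
    length_um.append(soma.length)

    last_comp_of_sec = {tree.root: 0}
    half_res_dist = {0: 0.0}  # axial half-resistance (Ω) at each comp's distal end

    for s in tree.sections:
        if s.kind == mo.SOMA:
            continue
        if s.parent not in last_comp_of_sec:
            raise StructuralError(f"section {s.id}: parent not discretized")
        # AC length constant at 100 Hz from section-midpoint properties
        mid_path = tree.path_length(s.id, 0.5)
        d_mean = 0.5 * (s.diam_prox + s.diam_dist)
        rm = float(pas.rm_at(mid_path))
        lam_dc = math.sqrt(rm * d_mean * 1e-4 / (4.0 * pas.ri))  # cm
        tau_ms = rm * pas.cm * 1e-3
        w = 2.0 * math.pi * 0.1  # rad/ms at 100 Hz
        lam_ac = lam_dc / math.sqrt(0.5 * (1.0 + math.sqrt(1.0 + (w * tau_ms) ** 2)))
        L_cm = s.length * 1e-4
        ncomp = max(int(math.ceil(L_cm / (max_electrotonic_segment * lam_ac))), 1)
        dx = s.length / ncomp
        p_comp = last_comp_of_sec[s.parent]
        for i in range(ncomp):
            arc_mid = (i + 0.5) / ncomp
            arc_lo = i / ncomp
            d_mid = s.diam_at(arc_mid)
            d_lo = s.diam_at(arc_lo)
            # frustum axial resistance: R = (4 Ri / pi) * L / (d_a * d_b)
            r_prox_half = (4.0 * pas.ri / math.pi) * (dx / 2 * 1e-4) / (d_lo * d_mid * 1e-8)
            r_link = half_res_dist[p_comp] + r_prox_half
            comp_id = len(parent)
            parent.append(p_comp)
            gax.append(1e6 / r_link)  # Ω → μS
            area.append(math.pi * d_mid * dx * 1e-8)
            path_um.append(tree.path_length(s.id, arc_mid))
            kind.append(_KIND_CODE[s.kind])
            length_um.append(dx)
            d_hi = s.diam_at((i + 1.0) / ncomp)
            half_res_dist[comp_id] = (
                (4.0 * pas.ri / math.pi) * (dx / 2 * 1e-4) / (d_mid * d_hi * 1e-8)
            )
            p_comp = comp_id
        last_comp_of_sec[s.id] = p_comp

    area = np.asarray(area)
    path_um_arr = np.asarray(path_um)
    kind_arr = np.asarray(kind, dtype=np.int64)

    rm_comp = np.where(kind_arr == 1, pas.rm_at(path_um_arr), pas.rm_soma)
    # the axon stub uses the somatic (shunted) resistivity
    arrays = dict(
        parent=np.asarray(parent, dtype=np.int64),
        gax=np.asarray(gax),
        area=area,
        path_um=path_um_arr,
        kind=kind_arr,
        length_um=np.asarray(length_um),
        cm_nF=pas.cm * area * 1e3,
        g_leak=1e6 * area / rm_comp,
        e_leak=np.full(len(area), pas.e_leak),
        P=_gate_table(spec),
    )
    model = CompartmentalModel(tree, spec, arrays)
    _place_by_kind(model)
    if abs(model.total_area() - tree.total_area() * 1e-8) > 1e-3 * model.total_area():
        raise StructuralError("discretized membrane area deviates from tree area")
    return model


def _place_by_kind(model: CompartmentalModel) -> None:
    ch = model.spec.channels
    n, kind, area = model.n, model.kind, model.area
    z = np.zeros(n)
    model.g_na, model.g_kdr, model.g_nap = z.copy(), z.copy(), z.copy()
    model.g_can, model.g_kca = z.copy(), z.copy()
    soma = kind == 0
    axon = (kind == 2) | (kind == 3)
    model.g_na[soma] = ch["na"].gbar * 1e3 * area[soma]
    model.g_kdr[soma] = ch["kdr"].gbar * 1e3 * area[soma]
    model.g_nap[soma] = ch["nap"].gbar * 1e3 * area[soma]
    model.g_can[soma] = ch["can"].gbar * 1e3 * area[soma]
    model.g_kca[soma] = ch["kca"].gbar * 1e3 * area[soma]
    model.g_na[axon] = ch["na_axon"].gbar * 1e3 * area[axon]
    model.g_kdr[axon] = ch["kdr_axon"].gbar * 1e3 * area[axon]
    model.g_nap[axon] = ch["nap_axon"].gbar * 1e3 * area[axon]


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _simulate_kernel(
    parent, gax, cmdt, gl, el,
    g_na, g_kdr, g_nap, g_can, g_kca, g_cal, g_aff_unit, g_syn_unit,
    idx_na, idx_kdr, idx_nap, idx_can, idx_kca, idx_cal, band_idx,
    P, ena, ek, eca, esyn,
    ca_rest, ca_tau, ca_kin, kca_kd, kca_n, soma_area,
    V, gates, ca,
    dt, nsteps,
    i_soma, aff_dens, syn_dens,
    clamp_on, clamp_cmd,
    rec,
):
    n = V.shape[0]
    d = np.empty(n)
    r = np.empty(n)
    Gtot = np.empty(n)
    B = np.empty(n)
    gax_sum = np.zeros(n)
    for i in range(1, n):
        gax_sum[i] += gax[i]
        gax_sum[parent[i]] += gax[i]

    rec[0, 0] = V[0]
    nb = band_idx.shape[0]
    if nb > 0:
        sv = 0.0
        sm = 0.0
        for j in range(nb):
            sv += V[band_idx[j]]
            sm += gates[M_CAL, band_idx[j]]
        rec[1, 0] = sv / nb
        rec[2, 0] = sm / nb
    rec[3, 0] = 0.0
    rec[4, 0] = ca

    for t in range(nsteps):
        # --- gates: exact exponential relaxation at pre-step voltage -------
        for gi, idx in (
            (M_NA, idx_na), (H_NA, idx_na), (N_KDR, idx_kdr), (M_NAP, idx_nap),
            (M_CAN, idx_can), (H_CAN, idx_can), (M_CAL, idx_cal),
        ):
            vh = P[gi, 0]
            k = P[gi, 1]
            tb = P[gi, 2]
            ta = P[gi, 3]
            tvh = P[gi, 4]
            tk = P[gi, 5]
            for j in range(idx.shape[0]):
                i = idx[j]
                v = V[i]
                minf = 1.0 / (1.0 + math.exp(-(v - vh) / k))
                tau = tb + ta / (1.0 + math.exp((v - tvh) / tk))
                gates[gi, i] = minf + (gates[gi, i] - minf) * math.exp(-dt / tau)

        # --- somatic calcium pool (driven by the N-type current) -----------
        i_can_dens = 0.0
        for j in range(idx_can.shape[0]):
            i = idx_can[j]
            g = g_can[i] * gates[M_CAN, i] ** 2 * gates[H_CAN, i]
            i_can_dens += g * (V[i] - eca)  # nA (inward negative)
        i_can_dens = i_can_dens * 1e-6 / soma_area  # mA/cm²
        ca += dt * (-ca_kin * i_can_dens - (ca - ca_rest) / ca_tau)
        if ca < ca_rest:
            ca = ca_rest

        # --- assemble conductances and driving terms -----------------------
        ad = aff_dens[t]
        sd = syn_dens[t]
        for i in range(n):
            g_syn_tot = g_aff_unit[i] * ad + g_syn_unit[i] * sd
            Gtot[i] = gl[i] + g_syn_tot
            B[i] = gl[i] * el[i] + g_syn_tot * esyn
        for j in range(idx_na.shape[0]):
            i = idx_na[j]
            g = g_na[i] * gates[M_NA, i] ** 3 * gates[H_NA, i]
            Gtot[i] += g
            B[i] += g * ena
        for j in range(idx_kdr.shape[0]):
            i = idx_kdr[j]
            g = g_kdr[i] * gates[N_KDR, i] ** 4
            Gtot[i] += g
            B[i] += g * ek
        for j in range(idx_nap.shape[0]):
            i = idx_nap[j]
            g = g_nap[i] * gates[M_NAP, i]
            Gtot[i] += g
            B[i] += g * ena
        for j in range(idx_can.shape[0]):
            i = idx_can[j]
            g = g_can[i] * gates[M_CAN, i] ** 2 * gates[H_CAN, i]
            Gtot[i] += g
            B[i] += g * eca
        can_pow = ca ** kca_n
        popen_kca = can_pow / (can_pow + kca_kd ** kca_n)
        for j in range(idx_kca.shape[0]):
            i = idx_kca[j]
            g = g_kca[i] * popen_kca
            Gtot[i] += g
            B[i] += g * ek
        for j in range(idx_cal.shape[0]):
            i = idx_cal[j]
            g = g_cal[i] * gates[M_CAL, i]
            Gtot[i] += g
            B[i] += g * eca
        B[0] += i_soma[t]

        # --- Crank-Nicolson tree solve -------------------------------------
        for i in range(n):
            d[i] = cmdt[i] + 0.5 * (Gtot[i] + gax_sum[i])
            r[i] = (cmdt[i] - 0.5 * (Gtot[i] + gax_sum[i])) * V[i] + B[i]
        for i in range(1, n):
            p = parent[i]
            r[p] += 0.5 * gax[i] * V[i]
            r[i] += 0.5 * gax[i] * V[p]
        v0_old = V[0]
        # leaf→root elimination (parent index always < child index)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = (-0.5 * gax[i]) / d[i]
            d[p] -= f * (-0.5 * gax[i])
            r[p] -= f * r[i]
        if clamp_on == 1:
            V[0] = clamp_cmd[t]
        else:
            V[0] = r[0] / d[0]
        for i in range(1, n):
            p = parent[i]
            V[i] = (r[i] + 0.5 * gax[i] * V[p]) / d[i]

        # --- clamp current (current needed to hold the command) ------------
        i_clamp = 0.0
        if clamp_on == 1:
            ax = 0.0
            for i in range(1, n):
                if parent[i] == 0:
                    ax += gax[i] * (V[i] - V[0])
            i_clamp = cmdt[0] * dt * 0.0  # holding: no capacitive term at steady command
            i_clamp = cmdt[0] * (V[0] - v0_old) + Gtot[0] * V[0] - B[0] - ax

        rec[0, t + 1] = V[0]
        if nb > 0:
            sv = 0.0
            sm = 0.0
            for j in range(nb):
                sv += V[band_idx[j]]
                sm += gates[M_CAL, band_idx[j]]
            rec[1, t + 1] = sv / nb
            rec[2, t + 1] = sm / nb
        rec[3, t + 1] = i_clamp
        rec[4, t + 1] = ca

        if (t & 1023) == 0:
            for i in range(n):
                if not math.isfinite(V[i]) or V[i] > 200.0 or V[i] < -200.0:
                    return -1, i, t
    for i in range(n):
        if not math.isfinite(V[i]):
            return -1, i, nsteps - 1
    return 0, 0, nsteps


# ---------------------------------------------------------------------------
# Run wrappers
# ---------------------------------------------------------------------------

_MODES = ("all", "passive_dendrites", "cal_only", "no_cal", "qx314", "passive")


def _masked_conductances(model: CompartmentalModel, mode: str):
    """Per-mode active-conductance masks.

    ``passive_dendrites``: dendritic Cav1.3 off (I_N measurements).
    ``cal_only``: only Cav1.3 active (PIC calibration ramps).
    ``qx314``: soma/hillock/IS voltage-gated channels blocked.
    ``passive``: everything off.
    """
    if mode not in _MODES:
        raise ParameterError(f"unknown mode {mode!r}")
    g = {
        "na": model.g_na, "kdr": model.g_kdr, "nap": model.g_nap,
        "can": model.g_can, "kca": model.g_kca, "cal": model.g_cal,
    }
    if mode == "all":
        return g
    g = {k: v.copy() for k, v in g.items()}
    if mode in ("passive_dendrites", "no_cal"):
        g["cal"][:] = 0.0
    elif mode == "cal_only":
        for k in ("na", "kdr", "nap", "can", "kca"):
            g[k][:] = 0.0
    elif mode == "qx314":
        blocked = model.kind != 1
        for k in ("na", "kdr", "nap", "can", "kca"):
            g[k][blocked] = 0.0
    elif mode == "passive":
        for k in g:
            g[k][:] = 0.0
    return g


def _nonzero_idx(a: np.ndarray) -> np.ndarray:
    return np.nonzero(a > 0.0)[0].astype(np.int64)


def run(
    model: CompartmentalModel,
    duration: float,
    dt: float = 0.025,
    i_soma=None,
    aff_density=None,
    syn_density=None,
    clamp=None,
    state: SimState | None = None,
    mode: str = "all",
) -> tuple[TraceSet, SimState]:
    """Integrate the model for ``duration`` ms under the given drive.

    ``i_soma`` (nA), ``aff_density`` (μS/cm²) and ``syn_density`` (mS/cm²)
    are waveforms: scalars, arrays of per-step values, or callables of time
    (ms).  ``clamp`` pins the somatic voltage to a command waveform (ideal
    clamp) and records the holding current.  Deterministic; spike times are
    extracted from the somatic trace by upward 0 mV crossings with a 1 ms
    lockout.
    """
    nsteps = int(round(duration / dt))
    if abs(nsteps * dt - duration) > 1e-9 * max(1.0, duration):
        raise ParameterError("duration must be a multiple of dt")

    def as_wave(w, default=0.0):
        if w is None:
            return np.full(nsteps, float(default))
        if callable(w):
            return np.asarray(w((np.arange(nsteps) + 0.5) * dt), dtype=float)
        w = np.asarray(w, dtype=float)
        if w.ndim == 0:
            return np.full(nsteps, float(w))
        if len(w) != nsteps:
            raise ParameterError("waveform length does not match step count")
        return w

    i_wave = as_wave(i_soma)
    aff_wave = as_wave(aff_density)
    syn_wave = as_wave(syn_density)
    clamp_on = 0 if clamp is None else 1
    clamp_wave = as_wave(clamp, default=model.spec.passive.e_leak)

    g = _masked_conductances(model, mode)
    st = state if state is not None else model.initial_state()
    V = st.v.copy()
    gates = st.gates.copy()
    ca = st.ca

    rec = np.empty((5, nsteps + 1))
    pool = model.spec.ca_pool
    kca = model.spec.channels["kca"]
    status, comp, step = _simulate_kernel(
        model.parent, model.gax, model.cm_nF / dt, model.g_leak, model.e_leak,
        g["na"], g["kdr"], g["nap"], g["can"], g["kca"], g["cal"],
        model.g_aff_unit, model.g_syn_unit,
        _nonzero_idx(g["na"]), _nonzero_idx(g["kdr"]), _nonzero_idx(g["nap"]),
        _nonzero_idx(g["can"]), _nonzero_idx(g["kca"]), _nonzero_idx(g["cal"]),
        model.band_idx.astype(np.int64),
        model.P,
        model.spec.channels["na"].erev, model.spec.channels["kdr"].erev,
        model.spec.channels["cal"].erev, model.spec.e_syn,
        pool.rest, pool.tau, pool.k_in, kca.ca_kd, kca.ca_hill_n,
        float(model.area[0]),
        V, gates, ca,
        dt, nsteps,
        i_wave, aff_wave, syn_wave,
        clamp_on, clamp_wave,
        rec,
    )
    if status != 0:
        raise IntegrationError(
            f"non-finite voltage in compartment {comp} at t={step * dt:.3f} ms"
        )
    traces = TraceSet(
        dt=dt,
        channels={
            "v_soma": rec[0],
            "v_band": rec[1],
            "m_cal": rec[2],
            "i_clamp": rec[3],
            "ca": rec[4],
            "i_soma": np.concatenate(([i_wave[0]], i_wave)),
            "g_aff": np.concatenate(([aff_wave[0]], aff_wave)),
            "g_syn": np.concatenate(([syn_wave[0]], syn_wave)),
        },
    )
    traces.spikes = detect_spikes(rec[0], dt)
    new_state = SimState(v=V, gates=gates, ca=rec[4, -1], t=st.t + duration)
    return traces, new_state


def detect_spikes(v_soma: np.ndarray, dt: float, threshold: float = 0.0,
                  lockout: float = 1.0) -> np.ndarray:
    """Spike times (ms) from upward threshold crossings with a lockout."""
    above = v_soma >= threshold
    crossings = np.nonzero(~above[:-1] & above[1:])[0] + 1
    times = []
    last = -np.inf
    for i in crossings:
        t = i * dt
        if t - last >= lockout:
            times.append(t)
            last = t
    return np.asarray(times)


def advance(model: CompartmentalModel, state: SimState, drive: dict | None = None,
            dt: float = 0.025) -> SimState:
    """Advance the model one step (thin wrapper over the run kernel)."""
    if dt <= 0:
        raise ParameterError("dt must be positive")
    drive = drive or {}
    _, new_state = run(
        model, duration=dt, dt=dt,
        i_soma=drive.get("i_soma", 0.0),
        aff_density=drive.get("aff_density", 0.0),
        syn_density=drive.get("syn_density", 0.0),
        clamp=drive.get("clamp"),
        state=state, mode=drive.get("mode", "all"),
    )
    return new_state


def voltage_clamp(
    model: CompartmentalModel,
    command,
    duration: float,
    dt: float = 0.025,
    mode: str = "all",
    state: SimState | None = None,
    aff_density=None,
    syn_density=None,
) -> TraceSet:
    """Ideal somatic voltage clamp; returns traces incl. the clamp current.

    The clamp current is the external current required to hold the command
    (positive = injected depolarizing current).
    """
    traces, _ = run(
        model, duration, dt=dt, clamp=command, mode=mode, state=state,
        aff_density=aff_density, syn_density=syn_density,
    )
    return traces


# ---------------------------------------------------------------------------
# Passive steady state / input resistance
# ---------------------------------------------------------------------------

def passive_steady_state(model: CompartmentalModel, i_inj: np.ndarray,
                         extra_g: np.ndarray | None = None,
                         extra_ge: np.ndarray | None = None) -> np.ndarray:
    """Steady-state voltages of the passive tree under per-compartment
    current injection (nA), by direct tree-matrix elimination."""
    n = model.n
    Gtot = model.g_leak.copy()
    B = model.g_leak * model.e_leak + i_inj
    if extra_g is not None:
        Gtot += extra_g
        B += extra_ge if extra_ge is not None else 0.0
    gax, parent = model.gax, model.parent
    gax_sum = np.zeros(n)
    for i in range(1, n):
        gax_sum[i] += gax[i]
        gax_sum[parent[i]] += gax[i]
    d = Gtot + gax_sum
    r = B.copy()
    o = -gax
    for i in range(n - 1, 0, -1):
        p = parent[i]
        f = o[i] / d[i]
        d[p] -= f * o[i]
        r[p] -= f * r[i]
    v = np.empty(n)
    v[0] = r[0] / d[0]
    for i in range(1, n):
        v[i] = (r[i] - o[i] * v[parent[i]]) / d[i]
    return v


def input_resistance(model: CompartmentalModel, comp: int = 0,
                     i_test: float = -0.1) -> float:
    """Input resistance (MΩ) at a compartment from a small steady injection.

    Active conductances are frozen at rest (passive mode).
    """
    i0 = np.zeros(model.n)
    v0 = passive_steady_state(model, i0)
    i1 = i0.copy()
    i1[comp] = i_test
    v1 = passive_steady_state(model, i1)
    return float((v1[comp] - v0[comp]) / i_test)  # mV/nA = MΩ
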