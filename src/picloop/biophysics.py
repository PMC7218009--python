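"""Membrane biophysics: passive parameters, gate kinetics, channels, calcium.

Gating follows the standard Boltzmann / first-order-relaxation form used in
motoneuron modelling:

    m_inf(V) = 1 / (1 + exp(-(V - V_half) / k))
    tau(V)   = tau_base + tau_amp / (1 + exp((V - tau_vhalf) / tau_k))
    dm/dt    = (m_inf(V) - m) / tau(V)

integrated exactly over a step at frozen voltage (CNEXP-style exponential
relaxation).  Currents are ohmic, inward-negative:

    I = g_bar * prod(gate^exp) * (V - E_rev)      [mA/cm² for densities]

The Ca-dependent potassium channel carries no voltage gate; its open
fraction is a Hill function of somatic calcium.  The somatic calcium pool
is a thin-shell model driven by the somatic N-type calcium current:

    d[Ca]/dt = -k_in * I_CaN - ([Ca] - [Ca]_rest) / tau_ca

whose removal constant tau_ca is the knob matched to the muscle twitch by
the AHP/twitch speed-coupling calibration.

The kinetic constants below are this package's defaults for a slow-type cat
motoneuron (rest near -70 mV, rheobase of a few nA, AHP in the 250 ms
class, low-voltage-activated dendritic Cav1.3 with slow deactivation); they
are deliberately configurable since such constants vary across published
motoneuron models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ContractError, ParameterError


# ---------------------------------------------------------------------------
# Passive parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane/axial properties.

    Specific membrane resistivity is nonuniform: low at the soma (somatic
    shunt) rising sigmoidally with dendritic path length to a high distal
    value, as in step/sigmoidal R_m models of cat motoneurons.  Capacitance
    and axial resistivity are uniform.
    """

    cm: float = 1.0          # μF/cm²
    ri: float = 70.0         # Ω·cm
    rm_soma: float = 225.0   # Ω·cm²
    rm_dend: float = 11000.0  # Ω·cm²
    rm_mid_um: float = 60.0   # sigmoid midpoint, μm of path
    rm_slope_um: float = 40.0  # sigmoid steepness, μm
    e_leak: float = -70.0    # mV

    def rm_at(self, path_um):
        """R_m (Ω·cm²) at dendritic path length(s) ``path_um`` from the soma."""
        x = np.asarray(path_um, dtype=float)
        sig = 1.0 / (1.0 + np.exp(-(x - self.rm_mid_um) / self.rm_slope_um))
        return self.rm_soma + (self.rm_dend - self.rm_soma) * sig

    def lambda_at(self, path_um, diam_um):
        """Local DC space constant (cm) for diameter ``diam_um``."""
        rm = self.rm_at(path_um)
        return np.sqrt(rm * (np.asarray(diam_um) * 1e-4) / (4.0 * self.ri))


# ---------------------------------------------------------------------------
# Gates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateSpec:
    """One activation/inactivation gate (Boltzmann steady state, sigmoid tau)."""

    vhalf: float          # mV
    slope: float          # mV; negative slope -> inactivation gate
    tau_base: float       # ms
    tau_amp: float = 0.0  # ms
    tau_vhalf: float = 0.0
    tau_k: float = 1.0
    exponent: int = 1

    def __post_init__(self):
        if self.slope == 0:
            raise ParameterError("gate slope must be nonzero")
        if self.tau_base <= 0:
            raise ParameterError("tau_base must be positive")

    def minf(self, v):
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - self.vhalf) / self.slope))

    def tau(self, v):
        return self.tau_base + self.tau_amp / (
            1.0 + np.exp((np.asarray(v, dtype=float) - self.tau_vhalf) / self.tau_k)
        )


def steady_state_activation(gate: GateSpec, v: float) -> float:
    """Boltzmann steady-state open fraction of ``gate`` at voltage ``v``."""
    if not math.isfinite(v):
        raise ParameterError("voltage must be finite")
    return float(gate.minf(v))


def gate_step(gate: GateSpec, v: float, m: float, dt: float) -> float:
    """Advance a gate by ``dt`` at frozen voltage (exact exponential update).

    m' = m_inf + (m - m_inf) * exp(-dt / tau(V))
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if not 0.0 <= m <= 1.0:
        raise ContractError("gate fraction out of [0, 1]")
    minf = float(gate.minf(v))
    tau = float(gate.tau(v))
    return minf + (m - minf) * math.exp(-dt / tau)


# ---------------------------------------------------------------------------
# Channels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelSpec:
    """A conductance-based channel: gates, density, reversal potential.

    ``ca_gated`` marks the KCa channel (no voltage gates; open fraction is
    Hill in somatic [Ca]).  ``ca_source`` marks channels whose current feeds
    the somatic calcium pool.
    """

    name: str
    gbar: float                     # mS/cm²
    erev: float                     # mV
    gates: tuple[GateSpec, ...] = ()
    ca_gated: bool = False
    ca_hill_n: float = 2.0
    ca_kd: float = 0.4              # μM
    ca_source: bool = False

    def __post_init__(self):
        if self.gbar < 0:
            raise ParameterError(f"{self.name}: conductance must be >= 0")
        if self.ca_gated and self.gates:
            raise ParameterError(f"{self.name}: KCa-style channel carries no voltage gate")


def channel_current(spec: ChannelSpec, v: float, gates, ca: float = 0.0) -> float:
    """Instantaneous current density (mA/cm²), inward negative.

    ``gates`` is the vector of current gate fractions matching ``spec.gates``.
    """
    if spec.ca_gated:
        if len(gates) != 0:
            raise ContractError(f"{spec.name}: expected no gate values")
        can = ca ** spec.ca_hill_n
        popen = can / (can + spec.ca_kd ** spec.ca_hill_n)
    else:
        if len(gates) != len(spec.gates):
            raise ContractError(
                f"{spec.name}: expected {len(spec.gates)} gate values, got {len(gates)}"
            )
        popen = 1.0
        for g, gs in zip(gates, spec.gates):
            popen *= g ** gs.exponent
    return spec.gbar * 1e-3 * popen * (v - spec.erev)  # mS→S keeps mA/cm²


@dataclass(frozen=True)
class CalciumPool:
    """Thin-shell somatic calcium pool (concentrations in μM)."""

    rest: float = 0.05     # μM
    tau: float = 80.0      # ms; removal constant, set by AHP calibration
    k_in: float = 10.0     # μM per (mA/cm²·ms) of inward Ca current

    def __post_init__(self):
        if self.tau <= 0:
            raise ParameterError("calcium removal time constant must be positive")


# ---------------------------------------------------------------------------
# Default channel set
# ---------------------------------------------------------------------------

# L-type Cav1.3: low-voltage activated (half-activation -45 mV) with strongly
# voltage-dependent kinetics -- fast-ish near threshold, seconds-slow
# deactivation below -60 mV.  The slow tail is what carries residual PIC
# activation across ~1 s gaps between repeated stimuli (warm-up).
CAL_GATE = GateSpec(vhalf=-45.0, slope=4.5, tau_base=60.0,
                    tau_amp=8000.0, tau_vhalf=-62.0, tau_k=2.0)


def default_channels() -> dict[str, ChannelSpec]:
    """Default somatic/axonal channel set plus the dendritic Cav1.3 spec.

    Somatic spiking currents: fast Na (m³h), delayed-rectifier K (n⁴),
    persistent Na (m), N-type Ca (m²h, feeds the Ca pool), Ca-dependent K
    (Hill in [Ca]).  The hillock and initial segment carry Na/KDR/NaP at
    higher density.  ``cal`` has gbar 0 here: its density is set per
    hot-spot band by the PIC calibration.
    """
    na_m = GateSpec(vhalf=-41.0, slope=6.0, tau_base=0.05, tau_amp=0.2,
                    tau_vhalf=-40.0, tau_k=12.0, exponent=3)
    na_h = GateSpec(vhalf=-45.0, slope=-7.0, tau_base=0.6, tau_amp=6.0,
                    tau_vhalf=-48.0, tau_k=7.0)
    kdr_n = GateSpec(vhalf=-35.0, slope=6.0, tau_base=1.5, exponent=4)
    nap_m = GateSpec(vhalf=-51.0, slope=4.0, tau_base=5.0)
    can_m = GateSpec(vhalf=-28.0, slope=5.0, tau_base=4.0, exponent=2)
    can_h = GateSpec(vhalf=-45.0, slope=-5.0, tau_base=40.0)
    return {
        "na": ChannelSpec("na", 120.0, 50.0, (na_m, na_h)),
        "kdr": ChannelSpec("kdr", 400.0, -80.0, (kdr_n,)),
        "nap": ChannelSpec("nap", 0.10, 50.0, (nap_m,)),
        "can": ChannelSpec("can", 1.6, 60.0, (can_m, can_h), ca_source=True),
        "kca": ChannelSpec("kca", 30.0, -80.0, ca_gated=True, ca_kd=0.5),
        "na_axon": ChannelSpec("na_axon", 360.0, 50.0, (na_m, na_h)),
        "kdr_axon": ChannelSpec("kdr_axon", 800.0, -80.0, (kdr_n,)),
        "nap_axon": ChannelSpec("nap_axon", 0.3, 50.0, (nap_m,)),
        "cal": ChannelSpec("cal", 0.0, 60.0, (CAL_GATE,)),
    }


@dataclass
class MembraneSpec:
    """Bundle of passive set, channel set and calcium pool for model building."""

    passive: PassiveParams = field(default_factory=PassiveParams)
    channels: dict[str, ChannelSpec] = field(default_factory=default_channels)
    ca_pool: CalciumPool = field(default_factory=CalciumPool)
    e_syn: float = 0.0  # excitatory synaptic reversal, mV

    def with_cal_density(self, gbar: float) -> "MembraneSpec":
        ch = dict(self.channels)
        ch["cal"] = replace(ch["cal"], gbar=gbar)
        return MembraneSpec(self.passive, ch, self.ca_pool, self.e_syn)

    def with_ca_tau(self, tau: float) -> "MembraneSpec":
        return MembraneSpec(
            self.passive, dict(self.channels), replace(self.ca_pool, tau=tau), self.e_syn
        )
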