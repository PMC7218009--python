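"""Three-module muscle unit: spikes → sarcoplasmic Ca → activation → force.

The muscle transforms the motoneuron spike train into isometric force at a
fixed muscle length ``X_m`` (mm, relative to maximum physiological length:
-16 shortest, -8 optimal, 0 longest), mirroring the slow-twitch cat soleus
operating range of 1-100 Hz drive:

* module 1 — each arriving spike releases a saturable calcium increment
  ``R * (1 - Ca/Ca_sat)``; between spikes Ca decays first-order with the
  uptake time constant;
* module 2 — bimolecular Ca-troponin binding
  d(CaT)/dt = k_on*Ca*(1-CaT) - k_off*CaT, with activation a Hill function
  of CaT whose half-activation K_A rises as the muscle shortens (the
  short-length degradation of activation);
* module 3 — force relaxes toward A * FL(X_m) with time constant tau_f
  (Hill-type isometric mechanics), normalized to the fused tetanus at the
  optimal length.

The force-length factor FL is a skewed Gaussian peaking at X_opt = -8 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .errors import ContractError, ParameterError

X_MIN, X_MAX = -16.0, 0.0


@dataclass(frozen=True)
class MuscleParams:
    """Muscle-unit constants.  Times in ms; Ca/CaT in normalized units."""

    f_max: float = 1.0          # fused tetanus at optimal length (normalization)
    x_opt: float = -8.0         # mm
    fl_short: float = 0.55      # FL at -16 mm
    fl_long: float = 0.85       # FL at 0 mm
    ca_release: float = 0.35    # per-spike release increment
    ca_sat: float = 2.5         # release saturation level
    tau_uptake: float = 55.0    # ms, Ca removal (twitch-duration knob)
    k_on: float = 0.04          # /ms per unit Ca
    k_off: float = 0.02         # /ms
    hill_n: float = 4.0
    ka_anchors: tuple = ((-16.0, 0.42), (-8.0, 0.30), (0.0, 0.24))
    tau_f: float = 40.0         # ms, force low-pass

    def __post_init__(self):
        for name in ("ca_release", "ca_sat", "tau_uptake", "k_on", "k_off", "tau_f"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        ka = [v for _, v in self.ka_anchors]
        if not all(a > b for a, b in zip(ka, ka[1:])):
            raise ParameterError("K_A must decrease with muscle length")

    def ka_at(self, x_m: float) -> float:
        xs = [x for x, _ in self.ka_anchors]
        vs = [v for _, v in self.ka_anchors]
        return float(np.interp(x_m, xs, vs))

    def fl_at(self, x_m: float) -> float:
        """Force-length factor: skewed Gaussian, FL(x_opt) = 1."""
        dx = x_m - self.x_opt
        if dx < 0:
            w = 8.0 / math.sqrt(-math.log(self.fl_short))
        else:
            w = 8.0 / math.sqrt(-math.log(self.fl_long))
        return math.exp(-((dx / w) ** 2))

    def with_tau_uptake(self, tau: float) -> "MuscleParams":
        return replace(self, tau_uptake=tau)


@dataclass
class MuscleState:
    """Instantaneous muscle state at fixed length ``x_m``."""

    ca: float = 0.0
    cat: float = 0.0
    a: float = 0.0
    f_t: float = 0.0
    x_m: float = -8.0


def _check_length(x_m: float) -> None:
    if not X_MIN <= x_m <= X_MAX:
        raise ParameterError(f"X_m={x_m} outside [{X_MIN}, {X_MAX}] mm")


# -- module updates (single-step reference implementations) -----------------

def calcium_from_spikes(state: MuscleState, spikes_in_step: int, dt: float,
                        params: MuscleParams) -> MuscleState:
    """Module 1: saturable per-spike release plus first-order uptake."""
    if dt <= 0:
        raise ParameterError("dt must be positive")
    ca = state.ca
    for _ in range(spikes_in_step):
        ca += params.ca_release * (1.0 - ca / params.ca_sat)
    ca *= math.exp(-dt / params.tau_uptake)
    state.ca = ca
    return state


def activation_from_calcium(state: MuscleState, dt: float,
                            params: MuscleParams) -> MuscleState:
    """Module 2: Ca-troponin binding and Hill activation."""
    kon = params.k_on * state.ca
    rate = kon + params.k_off
    cat_inf = kon / rate if rate > 0 else 0.0
    state.cat = cat_inf + (state.cat - cat_inf) * math.exp(-rate * dt)
    ka = params.ka_at(state.x_m)
    cn = state.cat ** params.hill_n
    state.a = cn / (cn + ka ** params.hill_n)
    return state


def force_from_activation(state: MuscleState, dt: float,
                          params: MuscleParams) -> MuscleState:
    """Module 3: first-order relaxation toward A * FL(X_m)."""
    target = state.a * params.fl_at(state.x_m) * params.f_max
    state.f_t = target + (state.f_t - target) * math.exp(-dt / params.tau_f)
    return state


# -- full simulation (numba kernel chains the three modules) ----------------

@njit(cache=True)
def _muscle_kernel(spike_steps, nsteps, dt, ca_release, ca_sat, tau_u,
                   k_on, k_off, hill_n, ka, fl, f_max, tau_f, out):
    ca = 0.0
    cat = 0.0
    f = 0.0
    si = 0
    decay_u = math.exp(-dt / tau_u)
    decay_f = math.exp(-dt / tau_f)
    kan = ka ** hill_n
    for t in range(nsteps):
        while si < spike_steps.shape[0] and spike_steps[si] == t:
            ca += ca_release * (1.0 - ca / ca_sat)
            si += 1
        ca *= decay_u
        kon = k_on * ca
        rate = kon + k_off
        cat_inf = kon / rate
        cat = cat_inf + (cat - cat_inf) * math.exp(-rate * dt)
        cn = cat ** hill_n
        a = cn / (cn + kan)
        target = a * fl * f_max
        f = target + (f - target) * decay_f
        out[t + 1] = f
    return f


def simulate_muscle(spikes, x_m: float, duration: float, dt: float,
                    params: MuscleParams | None = None) -> np.ndarray:
    """Isometric force trace (length ``duration/dt + 1``) from a spike train.

    ``spikes`` are arrival times at the muscle in ms (efferent conduction
    delay already applied).  Deterministic.
    """
    params = params or MuscleParams()
    _check_length(x_m)
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size and np.any(np.diff(spikes) <= 0):
        raise ContractError("spike times must be strictly increasing")
    nsteps = int(round(duration / dt))
    spike_steps = np.floor(spikes[(spikes >= 0) & (spikes < duration)] / dt).astype(np.int64)
    out = np.zeros(nsteps + 1)
    _muscle_kernel(
        spike_steps, nsteps, dt,
        params.ca_release, params.ca_sat, params.tau_uptake,
        params.k_on, params.k_off, params.hill_n,
        params.ka_at(x_m), params.fl_at(x_m), params.f_max, params.tau_f,
        out,
    )
    return out


@dataclass(frozen=True)
class TwitchMetrics:
    peak: float
    time_to_peak: float      # ms from onset
    duration: float          # ms, onset (1% peak) to decay below 10% peak
    onset_time: float


def twitch_metrics(force: np.ndarray, dt: float, spikes=None) -> TwitchMetrics | None:
    """Twitch shape metrics from a single-spike force trace.

    Duration runs from force onset (first sample above 1% of the twitch
    peak) to the decay below 10% of the peak; thresholds are relative, so
    the result is amplitude-scale invariant.  Returns ``None`` for an
    all-zero trace (no twitch).
    """
    if spikes is not None and len(np.atleast_1d(spikes)) > 1:
        raise ContractError("twitch metrics require a single-spike trace")
    force = np.asarray(force, dtype=float)
    peak = float(force.max())
    if peak <= 0.0:
        return None
    ipk = int(force.argmax())
    above_on = np.nonzero(force > 0.01 * peak)[0]
    onset = int(above_on[0])
    after = np.nonzero(force[ipk:] < 0.10 * peak)[0]
    end = ipk + int(after[0]) if after.size else len(force) - 1
    return TwitchMetrics(
        peak=peak,
        time_to_peak=(ipk - onset) * dt,
        duration=(end - onset) * dt,
        onset_time=onset * dt,
    )


def single_twitch(params: MuscleParams, x_m: float = -8.0, duration: float = 1200.0,
                  dt: float = 0.5) -> np.ndarray:
    """Force trace for one spike delivered at t=0 at length ``x_m``."""
    return simulate_muscle(np.array([0.0]), x_m, duration, dt, params)
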