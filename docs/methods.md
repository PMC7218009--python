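# Methods

`picloop` simulates a closed-loop mammalian motor unit: a branched-cable
cat α-motoneuron whose dendrites carry a relocatable hot-spot of L-type
Ca_v1.3 channels (the source of the persistent inward current, PIC), a
three-module muscle unit converting the motoneuron spike train into
isometric force at a fixed muscle length X_m, and muscle-spindle afferent
feedback whose strength depends on X_m. This note records the model, its
assumptions, the calibration constraints, the numerical scheme, and the
design decisions taken where the problem was genuinely open.

## Motoneuron

**Morphology.** The default cell is a parametric synthetic arbor: ten stem
dendrites (13 μm at the soma) leaving a collapsed cylindrical soma
(48.8 μm diameter = length), each stem branching twice more into
Rall-compatible children (d_parent^1.5 = Σ d_child^1.5) and reaching at
least 1.8 mm of dendritic path; diameters taper linearly by 30 % per mm.
An axonal hillock (20 μm, tapering 13 → 3.3 μm) and initial segment
(30 μm at 3.3 μm) are attached to the soma. Stem diameter and taper were
chosen so that the 0.1–1.0 mm band grid spans roughly 0.05–0.6 λ of mean
electrotonic distance, the range reported for adult cat α-motoneuron
dendrites; with the originally considered 8 μm stems every band sat about
twice as far electrotonically, outside the cat range. Real SWC
reconstructions can be loaded instead (`load_swc`); the soma samples are
collapsed to one equivalent-area section and the same axon stub is
appended.

**Passive properties.** C_m = 1 μF/cm² and R_i = 70 Ω·cm uniformly.
Specific membrane resistivity is nonuniform — 225 Ω·cm² at the soma (a
somatic shunt) rising sigmoidally (midpoint 60 μm, slope 40 μm of path) to
11 kΩ·cm² over the dendrites — the step/sigmoidal R_m structure used for
cat motoneurons. Resting potential −70 mV.

**Channels.** Somatic spiking machinery: fast Na (m³h, 120 mS/cm²),
delayed-rectifier K (n⁴, 400 mS/cm²), persistent Na (m, 0.1 mS/cm²),
N-type Ca (m²h, 1.6 mS/cm²) feeding the somatic calcium pool, and a
Ca-dependent K (Hill n = 2, K_d = 0.5 μM, 30 mS/cm²) producing the AHP.
The hillock/initial segment carry Na/K_DR/NaP at 3×/2×/3× somatic
density. All gates use Boltzmann steady states with sigmoidal voltage-
dependent time constants; the exact constants (see `biophysics.py`) are
this package's own: published motoneuron models differ in these values,
so the defaults were tuned to satisfy the behavioural property suite — a
rest near −70 mV, a rheobase of ~8–10 nA on the reduced test cell, a
primary range of roughly 5–30 Hz over 10–50 nA without depolarization
block, and a ~250 ms AHP class after calibration.

**Dendritic Ca_v1.3 (the PIC).** A single non-inactivating activation gate
with V_half = −45 mV (low-voltage activated: half open at −45 mV) and
slope 4.5 mV. Its time constant is strongly voltage dependent:
τ(V) = 60 + 8000 / (1 + exp((V + 62)/2)) ms — a few hundred ms in the
ignition range near −55 mV and 6–8 s below −65 mV. The slow hyperpolarized
tail is what carries residual activation across the ~1–2 s gaps between
repeated stimuli and thereby produces warm-up; the faster mid-range lets
plateaus ignite within one triangular ramp. Channels are placed as a
*hot-spot*: every dendritic segment whose path distance from the soma
falls within D_path ± 0.1 mm, on all branches, receives the same density,
which is then set by calibration (below).

**Somatic calcium pool.** Thin-shell dynamics
d[Ca]/dt = −k_in·I_CaN − ([Ca] − [Ca]_rest)/τ_Ca with k_in = 10 μM per
mA·cm⁻²·ms and [Ca]_rest = 0.05 μM. τ_Ca is a free parameter fixed by the
AHP/twitch speed-coupling calibration.

## Muscle unit

Three chained modules at fixed length X_m ∈ [−16, 0] mm (isometric only;
−8 mm is the optimal length, −16 the physiological minimum, 0 the
maximum):

1. *Spikes → Ca.* Each arriving spike (10 ms efferent conduction delay)
   releases ΔCa = R·(1 − Ca/Ca_sat) with R = 0.35 and Ca_sat = 2.5
   (normalized units); between spikes Ca decays with the uptake constant
   τ_u (calibrated, of order 100 ms).
2. *Ca → activation.* Bimolecular troponin binding
   d(CaT)/dt = k_on·Ca·(1 − CaT) − k_off·CaT (k_on = 0.04 /ms per unit Ca,
   k_off = 0.02 /ms), then a Hill activation
   A = CaT⁴ / (CaT⁴ + K_A(X_m)⁴) whose half-activation K_A rises as the
   muscle shortens (piecewise-linear anchors 0.42/0.30/0.24 at
   −16/−8/0 mm). This is the short-length degradation of activation: the
   same CaT activates less at short lengths, and the deficit is largest
   for twitch/subtetanic (< 20 Hz) drive.
3. *Activation → force.* F relaxes toward A·FL(X_m) with τ_f = 40 ms.
   FL is a skewed Gaussian peaking at −8 mm with FL(−16) = 0.55 and
   FL(0) = 0.85 (exact printed values for these endpoints are not
   available; the defaults only fix the required ordering). Force is
   normalized to the fused tetanus at the optimal length.

## Muscle spindle feedback

Group Ia + II drive during an isometric hold is a tonic excitatory
conductance (E_syn = 0 mV) spread uniformly over the soma and every
dendritic compartment within 1.4 mm of path. Its density G_aff(X_m)
interpolates linearly through three calibrated anchors at −16, −8 and
0 mm; only the anchor lengths are ever simulated in the reference
protocols, so the interpolation rule is this package's choice. Motor-unit
contraction does not feed back onto the spindle. A 10 ms afferent delay
applies when G_aff varies in time (the warm-up sinusoid); it is irrelevant
for constant holds.

## Calibrations

All calibrations bracket monotonically and bisect to a 2 % relative
tolerance (60-iteration cap), and are deterministic:

* **AHP/twitch speed coupling** — τ_u is set so a single-spike twitch at
  −8 mm lasts ≈ 250 ms (onset at 1 % of twitch peak to decay below 10 %),
  and τ_Ca so the AHP (spike until return within 1 mV of rest) matches the
  same 250 ms, the slow-motor-unit value. The AHP is measured with the
  dendritic Ca_v1.3 disabled: it is a somatic property and residual PIC
  would contaminate the return to rest.
* **PIC conductance** — for each hot-spot band, G_CaL is set so the
  leak-subtracted peak inward clamp deflection during a slow somatic
  voltage-clamp ramp (−70 → −30 mV over 5 s, Ca_v1.3 the only active
  channel, leak measured by an identical ramp at G_CaL = 0) equals the
  22 nA effective calcium current. The clamp holding/ramp range is not
  dictated by the source experiments in detail; the ramp from rest through
  the PIC activation range follows the usual convention for measuring
  PIC at the soma. Distal bands need higher densities than proximal ones
  (voltage-transfer attenuation), mirroring the reported density-distance
  table.
* **Spindle anchors** — G_aff at −8 and 0 mm is set so the effective
  synaptic current I_N at the soma (clamped at rest, all membrane passive,
  I_N = minus the clamp-current deflection, positive for excitation)
  equals 2.5 and 5 nA; the −16 mm anchor is exactly 0.
* **Dendritic drive** — the peak of the triangular test conductance
  G_syn placed on the hot-spot band is set so the maximum I_N equals
  16 nA. Bisection runs on the quasi-static steady measurement; the
  reported value re-measures with the full 20 s triangle.

## Stimulation protocols

* *Somatic ramp*: triangular I_S, 0 → 20 nA at 5 s → 0 at 10 s.
* *Dendritic ramp*: triangular G_syn on the hot-spot sites peaking at
  10 s (peak from calibration; 20 s total). The input axis for analysis is
  I_N, obtained by composing the G_syn waveform with the measured,
  effectively linear, conductance-to-current map of the passive tree.
* *Somatic warm-up*: four −5 → +10 nA triangles of 2 s with 1 s gaps
  (8 s of triangle time over 11 s); the −5 nA floor is held between
  triangles.
* *Dendritic warm-up*: G_aff swings sinusoidally (2 s period, 16 s total)
  while a −1 → −0.5 nA step (switch at 4 s) holds the soma, with all
  voltage-gated channels on soma/hillock/initial segment blocked — the
  QX-314 condition, so the dendritic response is observed without
  spiking. The sinusoid swings between G_aff(X_m) and G_aff(0 mm):
  tendon vibration from the held length up to the maximal length. At
  X_m = −16 this reproduces the full 0-to-maximum swing of the reference
  protocol; at longer holds the elevated floor is what abolishes warm-up.
  (The alternative reading — a fixed 0-to-maximum swing regardless of
  X_m — would make the held length irrelevant under QX-314 and could not
  produce any length dependence.)

Every run settles for 1 s under the protocol's starting drive before
recording. Spikes are forwarded to the muscle with the 10 ms efferent
delay.

## Input-output indices

From each ramp, force and firing rate are resampled against the stimulus
(grid 0.05 nA; boundary ties resolve toward the earlier time) separately
for the ascending and descending phases.

* **DCT** = force-initiation current − force-cessation current (force
  crossing 1 % of the run's peak force on each phase). Positive DCT means
  force persists below the ascending threshold: self-sustained force.
* **DCI** = current interval from force initiation to 63 % of the
  ascending peak force (linear interpolation between grid samples);
  1/DCI is the rate of force development.
* **PIC onset** = first ascending stimulus from which the local f–I slope
  exceeds 2× the primary-range slope (fitted over the first ~1 nA above
  recruitment) sustained over ≥ 0.5 nA; absent if never. The onset
  criterion is not printed in the source experiments; the factor and
  window are declared defaults, robust to twitch ripple.
* **DFG** = descending-minus-ascending force read at the PIC-onset
  current, forced to zero when onset is absent or within 0.5 nA of
  recruitment (no bistable transition to potentiate force).
* **Firing types**: I — no acceleration, no hysteresis; IV — acceleration
  above recruitment with hysteresis; III — acceleration at recruitment
  with hysteresis.
* **Warm-up flag** — per-trial peaks must increase strictly by > 1 %
  relative at every step. For spiking trials the series is the peak
  instantaneous firing rate (per-trial peak force is reported alongside
  but saturates near tetanic fusion, so it is not the flag criterion);
  under QX-314 the series are the per-cycle peak somatic and
  dendritic-site depolarizations measured from the resting potential,
  both required to grow.

## Numerics

Fixed-step integration at dt = 0.025 ms by default. Gates advance by the
exact exponential (CNEXP-style) update at the pre-step voltage; voltages
solve implicitly with a symmetric Crank–Nicolson scheme via one
leaf-to-root elimination and back-substitution on the tree matrix
(unconditionally stable on passive trees; second order in time). Spatial
grid: every compartment shorter than 0.1 of the local 100 Hz space
constant (0.2 in the reduced test profile). Somatic spikes are upward
0 mV crossings with a 1 ms lockout. The voltage clamp is ideal
(infinite gain): the somatic voltage is pinned each step and the holding
current reported. Clamp-based calibrations, which involve no spikes, use
dt = 0.1 ms; free-running sweep and warm-up runs in the test profile use
dt = 0.05 ms. The muscle integrates at dt = 0.5 ms (its fastest time
constant is tens of ms). The cable inner loop is compiled with numba.

## Study scales

The acceptance script and the examples that need the full cell use the
default ten-stem arbor at the 0.1 λ grid (≈ 1900 compartments). The test
suite's sweep fixtures use a four-stem, two-branch-order arbor at 0.2 λ
(≈ 180 compartments), the package's desk-scale study profile; all
calibrations are re-run on that profile, so its results are
self-consistent rather than transplanted from the large cell.

## What the synthetic generator does and does not emulate

It reproduces the *scale* of an adult cat α-motoneuron — stem count, path
lengths, tapering, electrotonic extent — with deterministic seeded jitter
in branch positions. It does not reproduce the irregular branch-length
and diameter statistics, the per-branch asymmetry, or the 3-D embedding
of a real reconstruction. Consequences: calibrated densities (G_CaL per
band, G_aff anchors, G_syn peak) differ numerically from values obtained
on any particular reconstruction — they are morphology-specific by
construction — while the calibrated *currents* (22 / 2.5 / 5 / 16 nA) and
the qualitative location–length structure are morphology-independent
claims. Passing tests therefore certify the mechanisms and the calibrated
operating point, not reconstruction-specific conductance values.

## Known limitations

* Isometric contractions only; no force–velocity dynamics, tendon
  compliance, fatigue or sag.
* No Na-type PIC (Na_v1.1/1.6), no Ib/Golgi tendon organ pathway, no
  background synaptic noise or inhibition, no contraction-to-spindle
  coupling — all outside the model's scope.
* The calcium reversal is ohmic and fixed (+60 mV); no GHK flux.
* When a ramp ends with force still above the 1 % threshold (the
  descending stimulus reaches its floor before the plateau collapses),
  the cessation current saturates at the stimulus floor and DCT reduces
  to the initiation current. In that floor-bound regime DCT inherits the
  initiation current's mild *decrease* with hot-spot distance (distal
  hot-spots pass more tonic/subthreshold PIC to the soma), so the
  monotone growth of DCT with D_path holds where derecruitment stays
  positive — robustly at the shortest length under somatic drive — but
  degrades at long muscle lengths and under dendritic drive, where
  nearly every location self-sustains to the end of the protocol. The
  same tonic-PIC effect can make the proximal force development at the
  longest length marginally faster than mid-band, and the delayed full
  ignition of very distal plateaus under somatic drive can leave a
  positive DFG at 0.9–1.0 mm at the shortest length. These deviations are
  properties of the present cell and kinetics at desk scale; the
  corresponding acceptance checks are left failing rather than weakened.
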