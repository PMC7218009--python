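# picloop

Closed-loop motor unit simulation with relocatable dendritic PIC
hot-spots.

A motor unit — one spinal motoneuron plus the muscle fibres it innervates
— turns synaptic drive into force. Motoneuron dendrites carry L-type
Ca_v1.3 channels whose persistent inward current (PIC) makes firing
nonlinear: rate acceleration on rising input, self-sustained firing on
falling input (counterclockwise hysteresis). *Where* those channels sit
along the dendrites, and *how long* the muscle is held, jointly shape the
force output. `picloop` implements the full loop so both factors can be
varied systematically:

* a branched-cable cat α-motoneuron (synthetic parametric arbor or SWC
  reconstruction) with nonuniform passive properties, somatic/axonal
  spiking channels, and a Ca_v1.3 *hot-spot* placed on all branches at a
  chosen path distance D_path from the soma;
* a three-module muscle unit (spikes → sarcoplasmic Ca → Ca-troponin/
  activation → Hill-type force) with length-dependent activation and a
  force–length curve peaking at the optimal length X_m = −8 mm;
* tonic muscle-spindle feedback distributed over the proximal 1.4 mm of
  dendrite, calibrated per muscle length;
* the standard stimulation protocols (triangular somatic current ramp,
  triangular dendritic conductance ramp, repeated triangles and
  sinusoidal afferent drive for warm-up) and the input–output indices

  - **DCT** (nA) — force-threshold difference between ascending and
    descending phases: the self-sustained force range,
  - **DCI** (nA) — current from force initiation to 63 % of peak force;
    1/DCI is the rate of force development,
  - **DFG** — descending-minus-ascending force at the current where the
    firing rate accelerates (full PIC activation): force potentiation,
  - the **warm-up** flag — strict growth of response peaks across
    repeated identical stimuli.

Free parameters are pinned by calibration, not by hand: twitch and AHP
durations speed-coupled at ≈ 250 ms (slow motor unit), the PIC sized to a
22 nA effective calcium current at the clamped soma, spindle drive sized
to effective synaptic currents of 0 / 2.5 / 5 nA at muscle lengths
−16 / −8 / 0 mm, and the dendritic test drive to a 16 nA peak.

See `docs/methods.md` for the model equations, assumptions and numerical
scheme.

## Worked example

```bash
python examples/03_somatic_ramp.py
```

calibrates a reduced four-stem model, applies the 0 → 20 → 0 nA somatic
triangle with the hot-spot at D_path 0.6 mm and the muscle at the optimal
length, and prints:

```
spikes: 101, peak force: 0.918 F_max
recruitment:   5.64 nA
derecruitment: 2.58 nA
PIC onset:     16.73 nA
DCT: 4.45 nA   DCI: 2.83 nA   DFG: 0.089
firing pattern: type IV
```

Firing starts at 5.64 nA but persists down to 2.58 nA on the descending
phase; force outlasts its onset threshold by 4.45 nA (DCT — self-sustained
force from the dendritic plateau); the rate accelerates at 16.73 nA, well
above recruitment, and the force measured there is 0.089 F_max higher on
the way down than on the way up (DFG — PIC-induced potentiation). That
combination — acceleration above recruitment plus hysteresis — is the
type IV input–output pattern.

The other examples cover the remaining capabilities: `01` morphology and
electrotonic band structure, `02` the calibration chain and its report,
`04` a reduced hot-spot location sweep, `05` warm-up under repeated
somatic triangles.

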