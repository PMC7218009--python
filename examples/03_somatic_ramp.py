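"""Run a triangular somatic current ramp and compute the hysteresis indices.

A 0-20-0 nA triangle (peak at 5 s) drives the calibrated motoneuron with
the Cav1.3 hot-spot at D_path 0.6 mm during an isometric hold at the
optimal muscle length.  The force-vs-current loop is summarized by DCT
(self-sustained force range, nA), DCI (current from force onset to 63% of
peak force; 1/DCI is the rate of force development) and DFG (descending-
minus-ascending force at the PIC acceleration current).
"""

from picloop import ProtocolSpec, build_io_curve, compute_indices, run_ramp
from picloop.config import RunConfig, SyntheticMorphology, cmd_calibrate

config = RunConfig(
    synthetic=SyntheticMorphology(n_stems=4, branch_depth=2, seed=1),
    max_electrotonic_segment=0.2,
    d_path=0.6,
)
cal = cmd_calibrate(config)

proto = ProtocolSpec(mode="somatic_ramp", x_m=-8.0, d_path=0.6)
traces, force = run_ramp(cal.model, proto, cal.anchors, cal.muscle, dt=0.05)
io = build_io_curve(traces, traces.channels["force"], mode="somatic")
idx = compute_indices(io)

print(f"spikes: {len(traces.spikes)}, peak force: {io.peak_force:.3f} F_max")
print(f"recruitment:   {idx.recruitment:.2f} nA")
print(f"derecruitment: {idx.derecruitment:.2f} nA")
print(f"PIC onset:     {idx.pic_onset and round(idx.pic_onset, 2)} nA")
print(f"DCT: {idx.dct:.2f} nA   DCI: {idx.dci:.2f} nA   DFG: {idx.dfg:.3f}")
print(f"firing pattern: type {idx.firing_type}")
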