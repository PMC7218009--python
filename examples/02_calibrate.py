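"""Calibrate the closed-loop motor unit and print the calibration report.

Runs the four calibration routines in dependency order on a reduced
(four-stem) model: AHP/twitch speed coupling at ~250 ms, Cav1.3 density
for a 22 nA effective calcium current at the soma, spindle conductance
anchors for effective synaptic currents of 0/2.5/5 nA at muscle lengths
-16/-8/0 mm, and the dendritic test-drive peak for a 16 nA maximum.
"""

from picloop.config import RunConfig, SyntheticMorphology, cmd_calibrate

config = RunConfig(
    synthetic=SyntheticMorphology(n_stems=4, branch_depth=2, seed=1),
    max_electrotonic_segment=0.2,
    d_path=0.6,
)
cal = cmd_calibrate(config)

print(f"{'parameter':>18} {'value':>10} {'target':>8} {'achieved':>9} {'resid':>7}")
for rep in cal.manifest["reports"]:
    print(f"{rep['parameter']:>18} {rep['value']:>10.4g} {rep['target']:>8.4g} "
          f"{rep['achieved']:>9.4g} {rep['residual']:>7.1%}")
print(f"\nspindle anchors (X_m mm -> G_aff uS/cm^2): {cal.anchors}")
print(f"band mean electrotonic length: "
      f"{cal.manifest['mean_electrotonic_length']:.3f} lambda")
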