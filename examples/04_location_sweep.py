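"""Sweep the PIC hot-spot location and tabulate the motor-output indices.

Maps DCT, DCI and DFG over three hot-spot distances at the shortest and
optimal muscle lengths under somatic stimulation — a reduced version of
the full 10x3 location-length grid.
"""

from picloop.config import RunConfig, SyntheticMorphology, cmd_calibrate, cmd_sweep

config = RunConfig(
    synthetic=SyntheticMorphology(n_stems=4, branch_depth=2, seed=1),
    max_electrotonic_segment=0.2,
    d_path=0.6,
)
cal = cmd_calibrate(config)
df = cmd_sweep(cal, config, dpath_grid=[0.2, 0.6, 1.0], xm_grid=[-16.0, -8.0],
               mode="somatic_ramp", dt=0.05)
cols = ["d_path", "x_m", "lambda_mean", "g_cal", "recruitment",
        "derecruitment", "dct", "dci", "dfg"]
print(df[cols].round(3).to_string(index=False))
print("\nDCT grows as the hot-spot moves distally (derecruitment falls much"
      "\nfaster than recruitment), and force potentiation (DFG > 0) appears"
      "\nonly once the hot-spot is electrotonically remote enough for its"
      "\nplateau to outlast the somatic drive.")
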