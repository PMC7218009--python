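"""Build a synthetic cat-scale motoneuron arbor and inspect its hot-spot bands.

Generates the default ten-stem dendritic tree, then selects the Cav1.3
hot-spot band at each path distance D_path on the 0.1-1.0 mm grid and
prints the band's mean electrotonic distance (in units of the local space
constant lambda) and membrane area — the geometry that determines how a
PIC placed there couples to the soma.
"""

from picloop import PassiveParams, generate_synthetic_tree, select_band

tree = generate_synthetic_tree(seed=1)
passive = PassiveParams()

print(f"sections: {len(tree.sections)}, "
      f"max dendritic path: {tree.max_dendritic_path() / 1000:.2f} mm, "
      f"dendritic area: {tree.total_dendritic_area() / 1e4:.0f} x10^4 um^2")
print(f"{'D_path (mm)':>12} {'mean lambda':>12} {'sites':>6} {'area (um^2)':>12}")
for i in range(1, 11):
    center = round(0.1 * i, 1)
    band = select_band(tree, center, 0.1, passive)
    print(f"{center:>12.1f} {band.mean_electrotonic_length:>12.3f} "
          f"{len(band.sites):>6d} {band.total_area:>12.0f}")
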