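"""Cell capacity of hexagonally packed microcavity arrays.

The arrays are 11 mm circular carriers densely packed with cavities separated
by 3 µm walls. The idealized lattice estimate below reproduces the array
capacities used to argue that cultures never saturate the scaffold.
"""

from nichepls import GEOMETRY_PRESETS, ArrayGeometry, array_capacity

for name in ("cav15", "cav40"):
    geom = GEOMETRY_PRESETS[name]
    cavities, cells = array_capacity(geom)
    print(
        f"{geom.cavity_diameter:.0f} um cavities (pitch {geom.pitch:.0f} um, "
        f"{geom.cells_per_cavity} cell/cavity): "
        f"{cavities:,} cavities -> max {cells:.2e} cells"
    )

# capacity scales with the inverse square of the pitch
half = ArrayGeometry(array_diameter=11_000, cavity_diameter=7.5, wall_thickness=1.5)
print(f"halving the pitch quadruples capacity: {array_capacity(half)[0]:,} cavities")
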