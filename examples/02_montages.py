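"""Construct the fifteen study montage configurations.

Prints, for each configuration, the electrode sizes and the edge-to-edge
scalp distance.  The size round (APPS_1X1..7X5) shares one matched distance;
the distance round (APPS_P0..P8) steps it by +2 cm; OPT_APPS is 2 cm closer
than the 1x1 baseline.
"""

from tdcsim import PhantomSpec, build_phantom, edge_to_edge_distance, locate_1010
from tdcsim.montage import MONTAGE_NAMES, build_study_montage

phantom = build_phantom(PhantomSpec())
eeg = locate_1010(phantom)

print(f"{'montage':10s} {'round':7s} {'electrodes':26s} edge-to-edge")
for name in MONTAGE_NAMES:
    m = build_study_montage(name, phantom, eeg)
    shapes = []
    for el in m.electrodes:
        if el.shape.kind == "rect":
            shapes.append(f"{el.shape.width_cm:g}x{el.shape.height_cm:g}")
        else:
            shapes.append(f"disc{el.shape.diameter_cm:g}")
    d = edge_to_edge_distance(m, phantom)
    print(f"{name:10s} {m.round_tag:7s} {'+'.join(shapes):26s} {d:6.2f} cm")
# The printed distances are phantom-specific: on real heads the CP3-FC3
# baseline averages 2.12 cm (7x5 pads) and 6.12 cm (1x1 pads).
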