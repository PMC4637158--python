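"""Conduction velocities of the homogeneous tissue (Bondarenko kinetics).

A plane wave is launched along (LP) and across (TP) the fiber
direction of calibrated homogeneous strips of the discrete model.
Expected output: LP about 410 um/ms, TP about 130 um/ms, anisotropy
ratio TP/LP about 0.32.  Runtime: a few minutes (the reaction substep
is 0.1 us because of the stiff Markov-chain kinetics).
"""

from fibrosim import build_template, tile_template, reduce_to_network
from fibrosim import BondarenkoModel, MonodomainParams
from fibrosim.discrete import simulate_discrete, network_plane_protocol
from fibrosim.analysis import plane_activation_cv

model = BondarenkoModel()
params = MonodomainParams()
unit = build_template()

cv = {}
for direction, tiles, side, T in (("LP", (8, 1), "left", 16.0),
                                  ("TP", (1, 21), "bottom", 32.0)):
    net = reduce_to_network(tile_template(unit, *tiles))
    prot = network_plane_protocol(net, model, side)
    res = simulate_discrete(net, model, params, prot, T_end=T)
    axis = 0 if direction == "LP" else 1
    cv[direction] = plane_activation_cv(res.activation_map, net.centroid_um[:, axis])
    print(f"CV {direction}: {cv[direction]:6.1f} um/ms")

print(f"anisotropy ratio TP/LP: {cv['TP'] / cv['LP']:.3f}")
print("Interpretation: the fiber-aligned myocyte geometry and the")
print("plicate/interplicate/combined-plicate junction placement make the")
print("tissue conduct ~3x faster along the fibers than across them.")
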