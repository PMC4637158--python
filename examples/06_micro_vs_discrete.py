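"""Microscopic vs discrete model: one action potential, side by side.

Both models simulate the same homogeneous two-unit strip with the
Bondarenko kinetics; the voltage at the cell nearest the strip centre
(its centroid volume in the microscopic mesh) is compared.  The
printed summary shows where the one-node-per-myocyte reduction is
faithful (morphology, repolarization) and where its lumped nature
shows (later activation, electrotonically flattened peak).
Runtime: several minutes (the microscopic run integrates ~2000 volumes
at a 0.1 us reaction substep).
"""

import numpy as np

from fibrosim import build_template, tile_template, reduce_to_network
from fibrosim import BondarenkoModel, MonodomainParams
from fibrosim.micro import simulate_microscopic, mesh_plane_protocol
from fibrosim.discrete import simulate_discrete, network_plane_protocol

model = BondarenkoModel()
params = MonodomainParams()
mesh = tile_template(build_template(), 2, 1)
net = reduce_to_network(mesh)

cell = int(np.argmin(((net.centroid_um - [net.extent_um[0] / 2,
                                          net.extent_um[1] / 2]) ** 2).sum(axis=1)))
vx = int(net.centroid_um[cell, 0] / mesh.h)
vy = int(net.centroid_um[cell, 1] / mesh.h)

res_m = simulate_microscopic(
    mesh, model, params,
    mesh_plane_protocol(mesh, model, "left", depth_volumes=16),
    T_end=30.0, probes=[vy * mesh.nx + vx])
res_d = simulate_discrete(
    net, model, params,
    network_plane_protocol(net, model, "left"),
    T_end=30.0, probes=[cell])

t = res_m.times
for name, tr in (("microscopic", res_m.probe_traces[0]),
                 ("discrete", res_d.probe_traces[0])):
    i_act = np.argmax(tr > -60.0)
    print(f"{name:12s}: activation {t[i_act]:5.2f} ms, "
          f"peak {tr.max():6.1f} mV, V(25 ms) {tr[int(25 / 0.01)]:7.1f} mV")
print("Interpretation: the reduction reproduces the AP waveform; its")
print("isopotential cells activate slightly later and peak lower because")
print("the whole lumped membrane charges at once.")
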