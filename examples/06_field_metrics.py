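"""Compare two simulated fields with the standard summary statistics.

Solves the same two-layer slab with arithmetic and harmonic face
interpolation of the conductivity, then reports percentile tables, the
relative magnitude difference, the angle difference, and a line profile —
the toolkit used to contrast independent tES pipelines.
"""

import numpy as np

from tesfv import (
    BoundarySpec,
    SolverConfig,
    TissueTable,
    angle_difference_map,
    assemble,
    gradient_lsq,
    hotspot_mask,
    isotropic_field,
    magnitude_stats,
    ortho_box_mesh,
    relative_difference_map,
    sample_line,
    solve_potential,
)

mesh = ortho_box_mesh((3, 3, 8), label_of_k=lambda k: np.where(k < 4, 1, 2))
cond = isotropic_field(mesh, TissueTable({1: 1.0, 2: 0.25}))
bc = BoundarySpec({"zmin": 5.0, "zmax": -5.0})

fields = {}
for mode in ("arithmetic", "harmonic"):
    system = assemble(mesh, cond, bc, SolverConfig(face_interpolation=mode))
    fields[mode] = gradient_lsq(system, solve_potential(system))

for mode, E in fields.items():
    s = magnitude_stats(E, mesh, compartment=2)
    print(f"{mode:>10} |E| in layer 2: mean {s.mean:.1f}  p90 {s.p90:.1f}  p99 {s.p99:.1f} V/m")

rel = relative_difference_map(fields["harmonic"], fields["arithmetic"])
ang = angle_difference_map(fields["harmonic"], fields["arithmetic"])
print(f"relative |E| difference: median {np.nanmedian(rel):.2f} %")
print(f"angle difference:        median {np.nanmedian(ang):.3f} deg")
print(f"hotspot cells (>p90 of |E|): {hotspot_mask(fields['harmonic']).sum()} of {mesh.n_cells}")

prof = sample_line(mesh, np.linalg.norm(fields["harmonic"], axis=1), [1.2, 1.2, 0.0], [1.2, 1.2, 7.0], 8)
print("line profile of |E| (V/m) across the interface:")
for t, v, lab in zip(prof["t"], prof["value"], prof["label"]):
    print(f"  z={t:4.1f} mm  layer {lab}:  {v:8.2f}")
# the two interpolation modes agree in direction (angle ~0) but differ in
# magnitude near the conductivity jump, where harmonic weighting is the
# physically consistent choice; the profile shows the 1:4 field jump.
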