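"""Compute 10-20 electrode positions on a scalp from four fiducials.

On the unit sphere with canonical fiducials the construction has a closed
form (great-circle arc fractions), so the printed positions can be checked
by eye: Cz at the vertex, C3/C4 at 36 degrees colatitude, Oz/Fpz at 72.
"""

import numpy as np
import trimesh

from tesfv import FiducialSet, TriSurface, locate_1020

ico = trimesh.creation.icosphere(subdivisions=5, radius=1.0)
scalp = TriSurface(np.asarray(ico.vertices), np.asarray(ico.faces), name="scalp")
fid = FiducialSet(
    nasion=[0, 1, 0], inion=[0, -1, 0], tragus_left=[-1, 0, 0], tragus_right=[1, 0, 0]
)

positions = locate_1020(scalp, fid)
for name in ("Cz", "C3", "C4", "Fz", "Pz", "Oz", "Fpz", "T3", "T4", "O1", "O2"):
    x, y, z = positions[name]
    colat = np.degrees(np.arccos(np.clip(z, -1, 1)))
    print(f"{name:>4}: ({x:+.3f}, {y:+.3f}, {z:+.3f})   colatitude {colat:6.2f} deg")
# C3/C4 should sit at 36.00 deg colatitude toward the left/right tragus and
# mirror each other through the sagittal plane; Oz/Fpz at 72.00 deg along
# the inion/nasion meridian.
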