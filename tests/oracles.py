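"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities with different algorithms than the
package (plane-intersection ray casting along a fixed axis, closed-form
geometry, order statistics) so agreement is a genuine cross-check.
"""

import numpy as np


def ray_crossing_contains(points, surface, axis=0):
    """Point-in-polyhedron by counting +axis ray crossings (brute force).

    For each triangle: intersect the ray with the triangle plane, then test
    the projected 2-D point against the projected triangle with barycentric
    coordinates.
    """
    points = np.atleast_2d(np.asarray(points, float))
    v = surface.vertices
    t = surface.triangles
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    n = np.cross(b - a, c - a)
    u, w = [ax for ax in range(3) if ax != axis]
    denom = n[:, axis]
    ok = np.abs(denom) > 1e-14

    out = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        tt = np.einsum("ij,ij->i", n, a - p) / np.where(ok, denom, 1.0)
        # 2-D barycentric test in the projection plane
        p2 = p[[u, w]]
        a2, b2, c2 = a[:, [u, w]], b[:, [u, w]], c[:, [u, w]]

        def cross2(x, y):
            return x[:, 0] * y[:, 1] - x[:, 1] * y[:, 0]

        d = cross2(b2 - a2, c2 - a2)
        dn = np.where(np.abs(d) > 1e-300, d, 1.0)
        l1 = cross2(b2 - p2[None, :] * np.ones_like(b2), c2 - p2) / dn
        l2 = cross2(c2 - p2[None, :] * np.ones_like(c2), a2 - p2) / dn
        l3 = 1.0 - l1 - l2
        hit = ok & (tt > 0) & (l1 >= 0) & (l2 >= 0) & (l3 >= 0)
        out[i] = hit.sum() % 2 == 1
    return out
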