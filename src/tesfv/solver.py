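"""Cell-centered finite-volume solver for the quasi-static potential.

Under the quasi-static approximation the potential obeys
``div(sigma grad phi) = 0`` with Dirichlet values on the electrode surfaces
(+5/-5 V by default) and zero-gradient Neumann elsewhere.  The Laplacian is
discretized with the Gauss scheme and linear (distance-weighted) face
interpolation; the flux through each internal face is split, over-relaxed,
into an implicit orthogonal 2-point part

    a_f = sigma_nn |A_f|^2 / (A_f . d_ON)

and an explicit non-orthogonality correction driven by least-squares cell
gradients.  The correction is lagged: the linear system is re-solved (inner
relative residual 1e-6) with an updated correction until the residual of the
full discretization falls below 1e-5.

``E = -grad phi`` (weighted least squares), ``J = sigma E``, and the linear
solution is finally scaled by ``s = I_target / I_measured`` with
``I_measured`` integrated over the electrode-scalp contact surface.

Cells whose conductivity is at the insulator sentinel are excluded from the
computational domain (their boundary becomes zero-flux), mirroring the
treatment of air as a perfect insulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .conductivity import ConductivityField
from .mesh import TetMesh

__all__ = [
    "BoundarySpec",
    "SolverConfig",
    "FieldSolution",
    "FVSystem",
    "assemble",
    "solve_potential",
    "gradient_lsq",
    "current_density",
    "integrate_current",
    "scale_solution",
    "solve_tes",
]


@dataclass
class BoundarySpec:
    """Dirichlet patches (per-patch constant or per-face values, V); all other
    boundary faces are zero-gradient Neumann."""

    dirichlet: Mapping[str, float | np.ndarray]
    target_current: float = 1e-3  # A
    anode_contact: str | None = None
    cathode_contact: str | None = None

    def validate(self) -> None:
        if not self.dirichlet:
            raise ValueError("at least one Dirichlet patch is required")
        if self.target_current <= 0:
            raise ValueError("target current must be positive")


@dataclass
class SolverConfig:
    inner_tol: float = 1e-6  # linear-solver relative residual
    outer_tol: float = 1e-5  # residual of the fully corrected discretization
    max_outer: int = 200
    correction: str = "corrected"  # none | corrected | limited
    alpha: float = 1.0  # blend of the explicit correction in "limited" mode
    correction_relaxation: float = 0.7  # under-relaxation of the lagged correction
    face_interpolation: str = "arithmetic"  # or "harmonic" (normal component)
    insulator_threshold: float = 1e-12  # S/m; below -> cell excluded
    exclude_insulators: bool = True
    direct_below: int = 20000  # use a sparse direct solve for small systems
    preconditioner: str = "auto"  # auto | jacobi | ilu

    def __post_init__(self) -> None:
        if self.correction not in {"none", "corrected", "limited"}:
            raise ValueError(f"unknown correction mode {self.correction!r}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if min(self.inner_tol, self.outer_tol) <= 0:
            raise ValueError("tolerances must be positive")

    @property
    def correction_factor(self) -> float:
        if self.correction == "none":
            return 0.0
        if self.correction == "limited":
            return self.alpha
        return 1.0


@dataclass
class FieldSolution:
    """Per-cell potential, field, current density and the current scaling."""

    phi: np.ndarray  # V
    E: np.ndarray  # V/m
    J: np.ndarray  # A/m^2
    s: float = 1.0
    I_measured: float | None = None  # A, before scaling
    residuals: list = field(default_factory=list)
    active: np.ndarray | None = None


class FVSystem:
    """Assembled sparse system plus the face data for corrections/gradients."""

    def __init__(self, mesh: TetMesh, cond: ConductivityField, bc: BoundarySpec, cfg: SolverConfig):
        bc.validate()
        if cond.n_cells != mesh.n_cells:
            raise ValueError("conductivity field does not match the mesh")
        self.mesh, self.cfg, self.bc = mesh, cfg, bc
        geo = mesh.geometry
        self.geo = geo
        T = cond.tensors

        sig_scale = np.einsum("kii->k", T) / 3.0
        bad = ~np.isfinite(sig_scale) | (sig_scale <= 0)
        if bad.any():
            raise ValueError(f"cell {int(np.flatnonzero(bad)[0])} has a singular conductivity tensor")
        if cfg.exclude_insulators:
            self.active = sig_scale > cfg.insulator_threshold
        else:
            self.active = np.ones(mesh.n_cells, dtype=bool)
        self.cell_index = np.full(mesh.n_cells, -1, dtype=np.int64)
        self.cell_index[self.active] = np.arange(int(self.active.sum()))
        self.n = int(self.active.sum())

        # --- internal faces between two active cells -----------------------
        keep = self.active[geo.int_owner] & self.active[geo.int_neighbour]
        o, nb = geo.int_owner[keep], geo.int_neighbour[keep]
        A = geo.int_area_vec[keep]
        xf = geo.int_centroid[keep]
        xo, xn = geo.cell_centroids[o], geo.cell_centroids[nb]
        d = xn - xo
        t = np.einsum("ij,ij->i", xf - xo, d) / np.einsum("ij,ij->i", d, d)
        t = np.clip(t, 0.0, 1.0)
        sig_f = (1 - t)[:, None, None] * T[o] + t[:, None, None] * T[nb]
        nrm = A / np.linalg.norm(A, axis=1, keepdims=True)
        if cfg.face_interpolation == "harmonic":
            s_o = np.einsum("ij,ijk,ik->i", nrm, T[o], nrm)
            s_n = np.einsum("ij,ijk,ik->i", nrm, T[nb], nrm)
            sig_nn = 1.0 / ((1 - t) / s_o + t / s_n)
            # keep the explicit correction consistent with the harmonic
            # normal coefficient: replace the normal-normal component of the
            # interpolated face tensor
            delta = sig_nn - np.einsum("ij,ijk,ik->i", nrm, sig_f, nrm)
            sig_f = sig_f + delta[:, None, None] * nrm[:, :, None] * nrm[:, None, :]
        elif cfg.face_interpolation == "arithmetic":
            sig_nn = np.einsum("ij,ijk,ik->i", nrm, sig_f, nrm)
        else:
            raise ValueError(f"unknown face interpolation {cfg.face_interpolation!r}")
        AdotD = np.einsum("ij,ij->i", A, d)
        if np.any(AdotD <= 0):
            raise ValueError("face area vector anti-aligned with centroid line (inverted cell?)")
        self.f_owner, self.f_neigh = o, nb
        self.f_area, self.f_d, self.f_t = A, d, t
        self.f_sig = sig_f
        self.f_a = sig_nn * np.einsum("ij,ij->i", A, A) / AdotD

        # --- Dirichlet boundary faces --------------------------------------
        d_faces, d_vals = [], []
        for patch, value in bc.dirichlet.items():
            idx = geo.boundary_face_indices(patch)
            vals = np.broadcast_to(np.asarray(value, dtype=float), idx.shape)
            d_faces.append(idx)
            d_vals.append(np.array(vals))
        d_idx = np.concatenate(d_faces)
        self.b_vals = np.concatenate(d_vals)
        ow = geo.bnd_owner[d_idx]
        if not self.active[ow].all():
            raise ValueError("Dirichlet patch touches an excluded (insulator) cell")
        Ab = geo.bnd_area_vec[d_idx]
        xb = geo.bnd_centroid[d_idx]
        db = xb - geo.cell_centroids[ow]
        nrm_b = Ab / np.linalg.norm(Ab, axis=1, keepdims=True)
        sig_b = np.einsum("ij,ijk,ik->i", nrm_b, T[ow], nrm_b)
        AdotDb = np.einsum("ij,ij->i", Ab, db)
        self.b_owner, self.b_area, self.b_d = ow, Ab, db
        self.b_sig_tensor = T[ow]
        self.b_a = sig_b * np.einsum("ij,ij->i", Ab, Ab) / AdotDb
        self.b_faces = d_idx

        # --- sparse SPD matrix ---------------------------------------------
        io, in_ = self.cell_index[o], self.cell_index[nb]
        ib = self.cell_index[ow]
        rows = np.concatenate([io, in_, io, in_, ib])
        cols = np.concatenate([io, in_, in_, io, ib])
        vals = np.concatenate([self.f_a, self.f_a, -self.f_a, -self.f_a, self.b_a])
        self.M = sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))
        self.b0 = np.zeros(self.n)
        np.add.at(self.b0, ib, self.b_a * self.b_vals)

        self._build_lsq()
        self._factorized = None

    # -- least-squares gradient ---------------------------------------------
    def _build_lsq(self) -> None:
        n = self.n
        io = self.cell_index[self.f_owner]
        in_ = self.cell_index[self.f_neigh]
        ib = self.cell_index[self.b_owner]
        dx_int = self.f_d
        w2_int = 1.0 / np.einsum("ij,ij->i", dx_int, dx_int)  # (1/|dx|)^2
        dx_b = self.b_d
        w2_b = 1.0 / np.einsum("ij,ij->i", dx_b, dx_b)

        G = np.zeros((n, 3, 3))
        contrib_int = w2_int[:, None, None] * dx_int[:, :, None] * dx_int[:, None, :]
        contrib_b = w2_b[:, None, None] * dx_b[:, :, None] * dx_b[:, None, :]
        np.add.at(G, io, contrib_int)
        np.add.at(G, in_, contrib_int)
        np.add.at(G, ib, contrib_b)
        # cells with < 3 independent neighbour directions (e.g. corner cells
        # with two Neumann faces): their Neumann faces join the stencil as
        # zero-normal-gradient pseudo-neighbours (phi_face = phi_cell), which
        # contributes to the normal matrix but never to the right-hand side.
        deficient = np.linalg.eigvalsh(G)[:, 0] < 1e-8
        if deficient.any():
            geo = self.geo
            is_dirichlet = np.zeros(geo.n_boundary_faces, dtype=bool)
            is_dirichlet[self.b_faces] = True
            own_idx = self.cell_index[geo.bnd_owner]
            neu = (
                (~is_dirichlet)
                & self.active[geo.bnd_owner]
                & deficient[np.maximum(own_idx, 0)]
            )
            # constraint direction = face normal (d(phi)/dn = 0), weighted like
            # a neighbour at the face distance
            An = geo.bnd_area_vec[neu]
            nhat = An / np.linalg.norm(An, axis=1, keepdims=True)
            np.add.at(G, own_idx[neu], nhat[:, :, None] * nhat[:, None, :])
            if np.any(np.linalg.eigvalsh(G)[deficient, 0] < 1e-8):
                bad = int(np.flatnonzero(self.active)[np.argmin(np.linalg.eigvalsh(G)[:, 0])])
                raise ValueError(f"cell {bad}: fewer than 3 independent neighbour directions")
        self._lsq_Ginv = np.linalg.inv(G)
        self._lsq = (io, in_, ib, dx_int, w2_int, dx_b, w2_b)

    def gradient(self, phi: np.ndarray) -> np.ndarray:
        """Weighted least-squares gradient of the active-cell field ``phi``."""
        io, in_, ib, dx_int, w2_int, dx_b, w2_b = self._lsq
        rhs = np.zeros((self.n, 3))
        dphi = phi[in_] - phi[io]
        np.add.at(rhs, io, (w2_int * dphi)[:, None] * dx_int)
        np.add.at(rhs, in_, (w2_int * dphi)[:, None] * dx_int)
        dphib = self.b_vals - phi[ib]
        np.add.at(rhs, ib, (w2_b * dphib)[:, None] * dx_b)
        return np.einsum("nij,nj->ni", self._lsq_Ginv, rhs)

    # -- deferred non-orthogonality correction ------------------------------
    def correction_rhs(self, grad: np.ndarray, include_boundary: bool = True) -> np.ndarray:
        """Explicit flux remainder for the current gradient estimate.

        ``include_boundary=False`` restricts to internal faces (the boundary
        half-cell vectors carry their own non-orthogonality even on meshes
        whose internal faces are perfectly orthogonal).
        """
        io = self.cell_index[self.f_owner]
        in_ = self.cell_index[self.f_neigh]
        gf = (1 - self.f_t)[:, None] * grad[io] + self.f_t[:, None] * grad[in_]
        flux = np.einsum("fij,fj,fi->f", self.f_sig, gf, self.f_area)
        flux -= self.f_a * np.einsum("fj,fj->f", self.f_d, gf)
        c = np.zeros(self.n)
        np.add.at(c, io, flux)
        np.add.at(c, in_, -flux)
        if not include_boundary:
            return c
        ib = self.cell_index[self.b_owner]
        gb = grad[ib]
        fluxb = np.einsum("fij,fj,fi->f", self.b_sig_tensor, gb, self.b_area)
        fluxb -= self.b_a * np.einsum("fj,fj->f", self.b_d, gb)
        np.add.at(c, ib, fluxb)
        return c

    def rhs(self, phi: np.ndarray) -> np.ndarray:
        fac = self.cfg.correction_factor
        if fac == 0.0:
            return self.b0
        return self.b0 + fac * self.correction_rhs(self.gradient(phi))

    def residual(self, phi: np.ndarray) -> float:
        """Normalized residual of the fully corrected discretization."""
        b = self.rhs(phi)
        r = self.M @ phi - b
        scale = max(np.linalg.norm(b), np.linalg.norm(self.M @ phi), 1e-300)
        return float(np.linalg.norm(r) / scale)

    # -- linear solve --------------------------------------------------------
    def _precond_mode(self) -> str:
        """Jacobi-CG for mild conductivity contrast, ILU-BiCGStab otherwise.

        Strong jumps (electrode metal over resistive skull, ~3000:1) defeat a
        diagonal preconditioner; an incomplete-LU factorization handles them
        at the cost of a one-time setup.  Both paths are deterministic.
        """
        if self.cfg.preconditioner != "auto":
            return self.cfg.preconditioner
        d = self.M.diagonal()
        contrast = d.max() / d.min()
        return "jacobi" if contrast < 500.0 else "ilu"

    def _solve_linear(self, b: np.ndarray, x0: np.ndarray) -> np.ndarray:
        if self.n <= self.cfg.direct_below:
            if self._factorized is None:
                self._factorized = spla.factorized(self.M.tocsc())
            return self._factorized(b)
        maxiter = 50 * int(np.sqrt(self.n) + 100)
        if self._factorized is None:
            if self._precond_mode() == "jacobi":
                self._factorized = ("jacobi", sp.diags(1.0 / self.M.diagonal()))
            else:
                ilu = spla.spilu(self.M.tocsc(), drop_tol=1e-5, fill_factor=12)
                op = spla.LinearOperator((self.n, self.n), ilu.solve)
                self._factorized = ("ilu", op)
        kind, Mpre = self._factorized
        if kind == "jacobi":
            x, info = spla.cg(
                self.M, b, x0=x0, rtol=self.cfg.inner_tol, atol=0.0,
                maxiter=maxiter, M=Mpre,
            )
        else:
            x, info = spla.bicgstab(
                self.M, b, x0=x0, rtol=self.cfg.inner_tol, atol=0.0,
                maxiter=maxiter, M=Mpre,
            )
        if info != 0:
            raise RuntimeError(
                f"inner linear solve ({kind}) did not reach rtol={self.cfg.inner_tol} (info={info})"
            )
        return x

    def expand(self, phi_active: np.ndarray) -> np.ndarray:
        full = np.zeros(self.mesh.n_cells)
        full[self.active] = phi_active
        return full


def assemble(
    mesh: TetMesh, cond: ConductivityField, bc: BoundarySpec, cfg: SolverConfig | None = None
) -> FVSystem:
    """Build the sparse FV system and face data for a mesh/conductivity/BC set."""
    return FVSystem(mesh, cond, bc, cfg or SolverConfig())


def solve_potential(system: FVSystem, return_history: bool = False):
    """Outer-corrected solve of the assembled system; returns per-cell phi.

    Each outer iteration recomputes the explicit non-orthogonality correction
    from the current least-squares gradient and re-solves the linear system;
    iteration stops when the residual of the whole (corrected) discretization
    drops below the outer tolerance.  Deterministic: initial guess phi = 0.
    """
    cfg = system.cfg
    phi = np.zeros(system.n)
    history: list[float] = []
    n_iter = cfg.max_outer if cfg.correction_factor > 0 else 1
    c_prev: np.ndarray | None = None
    beta = cfg.correction_relaxation
    for _ in range(n_iter):
        fac = cfg.correction_factor
        if fac == 0.0:
            b = system.b0
        else:
            c = fac * system.correction_rhs(system.gradient(phi))
            if c_prev is not None and beta < 1.0:
                # under-relax the lagged correction: damps the oscillation the
                # explicit term can develop on strongly non-orthogonal faces
                c = (1.0 - beta) * c_prev + beta * c
            c_prev = c
            b = system.b0 + c
        phi = system._solve_linear(b, x0=phi)
        res = system.residual(phi)
        history.append(res)
        if res < cfg.outer_tol:
            break
    else:
        if cfg.correction_factor > 0:
            raise RuntimeError(
                f"outer correction loop did not converge below {cfg.outer_tol:g}; "
                f"residual history tail: {[f'{r:.3e}' for r in history[-5:]]}"
            )
    full = system.expand(phi)
    return (full, history) if return_history else full


def gradient_lsq(system: FVSystem, phi: np.ndarray) -> np.ndarray:
    """E = -grad(phi) per cell in V/m (zero on excluded cells).

    The mesh is in mm, so the V/mm least-squares gradient is converted.
    """
    g = system.gradient(phi[system.active])
    E = np.zeros((system.mesh.n_cells, 3))
    E[system.active] = -g * 1e3
    return E


def current_density(E: np.ndarray, cond: ConductivityField) -> np.ndarray:
    """J = sigma E, full tensor product per cell."""
    return np.einsum("nij,nj->ni", cond.tensors, E)


def integrate_current(
    mesh: TetMesh, J: np.ndarray, contact_patch: str, electrode_label: int | None = None
) -> float:
    """Net current (A) through a named patch.

    Interface patches use the distance-weighted face interpolation of the two
    adjacent cell values.  Orientation: ``electrode_label`` (faces oriented
    away from that compartment) wins if given; otherwise the stored winding
    of the patch triangles defines the positive side (electrode-tagging
    stores them electrode -> tissue).  Boundary patches use the owner value
    and the outward normal.  Areas are mm^2 while J is A/m^2, hence 1e-6.
    """
    geo = mesh.geometry
    if contact_patch not in mesh.patches:
        raise KeyError(f"no patch named {contact_patch!r}")
    if len(mesh.patches[contact_patch]) == 0:
        raise ValueError(f"patch {contact_patch!r} is empty")
    if geo.patch_is_boundary(contact_patch):
        idx = geo.boundary_face_indices(contact_patch)
        A = geo.bnd_area_vec[idx]
        Jf = J[geo.bnd_owner[idx]]
        return float(np.einsum("ij,ij->", Jf, A) * 1e-6)
    idx = geo.internal_face_indices(contact_patch)
    o, nb = geo.int_owner[idx], geo.int_neighbour[idx]
    xf = geo.int_centroid[idx]
    xo, xn = geo.cell_centroids[o], geo.cell_centroids[nb]
    d = xn - xo
    t = np.clip(np.einsum("ij,ij->i", xf - xo, d) / np.einsum("ij,ij->i", d, d), 0, 1)
    Jf = (1 - t)[:, None] * J[o] + t[:, None] * J[nb]
    A = geo.int_area_vec[idx].copy()
    if electrode_label is not None:
        flip = mesh.cell_labels[nb] == electrode_label  # orient away from electrode
        A[flip] *= -1.0
    else:
        # respect the stored triangle winding of the patch
        tris = mesh.patches[contact_patch]
        p = mesh.points
        patch_n = np.cross(p[tris[:, 1]] - p[tris[:, 0]], p[tris[:, 2]] - p[tris[:, 0]])
        flip = np.einsum("ij,ij->i", patch_n, A) < 0
        A[flip] *= -1.0
    return float(np.einsum("ij,ij->", Jf, A) * 1e-6)


def scale_solution(sol: FieldSolution, I_target: float) -> FieldSolution:
    """Scale the linear solution so the contact current equals ``I_target``."""
    if sol.I_measured is None or sol.I_measured == 0:
        raise ValueError("degenerate solution: measured current is zero or missing")
    s = I_target / sol.I_measured
    return FieldSolution(
        phi=sol.phi * s, E=sol.E * s, J=sol.J * s, s=sol.s * s,
        I_measured=sol.I_measured, residuals=list(sol.residuals), active=sol.active,
    )


def solve_tes(
    mesh: TetMesh,
    cond: ConductivityField,
    bc: BoundarySpec,
    cfg: SolverConfig | None = None,
    scale: bool = True,
) -> FieldSolution:
    """Assemble, solve, differentiate and (optionally) current-scale in one go.

    Scaling requires ``bc.anode_contact`` to name the electrode-scalp contact
    patch; the measured current is integrated there.
    """
    cfg = cfg or SolverConfig()
    system = assemble(mesh, cond, bc, cfg)
    phi, history = solve_potential(system, return_history=True)
    E = gradient_lsq(system, phi)
    J = current_density(E, cond)
    sol = FieldSolution(phi=phi, E=E, J=J, residuals=history, active=system.active)
    if scale and bc.anode_contact is not None:
        # magnitude of the current through the anode contact; the patch
        # orientation only fixes the sign, which must not flip the fields
        sol.I_measured = abs(integrate_current(mesh, J, bc.anode_contact))
        sol = scale_solution(sol, bc.target_current)
    return sol
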