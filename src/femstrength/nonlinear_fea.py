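"""Displacement-controlled nonlinear finite element solver.

Linear (constant-strain) tetrahedra carry the bone volume, triangular
membranes the 0.2 mm outer cortex. Plasticity is elastic-perfectly-plastic
with the Drucker-Prager surface f = alpha*I1 + sqrt(J2) - k and associated
flow, integrated by closed-form return mapping (radial in the deviatoric
plane, with an apex projection for states beyond the cone tip). Loading is
quasi-static: the resin-cap node set is driven in equal displacement
increments along the load axis while the resin-box set is fully fixed, and
the reaction on the driven set is recorded after each converged step,
yielding the predicted force-displacement curve.

Voigt convention: (xx, yy, zz, xy, yz, zx) with engineering shear strains.
Units are mm, MPa and N throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .femur_meshing import TetMesh
from .fracture_metrics import ForceDisplacementCurve
from .material_mapping import DruckerPragerParams, MaterialField, dp_params

_VOIGT_ID = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])


class SolverError(RuntimeError):
    pass


@dataclass
class BoundaryConditions:
    """Resin-box (fixed) and resin-cap (driven) constraint sets.

    ``load_axis`` must be a signed coordinate axis; the meshing stage rotates
    the specimen so the stance load is global -z. Driven nodes share the
    prescribed displacement along the load axis and are free laterally.
    """

    fixed_nodes: np.ndarray
    driven_nodes: np.ndarray
    load_axis: tuple[float, float, float] = (0.0, 0.0, -1.0)
    increment: float = 0.1
    n_steps: int = 20

    def __post_init__(self) -> None:
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=np.int64)
        self.driven_nodes = np.asarray(self.driven_nodes, dtype=np.int64)
        if self.fixed_nodes.size == 0 or self.driven_nodes.size == 0:
            raise ValueError("fixed and driven node sets must be non-empty")
        if np.intersect1d(self.fixed_nodes, self.driven_nodes).size:
            raise ValueError("fixed and driven node sets must be disjoint")
        axis = np.asarray(self.load_axis, dtype=float)
        if not np.isclose(np.linalg.norm(axis), 1.0):
            raise ValueError("load_axis must be a unit vector")
        comp = np.argmax(np.abs(axis))
        if not np.isclose(np.abs(axis[comp]), 1.0):
            raise ValueError("load_axis must be aligned with a coordinate axis")
        self._axis_comp = int(comp)
        self._axis_sign = float(np.sign(axis[comp]))

    def constraints(self, prescribed_u: float) -> tuple[np.ndarray, np.ndarray]:
        """(dofs, values) for a prescribed displacement magnitude (mm)."""
        fdofs = (3 * self.fixed_nodes[:, None] + np.arange(3)).ravel()
        ddofs = 3 * self.driven_nodes + self._axis_comp
        dofs = np.concatenate([fdofs, ddofs])
        vals = np.concatenate(
            [np.zeros(fdofs.size), np.full(ddofs.size, prescribed_u * self._axis_sign)]
        )
        return dofs, vals

    def driven_dofs(self) -> np.ndarray:
        return 3 * self.driven_nodes + self._axis_comp


@dataclass
class SolverConfig:
    newton_tol: float = 1e-6
    max_iters: int = 25
    linear_solver: str = "direct"

    def __post_init__(self) -> None:
        if self.newton_tol <= 0 or self.max_iters < 1:
            raise ValueError("newton_tol must be > 0 and max_iters >= 1")


@dataclass
class SolveResult:
    curve: ForceDisplacementCurve
    yielded_fraction_per_step: np.ndarray
    convergence_log: list[dict] = field(default_factory=list)
    completed: bool = True


# ---------------------------------------------------------------------------
# element matrices


def isotropic_D(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix (engineering-shear Voigt)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    d = np.zeros((6, 6))
    d[:3, :3] = lam
    d[np.arange(3), np.arange(3)] += 2 * mu
    d[np.arange(3, 6), np.arange(3, 6)] = mu
    return d


def _tet_b_matrix(coords: np.ndarray) -> tuple[np.ndarray, float]:
    a = coords[1:] - coords[0]
    vol = float(np.linalg.det(a)) / 6.0
    if vol <= 1e-12:
        raise SolverError(f"degenerate tetrahedron (signed volume {vol:.3g})")
    grads = np.zeros((4, 3))
    grads[1:] = np.linalg.inv(a.T)  # rows: gradients of barycentric coords 1..3
    grads[0] = -grads[1:].sum(axis=0)
    b = np.zeros((6, 12))
    for i in range(4):
        gx, gy, gz = grads[i]
        c = 3 * i
        b[0, c] = gx
        b[1, c + 1] = gy
        b[2, c + 2] = gz
        b[3, c] = gy
        b[3, c + 1] = gx
        b[4, c + 1] = gz
        b[4, c + 2] = gy
        b[5, c] = gz
        b[5, c + 2] = gx
    return b, vol


def tet4_stiffness(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12x12 constant-strain tetrahedron stiffness (symmetric PSD)."""
    b, vol = _tet_b_matrix(np.asarray(coords, dtype=float))
    return vol * b.T @ isotropic_D(E, nu) @ b


def membrane_stiffness(coords: np.ndarray, thickness: float, E: float, nu: float) -> np.ndarray:
    """9x9 constant-strain triangular membrane stiffness (in-plane only)."""
    coords = np.asarray(coords, dtype=float)
    e1 = coords[1] - coords[0]
    n = np.cross(e1, coords[2] - coords[0])
    area2 = np.linalg.norm(n)
    if area2 <= 1e-12:
        raise SolverError("degenerate (zero-area) shell triangle")
    n /= area2
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    area = 0.5 * area2
    xy = np.column_stack([(coords - coords[0]) @ e1, (coords - coords[0]) @ e2])
    x, y = xy[:, 0], xy[:, 1]
    bmat = np.zeros((3, 6))
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        bi = y[j] - y[k]
        ci = x[k] - x[j]
        bmat[0, 2 * i] = bi
        bmat[1, 2 * i + 1] = ci
        bmat[2, 2 * i] = ci
        bmat[2, 2 * i + 1] = bi
    bmat /= 2.0 * area
    dmat = (E / (1 - nu**2)) * np.array([[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]])
    k_loc = thickness * area * bmat.T @ dmat @ bmat
    t = np.zeros((6, 9))
    for i in range(3):
        t[2 * i, 3 * i : 3 * i + 3] = e1
        t[2 * i + 1, 3 * i : 3 * i + 3] = e2
    return t.T @ k_loc @ t


# ---------------------------------------------------------------------------
# assembly


class FEModel:
    """Precomputed element data for repeated assembly and stress recovery."""

    def __init__(self, mesh: TetMesh, materials: MaterialField):
        if len(materials) != mesh.n_tets:
            raise ValueError(
                f"material field covers {len(materials)} elements, mesh has {mesh.n_tets}"
            )
        self.mesh = mesh
        self.materials = materials
        t = mesh.n_tets
        self.B = np.zeros((t, 6, 12))
        self.vol = np.zeros(t)
        for e in range(t):
            try:
                self.B[e], self.vol[e] = _tet_b_matrix(mesh.nodes[mesh.tets[e]])
            except SolverError as exc:
                raise SolverError(f"element {e}: {exc}") from exc
        nu = materials.nu
        e_arr = materials.E
        self.lam = e_arr * nu / ((1 + nu) * (1 - 2 * nu))
        self.mu = e_arr / (2 * (1 + nu))
        self.bulk = self.lam + 2.0 * self.mu / 3.0
        self.D = np.zeros((t, 6, 6))
        self.D[:, :3, :3] = self.lam[:, None, None]
        for i in range(3):
            self.D[:, i, i] += 2 * self.mu
            self.D[:, 3 + i, 3 + i] = self.mu
        ratio = np.divide(
            materials.sigma_t, materials.sigma_c, out=np.full(t, 0.8), where=materials.sigma_c > 0
        )
        self.alpha = np.zeros(t)
        self.k = np.zeros(t)
        for e in range(t):
            p = dp_params(float(materials.sigma_c[e]), float(np.clip(ratio[e], 1e-6, 1.0)))
            self.alpha[e], self.k[e] = p.alpha, p.k
        self.edofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(t, 12)
        self.n_dofs = 3 * mesh.n_nodes
        self.K_shell = self._assemble_shells()
        self.K_elastic = self.assemble_tangent(self.D) + self.K_shell

    def _assemble_shells(self) -> sp.csr_matrix:
        k = sp.csr_matrix((self.n_dofs, self.n_dofs))
        if not self.mesh.shell:
            return k
        shell_mat = self.materials.shell
        if shell_mat is None:
            raise ValueError("mesh has shell elements but materials carry no shell record")
        rows, cols, vals = [], [], []
        for tri_idx, thickness in self.mesh.shell.items():
            if thickness <= 0:
                continue
            tri = self.mesh.boundary_tris[tri_idx]
            ke = membrane_stiffness(self.mesh.nodes[tri], thickness, shell_mat.E, shell_mat.nu)
            dofs = (3 * tri[:, None] + np.arange(3)).ravel()
            rows.append(np.repeat(dofs, 9))
            cols.append(np.tile(dofs, 9))
            vals.append(ke.ravel())
        if not rows:
            return k
        return sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_dofs, self.n_dofs),
        ).tocsr()

    def assemble_tangent(self, D: np.ndarray) -> sp.csr_matrix:
        """Assemble sum_e vol_e B^T D_e B for per-element 6x6 moduli."""
        ke = np.einsum("eji,ejk,ekl,e->eil", self.B, D, self.B, self.vol)
        rows = np.repeat(self.edofs, 12, axis=1).ravel()
        cols = np.tile(self.edofs, 12).ravel()
        return sp.coo_matrix(
            (ke.ravel(), (rows, cols)), shape=(self.n_dofs, self.n_dofs)
        ).tocsr()

    def strains(self, u: np.ndarray) -> np.ndarray:
        return np.einsum("eij,ej->ei", self.B, u[self.edofs])

    def internal_force(self, stress: np.ndarray, u: np.ndarray) -> np.ndarray:
        fe = np.einsum("eji,ej,e->ei", self.B, stress, self.vol)
        f = np.zeros(self.n_dofs)
        np.add.at(f, self.edofs.ravel(), fe.ravel())
        return f + self.K_shell @ u


def assemble(mesh: TetMesh, materials: MaterialField) -> tuple[sp.csr_matrix, np.ndarray]:
    """Global elastic stiffness and the (node, component) -> dof map."""
    model = FEModel(mesh, materials)
    dof_map = np.arange(3 * mesh.n_nodes).reshape(-1, 3)
    return model.K_elastic, dof_map


# ---------------------------------------------------------------------------
# linear solve


def solve_constrained(
    K: sp.csr_matrix,
    dofs: np.ndarray,
    values: np.ndarray,
    rhs: np.ndarray | None = None,
    linear_solver: str = "direct",
) -> np.ndarray:
    """Solve K u = rhs with Dirichlet values on ``dofs`` by elimination."""
    n = K.shape[0]
    free = np.setdiff1d(np.arange(n), dofs)
    u = np.zeros(n)
    u[dofs] = values
    b = (rhs[free] if rhs is not None else 0.0) - K[free][:, dofs] @ values
    kff = K[free][:, free].tocsc()
    try:
        if linear_solver == "iterative":
            m = spla.LinearOperator((len(free),) * 2, matvec=lambda x: x / kff.diagonal())
            sol, info = spla.cg(kff, b, M=m, rtol=1e-12, atol=0.0, maxiter=5000)
            if info != 0:
                raise RuntimeError(f"CG did not converge (info={info})")
        else:
            sol = spla.splu(kff).solve(b)
    except RuntimeError as exc:
        raise SolverError(
            f"linear system could not be solved ({exc}); check that the constraints "
            "remove all rigid-body modes"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise SolverError("singular constrained system; insufficient constraints?")
    u[free] = sol
    return u


def solve_linear(
    K: sp.csr_matrix, bc: BoundaryConditions, prescribed_u: float,
    linear_solver: str = "direct",
) -> tuple[np.ndarray, float]:
    """Elastic solve at one prescribed displacement; returns (u, reaction).

    The reaction is the total force on the driven node set along the load
    axis, positive when resisting the prescribed motion.
    """
    dofs, values = bc.constraints(prescribed_u)
    u = solve_constrained(K, dofs, values, linear_solver=linear_solver)
    f = K @ u
    reaction = float(f[bc.driven_dofs()].sum() * bc._axis_sign)
    return u, reaction


# ---------------------------------------------------------------------------
# Drucker-Prager stress update


def dp_yield_value(stress: np.ndarray, params: DruckerPragerParams) -> float:
    """f = alpha*I1 + sqrt(J2) - k for a symmetric 3x3 stress (MPa)."""
    s = np.asarray(stress, dtype=float)
    i1 = np.trace(s)
    dev = s - (i1 / 3.0) * np.eye(3)
    j2 = 0.5 * float(np.tensordot(dev, dev))
    return float(params.alpha * i1 + np.sqrt(j2) - params.k)


def return_map(
    trial_stress: np.ndarray,
    params: DruckerPragerParams,
    E: float,
    nu: float,
) -> tuple[np.ndarray, bool]:
    """Closest-point return of a 3x3 trial stress to the yield surface.

    Elastic-perfectly-plastic, associated flow. Trial states inside the
    surface pass through unchanged; states beyond the cone apex project to
    the apex (flagged plastic as well).
    """
    s = np.asarray(trial_stress, dtype=float)
    voigt = np.array([s[0, 0], s[1, 1], s[2, 2], s[0, 1], s[1, 2], s[2, 0]])
    mu = E / (2 * (1 + nu))
    bulk = E / (3 * (1 - 2 * nu))
    out, plastic, _ = _return_map_voigt(
        voigt[None, :],
        np.array([params.alpha]),
        np.array([params.k]),
        np.array([mu]),
        np.array([bulk]),
    )
    v = out[0]
    corrected = np.array(
        [[v[0], v[3], v[5]], [v[3], v[1], v[4]], [v[5], v[4], v[2]]]
    )
    return corrected, bool(plastic[0])


def _return_map_voigt(trial, alpha, k, mu, bulk):
    """Vectorized DP return map on (n, 6) Voigt stresses.

    Returns (corrected stress, plastic mask, apex mask).
    """
    i1 = trial[:, :3].sum(axis=1)
    dev = trial.copy()
    dev[:, :3] -= (i1 / 3.0)[:, None]
    j2 = 0.5 * np.einsum("ij,ij->i", dev[:, :3], dev[:, :3]) + np.einsum(
        "ij,ij->i", dev[:, 3:], dev[:, 3:]
    )
    sqj2 = np.sqrt(j2)
    f = alpha * i1 + sqj2 - k
    plastic = f > 0
    out = trial.copy()
    if not plastic.any():
        return out, plastic, np.zeros_like(plastic)
    dl = np.where(plastic, f / (9.0 * bulk * alpha**2 + mu), 0.0)
    sq_new = sqj2 - mu * dl
    apex = plastic & (sq_new < 0) & (alpha > 0)
    reg = plastic & ~apex
    scale = np.ones_like(sqj2)
    nz = reg & (sqj2 > 0)
    scale[nz] = sq_new[nz] / sqj2[nz]
    i1_new = np.where(reg, i1 - 9.0 * bulk * alpha * dl, i1)
    out[reg] = dev[reg] * scale[reg, None]
    out[reg, :3] += (i1_new[reg] / 3.0)[:, None]
    if apex.any():
        out[apex] = 0.0
        out[apex, :3] = (k[apex] / (3.0 * alpha[apex]))[:, None]
    return out, plastic, apex


# ---------------------------------------------------------------------------
# nonlinear solve


def solve_nonlinear(
    mesh: TetMesh,
    materials: MaterialField,
    bc: BoundaryConditions,
    cfg: SolverConfig | None = None,
) -> SolveResult:
    """Incremental displacement-driven solve with Newton equilibrium iteration.

    Each step advances the driven set by ``bc.increment`` mm, iterates with
    the elastoplastic tangent (falling back to the elastic stiffness after
    10 iterations), and appends one (displacement, reaction) sample to the
    force-displacement curve. A step that fails to converge terminates the
    analysis with the partial curve flagged; failure at step 1 is an error.
    """
    cfg = cfg or SolverConfig()
    if bc.increment <= 0:
        raise ValueError("bc.increment must be positive")
    model = FEModel(mesh, materials)
    n_tets = mesh.n_tets
    eps_p = np.zeros((n_tets, 6))
    ever_yielded = np.zeros(n_tets, dtype=bool)
    u = np.zeros(model.n_dofs)
    disp, force, yfrac = [0.0], [0.0], []
    log: list[dict] = []
    completed = True

    all_dofs = np.arange(model.n_dofs)
    c_dofs, _ = bc.constraints(0.0)
    free = np.setdiff1d(all_dofs, c_dofs)
    dsign = bc._axis_sign
    ddofs = bc.driven_dofs()
    k_ref = float(np.median(model.k[np.isfinite(model.k) & (model.k < 1e19)])) if np.any(
        model.k < 1e19
    ) else 1.0

    def evaluate(u_vec):
        strains = model.strains(u_vec)
        trial = np.einsum("eij,ej->ei", model.D, strains - eps_p)
        stress, plastic, apex = _return_map_voigt(
            trial, model.alpha, model.k, model.mu, model.bulk
        )
        f_int = model.internal_force(stress, u_vec)
        return trial, stress, plastic, apex, f_int

    # committed-state snapshot drives the predictor tangent of the next step
    committed = (np.zeros((n_tets, 6)), np.zeros(n_tets, dtype=bool), np.zeros(n_tets, dtype=bool))

    def tangent_matrix(t_trial, t_plastic, t_apex) -> sp.csr_matrix:
        if t_plastic.any():
            d_tan = _elastoplastic_tangent(model, t_trial, t_plastic, t_apex)
            return model.assemble_tangent(d_tan) + model.K_shell
        return model.K_elastic

    for step in range(1, bc.n_steps + 1):
        target = step * bc.increment
        _, values = bc.constraints(target)
        # tangent predictor: advance the constrained dofs through the
        # linearization at the committed state before touching plasticity
        k_t = tangent_matrix(*committed)
        d_uc = values - u[c_dofs]
        kff = k_t[free][:, free].tocsc()
        du_pred = spla.splu(kff).solve(-(k_t[free][:, c_dofs] @ d_uc))
        u[c_dofs] = values
        u[free] += du_pred

        converged = False
        res_norm = np.inf
        ref_norm = k_ref
        trial, stress, plastic, apex, f_int = evaluate(u)
        for it in range(1, cfg.max_iters + 1):
            res = -f_int[free]
            res_norm = float(np.linalg.norm(res))
            ref_norm = max(float(np.linalg.norm(f_int[c_dofs])), 1e-9 * k_ref)
            if res_norm <= cfg.newton_tol * ref_norm:
                converged = True
                break
            # tangent from the current trial state; elastic fallback late
            if it <= 10:
                k_t = tangent_matrix(trial, plastic, apex)
            else:
                k_t = model.K_elastic
            kff = k_t[free][:, free].tocsc()
            try:
                du = spla.splu(kff).solve(res)
            except RuntimeError:
                du = spla.splu(model.K_elastic[free][:, free].tocsc()).solve(res)
            if not np.all(np.isfinite(du)):
                break
            # backtracking line search on the residual norm
            accepted = None
            for scale in (1.0, 0.5, 0.25, 0.125, 0.0625):
                u_try = u.copy()
                u_try[free] += scale * du
                cand = evaluate(u_try)
                if float(np.linalg.norm(cand[4][free])) < res_norm or scale == 0.0625:
                    accepted = (u_try, cand)
                    break
            u, (trial, stress, plastic, apex, f_int) = accepted
        log.append({"step": step, "iterations": it, "residual": res_norm / max(ref_norm, 1e-300)})
        if not converged:
            if step == 1:
                raise SolverError(
                    f"no convergence at step 1 (relative residual {res_norm / ref_norm:.3g} "
                    f"after {cfg.max_iters} iterations)"
                )
            completed = False
            break
        # commit plastic state from the converged evaluation
        eps_p += _apply_compliance(model, trial - stress)
        ever_yielded |= plastic
        committed = (trial, plastic, apex)
        disp.append(target)
        force.append(float(f_int[ddofs].sum() * dsign))
        yfrac.append(float(ever_yielded.mean()))

    curve = ForceDisplacementCurve(
        displacement=np.array(disp), force=np.array(force), source="fea"
    )
    return SolveResult(
        curve=curve,
        yielded_fraction_per_step=np.array(yfrac),
        convergence_log=log,
        completed=completed,
    )


def _apply_compliance(model: FEModel, d_sig: np.ndarray) -> np.ndarray:
    """Per-element inverse elasticity applied to Voigt stress increments."""
    e_arr = 9.0 * model.bulk * model.mu / (3.0 * model.bulk + model.mu)
    nu = (3.0 * model.bulk - 2.0 * model.mu) / (2.0 * (3.0 * model.bulk + model.mu))
    out = np.empty_like(d_sig)
    s = d_sig[:, :3].sum(axis=1)
    out[:, :3] = ((1 + nu)[:, None] * d_sig[:, :3] - (nu * s)[:, None]) / e_arr[:, None]
    out[:, 3:] = d_sig[:, 3:] / model.mu[:, None]
    return out


def _elastoplastic_tangent(model: FEModel, trial: np.ndarray, plastic: np.ndarray, apex: np.ndarray):
    """Continuum EPP tangent D - (Dn)(Dn)^T / (n^T D n), regularized.

    A 1e-3 residual stiffness keeps the fully plastic system well
    conditioned; the tangent is only a Newton preconditioner, the residual
    (hence the converged solution) is exact elastic-perfectly-plastic.
    """
    d_tan = model.D.copy()
    m = _VOIGT_ID
    idx = np.where(plastic & ~apex)[0]
    if idx.size:
        tr = trial[idx]
        alpha = model.alpha[idx]
        mu = model.mu[idx]
        bulk = model.bulk[idx]
        k = model.k[idx]
        i1 = tr[:, :3].sum(axis=1)
        dev = tr.copy()
        dev[:, :3] -= (i1 / 3.0)[:, None]
        j2 = 0.5 * np.einsum("ij,ij->i", dev[:, :3], dev[:, :3]) + np.einsum(
            "ij,ij->i", dev[:, 3:], dev[:, 3:]
        )
        sqj2 = np.sqrt(np.maximum(j2, 1e-300))
        f = alpha * i1 + sqj2 - k
        c1 = 1.0 / (mu + 9.0 * bulk * alpha**2)
        dl = f * c1
        beta = 1.0 - mu * dl / sqj2
        # flow normal n = alpha*m + dev_hat/(2 sqrt(J2)) in engineering Voigt
        n = np.zeros((idx.size, 6))
        n[:, :3] = alpha[:, None] + dev[:, :3] / (2 * sqj2[:, None])
        n[:, 3:] = dev[:, 3:] / sqj2[:, None]
        g_f = np.einsum("eij,ej->ei", model.D[idx], n)  # grad of f wrt strain
        # sigma = beta*s_t + (p_t - 3*K*alpha*dl)*m; differentiate wrt strain
        grad_beta = -(mu * c1 / sqj2)[:, None] * g_f + (
            mu[:, None] * dl[:, None] / j2[:, None]
        ) * np.einsum("eij,ej->ei", model.D[idx], np.concatenate(
            [dev[:, :3] / (2 * sqj2[:, None]), dev[:, 3:] / sqj2[:, None]], axis=1
        ))
        d_dev = model.D[idx] - bulk[:, None, None] * np.einsum("i,j->ij", m, m)
        d_c = (
            beta[:, None, None] * d_dev
            + np.einsum("e,i,j->eij", bulk, m, m)
            - np.einsum("e,i,ej->eij", 3.0 * bulk * alpha * c1, m, g_f)
            + np.einsum("ei,ej->eij", dev, grad_beta)
        )
        # symmetrize (associated flow) and keep residual conditioning
        d_c = 0.5 * (d_c + np.transpose(d_c, (0, 2, 1))) + 1e-6 * model.D[idx]
        d_tan[idx] = d_c
    aidx = np.where(apex)[0]
    if aidx.size:
        d_tan[aidx] = 1e-4 * model.D[aidx]
    return d_tan


# ---------------------------------------------------------------------------
# curve I/O


def curve_to_csv(result: SolveResult, path) -> None:
    import pandas as pd

    n = len(result.curve.displacement)
    yf = np.concatenate([[0.0], result.yielded_fraction_per_step])[:n]
    pd.DataFrame(
        {
            "step": np.arange(n),
            "displacement_mm": result.curve.displacement,
            "force_N": result.curve.force,
            "yielded_fraction": yf,
        }
    ).to_csv(path, index=False)
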