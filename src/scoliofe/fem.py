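"""Small-strain linear-elastic static solver for hex + spring spine models.

Trilinear 8-node hexahedra with full 2x2x2 Gauss integration, spring
elements as rank-one stiffness terms, anisotropic eigenstrain (growth)
loading, fixed-point iteration for tension-only springs, the two-pass
anti-gravity protocol, and volume-weighted IVD quadrant stress extraction.

Sign convention: tension-positive stress internally; compression-positive
only at the reporting boundary (:func:`ivd_quadrant_stress`).

Voigt order: [xx, yy, zz, xy, yz, zx] with engineering shear strain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .template import HexMeshModel, QUADRANTS

log = logging.getLogger(__name__)

G_ACCEL = 9.81  # m/s^2; forces in N with masses in kg

# natural coordinates of the VTK hex corners
_XI = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)

_GP = np.array([[sx, sy, sz] for sz in (-1, 1) for sy in (-1, 1)
                for sx in (-1, 1)], dtype=float) / np.sqrt(3.0)


def _shape_derivs(xi: np.ndarray) -> np.ndarray:
    """dN/d(xi) at one natural point -> (8, 3)."""
    out = np.empty((8, 3))
    for n in range(8):
        a, b, c = _XI[n]
        out[n, 0] = a * (1 + b * xi[1]) * (1 + c * xi[2]) / 8.0
        out[n, 1] = b * (1 + a * xi[0]) * (1 + c * xi[2]) / 8.0
        out[n, 2] = c * (1 + a * xi[0]) * (1 + b * xi[1]) / 8.0
    return out

_DN_GP = np.stack([_shape_derivs(gp) for gp in _GP])     # (8gp, 8n, 3)
_DN_CENTER = _shape_derivs(np.zeros(3))


def elastic_matrix(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Isotropic Hooke matrices, (m, 6, 6)."""
    E = np.atleast_1d(np.asarray(E, dtype=float))
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    m = len(E)
    D = np.zeros((m, 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
        D[:, 3 + i, 3 + i] = mu
    return D


def _b_matrices(grad: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices from shape gradients (m, 8, 3) -> (m, 6, 24)."""
    m = grad.shape[0]
    B = np.zeros((m, 6, 8, 3))
    B[:, 0, :, 0] = grad[:, :, 0]
    B[:, 1, :, 1] = grad[:, :, 1]
    B[:, 2, :, 2] = grad[:, :, 2]
    B[:, 3, :, 0] = grad[:, :, 1]
    B[:, 3, :, 1] = grad[:, :, 0]
    B[:, 4, :, 1] = grad[:, :, 2]
    B[:, 4, :, 2] = grad[:, :, 1]
    B[:, 5, :, 0] = grad[:, :, 2]
    B[:, 5, :, 2] = grad[:, :, 0]
    return B.reshape(m, 6, 24)


def _element_geometry(nodes: np.ndarray, hexes: np.ndarray):
    """Per-Gauss-point B matrices and integration weights for all hexes."""
    X = nodes[hexes]  # (m, 8, 3)
    Bs, dVs = [], []
    for g in range(8):
        dN = _DN_GP[g]                                   # (8, 3)
        J = np.einsum("na,mni->mai", dN, X)              # (m, 3, 3)
        detJ = np.linalg.det(J)
        invJ = np.linalg.inv(J)
        # J[a, i] = dx_i/dxi_a, so dN/dx_i = dN/dxi_a * invJ[i, a]
        grad = np.einsum("na,mia->mni", dN, invJ)
        Bs.append(_b_matrices(grad))
        dVs.append(detJ)
    return Bs, dVs


def hex_stiffness(nodes: np.ndarray, hexes: np.ndarray,
                  E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Per-element 24x24 stiffness matrices (m, 24, 24)."""
    D = elastic_matrix(E, nu)
    Bs, dVs = _element_geometry(nodes, hexes)
    m = hexes.shape[0]
    Ke = np.zeros((m, 24, 24))
    for B, dV in zip(Bs, dVs):
        DB = np.einsum("mij,mjk->mik", D, B)
        Ke += np.einsum("mji,mjk,m->mik", B, DB, dV)
    return Ke


def eigenstrain_forces(nodes: np.ndarray, hexes: np.ndarray,
                       E: np.ndarray, nu: np.ndarray,
                       eps0: np.ndarray) -> np.ndarray:
    """Equivalent nodal forces of per-element eigenstrains (m, 6) -> (m, 24)."""
    D = elastic_matrix(E, nu)
    Bs, dVs = _element_geometry(nodes, hexes)
    m = hexes.shape[0]
    fe = np.zeros((m, 24))
    sig0 = np.einsum("mij,mj->mi", D, eps0)
    for B, dV in zip(Bs, dVs):
        fe += np.einsum("mji,mj,m->mi", B, sig0, dV)
    return fe


def element_volumes(nodes: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    X = nodes[hexes]
    vol = np.zeros(hexes.shape[0])
    for g in range(8):
        J = np.einsum("na,mni->mai", _DN_GP[g], X)
        vol += np.linalg.det(J)
    return vol


@dataclass
class LoadCase:
    """Nodal forces (N) plus optional per-element Voigt eigenstrains."""

    forces: Optional[np.ndarray] = None       # (n, 3)
    eigenstrain: Optional[np.ndarray] = None  # (m, 6), stress-free strain

    def validate(self, model: HexMeshModel) -> None:
        if self.forces is not None:
            if self.forces.shape != (model.n_nodes, 3):
                raise ValueError("forces must be (n_nodes, 3)")
            if not np.all(np.isfinite(self.forces)):
                raise ValueError("non-finite nodal force")
        if self.eigenstrain is not None:
            if self.eigenstrain.shape != (model.n_hexes, 6):
                raise ValueError("eigenstrain must be (n_hexes, 6)")
            if np.max(np.abs(self.eigenstrain)) >= 0.2:
                raise ValueError("eigenstrain exceeds the small-strain bound "
                                 "0.2; use a smaller growth step")


@dataclass
class StressState:
    """Element-center stress tensors in Voigt order, tension-positive."""

    sigma: np.ndarray                      # (m, 6) MPa
    displacements: np.ndarray              # (n, 3) mm
    active_springs: List[int] = field(default_factory=list)

    def tensor(self, e: int) -> np.ndarray:
        s = self.sigma[e]
        return np.array([[s[0], s[3], s[5]],
                         [s[3], s[1], s[4]],
                         [s[5], s[4], s[2]]])


def _spring_stiffness_entries(model: HexMeshModel, active: Sequence[int]):
    rows, cols, vals = [], [], []
    for idx in active:
        s = model.springs[idx]
        axis = model.nodes[s.node_b] - model.nodes[s.node_a]
        L = np.linalg.norm(axis)
        if L == 0:
            raise ValueError(f"zero-length spring {idx}")
        n = axis / L
        kb = s.stiffness * np.outer(n, n)
        da = 3 * s.node_a + np.arange(3)
        db = 3 * s.node_b + np.arange(3)
        for bi, (r3, c3, sign) in enumerate(
                ((da, da, 1.0), (da, db, -1.0), (db, da, -1.0), (db, db, 1.0))):
            for i in range(3):
                for j in range(3):
                    rows.append(r3[i])
                    cols.append(c3[j])
                    vals.append(sign * kb[i, j])
    return rows, cols, vals


def assemble(model: HexMeshModel, active_springs: Sequence[int] | None = None,
             hex_Ke: np.ndarray | None = None) -> sp.csr_matrix:
    """Global stiffness from hexes plus the given active spring subset."""
    if model.elem_E is None:
        raise ValueError("materials not assigned; call assign_materials first")
    if hex_Ke is None:
        hex_Ke = hex_stiffness(model.nodes, model.hexes, model.elem_E,
                               model.elem_nu)
    edofs = (model.hexes[:, :, None] * 3
             + np.arange(3)[None, None, :]).reshape(-1, 24)
    rows = np.repeat(edofs, 24, axis=1).ravel()
    cols = np.tile(edofs, (1, 24)).ravel()
    vals = hex_Ke.ravel()
    if active_springs is None:
        active_springs = range(len(model.springs))
    sr, sc, sv = _spring_stiffness_entries(model, list(active_springs))
    ndof = 3 * model.n_nodes
    K = sp.coo_matrix(
        (np.concatenate([vals, sv]),
         (np.concatenate([rows, np.array(sr, dtype=int)]),
          np.concatenate([cols, np.array(sc, dtype=int)]))),
        shape=(ndof, ndof)).tocsr()
    return K


def _assemble_rhs(model: HexMeshModel, loadcase: LoadCase) -> np.ndarray:
    ndof = 3 * model.n_nodes
    f = np.zeros(ndof)
    if loadcase.forces is not None:
        f += loadcase.forces.ravel()
    if loadcase.eigenstrain is not None:
        fe = eigenstrain_forces(model.nodes, model.hexes, model.elem_E,
                                model.elem_nu, loadcase.eigenstrain)
        edofs = (model.hexes[:, :, None] * 3
                 + np.arange(3)[None, None, :]).reshape(-1, 24)
        np.add.at(f, edofs.ravel(), fe.ravel())
    return f


def _solve_linear(model: HexMeshModel, K: sp.csr_matrix,
                  f: np.ndarray) -> np.ndarray:
    free = ~model.fixed.ravel()
    if not np.any(model.fixed):
        raise ValueError("no constraints; rigid-body modes unconstrained")
    Kff = K[free][:, free].tocsc()
    u = np.zeros(3 * model.n_nodes)
    try:
        u[free] = spla.spsolve(Kff, f[free])
    except Exception as exc:  # pragma: no cover - singularity path
        raise ValueError(f"singular system: {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise ValueError("singular system: solution contains non-finite "
                         "values (unconstrained modes?)")
    return u


def element_center_stress(model: HexMeshModel, u: np.ndarray,
                          eigenstrain: np.ndarray | None = None) -> np.ndarray:
    """Stress at each hex center from strain minus eigenstrain (m, 6)."""
    X = model.nodes[model.hexes]
    J = np.einsum("na,mni->mai", _DN_CENTER, X)
    invJ = np.linalg.inv(J)
    grad = np.einsum("na,mia->mni", _DN_CENTER, invJ)
    B = _b_matrices(grad)
    ue = u.reshape(-1, 3)[model.hexes].reshape(-1, 24)
    strain = np.einsum("mij,mj->mi", B, ue)
    if eigenstrain is not None:
        strain = strain - eigenstrain
    D = elastic_matrix(model.elem_E, model.elem_nu)
    return np.einsum("mij,mj->mi", D, strain)


def _spring_elongations(model: HexMeshModel, u: np.ndarray) -> np.ndarray:
    disp = u.reshape(-1, 3)
    out = np.empty(len(model.springs))
    for i, s in enumerate(model.springs):
        axis = model.nodes[s.node_b] - model.nodes[s.node_a]
        n = axis / np.linalg.norm(axis)
        out[i] = n @ (disp[s.node_b] - disp[s.node_a])
    return out


def resolve_tension_only(model: HexMeshModel, loadcase: LoadCase,
                         hex_Ke: np.ndarray | None = None,
                         max_iter: int = 20
                         ) -> Tuple[np.ndarray, List[int]]:
    """Fixed-point iteration on the active set of tension-only springs.

    Springs found in compression are deactivated and the system re-solved
    until the active set is stable.  Returns (u, active spring indices).
    """
    loadcase.validate(model)
    if hex_Ke is None and model.n_hexes:
        hex_Ke = hex_stiffness(model.nodes, model.hexes, model.elem_E,
                               model.elem_nu)
    f = _assemble_rhs(model, loadcase)
    tension_ids = [i for i, s in enumerate(model.springs) if s.tension_only]
    rigid_ids = [i for i, s in enumerate(model.springs) if not s.tension_only]
    active = set(tension_ids)
    history = []
    for _ in range(max_iter):
        K = assemble(model, rigid_ids + sorted(active), hex_Ke=hex_Ke)
        u = _solve_linear(model, K, f)
        elo = _spring_elongations(model, u)
        new_active = {i for i in tension_ids if elo[i] > -1e-12}
        if new_active == active:
            return u, rigid_ids + sorted(active)
        history.append(frozenset(active))
        active = new_active
    raise RuntimeError(
        "tension-only iteration did not converge in "
        f"{max_iter} iterations; last two active sets: "
        f"{sorted(history[-1])} vs {sorted(active)}")


def solve_static(model: HexMeshModel, loadcase: LoadCase) -> StressState:
    """Solve one static case (with tension-only spring resolution)."""
    u, active = resolve_tension_only(model, loadcase)
    sigma = element_center_stress(model, u, loadcase.eigenstrain)
    _check_equilibrium(model, active, loadcase, u)
    return StressState(sigma=sigma, displacements=u.reshape(-1, 3),
                       active_springs=active)


def _check_equilibrium(model: HexMeshModel, active: Sequence[int],
                       loadcase: LoadCase, u: np.ndarray) -> None:
    K = assemble(model, active)
    f = _assemble_rhs(model, loadcase)
    residual = K @ u - f
    free = ~model.fixed.ravel()
    scale = max(np.abs(f).max(), np.abs(K @ u).max(), 1e-12)
    rel = np.abs(residual[free]).max() / scale
    if rel > 1e-8:
        warnings.warn(f"equilibrium residual {rel:.2e} above 1e-8",
                      stacklevel=2)


def reaction_forces(model: HexMeshModel, u: np.ndarray, loadcase: LoadCase,
                    active: Sequence[int] | None = None) -> np.ndarray:
    """Residual K u - f, nonzero only at constrained dofs -> (n, 3)."""
    K = assemble(model, active)
    f = _assemble_rhs(model, loadcase)
    return (K @ u.ravel() - f).reshape(-1, 3)


# ---------------------------------------------------------------------------
# Gravity
# ---------------------------------------------------------------------------


def gravity_forces(model: HexMeshModel, weight_kg: float,
                   table: Dict[str, float], direction: float = -1.0
                   ) -> np.ndarray:
    """Per-level bodyweight-fraction forces spread over each body's nodes.

    Equal nodal shares approximate application at the geometric centroid of
    each vertebral body.  ``direction`` -1 is gravity, +1 anti-gravity.
    """
    if any(v < 0 for v in table.values()):
        raise ValueError("gravity fractions must be >= 0")
    forces = np.zeros((model.n_nodes, 3))
    for level, fraction in table.items():
        nodes = model.groups[level]["body_nodes"]
        total = direction * fraction * weight_kg * G_ACCEL
        forces[nodes, 2] += total / len(nodes)
    return forces


def apply_gravity_two_pass(model: HexMeshModel, weight_kg: float,
                           table: Dict[str, float],
                           deviation_warn_mm: float = 2.0) -> StressState:
    """Two-pass anti-gravity protocol returning stresses at imaged geometry.

    Pass 1 applies upward per-level forces, moves the nodes to the displaced
    unloaded geometry and zeroes all stress; pass 2 applies the same forces
    downward from there.  Under linear kinematics the final geometry matches
    the imaged one; deviation beyond the tolerance is warned about.  The
    model's nodes are restored to the imaged geometry before returning.
    """
    imaged = model.nodes.copy()
    up = LoadCase(forces=gravity_forces(model, weight_kg, table, +1.0))
    u1, _ = resolve_tension_only(model, up)
    model.nodes = imaged + u1.reshape(-1, 3)     # unloaded geometry, stress zeroed
    try:
        down = LoadCase(forces=gravity_forces(model, weight_kg, table, -1.0))
        state = solve_static(model, down)
        final = model.nodes + state.displacements
        rms = np.sqrt(np.mean(np.sum((final - imaged) ** 2, axis=1)))
        if rms > deviation_warn_mm:
            warnings.warn(
                f"two-pass final geometry deviates {rms:.2f} mm RMS from the "
                "imaged geometry (geometric nonlinearity)", stacklevel=2)
    finally:
        model.nodes = imaged
    return state


# ---------------------------------------------------------------------------
# Local frames and IVD quadrant stresses
# ---------------------------------------------------------------------------


def level_axis(model: HexMeshModel, level: str) -> np.ndarray:
    """Local spine axis of a vertebral body: bottom-to-top face centroid."""
    g = model.groups[level]
    top = model.nodes[g["top_face"]].mean(axis=0)
    bot = model.nodes[g["bottom_face"]].mean(axis=0)
    axis = top - bot
    return axis / np.linalg.norm(axis)


def ivd_axis(model: HexMeshModel, upper: str, lower: str) -> np.ndarray:
    top = model.nodes[model.groups[upper]["bottom_face"]].mean(axis=0)
    bot = model.nodes[model.groups[lower]["top_face"]].mean(axis=0)
    axis = top - bot
    return axis / np.linalg.norm(axis)


def level_frame(model: HexMeshModel, level: str) -> np.ndarray:
    """Columns (ap, lateral, vertical); vertical = local spine axis."""
    zl = level_axis(model, level)
    y = np.array([0.0, 1.0, 0.0])
    yl = y - (y @ zl) * zl
    yl /= np.linalg.norm(yl)
    xl = np.cross(yl, zl)
    return np.column_stack([xl, yl, zl])


def quadrant_stresses(model: HexMeshModel, state: StressState,
                      level: str) -> Dict[str, float]:
    """Volume-weighted axial stress (tension-positive, MPa) per IVD quadrant
    of the disc adjacent to ``level``, keyed by left/right quadrant tags."""
    label = model.ivd_level_label(level)
    upper, lower = label.split("/")
    axis = ivd_axis(model, upper, lower)
    elems = model.hexes_of(structure="ivd", level=label)
    if len(elems) == 0:
        raise ValueError(f"no IVD elements at {label}")
    vols = element_volumes(model.nodes, model.hexes[elems])
    out = {}
    for quadrant in QUADRANTS:
        mask = model.region[elems] == quadrant
        idx = elems[mask]
        if len(idx) == 0:
            raise ValueError(f"no {quadrant} elements in IVD {label}")
        axial = np.array([axis @ state.tensor(e) @ axis for e in idx])
        w = vols[mask]
        out[quadrant] = float(np.sum(axial * w) / np.sum(w))
    return out


def ivd_quadrant_stress(model: HexMeshModel, state: StressState, level: str,
                        convex_side: str) -> Dict[str, float]:
    """Anterior/posterior x convex/concave quadrant stresses in MPa,
    compression-positive (reporting convention)."""
    if convex_side not in ("left", "right"):
        raise ValueError("convex_side must be 'left' or 'right'")
    lr = quadrant_stresses(model, state, level)
    concave = "right" if convex_side == "left" else "left"
    return {
        "anterior_convex": -lr[f"ant_{convex_side}"],
        "anterior_concave": -lr[f"ant_{concave}"],
        "posterior_convex": -lr[f"post_{convex_side}"],
        "posterior_concave": -lr[f"post_{concave}"],
    }
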