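"""Small-strain linear-elastic FE on linear tetrahedra with contact.

The solver supports displacement-controlled loading through a reference
point kinematically coupled to a node set, tied (bonded) interfaces as
multipoint constraints, and finite-sliding frictionless node-to-surface
penalty contact.  Slave-master pairing is re-evaluated as the surfaces move
(by default along the loading axis, which is stable on piecewise-linear
voxel surfaces); each frozen pairing yields a convex quadratic problem
that an inner semismooth-Newton loop solves exactly, with the penalty term
handled as a low-rank Woodbury update of the once-factored elastic matrix.

Units: mm / N / MPa throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .meshing import TetMesh

__all__ = [
    "Material",
    "LoadProtocol",
    "ContactPair",
    "TiedInterface",
    "Coupling",
    "Constraints",
    "FESolution",
    "StepSolution",
    "ContactConvergenceError",
    "assemble_stiffness",
    "element_operators",
    "apply_coupling",
    "apply_tie",
    "solve_linear",
    "solve_contact_steps",
    "von_mises",
    "reaction_history",
    "default_materials",
]


class ContactConvergenceError(RuntimeError):
    def __init__(self, msg, max_penetration=None, oscillations=None):
        super().__init__(msg)
        self.max_penetration = max_penetration
        self.oscillations = oscillations


@dataclass
class Material:
    """Linear isotropic elasticity: Young's modulus (MPa), Poisson ratio."""

    young_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if not self.young_modulus > 0:
            raise ValueError("E must be positive")
        if not 0 < self.poisson_ratio < 0.5:
            raise ValueError("nu must be in (0, 0.5)")

    @property
    def lame(self) -> tuple[float, float]:
        E, nu = self.young_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        return lam, mu

    def d_matrix(self) -> np.ndarray:
        """6x6 stiffness for (xx, yy, zz, xy, yz, zx) engineering strains."""
        lam, mu = self.lame
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


def default_materials() -> dict[str, Material]:
    """Tissue properties used for the joint models.

    Cartilage E = 6 MPa, nu = 0.49; meniscus (the whole structure,
    calcifications included) E = 59 MPa, nu = 0.49; bone E = 18000 MPa,
    nu = 0.3.
    """
    cart = Material(6.0, 0.49)
    bone = Material(18000.0, 0.3)
    menisc = Material(59.0, 0.49)
    return {
        "femur_bone": bone,
        "tibia_bone": bone,
        "calcified_meniscus": menisc,
        "femur_cartilage": cart,
        "tibia_cartilage": cart,
        "soft_meniscus": menisc,
    }


@dataclass
class LoadProtocol:
    """Displacement-controlled axial loading protocol (micrometres).

    The femur is lifted by ``gap_translation_um`` when the geometry is built;
    the reference point is then driven back by ``initialization_displacement_um``
    to initialise contact, followed by ``loading_displacement_um`` applied in
    ``n_steps`` equal steps.  ``direction`` is the unit vector of reference
    point motion (default: -z, axial compression).
    """

    gap_translation_um: float = 87.0
    initialization_displacement_um: float = 87.0
    loading_displacement_um: float = 30.0
    n_steps: int = 4
    n_init_substeps: int = 1
    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)

    def __post_init__(self) -> None:
        if min(self.gap_translation_um, self.initialization_displacement_um,
               self.loading_displacement_um) < 0:
            raise ValueError("protocol displacements must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        d = np.asarray(self.direction, dtype=float)
        self.direction = tuple(d / np.linalg.norm(d))

    def schedule_mm(self) -> tuple[np.ndarray, int]:
        """Cumulative RP displacement magnitudes (mm) and index of the first
        loading step in that schedule."""
        init = self.initialization_displacement_um * 1e-3
        load = self.loading_displacement_um * 1e-3
        subs = max(1, self.n_init_substeps)
        mags = [init * (i + 1) / subs for i in range(subs)]
        first_loading = len(mags)
        mags += [init + load * (i + 1) / self.n_steps for i in range(self.n_steps)]
        return np.asarray(mags), first_loading


@dataclass
class ContactPair:
    """Frictionless node-to-surface penalty pair.

    ``master`` and ``slave`` name facet sets of the mesh; slave nodes are the
    nodes of the slave facet set and carry tributary areas from it.
    ``penalty_stiffness`` is a pressure per penetration depth (MPa/mm); if
    None it defaults to ``50 * E_slave / h`` with ``h`` the mean slave facet
    edge length.  ``mode`` selects the gap evaluation: ``"ray"`` pairs each
    slave node with the master facet pierced by its ray along the loading
    axis (robust on staircased voxel surfaces), ``"closest"`` uses
    closest-point projection.
    """

    master: str
    slave: str
    penalty_stiffness: float | None = None
    friction: float = 0.0
    mode: str = "ray"

    def __post_init__(self) -> None:
        if self.friction != 0.0:
            raise ValueError("only frictionless contact is supported")
        if self.mode not in ("ray", "closest"):
            raise ValueError("mode must be 'ray' or 'closest'")


@dataclass
class TiedInterface:
    """Bonded interface: slave nodes follow master facets (MPC)."""

    slave_nodes: str
    master_facets: str
    gap_tolerance_mm: float = 1e-6


@dataclass
class Coupling:
    """Kinematic translation coupling of a node set to a reference point."""

    node_ids: np.ndarray
    reference_point: np.ndarray


def apply_coupling(mesh: TetMesh, node_set: str,
                   reference_point=None) -> Coupling:
    """Couple all translations of a node set to a reference point.

    The reference point defaults to the centroid of the coupled nodes (the
    centre of the top surface of the femur when used with
    ``femur_top_coupled``).  Rotational coupling is not modelled.
    """
    ids = np.asarray(mesh.node_sets[node_set])
    if ids.size == 0:
        raise ValueError(f"node set {node_set!r} is empty")
    rp = (np.asarray(reference_point, dtype=float)
          if reference_point is not None else mesh.nodes[ids].mean(axis=0))
    return Coupling(node_ids=ids, reference_point=rp)


# -- element operators and stiffness assembly --------------------------

def element_operators(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients (M,4,3) and volumes (M,) of all tets."""
    x = mesh.nodes[mesh.elements]  # (M,4,3)
    vol = np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0
    if np.any(vol <= 0):
        bad = int(np.argmin(vol))
        raise ValueError(f"inverted element {bad} (volume {vol[bad]:g})")
    M4 = np.concatenate([np.ones((len(x), 4, 1)), x], axis=2)  # (M,4,4)
    C = np.linalg.inv(M4)
    grads = np.transpose(C[:, 1:4, :], (0, 2, 1))  # (M,4,3): grad N_a = C[1:4,a]
    return grads, vol


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (M,6,12), engineering shear."""
    M = len(grads)
    B = np.zeros((M, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B


def assemble_stiffness(mesh: TetMesh, materials: dict[str, Material],
                       chunk: int = 50000) -> sp.csr_matrix:
    """Constant-strain-tet global stiffness (symmetric, 3N x 3N)."""
    for name in mesh.region_names:
        if name not in materials:
            raise ValueError(f"no material for region {name!r}")
    grads, vol = element_operators(mesh)
    D = np.stack([materials[name].d_matrix() for name in mesh.region_names])
    n = 3 * mesh.n_nodes
    K = sp.csr_matrix((n, n))
    dof = (3 * mesh.elements[:, :, None]
           + np.arange(3)[None, None, :]).reshape(-1, 12)
    for s in range(0, mesh.n_elements, chunk):
        e = min(s + chunk, mesh.n_elements)
        B = _b_matrices(grads[s:e])
        Dm = D[mesh.element_region[s:e]]
        Ke = np.einsum("mia,mij,mjb,m->mab", B, Dm, B, vol[s:e], optimize=True)
        rows = np.repeat(dof[s:e], 12, axis=1).ravel()
        cols = np.tile(dof[s:e], (1, 12)).ravel()
        K = K + sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


def element_stresses(mesh: TetMesh, materials: dict[str, Material],
                     u: np.ndarray, grads=None) -> np.ndarray:
    """Cauchy stress (M,6) per element, order (xx, yy, zz, xy, yz, zx)."""
    if grads is None:
        grads, _ = element_operators(mesh)
    ue = u.reshape(-1, 3)[mesh.elements]  # (M,4,3)
    eps = np.zeros((mesh.n_elements, 6))
    eps[:, 0] = np.einsum("ma,ma->m", grads[:, :, 0], ue[:, :, 0])
    eps[:, 1] = np.einsum("ma,ma->m", grads[:, :, 1], ue[:, :, 1])
    eps[:, 2] = np.einsum("ma,ma->m", grads[:, :, 2], ue[:, :, 2])
    eps[:, 3] = (np.einsum("ma,ma->m", grads[:, :, 1], ue[:, :, 0])
                 + np.einsum("ma,ma->m", grads[:, :, 0], ue[:, :, 1]))
    eps[:, 4] = (np.einsum("ma,ma->m", grads[:, :, 2], ue[:, :, 1])
                 + np.einsum("ma,ma->m", grads[:, :, 1], ue[:, :, 2]))
    eps[:, 5] = (np.einsum("ma,ma->m", grads[:, :, 2], ue[:, :, 0])
                 + np.einsum("ma,ma->m", grads[:, :, 0], ue[:, :, 2]))
    D = np.stack([materials[name].d_matrix() for name in mesh.region_names])
    return np.einsum("mij,mj->mi", D[mesh.element_region], eps)


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises invariant of stresses in (xx, yy, zz, xy, yz, zx) order."""
    s = np.atleast_2d(np.asarray(stress, dtype=float))
    sxx, syy, szz, sxy, syz, szx = (s[:, i] for i in range(6))
    vm = np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
                 + 3.0 * (sxy**2 + syz**2 + szx**2))
    return vm if stress.ndim > 1 else float(vm[0])


# -- constraints -------------------------------------------------------

class Constraints:
    """Affine reduction u = T q + g for Dirichlet and multipoint constraints.

    A DOF may be fixed or be the slave of exactly one MPC; constraint chains
    (a slave whose master is itself a slave) are rejected.
    """

    def __init__(self, n_dof: int):
        self.n_dof = n_dof
        self.fixed: dict[int, float] = {}
        self.mpc: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def add_extra_dofs(self, k: int) -> np.ndarray:
        idx = np.arange(self.n_dof, self.n_dof + k)
        self.n_dof += k
        return idx

    def fix_dof(self, dof: int, value: float = 0.0) -> None:
        if dof in self.mpc:
            raise ValueError(f"dof {dof} already constrained by an MPC")
        self.fixed[int(dof)] = float(value)

    def fix_nodes(self, node_ids, values=(0.0, 0.0, 0.0)) -> None:
        values = np.asarray(values, dtype=float)
        for nid in np.asarray(node_ids).ravel():
            for c in range(3):
                self.fix_dof(3 * int(nid) + c, values[c])

    def add_mpc(self, slave_dof: int, master_dofs, weights) -> None:
        slave_dof = int(slave_dof)
        if slave_dof in self.fixed or slave_dof in self.mpc:
            raise ValueError(
                f"dof {slave_dof} is in two conflicting constraints")
        self.mpc[slave_dof] = (np.asarray(master_dofs, dtype=int),
                               np.asarray(weights, dtype=float))

    def build(self) -> tuple[sp.csr_matrix, np.ndarray]:
        slaves = set(self.mpc)
        for s, (md, _) in self.mpc.items():
            for m in md:
                if int(m) in slaves:
                    raise ValueError(
                        f"constraint chain: master dof {m} is itself a slave")
        n = self.n_dof
        is_master = np.ones(n, dtype=bool)
        for d in self.fixed:
            is_master[d] = False
        for d in self.mpc:
            is_master[d] = False
        master_ids = np.nonzero(is_master)[0]
        self.master_ids = master_ids
        col = -np.ones(n, dtype=int)
        col[master_ids] = np.arange(len(master_ids))
        rows, cols, vals = [], [], []
        g = np.zeros(n)
        rows.append(master_ids)
        cols.append(col[master_ids])
        vals.append(np.ones(len(master_ids)))
        for d, v in self.fixed.items():
            g[d] = v
        for s, (md, w) in self.mpc.items():
            for m, wi in zip(md, w):
                if int(m) in self.fixed:
                    g[s] += wi * self.fixed[int(m)]
                else:
                    rows.append([s])
                    cols.append([col[int(m)]])
                    vals.append([wi])
        T = sp.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, len(master_ids))).tocsr()
        return T, g


def _project_points_on_triangles(p: np.ndarray, tri: np.ndarray):
    """Closest points of ``p[i]`` on triangles ``tri[i]`` (vectorised).

    Returns (closest point, barycentric coords, distance vector p - cp).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp_ = p - c
    d5 = np.einsum("ij,ij->i", ab, cp_)
    d6 = np.einsum("ij,ij->i", ac, cp_)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    n = len(p)
    out_v = np.zeros(n)
    out_w = np.zeros(n)
    done = np.zeros(n, dtype=bool)

    def assign(cond, v_val, w_val):
        nonlocal done
        m = cond & ~done
        out_v[m] = np.broadcast_to(v_val, (n,))[m]
        out_w[m] = np.broadcast_to(w_val, (n,))[m]
        done |= m

    def safe_div(num, den):
        return num / np.where(den == 0, 1.0, den)

    # Ericson's sequential Voronoi-region tests, vectorised
    assign((d1 <= 0) & (d2 <= 0), 0.0, 0.0)                       # vertex a
    assign((d3 >= 0) & (d4 <= d3), 1.0, 0.0)                      # vertex b
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0),
           safe_div(d1, d1 - d3), 0.0)                            # edge ab
    assign((d6 >= 0) & (d5 <= d6), 0.0, 1.0)                      # vertex c
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0),
           0.0, safe_div(d2, d2 - d6))                            # edge ac
    t_bc = safe_div(d4 - d3, (d4 - d3) + (d5 - d6))
    assign((va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0),
           1.0 - t_bc, t_bc)                                      # edge bc
    denom = va + vb + vc
    assign(np.ones(n, dtype=bool), safe_div(vb, denom),
           safe_div(vc, denom))                                   # interior
    bary = np.stack([1.0 - out_v - out_w, out_v, out_w], axis=1)
    cp = np.einsum("ik,ikj->ij", bary, tri)
    return cp, bary, p - cp


def apply_tie(mesh: TetMesh, tie: TiedInterface,
              constraints: Constraints) -> int:
    """Bond slave nodes to master facets as multipoint constraints.

    Each slave node's displacement is set to the barycentric interpolation of
    its closest master facet's nodal displacements; slave nodes farther than
    the gap tolerance are reported as an error.
    """
    slaves = np.asarray(mesh.node_sets[tie.slave_nodes])
    facets = np.asarray(mesh.facet_sets[tie.master_facets])
    tris = mesh.nodes[facets]
    centroids = tris.mean(axis=1)
    tree = cKDTree(centroids)
    p = mesh.nodes[slaves]
    k = min(8, len(facets))
    _, cand = tree.query(p, k=k)
    cand = np.atleast_2d(cand.reshape(len(p), -1))
    best_d = np.full(len(p), np.inf)
    best_bary = np.zeros((len(p), 3))
    best_f = np.zeros(len(p), dtype=int)
    for j in range(cand.shape[1]):
        fj = cand[:, j]
        _, bary, dvec = _project_points_on_triangles(p, tris[fj])
        d = np.linalg.norm(dvec, axis=1)
        upd = d < best_d
        best_d[upd] = d[upd]
        best_bary[upd] = bary[upd]
        best_f[upd] = fj[upd]
    far = best_d > tie.gap_tolerance_mm
    if far.any():
        raise ValueError(
            f"{int(far.sum())} tie slave nodes beyond gap tolerance "
            f"(max distance {best_d.max():g} mm): nodes "
            f"{slaves[far][:10].tolist()}")
    n_added = 0
    for i, s in enumerate(slaves):
        mnodes = facets[best_f[i]]
        w = best_bary[i]
        keep = w > 1e-12
        for c in range(3):
            constraints.add_mpc(3 * s + c, 3 * mnodes[keep] + c, w[keep])
        n_added += 3
    return n_added


# -- linear and contact solves -----------------------------------------

def _solve_reduced(K: sp.csr_matrix, f: np.ndarray, T: sp.csr_matrix,
                   g: np.ndarray) -> np.ndarray:
    A = (T.T @ K @ T).tocsc()
    rhs = T.T @ (f - K @ g)
    lu = spla.splu(A)
    q = lu.solve(rhs)
    return T @ q + g


class _PenaltySystemSolver:
    """Solves (K_red + W diag(kA) W^T) q = rhs with K_red factored once.

    The penalty term is a low-rank update handled by the Woodbury identity;
    the expensive back-solves ``K_red^-1 w`` are cached per contact
    constraint (slave node, master facet), which is effective because the
    constraint vectors barely change between contact iterations.  Any drift
    of the cached columns is absorbed by iterative refinement with the exact
    model residual; if refinement stalls the columns are refreshed, and as a
    last resort the full matrix is factored directly.
    """

    def __init__(self, K_red: sp.csc_matrix, max_cached: int = 2000,
                 drift_tol: float = 1.5e-2, model_rtol: float = 3e-7):
        self.K_red = K_red.tocsc()
        self.lu = spla.splu(self.K_red)
        self.max_cached = max_cached
        self.drift_tol = drift_tol
        self.model_rtol = model_rtol
        self._cache: dict = {}   # key -> (w_values, K^-1 w)

    def _columns(self, W: sp.csc_matrix, keys) -> np.ndarray:
        Wc = W.tocsc()
        missing = []
        for i, k in enumerate(keys):
            hit = self._cache.get(k)
            if hit is None:
                missing.append(i)
                continue
            w_cur = Wc[:, i]
            dw = (w_cur - hit[0])
            if float(np.abs(dw.data).max() if dw.nnz else 0.0) > self.drift_tol:
                missing.append(i)
        if missing:
            if len(self._cache) + len(missing) > self.max_cached:
                self._cache.clear()
                missing = list(range(len(keys)))
            sols = np.asarray(self.lu.solve(
                np.asarray(Wc[:, missing].todense(), order="F")))
            sols = sols.reshape(W.shape[0], len(missing))
            for j, i in enumerate(missing):
                self._cache[keys[i]] = (Wc[:, i].copy(), sols[:, j].copy())
        return np.stack([self._cache[k][1] for k in keys], axis=1)

    def solve(self, rhs: np.ndarray, W: sp.csc_matrix | None,
              kA: np.ndarray | None, keys=None) -> np.ndarray:
        if W is None or W.shape[1] == 0:
            return self.lu.solve(rhs)
        X = self._columns(W, keys)

        def matvec(q):
            return self.K_red @ q + W @ (kA * (W.T @ q))

        nrhs = max(float(np.linalg.norm(rhs)), 1e-300)
        S = np.diag(1.0 / kA) + (W.T @ X)

        def apply_inverse(v):
            y = self.lu.solve(v)
            return y - X @ np.linalg.solve(S, W.T @ y)

        q = apply_inverse(rhs)
        for _ in range(10):
            r = rhs - matvec(q)
            if np.linalg.norm(r) <= self.model_rtol * nrhs:
                return q
            q = q + apply_inverse(r)
        # fallback: direct factorisation of the full penalty system
        A = (self.K_red + (W.multiply(kA[None, :])) @ W.T).tocsc()
        return spla.splu(A).solve(rhs)


def solve_linear(mesh: TetMesh, materials: dict[str, Material],
                 constraints: Constraints,
                 K: sp.csr_matrix | None = None,
                 f: np.ndarray | None = None) -> np.ndarray:
    """Solve K u = f under the given constraints; returns u (n_dof,)."""
    if K is None:
        K = assemble_stiffness(mesh, materials)
    n = constraints.n_dof
    if K.shape[0] < n:  # extra (reference point) dofs carry no stiffness
        K = sp.block_diag([K, sp.csr_matrix((n - K.shape[0],
                                             n - K.shape[0]))]).tocsr()
    if f is None:
        f = np.zeros(n)
    T, g = constraints.build()
    return _solve_reduced(K, f, T, g)


@dataclass
class StepSolution:
    rp_displacement_mm: float
    displacement: np.ndarray           # (N,3) mm
    reaction_force: np.ndarray         # (3,) N at the reference point
    axial_reaction_n: float            # along the loading direction
    element_stress: np.ndarray         # (M,6) MPa
    element_von_mises: np.ndarray      # (M,) MPa
    contact: dict = field(default_factory=dict)
    # contact[name] = dict(slave_nodes, pressure, active, force_z, area)
    max_penetration_mm: float = 0.0
    contact_residual_rel: float = 0.0
    n_iterations: int = 0
    is_loading_step: bool = True


@dataclass
class FESolution:
    """Per-step displacements, stresses, contact pressures and reactions."""

    mesh: TetMesh
    steps: list[StepSolution]
    protocol: LoadProtocol
    reference_point: np.ndarray | None = None

    def loading_steps(self) -> list[StepSolution]:
        return [s for s in self.steps if s.is_loading_step]


def reaction_history(sol: FESolution) -> list[tuple[int, float]]:
    """Axial reference-point reaction (N) per loading step."""
    return [(i, s.axial_reaction_n)
            for i, s in enumerate(sol.loading_steps())]


def _pair_setup(mesh: TetMesh, pair: ContactPair,
                materials: dict[str, Material]):
    """Slave nodes, tributary areas, and default penalty for a pair."""
    sfacets = np.asarray(mesh.facet_sets[pair.slave])
    slave_nodes = np.unique(sfacets)
    tri = mesh.nodes[sfacets]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    trib = np.zeros(mesh.n_nodes)
    np.add.at(trib, sfacets.ravel(), np.repeat(areas / 3.0, 3))
    trib = trib[slave_nodes]
    kp = pair.penalty_stiffness
    if kp is None:
        edges = np.concatenate([
            np.linalg.norm(tri[:, 1] - tri[:, 0], axis=1),
            np.linalg.norm(tri[:, 2] - tri[:, 1], axis=1),
            np.linalg.norm(tri[:, 0] - tri[:, 2], axis=1)])
        h = float(edges.mean())
        # penalty scaled to the softer of the two contacting tissues: the
        # softer side governs the contact compliance, and a penalty scaled
        # to a much stiffer slave only ill-conditions the iteration
        def _surface_modulus(facet_set):
            nids = np.unique(np.asarray(mesh.facet_sets[facet_set]))
            rid = mesh.element_region[np.isin(mesh.elements,
                                              nids).any(axis=1)]
            name = mesh.region_names[int(np.bincount(rid).argmax())]
            return materials[name].young_modulus
        e_soft = min(_surface_modulus(pair.slave),
                     _surface_modulus(pair.master))
        kp = 50.0 * e_soft / h
    mfacets = np.asarray(mesh.facet_sets[pair.master])
    # area-weighted vertex normals of the master surface (reference config)
    mtri = mesh.nodes[mfacets]
    mcross = np.cross(mtri[:, 1] - mtri[:, 0], mtri[:, 2] - mtri[:, 0])
    vert_nrm = np.zeros((mesh.n_nodes, 3))
    np.add.at(vert_nrm, mfacets.ravel(),
              np.repeat(mcross, 3, axis=0).reshape(-1, 3))
    nn = np.linalg.norm(vert_nrm, axis=1, keepdims=True)
    vert_nrm = vert_nrm / np.where(nn > 0, nn, 1.0)
    return slave_nodes, trib, float(kp), mfacets, vert_nrm


def _contact_state_ray(nodes, u3, slave_nodes, mfacets, axis,
                       search_radius, vertex_normals=None):
    """Gap along a fixed axis: each slave node pairs with the master facet
    its axial ray pierces.

    Suited to axial displacement protocols on voxel (staircased) master
    surfaces: the facet assignment is unique, so the gap is a stable,
    piecewise-continuous function of the displacement, unlike closest-point
    projection, which flickers between staircase treads.  The gap keeps the
    normal-projection sign convention (negative = penetration through the
    master's outward normal).
    """
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    # orthonormal in-plane basis for the 2D point-in-triangle test
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(a @ tmp) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    xm = nodes + u3
    # facets nearly parallel to the ray cannot be pierced; drop them up
    # front so their centroids do not crowd the candidate search.  The
    # filter uses *reference* normals so the admissible facet set never
    # flickers as the surface deforms
    tris_ref = nodes[mfacets]
    nrm_ref = np.cross(tris_ref[:, 1] - tris_ref[:, 0],
                       tris_ref[:, 2] - tris_ref[:, 0])
    nrm_ref /= np.maximum(np.linalg.norm(nrm_ref, axis=1, keepdims=True),
                          1e-300)
    usable = np.abs(nrm_ref @ a) > 0.2
    fmap = np.nonzero(usable)[0]
    if len(fmap) == 0:
        n_empty = len(slave_nodes)
        return (np.full(n_empty, np.inf), np.zeros((n_empty, 3)),
                np.zeros((n_empty, 3)), np.zeros(n_empty, dtype=int))
    tris = xm[mfacets[fmap]]
    centroids = tris.mean(axis=1)
    c2 = np.stack([centroids @ e1, centroids @ e2], axis=1)
    tree = cKDTree(c2)
    p = xm[slave_nodes]
    p2 = np.stack([p @ e1, p @ e2], axis=1)
    k = min(24, len(fmap))
    dists, cand = tree.query(p2, k=k, distance_upper_bound=search_radius)
    cand = np.atleast_2d(cand.reshape(len(p), -1))
    dists = np.atleast_2d(dists.reshape(len(p), -1))
    n_p = len(p)
    gap = np.full((2, n_p), np.inf)
    normal = np.zeros((2, n_p, 3))
    bary = np.zeros((2, n_p, 3))
    fidx = np.zeros((2, n_p), dtype=int)
    best = np.full((2, n_p), np.inf)
    found = np.zeros((2, n_p), dtype=bool)
    for j in range(cand.shape[1]):
        ok = np.isfinite(dists[:, j])
        if not ok.any():
            continue
        fj = np.where(ok, cand[:, j], 0)
        tri = tris[fj]
        t2 = np.stack([tri @ e1, tri @ e2], axis=2)  # (n,3,2)
        # 2D barycentric of the slave point in the projected triangle
        v0 = t2[:, 1] - t2[:, 0]
        v1 = t2[:, 2] - t2[:, 0]
        v2 = p2 - t2[:, 0]
        den = v0[:, 0] * v1[:, 1] - v1[:, 0] * v0[:, 1]
        den = np.where(np.abs(den) < 1e-300, 1e-300, den)
        l1 = (v2[:, 0] * v1[:, 1] - v1[:, 0] * v2[:, 1]) / den
        l2 = (v0[:, 0] * v2[:, 1] - v2[:, 0] * v0[:, 1]) / den
        l0 = 1.0 - l1 - l2
        nrm = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        nn = np.linalg.norm(nrm, axis=1, keepdims=True)
        nrm = nrm / np.maximum(nn, 1e-300)
        # degenerate-deformation guard only; admissibility was
        # fixed by the reference-normal pre-filter
        not_parallel = np.abs(nrm @ a) > 0.05
        bj = np.stack([l0, l1, l2], axis=1)
        xi = np.einsum("ik,ikj->ij", bj, tri)
        g_n = np.einsum("ij,ij->i", p - xi, nrm)
        lmin = np.minimum(np.minimum(l0, l1), l2)
        # tier 0: the ray pierces the facet itself (stable, near-unique);
        # tier 1: small negative-barycentric extension, fallback for
        # boundary nodes that drift marginally outside the footprint
        for tier, tol in ((0, -1e-9), (1, -0.08)):
            inside = ok & not_parallel & (lmin >= tol)
            upd = inside & (np.abs(g_n) < best[tier])
            best[tier][upd] = np.abs(g_n)[upd]
            gap[tier][upd] = g_n[upd]
            normal[tier][upd] = nrm[upd]
            bary[tier][upd] = bj[upd]
            fidx[tier][upd] = fj[upd]
            found[tier] |= inside
    use = np.where(found[0], 0, 1)
    ar = np.arange(n_p)
    gap_o, normal_o, bary_o, fidx_o = (gap[use, ar], normal[use, ar],
                                       bary[use, ar], fidx[use, ar])
    fidx_o = fmap[fidx_o]   # back to indices into the full facet set
    if vertex_normals is not None:
        # Phong normals: barycentric blend of vertex-averaged normals gives
        # a force direction continuous across facet edges
        ok = np.isfinite(gap_o)
        vn = np.einsum("ik,ikj->ij", bary_o[ok],
                       vertex_normals[mfacets[fidx_o[ok]]])
        vn /= np.maximum(np.linalg.norm(vn, axis=1, keepdims=True), 1e-300)
        normal_o[ok] = vn
    return gap_o, normal_o, bary_o, fidx_o


def _contact_state(nodes, u3, slave_nodes, mfacets, search_radius,
                   edge_extension=None):
    """Project deformed slave nodes on deformed master facets.

    For each slave node the candidate master facets (nearest by centroid)
    are scanned; the gap is the *normal* distance to the facet plane, which
    keeps the evaluation consistent with the linearised gap ``c + w.u`` and
    well-behaved for nodes that slightly overhang a facet edge.  A facet is
    admissible when the tangential offset of the closest point is at most
    ``edge_extension`` (default: 40% of the mean facet edge); among
    admissible facets the one with the smallest |normal gap| wins.  Nodes
    with no admissible facet within ``search_radius`` get gap = +inf.
    """
    xm = nodes + u3
    tris = xm[mfacets]
    centroids = tris.mean(axis=1)
    if edge_extension is None:
        e = np.linalg.norm(tris[:, 1] - tris[:, 0], axis=1)
        edge_extension = 0.4 * float(e.mean())
    tree = cKDTree(centroids)
    p = xm[slave_nodes]
    k = min(10, len(mfacets))
    dists, cand = tree.query(p, k=k, distance_upper_bound=search_radius)
    cand = np.atleast_2d(cand.reshape(len(p), -1))
    dists = np.atleast_2d(dists.reshape(len(p), -1))
    gap = np.full(len(p), np.inf)
    normal = np.zeros((len(p), 3))
    bary = np.zeros((len(p), 3))
    fidx = np.zeros(len(p), dtype=int)
    best = np.full(len(p), np.inf)
    for j in range(cand.shape[1]):
        fj = cand[:, j]
        ok = np.isfinite(dists[:, j])
        if not ok.any():
            continue
        fj = np.where(ok, fj, 0)
        tri_j = tris[fj]
        cp, bj, dvec = _project_points_on_triangles(p, tri_j)
        nrm = np.cross(tri_j[:, 1] - tri_j[:, 0], tri_j[:, 2] - tri_j[:, 0])
        nrm /= np.maximum(np.linalg.norm(nrm, axis=1, keepdims=True), 1e-300)
        g_n = np.einsum("ij,ij->i", dvec, nrm)
        t_off = np.linalg.norm(dvec - g_n[:, None] * nrm, axis=1)
        upd = ok & (t_off <= edge_extension) & (np.abs(g_n) < best)
        best[upd] = np.abs(g_n)[upd]
        gap[upd] = g_n[upd]
        normal[upd] = nrm[upd]
        bary[upd] = bj[upd]
        fidx[upd] = fj[upd]
    return gap, normal, bary, fidx


def solve_contact_steps(mesh: TetMesh, materials: dict[str, Material],
                        protocol: LoadProtocol, pairs: list[ContactPair],
                        ties: list[TiedInterface] | None = None,
                        fixed_sets: list[str] | None = None,
                        coupling: Coupling | None = None,
                        coupled_set: str = "femur_top_coupled",
                        max_iterations: int = 40,
                        force_rtol: float = 1e-3,
                        floor_rtol: float = 0.03,
                        freeze_pairing_after: int = 5,
                        store_stress: bool = True,
                        verbose: bool = False) -> FESolution:
    """Displacement-controlled multi-step solve with penalty contact.

    At every step the reference point advances along the protocol direction;
    an active-set loop re-projects each slave node on the nearest master
    facet (finite sliding), applies penalty forces where the signed gap is
    negative, and repeats until the active set is stable and the displacement
    update is below tolerance.
    """
    ties = ties or []
    fixed_sets = fixed_sets if fixed_sets is not None else ["tibia_distal_fixed"]
    if coupling is None:
        coupling = apply_coupling(mesh, coupled_set)

    K0 = assemble_stiffness(mesh, materials)
    grads, _ = element_operators(mesh)
    n_struct = 3 * mesh.n_nodes

    pair_data = [_pair_setup(mesh, p, materials) for p in pairs]
    h_search = mesh.grid_spacing_mm or 0.05
    search_radius = 8.0 * h_search

    direction = np.asarray(protocol.direction)
    mags, first_loading = protocol.schedule_mm()

    steps: list[StepSolution] = []
    u = np.zeros(n_struct)
    K0_aug = sp.block_diag([K0, sp.csr_matrix((3, 3))]).tocsr()

    # constraints: the pattern (T) is step-independent, only the prescribed
    # reference-point displacement in g changes, so the reduced elastic
    # operator is assembled and factored once
    con = Constraints(n_struct)
    rp_dofs = con.add_extra_dofs(3)
    for c in range(3):
        con.fix_dof(rp_dofs[c], 0.0)
    for nid in coupling.node_ids:
        for c in range(3):
            con.add_mpc(3 * int(nid) + c, [rp_dofs[c]], [1.0])
    for name in fixed_sets:
        con.fix_nodes(mesh.node_sets[name])
    for tie in ties:
        apply_tie(mesh, tie, con)
    T, _ = con.build()
    solver = _PenaltySystemSolver((T.T @ K0_aug @ T).tocsc())

    for istep, mag in enumerate(mags):
        rp_disp = direction * mag
        for c in range(3):
            con.fixed[int(rp_dofs[c])] = float(rp_disp[c])
        _, g = con.build()
        b0 = -(T.T @ (K0_aug @ g))

        u_full = np.concatenate([u, rp_disp])
        active_sets: list[tuple] = []
        n_osc = 0
        n_stall = 0
        alpha = 1.0
        res_hist: list[float] = []
        res_rel = np.inf
        res_prev = np.inf
        converged = False
        states = None
        increment_mm = float(mag - (mags[istep - 1] if istep else 0.0))
        frozen = False
        for it in range(max_iterations):
            # a handful of slave nodes can sit on folds of the piecewise
            # linear surfaces where the pierced-facet assignment is genuinely
            # discontinuous in the displacement; if the re-pairing loop has
            # not settled after several updates, the pairing is frozen so
            # the step closes on one well-posed convex problem
            if it >= freeze_pairing_after and not frozen:
                frozen = True
            # evaluate the true (clipped) contact forces at the current state
            prev_states = states
            states = []
            f_contact = np.zeros(n_struct + 3)
            current_active = []
            for ipair, (pair, (snodes, trib, kp, mfacets, vn)) \
                    in enumerate(zip(pairs, pair_data)):
                if frozen and prev_states is not None:
                    gap0, nrm, bary, fidx = prev_states[ipair]
                    # frozen pairing: same facet/bary/normal, fresh geometry
                    u3 = u_full[:n_struct].reshape(-1, 3)
                    fin = np.isfinite(gap0)
                    gap = np.full_like(gap0, np.inf)
                    if fin.any():
                        xs = (mesh.nodes + u3)[snodes[fin]]
                        tri = (mesh.nodes + u3)[mfacets[fidx[fin]]]
                        xi = np.einsum("ik,ikj->ij", bary[fin], tri)
                        gap[fin] = np.einsum("ij,ij->i", xs - xi, nrm[fin])
                elif pair.mode == "ray":
                    gap, nrm, bary, fidx = _contact_state_ray(
                        mesh.nodes, u_full[:n_struct].reshape(-1, 3),
                        snodes, mfacets, direction, search_radius,
                        vertex_normals=vn)
                else:
                    gap, nrm, bary, fidx = _contact_state(
                        mesh.nodes, u_full[:n_struct].reshape(-1, 3),
                        snodes, mfacets, search_radius)
                states.append((gap, nrm, bary, fidx))
                act = gap < 0
                current_active.append(np.nonzero(act)[0])
                if not act.any():
                    continue
                s_act = snodes[act]
                m_act = mfacets[fidx[act]]
                fvec = (kp * trib[act] * (-gap[act]))[:, None] * nrm[act]
                sdofs = 3 * s_act[:, None] + np.arange(3)[None, :]
                np.add.at(f_contact, sdofs.ravel(), fvec.ravel())
                mdofs = (3 * m_act[:, :, None]
                         + np.arange(3)[None, None, :])
                fm = -bary[act][:, :, None] * fvec[:, None, :]
                np.add.at(f_contact, mdofs.ravel(), fm.ravel())
            # nonlinear residual on the free (reduced) dofs; the grazing
            # nodes that chatter in and out of the active set do not spoil
            # this criterion because their forces are ~0 either way
            resid_full = K0_aug @ u_full - f_contact
            res = float(np.linalg.norm(T.T @ resid_full))
            # force scale: contact forces and support/reference reactions
            fscale = max(1e-8, float(np.linalg.norm(f_contact)),
                         float(np.linalg.norm(resid_full)))
            res_rel = res / fscale
            aset = tuple(tuple(a.tolist()) for a in current_active)
            if verbose:
                import sys
                import time as _time
                print(f"  step {istep} it {it}: active "
                      f"{sum(len(a) for a in current_active)}, "
                      f"res {res:.3e} / scale {fscale:.3e} "
                      f"t={_time.time():.1f}", file=sys.stderr)
            if it > 0 and res <= force_rtol * fscale:
                converged = True
                break
            # frictionless contact on piecewise-linear surfaces re-pairs
            # slave nodes as they slide, which leaves a small re-projection
            # noise floor in the residual; accept once the iteration has
            # clearly reached that floor
            if it >= 5 and res <= floor_rtol * fscale \
                    and res > 0.5 * min(res_hist[-3:]):
                converged = True
                break
            res_hist.append(res)
            # outer stagnation: damp the projection update, relax on progress
            if it >= 3 and res > 0.7 * res_prev:
                n_stall += 1
                alpha = max(0.25, alpha * 0.5)
            elif res < 0.5 * res_prev:
                alpha = min(1.0, alpha * 1.4)
            res_prev = res
            active_sets.append(aset)
            # freeze the projections and solve the linearised contact
            # problem *exactly* (inner active-set / complementarity loop on
            # the frozen gap functions g_i(u) = c_i + w_i.u); candidate
            # constraints are all paired nodes within a gap band that the
            # current increment could close
            band = (mesh.grid_spacing_mm or 0.05) + increment_mm
            w_rows, w_cols, w_vals_all = [], [], []
            kA_all, c_all, keys = [], [], []
            ncon = 0
            for ipair, ((pair, (snodes, trib, kp, mfacets, vn)),
                        (gap, nrm, bary, fidx)) \
                    in enumerate(zip(zip(pairs, pair_data), states)):
                cand = np.isfinite(gap) & (gap < band)
                if not cand.any():
                    continue
                cidx = np.nonzero(cand)[0]
                s_c = snodes[cand]
                m_c = mfacets[fidx[cand]]
                w_dofs = np.concatenate(
                    [3 * s_c[:, None] + np.arange(3)[None, :],
                     (3 * m_c[:, :, None]
                      + np.arange(3)[None, None, :]).reshape(len(s_c), 9)],
                    axis=1)  # (C,12)
                nr = nrm[cand]
                br = bary[cand]
                w_vals = np.concatenate(
                    [nr, (-br[:, :, None] * nr[:, None, :])
                     .reshape(len(s_c), 9)], axis=1)
                kA = kp * trib[cand]
                wu = np.einsum("ij,ij->i", w_vals, u_full[w_dofs])
                w_rows.append(w_dofs.ravel())
                w_cols.append(np.repeat(np.arange(ncon, ncon + len(s_c)), 12))
                w_vals_all.append(w_vals.ravel())
                kA_all.append(kA)
                c_all.append(gap[cand] - wu)
                keys.extend((ipair, int(a), int(f))
                            for a, f in zip(cidx, fidx[cand]))
                ncon += len(s_c)
            if ncon == 0:
                q = solver.solve(b0, None, None)
                u_full = T @ q + g
                continue
            Wfull = sp.coo_matrix(
                (np.concatenate(w_vals_all),
                 (np.concatenate(w_rows), np.concatenate(w_cols))),
                shape=(n_struct + 3, ncon)).tocsc()
            Wred = (T.T @ Wfull).tocsc()
            kA_vec = np.concatenate(kA_all)
            c_vec = np.concatenate(c_all)
            Wg = np.asarray(Wfull.T @ g).ravel()
            cgq = c_vec + Wg   # frozen gap constants in reduced coordinates
            WredT = Wred.T.tocsr()
            q_cur = u_full[con.master_ids]

            def grad_and_energy(qv):
                g_lin = cgq + WredT @ qv
                pen = np.minimum(g_lin, 0.0)
                Kq = solver.K_red @ qv
                E = (0.5 * float(qv @ Kq) - float(b0 @ qv)
                     + 0.5 * float((kA_vec * pen) @ pen))
                grad = Kq - b0 + Wred @ (kA_vec * pen)
                return grad, E, g_lin

            grad, E_cur, g_lin = grad_and_energy(q_cur)
            gscale = max(1e-12, float(np.linalg.norm(b0)),
                         float(np.linalg.norm(grad)))
            # the frozen problem is a convex QP (quadratic + one-sided
            # quadratic penalty): semismooth Newton with a backtracking
            # energy line search converges globally
            for inner in range(30):
                if verbose and it < 15:
                    import sys
                    print(f"    inner {inner}: E {E_cur:.10e} |grad| "
                          f"{np.linalg.norm(grad):.3e} gscale {gscale:.3e} "
                          f"act {int((g_lin < 0).sum())}", file=sys.stderr)
                if float(np.linalg.norm(grad)) <= 1e-8 * gscale:
                    break
                active = g_lin < 0
                ai = np.nonzero(active)[0]
                if len(ai):
                    Wa = Wred[:, ai].tocsc()
                    kAa = kA_vec[ai]
                    rhs = b0 - Wa @ (kAa * cgq[ai])
                    q_new = solver.solve(rhs, Wa, kAa, [keys[i] for i in ai])
                else:
                    q_new = solver.solve(b0, None, None)
                d = q_new - q_cur
                t = 1.0
                for _ in range(15):
                    g_t, E_t, gl_t = grad_and_energy(q_cur + t * d)
                    if E_t <= E_cur - 1e-14 * abs(E_cur):
                        break
                    t *= 0.5
                else:
                    n_osc += 1
                    break
                if t < 1.0:
                    n_osc += 1
                q_cur = q_cur + t * d
                grad, E_cur, g_lin = g_t, E_t, gl_t
            u_full = T @ q_cur + g
        # contact summary at the converged displacement
        contact = {}
        f_contact = np.zeros(n_struct + 3)
        master_force = {}   # master facet-set name -> (n_nodes, 3) forces
        max_pen = 0.0
        for (pair, (snodes, trib, kp, mfacets, vn)), (gap, nrm, bary, fidx) \
                in zip(zip(pairs, pair_data), states or []):
            pen = np.where(np.isfinite(gap), np.minimum(gap, 0.0), 0.0)
            pressure = kp * (-pen)
            act = pen < 0
            if pair.master not in master_force:
                master_force[pair.master] = np.zeros((mesh.n_nodes, 3))
            if act.any():
                max_pen = max(max_pen, float(-pen.min()))
                s_act = snodes[act]
                m_act = mfacets[fidx[act]]
                fvec = (kp * trib[act] * (-pen[act]))[:, None] * nrm[act]
                sdofs = (3 * s_act[:, None] + np.arange(3)[None, :])
                np.add.at(f_contact, sdofs.ravel(), fvec.ravel())
                mdofs = (3 * m_act[:, :, None] + np.arange(3)[None, None, :])
                fm = -bary[act][:, :, None] * fvec[:, None, :]
                np.add.at(f_contact, mdofs.ravel(), fm.ravel())
                np.add.at(master_force[pair.master], m_act.ravel(),
                          fm.reshape(-1, 3))
            contact[f"{pair.master}|{pair.slave}"] = {
                "slave_nodes": snodes,
                "pressure": pressure,
                "active": act,
                "tributary_area": trib,
                "force": (kp * trib * (-pen))[:, None] * nrm,
            }
        # pressure received by each master surface, aggregated over the
        # pairs that load it (the quantity mapped in the joint comparison)
        for mname, forces in master_force.items():
            facets = np.asarray(mesh.facet_sets[mname])
            tri = mesh.nodes[facets]
            areas = 0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]),
                axis=1)
            trib_m = np.zeros(mesh.n_nodes)
            np.add.at(trib_m, facets.ravel(), np.repeat(areas / 3.0, 3))
            mnodes = np.unique(facets)
            fmag = np.linalg.norm(forces[mnodes], axis=1)
            p_m = fmag / np.maximum(trib_m[mnodes], 1e-300)
            contact[f"master::{mname}"] = {
                "slave_nodes": mnodes,
                "pressure": p_m,
                "active": p_m > 0,
                "tributary_area": trib_m[mnodes],
                "force": forces[mnodes],
                "is_master_surface": True,
            }
        if not converged:
            raise ContactConvergenceError(
                f"contact iteration did not converge in {max_iterations} "
                f"iterations at step {istep} (last penetration "
                f"{max_pen:g} mm, {n_osc} active-set oscillations)",
                max_penetration=max_pen, oscillations=n_osc)

        u = u_full[:n_struct]
        residual = K0 @ u - f_contact[:n_struct]
        r3 = residual.reshape(-1, 3)
        rp_reaction = r3[coupling.node_ids].sum(axis=0)
        axial = float(rp_reaction @ direction)
        if store_stress:
            stress = element_stresses(mesh, materials, u, grads)
            vm = von_mises(stress)
        else:
            stress = np.zeros((0, 6))
            vm = np.zeros(0)
        steps.append(StepSolution(
            rp_displacement_mm=float(mag),
            displacement=u.reshape(-1, 3).copy(),
            reaction_force=rp_reaction,
            axial_reaction_n=axial,
            element_stress=stress,
            element_von_mises=vm,
            contact=contact,
            max_penetration_mm=max_pen,
            contact_residual_rel=float(res_rel),
            n_iterations=it + 1,
            is_loading_step=istep >= first_loading,
        ))
    return FESolution(mesh=mesh, steps=steps, protocol=protocol,
                      reference_point=coupling.reference_point)
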