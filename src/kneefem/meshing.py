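"""Multi-region linear tetrahedral meshing of voxel label masks.

Each labelled voxel is split into six tetrahedra (Kuhn subdivision: all six
tets share the main diagonal of the cube).  Because every cube uses the same
diagonal orientation, the triangulated faces of neighbouring cubes coincide,
so the mesh is conforming across region interfaces by construction, and the
union of the six tets reproduces the cube exactly, so per-tissue volume is
conserved to floating point at 1-voxel coarsening.

Coarsening toward a target edge length is an integer downsampling of the
label grid by majority vote; all tissues share one mesh grid so conformity
is never lost (the bone is simply over-refined relative to its own target).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .image import LabelMask

__all__ = [
    "TetMesh",
    "MeshParams",
    "voxels_to_tets",
    "extract_named_sets",
    "mesh_quality",
    "concatenate",
    "write_vtu",
    "read_vtu",
    "write_inp",
]


@dataclass
class MeshParams:
    """Meshing targets (micrometres).

    The effective mesh grid spacing is the voxel spacing multiplied by
    ``round(target_edge_soft_um / spacing_um)`` (at least 1): the soft-tissue
    target drives the shared grid, the bone target is reported but the bone is
    meshed on the same grid to keep interfaces conforming.
    """

    target_edge_bone_um: float = 100.0
    target_edge_soft_um: float = 5.0

    def __post_init__(self) -> None:
        if self.target_edge_bone_um <= 0 or self.target_edge_soft_um <= 0:
            raise ValueError("target edges must be positive")
        if self.target_edge_soft_um > self.target_edge_bone_um:
            raise ValueError("soft-tissue target edge must be <= bone target")

    def coarsen_factor(self, spacing_um: float) -> int:
        return max(1, int(round(self.target_edge_soft_um / spacing_um)))


@dataclass
class TetMesh:
    """Multi-region linear tetrahedral mesh with named node/facet sets.

    ``facet_sets`` store oriented triangles (outward right-hand normal) as
    node-index triples.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_region: np.ndarray
    region_names: list[str]
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    facet_sets: dict[str, np.ndarray] = field(default_factory=dict)
    grid_spacing_mm: float | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def signed_volumes(self) -> np.ndarray:
        x = self.nodes[self.elements]
        return np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0

    def region_id(self, name: str) -> int:
        return self.region_names.index(name)

    def region_volume(self, name: str) -> float:
        rid = self.region_id(name)
        return float(self.signed_volumes()[self.element_region == rid].sum())

    def region_elements(self, name: str) -> np.ndarray:
        return self.elements[self.element_region == self.region_id(name)]

    def facet_areas(self, name: str) -> np.ndarray:
        tri = self.nodes[self.facet_sets[name]]
        cr = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def validate(self) -> None:
        vol = self.signed_volumes()
        if not np.all(vol > 0):
            bad = int(np.argmin(vol))
            raise ValueError(f"element {bad} has non-positive volume {vol[bad]:g}")
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.elements.ravel()] = True
        if not used.all():
            raise ValueError(f"{int((~used).sum())} orphan nodes")


# -- Kuhn subdivision --------------------------------------------------

def _kuhn_tets() -> np.ndarray:
    """Six tets per cube as corner indices (corner id = 4*dx + 2*dy + dz)."""
    def cid(d):
        return 4 * d[0] + 2 * d[1] + d[2]

    tets = []
    for perm in itertools.permutations(range(3)):
        steps = [np.zeros(3, dtype=int)]
        for ax in perm:
            nxt = steps[-1].copy()
            nxt[ax] = 1
            steps.append(nxt)
        quad = [cid(s) for s in steps]
        # fix orientation: permutation sign = sign of det([e_p0, e_p1, e_p2])
        sign = np.sign(np.linalg.det(np.eye(3)[list(perm)]))
        if sign < 0:
            quad[2], quad[3] = quad[3], quad[2]
        tets.append(quad)
    return np.asarray(tets, dtype=np.int64)


_KUHN = _kuhn_tets()
_CORNER_OFFSETS = np.array([[d >> 2 & 1, d >> 1 & 1, d & 1] for d in range(8)])

# faces of a positively oriented tet (a,b,c,d), outward orientation
_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


def _majority_downsample(labels: np.ndarray, f: int) -> np.ndarray:
    """Block-majority label downsampling (background competes too)."""
    if f == 1:
        return labels
    nx, ny, nz = labels.shape
    px, py, pz = (-nx) % f, (-ny) % f, (-nz) % f
    lab = np.pad(labels, ((0, px), (0, py), (0, pz)), constant_values=0)
    bx, by, bz = lab.shape[0] // f, lab.shape[1] // f, lab.shape[2] // f
    blocks = lab.reshape(bx, f, by, f, bz, f).transpose(0, 2, 4, 1, 3, 5)
    blocks = blocks.reshape(bx, by, bz, f**3)
    nlab = int(labels.max()) + 1
    counts = np.zeros((bx, by, bz, nlab), dtype=np.int32)
    for l in range(nlab):
        counts[..., l] = (blocks == l).sum(axis=-1)
    return np.argmax(counts, axis=-1).astype(labels.dtype)


def masks_to_labels(masks: list[LabelMask]) -> tuple[np.ndarray, list[str]]:
    """Stack disjoint masks into one integer label volume (0 = background)."""
    names = []
    base = masks[0]
    labels = np.zeros(base.shape, dtype=np.int16)
    for i, m in enumerate(masks):
        if not base.same_grid(m):
            raise ValueError("masks are not on a shared grid")
        if (labels[m.values] != 0).any():
            raise ValueError(
                f"mask {m.tissue!r} overlaps a previously added mask")
        labels[m.values] = i + 1
        names.append(m.tissue)
    return labels, names


def voxels_to_tets(masks: list[LabelMask],
                   params: MeshParams | None = None) -> TetMesh:
    """Convert disjoint label masks into a conforming multi-region tet mesh."""
    if params is None:
        sp = masks[0].spacing_um
        params = MeshParams(target_edge_bone_um=max(100.0, sp),
                            target_edge_soft_um=sp)
    labels, names = masks_to_labels(masks)
    spacing_mm = masks[0].spacing_mm
    origin = masks[0].origin_mm
    f = params.coarsen_factor(masks[0].spacing_um)
    labels = _majority_downsample(labels, f)
    h = spacing_mm * f  # mesh grid spacing
    corner0 = origin - 0.5 * spacing_mm  # corner (0,0,0) position

    vox = np.argwhere(labels > 0)
    if len(vox) == 0:
        raise ValueError("no labelled voxels to mesh")
    reg = labels[vox[:, 0], vox[:, 1], vox[:, 2]].astype(np.int16) - 1

    nyc = labels.shape[1] + 1
    nzc = labels.shape[2] + 1
    # global corner ids for the 8 corners of each voxel
    corners = vox[:, None, :] + _CORNER_OFFSETS[None, :, :]  # (V,8,3)
    cid = (corners[..., 0] * nyc + corners[..., 1]) * nzc + corners[..., 2]
    elements = cid[:, _KUHN].reshape(-1, 4)  # (V,6,4) -> (6V,4)
    element_region = np.repeat(reg, 6)

    uniq, inv = np.unique(elements, return_inverse=True)
    elements = inv.reshape(-1, 4).astype(np.int64)
    ci = np.empty((len(uniq), 3), dtype=np.int64)
    ci[:, 0] = uniq // (nyc * nzc)
    ci[:, 1] = (uniq // nzc) % nyc
    ci[:, 2] = uniq % nzc
    nodes = corner0[None, :] + h * ci

    mesh = TetMesh(nodes=nodes, elements=elements,
                   element_region=element_region, region_names=names,
                   grid_spacing_mm=h)
    return mesh


# -- boundary topology -------------------------------------------------

def _face_table(mesh: TetMesh):
    """All oriented tet faces with a canonical (sorted) key for matching."""
    faces = mesh.elements[:, _TET_FACES]               # (M,4,3)
    oriented = faces.reshape(-1, 3)
    key = np.sort(oriented, axis=1)
    owner = np.repeat(np.arange(mesh.n_elements), 4)
    return oriented, key, owner


def boundary_and_interfaces(mesh: TetMesh):
    """Classify every face: exterior boundary or region-interface.

    Returns ``(bfaces, bregion, ifaces, iregions)`` where ``bfaces`` are
    outward-oriented exterior triangles with the owning region id, and
    ``ifaces`` are interface triangles oriented outward from the region in
    ``iregions[:, 0]``.
    """
    oriented, key, owner = _face_table(mesh)
    order = np.lexsort(key.T[::-1])
    ks = key[order]
    same = np.all(ks[1:] == ks[:-1], axis=1)
    first = np.concatenate([[True], ~same])
    grp = np.cumsum(first) - 1
    counts = np.bincount(grp)
    if counts.max() > 2:
        raise ValueError("non-manifold face shared by more than two tets")
    single = counts[grp] == 1
    bidx = order[single]
    bfaces = oriented[bidx]
    bregion = mesh.element_region[owner[bidx]]
    # paired faces
    pair_first = order[first & (counts[grp] == 2)]
    pair_second = order[~first]
    r1 = mesh.element_region[owner[pair_first]]
    r2 = mesh.element_region[owner[pair_second]]
    diff = r1 != r2
    ifaces = oriented[pair_first[diff]]
    iregions = np.stack([r1[diff], r2[diff]], axis=1)
    return bfaces, bregion, ifaces, iregions


def _face_normals(mesh: TetMesh, faces: np.ndarray) -> np.ndarray:
    tri = mesh.nodes[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    return n / np.where(norm > 0, norm, 1.0)


def extract_named_sets(mesh: TetMesh, distal_layers: int = 2,
                       top_layers: int = 1,
                       normal_tol: float = 0.5) -> TetMesh:
    """Populate the boundary node/facet sets used by the joint models.

    * ``tibia_distal_fixed``: tibia-bone nodes within ``distal_layers`` mesh
      cells of the minimal tibia z extent (the fixed support).
    * ``femur_top_coupled``: femur-bone nodes within ``top_layers`` cells of
      the maximal femur z extent (coupled to the loading reference point).
    * ``femoral_cartilage_surface``: inferior-facing exterior faces of the
      femoral cartilage (contact master).
    * ``tibial_cartilage_surface``: superior-facing exterior faces of the
      tibial cartilage (contact slave), plus ``..._nodes``.
    * ``meniscus_superior`` / ``meniscus_inferior``: superior exterior faces
      of the soft meniscus, and its faces adjacent to the tibial cartilage.
    """
    h = mesh.grid_spacing_mm or float(np.median(
        np.linalg.norm(mesh.nodes[mesh.elements[:, 1]]
                       - mesh.nodes[mesh.elements[:, 0]], axis=1)))
    bfaces, bregion, ifaces, iregions = boundary_and_interfaces(mesh)
    names = mesh.region_names

    def region_nodes(rname):
        return np.unique(mesh.region_elements(rname))

    if "tibia_bone" in names:
        nid = region_nodes("tibia_bone")
        z = mesh.nodes[nid, 2]
        sel = nid[z <= z.min() + distal_layers * h + 1e-9]
        if sel.size == 0:
            raise ValueError("empty tibia_distal_fixed set")
        mesh.node_sets["tibia_distal_fixed"] = sel
    if "femur_bone" in names:
        nid = region_nodes("femur_bone")
        z = mesh.nodes[nid, 2]
        sel = nid[z >= z.max() - top_layers * h - 1e-9]
        if sel.size == 0:
            raise ValueError("empty femur_top_coupled set")
        mesh.node_sets["femur_top_coupled"] = sel

    bn = _face_normals(mesh, bfaces)

    def boundary_of(rname, direction):
        rid = names.index(rname)
        sel = (bregion == rid) & (bn @ np.asarray(direction) > normal_tol)
        return bfaces[sel]

    if "femur_cartilage" in names:
        fs = boundary_of("femur_cartilage", (0, 0, -1))
        if len(fs) == 0:
            raise ValueError("empty femoral_cartilage_surface")
        mesh.facet_sets["femoral_cartilage_surface"] = fs
    if "tibia_cartilage" in names:
        fs = boundary_of("tibia_cartilage", (0, 0, 1))
        if len(fs) == 0:
            raise ValueError("empty tibial_cartilage_surface")
        mesh.facet_sets["tibial_cartilage_surface"] = fs
        mesh.node_sets["tibial_cartilage_surface_nodes"] = np.unique(fs)
    if "soft_meniscus" in names:
        # the meniscus transmits load superiorly; keep only clearly
        # superior-facing faces so near-vertical flanks stay out of contact
        rid = names.index("soft_meniscus")
        sel = (bregion == rid) & (bn[:, 2] > max(normal_tol, 0.3))
        fs = bfaces[sel]
        if len(fs):
            mesh.facet_sets["meniscus_superior"] = fs
            mesh.node_sets["meniscus_superior_nodes"] = np.unique(fs)
        rid_m = names.index("soft_meniscus")
        if "tibia_cartilage" in names:
            rid_tc = names.index("tibia_cartilage")
            sel = ((iregions[:, 0] == rid_m) & (iregions[:, 1] == rid_tc)) | (
                (iregions[:, 1] == rid_m) & (iregions[:, 0] == rid_tc))
            if sel.any():
                mesh.facet_sets["meniscus_inferior"] = ifaces[sel]
                mesh.node_sets["meniscus_inferior_nodes"] = np.unique(ifaces[sel])
    return mesh


def smooth_surface_nodes(mesh: TetMesh, iterations: int = 4,
                         lam: float = 0.5, mu: float = -0.53,
                         pinned: np.ndarray | None = None) -> TetMesh:
    """Taubin smoothing of exterior boundary nodes (in place).

    Voxel meshes have staircased surfaces whose gap fields are discontinuous
    at tread edges; a few smoothing passes over the boundary nodes turn the
    staircase into a continuous piecewise-linear surface, which stabilises
    contact and regularises surface pressures.  Each iteration is a Taubin
    lambda/mu pair (a shrink pass followed by an inflate pass), which smooths
    without the volume loss of plain Laplacian smoothing.  Interior nodes and
    any ``pinned`` nodes (e.g. flat support faces) stay put; node moves that
    would invert an element are scaled back until all volumes are positive.
    """
    bfaces, _, ifaces, _ = boundary_and_interfaces(mesh)
    surf_nodes = np.unique(bfaces)
    movable = np.zeros(mesh.n_nodes, dtype=bool)
    movable[surf_nodes] = True
    # nodes on internal region interfaces keep the staircase (conformity and
    # volume bookkeeping matter more there than surface smoothness)
    if len(ifaces):
        movable[np.unique(ifaces)] = False
    if pinned is not None and len(pinned):
        movable[np.asarray(pinned)] = False
    # boundary-edge adjacency among surface nodes
    e01 = bfaces[:, [0, 1]]
    e12 = bfaces[:, [1, 2]]
    e20 = bfaces[:, [2, 0]]
    edges = np.vstack([e01, e12, e20])
    edges = np.vstack([edges, edges[:, ::-1]])
    order = np.lexsort(edges.T[::-1])
    edges = edges[order]
    keep = np.concatenate([[True], np.any(edges[1:] != edges[:-1], axis=1)])
    edges = edges[keep]
    n = mesh.n_nodes
    adj = sp.coo_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
                        shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    original = mesh.nodes.copy()
    pos = mesh.nodes
    for _ in range(iterations):
        for factor in (lam, mu):
            mean_nb = (adj @ pos) / deg[:, None]
            new = pos.copy()
            new[movable] = pos[movable] + factor * (mean_nb[movable]
                                                    - pos[movable])
            pos = new
    mesh.nodes = pos
    # inversion guard: pull offending moves back toward the original
    for _ in range(20):
        vol = mesh.signed_volumes()
        bad = vol <= 0
        if not bad.any():
            break
        bad_nodes = np.unique(mesh.elements[bad])
        mesh.nodes[bad_nodes] = 0.5 * (mesh.nodes[bad_nodes]
                                       + original[bad_nodes])
    else:
        mesh.nodes = original
        raise ValueError("surface smoothing could not avoid inverted "
                         "elements; reduce lam or iterations")
    return mesh


def mesh_quality(mesh: TetMesh) -> dict:
    """Deterministic quality report: scaled Jacobians, aspect ratios, volumes.

    Scaled Jacobian here is ``6*sqrt(2)*V / l_max^3`` (1 for the regular tet);
    aspect ratio is circumradius / (3 * inradius) (1 for the regular tet).
    """
    x = mesh.nodes[mesh.elements]
    vol = np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    el = np.stack([np.linalg.norm(x[:, a] - x[:, b], axis=1) for a, b in pairs],
                  axis=1)
    lmax = el.max(axis=1)
    sj = 6.0 * np.sqrt(2.0) * vol / lmax**3
    # faces areas for inradius r = 3V / (sum of face areas)
    area = np.zeros(len(vol))
    for f in _TET_FACES:
        tri = x[:, f]
        area += 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    rin = 3.0 * np.abs(vol) / area
    # circumradius via |a||b x c| formula
    a = x[:, 1] - x[:, 0]
    b = x[:, 2] - x[:, 0]
    c = x[:, 3] - x[:, 0]
    num = np.linalg.norm(
        (np.linalg.norm(a, axis=1, keepdims=True)**2 * np.cross(b, c)
         + np.linalg.norm(b, axis=1, keepdims=True)**2 * np.cross(c, a)
         + np.linalg.norm(c, axis=1, keepdims=True)**2 * np.cross(a, b)),
        axis=1)
    rcirc = num / (12.0 * np.abs(vol))
    aspect = rcirc / (3.0 * rin)
    report = {
        "n_elements": mesh.n_elements,
        "n_nodes": mesh.n_nodes,
        "min_scaled_jacobian": float(sj.min()),
        "median_scaled_jacobian": float(np.median(sj)),
        "max_aspect_ratio": float(aspect.max()),
        "median_aspect_ratio": float(np.median(aspect)),
        "n_flagged": int((sj < 0.05).sum()),
        "volume_per_region_mm3": {
            name: float(vol[mesh.element_region == i].sum())
            for i, name in enumerate(mesh.region_names)
        },
    }
    return report


def concatenate(a: TetMesh, b: TetMesh) -> TetMesh:
    """Stack two meshes without merging nodes (bodies stay separate)."""
    off = a.n_nodes
    regions = list(a.region_names)
    remap = []
    for name in b.region_names:
        if name in regions:
            remap.append(regions.index(name))
        else:
            regions.append(name)
            remap.append(len(regions) - 1)
    remap = np.asarray(remap, dtype=np.int16)
    node_sets = dict(a.node_sets)
    for k, v in b.node_sets.items():
        if k in node_sets:
            raise ValueError(f"node set name collision: {k}")
        node_sets[k] = v + off
    facet_sets = dict(a.facet_sets)
    for k, v in b.facet_sets.items():
        if k in facet_sets:
            raise ValueError(f"facet set name collision: {k}")
        facet_sets[k] = v + off
    return TetMesh(
        nodes=np.vstack([a.nodes, b.nodes]),
        elements=np.vstack([a.elements, b.elements + off]),
        element_region=np.concatenate(
            [a.element_region, remap[b.element_region]]),
        region_names=regions, node_sets=node_sets, facet_sets=facet_sets,
        grid_spacing_mm=a.grid_spacing_mm,
    )


# -- text-format I/O ---------------------------------------------------

def write_vtu(mesh: TetMesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Minimal ASCII VTU (unstructured grid, VTK tet type 10) writer."""
    pd = dict(point_data or {})
    cd = {"region": mesh.element_region.astype(float)}
    cd.update(cell_data or {})
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n'
                 '<VTKFile type="UnstructuredGrid" version="0.1" '
                 'byte_order="LittleEndian">\n<UnstructuredGrid>\n')
        fh.write(f'<Piece NumberOfPoints="{mesh.n_nodes}" '
                 f'NumberOfCells="{mesh.n_elements}">\n')
        fh.write('<Points>\n<DataArray type="Float64" '
                 'NumberOfComponents="3" format="ascii">\n')
        np.savetxt(fh, mesh.nodes, fmt="%.10g")
        fh.write('</DataArray>\n</Points>\n<Cells>\n')
        fh.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        np.savetxt(fh, mesh.elements, fmt="%d")
        fh.write('</DataArray>\n'
                 '<DataArray type="Int64" Name="offsets" format="ascii">\n')
        np.savetxt(fh, 4 * np.arange(1, mesh.n_elements + 1)[:, None], fmt="%d")
        fh.write('</DataArray>\n'
                 '<DataArray type="UInt8" Name="types" format="ascii">\n')
        np.savetxt(fh, np.full((mesh.n_elements, 1), 10), fmt="%d")
        fh.write('</DataArray>\n</Cells>\n<PointData>\n')
        for name, arr in pd.items():
            arr = np.asarray(arr, dtype=float)
            nc = 1 if arr.ndim == 1 else arr.shape[1]
            fh.write(f'<DataArray type="Float64" Name="{name}" '
                     f'NumberOfComponents="{nc}" format="ascii">\n')
            np.savetxt(fh, arr.reshape(mesh.n_nodes, nc), fmt="%.10g")
            fh.write('</DataArray>\n')
        fh.write('</PointData>\n<CellData>\n')
        for name, arr in cd.items():
            fh.write(f'<DataArray type="Float64" Name="{name}" '
                     f'NumberOfComponents="1" format="ascii">\n')
            np.savetxt(fh, np.asarray(arr, dtype=float)[:, None], fmt="%.10g")
            fh.write('</DataArray>\n')
        fh.write('</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n')


def read_vtu(path) -> tuple[TetMesh, dict, dict]:
    """Read the ASCII VTU subset produced by :func:`write_vtu`."""
    import xml.etree.ElementTree as ET

    root = ET.parse(str(path)).getroot()
    piece = root.find(".//Piece")

    def parse(da):
        return np.fromstring(da.text.replace("\n", " "), sep=" ")

    arrays = {}
    pts = parse(piece.find("Points/DataArray")).reshape(-1, 3)
    for da in piece.find("Cells"):
        arrays[da.get("Name")] = parse(da)
    conn = arrays["connectivity"].astype(np.int64).reshape(-1, 4)
    point_data, cell_data = {}, {}
    for da in piece.find("PointData") or []:
        nc = int(da.get("NumberOfComponents", "1"))
        arr = parse(da)
        point_data[da.get("Name")] = arr.reshape(-1, nc) if nc > 1 else arr
    for da in piece.find("CellData") or []:
        cell_data[da.get("Name")] = parse(da)
    region = cell_data.pop("region", np.zeros(len(conn))).astype(np.int16)
    nreg = int(region.max()) + 1 if len(region) else 1
    mesh = TetMesh(nodes=pts, elements=conn, element_region=region,
                   region_names=[f"region{i}" for i in range(nreg)])
    return mesh, point_data, cell_data


def write_inp(mesh: TetMesh, path, heading: str = "kneefem export") -> None:
    """Minimal Abaqus INP writer: nodes, C3D4 elements, ELSET/NSET/SURFACE."""
    with open(path, "w") as fh:
        fh.write(f"*HEADING\n{heading}\n*NODE\n")
        for i, p in enumerate(mesh.nodes, start=1):
            fh.write(f"{i}, {p[0]:.9g}, {p[1]:.9g}, {p[2]:.9g}\n")
        for rid, name in enumerate(mesh.region_names):
            els = np.nonzero(mesh.element_region == rid)[0]
            if not len(els):
                continue
            fh.write(f"*ELEMENT, TYPE=C3D4, ELSET={name.upper()}\n")
            for e in els:
                n = mesh.elements[e] + 1
                fh.write(f"{e + 1}, {n[0]}, {n[1]}, {n[2]}, {n[3]}\n")
        for name, nset in mesh.node_sets.items():
            fh.write(f"*NSET, NSET={name.upper()}\n")
            ids = nset + 1
            for i in range(0, len(ids), 8):
                fh.write(", ".join(str(v) for v in ids[i:i + 8]) + "\n")
        for name, faces in mesh.facet_sets.items():
            nodes = np.unique(faces) + 1
            fh.write(f"*NSET, NSET={name.upper()}_N\n")
            for i in range(0, len(nodes), 8):
                fh.write(", ".join(str(v) for v in nodes[i:i + 8]) + "\n")
            fh.write(f"*SURFACE, TYPE=NODE, NAME={name.upper()}\n"
                     f"{name.upper()}_N\n")
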