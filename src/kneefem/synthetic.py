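"""Parametric knee-like phantoms and solver benchmark geometries.

The phantom emulates the two micro-CT acquisitions of the imaging workflow
on a mouse-knee-scale analytic geometry with known ground truth:

* a *rest-position* scan in which bone and the calcified menisci are bright
  and cartilage is invisible, and
* two *stained* scans (femur and tibia separated and rigidly displaced by
  known transforms) in which the cartilage shells appear at intermediate
  intensity,

plus >= 15 paired landmarks per bone related exactly by the stored
transforms.

Geometry (superior = +z, lateral = +x): the femur is two spherical condyles
(truncated superiorly) bridged by a rectangular shaft plate with a flat top;
the tibia is a plateau slab with a shallow spherical pocket under each
condyle.  The ground-truth ("individual") tibial cartilage fills each pocket
up to a spherical surface concentric with its condyle, so the individual
joint surfaces are nearly conforming, while the bone pockets are much
flatter than the condyles — exactly the situation in which homogeneous
offset-shell cartilage reconstructed from bone alone produces localised,
non-conforming contact.  The medial compartment has a larger bone-to-bone
gap than the lateral one (deeper pocket filled by thicker cartilage), so a
single-thickness homogeneous layer leaves the medial condyle out of
contact.  Calcified meniscus arcs sit in the peripheral joint space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import LabelMask, VoxelImage
from .meshing import TetMesh, concatenate
from .registration import LandmarkSet, RigidTransform

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "generate_hertz_benchmark",
    "hertz_pressure",
    "MeshingError",
]


class MeshingError(RuntimeError):
    """Structured meshing failure (inverted cells, bad parameters)."""


@dataclass
class PhantomSpec:
    """Parameters of the knee phantom (lengths mm, spacing um).

    Intensities are arbitrary units with bone > stained cartilage >
    background; ``noise_sd`` is the additive Gaussian noise level.  The
    clearances are the rest-position gaps between the individual cartilage
    surfaces (lateral ~ touching, medial slightly open);
    ``extra_bone_gap_medial_um`` deepens the medial pocket (filled by thicker
    individual cartilage) so that bone-derived homogeneous layers cannot
    restore medial contact.  ``pocket_offset_y_mm`` shifts the bony pocket
    centres off the condylar axes, creating a subchondral prominence where
    the bone-to-bone gap is smaller than the cartilage stack: homogeneous
    offset layers sized by that minimal gap come out thin and touch only at
    the prominence, while the individual cartilage fills the true
    conforming geometry - the subject-specific feature the model variants
    are designed to probe.
    """

    condyle_radius_lateral_mm: float = 0.55
    condyle_radius_medial_mm: float = 0.50
    condyle_separation_mm: float = 1.25
    cartilage_thickness_femur_mm: float = 0.10
    cartilage_thickness_tibia_mm: float = 0.10
    plateau_extent_mm: float = 2.5
    plateau_width_mm: float = 1.2
    plateau_thickness_mm: float = 0.32
    pocket_radius_mm: float = 0.90
    condyle_engagement_mm: float = 0.05
    clearance_lateral_um: float = 18.0
    clearance_medial_um: float = 20.0
    extra_bone_gap_medial_um: float = 60.0
    pocket_offset_y_mm: float = 0.138
    meniscus_arc_deg: float = 200.0
    meniscus_tube_radius_mm: float = 0.04
    meniscus_ring_offset_mm: float = 0.56
    meniscus_ring_height_mm: float = 0.105
    cartilage_cap_half_angle_deg: float = 75.0
    annulus_thickness_mm: float = 0.06
    voxel_spacing_um: float = 17.4
    intensity_bone: float = 180.0
    intensity_cartilage_stained: float = 90.0
    intensity_background: float = 20.0
    noise_sd: float = 5.0
    separation_transform_femur: RigidTransform | None = None
    separation_transform_tibia: RigidTransform | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = [self.condyle_radius_lateral_mm, self.condyle_radius_medial_mm,
                   self.condyle_separation_mm, self.plateau_extent_mm,
                   self.plateau_width_mm, self.plateau_thickness_mm,
                   self.pocket_radius_mm, self.voxel_spacing_um]
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths and the spacing must be positive")
        if self.cartilage_thickness_femur_mm < 0 or \
                self.cartilage_thickness_tibia_mm < 0:
            raise ValueError("cartilage thicknesses must be >= 0")
        if self.cartilage_thickness_femur_mm >= self.condyle_radius_medial_mm:
            raise ValueError("cartilage thickness must be < condyle radius")
        if not (self.intensity_bone > self.intensity_cartilage_stained
                > self.intensity_background):
            raise ValueError(
                "need intensity_bone > intensity_cartilage_stained > background")
        if self.separation_transform_femur is None:
            self.separation_transform_femur = RigidTransform.from_axis_angle(
                (0.3, 1.0, 0.2), np.deg2rad(4.0),
                translation=(0.10, -0.05, 0.12), center=(0.0, 0.0, 0.8))
        if self.separation_transform_tibia is None:
            self.separation_transform_tibia = RigidTransform.from_axis_angle(
                (1.0, -0.4, 0.3), np.deg2rad(-3.0),
                translation=(-0.08, 0.06, -0.08), center=(0.0, 0.0, -0.15))


@dataclass
class PhantomTruth:
    """Ground truth: tissue masks, condyle labels, landmarks, transforms."""

    masks: dict[str, LabelMask]
    condyle_labels: np.ndarray          # 0 none, 1 medial, 2 lateral
    landmarks_rest: dict[str, LandmarkSet]
    landmarks_stained: dict[str, LandmarkSet]
    separation_transforms: dict[str, RigidTransform]


@dataclass
class _Geometry:
    """Derived analytic geometry of the phantom (all mm, rest frame)."""

    o_lat: np.ndarray
    o_med: np.ndarray
    r_lat: float
    r_med: float
    rho_lat: float          # individual cartilage surface radius, lateral
    rho_med: float
    gap_lat: float          # min bone-to-bone gap, lateral
    gap_med: float
    pocket_center_lat: np.ndarray
    pocket_center_med: np.ndarray
    pocket_radius: float
    z_cut: float            # superior truncation of the condyle spheres
    plate_z: tuple[float, float]
    plate_half_x: float
    plate_half_y: float
    slab_z: tuple[float, float]
    slab_half_x: float
    slab_half_y: float
    cap_cos: float
    annulus_r: tuple[float, float]


def _derive_geometry(spec: PhantomSpec) -> _Geometry:
    s2 = spec.condyle_separation_mm / 2.0
    tf = spec.cartilage_thickness_femur_mm
    tt = spec.cartilage_thickness_tibia_mm
    c_lat = spec.clearance_lateral_um * 1e-3
    c_med = spec.clearance_medial_um * 1e-3
    r_lat, r_med = spec.condyle_radius_lateral_mm, spec.condyle_radius_medial_mm
    zc_lat = r_lat + tf - spec.condyle_engagement_mm
    zc_med = r_med + tf - spec.condyle_engagement_mm
    gap_lat = tf + c_lat + tt
    gap_med = tf + c_med + tt + spec.extra_bone_gap_medial_um * 1e-3
    P = spec.pocket_radius_mm
    zp_lat = zc_lat - r_lat - gap_lat + P
    zp_med = zc_med - r_med - gap_med + P
    z_cut = max(zc_lat, zc_med) + 0.15
    tube = spec.meniscus_tube_radius_mm
    ann_in = spec.meniscus_ring_offset_mm - tube - 0.045
    ann_out = spec.meniscus_ring_offset_mm + tube + 0.045
    return _Geometry(
        o_lat=np.array([s2, 0.0, zc_lat]),
        o_med=np.array([-s2, 0.0, zc_med]),
        r_lat=r_lat, r_med=r_med,
        rho_lat=r_lat + tf + c_lat, rho_med=r_med + tf + c_med,
        gap_lat=gap_lat, gap_med=gap_med,
        pocket_center_lat=np.array([s2, spec.pocket_offset_y_mm, zp_lat]),
        pocket_center_med=np.array([-s2, spec.pocket_offset_y_mm, zp_med]),
        pocket_radius=P,
        z_cut=z_cut,
        # the plate starts exactly at the sphere truncation plane: the union
        # volume is then a closed-form sum (caps + box), and voxel layers on
        # either side of z_cut stay face-adjacent, hence connected
        plate_z=(z_cut, z_cut + 0.15),
        plate_half_x=s2 + 0.35,
        plate_half_y=0.45,
        slab_z=(-spec.plateau_thickness_mm, 0.0),
        slab_half_x=spec.plateau_extent_mm / 2.0,
        slab_half_y=spec.plateau_width_mm / 2.0,
        cap_cos=np.cos(np.deg2rad(spec.cartilage_cap_half_angle_deg)),
        annulus_r=(ann_in, ann_out),
    )


def _grid(spec: PhantomSpec, geo: _Geometry):
    sp = spec.voxel_spacing_um * 1e-3
    margin = 0.12
    lo = np.array([-(geo.slab_half_x + margin + 0.15),
                   -(geo.slab_half_y + margin + 0.25),
                   geo.slab_z[0] - margin])
    hi = np.array([geo.slab_half_x + margin + 0.15,
                   geo.slab_half_y + margin + 0.25,
                   geo.plate_z[1] + margin + 0.18])
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / sp)) + 1 for i in range(3))
    return lo, sp, shape


class _Solids:
    """Vectorised analytic membership tests in the rest frame."""

    def __init__(self, spec: PhantomSpec, geo: _Geometry):
        self.spec = spec
        self.geo = geo

    # helpers -----------------------------------------------------------
    def _d(self, x, y, z, center):
        return np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2
                       + (z - center[2]) ** 2)

    def _r_axis(self, x, y, center):
        return np.sqrt((x - center[0]) ** 2 + y**2)

    def femur_bone(self, x, y, z):
        g = self.geo
        sph = ((self._d(x, y, z, g.o_lat) <= g.r_lat)
               | (self._d(x, y, z, g.o_med) <= g.r_med)) & (z <= g.z_cut)
        plate = ((np.abs(x) <= g.plate_half_x) & (np.abs(y) <= g.plate_half_y)
                 & (z >= g.plate_z[0]) & (z <= g.plate_z[1]))
        return sph | plate

    def femur_cartilage(self, x, y, z):
        g, tf = self.geo, self.spec.cartilage_thickness_femur_mm
        if tf <= 0:
            return np.zeros(np.broadcast(x, y, z).shape, dtype=bool)
        out = np.zeros(np.broadcast(x, y, z).shape, dtype=bool)
        for o, r in ((g.o_lat, g.r_lat), (g.o_med, g.r_med)):
            d = self._d(x, y, z, o)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = (o[2] - z) / np.where(d > 0, d, 1.0)
            out |= (d > r) & (d < r + tf) & (cosang >= g.cap_cos)
        return out & ~self.femur_bone(x, y, z)

    def tibia_bone(self, x, y, z):
        g = self.geo
        slab = ((np.abs(x) <= g.slab_half_x) & (np.abs(y) <= g.slab_half_y)
                & (z >= g.slab_z[0]) & (z <= g.slab_z[1]))
        pockets = ((self._d(x, y, z, g.pocket_center_lat) < g.pocket_radius)
                   | (self._d(x, y, z, g.pocket_center_med) < g.pocket_radius))
        return slab & ~pockets

    def tibia_cartilage(self, x, y, z):
        g, tt = self.geo, self.spec.cartilage_thickness_tibia_mm
        if tt <= 0:
            return np.zeros(np.broadcast(x, y, z).shape, dtype=bool)
        foot = (np.abs(x) <= g.slab_half_x) & (np.abs(y) <= g.slab_half_y)
        out = np.zeros(np.broadcast(x, y, z).shape, dtype=bool)
        for o, rho, pc in ((g.o_lat, g.rho_lat, g.pocket_center_lat),
                           (g.o_med, g.rho_med, g.pocket_center_med)):
            pocket_fill = ((z <= g.slab_z[1])
                           & (self._d(x, y, z, pc) < g.pocket_radius)
                           & (self._d(x, y, z, o) > rho))
            r_ax = self._r_axis(x, y, o)
            annulus = ((z > g.slab_z[1])
                       & (z <= g.slab_z[1] + self.spec.annulus_thickness_mm)
                       & (r_ax >= g.annulus_r[0]) & (r_ax <= g.annulus_r[1]))
            out |= (pocket_fill | annulus)
        return out & foot & ~self.femur_cartilage(x, y, z)

    def calcified_meniscus(self, x, y, z):
        g, sp = self.geo, self.spec
        tube, zr = sp.meniscus_tube_radius_mm, sp.meniscus_ring_height_mm
        half_arc = np.cos(np.deg2rad(sp.meniscus_arc_deg / 2.0))
        out = np.zeros(np.broadcast(x, y, z).shape, dtype=bool)
        for o, outward in ((g.o_lat, 1.0), (g.o_med, -1.0)):
            r_ax = self._r_axis(x, y, o)
            ring = np.sqrt((r_ax - sp.meniscus_ring_offset_mm) ** 2
                           + (z - zr) ** 2) <= tube
            with np.errstate(invalid="ignore", divide="ignore"):
                cosphi = outward * (x - o[0]) / np.where(r_ax > 0, r_ax, 1.0)
            out |= ring & (cosphi >= half_arc)
        return out


def _femur_landmarks(geo: _Geometry) -> np.ndarray:
    pts = []
    for o, r in ((geo.o_lat, geo.r_lat), (geo.o_med, geo.r_med)):
        for theta, phi in [(170, 0), (140, 40), (140, 160), (120, 260),
                           (100, 90), (100, 310)]:
            th, ph = np.deg2rad(theta), np.deg2rad(phi)
            d = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                          np.cos(th)])
            pts.append(o + r * d)
    z0, z1 = geo.plate_z
    pts.append([geo.plate_half_x, geo.plate_half_y, z1])
    pts.append([-geo.plate_half_x, -geo.plate_half_y, z1])
    pts.append([geo.plate_half_x, -geo.plate_half_y, z0])
    return np.asarray(pts)  # 15 points


def _tibia_landmarks(geo: _Geometry) -> np.ndarray:
    hx, hy = geo.slab_half_x, geo.slab_half_y
    z0, z1 = geo.slab_z
    pts = [[hx, hy, z1], [hx, -hy, z1], [-hx, hy, z1], [-hx, -hy, z1],
           [hx, hy, z0], [-hx, -hy, z0], [hx, 0.0, z1], [-hx, 0.0, z1],
           [0.0, hy, z1], [0.0, -hy, z1], [hx, hy, 0.5 * (z0 + z1)],
           [-hx, hy, 0.5 * (z0 + z1)]]
    # pocket rim points (on the pocket sphere at plateau level)
    for pc in (geo.pocket_center_lat, geo.pocket_center_med):
        rf = np.sqrt(max(geo.pocket_radius**2 - pc[2] ** 2, 1e-6))
        pts.append([pc[0] + rf, 0.0, z1])
        pts.append([pc[0], min(rf, hy * 0.95), z1])
    return np.asarray(pts)  # 16 points


def generate_phantom(spec: PhantomSpec):
    """Build the phantom scans and ground truth.

    Returns ``(rest_scan, stained_femur_scan, stained_tibia_scan, truth)``.
    Deterministic under a fixed ``spec.seed``.
    """
    geo = _derive_geometry(spec)
    lo, sp, shape = _grid(spec, geo)
    solids = _Solids(spec, geo)
    rng = np.random.default_rng(spec.seed)

    cx = (lo[0] + sp * np.arange(shape[0]))[:, None, None]
    cy = (lo[1] + sp * np.arange(shape[1]))[None, :, None]
    cz = (lo[2] + sp * np.arange(shape[2]))[None, None, :]

    order = ["femur_bone", "tibia_bone", "calcified_meniscus",
             "femur_cartilage", "tibia_cartilage"]
    raw = {name: getattr(solids, name)(cx, cy, cz) for name in order}
    # analytic solids must be disjoint at the requested resolution
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            n_overlap = int((raw[a] & raw[b]).sum())
            if n_overlap:
                raise ValueError(
                    f"tissue solids {a!r} and {b!r} overlap in "
                    f"{n_overlap} voxels at {spec.voxel_spacing_um} um; "
                    "adjust the phantom parameters")
    masks = {name: LabelMask(raw[name], spec.voxel_spacing_um, lo, name)
             for name in order}

    condyle = np.zeros(shape, dtype=np.int8)
    cart = raw["femur_cartilage"] | raw["tibia_cartilage"]
    lateral = np.broadcast_to(cx > 0, shape)
    condyle[cart & lateral] = 2
    condyle[cart & ~lateral] = 1

    ib, ic, ibg = (spec.intensity_bone, spec.intensity_cartilage_stained,
                   spec.intensity_background)
    rest = np.full(shape, ibg)
    rest[raw["femur_bone"] | raw["tibia_bone"]
         | raw["calcified_meniscus"]] = ib
    if spec.noise_sd > 0:
        rest = rest + rng.normal(0.0, spec.noise_sd, shape)
    rest_scan = VoxelImage(rest, spec.voxel_spacing_um, lo)

    transforms = {"femur": spec.separation_transform_femur,
                  "tibia": spec.separation_transform_tibia}
    stained = {}
    for bone in ("femur", "tibia"):
        Tinv = transforms[bone].inverse()
        # membership of stained voxel x <=> rest-frame point T^-1(x) in solid
        R, t = Tinv.rotation, Tinv.translation
        xb = R[0, 0] * cx + R[0, 1] * cy + R[0, 2] * cz + t[0]
        yb = R[1, 0] * cx + R[1, 1] * cy + R[1, 2] * cz + t[1]
        zb = R[2, 0] * cx + R[2, 1] * cy + R[2, 2] * cz + t[2]
        img = np.full(shape, ibg)
        img[getattr(solids, f"{bone}_cartilage")(xb, yb, zb)] = ic
        img[getattr(solids, f"{bone}_bone")(xb, yb, zb)] = ib
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, shape)
        stained[bone] = VoxelImage(img, spec.voxel_spacing_um, lo)

    lm_rest = {"femur": LandmarkSet(_femur_landmarks(geo), frame="rest"),
               "tibia": LandmarkSet(_tibia_landmarks(geo), frame="rest")}
    lm_stained = {
        bone: LandmarkSet(transforms[bone].apply(lm_rest[bone].points),
                          list(lm_rest[bone].ids), f"stained_{bone}")
        for bone in ("femur", "tibia")}

    truth = PhantomTruth(masks=masks, condyle_labels=condyle,
                         landmarks_rest=lm_rest, landmarks_stained=lm_stained,
                         separation_transforms=transforms)
    return rest_scan, stained["femur"], stained["tibia"], truth


# -- Hertz benchmark geometry ------------------------------------------

def _graded(u: np.ndarray, a: float) -> np.ndarray:
    """Odd grading of [-1,1]: spacing ratio edge/centre = (3-2a)/a."""
    return a * u + (1.0 - a) * u**3


def _square_to_disk(a: np.ndarray, b: np.ndarray):
    """Elliptical square-to-disk map (smooth, orientation preserving)."""
    return (a * np.sqrt(1.0 - 0.5 * b**2), b * np.sqrt(1.0 - 0.5 * a**2))


def structured_hex_to_tets(grid: np.ndarray, region: str,
                           grid_spacing_mm: float | None = None) -> TetMesh:
    """Split a structured hex grid of nodes (ni,nj,nk,3) into Kuhn tets."""
    from .meshing import _KUHN  # same subdivision as the voxel mesher

    ni, nj, nk = grid.shape[:3]
    nodes = grid.reshape(-1, 3)

    def nid(i, j, k):
        return (i * nj + j) * nk + k

    cells = np.array([[i, j, k] for i in range(ni - 1)
                      for j in range(nj - 1) for k in range(nk - 1)])
    offs = np.array([[d >> 2 & 1, d >> 1 & 1, d & 1] for d in range(8)])
    corners = cells[:, None, :] + offs[None, :, :]
    cid = (corners[..., 0] * nj + corners[..., 1]) * nk + corners[..., 2]
    elements = cid[:, _KUHN].reshape(-1, 4)
    mesh = TetMesh(nodes=nodes, elements=elements,
                   element_region=np.zeros(len(elements), dtype=np.int16),
                   region_names=[region], grid_spacing_mm=grid_spacing_mm)
    vol = mesh.signed_volumes()
    if not np.all(vol > 0):
        raise MeshingError(
            f"hex-to-tet subdivision produced {int((vol <= 0).sum())} "
            "non-positive tets; the mapped grid is too distorted")
    return mesh


def generate_hertz_benchmark(radius_mm: float = 1.0,
                             layer: float | None = None,
                             edge_length_mm: float = 0.025,
                             cyl_radius_frac: float = 0.6,
                             height_frac: float = 0.8,
                             block_thickness_mm: float = 0.3,
                             grading: float = 0.35) -> TetMesh:
    """Sphere-capped cylinder above a flat block, graded toward contact.

    The deformable upper body is a cylinder of radius
    ``cyl_radius_frac * radius`` whose lower surface is the spherical cap of
    the given radius (apex touching z = 0); in-plane and vertical node
    spacings are graded so the elements nearest the contact apex are about
    ``edge_length_mm``.  The lower body is a coarse flat block whose top
    plane (exactly flat, hence geometrically exact master facets) is at
    z = 0.  Facet sets ``sphere_surface`` (slave) and ``block_top`` (master)
    and node sets ``sphere_top`` / ``block_bottom`` are provided.

    If ``layer`` is a thickness (mm), elements of the upper body within that
    distance of the spherical surface are labelled ``layer`` (e.g. a
    cartilage shell), the rest ``core``.
    """
    R = radius_mm
    Rc = cyl_radius_frac * R
    H = height_frac * R
    if not edge_length_mm < R / 4:
        raise MeshingError("edge_length must be < radius/4")
    m = max(4, int(np.ceil(grading * Rc / edge_length_mm)))
    u = np.linspace(-1.0, 1.0, 2 * m + 1)
    gu = _graded(u, grading)
    A, B = np.meshgrid(gu, gu, indexing="ij")
    X, Y = _square_to_disk(A, B)
    X, Y = Rc * X, Rc * Y
    rr = np.sqrt(X**2 + Y**2)
    zb = R - np.sqrt(np.maximum(R**2 - rr**2, 0.0))  # cap surface
    az = 0.4
    nz = max(4, int(np.ceil(az * H / (2.5 * edge_length_mm))))
    v = np.linspace(0.0, 1.0, nz + 1)
    gv = az * v + (1.0 - az) * v**2
    grid = np.empty((2 * m + 1, 2 * m + 1, nz + 1, 3))
    grid[..., 0] = X[:, :, None]
    grid[..., 1] = Y[:, :, None]
    grid[..., 2] = zb[:, :, None] + (H - zb[:, :, None]) * gv[None, None, :]
    sphere = structured_hex_to_tets(grid, "core",
                                    grid_spacing_mm=edge_length_mm)
    if layer is not None:
        center = np.array([0.0, 0.0, R])
        cent = sphere.nodes[sphere.elements].mean(axis=1)
        dsurf = R - np.linalg.norm(cent - center, axis=1)
        sphere.region_names = ["core", "layer"]
        sphere.element_region = np.where(dsurf <= layer, 1, 0).astype(np.int16)

    nb = 7
    bx = np.linspace(-Rc, Rc, nb)
    bz = np.linspace(-block_thickness_mm, 0.0, 4)
    bgrid = np.empty((nb, nb, 4, 3))
    bgrid[..., 0] = bx[:, None, None]
    bgrid[..., 1] = bx[None, :, None]
    bgrid[..., 2] = bz[None, None, :]
    block = structured_hex_to_tets(bgrid, "block",
                                   grid_spacing_mm=edge_length_mm)

    mesh = concatenate(sphere, block)
    from .meshing import boundary_and_interfaces, _face_normals

    bfaces, bregion, _, _ = boundary_and_interfaces(mesh)
    nrm = _face_normals(mesh, bfaces)
    rid_block = mesh.region_names.index("block")
    is_block = bregion == rid_block
    # curved lower surface of the upper body (slave side)
    sel = (~is_block) & (nrm[:, 2] < -0.3)
    mesh.facet_sets["sphere_surface"] = bfaces[sel]
    mesh.node_sets["sphere_surface_nodes"] = np.unique(bfaces[sel])
    topz = mesh.nodes[:, 2].max()
    sphere_nodes = np.unique(mesh.elements[mesh.element_region != rid_block])
    mesh.node_sets["sphere_top"] = sphere_nodes[
        mesh.nodes[sphere_nodes, 2] >= topz - 1e-9]
    sel = is_block & (nrm[:, 2] > 0.9)
    mesh.facet_sets["block_top"] = bfaces[sel]
    block_nodes = np.unique(mesh.elements[mesh.element_region == rid_block])
    botz = mesh.nodes[block_nodes, 2].min()
    mesh.node_sets["block_bottom"] = block_nodes[
        mesh.nodes[block_nodes, 2] <= botz + 1e-9]
    mesh.validate()
    return mesh


def hertz_pressure(force_n: float, radius_mm: float, e_star_mpa: float):
    """Closed-form Hertz sphere-on-rigid-plane peak pressure and radius.

    ``p0 = (6 F E*^2 / (pi^3 R^2))^(1/3)``, ``a = (3 F R / (4 E*))^(1/3)``,
    with ``E* = E / (1 - nu^2)`` of the deformable body.
    """
    p0 = (6.0 * force_n * e_star_mpa**2 / (np.pi**3 * radius_mm**2)) ** (1.0 / 3.0)
    a = (3.0 * force_n * radius_mm / (4.0 * e_star_mpa)) ** (1.0 / 3.0)
    return p0, a
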