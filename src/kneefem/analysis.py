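"""Joint-level post-processing and the four-variant comparison pipeline.

The four model variants mirror decreasing geometric fidelity:

1. ``individual_meniscus`` — subject-specific cartilage layers plus the soft
   meniscus wrapped around the calcified menisci,
2. ``individual`` — subject-specific cartilage layers only,
3. ``generic_two_thickness`` — homogeneous offset-shell cartilage with a
   different thickness per condyle (both condyles' layers just touch),
4. ``generic_one_thickness`` — one homogeneous thickness chosen so only the
   lateral condyle's layers touch.

All variants are solved with the same displacement protocol and compared at
the loading step whose reference-point reaction is closest to the target
force (0.3 N by default); contact-pressure statistics (mean, peak excluding
isolated points, frequency histogram, contact area) are reported per
condyle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import imageproc as ip
from .config import RunConfig, VARIANTS
from .fem import (ContactPair, FESolution, LoadProtocol, default_materials,
                  reaction_history, solve_contact_steps)
from .image import LabelMask, VoxelImage
from .meshing import MeshParams, TetMesh, extract_named_sets, voxels_to_tets
from .registration import two_step_register, resample
from .synthetic import PhantomSpec, generate_phantom

__all__ = [
    "select_step",
    "CondylePartition",
    "partition_condyles",
    "PressureSummary",
    "pressure_summary",
    "summaries_frame",
    "compare_models",
    "run_variant",
    "run_all_variants",
    "VariantResult",
]


def select_step(history: list[tuple[int, float]], target_n: float) -> int:
    """Index of the loading step with reaction closest to the target.

    Ties go to the earlier step.
    """
    if not history:
        raise ValueError("empty reaction history")
    forces = np.asarray([f for _, f in history])
    return int(np.argmin(np.abs(forces - target_n)))


@dataclass
class CondylePartition:
    """Medial/lateral split by a sagittal plane (normal = medio-lateral)."""

    plane_point: np.ndarray
    normal: np.ndarray          # points toward the lateral side

    def label_points(self, pts: np.ndarray) -> np.ndarray:
        """1 = medial, 2 = lateral for each point."""
        side = (np.asarray(pts) - self.plane_point) @ self.normal
        return np.where(side >= 0, 2, 1).astype(np.int8)


def partition_condyles(mesh: TetMesh, axis=(1.0, 0.0, 0.0),
                       plane_point=None) -> CondylePartition:
    """Split the articular surface at the sagittal plane through its centroid.

    The plane normal is the medio-lateral axis (+x lateral by the package
    convention); the plane passes through the centroid of the femoral
    articular surface unless ``plane_point`` overrides it.
    """
    if "femoral_cartilage_surface" not in mesh.facet_sets or \
            len(mesh.facet_sets["femoral_cartilage_surface"]) == 0:
        raise ValueError("femoral cartilage surface is empty")
    nodes = np.unique(mesh.facet_sets["femoral_cartilage_surface"])
    pts = mesh.nodes[nodes]
    n = np.asarray(axis, dtype=float)
    n = n / np.linalg.norm(n)
    p0 = (pts.mean(axis=0) if plane_point is None
          else np.asarray(plane_point, dtype=float))
    part = CondylePartition(plane_point=p0, normal=n)
    labels = part.label_points(pts)
    if (labels == 1).sum() == 0 or (labels == 2).sum() == 0:
        raise ValueError("condyle partition produced an empty side")
    return part


@dataclass
class PressureSummary:
    """Per-condyle contact pressure statistics at one loading step."""

    variant: str
    condyle: str                      # "medial" | "lateral"
    step_index: int
    reaction_n: float
    mean_pressure_mpa: float
    peak_pressure_mpa: float          # excluding isolated points
    raw_peak_mpa: float
    contact_area_mm2: float
    n_contacting: int
    histogram_edges: np.ndarray = field(default_factory=lambda: np.zeros(0))
    histogram_counts: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    no_contact: bool = False


def _gather_surface_state(sol: FESolution, step, surface: str = "cartilage"):
    """Stack nodes, pressures and areas of the reporting surface.

    ``surface="cartilage"`` (default) gathers every contact interface but
    flags the cartilage-on-cartilage pair: mean and peak pressure are the
    pressure *between the femoral and tibial cartilage layers*, while
    contact area and the frequency histogram cover the whole loaded surface
    (including the meniscus interface).  ``surface="slave"`` treats all
    pairs alike; ``surface="master"`` uses the master-side aggregate when
    present.  Returns ``(nodes, pressures, areas, stat_mask)`` where
    ``stat_mask`` marks the nodes entering mean/peak.
    """
    masters = {k: v for k, v in step.contact.items()
               if v.get("is_master_surface")}
    if surface == "master" and masters:
        entries = [(v, True) for v in masters.values()]
    else:
        entries = []
        for k, v in step.contact.items():
            if v.get("is_master_surface"):
                continue
            in_stats = (surface != "cartilage"
                        or "tibial_cartilage_surface" in k)
            entries.append((v, in_stats))
    nodes, press, areas, flags = [], [], [], []
    for state, in_stats in entries:
        nodes.append(state["slave_nodes"])
        press.append(state["pressure"])
        areas.append(state["tributary_area"])
        flags.append(np.full(len(state["slave_nodes"]), in_stats))
    if not nodes:
        return (np.zeros(0, int), np.zeros(0), np.zeros(0),
                np.zeros(0, bool))
    return (np.concatenate(nodes), np.concatenate(press),
            np.concatenate(areas), np.concatenate(flags))


def pressure_summary(sol: FESolution, step_index: int,
                     partition: CondylePartition, variant: str = "",
                     isolation_neighbors: int = 3,
                     isolation_radius_factor: float = 3.0,
                     histogram_bin_mpa: float = 0.2,
                     histogram_start_mpa: float = 0.2,
                     surface: str = "cartilage") -> list[PressureSummary]:
    """Per-condyle mean/peak/histogram of slave-node contact pressure.

    A node is contacting when its pressure is positive.  The peak excludes
    isolated points: a contacting node only qualifies when at least
    ``isolation_neighbors`` other contacting nodes lie within
    ``isolation_radius_factor`` times the median inter-node spacing of the
    slave surface.  The contact area is the summed tributary area of the
    contacting nodes.
    """
    step = sol.loading_steps()[step_index]
    nodes, press, areas, stat_mask = _gather_surface_state(sol, step, surface)
    pts = sol.mesh.nodes[nodes] if len(nodes) else np.zeros((0, 3))
    if len(nodes) > 1:
        tree = cKDTree(pts)
        dnn, _ = tree.query(pts, k=2)
        spacing = float(np.median(dnn[:, 1]))
    else:
        spacing = 0.0
    labels = partition.label_points(pts) if len(nodes) else np.zeros(0, np.int8)
    out = []
    for lab, name in ((1, "medial"), (2, "lateral")):
        sel = labels == lab
        p = press[sel]
        a = areas[sel]
        m_stat = stat_mask[sel]
        contacting = p > 0                 # any interface
        contacting_stat = contacting & m_stat  # cartilage-on-cartilage
        n_c = int(contacting.sum())
        if int(contacting_stat.sum()) == 0:
            out.append(PressureSummary(
                variant=variant, condyle=name, step_index=step_index,
                reaction_n=step.axial_reaction_n, mean_pressure_mpa=0.0,
                peak_pressure_mpa=0.0, raw_peak_mpa=0.0,
                contact_area_mm2=float(a[contacting].sum()),
                n_contacting=n_c, no_contact=True))
            continue
        cpts = pts[sel][contacting]
        cp = p[contacting]
        cp_stat = p[contacting_stat]
        # isolated-point exclusion: neighbours counted among all contacting
        # nodes, the peak taken over the cartilage-pair subset
        if n_c > 1 and spacing > 0:
            ctree = cKDTree(cpts)
            counts = np.asarray([
                len(ctree.query_ball_point(q, isolation_radius_factor * spacing)) - 1
                for q in pts[sel][contacting_stat]])
        else:
            counts = np.zeros(len(cp_stat), int)
        qualified = counts >= isolation_neighbors
        pmax = float(cp_stat.max())
        # if every contacting node is isolated there is nothing left to
        # exclude against; fall back to the raw maximum (the exclusion may
        # lower the peak, never invert mean <= peak)
        peak = float(cp_stat[qualified].max()) if qualified.any() else pmax
        hmax = float(cp.max())
        nbins = max(1, int(np.ceil(hmax / histogram_bin_mpa)))
        edges = np.concatenate([
            [0.0], histogram_start_mpa + histogram_bin_mpa * np.arange(nbins + 1)])
        edges = edges[edges <= hmax + histogram_bin_mpa]
        if edges[-1] <= hmax:
            edges = np.append(edges, hmax + 1e-12)
        counts_h, _ = np.histogram(cp, bins=edges)
        out.append(PressureSummary(
            variant=variant, condyle=name, step_index=step_index,
            reaction_n=step.axial_reaction_n,
            mean_pressure_mpa=float(cp_stat.mean()),
            peak_pressure_mpa=peak, raw_peak_mpa=pmax,
            contact_area_mm2=float(a[contacting].sum()),
            n_contacting=n_c,
            histogram_edges=edges, histogram_counts=counts_h))
    return out


def summaries_frame(summaries: list[PressureSummary]) -> pd.DataFrame:
    rows = [{
        "variant": s.variant, "condyle": s.condyle, "step": s.step_index,
        "reaction_n": s.reaction_n, "mean_mpa": s.mean_pressure_mpa,
        "peak_mpa": s.peak_pressure_mpa, "raw_peak_mpa": s.raw_peak_mpa,
        "area_mm2": s.contact_area_mm2, "n_contacting": s.n_contacting,
        "no_contact": s.no_contact,
    } for s in summaries]
    return pd.DataFrame(rows)


def compare_models(summaries: dict[str, list[PressureSummary]],
                   baseline_lateral: str = "generic_one_thickness",
                   baseline_medial: str = "generic_two_thickness") -> pd.DataFrame:
    """Cross-variant table with percent differences to the baseline model.

    Percent difference is ``100 * (x - x_base) / x_base``.  The lateral
    condyle is referenced to the simplest model; the medial condyle to the
    two-thickness model (the simplest has no medial contact).
    """
    frames = []
    for variant in VARIANTS:
        if variant not in summaries:
            frames.append(pd.DataFrame([{
                "variant": variant, "condyle": c, "missing": True}
                for c in ("medial", "lateral")]))
            continue
        df = summaries_frame(summaries[variant])
        df["missing"] = False
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)

    def base_value(condyle, col):
        bname = baseline_lateral if condyle == "lateral" else baseline_medial
        sel = (table["variant"] == bname) & (table["condyle"] == condyle) \
            & (~table["missing"])
        return float(table.loc[sel, col].iloc[0]) if sel.any() else np.nan

    for col in ("mean_mpa", "peak_mpa", "area_mm2"):
        pct = []
        for _, row in table.iterrows():
            if row.get("missing", False):
                pct.append(np.nan)
                continue
            b = base_value(row["condyle"], col)
            pct.append(100.0 * (row[col] - b) / b if b and np.isfinite(b)
                       else np.nan)
        table[f"pct_{col}"] = pct
    return table


# -- the full per-variant chain ----------------------------------------

@dataclass
class VariantResult:
    variant: str
    mesh: TetMesh
    solution: FESolution
    summaries: list[PressureSummary]
    matched_step: int
    history: list[tuple[int, float]]
    masks: dict[str, LabelMask]


def _phantom_spec(config: RunConfig) -> PhantomSpec:
    p = config.phantom
    return PhantomSpec(
        voxel_spacing_um=p.voxel_spacing_um, noise_sd=p.noise_sd,
        condyle_radius_lateral_mm=p.condyle_radius_lateral_mm,
        condyle_radius_medial_mm=p.condyle_radius_medial_mm,
        cartilage_thickness_femur_mm=p.cartilage_thickness_femur_mm,
        cartilage_thickness_tibia_mm=p.cartilage_thickness_tibia_mm,
        clearance_lateral_um=p.clearance_lateral_um,
        clearance_medial_um=p.clearance_medial_um,
        extra_bone_gap_medial_um=p.extra_bone_gap_medial_um,
        seed=config.seed)


def _clean_mask(mask: LabelMask, anchor: LabelMask, min_voxels: int) -> LabelMask:
    """Drop small/floating components not adjacent to the anchor tissue."""
    from scipy import ndimage

    lab, n = ndimage.label(mask.values)
    if n <= 1:
        return mask
    near = ndimage.binary_dilation(anchor.values,
                                   structure=np.ones((3, 3, 3), bool))
    keep = np.zeros(n + 1, bool)
    for c in range(1, n + 1):
        comp = lab == c
        if comp.sum() >= min_voxels and (comp & near).any():
            keep[c] = True
    return mask.with_values(keep[lab])


def segment_phantom(rest_scan: VoxelImage, config: RunConfig):
    """Bone segmentation of the rest scan: smooth, threshold, split parts."""
    seg = config.segmentation
    smooth = ip.gaussian_smooth(rest_scan, seg.smoothing_sigma_voxels)
    level = (seg.bone_threshold if seg.bone_threshold is not None
             else ip.suggest_threshold(smooth))
    bone_all = ip.threshold_segment(smooth, level)
    return ip.separate_bone_components(bone_all), level


def recover_cartilage(stained: VoxelImage, bone_part: LabelMask,
                      all_bone_masks: list[LabelMask],
                      landmarks_stained, landmarks_rest,
                      rest_scan: VoxelImage, config: RunConfig,
                      tissue: str) -> LabelMask:
    """Register a stained scan onto the rest grid and extract its cartilage.

    Two-step landmark registration (3 markers, then all landmarks), trilinear
    resampling, threshold at the stained-cartilage level, mask smoothing and
    Boolean subtraction of the (slightly dilated) bone masks.
    """
    from scipy import ndimage

    seg = config.segmentation
    coarse_ids = landmarks_stained.ids[:3]
    sub = [landmarks_stained.ids.index(i) for i in coarse_ids]
    from .registration import LandmarkSet
    coarse_src = LandmarkSet(landmarks_stained.points[sub], list(coarse_ids),
                             landmarks_stained.frame)
    coarse_dst = LandmarkSet(landmarks_rest.points[sub], list(coarse_ids),
                             landmarks_rest.frame)
    T = two_step_register(coarse_src, coarse_dst,
                          landmarks_stained, landmarks_rest)
    moved = resample(stained, T, rest_scan)
    smooth = ip.gaussian_smooth(moved, seg.smoothing_sigma_voxels)
    soft = ip.threshold_segment(smooth, seg.cartilage_threshold, tissue)
    soft = ip.mask_smooth(soft, seg.mask_smooth_radius_voxels)
    for bm in all_bone_masks:
        grown = bm.with_values(ndimage.binary_dilation(bm.values))
        soft = ip.mask_boolean(soft, grown, "subtract", tissue)
    return _clean_mask(soft, bone_part, seg.min_component_voxels)


def build_variant_masks(variant: str, parts: dict[str, LabelMask],
                        fem_cart: LabelMask | None,
                        tib_cart: LabelMask | None,
                        config: RunConfig) -> dict[str, LabelMask]:
    """Assemble the tissue masks of one variant and lift the femur.

    The femur (bone + cartilage) is translated superiorly by the protocol
    gap (rounded to whole voxels) before meshing, which separates the
    touching layers and initialises the contact search.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    fb, tb = parts["femur_bone"], parts["tibia_bone"]
    masks: dict[str, LabelMask] = {}
    if variant in ("individual_meniscus", "individual"):
        if fem_cart is None or tib_cart is None:
            raise ValueError("individual variants need recovered cartilage")
        fc, tc = fem_cart, tib_cart
    else:
        mode = ("one_thickness" if variant == "generic_one_thickness"
                else "two_thickness")
        gen = ip.build_generic_cartilage(fb, tb, mode)
        fc, tc = gen.femur_cartilage, gen.tibia_cartilage
    if variant == "individual_meniscus":
        from scipy import ndimage

        calc = parts["calcified_meniscus"]
        soft = ip.wrap_meniscus(
            calc, fc, tc, config.meniscus.max_gap_um,
            superior_clearance_voxels=config.meniscus.superior_clearance_voxels)
        # regularise the blocky wrap (its raw surface is rough at the voxel
        # scale, which shows up as spurious contact-pressure spikes), then
        # restore disjointness and the superior clearance; the volume-change
        # warning is expected here - thinning the ragged fill is the point
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            soft = ip.mask_smooth(
                soft, config.segmentation.mask_smooth_radius_voxels)
        cl = config.meniscus.superior_clearance_voxels
        keep_out = ndimage.binary_dilation(fc.values, ip._ball(cl)) if cl             else fc.values
        soft = soft.with_values(
            soft.values & ~keep_out & ~tc.values & ~calc.values
            & ~fb.values & ~tb.values)
        masks["calcified_meniscus"] = calc
        masks["soft_meniscus"] = soft
    lift = int(round(config.solver.gap_translation_um
                     / fb.spacing_um))
    masks_out = {
        "femur_bone": ip.translate_mask(fb, (0, 0, lift)),
        "femur_cartilage": ip.translate_mask(fc, (0, 0, lift)),
        "tibia_bone": tb,
        "tibia_cartilage": tc,
    }
    masks_out.update(masks)
    return masks_out


def mesh_variant(masks: dict[str, LabelMask], config: RunConfig) -> TetMesh:
    """Mesh the variant masks, smooth the staircased surfaces, name the sets.

    The flat support bands (distal tibia, femur top plate) are pinned during
    surface smoothing so the boundary conditions keep their geometry.
    """
    from .meshing import smooth_surface_nodes

    order = ["femur_bone", "tibia_bone", "femur_cartilage", "tibia_cartilage",
             "calcified_meniscus", "soft_meniscus"]
    mlist = [masks[k] for k in order if k in masks and masks[k].values.any()]
    mcfg = config.meshing
    params = MeshParams(target_edge_bone_um=mcfg.target_edge_bone_um,
                        target_edge_soft_um=mcfg.target_edge_soft_um)
    mesh = voxels_to_tets(mlist, params)
    if mcfg.surface_smooth_iterations > 0:
        h = mesh.grid_spacing_mm
        pinned = []
        for rname, band, layers in (("tibia_bone", "bottom", mcfg.distal_layers),
                                    ("femur_bone", "top", mcfg.top_layers)):
            nid = np.unique(mesh.region_elements(rname))
            z = mesh.nodes[nid, 2]
            if band == "bottom":
                pinned.append(nid[z <= z.min() + layers * h + 1e-9])
            else:
                pinned.append(nid[z >= z.max() - layers * h - 1e-9])
        smooth_surface_nodes(mesh, iterations=mcfg.surface_smooth_iterations,
                             lam=mcfg.surface_smooth_lambda,
                             pinned=np.concatenate(pinned))
    return extract_named_sets(mesh, distal_layers=mcfg.distal_layers,
                              top_layers=mcfg.top_layers,
                              normal_tol=mcfg.surface_normal_tol)


def solve_variant(mesh: TetMesh, config: RunConfig, variant: str,
                  store_stress: bool = True) -> FESolution:
    sol_cfg = config.solver
    # the geometric lift built into the masks is the gap rounded to whole
    # voxels; the initialization displacement must close exactly that
    vox = config.phantom.voxel_spacing_um
    actual_gap_um = round(sol_cfg.gap_translation_um / vox) * vox
    protocol = LoadProtocol(
        gap_translation_um=actual_gap_um,
        initialization_displacement_um=actual_gap_um,
        loading_displacement_um=sol_cfg.loading_displacement_um,
        n_steps=sol_cfg.n_steps,
        n_init_substeps=sol_cfg.n_init_substeps)
    pairs = [ContactPair(master="femoral_cartilage_surface",
                         slave="tibial_cartilage_surface",
                         penalty_stiffness=sol_cfg.penalty_stiffness)]
    if variant == "individual_meniscus" and "meniscus_superior" in mesh.facet_sets:
        pairs.append(ContactPair(master="femoral_cartilage_surface",
                                 slave="meniscus_superior",
                                 penalty_stiffness=sol_cfg.penalty_stiffness))
    return solve_contact_steps(
        mesh, default_materials(), protocol, pairs,
        fixed_sets=["tibia_distal_fixed"],
        coupled_set="femur_top_coupled",
        max_iterations=sol_cfg.max_iterations,
        force_rtol=sol_cfg.force_rtol,
        store_stress=store_stress)


def run_variant(config: RunConfig, variant: str,
                phantom_cache=None, store_stress: bool = False) -> VariantResult:
    """Execute the full chain for one variant on the phantom.

    ``phantom_cache`` may hold a previously generated
    ``(rest, stained_femur, stained_tibia, truth)`` tuple so the four
    variants share one phantom and segmentation.
    """
    if phantom_cache is None:
        phantom_cache = generate_phantom(_phantom_spec(config))
    rest, stained_f, stained_t, truth = phantom_cache
    parts, _ = segment_phantom(rest, config)
    fem_cart = tib_cart = None
    if variant in ("individual_meniscus", "individual"):
        bones = [parts["femur_bone"], parts["tibia_bone"],
                 parts["calcified_meniscus"]]
        fem_cart = recover_cartilage(
            stained_f, parts["femur_bone"], bones,
            truth.landmarks_stained["femur"], truth.landmarks_rest["femur"],
            rest, config, "femur_cartilage")
        tib_cart = recover_cartilage(
            stained_t, parts["tibia_bone"], bones,
            truth.landmarks_stained["tibia"], truth.landmarks_rest["tibia"],
            rest, config, "tibia_cartilage")
    masks = build_variant_masks(variant, parts, fem_cart, tib_cart, config)
    mesh = mesh_variant(masks, config)
    sol = solve_variant(mesh, config, variant, store_stress=store_stress)
    history = reaction_history(sol)
    step = select_step(history, config.analysis.target_force_n)
    part = partition_condyles(mesh)
    summaries = pressure_summary(
        sol, step, part, variant=variant,
        isolation_neighbors=config.analysis.isolation_neighbors,
        isolation_radius_factor=config.analysis.isolation_radius_factor,
        histogram_bin_mpa=config.analysis.histogram_bin_mpa,
        histogram_start_mpa=config.analysis.histogram_start_mpa,
        surface=config.analysis.report_surface)
    return VariantResult(variant=variant, mesh=mesh, solution=sol,
                         summaries=summaries, matched_step=step,
                         history=history, masks=masks)


def run_all_variants(config: RunConfig,
                     store_stress: bool = False) -> dict[str, VariantResult]:
    phantom_cache = generate_phantom(_phantom_spec(config))
    return {v: run_variant(config, v, phantom_cache=phantom_cache,
                           store_stress=store_stress)
            for v in config.variants}
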