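"""Image-space geometry operators for the knee model pipeline.

These are the building blocks of the geometry workflow: Gaussian smoothing of
the grayscale scans, single-level threshold segmentation, Boolean mask
algebra, boundary-regularising mask smoothing, the meniscus gap wrap, the
generic (homogeneous-thickness) cartilage builders, and integer-voxel mask
translation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import LabelMask, VoxelImage

__all__ = [
    "gaussian_smooth",
    "threshold_segment",
    "suggest_threshold",
    "ThresholdError",
    "mask_boolean",
    "mask_smooth",
    "wrap_meniscus",
    "build_generic_cartilage",
    "GenericCartilage",
    "translate_mask",
    "separate_bone_components",
]


class ThresholdError(ValueError):
    """Raised when no sensible automatic threshold exists (unimodal image)."""


def _check_same_grid(a, b) -> None:
    if not a.same_grid(b):
        raise ValueError("masks/images are not on the same grid")


def gaussian_smooth(img: VoxelImage, sigma_voxels: float = 1.0) -> VoxelImage:
    """Gaussian smoothing with reflective boundaries (sigma in voxels)."""
    if not sigma_voxels > 0:
        raise ValueError("sigma_voxels must be positive")
    if not np.all(np.isfinite(img.values)):
        raise ValueError("image contains non-finite values")
    out = ndimage.gaussian_filter(np.asarray(img.values, dtype=float),
                                  sigma=sigma_voxels, mode="reflect")
    return img.with_values(out)


def threshold_segment(img: VoxelImage, level: float,
                      tissue: str = "femur_bone") -> LabelMask:
    """Single-level threshold: mask of voxels with intensity >= ``level``."""
    values = img.values >= level
    if not values.any():
        warnings.warn("threshold produced an empty mask", stacklevel=2)
    return LabelMask(values, img.spacing_um, img.origin_mm, tissue)


def suggest_threshold(img: VoxelImage, bins: int = 256) -> float:
    """Histogram-based threshold between the two dominant intensity modes.

    Uses Otsu's criterion (maximising between-class variance), which places the
    level in the valley between the background and high-intensity (bone) modes
    of a bimodal histogram.  Raises :class:`ThresholdError` if the histogram
    has fewer than two modes.
    """
    from skimage.filters import threshold_otsu

    vals = np.asarray(img.values, dtype=float).ravel()
    if vals.max() == vals.min():
        raise ThresholdError(
            "image is constant; choose a manual threshold level")
    hist, edges = np.histogram(vals, bins=bins)
    # smooth the histogram and count local maxima to detect bimodality
    # (zero-padded so modes at the intensity extremes count as peaks)
    smooth = np.pad(ndimage.gaussian_filter1d(hist.astype(float), sigma=2.0),
                    1)
    interior = smooth[1:-1]
    peaks = (interior >= smooth[:-2]) & (interior > smooth[2:]) & (
        interior > 0.005 * smooth.max())
    if int(peaks.sum()) < 2:
        raise ThresholdError(
            "intensity histogram appears unimodal; choose a manual level")
    return float(threshold_otsu(vals, nbins=bins))


def mask_boolean(a: LabelMask, b: LabelMask, op: str,
                 tissue: str | None = None) -> LabelMask:
    """Voxelwise set algebra on masks: ``subtract``, ``union`` or ``intersect``."""
    _check_same_grid(a, b)
    if op == "subtract":
        values = a.values & ~b.values
    elif op == "union":
        values = a.values | b.values
    elif op == "intersect":
        values = a.values & b.values
    else:
        raise ValueError(f"unknown Boolean op {op!r}")
    return a.with_values(values, tissue)


def mask_smooth(m: LabelMask, radius_voxels: float = 2.0) -> LabelMask:
    """Boundary-regularising mask smoothing.

    The binary indicator is blurred with a Gaussian of sigma = radius/2 voxels
    and re-thresholded at 0.5 (a signed-distance-like regularisation).  The
    2-voxel default matches the cartilage-mask smoothing radius of the source
    workflow.
    """
    if radius_voxels < 1:
        raise ValueError("radius_voxels must be >= 1")
    blur = ndimage.gaussian_filter(m.values.astype(float),
                                   sigma=radius_voxels / 2.0, mode="constant")
    out = blur >= 0.5
    if m.values.any() and not out.any():
        raise ValueError("mask_smooth removed the whole mask; reduce radius")
    n_in, n_out = int(m.values.sum()), int(out.sum())
    if n_in and abs(n_out - n_in) > 0.10 * n_in:
        warnings.warn(
            f"mask_smooth changed the mask volume by "
            f"{100.0 * (n_out - n_in) / n_in:.1f}% (> 10%)", stacklevel=2)
    return m.with_values(out)


def _ball(radius_voxels: float) -> np.ndarray:
    r = int(np.ceil(radius_voxels))
    z = np.arange(-r, r + 1)
    dist2 = z[:, None, None] ** 2 + z[None, :, None] ** 2 + z[None, None, :] ** 2
    return dist2 <= radius_voxels**2


def wrap_meniscus(calcified: LabelMask, femur_cart: LabelMask,
                  tibia_cart: LabelMask, max_gap_um: float,
                  superior_clearance_voxels: int = 2) -> LabelMask:
    """Fill the gap between the calcified menisci and the cartilage surfaces.

    A morphological closing (ball structuring element of radius
    ``max_gap_um / 2``) of the union of the three masks bridges gaps up to
    ``max_gap_um``; the original masks are then subtracted so the result is
    the new soft-meniscus material only.  The wrap output is additionally
    trimmed ``superior_clearance_voxels`` below the femoral cartilage
    (hand-editing of the raw wrap is part of the workflow this emulates:
    without a clearance the wrap would weld the joint space shut and the
    meniscus could never engage gradually under load).  Fill components not
    connected to the calcified meniscus (spurious bridges far from the
    menisci) are discarded.
    """
    _check_same_grid(calcified, femur_cart)
    _check_same_grid(calcified, tibia_cart)
    if not calcified.values.any():
        raise ValueError("calcified meniscus mask is empty")
    radius_vox = 0.5 * max_gap_um / calcified.spacing_um
    union = calcified.values | femur_cart.values | tibia_cart.values
    if radius_vox < 0.5:
        out = np.zeros_like(union)
        warnings.warn("max_gap below one voxel: empty soft meniscus",
                      stacklevel=2)
        return calcified.with_values(out, "soft_meniscus")
    closed = ndimage.binary_closing(union, structure=_ball(radius_vox),
                                    border_value=0)
    fill = closed & ~union
    if superior_clearance_voxels > 0 and femur_cart.values.any():
        keep_out = ndimage.binary_dilation(
            femur_cart.values, _ball(superior_clearance_voxels))
        fill &= ~keep_out
    # keep only fill connected (26-neighbourhood) to the calcified meniscus
    lab, n = ndimage.label(fill, structure=np.ones((3, 3, 3), dtype=bool))
    if n:
        touching = np.unique(
            lab[ndimage.binary_dilation(
                calcified.values, structure=np.ones((3, 3, 3), dtype=bool))])
        keep = np.zeros(n + 1, dtype=bool)
        keep[touching[touching > 0]] = True
        fill = keep[lab]
    if not fill.any():
        warnings.warn("gap wider than max_gap everywhere: empty soft meniscus",
                      stacklevel=2)
    return calcified.with_values(fill, "soft_meniscus")


@dataclass
class GenericCartilage:
    """Homogeneous offset-shell cartilage layers and their thicknesses (mm)."""

    femur_cartilage: LabelMask
    tibia_cartilage: LabelMask
    thickness_lateral_mm: float
    thickness_medial_mm: float


def _side_masks(shape, x_coords_mm, plane_x_mm):
    """Boolean lateral (+x side) / medial (-x side) half-space masks."""
    lat = (x_coords_mm >= plane_x_mm)[:, None, None]
    lat = np.broadcast_to(lat, shape)
    return lat, ~lat


def build_generic_cartilage(bone_femur: LabelMask, bone_tibia: LabelMask,
                            mode: str = "one_thickness",
                            plane_x_mm: float | None = None) -> GenericCartilage:
    """Build homogeneous cartilage layers as constant-distance offset shells.

    ``one_thickness``: a single thickness ``t = g_lat / 2`` on both bones,
    chosen so that the two layers of the lateral condyle (the condyle with the
    smaller bone-to-bone gap ``g_lat``) just touch.  ``two_thickness``: per
    condyle thickness ``t_side = g_side / 2`` so both condyles' layers just
    touch.  The lateral condyle is the +x side of ``plane_x_mm`` (defaults to
    the mid-plane between the bone centroids).
    """
    _check_same_grid(bone_femur, bone_tibia)
    if (bone_femur.values & bone_tibia.values).any():
        raise ValueError("bone masks overlap")
    if mode not in ("one_thickness", "two_thickness"):
        raise ValueError(f"unknown mode {mode!r}")
    sp_mm = bone_femur.spacing_mm
    # distance (mm) from every voxel centre to each bone
    d_f = ndimage.distance_transform_edt(~bone_femur.values, sampling=sp_mm)
    d_t = ndimage.distance_transform_edt(~bone_tibia.values, sampling=sp_mm)
    gap = d_f + d_t  # bone-to-bone gap through each voxel

    xc = bone_femur.axis_coords_mm(0)
    if plane_x_mm is None:
        idx = np.nonzero(bone_femur.values | bone_tibia.values)
        plane_x_mm = float(xc[idx[0]].mean())
    lat, med = _side_masks(bone_femur.shape, xc, plane_x_mm)

    outside = ~(bone_femur.values | bone_tibia.values)
    g_lat = float(gap[lat & outside].min()) if (lat & outside).any() else np.inf
    g_med = float(gap[med & outside].min()) if (med & outside).any() else np.inf
    if not np.isfinite(g_lat) or not np.isfinite(g_med):
        raise ValueError("condyle gap not measurable (no opposing surfaces)")

    if mode == "one_thickness":
        t_lat = t_med = min(g_lat, g_med) / 2.0
    else:
        t_lat, t_med = g_lat / 2.0, g_med / 2.0

    # articular region: voxels near the inter-bone gap, so shells cover the
    # prospective contact patch without wrapping around the backs of the bones
    g_ref = max(g_lat if np.isfinite(g_lat) else 0.0,
                g_med if np.isfinite(g_med) else 0.0)
    region = gap <= g_ref + 0.5 * (t_lat + t_med) + 4.0 * sp_mm

    thick = np.where(lat, t_lat, t_med)
    fem = outside & region & (d_f <= thick)
    tib = outside & region & (d_t <= thick) & ~fem
    if not fem.any() or not tib.any():
        raise ValueError("generic cartilage construction produced empty layer")
    return GenericCartilage(
        femur_cartilage=bone_femur.with_values(fem, "femur_cartilage"),
        tibia_cartilage=bone_tibia.with_values(tib, "tibia_cartilage"),
        thickness_lateral_mm=t_lat,
        thickness_medial_mm=t_med,
    )


def translate_mask(m: LabelMask, offset_voxels) -> LabelMask:
    """Pure integer-voxel shift; the grid is padded so no voxels are lost."""
    off = np.asarray(offset_voxels, dtype=int).reshape(3)
    vals = m.values
    origin = m.origin_mm.copy()
    pad = [[0, 0], [0, 0], [0, 0]]
    for ax in range(3):
        if off[ax] > 0:
            idx = np.nonzero(vals.any(axis=tuple(a for a in range(3) if a != ax)))[0]
            need = 0 if idx.size == 0 else max(0, idx.max() + off[ax] - (vals.shape[ax] - 1))
            pad[ax][1] = int(need)
        elif off[ax] < 0:
            idx = np.nonzero(vals.any(axis=tuple(a for a in range(3) if a != ax)))[0]
            need = 0 if idx.size == 0 else max(0, -(idx.min() + off[ax]))
            pad[ax][0] = int(need)
            origin[ax] -= need * m.spacing_mm
    if any(p != [0, 0] for p in pad):
        vals = np.pad(vals, pad, mode="constant")
    out = np.zeros_like(vals)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax in range(3):
        o = off[ax]
        if o > 0:
            src[ax], dst[ax] = slice(0, vals.shape[ax] - o), slice(o, None)
        elif o < 0:
            src[ax], dst[ax] = slice(-o, None), slice(0, vals.shape[ax] + o)
    out[tuple(dst)] = vals[tuple(src)]
    res = LabelMask(out, m.spacing_um, origin, m.tissue)
    if res.count != m.count:
        raise AssertionError("translate_mask lost voxels despite padding")
    return res


def separate_bone_components(bone: LabelMask) -> dict[str, LabelMask]:
    """Split a bone+calcified-meniscus segmentation into anatomical parts.

    The connected component reaching highest (+z, superior) is the distal
    femur, the one reaching lowest is the proximal tibia, and any remaining
    components are the calcified menisci.
    """
    lab, n = ndimage.label(bone.values)
    if n < 2:
        raise ValueError("expected at least two bone components")
    # component z extents
    tops = np.full(n + 1, -np.inf)
    bots = np.full(n + 1, np.inf)
    zs = np.nonzero(bone.values)
    comp = lab[zs]
    for c in range(1, n + 1):
        zc = zs[2][comp == c]
        if zc.size:
            tops[c], bots[c] = zc.max(), zc.min()
    femur_c = int(np.argmax(tops))
    bots[femur_c] = np.inf
    tibia_c = int(np.argmin(bots[1:]) + 1)
    men = (lab > 0) & (lab != femur_c) & (lab != tibia_c)
    return {
        "femur_bone": bone.with_values(lab == femur_c, "femur_bone"),
        "tibia_bone": bone.with_values(lab == tibia_c, "tibia_bone"),
        "calcified_meniscus": bone.with_values(men, "calcified_meniscus"),
    }
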