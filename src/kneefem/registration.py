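"""Landmark rigid registration and image resampling.

Each stained-scan bone is mapped back into the rest-position scan by a rigid
transform estimated from paired landmarks: a rough 3-marker registration
followed by a refinement with >= 15 landmarks, both solved in closed form
(orthogonal Procrustes / Kabsch with a reflection guard), and the stained
image is resampled onto the rest grid with trilinear interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import VoxelImage

__all__ = [
    "LandmarkSet",
    "RigidTransform",
    "DegenerateLandmarksError",
    "fit_rigid",
    "two_step_register",
    "resample",
]


class DegenerateLandmarksError(ValueError):
    """Raised when landmark configurations are collinear or too few."""


@dataclass
class RigidTransform:
    """Rigid map x -> R x + t, coordinates in mm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float, translation=(0.0, 0.0, 0.0),
                        center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation about ``center`` plus translation."""
        a = np.asarray(axis, dtype=float)
        a = a / np.linalg.norm(a)
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * K @ K
        c = np.asarray(center, dtype=float)
        t = np.asarray(translation, dtype=float) + c - R @ c
        return cls(R, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Return self o first (apply ``first``, then ``self``)."""
        return RigidTransform(self.rotation @ first.rotation,
                              self.rotation @ first.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def as_matrix(self) -> np.ndarray:
        H = np.eye(4)
        H[:3, :3] = self.rotation
        H[:3, 3] = self.translation
        return H

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"matrix": self.as_matrix().tolist()}, fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            H = np.asarray(json.load(fh)["matrix"], dtype=float)
        return cls(H[:3, :3], H[:3, 3])


@dataclass
class LandmarkSet:
    """Ordered, id-tagged landmark coordinates (mm) in one scan frame."""

    points: np.ndarray
    ids: list[str] = field(default_factory=list)
    frame: str = "rest"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not self.ids:
            self.ids = [f"L{i:02d}" for i in range(len(self.points))]
        if len(self.ids) != len(self.points):
            raise ValueError("ids and points length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate landmark ids")
        if len(self.points) < 3:
            raise DegenerateLandmarksError("need at least 3 landmarks")

    def __len__(self) -> int:
        return len(self.points)

    def matched(self, other: "LandmarkSet") -> tuple[np.ndarray, np.ndarray]:
        """Return point arrays ordered by shared ids."""
        if set(self.ids) != set(other.ids):
            raise ValueError("landmark sets do not share the same ids")
        order = {lid: i for i, lid in enumerate(other.ids)}
        idx = [order[lid] for lid in self.ids]
        return self.points, other.points[idx]

    def save_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id,x_mm,y_mm,z_mm\n")
            for lid, p in zip(self.ids, self.points):
                fh.write(f"{lid},{p[0]:.9g},{p[1]:.9g},{p[2]:.9g}\n")

    @classmethod
    def load_csv(cls, path, frame: str = "rest") -> "LandmarkSet":
        ids, pts = [], []
        with open(path) as fh:
            next(fh)
            for line in fh:
                lid, x, y, z = line.strip().split(",")
                ids.append(lid)
                pts.append([float(x), float(y), float(z)])
        return cls(np.asarray(pts), ids, frame)


def fit_rigid(src: LandmarkSet, dst: LandmarkSet) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit T minimising sum ||T(src_i) - dst_i||^2.

    Closed-form Kabsch solution with a sign-corrected SVD so the result is a
    proper rotation (det = +1) even for noisy or near-planar configurations.
    Returns the transform and the per-coordinate RMS residual (mm), i.e.
    ``sqrt(sum_i ||T(src_i) - dst_i||^2 / (3 n))``, which for isotropic
    landmark noise of standard deviation sigma is close to sigma.
    """
    P, Q = src.matched(dst)
    if len(P) < 3:
        raise DegenerateLandmarksError("need at least 3 paired landmarks")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    s = np.linalg.svd(P0, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1e-300):
        raise DegenerateLandmarksError(
            "landmarks are collinear; rotation is not identifiable")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    T = RigidTransform(R, t)
    res = T.apply(P) - Q
    rms = float(np.sqrt((res**2).sum() / res.size))
    return T, rms


def two_step_register(coarse_src: LandmarkSet, coarse_dst: LandmarkSet,
                      fine_src: LandmarkSet, fine_dst: LandmarkSet,
                      fine_in_raw_frame: bool = True) -> RigidTransform:
    """Rough 3-marker registration followed by a >=15-landmark refinement.

    With ``fine_in_raw_frame=True`` (default) the fine landmarks are given in
    the original stained-scan frame and are mapped through the coarse
    transform before the fine fit; the returned transform is the composition
    fine o coarse.  If the coarse fit is exact the composition equals the
    single-step fine fit.
    """
    T_coarse, _ = fit_rigid(coarse_src, coarse_dst)
    if fine_in_raw_frame:
        fsrc = LandmarkSet(T_coarse.apply(fine_src.points), list(fine_src.ids),
                           fine_src.frame)
    else:
        fsrc = fine_src
    T_fine, _ = fit_rigid(fsrc, fine_dst)
    return T_fine.compose(T_coarse)


def resample(img: VoxelImage, T: RigidTransform, target: VoxelImage,
             fill_value: float | None = None) -> VoxelImage:
    """Resample ``img`` through rigid transform ``T`` onto ``target``'s grid.

    ``T`` maps source physical coordinates into target physical coordinates;
    interpolation is trilinear.  Out-of-field voxels receive ``fill_value``
    (default: the source image's background mode, estimated as the histogram
    mode, so edges do not turn into false bone after thresholding).
    """
    if fill_value is None:
        hist, edges = np.histogram(img.values, bins=128)
        k = int(np.argmax(hist))
        fill_value = float(0.5 * (edges[k] + edges[k + 1]))
    Tinv = T.inverse()
    sp_t, sp_s = target.spacing_mm, img.spacing_mm
    # index_src = (R_inv @ (origin_t + sp_t * index_t) + t_inv - origin_s)/sp_s
    A = Tinv.rotation * (sp_t / sp_s)
    b = (Tinv.rotation @ target.origin_mm + Tinv.translation - img.origin_mm) / sp_s
    out = ndimage.affine_transform(
        np.asarray(img.values, dtype=float), A, offset=b,
        output_shape=target.shape, order=1, mode="constant", cval=fill_value)
    return VoxelImage(out, target.spacing_um, target.origin_mm)
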