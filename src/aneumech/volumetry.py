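"""Image-domain volumetry: masks -> wall geometry -> luminal volumes.

Turns binary lumen segmentations into triangulated wall geometry, rigidly
overlays the baseline (C1) and stimulated (C2) acquisitions on their common
parent-vessel voxels, delimits the aneurysm with a persisted cut plane and
computes luminal volumes and their change ``delta V_exp``.

Two volume estimators are provided: voxel counting (default, the direct
image-domain measurement) and the enclosed volume of the watertight
marching-cubes surface; their agreement is the internal control.

Conventions: world coordinates in mm, right-handed; voxel indices 0-based;
a voxel belongs to a plane side when its center has positive signed
distance times ``side``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from .exceptions import GeometryError, RegistrationError, ValidationError

__all__ = [
    "SegmentationMask",
    "WallGeometry",
    "RegionDelimitation",
    "RigidTransform",
    "VolumeReport",
    "mesh_from_mask",
    "build_wall",
    "register_overlay",
    "apply_transform",
    "dice",
    "delimit_aneurysm",
    "luminal_volume",
    "volume_report",
]

log = logging.getLogger(__name__)


@dataclass
class SegmentationMask:
    """3-D binary lumen occupancy grid with voxel spacing and world affine."""

    occupancy: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = None
    label: str = ""

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValidationError("occupancy must be a 3-D grid")
        uniq = np.unique(occ)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError("occupancy values must be 0 or 1")
        self.occupancy = occ.astype(np.uint8)
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size).repeat(3)[:3])
        if any(v <= 0 for v in vs):
            raise ValidationError("voxel size must be positive on all axes")
        self.voxel_size = vs
        if self.affine is None:
            self.affine = np.diag([*vs, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def voxel_count_volume(self) -> float:
        """Lumen volume in mm^3 by voxel counting."""
        return float(self.occupancy.sum()) * self.voxel_volume

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to world mm (voxel centers)."""
        ijk1 = np.c_[indices, np.ones(len(indices))]
        return (self.affine @ ijk1.T).T[:, :3]

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.occupancy.astype(np.uint8), self.affine)
        img.header.set_zooms(self.voxel_size)
        if str(path).endswith(".gz"):
            # deterministic gzip (fixed mtime) so reruns are bit-identical
            import gzip
            import io

            buf = io.BytesIO()
            with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as fh:
                fh.write(img.to_bytes())
            Path(path).write_bytes(buf.getvalue())
        else:
            nib.save(img, str(path))

    @classmethod
    def load(cls, path, label: str = "") -> "SegmentationMask":
        img = nib.load(str(path))
        occ = np.asarray(img.dataobj).astype(np.uint8)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(occupancy=occ, voxel_size=zooms, affine=np.asarray(img.affine), label=label)


@dataclass
class RegionDelimitation:
    """Cut plane (world mm) separating artery from aneurysm.

    ``side=+1`` labels the half-space of positive signed distance along
    ``normal`` as the aneurysm.
    """

    point: np.ndarray
    normal: np.ndarray
    side: int = 1

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValidationError("plane normal must be non-zero")
        self.normal = n / norm
        if self.side not in (-1, 1):
            raise ValidationError("side must be +1 or -1")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.point) @ self.normal * self.side

    def flipped(self) -> "RegionDelimitation":
        return RegionDelimitation(self.point.copy(), self.normal.copy(), -self.side)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"point": self.point.tolist(), "normal": self.normal.tolist(), "side": self.side})
        )

    @classmethod
    def from_json(cls, path) -> "RegionDelimitation":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["point"]), np.array(d["normal"]), int(d["side"]))


@dataclass
class WallGeometry:
    """Wall built by offsetting the inner (luminal) surface outward."""

    inner_surface: trimesh.Trimesh
    outer_surface: trimesh.Trimesh
    thickness_um: float = 430.0
    region_labels: np.ndarray | None = None  # per-face: True where aneurysm

    @property
    def wall_volume(self) -> float:
        """Wall material volume in mm^3 (outer minus inner enclosed volume)."""
        return float(self.outer_surface.volume - self.inner_surface.volume)


@dataclass
class RigidTransform:
    """Rigid world-frame transform x -> R x + t (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({"matrix": self.matrix.tolist()}))

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        m = np.asarray(json.loads(Path(path).read_text())["matrix"])
        return cls(m[:3, :3], m[:3, 3])


@dataclass(frozen=True)
class VolumeReport:
    """Baseline/stimulated luminal volumes and their change."""

    v_c1: float  # mm^3
    v_c2: float  # mm^3
    delta_v: float  # mm^3
    delta_v_pct: float  # percent of v_c1

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path) -> "VolumeReport":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# meshing


def mesh_from_mask(mask: SegmentationMask) -> trimesh.Trimesh:
    """Triangulated luminal surface (world mm) via marching cubes at level 0.5.

    The largest connected component is taken (with a warning) if the lumen
    is fragmented; an empty mask is an error.
    """
    occ = mask.occupancy
    if occ.sum() == 0:
        raise ValidationError("cannot mesh an empty mask")
    labels, n = ndimage.label(occ)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        log.warning("mask has %d connected components; keeping the largest", n)
        occ = (labels == keep).astype(np.uint8)
    if occ.sum() < 8:
        raise GeometryError("lumen component too small to triangulate")
    padded = np.pad(occ.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=(1.0, 1.0, 1.0))
    verts -= 1.0  # undo padding shift (voxel index space)
    ijk1 = np.c_[verts, np.ones(len(verts))]
    world = (mask.affine @ ijk1.T).T[:, :3]
    mesh = trimesh.Trimesh(vertices=world, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise GeometryError("marching-cubes surface is not watertight")
    return mesh


def build_wall(inner: trimesh.Trimesh, thickness_um: float = 430.0) -> WallGeometry:
    """Offset the inner surface outward along vertex normals by the wall thickness.

    Valid for offsets small against the minimum curvature radius; a
    self-intersecting or volume-decreasing offset raises GeometryError.
    """
    if thickness_um <= 0:
        raise ValidationError("wall thickness must be positive")
    if not inner.is_watertight:
        raise GeometryError("inner surface must be closed and watertight")
    t_mm = thickness_um / 1000.0
    outer = inner.copy()
    outer.vertices = inner.vertices + inner.vertex_normals * t_mm
    if not outer.is_watertight or outer.volume <= inner.volume:
        raise GeometryError(
            "outward offset self-intersects (thickness too large for the local curvature)"
        )
    return WallGeometry(inner_surface=inner, outer_surface=outer, thickness_um=thickness_um)


# ---------------------------------------------------------------------------
# rigid overlay


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary grids of identical shape."""
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 0.0


def _artery_weight(mask: SegmentationMask, exclude: RegionDelimitation | None) -> np.ndarray:
    """1 on artery voxels, 0 on the aneurysm side of the exclusion plane."""
    if exclude is None:
        return np.ones(mask.occupancy.shape, dtype=np.float32)
    idx = np.indices(mask.occupancy.shape).reshape(3, -1).T
    world = mask.world_coordinates(idx)
    sd = exclude.signed_distance(world).reshape(mask.occupancy.shape)
    return (sd <= 0).astype(np.float32)


def _rot_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _resample_world(
    moving: SegmentationMask, transform: RigidTransform, reference: SegmentationMask, data: np.ndarray, order: int
) -> np.ndarray:
    """Sample ``data`` (on the moving grid) at reference voxel centers mapped
    through the inverse world transform."""
    # reference voxel -> world -> T^-1 -> moving world -> moving voxel
    inv = transform.inverse()
    A = np.linalg.inv(moving.affine) @ inv.matrix @ reference.affine
    return ndimage.affine_transform(
        data, A[:3, :3], offset=A[:3, 3], output_shape=reference.occupancy.shape, order=order, mode="constant"
    )


def apply_transform(
    moving: SegmentationMask, transform: RigidTransform, reference: SegmentationMask
) -> SegmentationMask:
    """Resample ``moving`` into the reference grid under the world transform."""
    out = _resample_world(moving, transform, reference, moving.occupancy.astype(np.float32), order=1)
    return SegmentationMask(
        occupancy=(out >= 0.5).astype(np.uint8),
        voxel_size=reference.voxel_size,
        affine=reference.affine.copy(),
        label=moving.label,
    )


def register_overlay(
    c1: SegmentationMask,
    c2: SegmentationMask,
    exclude: RegionDelimitation | None = None,
    min_dice: float = 0.5,
) -> RigidTransform:
    """Rigid transform that overlays C2 onto C1, maximizing overlap of the
    parent-vessel (artery) voxels.

    The aneurysm side of ``exclude`` is removed from the metric so that sac
    deformation does not bias the alignment.  Raises RegistrationError when
    the final artery-restricted Dice falls below ``min_dice``.
    """
    from scipy.optimize import minimize

    w1 = _artery_weight(c1, exclude)
    fixed = ndimage.gaussian_filter(c1.occupancy.astype(np.float32) * w1, 1.0)
    moving = ndimage.gaussian_filter(c2.occupancy.astype(np.float32), 1.0)

    # initialize from artery centroids (world frame)
    def centroid(mask, data):
        idx = np.argwhere(data > 0.5)
        if len(idx) == 0:
            raise RegistrationError("empty artery region")
        return mask.world_coordinates(idx).mean(axis=0)

    w2 = _artery_weight(c2, exclude)
    com1 = centroid(c1, c1.occupancy * w1)
    com2 = centroid(c2, c2.occupancy * w2)
    t0 = com1 - com2
    center = com2  # rotate about the moving artery centroid

    def to_transform(p):
        R = _rot_matrix(p[3], p[4], p[5])
        t = p[:3] + center - R @ center
        return RigidTransform(R, t)

    def loss(p):
        T = to_transform(p)
        res = _resample_world(c2, T, c1, moving, order=1) * w1
        num = float((res * fixed).sum())
        den = float(res.sum() + fixed.sum()) + 1e-9
        return -2.0 * num / den

    p0 = np.r_[t0, 0.0, 0.0, 0.0]
    scale = np.array([1.0, 1.0, 1.0, 0.2, 0.2, 0.2])
    res = minimize(
        lambda q: loss(p0 + q * scale),
        np.zeros(6),
        method="Powell",
        options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 4000},
    )
    T = to_transform(p0 + res.x * scale)
    aligned = apply_transform(c2, T, c1)
    d = dice(aligned.occupancy * (w1 > 0.5), c1.occupancy * (w1 > 0.5))
    if d < min_dice:
        raise RegistrationError(f"registration failed: artery Dice {d:.3f} < {min_dice}")
    return T


# ---------------------------------------------------------------------------
# delimitation and volumes


def delimit_aneurysm(geometry, plane: RegionDelimitation) -> np.ndarray:
    """Per-face labels: True where a face centroid lies on the aneurysm side.

    ``geometry`` is a mesh or a WallGeometry (labels attach to its inner
    surface).  A plane missing the geometry entirely is an error.
    """
    mesh = geometry.inner_surface if isinstance(geometry, WallGeometry) else geometry
    sd = plane.signed_distance(mesh.triangles_center)
    labels = sd > 0
    if labels.all() or (~labels).all():
        raise ValidationError("cut plane does not intersect the geometry")
    if isinstance(geometry, WallGeometry):
        geometry.region_labels = labels
    return labels


def luminal_volume(mask_or_mesh, region: RegionDelimitation | None = None) -> float:
    """Lumen volume (mm^3) of the aneurysm-side region.

    Voxel estimator for SegmentationMask inputs (centers classified against
    the plane); enclosed-volume estimator for watertight meshes (plane cut
    capped).  With ``region=None`` the full lumen volume is returned.
    """
    if isinstance(mask_or_mesh, SegmentationMask):
        mask = mask_or_mesh
        if region is None:
            v = mask.voxel_count_volume()
        else:
            idx = np.argwhere(mask.occupancy > 0)
            if len(idx) == 0:
                raise ValidationError("empty mask")
            world = mask.world_coordinates(idx)
            inside = region.signed_distance(world) > 0
            v = float(inside.sum()) * mask.voxel_volume
        if v == 0:
            raise ValidationError("region contains no lumen voxels")
        return v
    mesh = mask_or_mesh
    if region is None:
        return float(mesh.volume)
    cut = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=region.normal * region.side, plane_origin=region.point, cap=False
    )
    if cut is None or len(cut.faces) == 0:
        raise ValidationError("region contains no lumen volume")
    # enclosed volume via signed tetrahedra with apex on the cut plane: the
    # (untriangulated) planar cap then contributes exactly zero
    o = region.point
    tri = cut.triangles - o
    v = float(np.abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0))
    if v == 0:
        raise ValidationError("region contains no lumen volume")
    return v


def volume_report(v_c1: float, v_c2: float) -> VolumeReport:
    """Experimental volume change between the baseline and stimulated lumina."""
    if v_c1 <= 0:
        raise ValidationError("baseline volume must be positive")
    dv = v_c2 - v_c1
    return VolumeReport(v_c1=v_c1, v_c2=v_c2, delta_v=dv, delta_v_pct=dv / v_c1 * 100.0)
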