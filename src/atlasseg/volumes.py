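"""Grid geometry, interpolation, resampling, projections, and file I/O.

Coordinate conventions
----------------------
Volumes are axis-aligned 3-D scalar grids indexed ``(i, j, k)`` with
``i -> x`` (right-left), ``j -> y`` (anterior-posterior) and
``k -> z`` (inferior-superior).  Voxel indices are 0-based and map to
world millimetres by ``world = origin + index * spacing``; there is no
direction-cosine support.  Displacement fields follow the *backward*
convention: the vector stored at test voxel ``p`` is the world offset
added to ``p``'s world coordinate to find the location at which the
source (atlas) image is sampled.  Backward, output-driven resampling
never leaves holes in the warped result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "RigidTransform3D",
    "DisplacementField",
    "voxel_to_world",
    "world_to_voxel",
    "trilinear_sample",
    "project_mean",
    "apply_displacement",
    "apply_rigid",
    "compose_rigid_and_field",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]

#: default structure set for head-and-neck organ-at-risk contouring
DEFAULT_STRUCTURES = (
    "brain",
    "brainstem",
    "cochleae",
    "eyes",
    "lungs",
    "mandible",
    "parotid_glands",
    "spinal_cord",
)

AIR_HU = -1000.0


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise ValueError(f"{name} must have 3 components, got {v.size}")
    return v


@dataclass
class ImageVolume:
    """A 3-D scalar image (Hounsfield-like units) on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (ni, nj, nk)
        Scalar intensities indexed (i, j, k).
    spacing : (3,) array-like
        Voxel size in mm along (x, y, z); all components > 0.
    origin : (3,) array-like
        World coordinate (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("each grid extent must be >= 1")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_geometry(self, other: "ImageVolume | BinaryMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def world_grid(self) -> np.ndarray:
        """World coordinates (mm) of every voxel centre, shape (ni, nj, nk, 3)."""
        idx = np.indices(self.shape, dtype=float)
        return np.moveaxis(idx, 0, -1) * self.spacing + self.origin

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.spacing.copy(), self.origin.copy())


@dataclass
class BinaryMask:
    """A named boolean labelling on an :class:`ImageVolume` grid."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    structure_name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask data must be 3-D, got ndim={self.data.ndim}")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    same_geometry = ImageVolume.same_geometry
    world_grid = ImageVolume.world_grid

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_mm3(self) -> float:
        """Structure volume = foreground voxel count x voxel volume."""
        return float(self.data.sum()) * self.voxel_volume_mm3

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.data.copy(), self.spacing.copy(), self.origin.copy(),
                          self.structure_name)


@dataclass
class RigidTransform3D:
    """Rigid world-coordinate map ``T(x) = R (x - c) + c + t``.

    ``rotation_deg`` are Euler angles in degrees applied x-then-y-then-z
    about the fixed world axes (extrinsic), ``translation_mm`` is ``t``
    and ``center_mm`` is the rotation centre ``c``.
    """

    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation_deg = _as_vec3(self.rotation_deg, "rotation_deg")
        self.translation_mm = _as_vec3(self.translation_mm, "translation_mm")
        self.center_mm = _as_vec3(self.center_mm, "center_mm")

    @classmethod
    def identity(cls) -> "RigidTransform3D":
        return cls()

    @property
    def matrix(self) -> np.ndarray:
        # extrinsic x-y-z: R = Rz @ Ry @ Rx
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def is_identity(self, atol: float = 1e-12) -> bool:
        return bool(
            np.allclose(self.rotation_deg, 0, atol=atol)
            and np.allclose(self.translation_mm, 0, atol=atol)
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map world points (..., 3) through the transform."""
        p = np.asarray(points, dtype=float)
        return (p - self.center_mm) @ self.matrix.T + self.center_mm + self.translation_mm

    def compose(self, other: "RigidTransform3D") -> "RigidTransform3D":
        """Return ``self o other`` (apply *other* first); centres must match."""
        if not np.allclose(self.center_mm, other.center_mm, atol=1e-9):
            raise ValueError("can only compose transforms sharing a rotation centre")
        r_self = Rotation.from_euler("xyz", self.rotation_deg, degrees=True)
        r_other = Rotation.from_euler("xyz", other.rotation_deg, degrees=True)
        r = r_self * r_other
        return RigidTransform3D(
            rotation_deg=r.as_euler("xyz", degrees=True),
            translation_mm=r_self.apply(other.translation_mm) + self.translation_mm,
            center_mm=self.center_mm,
        )

    def inverse(self) -> "RigidTransform3D":
        rot_inv = Rotation.from_euler("xyz", self.rotation_deg, degrees=True).inv()
        return RigidTransform3D(
            rotation_deg=rot_inv.as_euler("xyz", degrees=True),
            translation_mm=-rot_inv.apply(self.translation_mm),
            center_mm=self.center_mm,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "type": "rigid3d",
                "rotation_deg_xyz_extrinsic": self.rotation_deg.tolist(),
                "translation_mm": self.translation_mm.tolist(),
                "center_mm": self.center_mm.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform3D":
        d = json.loads(text)
        return cls(d["rotation_deg_xyz_extrinsic"], d["translation_mm"], d["center_mm"])


@dataclass
class DisplacementField:
    """Backward-mapping displacement vectors (mm) on the test grid.

    ``vectors[i, j, k]`` is the world offset added to voxel (i, j, k)'s
    world coordinate to find the source sampling location.
    """

    vectors: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("vectors must have shape (ni, nj, nk, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement components must be finite")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    @classmethod
    def zeros_like(cls, vol: ImageVolume | BinaryMask) -> "DisplacementField":
        return cls(np.zeros(vol.shape + (3,)), vol.spacing.copy(), vol.origin.copy())

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.vectors ** 2).sum(axis=-1))

    def same_geometry(self, other, atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


# ---------------------------------------------------------------------------
# coordinate maps and interpolation


def voxel_to_world(index, volume: ImageVolume | BinaryMask) -> np.ndarray:
    """World coordinate (mm) of a voxel index; errors on out-of-extent indices."""
    idx = np.asarray(index)
    if np.any(idx < 0) or np.any(idx >= np.asarray(volume.shape)):
        raise IndexError(f"index {index} outside grid extents {volume.shape}")
    return volume.origin + idx * volume.spacing


def world_to_voxel(point, volume: ImageVolume | BinaryMask) -> np.ndarray:
    """Continuous voxel coordinate of a world point (inverse of voxel_to_world)."""
    return (np.asarray(point, dtype=float) - volume.origin) / volume.spacing


def trilinear_sample(volume: ImageVolume, points, fill: float = AIR_HU) -> np.ndarray:
    """Trilinear interpolation at world points (mm); outside the grid -> *fill*.

    ``points`` may be a single 3-vector or an (..., 3) array; the result has
    the points' leading shape.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    vox = (pts - volume.origin) / volume.spacing  # (n, 3) continuous indices
    inside = np.all((vox >= 0) & (vox <= np.asarray(volume.shape) - 1), axis=-1)
    out = np.full(vox.shape[0], float(fill))
    if inside.any():
        coords = vox[inside].T
        out[inside] = map_coordinates(
            volume.data.astype(float), coords, order=1, mode="nearest"
        )
    out = out.reshape(np.asarray(points, dtype=float).shape[:-1])
    return float(out) if single else out


def project_mean(volume: ImageVolume, axis: str):
    """Mean-intensity 2-D projection along the collapsed axis.

    ``axis='sagittal'`` collapses x (result indexed (j, k) = (y, z));
    ``axis='coronal'`` collapses y (result indexed (i, k) = (x, z)).
    Returns ``(image2d, spacing2d)`` where spacing2d are the two
    surviving voxel spacings in mm.
    """
    axes = {"sagittal": 0, "coronal": 1}
    if axis not in axes:
        raise ValueError(f"axis must be one of {sorted(axes)}, got {axis!r}")
    a = axes[axis]
    img = volume.data.astype(float).mean(axis=a)
    spacing2d = np.delete(volume.spacing, a)
    return img, spacing2d


def _resample_backward(source, sample_points_world, interpolation: str, fill: float):
    """Sample *source* (volume or mask) at given world points (..., 3)."""
    is_mask = isinstance(source, BinaryMask)
    data = source.data.astype(float)
    vox = (sample_points_world - source.origin) / source.spacing
    shape = vox.shape[:-1]
    coords = vox.reshape(-1, 3)
    inside = np.all((coords >= 0) & (coords <= np.asarray(source.shape) - 1), axis=-1)
    out = np.full(coords.shape[0], float(fill))
    if inside.any():
        order = 0 if interpolation == "nearest" else 1
        out[inside] = map_coordinates(data, coords[inside].T, order=order, mode="nearest")
    out = out.reshape(shape)
    if is_mask:
        return out >= 0.5 if interpolation == "trilinear" else out > 0.5
    return out


def apply_displacement(
    obj: ImageVolume | BinaryMask,
    fld: DisplacementField,
    interpolation: str | None = None,
    fill: float = AIR_HU,
):
    """Warp an image or mask through a backward displacement field.

    Each output voxel at world coordinate ``x`` samples the source at
    ``x + field(x)``.  Masks default to trilinear sampling followed by a
    0.5 threshold (smoother boundaries); pass ``interpolation='nearest'``
    for label-preserving nearest-neighbour warping.
    """
    is_mask = isinstance(obj, BinaryMask)
    if interpolation is None:
        interpolation = "trilinear"
    if interpolation not in ("nearest", "trilinear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    target_world = np.moveaxis(np.indices(fld.shape, dtype=float), 0, -1) * fld.spacing + fld.origin
    sample = target_world + fld.vectors
    warped = _resample_backward(obj, sample, interpolation, 0.0 if is_mask else fill)
    if is_mask:
        return BinaryMask(warped, fld.spacing.copy(), fld.origin.copy(), obj.structure_name)
    return ImageVolume(warped, fld.spacing.copy(), fld.origin.copy())


def apply_rigid(
    obj: ImageVolume | BinaryMask,
    t: RigidTransform3D,
    interpolation: str | None = None,
    fill: float = AIR_HU,
    target: ImageVolume | BinaryMask | None = None,
):
    """Resample an object through a rigid transform (backward mapping).

    ``t`` maps the source (moving) frame into the target (fixed) frame, so
    each output voxel's world coordinate is pulled back through ``t^{-1}``
    and the source sampled there.  The output grid defaults to the source
    grid; pass ``target`` to resample onto another geometry.
    """
    is_mask = isinstance(obj, BinaryMask)
    if interpolation is None:
        interpolation = "trilinear"
    ref = obj if target is None else target
    target_world = np.moveaxis(np.indices(ref.shape, dtype=float), 0, -1) * ref.spacing + ref.origin
    sample = t.inverse().apply(target_world)
    warped = _resample_backward(obj, sample, interpolation, 0.0 if is_mask else fill)
    if is_mask:
        return BinaryMask(warped, ref.spacing.copy(), ref.origin.copy(), obj.structure_name)
    return ImageVolume(warped, ref.spacing.copy(), ref.origin.copy())


def compose_rigid_and_field(
    obj: ImageVolume | BinaryMask,
    t: RigidTransform3D,
    fld: DisplacementField,
    interpolation: str | None = None,
    fill: float = AIR_HU,
):
    """Warp through rigid-then-displacement as ONE resampling pass.

    Equivalent to ``apply_displacement(apply_rigid(obj, t, target=...), fld)``
    but with a single interpolation, which matters for structures only a
    couple of voxels across.  Output voxel at world ``x`` samples the source
    at ``t^{-1}(x + field(x))``.
    """
    is_mask = isinstance(obj, BinaryMask)
    if interpolation is None:
        interpolation = "trilinear"
    target_world = np.moveaxis(np.indices(fld.shape, dtype=float), 0, -1) * fld.spacing + fld.origin
    sample = target_world + fld.vectors
    if not t.is_identity():
        sample = t.inverse().apply(sample)
    warped = _resample_backward(obj, sample, interpolation, 0.0 if is_mask else fill)
    if is_mask:
        return BinaryMask(warped, fld.spacing.copy(), fld.origin.copy(), obj.structure_name)
    return ImageVolume(warped, fld.spacing.copy(), fld.origin.copy())


# ---------------------------------------------------------------------------
# NIfTI I/O (axis-aligned affines only)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def write_volume(vol: ImageVolume, path) -> None:
    data = np.round(np.asarray(vol.data)).astype(np.int16)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def read_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise ValueError(f"{path}: only axis-aligned volumes are supported")
    return ImageVolume(
        np.asarray(img.dataobj).astype(float),
        np.abs(np.diag(aff[:3, :3])),
        aff[:3, 3].astype(float),
    )


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing, mask.origin))
    nib.save(img, str(path))


def read_mask(path, structure_name: str = "") -> BinaryMask:
    img = nib.load(str(path))
    aff = img.affine
    return BinaryMask(
        np.asarray(img.dataobj) >= 1,
        np.abs(np.diag(aff[:3, :3])),
        aff[:3, 3].astype(float),
        structure_name,
    )


def write_field(fld: DisplacementField, path) -> None:
    """Serialize a displacement field as a 4-D NIfTI with vector dimension last."""
    img = nib.Nifti1Image(fld.vectors.astype(np.float32), _affine(fld.spacing, fld.origin))
    nib.save(img, str(path))


def read_field(path) -> DisplacementField:
    img = nib.load(str(path))
    aff = img.affine
    return DisplacementField(
        np.asarray(img.dataobj).astype(float),
        np.abs(np.diag(aff[:3, :3])),
        aff[:3, 3].astype(float),
    )
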