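"""Seeded synthetic head-and-neck phantoms and simulation fixtures.

The generator produces schematic CT-like volumes at phantom fidelity:
eight organ-like structures of varied size (large brain, paired 2-voxel
cochleae, tubular spinal cord and paired lungs reaching the inferior image
boundary, a horseshoe mandible), Hounsfield-like tissue-class intensities
with Gaussian noise and a smooth multiplicative bias field, plus
non-contoured bony context (skull shell, vertebral canal, temporal bone)
that provides the intensity gradients real CT anatomy offers to
intensity-driven registration.

Atlas cohorts emulate inter-subject variation as a random rigid motion, a
smooth non-rigid deformation, and a variable inferior scan extent
(truncation of 0-8 slices), reproducing the scan-extent artifact that
motivates slice-restricted "modified" metrics for lungs and spinal cord.

All generators are pure functions of (spec, seed): a master seed fans out
to per-case child seeds through :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volumes import (
    DEFAULT_STRUCTURES,
    BinaryMask,
    DisplacementField,
    ImageVolume,
    RigidTransform3D,
    compose_rigid_and_field,
    write_mask,
    write_volume,
)

__all__ = [
    "PhantomSpec",
    "AtlasCase",
    "make_phantom",
    "random_smooth_displacement",
    "make_atlas_cohort",
    "simulate_raters",
    "simulate_rating_pairs",
    "write_atlas_dir",
    "read_atlas_dir",
]

#: Hounsfield-like tissue-class means for the contoured structures
DEFAULT_TISSUE_MEANS = {
    "brain": 30.0,
    "brainstem": 25.0,
    "cochleae": 10.0,
    "eyes": 5.0,
    "lungs": -700.0,
    "mandible": 800.0,
    "parotid_glands": -40.0,
    "spinal_cord": 45.0,
}

#: intensity-only context classes (not contoured): soft tissue, bone shells
SOFT_TISSUE_HU = 60.0
BONE_HU = 700.0
AIR_HU = -1000.0


@dataclass
class PhantomSpec:
    """Geometry and intensity description of the synthetic phantom.

    Defaults describe a 96 x 96 x 64 grid at 2 mm isotropic spacing
    (192 x 192 x 128 mm field of view, z = 0 at the inferior boundary).
    Structure primitives scale with the field of view so smaller test-size
    grids (e.g. 48 x 48 x 32 at 4 mm) keep the same anatomy.
    """

    shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tissue_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    noise_sd: float = 20.0
    bias_amplitude: float = 0.02   # relative amplitude of the multiplicative bias
    bias_smoothness_mm: float = 60.0
    structures: tuple[str, ...] = DEFAULT_STRUCTURES
    drop_structures: tuple[str, ...] = ()   # e.g. a surgically removed parotid

    @property
    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)


def _ellipsoid(world, center, semi):
    d = (world - np.asarray(center)) / np.asarray(semi)
    return (d ** 2).sum(axis=-1) <= 1.0


def _sphere(world, center, radius):
    return _ellipsoid(world, center, (radius, radius, radius))


def _tube_z(world, cx, cy, radius, z_lo, z_hi):
    r2 = (world[..., 0] - cx) ** 2 + (world[..., 1] - cy) ** 2
    return (r2 <= radius ** 2) & (world[..., 2] >= z_lo) & (world[..., 2] <= z_hi)


def _structure_masks(spec: PhantomSpec, world: np.ndarray) -> dict[str, np.ndarray]:
    """Boolean primitive per structure, in world mm; scaled to the field of view."""
    fx, fy, fz = spec.fov_mm
    mx = fx / 2.0  # midline x
    m: dict[str, np.ndarray] = {}

    m["brain"] = _ellipsoid(world, (mx, 0.48 * fy, 0.80 * fz), (0.28 * fx, 0.33 * fy, 0.17 * fz))
    m["brainstem"] = _tube_z(world, mx, 0.53 * fy, 0.045 * fx, 0.44 * fz, 0.64 * fz)
    # cochleae: paired spheres of 2-voxel radius, embedded in temporal bone
    # at the skull base, inferior-lateral to the brain
    r_coch = 2.0 * spec.spacing[0]
    m["cochleae"] = _sphere(world, (0.30 * fx, 0.50 * fy, 0.60 * fz), r_coch) | _sphere(
        world, (0.70 * fx, 0.50 * fy, 0.60 * fz), r_coch
    )
    # eyes: anterior-inferior to the brain so the spheres never intersect it
    r_eye = 0.052 * fx
    m["eyes"] = _sphere(world, (0.355 * fx, 0.17 * fy, 0.68 * fz), r_eye) | _sphere(
        world, (0.645 * fx, 0.17 * fy, 0.68 * fz), r_eye
    )
    # lungs: large paired ellipsoids centred below the image, truncated by z = 0
    m["lungs"] = _ellipsoid(world, (0.36 * fx, 0.52 * fy, -0.12 * fz), (0.12 * fx, 0.16 * fy, 0.33 * fz)) | _ellipsoid(
        world, (0.64 * fx, 0.52 * fy, -0.12 * fz), (0.12 * fx, 0.16 * fy, 0.33 * fz)
    )
    # mandible: horseshoe arc (anterior-opening circle segment) of bone
    phi = np.arctan2(0.42 * fy - world[..., 1], world[..., 0] - mx)  # angle from +x toward -y
    arc_r = np.hypot(world[..., 0] - mx, world[..., 1] - 0.42 * fy)
    in_arc = (phi >= np.deg2rad(15)) & (phi <= np.deg2rad(165))
    tube = (np.abs(arc_r - 0.20 * fx) <= 0.035 * fx) & (np.abs(world[..., 2] - 0.50 * fz) <= 0.045 * fz)
    m["mandible"] = tube & in_arc
    m["parotid_glands"] = _ellipsoid(
        world, (0.275 * fx, 0.50 * fy, 0.54 * fz), (0.055 * fx, 0.085 * fy, 0.085 * fz)
    ) | _ellipsoid(world, (0.725 * fx, 0.50 * fy, 0.54 * fz), (0.055 * fx, 0.085 * fy, 0.085 * fz))
    # spinal cord: thin midline tube reaching the inferior image boundary
    m["spinal_cord"] = _tube_z(world, mx, 0.53 * fy, 0.021 * fx, 0.0, 0.44 * fz)
    return m


def _context_intensity(spec: PhantomSpec, world: np.ndarray) -> np.ndarray:
    """Soft tissue body + bony context, before organ classes are painted in."""
    fx, fy, fz = spec.fov_mm
    mx = fx / 2.0
    img = np.full(world.shape[:-1], AIR_HU)

    head = _ellipsoid(world, (mx, 0.48 * fy, 0.78 * fz), (0.36 * fx, 0.42 * fy, 0.24 * fz))
    neck = _tube_z(world, mx, 0.50 * fy, 0.17 * fx, 0.30 * fz, 0.70 * fz)
    thorax = _ellipsoid(world, (mx, 0.52 * fy, -0.05 * fz), (0.42 * fx, 0.30 * fy, 0.42 * fz))
    img[head | neck | thorax] = SOFT_TISSUE_HU

    # skull: shell between the head ellipsoid and a slightly shrunk copy
    inner = _ellipsoid(world, (mx, 0.48 * fy, 0.78 * fz), (0.31 * fx, 0.37 * fy, 0.20 * fz))
    img[head & ~inner] = BONE_HU
    # temporal bone blocks hosting the cochleae
    for sx in (0.30, 0.70):
        img[_ellipsoid(world, (sx * fx, 0.50 * fy, 0.60 * fz), (0.07 * fx, 0.06 * fy, 0.05 * fz))] = BONE_HU
    # vertebral canal: bone annulus hugging the cord/brainstem axis (organ
    # classes are painted afterwards and carve their own lumen)
    r = np.hypot(world[..., 0] - mx, world[..., 1] - 0.53 * fy)
    canal = (r >= 0.025 * fx) & (r <= 0.075 * fx) & (world[..., 2] <= 0.64 * fz)
    img[canal & (img > AIR_HU)] = BONE_HU
    return img


def make_phantom(spec: PhantomSpec | None = None, seed: int = 0):
    """Generate a phantom image and its eight structure masks.

    Image = per-class mean intensity x smooth multiplicative bias +
    Gaussian noise.  Masks are mutually disjoint (painted in a fixed
    priority order; earlier structures win ties).  Deterministic given
    ``(spec, seed)``.

    Returns
    -------
    (ImageVolume, dict[str, BinaryMask])
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    origin = np.asarray(spec.origin, dtype=float)
    world = np.moveaxis(np.indices(shape, dtype=float), 0, -1) * spacing + origin

    raw = _structure_masks(spec, world)
    img = _context_intensity(spec, world)

    masks: dict[str, BinaryMask] = {}
    occupied = np.zeros(shape, dtype=bool)
    for name in spec.structures:
        if name not in raw:
            raise ValueError(f"no primitive defined for structure {name!r}")
        vox = raw[name] & ~occupied
        if not vox.any():
            raise ValueError(f"structure {name!r} exceeds the grid or is fully occluded")
        occupied |= vox
        img[vox] = spec.tissue_means[name]
        if name not in spec.drop_structures:
            masks[name] = BinaryMask(vox, spacing.copy(), origin.copy(), name)

    # smooth multiplicative bias, then additive noise
    sig = spec.bias_smoothness_mm / spacing
    bias = gaussian_filter(rng.standard_normal(shape), sigma=sig, mode="nearest")
    peak = np.abs(bias).max()
    if peak > 0:
        bias = 1.0 + spec.bias_amplitude * bias / peak
    else:
        bias = np.ones(shape)
    img = img * bias
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, shape)

    return ImageVolume(img, spacing, origin), masks


def random_smooth_displacement(
    grid: ImageVolume | BinaryMask,
    amplitude_mm: float,
    smoothness_mm: float = 12.0,
    seed: int = 0,
) -> DisplacementField:
    """Gaussian-smoothed white-noise vector field with max |v| = amplitude.

    Deterministic given the seed; ``amplitude_mm=0`` yields the zero field.
    """
    if amplitude_mm < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude_mm}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    vec = np.zeros(grid.shape + (3,))
    if amplitude_mm > 0:
        sig = np.asarray(smoothness_mm, dtype=float) / np.asarray(grid.spacing)
        for c in range(3):
            vec[..., c] = gaussian_filter(rng.standard_normal(grid.shape), sigma=sig, mode="nearest")
        mag = np.sqrt((vec ** 2).sum(axis=-1))
        peak = mag.max()
        if peak > 0:
            vec *= amplitude_mm / peak
    return DisplacementField(vec, np.asarray(grid.spacing, dtype=float).copy(),
                             np.asarray(grid.origin, dtype=float).copy())


@dataclass
class AtlasCase:
    """One atlas patient: image, named structure masks, and provenance."""

    case_id: str
    image: ImageVolume
    masks: dict[str, BinaryMask]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, mask in self.masks.items():
            if not self.image.same_geometry(mask):
                raise ValueError(f"mask {name!r} geometry differs from case image")


def _truncate_inferior(vol, n_slices: int):
    """Drop the n most-inferior (lowest-z) slices, shifting the origin up."""
    if n_slices <= 0:
        return vol.copy()
    data = vol.data[:, :, n_slices:]
    origin = vol.origin.copy()
    origin[2] += n_slices * vol.spacing[2]
    if isinstance(vol, BinaryMask):
        return BinaryMask(data.copy(), vol.spacing.copy(), origin, vol.structure_name)
    return ImageVolume(data.copy(), vol.spacing.copy(), origin)


def make_atlas_cohort(
    base_image: ImageVolume,
    base_masks: dict[str, BinaryMask],
    n: int = 12,
    max_rotation_deg: float = 5.0,
    max_translation_mm: float = 10.0,
    deform_amplitude_mm: float = 6.0,
    deform_smoothness_mm: float = 12.0,
    max_truncation_slices: int = 8,
    seed: int = 0,
    drop_structure_in_case: dict[int, str] | None = None,
) -> list[AtlasCase]:
    """Derive *n* atlas cases from a base phantom by random rigid motion,
    smooth non-rigid deformation, and variable inferior scan extent.

    Rotations are sampled per axis within +/- max_rotation_deg about x and
    y (z-rotation is left at 0 so the cohort stays within what the
    projection-based rigid step can recover); translations per axis within
    +/- max_translation_mm.  Each case keeps the deformation parameters in
    its provenance record.  ``drop_structure_in_case`` removes one named
    structure from selected cases (e.g. a surgically absent parotid).
    """
    if n < 1:
        raise ValueError(f"atlas size must be >= 1, got {n}")
    children = np.random.SeedSequence(seed).spawn(n)
    drop_structure_in_case = drop_structure_in_case or {}
    center = base_image.origin + (np.asarray(base_image.shape) - 1) * base_image.spacing / 2.0

    cases = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        rot = rng.uniform(-max_rotation_deg, max_rotation_deg, 3)
        rot[2] = 0.0
        trans = rng.uniform(-max_translation_mm, max_translation_mm, 3)
        rigid = RigidTransform3D(rot, trans, center)
        fld = random_smooth_displacement(
            base_image, deform_amplitude_mm, deform_smoothness_mm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        n_trunc = int(rng.integers(0, max_truncation_slices + 1))

        # the case is the base warped forward: sample base at rigid^-1(x + v(x))
        img = compose_rigid_and_field(base_image, rigid, fld)
        img = _truncate_inferior(img, n_trunc)
        masks = {}
        for name, mask in base_masks.items():
            if drop_structure_in_case.get(i) == name:
                continue
            wm = compose_rigid_and_field(mask, rigid, fld)
            masks[name] = _truncate_inferior(wm, n_trunc)
        cases.append(
            AtlasCase(
                case_id=f"case{i:03d}",
                image=img,
                masks=masks,
                provenance={
                    "rotation_deg": rot.tolist(),
                    "translation_mm": trans.tolist(),
                    "center_mm": center.tolist(),
                    "deform_amplitude_mm": float(deform_amplitude_mm),
                    "deform_smoothness_mm": float(deform_smoothness_mm),
                    "truncated_slices": n_trunc,
                },
            )
        )
    return cases


def simulate_raters(
    truth: BinaryMask,
    sensitivities,
    specificities,
    seed: int = 0,
) -> list[BinaryMask]:
    """Independent per-voxel raters with given sensitivity/specificity.

    Rater *j* marks a truth-foreground voxel with probability p_j and
    leaves a background voxel clear with probability q_j.
    """
    p = np.asarray(sensitivities, dtype=float)
    q = np.asarray(specificities, dtype=float)
    if p.shape != q.shape:
        raise ValueError("sensitivities and specificities must have equal length")
    if np.any((p < 0) | (p > 1)) or np.any((q < 0) | (q > 1)):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = []
    fg = truth.data
    for pj, qj in zip(p, q):
        u = rng.random(truth.shape)
        rated = np.where(fg, u < pj, u >= qj)
        out.append(BinaryMask(rated, truth.spacing.copy(), truth.origin.copy(),
                              truth.structure_name))
    return out


_CATEGORY_PAIRS = {
    "I": [("NO_EDITS", "NO_EDITS"), ("MINOR_EDITS", "MINOR_EDITS"), ("MAJOR_EDITS", "MAJOR_EDITS")],
    "II": [("NO_EDITS", "MINOR_EDITS"), ("MINOR_EDITS", "NO_EDITS")],
    "III": [
        ("MAJOR_EDITS", "NO_EDITS"),
        ("MAJOR_EDITS", "MINOR_EDITS"),
        ("NO_EDITS", "MAJOR_EDITS"),
        ("MINOR_EDITS", "MAJOR_EDITS"),
    ],
}


def simulate_rating_pairs(
    n: int,
    category_proportions=(0.45, 0.48, 0.07),
    seed: int = 0,
    structures=DEFAULT_STRUCTURES,
) -> pd.DataFrame:
    """Paired (primary, outside) ordinal ratings with given agreement mix.

    Each row's agreement category is drawn from ``category_proportions``
    (I, II, III) and a rating pair is drawn uniformly within the category.
    Returns a DataFrame with columns case_id, structure, rating_primary,
    rating_outside.
    """
    props = np.asarray(category_proportions, dtype=float)
    if props.size != 3 or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("category proportions must be 3 non-negative values summing to 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cats = rng.choice(["I", "II", "III"], size=n, p=props)
    rows = []
    for i, cat in enumerate(cats):
        pairs = _CATEGORY_PAIRS[cat]
        prim, out = pairs[int(rng.integers(len(pairs)))]
        rows.append(
            {
                "case_id": f"case{i // len(structures):03d}",
                "structure": structures[i % len(structures)],
                "rating_primary": prim,
                "rating_outside": out,
            }
        )
    return pd.DataFrame(rows, columns=["case_id", "structure", "rating_primary", "rating_outside"])


# ---------------------------------------------------------------------------
# atlas directory layout: one subdirectory per case


def write_atlas_dir(cases: list[AtlasCase], root) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for case in cases:
        d = root / case.case_id
        d.mkdir(exist_ok=True)
        write_volume(case.image, d / "image.nii")
        for name, mask in case.masks.items():
            write_mask(mask, d / f"mask_{name}.nii")
        (d / "provenance.json").write_text(json.dumps(case.provenance, indent=2))


def read_atlas_dir(root) -> list[AtlasCase]:
    from .volumes import read_mask, read_volume

    root = Path(root)
    cases = []
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        img_path = d / "image.nii"
        if not img_path.exists():
            raise FileNotFoundError(f"atlas case {d.name}: missing image.nii")
        image = read_volume(img_path)
        masks = {}
        for mpath in sorted(d.glob("mask_*.nii")):
            name = mpath.stem[len("mask_"):]
            masks[name] = read_mask(mpath, name)
        prov = {}
        pj = d / "provenance.json"
        if pj.exists():
            prov = json.loads(pj.read_text())
        cases.append(AtlasCase(d.name, image, masks, prov))
    if not cases:
        raise FileNotFoundError(f"no atlas cases found under {root}")
    return cases
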