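"""Contour propagation and STAPLE label fusion with a tissue-appearance model.

The propagated per-atlas contours are combined by Simultaneous Truth And
Performance Level Estimation (STAPLE): an EM algorithm that alternates
between estimating the hidden consensus segmentation (E-step) and each
input's sensitivity p_j and specificity q_j (M-step).  The tissue
appearance model is a two-Gaussian intensity likelihood fitted to the
propagated consensus; its voxelwise foreground posterior is blended into
the STAPLE prior with weight lambda (lambda = 0 recovers classic STAPLE).

EM runs only on voxels within a dilated union of the input masks; the vast
uninformative background would otherwise inflate every specificity
estimate toward 1 and wash out the prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, generate_binary_structure, label

from .volumes import (
    BinaryMask,
    DisplacementField,
    ImageVolume,
    RigidTransform3D,
    compose_rigid_and_field,
)

__all__ = [
    "AppearanceModel",
    "FusionConfig",
    "FusionResult",
    "propagate_contours",
    "fit_appearance_model",
    "staple_fuse",
    "majority_vote",
]


@dataclass
class AppearanceModel:
    """Two-Gaussian intensity model: foreground and background tissue classes.

    ``mixing_weight`` (lambda) controls how strongly the appearance
    posterior modulates the STAPLE prior; the variance floor keeps the
    densities proper on (near-)constant images.
    """

    fg_mean: float
    fg_sd: float
    bg_mean: float
    bg_sd: float
    mixing_weight: float = 0.5
    variance_floor: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.mixing_weight <= 1.0:
            raise ValueError("mixing weight must lie in [0, 1]")
        floor_sd = float(np.sqrt(self.variance_floor))
        self.fg_sd = max(float(self.fg_sd), floor_sd)
        self.bg_sd = max(float(self.bg_sd), floor_sd)

    def _logpdf(self, x, mean, sd):
        return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)

    def foreground_posterior(self, intensities, prior: float) -> np.ndarray:
        """P(foreground | intensity) under the two-Gaussian mixture."""
        lf = self._logpdf(np.asarray(intensities, dtype=float), self.fg_mean, self.fg_sd)
        lb = self._logpdf(np.asarray(intensities, dtype=float), self.bg_mean, self.bg_sd)
        num = prior * np.exp(lf - np.maximum(lf, lb))
        den = num + (1 - prior) * np.exp(lb - np.maximum(lf, lb))
        return num / den

    def likelihood_ratio(self, intensity: float) -> float:
        lf = self._logpdf(float(intensity), self.fg_mean, self.fg_sd)
        lb = self._logpdf(float(intensity), self.bg_mean, self.bg_sd)
        return float(np.exp(lf - lb))


@dataclass
class FusionConfig:
    """STAPLE fusion parameters."""

    init_sensitivity: float = 0.99
    init_specificity: float = 0.99
    max_iterations: int = 100
    param_tolerance: float = 1e-6
    prior: float | str = "mean"   # "mean" = mean rater foreground fraction
    appearance_weight: float = 0.5   # lambda; 0 disables the appearance model
    dilation_margin_mm: float = 10.0
    threshold: float = 0.5
    # "largest": keep only the largest connected component; "relative":
    # keep every component at least ``component_min_fraction`` of the
    # largest one (paired organs keep both sides); "none": no filtering.
    component_filter: str = "largest"
    component_min_fraction: float = 0.25


@dataclass
class FusionResult:
    """Fused probability map, mask, and per-input performance estimates."""

    probability: np.ndarray
    fused_mask: BinaryMask
    sensitivities: np.ndarray
    specificities: np.ndarray
    iterations: int
    log_likelihood: list[float] = field(default_factory=list)
    appearance: AppearanceModel | None = None

    def __post_init__(self):
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValueError("posterior probabilities must lie in [0, 1]")


def _dilate_mm(mask: np.ndarray, spacing, margin_mm: float) -> np.ndarray:
    if margin_mm <= 0 or not mask.any():
        return mask.copy()
    it = int(np.ceil(margin_mm / float(min(spacing))))
    return binary_dilation(mask, structure=generate_binary_structure(3, 1), iterations=it)


def propagate_contours(
    atlas_masks: list[BinaryMask | None],
    rigids: list[RigidTransform3D],
    fields: list[DisplacementField],
    structure_name: str = "",
    interpolation: str | None = None,
) -> tuple[list[BinaryMask], list[bool]]:
    """Map each atlas structure mask onto the test grid.

    Every mask is pulled through its case's rigid initialization and
    displacement field in a single resampling pass.  ``None`` entries (the
    structure is absent from that atlas case) yield an empty mask flagged
    missing; fusion excludes them.

    Returns ``(masks_on_test_grid, missing_flags)``.
    """
    if not (len(atlas_masks) == len(rigids) == len(fields)):
        raise ValueError("atlas_masks, rigids and fields must have equal lengths")
    out, missing = [], []
    for mask, t, fld in zip(atlas_masks, rigids, fields):
        if mask is None:
            empty = BinaryMask(
                np.zeros(fld.shape, dtype=bool), fld.spacing.copy(), fld.origin.copy(),
                structure_name,
            )
            out.append(empty)
            missing.append(True)
            continue
        warped = compose_rigid_and_field(mask, t, fld, interpolation=interpolation)
        warped.structure_name = structure_name or mask.structure_name
        out.append(warped)
        missing.append(False)
    return out, missing


def fit_appearance_model(
    image: ImageVolume,
    consensus: np.ndarray,
    mixing_weight: float = 0.5,
    variance_floor: float = 1.0,
    band_margin_mm: float = 10.0,
) -> AppearanceModel:
    """Fit the two-Gaussian tissue model to a soft consensus.

    The foreground Gaussian is the consensus-probability-weighted mean/SD
    of the image; the background Gaussian uses weights (1 - consensus)
    restricted to a dilation band around the consensus support, so it
    describes the tissue immediately surrounding the structure rather than
    the whole scan.
    """
    w_fg = np.asarray(consensus, dtype=float)
    if w_fg.shape != image.shape:
        raise ValueError("consensus must be defined on the image grid")
    if w_fg.sum() <= 0:
        raise ValueError("empty consensus: no propagated foreground to model")
    x = image.data.astype(float)

    def wstats(w):
        sw = w.sum()
        mean = float((w * x).sum() / sw)
        var = float((w * (x - mean) ** 2).sum() / sw)
        return mean, np.sqrt(max(var, 0.0))

    fg_mean, fg_sd = wstats(w_fg)
    band = _dilate_mm(w_fg > 0, image.spacing, band_margin_mm)
    w_bg = np.where(band, 1.0 - w_fg, 0.0)
    if w_bg.sum() <= 0:
        w_bg = np.where(band, 1.0, 0.0)
    bg_mean, bg_sd = wstats(w_bg)
    return AppearanceModel(fg_mean, fg_sd, bg_mean, bg_sd, mixing_weight, variance_floor)


def staple_fuse(
    rater_masks: list[BinaryMask],
    image: ImageVolume | None = None,
    cfg: FusionConfig | None = None,
    missing: list[bool] | None = None,
) -> FusionResult:
    """STAPLE EM fusion of binary segmentations, optionally appearance-aware.

    E-step (per voxel i, decisions D_ij):
        a_i = prod_j p_j^D (1-p_j)^(1-D),  b_i = prod_j (1-q_j)^D q_j^(1-D)
        W_i = a_i pi_i / (a_i pi_i + b_i (1 - pi_i))
    M-step:
        p_j = sum_i W_i D_ij / sum_i W_i
        q_j = sum_i (1-W_i)(1-D_ij) / sum_i (1-W_i)

    The voxel prior pi_i is the global prior pi0 (mean rater foreground
    fraction over the EM region, or the configured constant), blended with
    the appearance posterior when an image is supplied:
    pi_i = (1-lambda) pi0 + lambda P(fg | intensity_i).

    Stops when the largest change of any (p_j, q_j) falls below the
    tolerance or at the iteration cap.  The fused mask thresholds W at 0.5
    (ties count as foreground) and keeps the largest connected component
    when configured.
    """
    cfg = cfg or FusionConfig()
    if missing is not None:
        rater_masks = [m for m, miss in zip(rater_masks, missing) if not miss]
    if len(rater_masks) < 2:
        raise ValueError("STAPLE fusion needs at least 2 non-missing input masks")
    ref = rater_masks[0]
    for m in rater_masks[1:]:
        if not ref.same_geometry(m):
            raise ValueError("all rater masks must share one grid")
    D_full = np.stack([m.data for m in rater_masks], axis=0)  # (J, ni, nj, nk)
    union = D_full.any(axis=0)
    if not union.any():
        raise ValueError("all rater masks are empty")
    region = _dilate_mm(union, ref.spacing, cfg.dilation_margin_mm)
    idx = np.where(region.ravel())[0]
    D = D_full.reshape(len(rater_masks), -1)[:, idx].astype(float)  # (J, N)
    J, N = D.shape

    pi0 = float(D.mean()) if cfg.prior == "mean" else float(cfg.prior)
    pi0 = min(max(pi0, 1e-6), 1 - 1e-6)

    appearance = None
    if image is not None and cfg.appearance_weight > 0:
        if image.shape != ref.shape:
            raise ValueError("image grid must match the rater masks")
        consensus = D_full.mean(axis=0)
        appearance = fit_appearance_model(
            image, consensus, cfg.appearance_weight, band_margin_mm=cfg.dilation_margin_mm
        )
        app_post = appearance.foreground_posterior(image.data.ravel()[idx], pi0)
        pi = (1 - cfg.appearance_weight) * pi0 + cfg.appearance_weight * app_post
    else:
        pi = np.full(N, pi0)
    pi = np.clip(pi, 1e-9, 1 - 1e-9)

    p = np.full(J, cfg.init_sensitivity)
    q = np.full(J, cfg.init_specificity)
    eps = 1e-12
    ll_trace: list[float] = []
    W = np.full(N, pi0)
    iterations = 0
    for iterations in range(1, cfg.max_iterations + 1):
        log_a = (np.log(np.clip(p, eps, 1))[:, None] * D
                 + np.log(np.clip(1 - p, eps, 1))[:, None] * (1 - D)).sum(axis=0)
        log_b = (np.log(np.clip(1 - q, eps, 1))[:, None] * D
                 + np.log(np.clip(q, eps, 1))[:, None] * (1 - D)).sum(axis=0)
        num = np.log(pi) + log_a
        den = np.log(1 - pi) + log_b
        mx = np.maximum(num, den)
        ll_trace.append(float((mx + np.log(np.exp(num - mx) + np.exp(den - mx))).sum()))
        W = 1.0 / (1.0 + np.exp(den - num))

        sw = W.sum()
        snw = (1 - W).sum()
        p_new = (W[None, :] * D).sum(axis=1) / max(sw, eps)
        q_new = ((1 - W)[None, :] * (1 - D)).sum(axis=1) / max(snw, eps)
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < cfg.param_tolerance:
            break

    prob = np.zeros(ref.shape, dtype=float).ravel()
    prob[idx] = W
    prob = prob.reshape(ref.shape)
    fused = prob >= cfg.threshold
    if cfg.component_filter != "none" and fused.any():
        lab, n = label(fused)
        if n > 1:
            sizes = np.bincount(lab.ravel())[1:]
            if cfg.component_filter == "largest":
                fused = lab == (int(np.argmax(sizes)) + 1)
            elif cfg.component_filter == "relative":
                keep = np.where(sizes >= cfg.component_min_fraction * sizes.max())[0] + 1
                fused = np.isin(lab, keep)
            else:
                raise ValueError(f"unknown component filter {cfg.component_filter!r}")
    fused_mask = BinaryMask(fused, ref.spacing.copy(), ref.origin.copy(), ref.structure_name)
    return FusionResult(
        probability=prob,
        fused_mask=fused_mask,
        sensitivities=p,
        specificities=q,
        iterations=iterations,
        log_likelihood=ll_trace,
        appearance=appearance,
    )


def majority_vote(rater_masks: list[BinaryMask]) -> BinaryMask:
    """Voxel foreground iff strictly more than half the raters mark it.

    An exact half-half split is background (documented tie-break).
    """
    if len(rater_masks) < 1:
        raise ValueError("majority vote needs at least 1 mask")
    ref = rater_masks[0]
    votes = np.zeros(ref.shape, dtype=int)
    for m in rater_masks:
        if not ref.same_geometry(m):
            raise ValueError("all masks must share one grid")
        votes += m.data.astype(int)
    out = votes * 2 > len(rater_masks)
    return BinaryMask(out, ref.spacing.copy(), ref.origin.copy(), ref.structure_name)
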