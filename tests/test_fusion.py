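"""Contour propagation, STAPLE fusion and the tissue-appearance model.

The STAPLE checks compare against an independently coded brute-force EM
oracle written with explicit per-voxel/per-rater loops.
"""

import itertools

import numpy as np
import pytest

from atlasseg.fusion import (
    AppearanceModel,
    FusionConfig,
    fit_appearance_model,
    majority_vote,
    propagate_contours,
    staple_fuse,
)
from atlasseg.metrics import dice
from atlasseg.phantom import simulate_raters
from atlasseg.volumes import BinaryMask, DisplacementField, ImageVolume, RigidTransform3D


def mask_from(bits, shape=None):
    arr = np.asarray(bits, dtype=bool)
    if shape is not None:
        arr = arr.reshape(shape)
    if arr.ndim == 1:
        arr = arr.reshape(1, 1, -1)
    return BinaryMask(arr)


def staple_oracle(D, pi0, max_iter=100, tol=1e-6, p0=0.99, q0=0.99):
    """Brute-force STAPLE EM with explicit loops (no shared code paths)."""
    J = len(D)
    N = len(D[0])
    p = [p0] * J
    q = [q0] * J
    W = [0.0] * N
    for _ in range(max_iter):
        for i in range(N):
            a = pi0
            b = 1.0 - pi0
            for j in range(J):
                if D[j][i]:
                    a *= p[j]
                    b *= 1.0 - q[j]
                else:
                    a *= 1.0 - p[j]
                    b *= q[j]
            W[i] = a / (a + b)
        p_new, q_new = [], []
        for j in range(J):
            num_p = sum(W[i] for i in range(N) if D[j][i])
            num_q = sum(1 - W[i] for i in range(N) if not D[j][i])
            p_new.append(num_p / sum(W))
            q_new.append(num_q / sum(1 - w for w in W))
        delta = max(max(abs(a - b) for a, b in zip(p, p_new)),
                    max(abs(a - b) for a, b in zip(q, q_new)))
        p, q = p_new, q_new
        if delta < tol:
            break
    return W, p, q


class TestStapleOracle:
    def test_printed_toy_matches_oracle(self):
        """Three raters on a 1x1x4 grid, flat prior 0.5, no appearance."""
        D = [[1, 1, 0, 0], [1, 1, 1, 0], [1, 0, 0, 0]]
        masks = [mask_from(d) for d in D]
        cfg = FusionConfig(prior=0.5, appearance_weight=0.0, component_filter="none",
                           dilation_margin_mm=100.0)
        res = staple_fuse(masks, None, cfg)
        W, p, q = staple_oracle(D, 0.5)
        assert np.allclose(res.probability.ravel(), W, atol=1e-6)
        assert np.allclose(res.sensitivities, p, atol=1e-6)
        assert np.allclose(res.specificities, q, atol=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_tiny_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        J = int(rng.integers(2, 5))
        N = int(rng.integers(6, 21))
        D = (rng.random((J, N)) < 0.5).astype(int)
        if not D.any() or D.all():
            D[0, 0] = 1
            D[-1, -1] = 0
        masks = [mask_from(row) for row in D]
        cfg = FusionConfig(prior=0.5, appearance_weight=0.0, component_filter="none",
                           dilation_margin_mm=1000.0)
        res = staple_fuse(masks, None, cfg)
        W, p, q = staple_oracle([list(r) for r in D], 0.5)
        assert np.allclose(res.probability.ravel(), W, atol=1e-6)
        assert np.allclose(res.sensitivities, p, atol=1e-6)
        assert np.allclose(res.specificities, q, atol=1e-6)

    def test_log_likelihood_non_decreasing(self, phantom48):
        _, masks = phantom48
        raters = simulate_raters(masks["parotid_glands"], [0.9, 0.8, 0.85], [0.9, 0.95, 0.85],
                                 seed=4)
        res = staple_fuse(raters, None, FusionConfig(appearance_weight=0.0))
        ll = np.asarray(res.log_likelihood)
        assert np.all(np.diff(ll) >= -1e-8)


class TestStapleBehaviour:
    def test_unanimous_raters_fixed_point(self):
        m = np.zeros((7, 7, 7), bool)
        m[2:5, 2:5, 2:5] = True
        masks = [BinaryMask(m.copy()) for _ in range(4)]
        res = staple_fuse(masks, None, FusionConfig(appearance_weight=0.0))
        assert np.array_equal(res.fused_mask.data, m)
        assert np.all(res.sensitivities >= 0.99)
        assert np.all(res.specificities >= 0.99)

    def test_fused_beats_every_rater_on_phantom(self, phantom48):
        img, masks = phantom48
        truth = masks["parotid_glands"]
        raters = simulate_raters(truth, [0.9] * 5, [0.9] * 5, seed=3)
        res = staple_fuse(raters, img, FusionConfig(component_filter="relative"))
        fused_dsc = dice(res.fused_mask, truth)
        for r in raters:
            assert fused_dsc >= dice(r, truth)

    def test_unanimity_respected(self, phantom48):
        """W >= 0.5 wherever all raters mark foreground (with sane p, q)."""
        _, masks = phantom48
        truth = masks["brain"]
        raters = simulate_raters(truth, [0.95, 0.9, 0.92], [0.95, 0.9, 0.93], seed=5)
        res = staple_fuse(raters, None, FusionConfig(appearance_weight=0.0))
        if np.all(res.sensitivities >= 0.5) and np.all(res.specificities >= 0.5):
            everyone = np.logical_and.reduce([r.data for r in raters])
            assert np.all(res.probability[everyone] >= 0.5)

    def test_adversarial_rater_is_tolerated(self, phantom48):
        """A complement-of-truth rater degrades fused DSC by < 0.05."""
        img, masks = phantom48
        truth = masks["parotid_glands"]
        good = simulate_raters(truth, [0.9] * 5, [0.9] * 5, seed=6)
        base = dice(staple_fuse(good, img, FusionConfig()).fused_mask, truth)
        bad = BinaryMask(~truth.data, truth.spacing, truth.origin, truth.structure_name)
        withbad = dice(staple_fuse(good + [bad], img, FusionConfig()).fused_mask, truth)
        assert base - withbad < 0.05

    def test_matches_majority_vote_without_appearance(self):
        """lambda = 0, symmetric raters: fused equals majority vote on all
        3-rater configurations with a clear vote margin."""
        for bits in itertools.product([0, 1], repeat=9):
            D = np.asarray(bits).reshape(3, 3)
            if D.sum() in (0, 9):
                continue
            margins = np.abs(2 * D.sum(axis=0) - 3)
            if margins.min() < 1:
                continue
            masks = [mask_from(row) for row in D]
            cfg = FusionConfig(prior=0.5, appearance_weight=0.0, component_filter="none",
                               dilation_margin_mm=1000.0)
            try:
                res = staple_fuse(masks, None, cfg)
            except ValueError:
                continue
            mv = majority_vote(masks)
            # identical raters give degenerate EM; skip symmetric-failure cases
            if np.all(res.sensitivities > 0.5) and np.all(res.specificities > 0.5):
                assert np.array_equal(res.fused_mask.data, mv.data)

    def test_too_few_masks_rejected(self):
        with pytest.raises(ValueError):
            staple_fuse([mask_from([1, 0, 1])], None, FusionConfig())

    def test_all_empty_rejected(self):
        masks = [mask_from([0, 0, 0]) for _ in range(3)]
        with pytest.raises(ValueError):
            staple_fuse(masks, None, FusionConfig())


class TestMajorityVote:
    def test_identical_masks(self):
        m = mask_from([1, 0, 1, 1])
        out = majority_vote([m, m, m])
        assert np.array_equal(out.data, m.data)

    def test_tie_break_background(self):
        a, b = mask_from([1, 1]), mask_from([1, 0])
        out = majority_vote([a, b])
        assert out.data.ravel().tolist() == [True, False]

    def test_matches_counting_oracle(self, rng):
        masks = [BinaryMask(rng.random((8, 8, 8)) > 0.5) for _ in range(5)]
        out = majority_vote(masks)
        for idx in np.ndindex(8, 8, 8):
            votes = sum(m.data[idx] for m in masks)
            assert out.data[idx] == (votes * 2 > 5)


class TestAppearanceModel:
    def test_exact_means_on_two_constant_regions(self):
        data = np.full((10, 10, 10), -20.0)
        data[3:7, 3:7, 3:7] = 40.0
        img = ImageVolume(data, (2, 2, 2), (0, 0, 0))
        consensus = np.zeros((10, 10, 10))
        consensus[3:7, 3:7, 3:7] = 1.0
        model = fit_appearance_model(img, consensus)
        assert model.fg_mean == pytest.approx(40.0)
        assert model.bg_mean == pytest.approx(-20.0)

    def test_constant_image_no_influence(self):
        img = ImageVolume(np.full((8, 8, 8), 30.0), (2, 2, 2), (0, 0, 0))
        consensus = np.zeros((8, 8, 8))
        consensus[2:5, 2:5, 2:5] = 1.0
        model = fit_appearance_model(img, consensus)
        assert model.likelihood_ratio(30.0) == pytest.approx(1.0)

    def test_phantom_parotid_is_distinguishable(self, phantom48):
        img, masks = phantom48
        consensus = masks["parotid_glands"].data.astype(float)
        model = fit_appearance_model(img, consensus)
        assert model.likelihood_ratio(-40.0) > 1.0   # parotid-like intensity

    def test_empty_consensus_rejected(self):
        img = ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError):
            fit_appearance_model(img, np.zeros((4, 4, 4)))

    def test_invalid_mixing_weight_rejected(self):
        with pytest.raises(ValueError):
            AppearanceModel(0, 1, 0, 1, mixing_weight=1.5)


class TestPropagation:
    def test_identity_propagation(self, phantom48):
        img, masks = phantom48
        atlas_masks = [masks["brain"], masks["eyes"]]
        idt = RigidTransform3D.identity()
        zero = DisplacementField.zeros_like(img)
        out, missing = propagate_contours(atlas_masks, [idt, idt], [zero, zero])
        assert missing == [False, False]
        for orig, prop in zip(atlas_masks, out):
            assert np.array_equal(orig.data, prop.data)

    def test_atlas_size_preserved(self, phantom48):
        """12 atlas cases yield 12 individual contours."""
        img, masks = phantom48
        idt = RigidTransform3D.identity()
        zero = DisplacementField.zeros_like(img)
        out, _ = propagate_contours([masks["brain"]] * 12, [idt] * 12, [zero] * 12)
        assert len(out) == 12

    def test_missing_structure_flagged_and_fusable(self, phantom48):
        img, masks = phantom48
        idt = RigidTransform3D.identity()
        zero = DisplacementField.zeros_like(img)
        inputs = [masks["brain"], None, masks["brain"]]
        out, missing = propagate_contours(inputs, [idt] * 3, [zero] * 3, "brain")
        assert missing == [False, True, False]
        assert out[1].is_empty()
        res = staple_fuse(out, img, FusionConfig(), missing=missing)
        assert dice(res.fused_mask, masks["brain"]) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self, phantom48):
        img, masks = phantom48
        idt = RigidTransform3D.identity()
        zero = DisplacementField.zeros_like(img)
        with pytest.raises(ValueError):
            propagate_contours([masks["brain"]], [idt, idt], [zero])
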