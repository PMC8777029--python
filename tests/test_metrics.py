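"""Dice/HD/ASSD against brute-force set arithmetic over voxel coordinates."""

import itertools

import numpy as np
import pytest

from segan3d.metrics import (BinaryMaskPair, assd, dice, hausdorff,
                             surface_voxels)


# -- brute-force oracle --------------------------------------------------------

def _brute_surface(mask):
    """Voxels with a face-adjacent background neighbour (outside = background)."""
    out = np.zeros_like(mask, dtype=bool)
    for idx in np.argwhere(mask):
        for axis in range(3):
            for d in (-1, 1):
                nb = idx.copy()
                nb[axis] += d
                if np.any(nb < 0) or np.any(nb >= np.array(mask.shape)):
                    out[tuple(idx)] = True
                    break
                if not mask[tuple(nb)]:
                    out[tuple(idx)] = True
                    break
            if out[tuple(idx)]:
                break
    return out


def _brute_distances(a, b, spacing):
    sa = np.argwhere(_brute_surface(a)) * np.array(spacing)
    sb = np.argwhere(_brute_surface(b)) * np.array(spacing)
    d = np.sqrt(((sa[:, None, :] - sb[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1), d.min(axis=0)


def _brute_dice(a, b):
    na, nb = a.sum(), b.sum()
    if na + nb == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / (na + nb)


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.random((4, 4, 4)) > 0.5
        assert dice(BinaryMaskPair(a=m, b=m)) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((3, 3, 3), bool)
        b = np.zeros((3, 3, 3), bool)
        a[0, 0, 0] = b[2, 2, 2] = True
        assert dice(BinaryMaskPair(a=a, b=b)) == 0.0

    def test_half_overlap_hand_value(self):
        a = np.zeros((8, 1, 1), bool)
        b = np.zeros((8, 1, 1), bool)
        a[:4] = True
        b[2:6] = True
        assert dice(BinaryMaskPair(a=a, b=b)) == 0.5  # |A|=4, |B|=4, |A∩B|=2

    def test_empty_mask_conventions(self):
        e = np.zeros((2, 2, 2), bool)
        f = np.ones((2, 2, 2), bool)
        assert dice(BinaryMaskPair(a=e, b=e)) == 1.0
        assert dice(BinaryMaskPair(a=e, b=f)) == 0.0

    def test_symmetry(self, rng):
        a, b = rng.random((4, 4, 4)) > 0.5, rng.random((4, 4, 4)) > 0.5
        assert dice(BinaryMaskPair(a=a, b=b)) == dice(BinaryMaskPair(a=b, b=a))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            BinaryMaskPair(a=np.zeros((2, 2, 2)), b=np.zeros((3, 2, 2)))


class TestSurfaceDistances:
    def test_identical_masks_have_zero_distances(self, rng):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        p = BinaryMaskPair(a=m, b=m)
        assert hausdorff(p) == 0.0
        assert assd(p) == 0.0

    def test_single_voxel_pair_distance(self):
        a = np.zeros((5, 1, 1), bool)
        b = np.zeros((5, 1, 1), bool)
        a[0] = b[3] = True
        p = BinaryMaskPair(a=a, b=b)
        assert hausdorff(p) == pytest.approx(3.0)
        assert assd(p) == pytest.approx(3.0)

    def test_hausdorff_symmetry(self, rng):
        a = rng.random((4, 4, 4)) > 0.4
        b = rng.random((4, 4, 4)) > 0.4
        a[0, 0, 0] = b[1, 1, 1] = True  # keep non-empty
        assert hausdorff(BinaryMaskPair(a=a, b=b)) == \
            hausdorff(BinaryMaskPair(a=b, b=a))

    def test_empty_mask_is_an_error(self):
        e = np.zeros((2, 2, 2), bool)
        f = np.ones((2, 2, 2), bool)
        for fn in (hausdorff, assd):
            with pytest.raises(ValueError):
                fn(BinaryMaskPair(a=e, b=f))

    def test_assd_never_exceeds_hausdorff(self, rng):
        for _ in range(20):
            a = rng.random((4, 3, 3)) > 0.5
            b = rng.random((4, 3, 3)) > 0.5
            if not (a.any() and b.any()):
                continue
            p = BinaryMaskPair(a=a, b=b)
            assert assd(p) <= hausdorff(p) + 1e-12

    def test_spacing_linearity(self, rng):
        a = rng.random((4, 4, 3)) > 0.5
        b = rng.random((4, 4, 3)) > 0.5
        a[0, 0, 0] = b[1, 1, 1] = True
        p1 = BinaryMaskPair(a=a, b=b, spacing=(1, 1, 1))
        p3 = BinaryMaskPair(a=a, b=b, spacing=(3, 3, 3))
        assert hausdorff(p3) == pytest.approx(3 * hausdorff(p1))
        assert assd(p3) == pytest.approx(3 * assd(p1))
        assert dice(p3) == dice(p1)


class TestOracleEquivalence:
    def test_exhaustive_small_masks(self):
        # all pairs of non-trivial 3x1x1 masks against brute force
        masks = [np.array(bits, bool).reshape(3, 1, 1)
                 for bits in itertools.product([0, 1], repeat=3)]
        for a, b in itertools.product(masks, masks):
            p = BinaryMaskPair(a=a, b=b)
            assert dice(p) == _brute_dice(a, b)
            if a.any() and b.any():
                dab, dba = _brute_distances(a, b, (1, 1, 1))
                assert hausdorff(p) == pytest.approx(max(dab.max(), dba.max()))
                assert assd(p) == pytest.approx(np.concatenate([dab, dba]).mean())

    @pytest.mark.parametrize("seed", range(8))
    def test_random_masks_with_anisotropic_spacing(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((4, 4, 3)) > 0.5
        b = rng.random((4, 4, 3)) > 0.5
        a[2, 2, 1] = b[1, 2, 1] = True
        spacing = tuple(rng.uniform(0.5, 3.0, 3))
        p = BinaryMaskPair(a=a, b=b, spacing=spacing)
        assert np.array_equal(surface_voxels(a), _brute_surface(a))
        dab, dba = _brute_distances(a, b, spacing)
        assert hausdorff(p) == pytest.approx(max(dab.max(), dba.max()))
        assert assd(p) == pytest.approx(np.concatenate([dab, dba]).mean())
        assert dice(p) == _brute_dice(a, b)
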