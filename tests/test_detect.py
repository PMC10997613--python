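"""Egg/feces detection, damage segmentation, and patch machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitescan.detect import (SignificanceLevels, detect_eggs, detect_feces,
                             dilate_mask, make_patches, segment_damage,
                             split_dataset)
from mitescan.leaves import order_leaves, segment_leaves
from mitescan.scan_io import ABAXIAL, ADAXIAL
from mitescan.synthetic import PlantSpec, generate_plant
from mitescan.validate import match_objects


def leaf_crops(plant):
    """(side, crop, region, truth-leaf-index) for every leaf of a fixture."""
    out = []
    for key in ("ab", "ad"):
        scan = plant[key]
        for reg in order_leaves(segment_leaves(scan)):
            r0, c0, r1, c1 = reg.bbox
            out.append((scan.side, scan.pixels[r0:r1, c0:c1], reg, scan.um_per_px,
                        (r0, c0)))
    return out


class TestSignificanceLevels:
    @pytest.mark.parametrize("eggs,feces", [(0.79, 0.75), (0.96, 0.75),
                                            (0.9, 0.49), (0.9, 0.96)])
    def test_levels_outside_legal_range_rejected(self, eggs, feces):
        with pytest.raises(ValueError):
            SignificanceLevels(eggs=eggs, black_feces=feces)


class TestDetectEggs:
    def test_finds_every_egg_with_unit_precision(self, default_plant):
        truth = default_plant["truth"]
        tp = fp = fn = 0
        pred_by_side = {"abaxial": [], "adaxial": []}
        for side, crop, reg, um, (r0, c0) in leaf_crops(default_plant):
            dets = detect_eggs(crop, reg.mask, side, um, leaf_index=reg.leaf_index)
            pred_by_side[side] += [(d.center[0] + r0, d.center[1] + c0)
                                   for d in dets]
        for side, pred in pred_by_side.items():
            um = default_plant["ab"].um_per_px
            true = np.array([o.center for o in truth.objects_of("egg", side)]
                            ).reshape(-1, 2)
            m, up, ut = match_objects(np.array(pred).reshape(-1, 2), true,
                                      2 * 62.5 / um)
            tp, fp, fn = tp + len(m), fp + len(up), fn + len(ut)
        assert fn == 0  # perfect recall on the default noise level
        assert tp / (tp + fp) >= 0.9

    def test_bubbles_alone_yield_no_detections(self):
        n = 3
        spec = PlantSpec(n_leaves=n, leaf_lengths_mm=[8.0, 9.0, 10.0],
                         eggs_per_leaf=[0] * n, feces_per_leaf=[0] * n,
                         damage_fraction_per_leaf=[0.0] * n,
                         bubble_density=10.0, seed=21)
        _, ad, truth = generate_plant(spec)
        assert len(truth.objects_of("bubble")) >= 10
        for reg in segment_leaves(ad):
            r0, c0, r1, c1 = reg.bbox
            dets = detect_eggs(ad.pixels[r0:r1, c0:c1], reg.mask, ADAXIAL,
                               ad.um_per_px)
            assert dets == []

    def test_count_monotone_in_level(self, default_plant):
        for side, crop, reg, um, _ in leaf_crops(default_plant)[:4]:
            counts = [len(detect_eggs(crop, reg.mask, side, um,
                                      SignificanceLevels(eggs=lv)))
                      for lv in (0.8, 0.85, 0.9, 0.95)]
            assert counts == sorted(counts, reverse=True)

    def test_empty_mask_rejected(self, default_plant):
        _, crop, reg, um, _ = leaf_crops(default_plant)[0]
        with pytest.raises(ValueError, match="mask"):
            detect_eggs(crop, np.zeros_like(reg.mask), ABAXIAL, um)

    def test_missing_scale_rejected(self, default_plant):
        _, crop, reg, um, _ = leaf_crops(default_plant)[0]
        with pytest.raises(ValueError, match="um_per_px"):
            detect_eggs(crop, reg.mask, ABAXIAL, 0.0)


class TestDetectFeces:
    def test_counts_and_area_recovered(self, default_plant):
        truth = default_plant["truth"]
        n_det = area_det = area_true = 0.0
        n_true = len(truth.objects_of("feces"))
        for side, crop, reg, um, _ in leaf_crops(default_plant):
            dets = detect_feces(crop, reg.mask, side, um)
            n_det += len(dets)
            area_det += sum(d.area_mm2 for d in dets)
        area_true = truth.plant_totals["feces_area_mm2"]
        assert n_det == n_true
        assert area_det == pytest.approx(area_true, rel=0.10)

    def test_clean_leaf_has_no_detections(self, clean_plant):
        for side, crop, reg, um, _ in leaf_crops(clean_plant):
            assert detect_feces(crop, reg.mask, side, um) == []

    def test_count_monotone_in_level(self, default_plant):
        for side, crop, reg, um, _ in leaf_crops(default_plant)[:4]:
            lo = len(detect_feces(crop, reg.mask, side, um,
                                  SignificanceLevels(black_feces=0.5)))
            hi = len(detect_feces(crop, reg.mask, side, um,
                                  SignificanceLevels(black_feces=0.95)))
            assert hi <= lo

    def test_detections_lie_on_the_leaf(self, default_plant):
        for side, crop, reg, um, _ in leaf_crops(default_plant):
            for d in (detect_feces(crop, reg.mask, side, um)
                      + detect_eggs(crop, reg.mask, side, um)):
                r, c = int(d.center[0]), int(d.center[1])
                assert reg.mask[r, c]


class TestSegmentDamage:
    def test_single_patch_area_recovered(self):
        spec = PlantSpec(n_leaves=1, leaf_lengths_mm=[12.0], eggs_per_leaf=[0],
                         feces_per_leaf=[0],
                         damage_fraction_per_leaf=[0.0244],  # ~1 mm² on this blade
                         damage_side_overlap=1.0, bubble_density=0.0, seed=3)
        ab, _, truth = generate_plant(spec)
        true_area = float(truth.per_leaf.query("side == 'abaxial'")
                          ["damage_area_mm2"].iloc[0])
        assert 0.8 <= true_area <= 1.3  # sanity on the constructed patch
        reg = segment_leaves(ab)[0]
        r0, c0, r1, c1 = reg.bbox
        dm = segment_damage(ab.pixels[r0:r1, c0:c1], reg.mask, ABAXIAL, ab.um_per_px)
        assert dm.area_mm2 == pytest.approx(true_area, rel=0.15)

    def test_pristine_leaf_zero_area(self, clean_plant):
        for side, crop, reg, um, _ in leaf_crops(clean_plant):
            dm = segment_damage(crop, reg.mask, side, um)
            assert dm.area_mm2 == 0.0

    def test_mask_clipped_to_leaf(self, default_plant):
        for side, crop, reg, um, _ in leaf_crops(default_plant):
            dm = segment_damage(crop, reg.mask, side, um)
            assert not np.any(dm.mask & ~reg.mask)

    def test_deterministic(self, default_plant):
        side, crop, reg, um, _ = leaf_crops(default_plant)[2]
        a = segment_damage(crop, reg.mask, side, um)
        b = segment_damage(crop, reg.mask, side, um)
        assert np.array_equal(a.mask, b.mask)


def brute_force_dilate(mask, iterations):
    """Independent oracle: per-pixel 8-neighbourhood expansion."""
    m = mask.astype(bool).copy()
    for _ in range(iterations):
        out = m.copy()
        H, W = m.shape
        for r in range(H):
            for c in range(W):
                if m[r, c]:
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < H and 0 <= cc < W:
                                out[rr, cc] = True
        m = out
    return m


class TestPatches:
    def test_256_square_gives_four_patches(self, rng):
        img = rng.integers(0, 255, (256, 256, 3)).astype(np.uint8)
        patches = make_patches(img, np.zeros((256, 256), bool))
        assert len(patches) == 4
        for p, _ in patches:
            assert p.shape == (128, 128, 3)
            assert abs(p.mean()) < 1e-9
            assert np.allclose(p.std(axis=(0, 1)), 1.0)

    def test_remainders_padded_by_reflection(self, rng):
        img = rng.integers(0, 255, (130, 260, 3)).astype(np.uint8)
        patches = make_patches(img, np.zeros((130, 260), bool))
        assert len(patches) == 2 * 3  # ceil(130/128) x ceil(260/128)

    def test_zero_mask_stays_zero_after_dilation(self):
        m = np.zeros((64, 64), bool)
        assert not dilate_mask(m, 5).any()

    def test_five_iterations_grow_pixel_to_11_square(self):
        m = np.zeros((31, 31), bool)
        m[15, 15] = True
        got = dilate_mask(m, 5)
        expect = brute_force_dilate(m, 5)
        assert np.array_equal(got, expect)
        assert got.sum() == 11 * 11

    @given(st.integers(0, 4), st.integers(0, 63), st.integers(0, 63))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_dilation_matches_brute_force_oracle(self, iters, r, c):
        m = np.zeros((64, 64), bool)
        m[r, c] = True
        assert np.array_equal(dilate_mask(m, iters), brute_force_dilate(m, iters))


class TestSplitDataset:
    def test_hundred_items_follow_80_10_10(self):
        tr, va, te = split_dataset(list(range(100)))
        assert (len(tr), len(va), len(te)) == (80, 10, 10)

    def test_ten_items(self):
        tr, va, te = split_dataset(list(range(10)))
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    def test_deterministic_given_seed(self):
        a = split_dataset(list(range(57)), seed=9)
        b = split_dataset(list(range(57)), seed=9)
        assert a == b

    @given(st.integers(3, 200), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, derandomize=True)
    def test_partition_is_disjoint_and_exhaustive(self, n, seed):
        items = list(range(n))
        tr, va, te = split_dataset(items, seed=seed)
        assert sorted(tr + va + te) == items
        assert len(tr) >= len(va) >= 0 and len(te) >= 0

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2])

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(10)), ratios=(0.5, 0.2, 0.2))
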