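"""Damage merging, physical-unit bookkeeping, and manual corrections."""

import numpy as np
import pytest

from mitescan.detect import DamageMask, Detection
from mitescan.leaves import LeafPair, LeafRegion
from mitescan.quantify import (CorrectionEdit, apply_corrections, merge_damage,
                               quantify_leaf, summarize_plant)
from mitescan.scan_io import ABAXIAL, ADAXIAL

UM = 21.17
PX_MM2 = (UM / 1000.0) ** 2
W = 400  # plate width in px


def square_region(side, r0, c0, size=40, idx=0):
    return LeafRegion(side=side, mask=np.ones((size, size), bool),
                      bbox=(r0, c0, r0 + size, c0 + size),
                      centroid=(r0 + size / 2, c0 + size / 2),
                      area_mm2=size * size * PX_MM2, um_per_px=UM, leaf_index=idx)


def mirrored_pair(size=40, r0=10, c0=30, idx=0):
    """An abaxial square leaf and its exactly mirrored adaxial twin."""
    ab = square_region(ABAXIAL, r0, c0, size, idx)
    ad = square_region(ADAXIAL, r0, W - c0 - size, size, idx)
    return LeafPair(leaf_index=idx, abaxial=ab, adaxial=ad, iou=1.0)


def dmask(pixels_rc, side, size=40, idx=0):
    m = np.zeros((size, size), bool)
    for r, c in pixels_rc:
        m[r, c] = True
    return DamageMask(leaf_index=idx, side=side, mask=m, bbox=(0, 0, size, size),
                      area_mm2=float(len(pixels_rc)) * PX_MM2)


class TestMergeDamage:
    def test_union_matches_set_arithmetic(self):
        # A = 10 px, B' = 8 px, overlap 5 px -> union 13 px
        pair = mirrored_pair()
        A = [(5, c) for c in range(10)]
        # adaxial mask in the adaxial (mirrored) image: col -> size-1-col
        B_plate = [(5, c) for c in range(5, 13)]
        B = [(r, 40 - 1 - c) for r, c in B_plate]
        area, merged = merge_damage(dmask(A, ABAXIAL), dmask(B, ADAXIAL),
                                    pair, W, UM)
        assert np.count_nonzero(merged) == 13
        assert area == pytest.approx(13 * PX_MM2)

    def test_empty_adaxial_returns_abaxial(self):
        pair = mirrored_pair()
        A = [(5, c) for c in range(10)]
        area, _ = merge_damage(dmask(A, ABAXIAL), dmask([], ADAXIAL), pair, W, UM)
        assert area == pytest.approx(10 * PX_MM2)

    def test_idempotent_for_identical_masks(self):
        pair = mirrored_pair()
        A = [(r, c) for r in range(3, 8) for c in range(6, 12)]
        B = [(r, 40 - 1 - c) for r, c in A]
        area, _ = merge_damage(dmask(A, ABAXIAL), dmask(B, ADAXIAL), pair, W, UM)
        assert area == pytest.approx(len(A) * PX_MM2)

    def test_commutative_in_contributed_pixels(self):
        pair = mirrored_pair()
        A = [(5, c) for c in range(10)]
        B_plate = [(9, c) for c in range(4)]
        B = [(r, 39 - c) for r, c in B_plate]
        a1, _ = merge_damage(dmask(A, ABAXIAL), dmask(B, ADAXIAL), pair, W, UM)
        # swap the pixel sets between sides
        a2, _ = merge_damage(dmask(B_plate, ABAXIAL),
                             dmask([(r, 39 - c) for r, c in A], ADAXIAL),
                             pair, W, UM)
        assert a1 == pytest.approx(a2)

    def test_unpaired_leaf_passes_through(self):
        pair = LeafPair(leaf_index=0, abaxial=square_region(ABAXIAL, 10, 30),
                        adaxial=None, unpaired=True)
        A = [(5, c) for c in range(10)]
        area, _ = merge_damage(dmask(A, ABAXIAL), None, pair, W, UM)
        assert area == pytest.approx(10 * PX_MM2)

    def test_registration_recovers_union_on_real_leaves(self, default_plant):
        # the generator's exact per-leaf merged areas are the oracle
        from mitescan.leaves import order_leaves, pair_sides, segment_leaves
        from mitescan.detect import segment_damage
        ab = order_leaves(segment_leaves(default_plant["ab"]))
        ad = order_leaves(segment_leaves(default_plant["ad"]))
        pairs = pair_sides(ab, ad, default_plant["ad"].shape[1])
        truth = default_plant["truth"]
        got = true = 0.0
        for p in pairs:
            masks = {}
            for side, reg, scan in ((ABAXIAL, p.abaxial, default_plant["ab"]),
                                    (ADAXIAL, p.adaxial, default_plant["ad"])):
                r0, c0, r1, c1 = reg.bbox
                masks[side] = segment_damage(scan.pixels[r0:r1, c0:c1], reg.mask,
                                             side, scan.um_per_px)
            area, _ = merge_damage(masks[ABAXIAL], masks[ADAXIAL], p,
                                   default_plant["ad"].shape[1],
                                   default_plant["ab"].um_per_px)
            got += area
        true = truth.plant_totals["damage_area_mm2"]
        assert got == pytest.approx(true, rel=0.10)


class TestQuantifyLeaf:
    def make_detections(self):
        mk = lambda klass, side, i, area=0.0: Detection(
            klass=klass, box=(0, 0, 2, 2), confidence=1.0, side=side,
            leaf_index=0, area_mm2=area, object_id=f"{klass}_{side}_{i}")
        return ([mk("egg", ABAXIAL, i) for i in range(4)]
                + [mk("egg", ADAXIAL, 9)]
                + [mk("black_feces", ABAXIAL, i, 0.01) for i in range(3)]
                + [mk("black_feces", ADAXIAL, i + 5, 0.02) for i in range(2)])

    def test_counts_and_areas_per_side(self):
        pair = mirrored_pair()
        lr = quantify_leaf(pair, self.make_detections(), {}, UM, W)
        assert lr.egg_count == {ABAXIAL: 4, ADAXIAL: 1}
        assert lr.feces_count == {ABAXIAL: 3, ADAXIAL: 2}
        assert lr.feces_area_mm2[ABAXIAL] == pytest.approx(0.03)
        assert lr.feces_area_mm2[ADAXIAL] == pytest.approx(0.04)

    def test_area_scales_with_pixel_size(self):
        pair = mirrored_pair()
        A = [(5, c) for c in range(10)]
        lr1 = quantify_leaf(pair, [], {ABAXIAL: dmask(A, ABAXIAL)}, UM, W)
        bigger = dmask(A, ABAXIAL)
        bigger.area_mm2 *= 4  # the DamageMask itself carries the area
        lr2 = quantify_leaf(pair, [], {ABAXIAL: bigger}, 2 * UM, W)
        assert lr2.damage_area_mm2[ABAXIAL] == pytest.approx(
            4 * lr1.damage_area_mm2[ABAXIAL])

    def test_missing_scale_rejected(self):
        with pytest.raises(ValueError):
            quantify_leaf(mirrored_pair(), [], {}, 0.0, W)


class TestSummarizePlant:
    def leaf(self, idx, eggs_ab):
        lr_pair = mirrored_pair(idx=idx)
        dets = [Detection(klass="egg", box=(0, 0, 2, 2), confidence=1.0,
                          side=ABAXIAL, leaf_index=idx, object_id=f"e{idx}_{i}")
                for i in range(eggs_ab)]
        return quantify_leaf(lr_pair, dets, {}, UM, W), dets

    def test_oviposition_rate_is_eggs_per_female(self):
        leaves, dets = zip(*(self.leaf(i, 40) for i in range(3)))
        plant = summarize_plant(leaves, n_females=10,
                                detections=[d for ds in dets for d in ds])
        assert plant.totals["egg_count"] == 120
        assert plant.oviposition_rate == pytest.approx(12.0)

    def test_additional_eggs_enter_the_total_only(self):
        leaves, dets = zip(*(self.leaf(i, 23) for i in range(5)))
        plant = summarize_plant(leaves, additional_eggs=5,
                                detections=[d for ds in dets for d in ds])
        assert plant.totals["egg_count"] == 120
        assert sum(lr.total("egg_count") for lr in plant.leaf_results) == 115

    def test_no_leaves_all_zero(self):
        plant = summarize_plant([])
        assert plant.totals["egg_count"] == 0
        assert plant.oviposition_rate == 0.0

    def test_invalid_females_rejected(self):
        with pytest.raises(ValueError):
            summarize_plant([], n_females=0)


class TestCorrections:
    def plant(self):
        leaves, dets = zip(*(TestSummarizePlant().leaf(i, 3) for i in range(2)))
        return summarize_plant(leaves, detections=[d for ds in dets for d in ds])

    def test_add_two_remove_one_nets_plus_one(self):
        plant = self.plant()
        before = plant.totals["egg_count"]
        edits = [
            CorrectionEdit(action="add", klass="egg", side=ABAXIAL, leaf_index=0,
                           box=(1, 1, 5, 5)),
            CorrectionEdit(action="add", klass="egg", side=ADAXIAL, leaf_index=1,
                           box=(2, 2, 6, 6)),
            CorrectionEdit(action="remove", object_id="e0_0"),
        ]
        out = apply_corrections(plant, edits, UM)
        assert out.totals["egg_count"] == before + 1
        assert len(out.audit_log) == 3
        # conservation: totals still equal leaf sums
        assert out.totals["egg_count"] == sum(
            lr.total("egg_count") for lr in out.leaf_results)

    def test_edit_then_inverse_restores_counts(self):
        plant = self.plant()
        added = apply_corrections(plant, [CorrectionEdit(
            action="add", klass="egg", side=ABAXIAL, leaf_index=0, box=(1, 1, 5, 5))])
        new_id = [d.object_id for d in added.detections if d.manual][0]
        restored = apply_corrections(added, [CorrectionEdit(
            action="remove", object_id=new_id)])
        assert restored.totals == plant.totals

    def test_removing_unknown_id_names_it(self):
        with pytest.raises(KeyError, match="ghost"):
            apply_corrections(self.plant(), [CorrectionEdit(action="remove",
                                                            object_id="ghost")])

    def test_original_plant_untouched(self):
        plant = self.plant()
        before = plant.totals["egg_count"]
        apply_corrections(plant, [CorrectionEdit(
            action="add", klass="egg", side=ABAXIAL, leaf_index=0, box=(0, 0, 2, 2))])
        assert plant.totals["egg_count"] == before

    def test_malformed_edits_rejected(self):
        with pytest.raises(ValueError):
            CorrectionEdit(action="add")  # no box
        with pytest.raises(ValueError):
            CorrectionEdit(action="remove")  # no id
        with pytest.raises(ValueError):
            CorrectionEdit(action="replace", object_id="x")
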