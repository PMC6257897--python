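"""Fragment merging, cytoplasm sampling, and the 5-class decision tree."""

import math

import numpy as np
import pytest

import leukocount as lk
from leukocount.classification import DEFAULT_PROTOTYPES
from leukocount.synthetic import NUCLEUS_COLOR

from conftest import labeled_from_mask


def region_stub(label, xy, area=3000, solidity=0.95):
    return lk.NucleusRegion(
        label=label,
        centroid_xy=xy,
        area_px=area,
        perimeter_px=200.0,
        solidity=solidity,
        eccentricity=0.3,
        bbox=(0, 0, 1, 1),
    )


def union_find_groups(points, threshold):
    """Brute-force union-find oracle over the proximity graph."""
    parent = list(range(len(points)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            d = math.hypot(
                points[i][0] - points[j][0], points[i][1] - points[j][1]
            )
            if d < threshold:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(points)):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


REF_SHAPE = (1200, 1600)


class TestCentroidDistance:
    def test_3_4_5(self):
        assert lk.centroid_distance((0, 0), (3, 4)) == 5.0

    def test_identical_points(self):
        assert lk.centroid_distance((7.5, -2.0), (7.5, -2.0)) == 0.0

    def test_descriptor_table_pair(self):
        # the two lobed-nucleus objects of the worked descriptor table
        d = lk.centroid_distance((266, 1054), (866, 394))
        assert d == pytest.approx(math.sqrt(600**2 + 660**2))
        assert d == pytest.approx(891.96, abs=0.01)


class TestMergeFragments:
    def cfg(self):
        return lk.ClassifierConfig()

    def test_pair_below_threshold_merges(self):
        regs = [region_stub(1, (100, 100)), region_stub(2, (100, 214))]
        groups = lk.merge_fragments(regs, self.cfg(), REF_SHAPE)
        assert len(groups) == 1 and len(groups[0]) == 2

    def test_pair_at_threshold_does_not_merge(self):
        regs = [region_stub(1, (100, 100)), region_stub(2, (100, 215))]
        assert len(lk.merge_fragments(regs, self.cfg(), REF_SHAPE)) == 2

    def test_distant_descriptor_table_objects_stay_separate(self):
        regs = [region_stub(1, (266, 1054)), region_stub(2, (866, 394))]
        assert len(lk.merge_fragments(regs, self.cfg(), REF_SHAPE)) == 2

    def test_transitive_chain(self):
        regs = [
            region_stub(1, (0, 0)),
            region_stub(2, (100, 0)),
            region_stub(3, (200, 0)),
        ]
        groups = lk.merge_fragments(regs, self.cfg(), REF_SHAPE)
        assert len(groups) == 1 and len(groups[0]) == 3

    def test_threshold_scales_with_linear_dimension(self):
        # 300x400 is a quarter of the linear size -> threshold 28.75
        near = [region_stub(1, (10, 10)), region_stub(2, (10, 38))]
        far = [region_stub(1, (10, 10)), region_stub(2, (10, 40))]
        assert len(lk.merge_fragments(near, self.cfg(), (300, 400))) == 1
        assert len(lk.merge_fragments(far, self.cfg(), (300, 400))) == 2

    def test_partition_and_order_invariance(self):
        rng = np.random.default_rng(17)
        pts = [tuple(p) for p in rng.uniform(0, 800, size=(15, 2))]
        regs = [region_stub(i + 1, p) for i, p in enumerate(pts)]
        groups = lk.merge_fragments(regs, self.cfg(), REF_SHAPE)
        labels = sorted(r.label for g in groups for r in g)
        assert labels == list(range(1, 16))  # every region in exactly one group
        shuffled = [regs[i] for i in rng.permutation(15)]
        groups2 = lk.merge_fragments(shuffled, self.cfg(), REF_SHAPE)
        as_sets = lambda gs: {frozenset(r.label for r in g) for g in gs}
        assert as_sets(groups) == as_sets(groups2)

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(0, 13))
            pts = [tuple(p) for p in rng.uniform(0, 1500, size=(n, 2))]
            regs = [region_stub(i + 1, p) for i, p in enumerate(pts)]
            groups = lk.merge_fragments(regs, lk.ClassifierConfig(), REF_SHAPE)
            got = {frozenset(r.label - 1 for r in g) for g in groups}
            assert got == union_find_groups(pts, 115.0)


class TestCytoplasmSampling:
    def test_uniform_background_recovered_exactly(self):
        px = np.full((80, 80, 3), (200, 180, 190), dtype=np.uint8)
        px[30:50, 30:50] = (80, 40, 110)
        img = lk.SmearImage(pixels=px)
        lm = labeled_from_mask(px[:, :, 0] == 80)
        regs = lk.region_descriptors(lm)
        (color,) = lk.sample_cytoplasm_color(img, lm, [regs], 3, 10)
        assert color == (200.0, 180.0, 190.0)

    def test_synthetic_eosinophil_halo_recovered(self):
        cell = lk.make_cell(lk.WBCClass.EOSINOPHIL, (200.0, 200.0))
        recipe = lk.SmearRecipe(cells=(cell,), seed=3)
        img, labels, _ = lk.generate_smear(recipe)
        lm = labeled_from_mask(labels > 0)
        regs = lk.region_descriptors(lm)
        groups = lk.merge_fragments(regs, lk.ClassifierConfig(), img.shape)
        (color,) = lk.sample_cytoplasm_color(img, lm, groups, 3, 15)
        expect = DEFAULT_PROTOTYPES[lk.WBCClass.EOSINOPHIL]
        assert np.abs(np.array(color) - np.array(expect)).max() < 5

    def test_adjacent_cells_exclude_each_other(self):
        """Two nuclei with different halos close enough that naive annuli
        would overlap; exclusion keeps each sample on its own halo."""
        px = np.full((120, 260, 3), (228, 200, 192), dtype=np.uint8)
        # halos
        yy, xx = np.mgrid[0:120, 0:260]
        left = (yy - 60) ** 2 + (xx - 80) ** 2 <= 45**2
        right = (yy - 60) ** 2 + (xx - 180) ** 2 <= 45**2
        px[left] = (170, 190, 230)
        px[right] = (235, 140, 120)
        ln = (yy - 60) ** 2 + (xx - 80) ** 2 <= 25**2
        rn = (yy - 60) ** 2 + (xx - 180) ** 2 <= 25**2
        px[ln | rn] = (80, 40, 110)
        img = lk.SmearImage(pixels=px)
        lm = labeled_from_mask(ln | rn)
        regs = lk.region_descriptors(lm)
        groups = [[r] for r in regs]
        colors = lk.sample_cytoplasm_color(img, lm, groups, 3, 15)
        by_x = sorted(zip((r.centroid_xy[0] for r in regs), colors))
        assert np.abs(np.array(by_x[0][1]) - (170, 190, 230)).max() < 2
        assert np.abs(np.array(by_x[1][1]) - (235, 140, 120)).max() < 2


class TestClassifyCell:
    def cfg(self):
        return lk.ClassifierConfig()

    def test_compact_region_with_lymphocyte_halo(self):
        det = lk.classify_cell(
            [region_stub(1, (100, 100), solidity=0.965)],
            DEFAULT_PROTOTYPES[lk.WBCClass.LYMPHOCYTE],
            self.cfg(),
        )
        assert det.wbc_class == lk.WBCClass.LYMPHOCYTE
        assert det.rule_trace[0].startswith("mononuclear")

    @pytest.mark.parametrize(
        "solidity,proto,expected",
        [
            (0.778, lk.WBCClass.NEUTROPHIL, lk.WBCClass.NEUTROPHIL),
            (0.777, lk.WBCClass.EOSINOPHIL, lk.WBCClass.EOSINOPHIL),
        ],
    )
    def test_lobed_twins_separated_by_cytoplasm_tonality(
        self, solidity, proto, expected
    ):
        """Neutrophil and eosinophil nuclei are nearly identical in shape;
        only the halo color separates them."""
        det = lk.classify_cell(
            [region_stub(1, (50, 50), solidity=solidity)],
            DEFAULT_PROTOTYPES[proto],
            self.cfg(),
        )
        assert det.wbc_class == expected
        assert det.rule_trace[0].startswith("polymorphonuclear")

    def test_merged_fragments_become_one_neutrophil(self):
        regs = [
            region_stub(1, (100, 100), solidity=0.97),
            region_stub(2, (100, 190), solidity=0.97),
        ]
        groups = lk.merge_fragments(regs, self.cfg(), REF_SHAPE)
        assert len(groups) == 1
        det = lk.classify_cell(
            groups[0], DEFAULT_PROTOTYPES[lk.WBCClass.NEUTROPHIL], self.cfg()
        )
        assert det.wbc_class == lk.WBCClass.NEUTROPHIL
        assert det.n_lobes == 2

    def test_area_tiebreaker_splits_near_tie_by_nucleus_size(self):
        cfg = lk.ClassifierConfig(use_area_tiebreaker=True)
        midpoint = tuple(
            (a + b) / 2
            for a, b in zip(
                DEFAULT_PROTOTYPES[lk.WBCClass.LYMPHOCYTE],
                DEFAULT_PROTOTYPES[lk.WBCClass.MONOCYTE],
            )
        )
        small = lk.classify_cell(
            [region_stub(1, (10, 10), area=2100, solidity=0.97)], midpoint, cfg
        )
        big = lk.classify_cell(
            [region_stub(1, (10, 10), area=3200, solidity=0.97)], midpoint, cfg
        )
        assert small.wbc_class == lk.WBCClass.LYMPHOCYTE
        assert big.wbc_class == lk.WBCClass.MONOCYTE
        assert any(t.startswith("area_tiebreak") for t in big.rule_trace)

    def test_area_tiebreaker_inert_on_clear_colors(self):
        for cls in (lk.WBCClass.LYMPHOCYTE, lk.WBCClass.MONOCYTE):
            for area in (2100, 3200):
                with_tb = lk.classify_cell(
                    [region_stub(1, (10, 10), area=area, solidity=0.97)],
                    DEFAULT_PROTOTYPES[cls],
                    lk.ClassifierConfig(use_area_tiebreaker=True),
                )
                assert with_tb.wbc_class == cls

    def test_deterministic(self):
        args = (
            [region_stub(1, (10, 10), solidity=0.8)],
            (200.0, 180.0, 190.0),
            self.cfg(),
        )
        a = lk.classify_cell(*args)
        b = lk.classify_cell(*args)
        assert a == b


class TestDifferentialCount:
    def test_empty(self):
        counts = lk.differential_count([])
        assert counts == {c: 0 for c in lk.WBCClass}

    @staticmethod
    def _detection(i, cls):
        return lk.CellDetection(
            region_labels=(i,),
            group_centroid_xy=(float(i), 0.0),
            combined_area_px=3000,
            min_solidity=0.9,
            n_lobes=1,
            cytoplasm_color=(0.0, 0.0, 0.0),
            wbc_class=cls,
            rule_trace=("stub",),
        )

    def test_first_individual_tool_row(self):
        row = {
            lk.WBCClass.NEUTROPHIL: 21,
            lk.WBCClass.LYMPHOCYTE: 14,
            lk.WBCClass.BASOPHIL: 2,
            lk.WBCClass.MONOCYTE: 1,
            lk.WBCClass.EOSINOPHIL: 3,
        }
        dets = [
            self._detection(i, cls)
            for i, cls in enumerate(c for c, n in row.items() for _ in range(n))
        ]
        counts = lk.differential_count(dets)
        assert counts == row
        assert sum(counts.values()) == len(dets)


class TestTranslationInvariance:
    def test_shifted_scene_same_classes(self):
        cells = (
            lk.make_cell(lk.WBCClass.NEUTROPHIL, (300.0, 300.0), lobe_angle_deg=40.0),
            lk.make_cell(lk.WBCClass.MONOCYTE, (800.0, 600.0)),
        )
        base = lk.SmearRecipe(cells=cells, seed=8)
        shifted = lk.SmearRecipe(
            cells=tuple(
                lk.CellSpec(
                    **{
                        **c.__dict__,
                        "center_xy": (c.center_xy[0] + 17, c.center_xy[1] + 17),
                    }
                )
                for c in cells
            ),
            seed=8,
        )
        res_a = lk.analyze_image(lk.generate_smear(base)[0])
        res_b = lk.analyze_image(lk.generate_smear(shifted)[0])
        cls_a = sorted(d.wbc_class.name for d in res_a.detections)
        cls_b = sorted(d.wbc_class.name for d in res_b.detections)
        assert cls_a == cls_b == ["MONOCYTE", "NEUTROPHIL"]
        # detections moved with the scene
        xa = sorted(d.group_centroid_xy[0] for d in res_a.detections)
        xb = sorted(d.group_centroid_xy[0] for d in res_b.detections)
        assert np.allclose(np.array(xb) - np.array(xa), 17, atol=1.5)
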