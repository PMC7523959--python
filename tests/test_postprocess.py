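"""Rule-based refinement: merge / recover / expand and their composition."""

import numpy as np
import pytest

from fpfseg.postprocess import (
    PostprocessConfig,
    expand_cells_to_nuclei,
    merge_cells_sharing_nucleus,
    postprocess,
    recover_uncovered_regions,
)

SHAPE = (24, 24)


def rect(y0, y1, x0, x1, shape=SHAPE):
    m = np.zeros(shape, bool)
    m[y0:y1, x0:x1] = True
    return m


class TestMergeSharedNucleus:
    def test_no_shared_nucleus_is_noop(self, toy_set):
        cells = toy_set(SHAPE, [rect(2, 8, 2, 8), rect(12, 18, 12, 18)])
        nuclei = toy_set(SHAPE, [rect(4, 6, 4, 6), rect(14, 16, 14, 16)])
        out = merge_cells_sharing_nucleus(cells, nuclei)
        assert len(out) == 2
        assert sorted(m.sum() for m in out.masks) == sorted(m.sum() for m in cells.masks)

    def test_two_cells_one_nucleus_merge(self, toy_set):
        a, b = rect(2, 10, 2, 10), rect(2, 10, 10, 18)
        nucleus = rect(4, 8, 8, 12)       # straddles both
        out = merge_cells_sharing_nucleus(toy_set(SHAPE, [a, b]), toy_set(SHAPE, [nucleus]))
        assert len(out) == 1
        assert out.masks[0].sum() == (a | b).sum()

    def test_transitive_chain(self, toy_set):
        a, b, c = rect(2, 8, 0, 8), rect(2, 8, 8, 16), rect(2, 8, 16, 24)
        n1 = rect(4, 6, 6, 10)            # bridges a-b
        n2 = rect(4, 6, 14, 18)           # bridges b-c
        out = merge_cells_sharing_nucleus(toy_set(SHAPE, [a, b, c]), toy_set(SHAPE, [n1, n2]))
        assert len(out) == 1
        assert out.masks[0].sum() == (a | b | c).sum()


class TestRecoverRegions:
    CFG = PostprocessConfig(min_region_area=4, foreground_threshold=100.0,
                            morphology_radius=0)

    def test_full_coverage_is_noop(self, toy_set):
        img = np.where(rect(2, 10, 2, 10), 300.0, 0.0)
        cells = toy_set(SHAPE, [rect(2, 10, 2, 10)])
        out = recover_uncovered_regions(img, cells, self.CFG)
        assert len(out) == 1 and np.array_equal(out.masks[0], cells.masks[0])

    def test_rule_a_append_to_unique_neighbor(self, toy_set):
        img = np.where(rect(2, 10, 2, 14), 300.0, 0.0)
        cells = toy_set(SHAPE, [rect(2, 10, 2, 10)])      # misses columns 10-13
        out = recover_uncovered_regions(img, cells, self.CFG)
        assert len(out) == 1
        assert out.masks[0].sum() == rect(2, 10, 2, 14).sum()

    def test_rule_b_drop_bridging_region(self, toy_set):
        img = np.where(rect(2, 10, 2, 22), 300.0, 0.0)
        cells = toy_set(SHAPE, [rect(2, 10, 2, 8), rect(2, 10, 16, 22)])
        out = recover_uncovered_regions(img, cells, self.CFG)
        assert len(out) == 2
        assert sorted(m.sum() for m in out.masks) == sorted(m.sum() for m in cells.masks)

    def test_rule_c_new_instance(self, toy_set):
        img = np.where(rect(2, 8, 2, 8) | rect(14, 20, 14, 20), 300.0, 0.0)
        cells = toy_set(SHAPE, [rect(2, 8, 2, 8)])
        out = recover_uncovered_regions(img, cells, self.CFG)
        assert len(out) == 2

    def test_small_region_discarded(self, toy_set):
        img = np.where(rect(2, 8, 2, 8) | rect(20, 21, 20, 22), 300.0, 0.0)
        cells = toy_set(SHAPE, [rect(2, 8, 2, 8)])
        out = recover_uncovered_regions(img, cells, self.CFG)   # 2 px < min 4
        assert len(out) == 1


class TestExpandToNuclei:
    def test_covered_nuclei_noop(self, toy_set):
        cells = toy_set(SHAPE, [rect(2, 10, 2, 10)])
        nuclei = toy_set(SHAPE, [rect(4, 8, 4, 8)])
        out = expand_cells_to_nuclei(cells, nuclei)
        assert np.array_equal(out.masks[0], cells.masks[0])

    def test_half_covered_nucleus_grows_cell(self, toy_set):
        cells = toy_set(SHAPE, [rect(2, 10, 2, 10)])
        nucleus = rect(4, 8, 8, 14)       # half outside
        out = expand_cells_to_nuclei(cells, toy_set(SHAPE, [nucleus]))
        assert len(out) == 1
        assert (out.masks[0] & nucleus).sum() == nucleus.sum()

    def test_orphan_nucleus_becomes_cell(self, toy_set):
        cells = toy_set(SHAPE, [rect(2, 8, 2, 8)])
        nucleus = rect(16, 20, 16, 20)
        out = expand_cells_to_nuclei(cells, toy_set(SHAPE, [nucleus]))
        assert len(out) == 2
        assert any(np.array_equal(m, nucleus) for m in out.masks)


class TestComposition:
    CFG = PostprocessConfig(min_region_area=4, foreground_threshold=100.0,
                            morphology_radius=0)

    def _fixtures(self, toy_set):
        cases = []
        # consistent prediction
        img = np.where(rect(2, 10, 2, 10), 300.0, 0.0)
        cases.append((toy_set(SHAPE, [rect(2, 10, 2, 10)]),
                      toy_set(SHAPE, [rect(4, 8, 4, 8)]), img))
        # split cell over one nucleus
        img = np.where(rect(2, 10, 2, 18), 300.0, 0.0)
        cases.append((toy_set(SHAPE, [rect(2, 10, 2, 10), rect(2, 10, 10, 18)]),
                      toy_set(SHAPE, [rect(4, 8, 8, 12)]), img))
        # empty predictions, two nuclei
        img = np.zeros(SHAPE)
        cases.append((toy_set(SHAPE, []),
                      toy_set(SHAPE, [rect(2, 6, 2, 6), rect(12, 16, 12, 16)]), img))
        return cases

    def test_split_cell_merges(self, toy_set):
        cells, nuclei, img = self._fixtures(toy_set)[1]
        out = postprocess(cells, nuclei, img, self.CFG)
        assert len(out) == len(cells) - 1

    def test_empty_predictions_get_one_cell_per_nucleus(self, toy_set):
        cells, nuclei, img = self._fixtures(toy_set)[2]
        out = postprocess(cells, nuclei, img, self.CFG)
        assert len(out) == 2

    def test_idempotence_and_coverage(self, toy_set):
        for cells, nuclei, img in self._fixtures(toy_set):
            once = postprocess(cells, nuclei, img, self.CFG)
            twice = postprocess(once, nuclei, img, self.CFG)
            assert len(once) == len(twice)
            assert np.array_equal(
                sum(m.astype(int) for m in once.masks) if len(once) else np.zeros(SHAPE, int),
                sum(m.astype(int) for m in twice.masks) if len(twice) else np.zeros(SHAPE, int),
            )
            # every nucleus pixel covered by exactly one cell
            if len(once):
                cover = sum(m.astype(int) for m in once.masks)
                for nm in nuclei.masks:
                    assert (cover[nm] == 1).all()
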