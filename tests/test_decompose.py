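"""Plate/rod segmentation and volumetric reconstruction."""

import heapq

import numpy as np
import pytest

from conftest import VOX, line_volume, sheet_volume, strut_volume
from itsmorph import decompose as _dcmod  # noqa: F401
import importlib
dc = importlib.import_module("itsmorph.decompose")
sk = importlib.import_module("itsmorph.skeleton")
from itsmorph.volume import BinaryVolume


def decompose_mask(mask, **kw):
    return dc.decompose(BinaryVolume(np.asarray(mask, bool), VOX), **kw)


class TestSplitting:
    def test_single_line_is_one_rod(self):
        lm = decompose_mask(line_volume(10))
        assert [r.type for r in lm.records] == ["rod"]
        assert lm.junction_counts == {"RR": 0, "PR": 0, "PP": 0}

    def test_crossing_lines_merge_into_two_collinear_rods(self):
        m = np.zeros((5, 21, 21), bool)
        m[2, 10, 1:20] = True
        m[2, 1:20, 10] = True
        lm = decompose_mask(m)
        assert sorted(r.type for r in lm.records) == ["rod", "rod"]
        assert lm.junction_counts["RR"] == 1

    def test_t_junction_keeps_bar_and_stub_separate(self):
        m = np.zeros((5, 21, 21), bool)
        m[2, 10, 1:20] = True
        m[2, 1:10, 10] = True
        lm = decompose_mask(m)
        assert sorted(r.type for r in lm.records) == ["rod", "rod"]
        assert lm.junction_counts["RR"] == 1

    def test_sheet_with_attached_line_is_plate_plus_rod(self):
        m = np.zeros((14, 21, 21), bool)
        m[2, 1:20, 1:20] = True
        m[3:12, 10, 10] = True
        lm = decompose_mask(m)
        assert sorted(r.type for r in lm.records) == ["plate", "rod"]
        assert lm.junction_counts["PR"] == 1

    def test_non_collinear_arms_stay_separate(self):
        # struts meeting at ~53 degrees must not merge (threshold 30)
        c = (12, 12, 12)
        m = np.zeros((24, 24, 24), bool)
        for a in [(2, 4, 8), (2, 20, 8), (22, 12, 18), (2, 12, 18)]:
            m |= strut_volume((24, 24, 24), a, c, 1.25)
        lm = decompose_mask(m)
        assert sum(1 for r in lm.records if r.type == "rod") == 4
        assert lm.junction_counts["RR"] == 1


class TestReconstruction:
    def test_partition_of_bone_phase(self, phantom_battery):
        for m in phantom_battery[:10]:
            lm = decompose_mask(m)
            assert np.array_equal(lm.label_map > 0, m)
            assert sum(r.n_voxels for r in lm.records) == int(m.sum())

    def test_solid_slab_single_plate_full_tissue_fraction(self):
        m = np.zeros((10, 24, 24), bool)
        m[3:6, 2:22, 2:22] = True
        lm = decompose_mask(m)
        assert [r.type for r in lm.records] == ["plate"]
        assert lm.records[0].n_voxels == int(m.sum())

    def test_two_parallel_rods_recover_their_cylinders(self):
        m = np.zeros((20, 20, 20), bool)
        zz, yy, xx = np.indices((20, 20, 20))
        c1 = (yy - 5) ** 2 + (xx - 5) ** 2 <= 1.6**2
        c2 = (yy - 14) ** 2 + (xx - 14) ** 2 <= 1.6**2
        m = c1 | c2
        lm = decompose_mask(m)
        assert sorted(r.type for r in lm.records) == ["rod", "rod"]
        vols = sorted(r.n_voxels for r in lm.records)
        assert vols == sorted([int(c1.sum()), int(c2.sum())])
        # each label exactly one of the original cylinders
        lab1 = lm.label_map == 1
        assert np.array_equal(lab1, c1) or np.array_equal(lab1, c2)

    def test_labels_match_independent_geodesic_oracle(self):
        # Bellman-Ford relaxation oracle: per-segment geodesic distance
        # maps, label = argmin (ties -> lower ID)
        m = sheet_volume(12, 12, pad=3)
        m[3:12, 9, 9] = True  # plate + rod
        vol = BinaryVolume(m, VOX)
        skel = sk.skeletonize(vol)
        segs = dc.split_skeleton_into_trabeculae(skel)
        lm = dc.reconstruct_volumes(vol, segs)

        offs = dc._OFFS
        steps = dc._STEP
        ids = sorted(set(segs.label_skel[segs.label_skel > 0]))
        dmaps = []
        for sid in ids:
            d = np.full(m.shape, np.inf)
            d[segs.label_skel == sid] = 0.0
            changed = True
            while changed:
                changed = False
                for c in np.argwhere(m):
                    z, y, x = c
                    best = d[z, y, x]
                    for k in range(len(offs)):
                        nz_, ny_, nx_ = c + offs[k]
                        if not (
                            0 <= nz_ < m.shape[0]
                            and 0 <= ny_ < m.shape[1]
                            and 0 <= nx_ < m.shape[2]
                        ):
                            continue
                        if m[nz_, ny_, nx_] and d[nz_, ny_, nx_] + steps[k] < best - 1e-12:
                            best = d[nz_, ny_, nx_] + steps[k]
                    if best < d[z, y, x]:
                        d[z, y, x] = best
                        changed = True
            dmaps.append(d)
        dstack = np.stack(dmaps)
        order = np.argsort(dstack, axis=0, kind="stable")[0]
        oracle = np.where(m, np.array(ids)[order], 0)
        assert np.array_equal(lm.label_map, oracle)

    def test_skeleton_outside_bone_rejected(self):
        m = line_volume(8)
        vol = BinaryVolume(m, VOX)
        skel = sk.skeletonize(vol)
        segs = dc.split_skeleton_into_trabeculae(skel)
        shrunk = m.copy()
        shrunk[1, 1, 4] = False
        with pytest.raises(ValueError, match="subset"):
            dc.reconstruct_volumes(BinaryVolume(shrunk, VOX), segs)


class TestRecords:
    def test_thickness_of_odd_slab_within_half_voxel(self):
        m = np.zeros((11, 26, 26), bool)
        m[4:7, 2:24, 2:24] = True  # 3 voxels thick
        lm = decompose_mask(m)
        rec = lm.records[0]
        assert rec.type == "plate"
        assert rec.thickness_mm == pytest.approx(3 * VOX, abs=0.5 * VOX)

    def test_rod_length_counts_both_endpoints(self):
        lm = decompose_mask(line_volume(10))
        assert lm.records[0].length_mm == pytest.approx(10 * VOX, abs=1e-9)

    def test_plate_orientation_is_sheet_normal(self):
        lm = decompose_mask(sheet_volume(14, 14))
        n = np.abs(np.asarray(lm.records[0].orientation))
        np.testing.assert_allclose(n, [1, 0, 0], atol=1e-6)  # (z, y, x): normal = z

    def test_rod_orientation_is_chain_axis(self):
        lm = decompose_mask(line_volume(12))
        a = np.abs(np.asarray(lm.records[0].orientation))
        np.testing.assert_allclose(a, [0, 0, 1], atol=1e-6)  # along x

    def test_determinism(self):
        m = strut_volume((20, 20, 20), (1, 3, 3), (18, 16, 12), 1.4)
        m[10, 5:15, 5:15] = True  # add a sheet
        a = decompose_mask(m)
        b = decompose_mask(m)
        assert np.array_equal(a.label_map, b.label_map)
        assert a.junction_counts == b.junction_counts
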