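"""Image segmentation operators against geometric/analytic oracles."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from cardiopheno import segmentation as seg
from conftest import disk_image

PX = 0.65  # um / pixel


def _scene(channels, pixel_size=PX):
    return seg.ImageScene(channels=channels, pixel_size_um=pixel_size)


# ---------------------------------------------------------------------------
# Sliding parabola
# ---------------------------------------------------------------------------

def brute_force_parabola_envelope(img, curvature):
    """O(N^2) reference: sup of paraboloid translates fitting under img."""
    h, w = img.shape
    yy, xx = np.indices((h, w))
    pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    depth = d2 / (2.0 * curvature)       # parabola depth between pixel pairs
    f = img.ravel()
    apex = (f[None, :] + depth).min(axis=1)      # highest apex per translate
    env = (apex[:, None] - depth).max(axis=0)    # envelope = max of translates
    return env.reshape(h, w)


class TestSlidingParabola:
    def test_constant_image_maps_to_zero(self):
        out = seg.subtract_background(np.full((32, 32), 7.5), curvature=10)
        np.testing.assert_allclose(out, 0.0)

    def test_envelope_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        yy, xx = np.indices((64, 64), dtype=float)
        img = 0.5 * xx + 5 * np.sin(xx / 2.0) + rng.normal(0, 0.2, (64, 64))
        env = seg.sliding_parabola_envelope(img, curvature=10)
        oracle = brute_force_parabola_envelope(img, curvature=10)
        np.testing.assert_allclose(env, oracle, atol=1e-9)

    def test_ramp_removed_grating_survives(self):
        xx = np.indices((48, 48), dtype=float)[1]
        grating = 3.0 * np.sin(2 * np.pi * xx / 6.0)
        img = 0.5 * xx + grating + 10.0
        out = seg.subtract_background(img, curvature=10)
        # interior only: near the border the tangent paraboloid has no room
        mid = np.s_[:, 8:40]
        slope = np.polyfit(xx[mid][0], out[mid].mean(axis=0), 1)[0]
        assert abs(slope) < 0.05  # the 0.5/px ramp is gone
        # ... while the oscillation survives in the residual
        assert np.ptp(out[mid]) > 3.0
        r = np.corrcoef(out[mid].ravel(), grating[mid].ravel())[0, 1]
        assert r > 0.8

    def test_large_curvature_limit_is_global_min(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(10, 20, (24, 24))
        out = seg.subtract_background(img, curvature=1e9)
        np.testing.assert_allclose(out, img - img.min(), atol=1e-6)

    def test_opening_is_idempotent(self):
        # the morphological opening satisfies open(open(f)) = open(f)
        # exactly; repeated background subtraction is therefore stable
        # up to the residual's own envelope (small for sharp texture)
        rng = np.random.default_rng(2)
        img = ndi.gaussian_filter(rng.uniform(0, 100, (48, 48)), 2)
        env = seg.sliding_parabola_envelope(img, curvature=10)
        env2 = seg.sliding_parabola_envelope(env, curvature=10)
        np.testing.assert_allclose(env2, env, atol=1e-9)
        xx = np.indices((48, 48), dtype=float)[1]
        sharp = 5.0 * np.sin(2 * np.pi * xx / 4.0) + 5.0
        once = seg.subtract_background(sharp, curvature=10)
        twice = seg.subtract_background(once, curvature=10)
        assert np.abs(twice - once).max() < 0.15 * np.ptp(once)

    def test_invalid_curvature(self):
        with pytest.raises(ValueError):
            seg.subtract_background(np.zeros((4, 4)), curvature=0)


# ---------------------------------------------------------------------------
# find_nuclei
# ---------------------------------------------------------------------------

class TestFindNuclei:
    def test_blank_image_yields_no_objects(self):
        labels = seg.find_nuclei(np.zeros((64, 64)), PX)
        assert labels.max() == 0

    def test_separated_disks_counted_and_localized(self):
        r_px = 5.0 / PX
        centers = [(20 + 30 * i, 20 + 30 * j)
                   for i in range(5) for j in range(10)]
        img = disk_image((180, 320), centers, r_px)
        labels = seg.find_nuclei(img, PX)
        assert labels.max() == 50
        found = np.array(ndi.center_of_mass(labels > 0, labels,
                                            range(1, 51)))
        expect = np.array(sorted(centers))
        found = found[np.lexsort((found[:, 1], found[:, 0]))]
        assert np.abs(found - expect).max() <= 1.0

    def test_overlapping_pair_is_split(self):
        r_px = 5.0 / PX
        gap = 1.7 * r_px  # centres closer than 2r: 30% radius overlap
        img = disk_image((80, 80), [(40, 30), (40, 30 + gap)], r_px)
        labels = seg.find_nuclei(img, PX)
        assert labels.max() == 2

    def test_low_contrast_object_removed(self):
        # bright nucleus sets the robust max; a second object sits just
        # above the global threshold but barely above its own pedestal,
        # so its shell contrast is < 0.10 and it must be rejected
        img = disk_image((80, 160), [(40, 40)], 5.0 / PX, level=1000.0)
        img += disk_image((80, 160), [(40, 120)], 12.0 / PX, level=350.0)
        img += disk_image((80, 160), [(40, 120)], 5.0 / PX, level=75.0)
        labels = seg.find_nuclei(img, PX)
        assert labels.max() == 1
        # and the survivor is the bright one
        assert labels[40, int(40)] == 1


# ---------------------------------------------------------------------------
# select_nuclei / measure_regions
# ---------------------------------------------------------------------------

def _ellipse(shape, cy, cx, ry, rx):
    yy, xx = np.indices(shape, dtype=float)
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


class TestMeasureAndSelect:
    def test_uniform_region_mean_and_sd(self):
        labels = _ellipse((60, 60), 30, 30, 10, 10).astype(np.int32)
        chan = np.where(labels > 0, 42.0, 0.0)
        scene = _scene({"dapi": chan})
        rec = seg.measure_regions(scene, labels)
        assert rec["mean_dapi"].iloc[0] == pytest.approx(42.0)
        assert rec["sd_dapi"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_disk_roundness_high(self):
        labels = _ellipse((80, 80), 40, 40, 15, 15).astype(np.int32)
        rec = seg.measure_regions(_scene({"d": labels * 1.0}), labels)
        assert rec["roundness"].iloc[0] >= 0.9

    def test_disk_rounder_than_ellipse(self):
        disk = _ellipse((90, 90), 45, 45, 16, 16)
        ellipse = _ellipse((90, 90), 45, 45, 8, 32)  # same area, elongated
        labels = np.zeros((90, 180), dtype=np.int32)
        labels[:, :90][disk] = 1
        labels[:, 90:][ellipse] = 2
        rec = seg.measure_regions(_scene({"d": labels * 1.0}), labels)
        r = rec.set_index("label")["roundness"]
        assert r[1] > r[2]

    def test_select_keeps_round_drops_elongated_and_border(self):
        shape = (120, 260)
        labels = np.zeros(shape, dtype=np.int32)
        # round disk, area ~100 um^2 -> kept
        labels[_ellipse(shape, 60, 40, 5.7 / PX, 5.7 / PX)] = 1
        # 5:1 ellipse, area ~120 um^2 -> roundness < 0.6, removed
        a = np.sqrt(120 / np.pi / 5)
        labels[_ellipse(shape, 60, 120, a / PX, 5 * a / PX)] = 2
        # border-clipped disk -> removed
        labels[_ellipse(shape, 0, 220, 9.0 / PX, 9.0 / PX)] = 3
        scene = _scene({"d": labels * 1.0})
        rec = seg.measure_regions(scene, labels)
        assert rec.set_index("label").loc[2, "roundness"] < 0.6
        out = seg.select_nuclei(labels, rec)
        kept = set(np.unique(out)) - {0}
        assert len(kept) == 1
        assert (out > 0).sum() == (labels == 1).sum()


# ---------------------------------------------------------------------------
# cluster_nuclei_to_cells
# ---------------------------------------------------------------------------

class TestClustering:
    def _pair(self, gap_um):
        shape = (100, 140)
        r = 6.0 / PX
        labels = np.zeros(shape, dtype=np.int32)
        labels[_ellipse(shape, 50, 40, r, r)] = 1
        cx2 = 40 + 2 * r + gap_um / PX
        labels[_ellipse(shape, 50, cx2, r, r)] = 2
        return labels

    def test_close_pair_forms_one_binucleated_cell(self):
        cell_labels, cells = seg.cluster_nuclei_to_cells(self._pair(3.0), PX)
        assert len(cells) == 1
        assert cells[0].nuclei_count == 2

    def test_distant_pair_stays_two_cells(self):
        cell_labels, cells = seg.cluster_nuclei_to_cells(self._pair(8.0), PX)
        assert len(cells) == 2
        assert all(c.nuclei_count == 1 for c in cells)

    def test_zero_distance_no_merging(self):
        _, cells = seg.cluster_nuclei_to_cells(self._pair(3.0), PX,
                                               distance_um=0.0)
        assert len(cells) == 2

    def test_small_cluster_dropped_by_area(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[_ellipse((40, 40), 20, 20, 3.0 / PX, 3.0 / PX)] = 1  # ~28 um^2
        _, cells = seg.cluster_nuclei_to_cells(labels, PX)
        assert cells == []


# ---------------------------------------------------------------------------
# find_cytoplasm / perinuclear ring
# ---------------------------------------------------------------------------

class TestCytoplasm:
    def test_single_cell_claims_suprathreshold_blob(self):
        shape = (100, 100)
        blob = _ellipse(shape, 50, 50, 30, 30)
        seeds = _ellipse(shape, 50, 50, 8, 8).astype(np.int32)
        scene = _scene({"ch647": np.where(blob, 500.0, 0.0)})
        cyto = seg.find_cytoplasm(scene, seeds, "ch647")
        got = cyto == 1
        assert (got & blob).sum() / blob.sum() > 0.98
        # spill is confined to the smoothing halo at the blob edge
        halo = ndi.binary_dilation(blob, iterations=5)
        assert (got & ~halo).sum() == 0

    def test_zero_channel_degenerates_to_seeds(self):
        shape = (60, 60)
        seeds = _ellipse(shape, 30, 30, 8, 8).astype(np.int32)
        scene = _scene({"ch647": np.zeros(shape)})
        cyto = seg.find_cytoplasm(scene, seeds, "ch647")
        np.testing.assert_array_equal(cyto > 0, seeds > 0)

    def test_adjacent_cells_partition_the_blob(self):
        shape = (80, 160)
        blob = _ellipse(shape, 40, 80, 35, 75)
        seeds = np.zeros(shape, dtype=np.int32)
        seeds[_ellipse(shape, 40, 45, 8, 8)] = 1
        seeds[_ellipse(shape, 40, 115, 8, 8)] = 2
        scene = _scene({"ch647": np.where(blob, 500.0, 0.0)})
        cyto = seg.find_cytoplasm(scene, seeds, "ch647")
        r1, r2 = cyto == 1, cyto == 2
        assert not (r1 & r2).any()
        assert ((r1 | r2) & blob).sum() / blob.sum() > 0.98
        assert (r1 & (seeds == 1)).sum() == (seeds == 1).sum()

    def test_missing_channel_is_an_error(self):
        scene = _scene({"ch647": np.zeros((10, 10))})
        with pytest.raises(KeyError):
            seg.find_cytoplasm(scene, np.ones((10, 10), np.int32), "nope")


class TestPerinuclearRing:
    def test_annulus_area_matches_analytic(self):
        r = 20.0
        mask = _ellipse((120, 120), 60, 60, r, r)
        ring = seg.perinuclear_ring(mask, expand_fraction=0.75)
        r_eq = np.sqrt(mask.sum() / np.pi)
        expected = np.pi * r_eq ** 2 * (1.75 ** 2 - 1.0)
        assert ring.sum() == pytest.approx(expected, rel=0.05)

    def test_zero_expansion_is_empty_with_warning(self, caplog):
        mask = _ellipse((40, 40), 20, 20, 8, 8)
        with caplog.at_level("WARNING"):
            ring = seg.perinuclear_ring(mask, expand_fraction=0.0)
        assert not ring.any()
        assert "empty perinuclear ring" in caplog.text

    def test_ring_never_intersects_nucleus(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            cy, cx = rng.uniform(25, 40, 2)
            mask = _ellipse((64, 64), cy, cx, rng.uniform(4, 9),
                            rng.uniform(4, 9))
            ring = seg.perinuclear_ring(mask, 0.75)
            assert not (ring & mask).any()


# ---------------------------------------------------------------------------
# Scale invariance and end-to-end counting
# ---------------------------------------------------------------------------

def test_um_quantities_invariant_under_2x_upsampling():
    shape = (120, 120)
    dapi = disk_image(shape, [(60, 60)], 6.0 / PX)
    up = np.kron(dapi, np.ones((2, 2)))
    lab1 = seg.find_nuclei(dapi, PX)
    lab2 = seg.find_nuclei(up, PX / 2)
    a1 = (lab1 > 0).sum() * PX ** 2
    a2 = (lab2 > 0).sum() * (PX / 2) ** 2
    assert a2 == pytest.approx(a1, rel=0.05)


def test_nucleus_count_recovery_on_dense_scene(mixed_scene,
                                               mixed_segmentation):
    scene, truth = mixed_scene
    n_true = int(truth["nuclei_count"].sum())
    n_found = int(mixed_segmentation.nuclei_labels.max())
    # tolerance covers border-removed objects at the field edge
    assert abs(n_found - n_true) / n_true < 0.05


def test_cell_nuclei_counts_match_generator(mixed_scene, mixed_segmentation):
    scene, truth = mixed_scene
    found = sorted(c.nuclei_count for c in mixed_segmentation.cells)
    expected = sorted(truth["nuclei_count"])
    # distributions agree closely even if border cells differ
    assert abs(len(found) - len(expected)) <= 3
    assert abs(np.mean(found) - np.mean(expected)) < 0.1
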