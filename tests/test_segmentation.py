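"""Seed generation and the three seeded segmentation backends."""

import numpy as np
import pytest

from kneeus.localization import BoneSurface
from kneeus.segmentation import (
    GCParams,
    RWParams,
    SeedError,
    SeedParams,
    generate_seeds,
    graphcut_segment,
    random_walker,
    segment,
    watershed_segment,
    _postprocess,
)

SHAPE = (160, 120)


def _flat_surface(row, n_cols=SHAPE[1], n_rows=SHAPE[0]):
    rows = np.full(n_cols, row, dtype=int)
    return BoneSurface(
        rows=rows, confidence=np.ones(n_cols), n_rows=n_rows, path_rows=rows.copy()
    )


class TestSeeds:
    def test_mkt_offsets_in_pixels(self):
        # MKT 2.16 mm at 0.15 mm/px: fg round(1.08/0.15)=7, bg round(4.32/0.15)=29
        p = SeedParams()
        assert p.fg_offset_px == 7
        assert p.bg_offset_px == 29

    def test_flat_surface_fg_rows(self):
        seeds = generate_seeds(_flat_surface(100), SHAPE, SeedParams(dilate_px=0))
        fg_rows = np.nonzero(seeds.fg.any(axis=1))[0]
        assert list(fg_rows) == [93]
        assert seeds.fg[93].all()
        bg_rows = np.nonzero(seeds.bg.any(axis=1))[0]
        assert set(bg_rows) == {71, 129}

    def test_fg_strictly_above_surface(self):
        seeds = generate_seeds(_flat_surface(100), SHAPE, SeedParams())
        fg_rows = np.nonzero(seeds.fg.any(axis=1))[0]
        assert fg_rows.max() < 100

    def test_clipping_near_top_keeps_foreground(self):
        seeds = generate_seeds(_flat_surface(3), SHAPE, SeedParams())
        assert seeds.fg.any()
        assert seeds.bg.any()
        assert not (seeds.fg & seeds.bg).any()

    def test_all_sentinel_raises(self):
        n_cols, n_rows = SHAPE[1], SHAPE[0]
        surface = BoneSurface(
            rows=np.full(n_cols, n_rows, dtype=int),
            confidence=np.zeros(n_cols),
            n_rows=n_rows,
        )
        with pytest.raises(SeedError, match="no bone surface"):
            generate_seeds(surface, SHAPE, SeedParams())

    def test_gap_bridging_fills_sentinel_columns(self):
        rows = np.full(SHAPE[1], 100, dtype=int)
        rows[40:80] = SHAPE[0]  # sentinel gap
        surface = BoneSurface(rows=rows, confidence=np.ones(SHAPE[1]), n_rows=SHAPE[0])
        bridged = generate_seeds(surface, SHAPE, SeedParams(bridge_gaps=True))
        gappy = generate_seeds(surface, SHAPE, SeedParams(bridge_gaps=False))
        assert bridged.fg[:, 40:80].any()
        assert not gappy.fg[:, 40:80].any()


class TestRandomWalker:
    def test_uniform_image_linear_probability(self):
        img = np.full((60, 30), 0.5)
        labels = np.zeros((60, 30), dtype=np.uint8)
        labels[10] = 1
        labels[50] = 2
        from kneeus.segmentation import SeedImage

        res = random_walker(img, SeedImage(labels))
        prob = res.probabilities
        col = prob[:, 15]
        assert col[10] == 1.0 and col[50] == 0.0
        interior = col[11:50]
        expected = np.linspace(1, 0, 41)[1:-1]
        assert np.allclose(interior, expected, atol=0.02)
        assert abs(col[30] - 0.5) < 0.02

    def test_probabilities_harmonic_off_seeds(self):
        rng = np.random.default_rng(0)
        img = rng.random((40, 30))
        labels = np.zeros((40, 30), dtype=np.uint8)
        labels[5] = 1
        labels[35] = 2
        from kneeus.segmentation import SeedImage

        res = random_walker(img, SeedImage(labels), RWParams())
        prob = res.probabilities
        flat = img.ravel()
        n_rows, n_cols = img.shape
        grad2_max = 0.0
        # recompute the weight normalizer exactly as the implementation
        from kneeus.segmentation import _lattice_edges

        ei, ej = _lattice_edges(img.shape)
        grad2_max = ((flat[ei] - flat[ej]) ** 2).max()
        beta = RWParams().rw_beta
        r, c = 20, 15  # interior unlabeled pixel
        w_sum, acc = 0.0, 0.0
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            w = np.exp(-beta * (img[r, c] - img[r + dr, c + dc]) ** 2 / grad2_max)
            w_sum += w
            acc += w * prob[r + dr, c + dc]
        assert prob[r, c] == pytest.approx(acc / w_sum, abs=1e-8)

    def test_beta_zero_limit_ignores_image(self):
        rng = np.random.default_rng(1)
        labels = np.zeros((40, 30), dtype=np.uint8)
        labels[5] = 1
        labels[35] = 2
        from kneeus.segmentation import SeedImage

        params = RWParams(rw_beta=1e-9)
        a = random_walker(rng.random((40, 30)), SeedImage(labels), params)
        b = random_walker(rng.random((40, 30)), SeedImage(labels), params)
        assert np.allclose(a.probabilities, b.probabilities, atol=1e-6)

    def test_mask_agrees_with_skimage_on_two_region_image(self):
        # independent cross-check against the established implementation
        from skimage.segmentation import random_walker as sk_rw
        from kneeus.segmentation import SeedImage

        img = np.zeros((60, 40))
        img[32:] = 1.0
        labels = np.zeros((60, 40), dtype=np.uint8)
        labels[5] = 1
        labels[55] = 2
        ours = random_walker(img, SeedImage(labels)).mask
        theirs = sk_rw(img, labels.astype(int), beta=130.0, mode="cg_j") == 1
        assert (ours == theirs).mean() > 0.99


class TestWatershed:
    def test_ring_crest_separates_basins(self):
        yy, xx = np.mgrid[:81, :81]
        r = np.hypot(yy - 40, xx - 40)
        img = np.exp(-((r - 20.0) ** 2) / (2 * 2.0**2))  # bright ring
        labels = np.zeros((81, 81), dtype=np.uint8)
        labels[40, 40] = 1
        labels[2, 2] = 2
        from kneeus.segmentation import SeedImage

        res = watershed_segment(img, SeedImage(labels))
        inside = res.mask
        rr = r[inside]
        assert rr.max() <= 21.5  # basin bounded by the ring crest +- 1 px
        assert inside[40, 40]
        assert inside.sum() > 0.8 * np.pi * 19**2

    def test_constant_image_partitions_everything(self):
        img = np.full((40, 40), 0.5)
        labels = np.zeros((40, 40), dtype=np.uint8)
        labels[10, 10] = 1
        labels[30, 30] = 2
        from kneeus.segmentation import SeedImage

        res = watershed_segment(img, SeedImage(labels))
        assert res.mask[10, 10]
        assert not res.mask[30, 30]
        assert res.mask.any() and (~res.mask).any()


class TestGraphCut:
    def test_cut_cost_equals_flow_and_boundary_audit(self):
        rng = np.random.default_rng(3)
        img = rng.random((24, 20))
        labels = np.zeros((24, 20), dtype=np.uint8)
        labels[3] = 1
        labels[20] = 2
        from kneeus.segmentation import SeedImage, _lattice_edges

        params = GCParams()
        res = graphcut_segment(img, SeedImage(labels), params)
        mask = res.mask
        # audit: re-sum the capacities of edges crossing the returned cut
        flat = img.ravel()
        ei, ej = _lattice_edges(img.shape)
        w = params.gc_lambda * np.exp(
            -((flat[ei] - flat[ej]) ** 2) / (2.0 * params.gc_sigma**2)
        )
        caps = np.round(w * 10_000).astype(np.int64)
        side = mask.ravel()
        crossing = caps[side[ei] != side[ej]].sum()
        # the minimal cut cannot beat any other separating cut we can draw
        horizontal_cut = caps[(ei // img.shape[1] == 10) & (ej // img.shape[1] == 11)].sum()
        assert crossing <= horizontal_cut

    def test_zero_weight_ring_gives_free_cut(self):
        img = np.zeros((41, 41))
        yy, xx = np.mgrid[:41, :41]
        r = np.hypot(yy - 20, xx - 20)
        img[(r > 8) & (r < 10)] = 1.0  # huge gradients -> near-zero weights
        labels = np.zeros((41, 41), dtype=np.uint8)
        labels[20, 20] = 1
        labels[2, 2] = 2
        from kneeus.segmentation import SeedImage

        res = graphcut_segment(img, SeedImage(labels), GCParams(gc_sigma=0.05))
        assert res.mask[20, 20]
        assert not res.mask[2, 2]
        assert res.mask.sum() < np.pi * 12**2  # cut stays at the ring


class TestSegmentDispatch:
    def test_unknown_backend_rejected(self, default_features):
        surface = _flat_surface(100)
        with pytest.raises(SeedError, match="unknown backend"):
            segment(default_features["enhanced"], surface, backend="levelset")

    def test_empty_mask_reports_not_found(self):
        empty, found = _postprocess(np.zeros((20, 20), dtype=bool), None)
        assert not found and not empty.any()

    def test_masks_lie_above_bone_surface(self, suite_results):
        for entry in suite_results:
            surface = entry["rw"].surface
            mask = entry["rw"].segmentation.mask
            below = 0
            for c in np.nonzero(surface.valid)[0]:
                below += mask[surface.rows[c]:, c].sum()
            assert below <= 0.05 * max(mask.sum(), 1)

    def test_all_backends_recover_cartilage(self, suite_results):
        for backend in ("rw", "watershed", "graphcut"):
            scores = [entry[f"dsc_{backend}"] for entry in suite_results]
            assert np.mean(scores) >= 0.75, f"{backend}: {np.mean(scores):.3f}"

    def test_both_rw_and_watershed_overlap_truth(self, suite_results):
        entry = suite_results[0]
        assert entry["dsc_rw"] > 0.0
        assert entry["dsc_watershed"] > 0.0
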