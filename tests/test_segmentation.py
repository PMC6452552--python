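import numpy as np
import pytest

from rfstacks import (
    Candidate,
    CleanupConfig,
    FcmConfig,
    RefinementConfig,
    ZoomViewModel,
    classify_image,
    fcm_bipartition,
    iterative_refinement,
    morphological_cleanup,
    probability_map,
    segment,
)
from rfstacks.segmentation import vote_fraction


class StubTree:
    """A 'tree' that predicts a fixed label for every input row."""

    def __init__(self, label: int):
        self.label = label

    def predict(self, X):
        return np.full(X.shape[0], self.label)


class TestVoting:
    def test_hand_built_vote_outcomes(self):
        X = np.zeros((1, 4))
        assert vote_fraction([StubTree(1), StubTree(1), StubTree(0)], X)[0] > 0.5
        assert not vote_fraction([StubTree(1), StubTree(0), StubTree(0)], X)[0] > 0.5

    def test_exact_tie_counts_as_background(self):
        X = np.zeros((1, 4))
        frac = vote_fraction([StubTree(1), StubTree(0)], X)
        assert frac[0] == 0.5
        assert not (frac > 0.5)[0]

    def test_classification_is_deterministic(self, tiny_models, small_labeled,
                                             tiny_feature_cfg):
        full, _ = tiny_models
        a = classify_image(full.forest, small_labeled.image, tiny_feature_cfg)
        b = classify_image(full.forest, small_labeled.image, tiny_feature_cfg)
        assert np.array_equal(a, b)

    def test_feature_mismatch_rejected(self, tiny_models, small_labeled):
        from rfstacks import FeatureConfig

        full, _ = tiny_models
        other = FeatureConfig(enabled_families=("mean",), scales=(1.0,))
        with pytest.raises(ValueError, match="channels"):
            classify_image(full.forest, small_labeled.image, other)

    def test_coarse_results_order_matches_forest_order(self, tiny_models,
                                                       small_labeled,
                                                       tiny_feature_cfg):
        from rfstacks import coarse_results

        full, zoom = tiny_models
        crs = coarse_results(zoom, small_labeled.image, tiny_feature_cfg)
        assert len(crs) == zoom.n_groups
        single = ZoomViewModel(forests=[zoom.forests[0]], groups=[zoom.groups[0]])
        alone = coarse_results(single, small_labeled.image, tiny_feature_cfg)
        assert np.array_equal(alone[0], crs[0])


class TestProbabilityMap:
    def test_exact_fractions(self):
        rng = np.random.default_rng(0)
        crs = [rng.random((6, 7)) < 0.5 for _ in range(37)]
        pm = probability_map(crs)
        counts = np.sum(crs, axis=0)
        assert np.array_equal(pm.p, counts / 37)
        assert np.array_equal(pm.p, np.mean(crs, axis=0))

    def test_unanimous_and_empty_pixels(self):
        ones = [np.ones((3, 3), dtype=bool)] * 37
        zeros = [np.zeros((3, 3), dtype=bool)] * 37
        assert np.all(probability_map(ones).p == 1.0)
        assert np.all(probability_map(zeros).p == 0.0)
        half = [np.ones((1, 1), dtype=bool)] * 18 + [np.zeros((1, 1), dtype=bool)] * 19
        assert probability_map(half).p[0, 0] == 18 / 37

    def test_conservation(self):
        rng = np.random.default_rng(1)
        crs = [rng.random((5, 5)) < 0.3 for _ in range(7)]
        pm = probability_map(crs)
        assert pm.p.sum() == pytest.approx(sum(c.sum() for c in crs) / 7)

    def test_shape_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            probability_map([])
        with pytest.raises(ValueError):
            probability_map([np.zeros((2, 2), dtype=bool),
                             np.zeros((3, 3), dtype=bool)])


def brute_force_fcm(values, m=2.0, iters=500):
    """Plain pixelwise fixed-point FCM iteration (independent oracle)."""
    v = np.array([values.min(), values.max()], dtype=float)
    for _ in range(iters):
        d = np.abs(values[:, None] - v[None, :]) + 1e-12
        u = (1.0 / d**2) / (1.0 / d**2).sum(axis=1, keepdims=True)
        v = ((u**m) * values[:, None]).sum(axis=0) / (u**m).sum(axis=0)
    return np.sort(v)


class TestFcm:
    def test_binary_map_recovered_exactly(self):
        from rfstacks import ProbabilityMap

        p = np.zeros((6, 6))
        p[2:4, 2:4] = 1.0
        mask = fcm_bipartition(ProbabilityMap(p=p, n_sources=5))
        assert np.array_equal(mask, p == 1.0)

    def test_constant_map_degenerates_to_empty_mask(self):
        from rfstacks import ProbabilityMap

        with pytest.warns(UserWarning, match="constant"):
            mask = fcm_bipartition(ProbabilityMap(p=np.full((4, 4), 0.4), n_sources=5))
        assert not mask.any()

    def test_two_level_map_matches_fixed_point_oracle(self):
        from rfstacks import ProbabilityMap
        from rfstacks.segmentation import _fcm_scalar

        p = np.full((10, 10), 0.1)
        p[3:7, 3:7] = 0.9
        cfg = FcmConfig()
        lo, hi = _fcm_scalar(*np.unique(p, return_counts=True), cfg)
        oracle = brute_force_fcm(p.ravel())
        assert abs(lo - oracle[0]) < 1e-3
        assert abs(hi - oracle[1]) < 1e-3
        # with two distinct values the centroids sit on the values themselves
        assert abs(lo - 0.1) < 1e-3 and abs(hi - 0.9) < 1e-3
        mask = fcm_bipartition(ProbabilityMap(p=p, n_sources=10), cfg)
        assert np.array_equal(mask, p == 0.9)


class TestCleanup:
    def test_small_blob_removed(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:7, 5:10] = True  # 10 pixels
        out = morphological_cleanup(mask, CleanupConfig(min_component_area=50,
                                                        opening_radius=0))
        assert not out.any()

    def test_empty_passthrough(self):
        out = morphological_cleanup(np.zeros((8, 8), dtype=bool))
        assert not out.any()

    def test_large_blob_untouched_without_opening(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True  # 400 pixels
        out = morphological_cleanup(mask, CleanupConfig(min_component_area=50,
                                                        opening_radius=0))
        assert np.array_equal(out, mask)

    def test_never_adds_pixels(self):
        rng = np.random.default_rng(2)
        mask = rng.random((30, 30)) < 0.4
        out = morphological_cleanup(mask)
        assert not (out & ~mask).any()


def good_mask():
    m = np.zeros((30, 30), dtype=bool)
    m[8:22, 8:22] = True  # 196 px, survives opening radius 1 and min area 50
    return m


class TestRefinement:
    def test_no_filter_case_is_one_pass(self):
        rng = np.random.default_rng(3)
        crs = [np.asarray(good_mask() ^ (rng.random((30, 30)) < 0.02))
               for _ in range(5)]
        cfg = RefinementConfig(w1=1.0, w2=0.0)
        out, retained = iterative_refinement(crs, cfg)
        direct = morphological_cleanup(fcm_bipartition(probability_map(crs), cfg.fcm),
                                       cfg.cleanup)
        assert np.array_equal(out, direct)
        assert retained == list(range(5))  # w2=0 never drops anyone

    def test_identical_crs_are_a_fixed_point(self):
        crs = [good_mask()] * 4
        for w1, w2 in [(1.0, 0.0), (0.5, 0.3), (1.0, 0.9)]:
            out, _ = iterative_refinement(crs, RefinementConfig(w1=w1, w2=w2))
            assert np.array_equal(out, morphological_cleanup(good_mask()))

    def test_adversarial_cr_is_excluded(self):
        crs = [good_mask()] * 9 + [np.ones((30, 30), dtype=bool)]
        out, retained = iterative_refinement(crs, RefinementConfig(w1=1.0, w2=0.3))
        # all-foreground CR has Jaccard 196/900 < 0.3 to the good consensus
        assert retained == list(range(9))
        assert np.array_equal(out, morphological_cleanup(good_mask()))

    def test_empty_cr_list_rejected(self):
        with pytest.raises(ValueError):
            iterative_refinement([], RefinementConfig())

    @pytest.mark.parametrize("case_seed", range(8))
    def test_matches_brute_force_reimplementation(self, case_seed):
        """Independent re-enactment of the retained-set rule on tiny inputs."""
        from rfstacks import jaccard

        rng = np.random.default_rng(case_seed)
        n = int(rng.integers(1, 4))
        crs = [rng.random((8, 8)) < rng.uniform(0.2, 0.7) for _ in range(n)]
        cfg = RefinementConfig(w1=1.0, w2=0.3,
                               cleanup=CleanupConfig(min_component_area=3,
                                                     opening_radius=0))
        got_mask, got_retained = iterative_refinement(crs, cfg)

        # --- brute force: plain loop, no shared control flow ---
        def consensus_of(indices):
            pm = probability_map([crs[i] for i in indices])
            vals = np.unique(pm.p)
            if len(vals) < 2:
                core = pm.p >= 0.5 if (pm.p > 0).any() else np.zeros_like(pm.p, bool)
            else:
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    core = fcm_bipartition(pm, cfg.fcm)
                if not core.any() and (pm.p > 0).any():
                    core = pm.p >= 0.5
            return morphological_cleanup(core, cfg.cleanup)

        retained = list(range(n))
        cons = consensus_of(retained)
        for _ in range(cfg.max_iters):
            new = [i for i in range(n) if jaccard(crs[i], cons) >= cfg.w2]
            if not new or new == retained:
                break
            retained = new
            cons = consensus_of(retained)

        assert got_retained == retained
        assert np.array_equal(got_mask, cons)


class TestSegment:
    def test_candidates_agree_for_single_shared_forest(self, tiny_models,
                                                       small_labeled,
                                                       tiny_feature_cfg):
        full, zoom = tiny_models
        single_zoom = ZoomViewModel(forests=[full.forest], groups=[zoom.groups[0]])
        cfg = RefinementConfig(w1=1.0, w2=0.0)
        res = segment(small_labeled.image, full, single_zoom, cfg,
                      tiny_feature_cfg)
        assert np.array_equal(res.R1, res.R2)

    def test_gold_scoring_and_selection(self, tiny_models, small_labeled,
                                        tiny_feature_cfg):
        full, zoom = tiny_models
        res = segment(small_labeled.image, full, zoom, RefinementConfig(),
                      tiny_feature_cfg, gold=small_labeled.mask, auto_select=True)
        assert res.jaccard_R1 is not None and res.jaccard_R2 is not None
        expected = Candidate.R1 if res.jaccard_R1 >= res.jaccard_R2 else Candidate.R2
        assert res.selected == expected

    def test_no_gold_leaves_selection_unset(self, tiny_models, small_labeled,
                                            tiny_feature_cfg):
        full, zoom = tiny_models
        res = segment(small_labeled.image, full, zoom, RefinementConfig(),
                      tiny_feature_cfg)
        assert res.selected == Candidate.UNSET
        assert res.jaccard_R1 is None
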