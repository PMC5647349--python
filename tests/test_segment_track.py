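"""Random-walker segmentation, identity tracking and growth curves."""

import numpy as np
import pytest

from colonyscope.detection import BinaryMap
from colonyscope.evaluate import mask_metrics
from colonyscope.preprocess import autolevels
from colonyscope.segment_track import (
    ColonyTrack,
    GrowthCurve,
    RandomWalkerParams,
    growth_curve,
    link_tracks,
    random_walker,
    segment_frame,
)
from colonyscope.synth import GrowthParams, SceneConfig, generate_scene

from .conftest import coverage_bmap
from .oracles import absorbing_chain_probabilities


def track_label_maps(frames_by_day, truth, seed_day=12):
    """Segment every day using the coverage-oracle detection."""
    label_maps, prior = {}, None
    for day in sorted(truth.masks):
        if day > seed_day and prior is None:
            prior = np.zeros(truth.masks[day].shape, dtype=np.uint16)
        lm = segment_frame(coverage_bmap(truth.masks[day], day),
                           frames_by_day[day], day=day, seed_day=seed_day,
                           prior_labels=prior)
        label_maps[day] = lm
        if lm.any():
            prior = lm
    return label_maps


class TestRandomWalker:
    def test_uniform_strip_midpoint_symmetry(self):
        image = np.zeros((1, 5))
        seeds = np.zeros((1, 5), dtype=int)
        seeds[0, 0], seeds[0, 4] = 1, 2
        _, probs = random_walker(image, seeds)
        assert probs[0, 0, 2] == pytest.approx(0.5, abs=1e-12)
        assert probs[1, 0, 2] == pytest.approx(0.5, abs=1e-12)

    def test_seed_pixels_keep_probability_one(self):
        rng = np.random.default_rng(2)
        image = rng.uniform(0, 0.3, (4, 4))
        seeds = np.zeros((4, 4), dtype=int)
        seeds[0, 0], seeds[3, 3], seeds[0, 3] = 1, 2, 3
        labels, probs = random_walker(image, seeds)
        assert probs[0, 0, 0] == 1.0 and probs[1, 3, 3] == 1.0 and probs[2, 0, 3] == 1.0
        assert labels[0, 0] == 1 and labels[3, 3] == 2 and labels[0, 3] == 3

    def test_requires_two_labels(self):
        seeds = np.zeros((3, 3), dtype=int)
        seeds[0, 0] = 1
        with pytest.raises(ValueError):
            random_walker(np.zeros((3, 3)), seeds)

    def test_probabilities_form_simplex(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            H, W = rng.integers(2, 6, 2)
            image = rng.uniform(0, 1, (H, W))
            seeds = np.zeros((H, W), dtype=int)
            pos = rng.choice(H * W, 2, replace=False)
            seeds.flat[pos] = [1, 2]
            _, probs = random_walker(image, seeds, RandomWalkerParams(beta=50))
            assert np.all(probs >= 0) and np.all(probs <= 1)
            assert np.allclose(probs.sum(axis=0), 1.0, atol=1e-9)

    def test_matches_absorbing_chain_oracle(self):
        """Dirichlet solve equals fundamental-matrix absorption probabilities
        on every small grid."""
        rng = np.random.default_rng(11)
        worst = 0.0
        for H in (2, 3, 4):
            for W in (2, 3, 4):
                for n_labels in (2, 3):
                    if n_labels >= H * W:
                        continue
                    for uniform in (True, False):
                        image = (np.zeros((H, W)) if uniform
                                 else rng.uniform(0, 0.3, (H, W)))
                        seeds = np.zeros((H, W), dtype=int)
                        pos = rng.choice(H * W, n_labels, replace=False)
                        for k, p in enumerate(pos, start=1):
                            seeds.flat[p] = k
                        _, probs = random_walker(image, seeds,
                                                 RandomWalkerParams(beta=130))
                        oracle = absorbing_chain_probabilities(image, seeds, 130)
                        worst = max(worst, np.abs(probs - oracle).max())
        assert worst <= 1e-6

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        image = rng.uniform(0, 0.5, (6, 6))
        seeds = np.zeros((6, 6), dtype=int)
        seeds[0, 0], seeds[5, 5] = 1, 2
        _, p1 = random_walker(image, seeds)
        _, p2 = random_walker(image, seeds)
        assert np.array_equal(p1, p2)


class TestSegmentFrame:
    def test_pre_seed_day_connected_components(self):
        mask = np.zeros((300, 300), dtype=bool)
        mask[10:80, 10:80] = True
        mask[150:260, 150:260] = True
        labels = segment_frame(BinaryMap(mask=mask, day=10), seed_day=12)
        assert set(np.unique(labels)) == {0, 1, 2}

    def test_post_seed_day_requires_prior(self):
        bmap = BinaryMap(mask=np.zeros((200, 200), dtype=bool), day=15)
        with pytest.raises(ValueError, match="prior"):
            segment_frame(bmap, np.zeros((200, 200)), seed_day=12)

    def test_lost_prior_label_emits_empty_region(self):
        """A prior colony absent from today's detection disappears quietly."""
        prior = np.zeros((300, 300), dtype=np.uint16)
        prior[20:60, 20:60] = 1  # will vanish
        prior[200:260, 200:260] = 2
        mask = np.zeros((300, 300), dtype=bool)
        mask[190:280, 190:280] = True  # only colony 2 detected
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 1000, (300, 300))
        labels = segment_frame(BinaryMap(mask=mask, day=15), frame,
                               seed_day=12, prior_labels=prior)
        assert 1 not in np.unique(labels)
        assert 2 in np.unique(labels)

    def test_refinement_improves_iou_on_day_20(self, small_scene):
        """Random-walker refinement beats the raw blocky detection."""
        _, frames, truth = small_scene
        day = 20
        prior = truth.masks[day - 1].astype(np.uint16)  # idealized prior
        bmap = coverage_bmap(truth.masks[day], day)
        frame = autolevels([f for f in frames if f.day == day][0])
        refined = segment_frame(bmap, frame, day=day, seed_day=12,
                                prior_labels=prior)
        blocky = mask_metrics(bmap, truth.masks[day])
        fine = mask_metrics(refined > 0, truth.masks[day])
        for cid in fine.iou_per_colony:
            assert fine.iou_per_colony[cid] >= blocky.iou_per_colony[cid]


class TestLinkTracks:
    @staticmethod
    def disc_map(shape, discs):
        out = np.zeros(shape, dtype=np.uint16)
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        for lab, (cy, cx, r) in discs.items():
            out[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = lab
        return out

    def test_nested_growth_single_track(self):
        maps = {
            d: self.disc_map((200, 200), {1: (100, 100, 10 + 5 * (d - 8))})
            for d in range(8, 23)
        }
        tracks = link_tracks(maps)
        assert len(tracks) == 1
        assert tracks[0].first_positive_day == 8
        assert len(tracks[0].days) == 15

    def test_disjoint_colonies_never_merge(self):
        maps = {
            d: self.disc_map((300, 300), {1: (80, 80, 20 + d), 2: (220, 220, 15 + d)})
            for d in (10, 11, 12)
        }
        tracks = link_tracks(maps)
        assert len(tracks) == 2
        footprints = [set(t.regions.keys()) for t in tracks]
        assert footprints[0] == footprints[1] == {10, 11, 12}

    def test_needs_two_days(self):
        with pytest.raises(ValueError):
            link_tracks({8: np.zeros((10, 10), dtype=np.uint16)})

    def test_overlap_threshold_blocks_weak_links(self):
        a = np.zeros((100, 100), dtype=np.uint16)
        a[0:10, 0:10] = 1
        b = np.zeros((100, 100), dtype=np.uint16)
        b[8:40, 8:40] = 1  # overlap 4 px vs min area 100 -> 4% < 30%
        tracks = link_tracks({10: a, 11: b})
        (track,) = tracks
        assert track.first_positive_day == 11  # link rejected

    def test_five_colony_identity_recovery(self):
        """Tracks recover planted identities and first-positive days."""
        gp = [
            GrowthParams(3.0e4, 0.55, 7.5),
            GrowthParams(2.6e4, 0.50, 8.0),
            GrowthParams(3.4e4, 0.60, 8.5),
            GrowthParams(2.8e4, 0.55, 7.0),
            GrowthParams(3.2e4, 0.50, 9.0),
        ]
        cfg = SceneConfig(image_size=(1152, 1152), n_colonies=5,
                          growth_params=gp, rng_seed=13)
        frames, truth = generate_scene(cfg)
        frames = {f.day: autolevels(f) for f in frames}
        label_maps = track_label_maps(frames, truth)
        tracks = link_tracks(label_maps, seed_day=12)
        truth_fp = dict(zip(truth.picking_table.colony_id,
                            truth.picking_table.first_positive_day))
        final = truth.masks[max(truth.masks)]
        matched = 0
        for t in tracks:
            if max(t.days) != max(truth.masks):
                continue
            rid = t.regions[max(t.days)][0]
            vals = final[label_maps[max(t.days)] == rid]
            vals = vals[vals > 0]
            if len(vals) == 0:
                continue
            cid = int(np.bincount(vals).argmax())
            if abs(t.first_positive_day - truth_fp[cid]) <= 1:
                matched += 1
        assert matched >= 4

    def test_tie_break_prefers_larger_then_lower_id(self):
        prev = np.zeros((100, 100), dtype=np.uint16)
        prev[0:20, 0:20] = 1    # area 400
        prev[0:30, 30:60] = 2   # area 900
        cur = np.zeros((100, 100), dtype=np.uint16)
        cur[0:20, 10:40] = 1    # overlaps both priors by 200 px
        assert (((prev == 1) & (cur == 1)).sum()
                == ((prev == 2) & (cur == 1)).sum() == 200)
        (track,) = link_tracks({10: prev, 11: cur})
        assert track.regions[10][0] == 2  # equal overlap -> larger area wins


class TestGrowthCurve:
    def test_direct_construction(self):
        track = ColonyTrack(track_id=1, regions={8: (1, 100), 9: (1, 150)})
        curve = growth_curve(track)
        assert curve.days.tolist() == [8, 9]
        assert curve.areas.tolist() == [100.0, 150.0]

    def test_missing_day_absent(self):
        track = ColonyTrack(track_id=2, regions={8: (1, 100), 10: (1, 300)})
        curve = growth_curve(track)
        assert curve.days.tolist() == [8, 10]

    def test_empty_track_raises(self):
        with pytest.raises(ValueError):
            growth_curve(ColonyTrack(track_id=3))

    def test_tracked_areas_match_truth_within_ten_percent(self, small_scene):
        """Extracted growth curves follow the planted logistic areas."""
        _, frames, truth = small_scene
        frames = {f.day: autolevels(f) for f in frames}
        label_maps = track_label_maps(frames, truth)
        tracks = link_tracks(label_maps, seed_day=12)
        final_day = max(truth.masks)
        checked = 0
        for t in tracks:
            if final_day not in t.regions:
                continue
            vals = truth.masks[final_day][label_maps[final_day] == t.regions[final_day][0]]
            vals = vals[vals > 0]
            cid = int(np.bincount(vals).argmax())
            truth_curve = truth.colony_curve(cid)
            truth_by_day = dict(zip(truth_curve.days.tolist(), truth_curve.areas))
            curve = growth_curve(t)
            for d, a in zip(curve.days, curve.areas):
                if d > t.first_positive_day and truth_by_day.get(d, 0) > 0:
                    assert abs(a - truth_by_day[d]) / truth_by_day[d] <= 0.10
                    checked += 1
        assert checked >= 20
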