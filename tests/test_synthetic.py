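"""Synthetic barn generator: construction guarantees, determinism, calibration."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from feedcount import (
    Box,
    PipelineConfig,
    SimConfig,
    SimulationError,
    coverage_ratio,
    count_feeding_pigs,
    generate_batch,
    generate_scene,
    generate_timeseries,
    iou,
    make_interleaved_scene,
    write_dataset,
)


class TestGenerateScene:
    def test_empty_barn(self):
        scene, record = generate_scene(SimConfig(n_pigs=0), 1)
        assert scene.bodies() == [] and scene.heads() == []
        assert record.actual == 0
        assert len(scene.feeders()) == 2

    def test_everyone_feeding_by_construction(self):
        config = SimConfig(n_pigs=6, p_feeding=1.0)
        scene, record = generate_scene(config, 2)
        assert record.actual == 6
        feeders = [f.box for f in scene.feeders()]
        for head in scene.heads():
            assert max(iou(head.box, f) for f in feeders) > 0.01
        for b in scene.bodies():
            assert b.label == "Standing"

    def test_no_feeding_without_feeders(self):
        scene, record = generate_scene(SimConfig(n_pigs=5, n_feeders=0, p_feeding=0.0), 3)
        assert record.actual == 0 and len(scene.feeders()) == 0
        with pytest.raises(SimulationError, match="feeder"):
            generate_scene(SimConfig(n_pigs=5, n_feeders=0, p_feeding=1.0), 3)

    def test_bodies_cover_their_heads(self):
        scene, _ = generate_scene(SimConfig(n_pigs=8), 4)
        heads = scene.heads()
        bodies = scene.bodies()
        assert len(heads) == len(bodies) == 8
        # pigs never overlap, so each head's covering body is unambiguous
        for head in heads:
            cov = max(coverage_ratio(head.box, b.box) for b in bodies)
            assert cov >= 0.5

    def test_pigs_do_not_overlap(self):
        scene, _ = generate_scene(SimConfig(n_pigs=10), 5)
        from feedcount import intersection_area

        heads, bodies = scene.heads(), scene.bodies()
        for i in range(10):
            for j in range(10):
                if i != j:
                    assert intersection_area(heads[i].box, bodies[j].box) == 0.0
                    assert intersection_area(bodies[i].box, bodies[j].box) == 0.0

    def test_head_dropout_removes_heads_not_truth(self):
        config = SimConfig(n_pigs=8, head_dropout_prob=1.0, p_feeding=1.0)
        scene, record = generate_scene(config, 6)
        assert scene.heads() == []
        assert record.actual == 8

    def test_boxes_stay_in_frame_under_jitter(self):
        scene, _ = generate_scene(SimConfig(n_pigs=8, jitter_px=10.0), 7)
        for det in scene.detections:
            b = det.box
            assert 0 <= b.x_min <= b.x_max <= scene.width
            assert 0 <= b.y_min <= b.y_max <= scene.height

    def test_same_seed_identical_scenes(self):
        config = SimConfig(n_pigs=10, jitter_px=2.0, head_dropout_prob=0.2)
        s1, r1 = generate_scene(config, 42)
        s2, r2 = generate_scene(config, 42)
        assert s1 == s2 and r1 == r2

    def test_infeasible_placement_raises(self):
        cramped = SimConfig(
            image_width=200, image_height=200, n_pigs=30, max_retries=20
        )
        with pytest.raises(SimulationError, match="could not place"):
            generate_scene(cramped, 8)


class TestConfigValidation:
    def test_posture_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(posture_probs={"Standing": 0.5, "LyingBelly": 0.2, "LyingSide": 0.2})

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError, match="p_feeding"):
            SimConfig(p_feeding=1.5)

    def test_from_file_with_feeder_boxes(self, tmp_path):
        f = tmp_path / "sim.yaml"
        f.write_text(
            "n_pigs: 3\nfeeder_boxes:\n  - [10, 10, 110, 130]\n  - [400, 10, 500, 130]\n"
        )
        config = SimConfig.from_file(f)
        assert config.n_pigs == 3
        assert config.feeder_boxes == (Box(10, 10, 110, 130), Box(400, 10, 500, 130))


class TestTimeseries:
    def test_all_zero_schedule_gives_all_zero_actuals(self):
        scenes, records = generate_timeseries(
            SimConfig(n_pigs=4), [0.0] * 24, n_days=2, seed=9
        )
        assert len(scenes) == 48
        assert all(r.actual == 0 for r in records)

    def test_single_active_hour(self):
        schedule = [0.0] * 24
        schedule[12] = 1.0
        _, records = generate_timeseries(SimConfig(n_pigs=4), schedule, n_days=2, seed=10)
        for r in records:
            if r.timestamp.hour == 12:
                assert r.actual == 4
            else:
                assert r.actual == 0

    def test_one_scene_per_hour_per_day(self):
        scenes, records = generate_timeseries(SimConfig(n_pigs=2), [0.1] * 24, 3, seed=11)
        assert len(scenes) == len(records) == 3 * 24
        stamps = [s.timestamp for s in scenes]
        assert len(set(stamps)) == len(stamps)

    def test_incomplete_schedule_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            generate_timeseries(SimConfig(), {h: 0.1 for h in range(23)}, 1, seed=1)


class TestInterleavedScene:
    def test_heads_overlap_two_bodies_yet_map_correctly(self):
        from feedcount import intersection_area, map_heads_to_bodies

        scene, truth = make_interleaved_scene(3)
        heads, bodies = scene.heads(), scene.bodies()
        # the configuration is genuinely ambiguous: inner heads touch two bodies
        assert intersection_area(heads[0].box, bodies[1].box) > 0
        pairs = map_heads_to_bodies(heads, bodies)
        got = sorted((heads.index(p.head), bodies.index(p.body)) for p in pairs)
        assert got == truth

    def test_clean_interleaved_count(self):
        scene, _ = make_interleaved_scene(2)
        # no feeder in the mapping fixture → nothing is a candidate
        assert count_feeding_pigs(scene).predicted == 0


def test_feeding_fraction_converges_to_p_feeding():
    """Across many scenes the realised feeding rate matches p_feeding to 3 SE."""
    config = SimConfig(n_pigs=6, p_feeding=0.3)
    _, records = generate_batch(config, 1000, seed=13)
    n = 1000 * 6
    frac = sum(r.actual for r in records) / n
    se = np.sqrt(0.3 * 0.7 / n)
    assert abs(frac - 0.3) < 3 * se


def test_write_dataset_round_trip(tmp_path):
    from feedcount import read_coco_scenes, read_counts, read_manifest, read_yolo_scene

    config = SimConfig(n_pigs=5)
    scenes, records = generate_timeseries(config, [0.3] * 24, n_days=1, seed=14)
    write_dataset(scenes[:6], records[:6], tmp_path)
    assert sorted(p.name for p in (tmp_path / "labels").iterdir()) == sorted(
        f"{s.image_id}.txt" for s in scenes[:6]
    )
    coco = read_coco_scenes(tmp_path / "scenes.json")
    assert len(coco) == 6
    manifest = read_manifest(tmp_path / "manifest.csv")
    assert manifest[scenes[0].image_id] == scenes[0].timestamp
    truth = read_counts(tmp_path / "truth.csv")
    assert [r.actual for r in truth] == [r.actual for r in records[:6]]
    # YOLO labels reproduce the written scene to float precision
    yolo = read_yolo_scene(
        tmp_path / "labels" / f"{scenes[0].image_id}.txt",
        config.image_width,
        config.image_height,
    )
    assert len(yolo.detections) == len(scenes[0].detections)


def test_write_dataset_determinism(tmp_path):
    config = SimConfig(n_pigs=6, jitter_px=1.5)
    for sub in ("a", "b"):
        scenes, records = generate_batch(config, 4, seed=99)
        write_dataset(scenes, records, tmp_path / sub)
    files_a = sorted((tmp_path / "a").rglob("*"))
    files_b = sorted((tmp_path / "b").rglob("*"))
    assert [f.name for f in files_a] == [f.name for f in files_b]
    for fa, fb in zip(files_a, files_b):
        if fa.is_file():
            assert fa.read_bytes() == fb.read_bytes()
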