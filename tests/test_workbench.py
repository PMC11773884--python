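"""I/O round trips, ROI grids, coordinate mapping, and output export."""

import json

import numpy as np
import pandas as pd
import pytest

from finpose.augment import SplitStats
from finpose.codec import CodecConfig, Keypoints, encode_targets
from finpose.export import AnalysisRun, export_outputs
from finpose.io import (
    load_dataset,
    load_frames,
    load_image,
    save_dataset,
    save_image,
    save_movie,
    load_movie,
)
from finpose.kinematics import TrajectorySeries
from finpose.nn.model import NetworkConfig, build_network
from finpose.roi import Roi, crop_roi, make_roi_grid
from finpose.synthetic import (
    SceneSpec,
    TrajectoryScript,
    generate_dataset,
    generate_trajectory_movie,
    SceneRanges,
)
from finpose.tracking import letterbox, track_movie
from finpose.training import init_weights


class TestImageIO:
    def test_16bit_png_round_trip(self, tmp_path):
        img = np.random.default_rng(0).uniform(0, 1, (32, 32))
        save_image(img, tmp_path / "a.png")
        back = load_image(tmp_path / "a.png")
        assert np.abs(back - img).max() < 1.0 / 65535

    def test_16bit_max_value_scales_to_one(self, tmp_path):
        save_image(np.ones((8, 8)), tmp_path / "one.png")
        assert load_image(tmp_path / "one.png").max() == pytest.approx(1.0)

    def test_rgb_converted_by_luminance_average_with_warning(self, tmp_path):
        from PIL import Image

        rgb = np.zeros((8, 8, 3), dtype=np.uint8)
        rgb[..., 0] = 255  # pure red -> average 1/3
        Image.fromarray(rgb, mode="RGB").save(tmp_path / "rgb.png")
        with pytest.warns(UserWarning, match="RGB"):
            img = load_image(tmp_path / "rgb.png")
        assert img[0, 0] == pytest.approx(255 / 3 / 255)

    def test_directory_of_frames_loads_in_order(self, tmp_path):
        for i in range(5):
            save_image(np.full((8, 8), i / 10), tmp_path / f"{i:06d}.png")
        frames = load_frames(tmp_path)
        assert frames.shape == (5, 8, 8)
        np.testing.assert_allclose(frames[:, 0, 0], np.arange(5) / 10, atol=1e-4)

    def test_mixed_sizes_listed_in_error(self, tmp_path):
        save_image(np.zeros((8, 8)), tmp_path / "000000.png")
        save_image(np.zeros((9, 8)), tmp_path / "000001.png")
        with pytest.raises(ValueError, match="000001"):
            load_frames(tmp_path)


class TestDatasetIO:
    def test_dataset_round_trip(self, tmp_path):
        ds = generate_dataset(4, 3, SceneRanges(frame_size=(48, 48)), seed=1)
        save_dataset(ds, tmp_path / "ds")
        back = load_dataset(tmp_path / "ds")
        assert len(back) == 4 and back.n_keypoints == 3
        np.testing.assert_allclose(back.coords(), ds.coords(), atol=1e-12)
        assert np.abs(back.images() - ds.images()).max() < 1.0 / 65535

    def test_movie_round_trip(self, tmp_path):
        script = TrajectoryScript(framerate=50, duration=0.2, bout_schedule=[(0.0, 0.2, 3.0)])
        frames, truth = generate_trajectory_movie(script, SceneSpec(frame_size=(64, 64)), seed=0)
        save_movie(frames, truth, tmp_path / "mov", script.framerate, script.mm_per_px)
        back_frames, back_truth = load_movie(tmp_path / "mov")
        assert back_frames.shape == frames.shape
        np.testing.assert_allclose(back_truth.keypoints, truth.keypoints, atol=1e-12)
        assert back_truth.framerate == script.framerate


class TestRoiGrid:
    def test_24_well_layout(self):
        grid = make_roi_grid(4, 6, (0, 0, 600, 400))
        assert len(grid) == 24
        xs = {r.x0 for r in grid.rois}
        assert len(xs) == 6

    def test_single_well_mode_equals_bounds(self):
        grid = make_roi_grid(1, 1, (0, 0, 128, 128))
        roi = grid.rois[0]
        assert (roi.x0, roi.y0, roi.width, roi.height) == (0, 0, 128, 128)

    def test_crop_offset_maps_back_to_plate_coordinates(self):
        frame = np.zeros((300, 300))
        roi = Roi(100, 100, 50, 50)
        sub, offset = crop_roi(frame, roi)
        assert sub.shape == (50, 50)
        local = np.array([10.0, 10.0])
        plate = local + np.array(offset)
        np.testing.assert_array_equal(plate, [110.0, 110.0])

    def test_rois_are_disjoint(self):
        grid = make_roi_grid(2, 3, (10, 20, 90, 60))
        boxes = [(r.x0, r.y0, r.x0 + r.width, r.y0 + r.height) for r in grid.rois]
        for i, a in enumerate(boxes):
            for b in boxes[i + 1 :]:
                overlap_x = max(0, min(a[2], b[2]) - max(a[0], b[0]))
                overlap_y = max(0, min(a[3], b[3]) - max(a[1], b[1]))
                assert overlap_x * overlap_y == 0


class TestTracking:
    def test_letterbox_coordinate_round_trip(self):
        img = np.random.default_rng(0).uniform(0, 1, (100, 100))
        canvas, box = letterbox(img, (64, 64))
        assert canvas.shape == (64, 64)
        pts = np.array([[10.0, 20.0], [50.0, 80.0]])
        np.testing.assert_allclose(box.to_roi(box.to_network(pts)), pts, atol=1e-9)

    def test_codec_bypass_reproduces_ground_truth_within_half_pixel(self):
        """Plumbing oracle: if the 'network' returns the encoded target of the
        true keypoints (in network-input coordinates), tracking must map them
        back to plate coordinates within 0.5 px."""
        cfg = NetworkConfig(H=64, W=64, M=8, O=1, N=1)
        net = build_network(cfg)
        init_weights(net, 0)
        ccfg = CodecConfig(sigma=2.0)

        rng = np.random.default_rng(3)
        n_frames, size = 4, 100
        truth_plate = rng.uniform(30, 70, (n_frames, 1, 2))
        frames = np.full((n_frames, size, size), 0.5)
        roi = Roi(0, 0, size, size)
        _, box = letterbox(frames[0], (64, 64))
        state = {"t": 0}

        def oracle(_canvas):
            t = state["t"]
            state["t"] += 1
            net_coords = box.to_network(truth_plate[t])
            return encode_targets(Keypoints(net_coords), (32, 32), ccfg).values

        trajs = track_movie(
            frames, net, [roi], framerate=100.0, mm_per_px=0.1,
            heatmaps_override=oracle, batch_size=1,
        )
        err = np.linalg.norm(trajs[0].keypoints - truth_plate, axis=-1)
        assert err.max() <= 0.5

    def test_multiwell_movie_yields_one_series_per_roi(self):
        cfg = NetworkConfig(H=32, W=32, M=8, O=1, N=1)
        net = build_network(cfg)
        init_weights(net, 0)
        frames = np.random.default_rng(0).uniform(0.4, 0.6, (3, 64, 96))
        grid = make_roi_grid(2, 3, (0, 0, 96, 64))
        stats = SplitStats(mean=0.5, sd=0.1)
        trajs = track_movie(frames, net, grid, framerate=100.0, mm_per_px=0.1, stats=stats)
        assert len(trajs) == 6
        assert all(t.n_frames == 3 for t in trajs)


class TestExport:
    def make_run(self):
        rng = np.random.default_rng(0)
        kp = rng.uniform(10, 50, (30, 3, 2))
        traj = TrajectorySeries(keypoints=kp, framerate=100.0, mm_per_px=0.1)
        return AnalysisRun(trajectories=[traj, traj], seed=12, config={"rows": 1})

    def test_csv_round_trip_precision(self, tmp_path):
        run = self.make_run()
        export_outputs(run, tmp_path)
        table = pd.read_csv(tmp_path / "roi000_trajectory.csv")
        np.testing.assert_allclose(
            table[["x_0", "y_0"]].to_numpy(),
            run.trajectories[0].keypoints[:, 0, :],
            atol=1e-6,
        )

    def test_one_trajectory_csv_per_roi_plus_summary(self, tmp_path):
        run = self.make_run()
        export_outputs(run, tmp_path)
        assert (tmp_path / "roi000_trajectory.csv").exists()
        assert (tmp_path / "roi001_trajectory.csv").exists()
        assert (tmp_path / "roi000_events.csv").exists()
        assert (tmp_path / "roi000_trajectory.png").exists()
        summary = json.loads((tmp_path / "run_summary.json").read_text())
        assert summary["seed"] == 12
        assert "config_hash" in summary and summary["n_rois"] == 2
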