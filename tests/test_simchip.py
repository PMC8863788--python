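"""Simulator: layout geometry, rendering contracts, noise model, determinism."""

import dataclasses

import numpy as np
import pytest

from beadscreen import (
    PlacementError,
    SimConfig,
    default_panel,
    render_chip_image,
    sample_bead_layout,
)
from beadscreen.simchip import generate_screen_dataset, generate_timeseries, layout_to_frame


def _pairwise_min_distance(layout):
    centers = np.array([b.center for b in layout])
    from scipy.spatial import cKDTree

    d, _ = cKDTree(centers).query(centers, k=2)
    return d[:, 1].min()


class TestLayout:
    def test_zero_beads_gives_empty_layout(self, small_panel):
        cfg = SimConfig(populations=tuple(small_panel.populations), beads_per_population=0)
        assert sample_bead_layout(cfg) == []

    def test_counts_and_min_distance(self, small_config):
        layout = sample_bead_layout(small_config)
        assert len(layout) == 4 * 50
        per_pop = {p.population_id: 0 for p in small_config.populations}
        for b in layout:
            per_pop[b.population_id] += 1
        assert set(per_pop.values()) == {50}
        assert _pairwise_min_distance(layout) >= small_config.min_center_distance

    def test_layout_reproducible_for_fixed_seed(self, small_config):
        a = sample_bead_layout(small_config)
        b = sample_bead_layout(small_config)
        assert [x.center for x in a] == [x.center for x in b]
        assert [x.enc1 for x in a] == [x.enc1 for x in b]

    def test_encoding_intensities_match_generator_moments(self):
        """Sample mean of per-bead encoding draws sits within 3 SE of the
        nominal level for the configured coefficient of variation."""
        panel = default_panel(1)
        nominal = panel.populations[0].enc1  # 176.8 a.u. at ratio 2^-3.5
        cfg = SimConfig(
            populations=tuple(panel.populations), image_shape=(2200, 2200),
            beads_per_population=1000, min_center_distance=16.0, encoding_cv=0.05,
            seed=7,
        )
        layout = sample_bead_layout(cfg)
        vals = np.array([b.enc1 for b in layout])
        se = nominal * 0.05 / np.sqrt(1000)
        assert abs(vals.mean() - nominal) < 3 * se

    def test_capacity_error_when_chip_too_dense(self, small_panel):
        cfg = SimConfig(
            populations=tuple(small_panel.populations), image_shape=(120, 120),
            beads_per_population=200, min_center_distance=20.0,
        )
        with pytest.raises(PlacementError):
            sample_bead_layout(cfg)

    def test_truth_table_conserves_bead_count(self, small_config):
        layout = sample_bead_layout(small_config)
        frame = layout_to_frame(layout)
        assert len(frame) == small_config.beads_per_population * len(small_config.populations)
        assert frame["bead_id"].is_unique


class TestRendering:
    def test_center_pixel_equals_encoding_plus_background(self, noise_free_chip, noise_free_config):
        image, layout = noise_free_chip
        bg = noise_free_config.background_level
        for bead in layout[:20]:
            r, c = int(round(bead.center[0])), int(round(bead.center[1]))
            assert image.encode1[r, c] == pytest.approx(bead.enc1 + bg, rel=0.01)
            assert image.encode2[r, c] == pytest.approx(bead.enc2 + bg, rel=0.01)

    def test_zero_halo_measurement_channel_is_flat_background(self, small_panel):
        cfg = SimConfig(
            populations=tuple(small_panel.populations), image_shape=(400, 400),
            beads_per_population=10, min_center_distance=22.0,
            halo_amplitude_map={}, shot_noise=False, read_noise_sd=0.0,
        )
        layout = sample_bead_layout(cfg)
        image = render_chip_image(layout, cfg)
        assert np.all(image.measure == int(cfg.background_level))

    def test_same_seed_renders_bit_identical_images(self, small_config):
        rng1 = np.random.default_rng(small_config.seed)
        rng2 = np.random.default_rng(small_config.seed)
        l1 = sample_bead_layout(small_config, rng1)
        l2 = sample_bead_layout(small_config, rng2)
        i1 = render_chip_image(l1, small_config, rng1)
        i2 = render_chip_image(l2, small_config, rng2)
        assert np.array_equal(i1.encode1, i2.encode1)
        assert np.array_equal(i1.measure, i2.measure)

    def test_shot_noise_variance_tracks_mean(self, small_panel):
        """In photon-scaled units the pixel variance of a flat region grows
        ~1:1 with its mean when shot noise is on."""
        means, variances = [], []
        for level in (200.0, 800.0, 3200.0):
            cfg = SimConfig(
                populations=tuple(small_panel.populations), image_shape=(200, 200),
                beads_per_population=0, background_level=level,
                read_noise_sd=0.0, shot_noise=True, seed=5,
            )
            img = render_chip_image([], cfg)
            means.append(img.measure.astype(float).mean())
            variances.append(img.measure.astype(float).var())
        slope = np.polyfit(means, variances, 1)[0]
        assert slope == pytest.approx(1.0, rel=0.1)

    def test_rejects_bead_outside_image(self, small_panel):
        from beadscreen.simchip import BeadGroundTruth

        cfg = SimConfig(populations=tuple(small_panel.populations), image_shape=(100, 100))
        bad = BeadGroundTruth(0, (500.0, 500.0), 5.0, "P00", 2000.0, 500.0, 0.0)
        with pytest.raises(ValueError):
            render_chip_image([bad], cfg)


class TestScreenDataset:
    def test_programmed_amplitudes_follow_response_model(self, small_panel):
        import pandas as pd

        from beadscreen.doseresponse import predict

        doses = [0.0, 100.0, 1000.0]
        design = pd.DataFrame({"well": [f"w{i}" for i in range(3)], "dose": doses})
        cfg = SimConfig(
            populations=tuple(small_panel.populations), image_shape=(500, 500),
            beads_per_population=20, min_center_distance=22.0, seed=3,
        )

        def model(pop_id, dose):
            if pop_id == "P00":
                return predict("LL.3", {"b": 2.0, "d": 1000.0, "e": 150.0}, dose)
            return 300.0

        out = generate_screen_dataset(design, cfg, model)
        assert len(out) == 3
        for (image, truth, row), dose in zip(out, doses):
            expected = model("P00", dose)
            got = truth.loc[truth["population"] == "P00", "halo_amp"].unique()
            assert got == pytest.approx([expected])
            assert set(truth.loc[truth["population"] == "P01", "halo_amp"]) == {300.0}

    def test_unknown_population_in_response_model_rejected(self, small_panel):
        import pandas as pd

        cfg = SimConfig(populations=tuple(small_panel.populations), image_shape=(400, 400),
                        beads_per_population=5, min_center_distance=22.0)
        design = pd.DataFrame({"well": ["w0"], "dose": [0.0]})

        class Flat:
            def predict(self, dose):
                return 100.0

        with pytest.raises(ValueError, match="unknown population"):
            generate_screen_dataset(design, cfg, {"NOPE": Flat()})

    def test_timeseries_frames_share_layout_and_ramp_amplitude(self, small_panel):
        cfg = SimConfig(
            populations=tuple(small_panel.populations), image_shape=(400, 400),
            beads_per_population=10, min_center_distance=22.0, seed=9,
        )
        frames = generate_timeseries(
            cfg, lambda pid, t: 100.0 * t, times=[0.0, 1.0, 2.0, 3.0, 4.0]
        )
        assert len(frames) == 5
        amp_means = [truth["halo_amp"].mean() for _, _, truth in frames]
        assert amp_means == sorted(amp_means)
        pos0 = frames[0][2][["row", "col"]].to_numpy()
        pos4 = frames[4][2][["row", "col"]].to_numpy()
        assert np.array_equal(pos0, pos4)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"encoding_cv": 1.5},
            {"beads_per_population": -1},
            {"halo_amplitude_map": {"P00": -5.0}},
            {"halo_amplitude_map": {"NOPE": 5.0}},
            {"min_center_distance": 5.0},  # below largest diameter, no doublets
        ],
    )
    def test_invalid_configs_rejected(self, small_panel, kwargs):
        with pytest.raises(ValueError):
            SimConfig(populations=tuple(small_panel.populations), **kwargs)

    def test_roundtrip_tiff_and_truth(self, tmp_path, small_panel):
        from beadscreen import read_chip_tiff, write_chip

        cfg = SimConfig(
            populations=tuple(small_panel.populations), image_shape=(300, 300),
            beads_per_population=5, min_center_distance=22.0, seed=2,
        )
        layout = sample_bead_layout(cfg)
        image = render_chip_image(layout, cfg, well_id="A01")
        tiff_path, csv_path = write_chip(image, layout, tmp_path)
        back = read_chip_tiff(tiff_path)
        assert back.well_id == "A01"
        assert np.array_equal(back.measure, image.measure)
        assert csv_path.exists()
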