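"""Concentration estimation, merge occupancy, and detection limits."""

import numpy as np
import pytest

import flowim as f
from flowim.quantify import RoiClassCounts


class TestDilutionSeries:
    def test_parabolic_default_cumulative(self):
        assert f.dilution_series().cumulative_factors == [
            12, 120, 960, 5760, 23040, 46080
        ]

    def test_single_step(self):
        assert f.dilution_series([2]).cumulative_factors == [2]

    def test_empty_series(self):
        assert f.dilution_series([]).cumulative_factors == []

    def test_rejects_factor_at_or_below_one(self):
        with pytest.raises(ValueError):
            f.dilution_series([12, 1])


class TestEstimateConcentration:
    def test_known_arithmetic(self):
        # 62 cells in 100 frames of 0.062 uL at dilution 1 -> 1e4 /mL
        est = f.estimate_concentration(
            RoiClassCounts(in_focus_cells=62), frames=100,
            volume_per_frame_ul=0.062,
        )
        assert est.cells_per_ml == pytest.approx(1.0e4)
        assert est.merge_component == 0.0

    def test_zero_counts(self):
        est = f.estimate_concentration(RoiClassCounts(), frames=10,
                                       volume_per_frame_ul=0.062)
        assert est.cells_per_ml == 0.0

    def test_merge_linearity(self):
        base = f.estimate_concentration(
            RoiClassCounts(in_focus_cells=5), frames=10,
            volume_per_frame_ul=0.1,
        )
        with_merges = f.estimate_concentration(
            RoiClassCounts(in_focus_cells=5, multi_object_rois=10),
            merge_occupancy=2.0, frames=10, volume_per_frame_ul=0.1,
        )
        added = 10 * 2.0 / (10 * 0.1) * 1000
        assert with_merges.cells_per_ml == pytest.approx(
            base.cells_per_ml + added
        )

    def test_debris_and_out_of_focus_excluded(self):
        est = f.estimate_concentration(
            RoiClassCounts(in_focus_cells=10, out_of_focus_cells=50, debris=99),
            frames=1, volume_per_frame_ul=1.0,
        )
        assert est.cells_per_ml == pytest.approx(10 * 1000.0)

    def test_linearity_in_dilution_and_volume(self):
        c = RoiClassCounts(in_focus_cells=20)
        e1 = f.estimate_concentration(c, frames=4, volume_per_frame_ul=0.05,
                                      dilution=1.0)
        e2 = f.estimate_concentration(c, frames=4, volume_per_frame_ul=0.05,
                                      dilution=3.0)
        e3 = f.estimate_concentration(c, frames=4, volume_per_frame_ul=0.025,
                                      dilution=1.0)
        assert e2.cells_per_ml == pytest.approx(3 * e1.cells_per_ml)
        assert e3.cells_per_ml == pytest.approx(2 * e1.cells_per_ml)

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            f.estimate_concentration(RoiClassCounts(), frames=0)

    def test_low_occupancy_with_merges_rejected(self):
        with pytest.raises(ValueError):
            f.estimate_concentration(
                RoiClassCounts(multi_object_rois=3), merge_occupancy=1.0,
                frames=1,
            )

    def test_replicate_cv_recorded(self):
        est = f.estimate_concentration(
            RoiClassCounts(in_focus_cells=5), frames=1,
            volume_per_frame_ul=1.0,
            replicate_densities=[900.0, 1000.0, 1100.0],
        )
        assert est.replicate_cv == pytest.approx(0.1, abs=0.01)


class TestMergeOccupancy:
    def test_double_area_gives_two(self):
        assert f.merge_occupancy_estimate([20.0], 10.0) == 2.0

    def test_rounding(self):
        assert f.merge_occupancy_estimate([46.0], 10.0) == 5.0

    def test_floor_of_two(self):
        assert f.merge_occupancy_estimate([8.0], 10.0) == 2.0

    def test_mean_over_rois(self):
        assert f.merge_occupancy_estimate([20.0, 30.0], 10.0) == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            f.merge_occupancy_estimate([], 10.0)

    def test_synthetic_clusters_recovered(self, small_cfg):
        """Touching k-cell clusters: area-ratio occupancy lands near k."""
        s = small_cfg.sample_pixel_size
        d = 5.0
        single = f.render_scene(
            [f.ParticleSpec(center=(100 * s, 100 * s), diameter=d)],
            small_cfg, noise_sd=0.0, seed=1,
        )
        single_area = f.extract_features(
            f.segment_detect(single.frames, margin_um=2.0)[0]
        )["area"]
        ks, estimates = (2, 3, 4), []
        for k in ks:
            # k cells in a tight row, centers 0.9 d apart -> one blob
            parts = [
                f.ParticleSpec(center=((300 + i * 0.9 * d / s) * s, 300 * s),
                               diameter=d)
                for i in range(k)
            ]
            scene = f.render_scene(parts, small_cfg, noise_sd=0.0, seed=2)
            roi = f.segment_detect(scene.frames, margin_um=2.0)[0]
            area = f.extract_features(roi)["area"]
            estimates.append(f.merge_occupancy_estimate([area], single_area))
        assert np.mean(np.abs(np.array(estimates) - np.array(ks))) <= 0.5


class TestDetectionLimits:
    def test_all_zero_blanks(self):
        assert f.limit_of_blank([0.0, 0.0, 0.0]) == 0.0

    def test_lob_arithmetic(self):
        blanks = [2000 - 425.5, 2000 + 425.5]
        lob = f.limit_of_blank(blanks)
        expected = 2000 + 1.645 * np.std(blanks, ddof=1)
        assert lob == pytest.approx(expected)
        assert lob == pytest.approx(2990, rel=0.01)

    def test_lob_monotone_in_sd(self):
        a = f.limit_of_blank([1000, 1100])
        b = f.limit_of_blank([900, 1200])
        assert b > a

    def test_lod_equals_lob_when_noise_free(self):
        assert f.limit_of_detection(2700.0, [5000.0, 5000.0]) == 2700.0

    def test_lod_at_reported_scale(self):
        # LoB 2.7e3 plus z x sd ~ 304 -> ~3.2e3 particles/mL
        low = [5000 - 304, 5000 + 304]
        lod = f.limit_of_detection(2700.0, low)
        assert lod == pytest.approx(2700 + 1.645 * np.std(low, ddof=1))
        assert lod == pytest.approx(3407, rel=0.01)

    def test_lod_never_below_lob(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            lob = float(rng.uniform(0, 5000))
            low = rng.uniform(1000, 9000, size=5)
            assert f.limit_of_detection(lob, low) >= lob

    def test_too_few_measurements_rejected(self):
        with pytest.raises(ValueError):
            f.limit_of_blank([1.0])
        with pytest.raises(ValueError):
            f.limit_of_detection(0.0, [1.0])


class TestLoq:
    def test_cv_rule_application(self):
        # levels engineered with CVs ~ .5, .3, .15, .1
        levels = [
            [1000, 2000, 3000],          # CV .5
            [4000, 5600, 6900],          # CV .26
            [9000, 10000, 11500],        # CV .12
            [20000, 21000, 22000],       # CV .05
        ]
        loq = f.limit_of_quantitation(levels, cv_criterion=0.20)
        assert loq == pytest.approx(np.mean(levels[2]))

    def test_zero_cv_picks_lowest_level_at_or_above_lod(self):
        levels = [[100.0, 100.0], [1000.0, 1000.0], [5000.0, 5000.0]]
        assert f.limit_of_quantitation(levels, lod=500.0) == 1000.0

    def test_no_qualifying_level_returns_none(self):
        assert f.limit_of_quantitation([[1000, 3000]], cv_criterion=0.2) is None

    def test_chain_ordering_invariant(self):
        rng = np.random.default_rng(4)
        blanks = rng.normal(2000, 400, size=6)
        low = rng.normal(5000, 200, size=6)
        series = [list(rng.normal(m, 0.05 * m, size=4))
                  for m in (5e3, 2e4, 1e5, 1e6)]
        dl = f.detection_limits(blanks, low, series)
        assert dl.lob <= dl.lod
        assert dl.loq is None or dl.lod <= dl.loq

    def test_poisson_counting_model_loq_improves_with_volume(self):
        """More imaged volume -> lower counting CV -> lower LoQ."""
        rng = np.random.default_rng(5)
        true_densities = [2e3, 5e3, 2e4, 1e5]

        def loq_for(volume_ul):
            series = []
            for dens in true_densities:
                mean_count = dens * volume_ul / 1000.0
                reps = rng.poisson(mean_count, size=6) / volume_ul * 1000.0
                series.append(list(reps))
            return f.limit_of_quantitation(series, cv_criterion=0.20)

        small = loq_for(0.62)
        large = loq_for(62.0)
        assert large is not None
        assert small is None or large <= small
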