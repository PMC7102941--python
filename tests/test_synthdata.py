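"""Simulator unit and property tests: geometry, crosstalk construction,
planted overlap, motion, puncta populations and the dissociation rule."""

import numpy as np
import pandas as pd
import pytest

from trnafret.synthdata import (DENDRITE, GLIA, SOMA, FretSimConfig,
                                LocalizationSimSpec, MotionConfig,
                                PunctaDistConfig, SimConfig, SplitConfig,
                                apply_puromycin_dissociation,
                                make_neuron_geometry, simulate_fret_channels,
                                simulate_localizations,
                                simulate_puncta_population, simulate_tracks)


class TestGeometry:
    def test_no_dendrites_gives_soma_glia_background_only(self):
        cfg = SimConfig(seed=0, n_dendrites=0)
        masks = make_neuron_geometry(cfg)
        assert set(np.unique(masks.labels)) == {0, GLIA, SOMA}
        assert masks.centerlines == []

    def test_deterministic_for_fixed_seed(self):
        cfg = SimConfig(seed=42)
        m1 = make_neuron_geometry(cfg)
        m2 = make_neuron_geometry(SimConfig(seed=42))
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_different_seed_changes_dendrite_layout(self):
        m1 = make_neuron_geometry(SimConfig(seed=1))
        m2 = make_neuron_geometry(SimConfig(seed=2))
        assert not np.array_equal(m1.labels, m2.labels)

    def test_dendrite_pixel_count_matches_tube_area(self):
        # one dendrite of 200 x 5 px: rasterized tube pixel count within
        # [0.8, 1.2] x (length x width)
        cfg = SimConfig(image_size=(512, 512), seed=3, n_dendrites=1,
                        dendrite_length_px=200, dendrite_width_px=5,
                        soma_radius_px=20)
        masks = make_neuron_geometry(cfg)
        n_px = int((masks.labels == DENDRITE).sum())
        assert 0.8 * 1000 <= n_px <= 1.2 * 1000

    def test_geometry_that_does_not_fit_names_dimension(self):
        with pytest.raises(ValueError, match="dendrite_length_px"):
            make_neuron_geometry(SimConfig(image_size=(64, 64),
                                           dendrite_length_px=500))

    def test_dendrite_pixels_near_centerline(self):
        cfg = SimConfig(seed=5, n_dendrites=3, dendrite_width_px=6)
        masks = make_neuron_geometry(cfg)
        dend = np.argwhere(masks.labels == DENDRITE)
        all_cl = np.vstack(masks.centerlines)
        d2 = ((dend[:, None, :] - all_cl[None, :, :]) ** 2).sum(axis=2)
        # rasterized tube: within width/2 of the (subsampled) centerline,
        # plus half a pixel of rasterization slack
        assert np.sqrt(d2.min(axis=1)).max() <= cfg.dendrite_width_px / 2 + 0.75


class TestFretChannels:
    def test_no_sources_raw_fret_zero(self, default_geometry):
        cfg, masks = default_geometry
        tc = FretSimConfig(a_donor_bleed=0.0, b_acceptor_cross=0.0,
                           fret_fraction=0.0)
        sample, _, _, _ = simulate_fret_channels(masks, tc, cfg)
        assert np.all(sample.fret == 0)

    def test_donor_only_leakage_is_exact_fraction(self, default_geometry):
        cfg, masks = default_geometry
        tc = FretSimConfig(a_donor_bleed=0.3, b_acceptor_cross=0.2)
        _, donor_only, acceptor_only, truth = simulate_fret_channels(masks, tc, cfg)
        np.testing.assert_allclose(donor_only.fret, 0.3 * donor_only.donor,
                                   atol=1e-12)
        np.testing.assert_allclose(acceptor_only.fret, 0.2 * acceptor_only.acceptor,
                                   atol=1e-12)
        assert truth.a_donor_bleed == 0.3
        assert np.all(acceptor_only.donor == 0)

    def test_coefficient_bounds_enforced(self):
        with pytest.raises(ValueError, match="a_donor_bleed"):
            FretSimConfig(a_donor_bleed=1.5)

    def test_deterministic(self, default_geometry):
        cfg, masks = default_geometry
        s1, *_ = simulate_fret_channels(masks, FretSimConfig(), cfg)
        s2, *_ = simulate_fret_channels(masks, FretSimConfig(), cfg)
        np.testing.assert_array_equal(s1.fret, s2.fret)


class TestLocalizations:
    def test_full_overlap_channels_share_regions(self):
        cfg = SimConfig(seed=1)
        spec = LocalizationSimSpec(pairwise_overlap=1.0, triple_overlap=1.0)
        _, truth = simulate_localizations(cfg, spec)
        assert truth.planted_triple == 1.0
        assert truth.patch_membership.all()

    def test_zero_overlap_channels_disjoint(self):
        cfg = SimConfig(seed=1)
        spec = LocalizationSimSpec(pairwise_overlap=0.0, triple_overlap=0.0,
                                   patches_per_channel=8,
                                   field_size_nm=(4000.0, 4000.0))
        _, truth = simulate_localizations(cfg, spec)
        assert truth.planted_triple == 0.0
        assert all(v == 0.0 for v in truth.planted_pairwise.values())
        assert (truth.patch_membership.sum(axis=1) == 1).all()

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            LocalizationSimSpec(pairwise_overlap=0.2, triple_overlap=0.5)

    def test_mode_ratio_floor_enforced(self):
        with pytest.raises(ValueError, match="min_mode_ratio"):
            LocalizationSimSpec(clustered_density=0.002, diffuse_density=0.001)

    def test_tables_have_canonical_columns(self):
        tables, truth = simulate_localizations(SimConfig(seed=4),
                                               LocalizationSimSpec())
        for ch, tab in tables.items():
            assert list(tab.columns[:5]) == ["id", "frame", "x_nm", "y_nm", "channel"]
            assert len(truth.labels[ch]) == len(tab)


class TestTracks:
    def test_static_fraction_one_means_zero_displacement(self):
        cfg = SimConfig(seed=0, n_frames=10)
        _, ts, truth = simulate_tracks(cfg, MotionConfig(
            n_particles=5, static_fraction=1.0))
        for d in truth.displacements:
            assert np.all(d == 0)

    def test_constant_run_displacement_exact(self):
        # one particle at 20 nm/s with dt = 60 s: each step is 1200 nm
        cfg = SimConfig(seed=0, n_frames=5, frame_interval_s=60.0)
        mc = MotionConfig(n_particles=1, speed_median_nm_s=20.0,
                          speed_sigma_log=0.0, p_run_to_pause=0.0,
                          sigma_loc_nm=0.0)
        _, ts, truth = simulate_tracks(cfg, mc)
        steps = np.linalg.norm(truth.displacements[0], axis=1)
        np.testing.assert_allclose(steps, 1200.0, rtol=1e-9)
        assert truth.mean_speeds[0] == pytest.approx(20.0)

    def test_requires_two_frames(self):
        with pytest.raises(ValueError, match="n_frames"):
            simulate_tracks(SimConfig(n_frames=1), MotionConfig(n_particles=1))

    def test_truth_mean_speed_definition(self):
        cfg = SimConfig(seed=3, n_frames=12)
        _, ts, truth = simulate_tracks(cfg, MotionConfig(
            n_particles=8, p_run_to_pause=0.3, p_pause_to_run=0.4))
        for d, m in zip(truth.displacements, truth.mean_speeds):
            expect = np.mean(np.linalg.norm(d, axis=1)) / cfg.frame_interval_s
            assert m == pytest.approx(expect)


class TestPunctaPopulation:
    def test_degenerate_gsd_gives_constant_areas(self):
        pop = simulate_puncta_population(SimConfig(seed=0),
                                         PunctaDistConfig(n=50, gsd=1.0))
        np.testing.assert_allclose(pop["area_nm2"], 4786.3)

    def test_sample_median_recovers_planted(self):
        pop = simulate_puncta_population(SimConfig(seed=1),
                                         PunctaDistConfig(n=10_000))
        assert np.median(pop["area_nm2"]) == pytest.approx(4786.3, rel=0.05)

    def test_unit_quantization(self):
        dist = PunctaDistConfig(n=200, unit_area_nm2=100.0)
        pop = simulate_puncta_population(SimConfig(seed=2), dist)
        expect = np.ceil(pop["area_nm2"] / 100.0)
        np.testing.assert_array_equal(pop["signal_units"], expect)
        assert (pop["signal_units"] >= 1).all()

    def test_gsd_below_one_rejected(self):
        with pytest.raises(ValueError, match="geometric SD"):
            PunctaDistConfig(gsd=0.5)


class TestDissociation:
    def test_population_below_threshold_unchanged(self):
        pop = simulate_puncta_population(SimConfig(seed=0),
                                         PunctaDistConfig(n=20, gsd=1.0,
                                                          unit_area_nm2=4786.3))
        out = apply_puromycin_dissociation(pop, SplitConfig(threshold_units=6))
        pd.testing.assert_frame_equal(out, pop)

    def test_one_large_punctum_splits_conservatively(self):
        pop = pd.DataFrame({
            "id": [0], "x": [5.0], "y": [5.0], "area_px": [100.0],
            "area_nm2": [50_000.0], "mean_intensity": [10.0],
            "signal_units": [100], "compartment": ["soma"],
        })
        pop.attrs["unit_area_nm2"] = 500.0
        out = apply_puromycin_dissociation(pop, SplitConfig(threshold_units=6))
        assert out["signal_units"].sum() == 100
        assert out["signal_units"].max() <= 6
        assert len(out) > 1

    def test_conservation_and_histogram_shift(self):
        pop = simulate_puncta_population(SimConfig(seed=5),
                                         PunctaDistConfig(n=5000))
        out = apply_puromycin_dissociation(pop, SplitConfig(threshold_units=6, seed=5))
        assert out["signal_units"].sum() == pop["signal_units"].sum()
        assert len(out) >= len(pop)
        # dissociation signature: more tiny puncta, no very large ones left
        assert (out["signal_units"] <= 2).sum() > (pop["signal_units"] <= 2).sum()
        assert (pop["signal_units"] > 100).sum() > 0
        assert (out["signal_units"] > 100).sum() == 0
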