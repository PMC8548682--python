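"""Phantom generator ground truth, determinism, and the indentation simulator."""

import dataclasses
import json

import numpy as np
import pytest

from digitbone.synthetic import (
    LABEL_BACKGROUND,
    LABEL_CHANNEL,
    LABEL_CORTICAL,
    LABEL_TRABECULAR,
    IndentationEffects,
    PhantomSpec,
    generate_calibration_phantoms,
    generate_digit_phantom,
    polyline_length,
    render_cohort,
    simulate_indentation_study,
)


class TestPhantomGeometry:
    def test_straight_segment_polyline_length(self):
        # 100 collinear voxel centres at 3.9 um/voxel: 99 * 3.9 = 386.1 um
        line = np.column_stack([np.arange(100.0), np.zeros(100), np.zeros(100)])
        assert polyline_length(line, 3.9) == pytest.approx(386.1)

    def test_no_channels_means_void_free_interior(self):
        spec = PhantomSpec(n_channels=0, seed=5)
        _, truth = generate_digit_phantom(spec)
        assert truth.channel_centerline_length_um == 0.0
        assert not (truth.label_volume == LABEL_CHANNEL).any()

    def test_ground_truth_length_matches_polylines(self, noiseless_phantom):
        _, truth = noiseless_phantom
        total = sum(
            polyline_length(
                np.column_stack([line[:, 0], line[:, 1], line[:, 2]]), 3.9
            )
            for line in truth.channel_polylines
        )
        assert truth.channel_centerline_length_um == pytest.approx(total)
        assert truth.channel_centerline_length_um > 0

    def test_channels_confined_to_interior(self, noiseless_phantom):
        _, truth = noiseless_phantom
        # no channel voxel may sit in the background or breach the cortex
        channel = truth.label_volume == LABEL_CHANNEL
        assert channel.any()
        # every channel voxel was carved out of the trabecular compartment,
        # so cortical and background voxel counts are what a channel-free
        # phantom of the same spec would give or larger
        assert not (channel & (truth.label_volume == LABEL_BACKGROUND)).any()

    def test_ua_phantom_has_solid_cortical_interior(self):
        spec = PhantomSpec(status="UA", n_channels=0, seed=3)
        _, truth = generate_digit_phantom(spec)
        assert not (truth.label_volume == LABEL_TRABECULAR).any()
        assert (truth.label_volume == LABEL_CORTICAL).any()

    def test_mass_consistency_without_blur_or_noise(self, noiseless_phantom):
        """With no blur and no noise the rendered intensity is exactly the
        affine model applied to the compartment density."""
        vol, truth = noiseless_phantom
        for lab, dens in truth.compartment_density.items():
            region = truth.label_volume == lab
            if region.any():
                expected = truth.intensity_slope * dens + truth.intensity_intercept
                np.testing.assert_allclose(vol.data[region], expected, atol=1e-4)

    def test_determinism_and_seed_sensitivity(self):
        spec = PhantomSpec(seed=1, noise_sd=2.0, blur_sigma_voxels=0.8)
        v1, t1 = generate_digit_phantom(spec)
        v2, t2 = generate_digit_phantom(PhantomSpec(seed=1, noise_sd=2.0, blur_sigma_voxels=0.8))
        np.testing.assert_array_equal(v1.data, v2.data)
        assert t1.channel_centerline_length_um == t2.channel_centerline_length_um
        v3, t3 = generate_digit_phantom(dataclasses.replace(spec, seed=2))
        assert not np.array_equal(v1.data, v3.data)
        assert t1.channel_centerline_length_um != t3.channel_centerline_length_um

    @pytest.mark.parametrize(
        "bad",
        [
            dict(channel_radius_voxels=5, cortical_thickness_voxels=5),
            dict(bone_length_voxels=2),
            dict(outer_radius_distal=4.0, cortical_thickness_voxels=5),
            dict(density_trabecular=1.5),  # above cortical
            dict(density_cortical=-1.0, density_trabecular=-2.0,
                 density_background=-3.0),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_digit_phantom(PhantomSpec(**bad))


class TestCalibrationPhantoms:
    def test_identity_model_noiseless_interior_means_exact(self):
        low, high = generate_calibration_phantoms(
            densities=(0.25, 0.75), intensity_model=(1.0, 0.0), noise_sd=0.0
        )
        ny, nx = low.shape[1:]
        yy, xx = np.mgrid[0:ny, 0:nx]
        disc = (yy - (ny - 1) / 2) ** 2 + (xx - (nx - 1) / 2) ** 2 <= (0.4 * ny) ** 2
        assert low.data[:, disc].mean() == pytest.approx(0.25, abs=1e-12)
        assert high.data[:, disc].mean() == pytest.approx(0.75, abs=1e-12)

    def test_equal_densities_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            generate_calibration_phantoms(densities=(0.25, 0.25))

    def test_noisy_interior_mean_within_clt_bound(self):
        noise_sd = 5.0
        low, _ = generate_calibration_phantoms(
            densities=(0.25, 0.75), intensity_model=(1.0, 0.0),
            noise_sd=noise_sd, seed=4, shape=(60, 96, 96),
        )
        ny, nx = low.shape[1:]
        yy, xx = np.mgrid[0:ny, 0:nx]
        disc = (yy - (ny - 1) / 2) ** 2 + (xx - (nx - 1) / 2) ** 2 <= (0.4 * ny) ** 2
        vals = low.data[:, disc]
        n = vals.size
        assert abs(vals.mean() - 0.25) <= 3 * noise_sd / np.sqrt(n)


class TestIndentationSimulator:
    def test_noiseless_degenerate_returns_grand_mean(self):
        eff = IndentationEffects(
            status_effect=0.0, status_effect_H=0.0,
            sd_mouse=0.0, sd_site=0.0, sd_indent=0.0,
            sd_mouse_H=0.0, sd_site_H=0.0, sd_indent_H=0.0,
        )
        df = simulate_indentation_study(eff, seed=0)
        np.testing.assert_allclose(df["E"], 18.0)
        np.testing.assert_allclose(df["H"], 0.8)

    def test_design_counts(self):
        df = simulate_indentation_study(IndentationEffects(), seed=0)
        # 3 mice x 8 sites x 4 indents = 96 records per status group
        assert (df["status"] == "UA").sum() == 96
        assert (df["status"] == "D42").sum() == 96
        by_site = df.groupby(["mouse", "status", "site"]).size()
        assert (by_site == 4).all()
        assert df.groupby(["mouse", "status"])["site"].nunique().eq(8).all()

    def test_cell_mean_difference_converges_to_status_effect(self):
        """Monte-Carlo: mean (UA distal - D42 distal) over many replicates
        approaches 1.96 GPa within 3 standard errors."""
        eff = IndentationEffects()
        diffs = []
        for r in range(500):
            df = simulate_indentation_study(eff, seed=200_000 + r)
            distal = df[df["region"] == "distal"]
            cells = distal.groupby("status")["E"].mean()
            diffs.append(cells["UA"] - cells["D42"])
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - 1.96) <= 3 * se

    def test_reduced_modulus_consistent_with_youngs(self):
        from digitbone.biomechanics import reduced_to_youngs

        df = simulate_indentation_study(IndentationEffects(), seed=2)
        np.testing.assert_allclose(
            reduced_to_youngs(df["E_r"].to_numpy()), df["E"].to_numpy(), rtol=1e-10
        )


class TestRenderCohort:
    def test_cohort_layout_and_manifest(self, tmp_path):
        spec = PhantomSpec(bone_length_voxels=30, outer_radius_proximal=10.0,
                           outer_radius_distal=6.0, cortical_thickness_voxels=3,
                           channel_radius_voxels=1, n_channels=1)
        groups = {
            "UA": (dataclasses.replace(spec, status="UA"), 3),
            "D42": (spec, 3),
        }
        manifest_path = render_cohort(groups, tmp_path / "cohort", seed=9)
        manifest = json.loads(manifest_path.read_text())
        assert len(manifest["digits"]) == 6
        stack_dirs = [d for d in (tmp_path / "cohort").iterdir() if d.is_dir()]
        assert len(stack_dirs) == 6
        # manifest channel lengths are the exact per-phantom ground truth
        for entry in manifest["digits"]:
            _, truth = generate_digit_phantom(
                dataclasses.replace(
                    groups[entry["group"]][0], seed=entry["seed"]
                )
            )
            assert entry["channel_length_um"] == pytest.approx(
                truth.channel_centerline_length_um
            )

    def test_same_seed_byte_identical_manifest(self, tmp_path):
        spec = PhantomSpec(bone_length_voxels=30, outer_radius_proximal=10.0,
                           outer_radius_distal=6.0, cortical_thickness_voxels=3,
                           channel_radius_voxels=1, n_channels=1)
        p1 = render_cohort({"g": (spec, 2)}, tmp_path / "a", seed=3)
        p2 = render_cohort({"g": (spec, 2)}, tmp_path / "b", seed=3)
        assert p1.read_bytes() == p2.read_bytes()
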