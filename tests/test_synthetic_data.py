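"""Generator determinism, geometric ground-truth fidelity, preset means."""

import numpy as np
import pytest

from mitophen import synthetic_data as syn
from mitophen.errors import GeometryError


class TestAnaphaseMovies:
    def test_same_seed_is_bitwise_identical(self, small_movie_acq):
        a, ta = syn.generate_anaphase_movie(
            syn.get_preset("wt"), small_movie_acq, seed=5
        )
        b, tb = syn.generate_anaphase_movie(
            syn.get_preset("wt"), small_movie_acq, seed=5
        )
        assert np.array_equal(a.pixels, b.pixels)
        assert ta.plateau_chrom_um == tb.plateau_chrom_um
        assert np.array_equal(ta.pole_xy, tb.pole_xy)

    def test_jitter_free_plateau_reaches_preset_value(self):
        # 60 one-minute frames ~ 12 time constants: the ramp saturates
        acq = syn.AcquisitionParams(n_frames=60)
        preset = syn.get_preset("wt")
        _, truth = syn.generate_anaphase_movie(
            preset, acq, seed=0, jitter=False, apply_noise=False
        )
        assert truth.plateau_chrom_um == preset.max_chrom_sep_um
        assert truth.chrom_sep_um[-1] == pytest.approx(
            preset.max_chrom_sep_um, rel=1e-4
        )
        assert truth.pole_sep_um[-1] == pytest.approx(
            preset.max_pole_sep_um, rel=1e-4
        )
        assert truth.chrom_sep_um[0] == 0.0
        assert truth.pole_sep_um[0] == preset.initial_pole_sep_um

    def test_separations_are_monotone_ramps(self, wt_movie):
        _, truth = wt_movie
        assert np.all(np.diff(truth.chrom_sep_um) > 0)
        assert np.all(np.diff(truth.pole_sep_um) > 0)
        assert truth.plateau_chrom_um < truth.plateau_pole_um

    def test_plateau_exceeding_field_raises(self):
        acq = syn.AcquisitionParams(image_shape=(64, 64))  # 7 um field
        with pytest.raises(GeometryError):
            syn.generate_anaphase_movie(syn.get_preset("wt"), acq, seed=0)

    @pytest.mark.parametrize("name", ["wt", "e222q", "p144t", "r149q"])
    def test_preset_plateau_means_match_encoded_values(self, name):
        acq = syn.AcquisitionParams(n_frames=10)
        preset = syn.get_preset(name)
        plateaus = np.array([
            syn.generate_anaphase_movie(preset, acq, seed=s)[1].plateau_chrom_um
            for s in range(30)
        ])
        sem = plateaus.std(ddof=1) / np.sqrt(plateaus.size)
        assert abs(plateaus.mean() - preset.max_chrom_sep_um) < 3 * sem


class TestMonopoles:
    def test_jitter_free_blobs_sit_exactly_on_the_ring(self, default_acq):
        img, truth = syn.generate_monopolar_image(
            syn.get_preset("gfp_ctrl"), default_acq, seed=3, jitter=False
        )
        d_px = np.linalg.norm(
            truth.blob_xy - np.asarray(truth.center_xy), axis=1
        )
        d_um = d_px * img.pixel_size_um
        assert np.allclose(d_um, 3.0, atol=1e-9)
        assert truth.ring_radius_um == 3.0

    def test_radius_out_of_roi_raises(self, default_acq):
        from dataclasses import replace
        bad = replace(syn.get_preset("gfp_ctrl"), pef_radius_um=15.0)
        with pytest.raises(GeometryError):
            syn.generate_monopolar_image(bad, default_acq, seed=0)

    @pytest.mark.parametrize("name,encoded", [("gfp_ctrl", 3.0), ("gfp_kd", 1.2)])
    def test_ring_radius_means_match_encoded_values(self, default_acq, name, encoded):
        radii = np.array([
            syn.generate_monopolar_image(
                syn.get_preset(name), default_acq, seed=s
            )[1].ring_radius_um
            for s in range(30)
        ])
        sem = radii.std(ddof=1) / np.sqrt(radii.size)
        assert abs(radii.mean() - encoded) < 3 * sem

    def test_determinism(self, default_acq):
        a, _ = syn.generate_monopolar_image(
            syn.get_preset("gfp_kd"), default_acq, seed=9
        )
        b, _ = syn.generate_monopolar_image(
            syn.get_preset("gfp_kd"), default_acq, seed=9
        )
        assert np.array_equal(a.pixels, b.pixels)


class TestNucleusFields:
    def test_zero_texture_ellipse_is_nearly_convex(self):
        shape = syn.NucleusShapeParams(normal_scale=1e-9)
        from dataclasses import replace
        preset = replace(syn.PRESETS["gfp_ctrl"], abnormal_frac=0.0)
        _, truth = syn.generate_nucleus_field(
            preset, syn.nucleus_acquisition(4), 4, seed=2, shape_params=shape
        )
        assert np.all(truth.solidity >= 0.99)
        assert truth.labels == ["normal"] * 4

    def test_lobed_fraction_tracks_preset(self):
        preset = syn.PRESETS["p144t"]
        acq = syn.nucleus_acquisition(16)
        labels = []
        for s in range(25):
            _, truth = syn.generate_nucleus_field(preset, acq, 16, seed=s)
            labels.extend(truth.labels)
        frac = np.mean([lab == "lobed" for lab in labels])
        se = np.sqrt(preset.abnormal_frac * (1 - preset.abnormal_frac) / len(labels))
        assert abs(frac - preset.abnormal_frac) < 3 * se

    def test_overcrowded_field_raises(self):
        acq = syn.AcquisitionParams(image_shape=(128, 128))
        with pytest.raises(GeometryError):
            syn.generate_nucleus_field(syn.PRESETS["gfp_ctrl"], acq, 16, seed=0)

    def test_calibrated_texture_separates_components(self):
        """Lobed nuclei fall below the threshold; normals mostly do not."""
        shape = syn.default_shape_params()
        from dataclasses import replace
        lobed = replace(syn.PRESETS["gfp_ctrl"], abnormal_frac=1.0)
        normal = replace(syn.PRESETS["gfp_ctrl"], abnormal_frac=0.0)
        sol_l = syn.measure_control_solidity(
            syn.AcquisitionParams(), shape, 120, seed=6, preset=lobed
        )
        sol_n = syn.measure_control_solidity(
            syn.AcquisitionParams(), shape, 120, seed=6, preset=normal
        )
        assert np.mean(sol_l < 0.966) >= 0.95
        assert np.mean(sol_n >= 0.966) >= 0.95

    def test_zero_texture_raises_fifth_percentile(self):
        """Direction of the calibration: less texture -> higher percentile."""
        acq = syn.AcquisitionParams()
        flat = syn.measure_control_solidity(
            acq, syn.NucleusShapeParams(1e-9), 200, seed=4
        )
        calibrated = syn.measure_control_solidity(
            acq, syn.default_shape_params(), 200, seed=4
        )
        assert np.percentile(flat, 5) > np.percentile(calibrated, 5)


class TestExpressionImages:
    def test_fold_linearity_before_noise(self, default_acq):
        from dataclasses import replace
        base = syn.get_preset("gfp_ctrl")
        one, _ = syn.generate_expression_image(
            base, default_acq, seed=4, jitter=False, apply_noise=False
        )
        double, _ = syn.generate_expression_image(
            replace(base, expression_fold=2.0), default_acq, seed=4,
            jitter=False, apply_noise=False,
        )
        bg = default_acq.photon_scale * default_acq.background_level
        kif1 = one.pixels[0, 1, 0].astype(float) - bg
        kif2 = double.pixels[0, 1, 0].astype(float) - bg
        hot = kif1 > kif1.max() * 0.2
        ratio = kif2[hot] / kif1[hot]
        assert np.allclose(ratio, 2.0, atol=1e-3)

    def test_truth_records_realized_fold(self, default_acq):
        _, truth = syn.generate_expression_image(
            syn.get_preset("gfp_kd"), default_acq, seed=8, jitter=False
        )
        assert truth.expression_fold == 0.25


def test_noise_snr_decreases_with_background():
    """Photon-limited SNR falls monotonically as background rises."""
    snrs = []
    for bg in [0.3, 1.5, 6.0]:
        acq = syn.AcquisitionParams(background_level=bg)
        img, truth = syn.generate_monopolar_image(
            syn.get_preset("gfp_ctrl"), acq, seed=2
        )
        dna = img.pixels[0, 0, 0].astype(float)
        corner = dna[:40, :40]  # object-free region
        snrs.append((dna.max() - corner.mean()) / corner.std())
    assert snrs[0] > snrs[1] > snrs[2]
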