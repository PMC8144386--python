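"""Spectral pipeline: per-pixel spectra, beating classification, field metrics."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from npphen import (
    CiliaSimSpec,
    Patch,
    SpectralConfig,
    VideoField,
    aggregate,
    analyze_field,
    dominant_component,
    field_metrics,
    pixel_spectrum,
    simulate_cilia_video,
    spectral_map,
)
from conftest import dft_oracle


def sinusoid(amp, freq, n=720, fps=360.0, phase=0.0):
    t = np.arange(n) / fps
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestPixelSpectrum:
    def test_constant_series_has_zero_spectrum(self):
        f, m = pixel_spectrum(np.full(100, 7.0), 360.0)
        assert np.allclose(m, 0.0, atol=1e-12)

    def test_on_bin_sinusoid_recovers_amplitude_at_its_frequency(self):
        f, m = pixel_spectrum(sinusoid(3.0, 17.0), 360.0)
        k = np.flatnonzero(f == 17.0)
        assert k.size == 1
        assert m[k[0]] == pytest.approx(3.0, abs=1e-9)
        rest = np.delete(m, k[0])
        assert np.all(rest < 1e-9)

    def test_two_tone_series_is_linear(self):
        x = sinusoid(2.0, 10.0) + sinusoid(5.0, 40.0)
        f, m = pixel_spectrum(x, 360.0)
        assert m[f == 10.0][0] == pytest.approx(2.0, abs=1e-9)
        assert m[f == 40.0][0] == pytest.approx(5.0, abs=1e-9)

    @pytest.mark.parametrize(
        "bad", [np.arange(3.0), np.array([1.0, np.nan, 2.0, 3.0, 4.0])]
    )
    def test_short_or_nonfinite_series_rejected(self, bad):
        with pytest.raises(ValueError):
            pixel_spectrum(bad, 360.0)

    def test_matches_direct_dft_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 257))
            x = rng.normal(0, 1, n) * 10
            f, m = pixel_spectrum(x, 360.0)
            fo, mo = dft_oracle(x, 360.0)
            np.testing.assert_allclose(f, fo)
            scale = max(mo.max(), 1e-12)
            np.testing.assert_allclose(m, mo, rtol=0, atol=1e-8 * scale)

    @given(st.integers(min_value=8, max_value=64), st.integers())
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_property(self, n, seed):
        x = np.random.default_rng(abs(seed) % 2**31).normal(0, 5, n)
        f, m = pixel_spectrum(x, 100.0)
        _, mo = dft_oracle(x, 100.0)
        np.testing.assert_allclose(m, mo, rtol=0, atol=1e-8 * max(mo.max(), 1e-12))


class TestDominantComponent:
    def test_single_in_band_peak(self):
        f = np.array([10.0, 20.0, 30.0])
        m = np.array([0.01, 4.0, 0.02])
        assert dominant_component(f, m, (2, 60)) == (20.0, 4.0)

    def test_out_of_band_maximum_ignored(self):
        f = np.array([20.0, 70.0])
        m = np.array([3.0, 9.0])
        assert dominant_component(f, m, (2, 60)) == (20.0, 3.0)

    def test_tie_breaks_toward_lowest_frequency(self):
        f = np.array([10.0, 30.0])
        m = np.array([2.5, 2.5])
        assert dominant_component(f, m, (2, 60)) == (10.0, 2.5)

    def test_band_edges_are_closed(self):
        f = np.array([2.0, 60.0, 61.0])
        m = np.array([1.0, 5.0, 9.0])
        assert dominant_component(f, m, (2, 60)) == (60.0, 5.0)

    def test_empty_band_raises_with_resolution(self):
        f = np.array([10.0, 20.0])
        m = np.array([1.0, 2.0])
        with pytest.raises(ValueError, match="resolution"):
            dominant_component(f, m, (30, 40))


def tiny_field(amp, freq, n=720, fps=360.0, shape=(2, 2)):
    t = np.arange(n) / fps
    wave = amp * np.sin(2 * np.pi * freq * t)
    stack = 50.0 + np.tile(wave[:, None, None], (1, *shape))
    return VideoField(stack, fps=fps)


class TestSpectralMap:
    def test_subthreshold_amplitude_is_not_beating(self):
        smap = spectral_map(tiny_field(0.5, 17.0))
        assert not smap.beating.any()

    def test_amplitude_exactly_at_threshold_is_not_beating(self):
        # strict inequality: magnitude must exceed 1, not equal it
        smap = spectral_map(tiny_field(1.0, 17.0))
        assert not smap.beating.any()

    def test_suprathreshold_pixel_beats_at_true_frequency(self):
        smap = spectral_map(tiny_field(3.0, 17.0))
        assert smap.beating.all()
        assert np.all(smap.dominant_freq == 17.0)
        np.testing.assert_allclose(smap.dominant_mag, 3.0, atol=1e-6)

    def test_out_of_band_oscillation_is_not_beating(self):
        smap = spectral_map(tiny_field(5.0, 80.0))
        assert not smap.beating.any()

    def test_nonfinite_pixel_reported_with_coordinates(self):
        stack = np.zeros((8, 2, 3))
        stack[5, 1, 2] = np.inf
        with pytest.raises(ValueError, match=r"row=1, col=2"):
            spectral_map(VideoField(stack, fps=360.0))

    def test_off_bin_frequency_recovered_within_one_bin(self):
        # half-bin worst case plus leakage: |err| <= 1.5 * fps/N
        fps, n = 360.0, 720
        for true_f in (17.23, 33.91, 7.77):
            smap = spectral_map(tiny_field(5.0, true_f, n=n, fps=fps))
            assert smap.beating.all()
            assert np.all(np.abs(smap.dominant_freq - true_f) <= 1.5 * fps / n)


class TestFieldMetrics:
    def test_no_beating_pixels_yields_zero_cbs_and_undefined_cbf(self):
        m = analyze_field(tiny_field(0.2, 17.0))
        assert m.cbs_percent == 0.0
        assert not m.cbf_defined
        assert math.isnan(m.cbf_mean)

    def test_quarter_area_patch_gives_cbs_25(self):
        spec = CiliaSimSpec(
            height=32, width=32, frames=240, patches=[Patch(0, 0, 16, 16, 18.0, 5.0)],
            noise_sd=0.0, dtype="float64",
        )
        video, _ = simulate_cilia_video(spec)
        m = analyze_field(video)
        assert m.cbs_percent == 25.0
        assert m.cbf_mean == 18.0
        assert m.n_total == 32 * 32

    def test_cbf_is_arithmetic_mean_over_two_equal_patches(self):
        spec = CiliaSimSpec(
            height=32, width=32, frames=240, noise_sd=0.0, dtype="float64",
            patches=[
                Patch(0, 0, 16, 32, 15.0, 5.0),
                Patch(16, 0, 16, 32, 18.0, 5.0),
            ],
        )
        video, _ = simulate_cilia_video(spec)
        m = analyze_field(video)
        assert m.cbs_percent == 100.0
        assert m.cbf_mean == pytest.approx(16.5)

    def test_beating_mask_matches_simulator_ground_truth(self):
        spec = CiliaSimSpec(
            height=48, width=40, frames=240, noise_sd=0.0, dtype="float64",
            patches=[
                Patch(2, 3, 10, 12, 21.0, 4.0),
                Patch(30, 20, 8, 8, 9.0, 2.5),
                Patch(20, 0, 4, 4, 33.0, 0.5),  # subthreshold: not in truth
            ],
        )
        video, truth = simulate_cilia_video(spec)
        smap = spectral_map(video)
        np.testing.assert_array_equal(smap.beating, truth.mask)

    def test_cbs_non_decreasing_as_patches_added(self):
        base = [Patch(0, 0, 8, 8, 12.0, 5.0)]
        extra = [Patch(16, 16, 8, 8, 24.0, 5.0), Patch(0, 24, 6, 6, 30.0, 5.0)]
        prev = -1.0
        for k in range(3):
            spec = CiliaSimSpec(
                height=32, width=32, frames=120, noise_sd=0.0, dtype="float64",
                patches=base + extra[:k],
            )
            video, _ = simulate_cilia_video(spec)
            cbs = analyze_field(video).cbs_percent
            assert cbs >= prev
            prev = cbs


class TestAggregate:
    def make(self, cbs, cbf=17.0, field_id="f", well_id="w", donor_id="d"):
        from npphen.cilia import CiliaryFieldMetrics

        return CiliaryFieldMetrics(
            cbf_mean=cbf, cbs_percent=cbs, n_beating=10 if not math.isnan(cbf) else 0,
            n_total=100, field_id=field_id, well_id=well_id, donor_id=donor_id,
        )

    def test_identical_fields_have_zero_sem(self):
        fields = [self.make(25.0, field_id=f"f{i}") for i in range(10)]
        well, donor = aggregate(fields)
        assert well.loc[0, "cbs_mean"] == 25.0
        assert well.loc[0, "cbs_sem"] == 0.0
        assert well.loc[0, "n"] == 10

    def test_sem_matches_closed_form(self):
        fields = [self.make(v, field_id=f"f{v}") for v in (10.0, 20.0, 30.0)]
        well, _ = aggregate(fields)
        assert well.loc[0, "cbs_mean"] == pytest.approx(20.0)
        assert well.loc[0, "cbs_sem"] == pytest.approx(10.0 / math.sqrt(3))

    def test_undefined_cbf_fields_excluded_and_counted(self):
        fields = [self.make(0.0, cbf=math.nan)]
        well, donor = aggregate(fields)
        assert well.loc[0, "n_cbf"] == 0
        assert math.isnan(well.loc[0, "cbf_mean"])

    def test_donor_level_averages_wells_unweighted(self):
        fields = (
            [self.make(10.0, well_id="w1", field_id=f"a{i}") for i in range(4)]
            + [self.make(30.0, well_id="w2", field_id="b0")]
        )
        _, donor = aggregate(fields)
        # two wells at 10 and 30 -> donor mean 20, regardless of field counts
        assert donor.loc[0, "cbs_mean"] == pytest.approx(20.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            aggregate([])


class TestConfigValidation:
    def test_band_above_nyquist_rejected(self):
        cfg = SpectralConfig(band_high=60.0)
        with pytest.raises(ValueError, match="Nyquist"):
            cfg.validate_for(fps=100.0)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            SpectralConfig(band_low=60.0, band_high=2.0)

    def test_default_geometry_denominator(self):
        assert CiliaSimSpec().height * CiliaSimSpec().width == 786_432
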