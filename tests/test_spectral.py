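import numpy as np
import pytest

from voccspec.spectral import (
    Spectrum,
    cutoff_frequency,
    default_frequency_grid,
    exclude_first_peak,
    extract_features,
    first_peak_cut_index,
    inner_product_spectrum,
    lombscargle_psd,
    subject_spectral_features,
)
from voccspec.vocc import VoCCCurve


def lsq_sinusoid_power(t, x, f):
    """Independent oracle: half the fitted sum of squares of a*cos + b*sin."""
    D = np.column_stack([np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)])
    beta, *_ = np.linalg.lstsq(D, x, rcond=None)
    return 0.5 * np.sum((D @ beta) ** 2)


class TestFrequencyGrid:
    def test_unit_oversample_arithmetic_grid(self):
        freqs = default_frequency_grid(101, oversample=1)
        np.testing.assert_allclose(freqs, np.arange(1, 51) * 0.01)

    def test_oversample_densifies_without_moving_endpoints(self):
        base = default_frequency_grid(101, oversample=1)
        dense = default_frequency_grid(101, oversample=4)
        assert len(dense) == 4 * len(base)
        assert dense[-1] <= 0.5 and 0.5 - dense[-1] < dense[0]

    @pytest.mark.parametrize("n,oversample", [(4, 1), (64, 2.5), (500, 8)])
    def test_nyquist_bound(self, n, oversample):
        assert default_frequency_grid(n, oversample)[-1] <= 0.5

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="at least 4"):
            default_frequency_grid(3)


class TestLombScarglePSD:
    def test_constant_curve_has_no_power(self):
        spec = lombscargle_psd(np.full(50, 3.7), default_frequency_grid(50))
        assert np.all(spec.power <= 1e-10)

    def test_recovers_known_frequency(self):
        t = np.arange(1, 101)
        freqs = default_frequency_grid(100, oversample=2)
        spec = lombscargle_psd(np.cos(2 * np.pi * 0.1 * t), freqs)
        peak = spec.frequencies[np.argmax(spec.power)]
        assert abs(peak - 0.10) <= freqs[0]  # within one grid step

    def test_matches_least_squares_oracle(self, rng):
        x = rng.normal(size=40)
        t = np.arange(1, 41, dtype=float)
        freqs = default_frequency_grid(40, oversample=3)
        spec = lombscargle_psd(x, freqs)
        xc = x - x.mean()
        for f, p in zip(freqs[::5], spec.power[::5]):
            expected = lsq_sinusoid_power(t, xc, f)
            assert abs(p - expected) <= 1e-8 * max(expected, 1e-30)

    def test_uniform_sampling_matches_classical_periodogram(self, rng):
        # on a uniform grid LS reduces to the DFT periodogram (n/4 * |a|^2
        # at interior Fourier frequencies for amplitude-a components)
        n = 64
        x = rng.normal(size=n)
        x -= x.mean()
        t = np.arange(1, n + 1, dtype=float)
        k = np.arange(4, 28)
        freqs = k / n  # interior Fourier frequencies
        spec = lombscargle_psd(x, freqs)
        dft = np.abs(np.fft.rfft(x)) ** 2 / n  # classical periodogram at k/n
        np.testing.assert_allclose(spec.power, dft[k], rtol=1e-6)

    def test_power_scales_quadratically(self, rng):
        x = rng.normal(size=30)
        freqs = default_frequency_grid(30)
        base = lombscargle_psd(x, freqs).power
        scaled = lombscargle_psd(5.0 * x, freqs).power
        np.testing.assert_allclose(scaled, 25.0 * base, rtol=1e-9)

    def test_non_finite_curve_raises(self):
        bad = np.ones(20)
        bad[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            lombscargle_psd(bad, default_frequency_grid(20))


class TestInnerProductSpectrum:
    def test_multiplicative_identity(self, rng):
        f = default_frequency_grid(30)
        P = Spectrum(f, rng.uniform(size=f.size))
        ones = Spectrum(f, np.ones(f.size))
        np.testing.assert_array_equal(inner_product_spectrum(P, ones).power, P.power)

    def test_zero_annihilates(self, rng):
        f = default_frequency_grid(30)
        P = Spectrum(f, rng.uniform(size=f.size))
        zero = Spectrum(f, np.zeros(f.size))
        assert np.all(inner_product_spectrum(P, zero).power == 0)

    def test_elementwise_product(self, rng):
        f = default_frequency_grid(25)
        a, b = rng.uniform(size=f.size), rng.uniform(size=f.size)
        out = inner_product_spectrum(Spectrum(f, a), Spectrum(f, b))
        np.testing.assert_array_equal(out.power, a * b)

    def test_grid_mismatch_raises(self):
        f = np.linspace(0.01, 0.4, 10)
        with pytest.raises(ValueError, match="grid"):
            inner_product_spectrum(
                Spectrum(f, np.ones(10)), Spectrum(f + 0.005, np.ones(10))
            )


class TestExcludeFirstPeak:
    def test_hand_traced_rule(self):
        spec = Spectrum(np.arange(1, 6) * 0.1, np.array([9.0, 4, 1, 6, 3]))
        out = exclude_first_peak(spec)
        np.testing.assert_array_equal(out.power, [6.0, 3.0])

    def test_strictly_decreasing_spectrum_is_exhausted(self):
        spec = Spectrum(np.arange(1, 7) * 0.05, np.array([9.0, 7, 5, 3, 2, 1]))
        with pytest.raises(ValueError, match="spectrum exhausted"):
            exclude_first_peak(spec)

    def test_two_peak_spectrum_keeps_the_second_peak(self):
        f = default_frequency_grid(100, oversample=1)
        power = np.exp(-((f - 0.02) ** 2) / 0.0005) + 0.6 * np.exp(-((f - 0.2) ** 2) / 0.0005)
        out = exclude_first_peak(Spectrum(f, power))
        assert out.frequencies[np.argmax(out.power)] == pytest.approx(0.2, abs=0.01)

    def test_always_removes_a_nonempty_prefix(self, rng):
        """The retained spectrum is a proper suffix: the cut lands past the
        first descent, so at least the leading point always goes."""
        for _ in range(20):
            power = rng.uniform(0.1, 1.0, size=30)
            power[0] = 2.0  # the first point is the first local max
            spec = Spectrum(np.arange(1, 31) * 0.01, power)
            cut = first_peak_cut_index(spec.power)
            assert 1 <= cut <= 28
            out = exclude_first_peak(spec)
            np.testing.assert_array_equal(out.power, spec.power[cut:])
            np.testing.assert_array_equal(out.frequencies, spec.frequencies[cut:])

    def test_cut_index_on_short_spectrum_raises(self):
        with pytest.raises(ValueError, match="at least 5"):
            first_peak_cut_index(np.array([3.0, 1, 2, 1]))


class TestCutoffFrequency:
    def test_threshold_example(self):
        spec = Spectrum(np.array([0.1, 0.2, 0.3]), np.array([8.0, 4.0, 0.0]))
        assert cutoff_frequency(spec, epsilon=0.01) == pytest.approx(0.3)

    def test_falls_back_to_largest_frequency(self):
        spec = Spectrum(np.array([0.1, 0.2, 0.3]), np.array([8.0, 4.0, 2.0]))
        assert cutoff_frequency(spec, epsilon=0.01) == pytest.approx(0.3)

    def test_matches_suffix_scan_oracle(self, rng):
        f = default_frequency_grid(60)
        for _ in range(10):
            power = np.exp(-f * rng.uniform(5, 40)) * rng.uniform(0.5, 2)
            power += rng.uniform(0, 0.02, size=f.size) * power.max()
            spec = Spectrum(f, power)
            thr = 0.05 * power.max()
            candidates = [
                f[i] for i in range(f.size) if np.all(power[i:] < thr)
            ]
            expected = candidates[0] if candidates else f[-1]
            assert cutoff_frequency(spec, 0.05) == pytest.approx(expected)

    def test_monotone_non_increasing_in_epsilon(self, rng):
        f = default_frequency_grid(50)
        spec = Spectrum(f, np.exp(-10 * f) + 0.001 * rng.uniform(size=f.size))
        values = [cutoff_frequency(spec, e) for e in (0.001, 0.01, 0.1, 0.5)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_all_zero_spectrum_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            cutoff_frequency(Spectrum(np.array([0.1, 0.2]), np.zeros(2)))


class TestExtractFeatures:
    def test_identical_spectra_have_zero_difference_energy(self, rng):
        f = default_frequency_grid(30)
        P = Spectrum(f, rng.uniform(size=f.size))
        assert extract_features(P, P).difference_energy == 0.0

    def test_volumetric_energy_hand_arithmetic(self):
        f = np.array([0.1, 0.2])
        P12 = Spectrum(f, np.array([1.0, 2.0]))
        P23 = Spectrum(f, np.array([1.0, 2.0]))
        assert extract_features(P12, P23).total_volumetric_energy == pytest.approx(5.0)

    def test_raw_difference_energy_variant(self):
        f = np.array([0.1, 0.2])
        P12 = Spectrum(f, np.array([3.0, 2.0]))
        P23 = Spectrum(f, np.array([1.0, 1.0]))
        feats = extract_features(P12, P23, normalize_difference=False)
        assert feats.difference_energy == pytest.approx(3.0)
        normed = extract_features(P12, P23)
        assert normed.difference_energy == pytest.approx(3.0 / 7.0)

    def test_homogeneity_degrees_under_curve_scaling(self, rng):
        """Scaling the VoCC curve by k scales power by k^2, volumetric energy
        by k^4, and leaves the normalized difference energy unchanged."""
        x = rng.normal(size=41) ** 2
        k = 3.0
        c1 = VoCCCurve(np.arange(-20, 21), x, "pair12")
        c2 = VoCCCurve(np.arange(-20, 21), np.roll(x, 5), "pair23")
        c1k = VoCCCurve(c1.lags, k * c1.variance, "pair12")
        c2k = VoCCCurve(c2.lags, k * c2.variance, "pair23")
        base, _ = subject_spectral_features(c1, c2)
        scaled, _ = subject_spectral_features(c1k, c2k)
        assert scaled.total_volumetric_energy == pytest.approx(
            k**4 * base.total_volumetric_energy, rel=1e-9
        )
        assert scaled.difference_energy == pytest.approx(base.difference_energy, rel=1e-9)
        assert scaled.cutoff_frequency == pytest.approx(base.cutoff_frequency)


def test_subject_features_direction_on_phantom_classes():
    """Consistent-texture stacks give lower difference energy and a higher
    volumetric-energy-to-input-energy ratio than independent-texture stacks."""
    from voccspec.image_io import assemble_stack
    from voccspec.phantoms import PhantomConfig, generate_subject
    from voccspec.vocc import vocc_pair

    cfg = PhantomConfig(roi_size=(48, 48), slice_noise_sd=0.1, seed=0)
    diff = {"co-deleted": [], "non-deleted": []}
    ratio = {"co-deleted": [], "non-deleted": []}
    ss = np.random.SeedSequence(77)
    for label in diff:
        for child in ss.spawn(8):
            rng = np.random.default_rng(child)
            slices, masks = generate_subject(label, cfg, rng)
            stack = assemble_stack(slices, masks, label, "T1C", "x")
            c12 = vocc_pair(stack.slices[0], stack.slices[1], "pair12")
            c23 = vocc_pair(stack.slices[1], stack.slices[2], "pair23")
            feats, spectra = subject_spectral_features(c12, c23)
            diff[label].append(feats.difference_energy)
            input_energy = spectra["pair12"].power.sum() * spectra["pair23"].power.sum()
            ratio[label].append(feats.total_volumetric_energy / input_energy)
    assert np.mean(diff["co-deleted"]) < np.mean(diff["non-deleted"])
    assert np.mean(ratio["co-deleted"]) > np.mean(ratio["non-deleted"])
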