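"""Lomb-Scargle spectra of VoCC curves and the three classification features.

Each slice pair's VoCC curve is mean-centered and converted to a Lomb-Scargle
power spectral density sampled at integer lag positions.  The elementwise
product of the two pair spectra ("inner-product spectrum") measures whether
the same periodic structure persists through the whole 3-slice volume: peaks
survive the product only when they appear in both spectra at the same place.
The leading low-frequency peak — present in both classes — is excluded, and
three features summarize what remains:

* difference energy: |total power of spectrum(1,2) - total power of spectrum(2,3)|,
  normalized by the summed total power so the feature is scale-free
* total volumetric energy: total power of the inner-product spectrum
* cutoff frequency: where the inner-product spectrum becomes (and stays)
  negligible relative to its maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from voccspec.vocc import VoCCCurve

__all__ = [
    "Spectrum",
    "SpectralFeatures",
    "default_frequency_grid",
    "lombscargle_psd",
    "inner_product_spectrum",
    "first_peak_cut_index",
    "exclude_first_peak",
    "cutoff_frequency",
    "extract_features",
    "subject_spectral_features",
]


@dataclass
class Spectrum:
    """Frequency grid (cycles per lag unit, strictly increasing, > 0) + power."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape or self.frequencies.ndim != 1:
            raise ValueError("frequencies and power must be 1D arrays of equal length")
        if np.any(self.frequencies <= 0) or np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        if np.any(self.power < 0) or not np.all(np.isfinite(self.power)):
            raise ValueError("power must be finite and non-negative")

    def __len__(self) -> int:
        return self.frequencies.size


@dataclass
class SpectralFeatures:
    """The three per-subject, per-contrast classification features."""

    difference_energy: float
    total_volumetric_energy: float
    cutoff_frequency: float
    subject_id: str = ""
    contrast: str = ""
    label: str = ""
    grade: str = ""

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.difference_energy, self.total_volumetric_energy, self.cutoff_frequency]
        )


FEATURE_NAMES = ("difference_energy", "total_volumetric_energy", "cutoff_frequency")


def default_frequency_grid(n_samples: int, oversample: float = 4.0) -> np.ndarray:
    """Arithmetic frequency grid from 1/(oversample*T) up to the 0.5 Nyquist.

    ``T`` is the span of the lag axis (n_samples - 1 for unit-spaced lags);
    the step is 1/(oversample*T).  Unit lag spacing bounds usable frequencies
    at 0.5 cycles/lag.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples for spectral estimation")
    if oversample <= 0:
        raise ValueError("oversample must be positive")
    span = float(n_samples - 1)
    df = 1.0 / (oversample * span)
    k = int(np.floor(0.5 / df + 1e-9))
    return np.arange(1, k + 1) * df


def lombscargle_psd(
    curve: VoCCCurve | np.ndarray, frequencies: np.ndarray
) -> Spectrum:
    """Classical Lomb-Scargle power of a (mean-centered) VoCC curve.

    Sampling times are the integer lag positions 1..len(curve).  The power at
    each frequency is the classical Lomb (1976)/Scargle (1982) statistic with
    the per-frequency time offset tau, equal to half the sum of squares of the
    best-fit sinusoid a*cos(2*pi*f*t) + b*sin(2*pi*f*t).
    """
    y = curve.variance if isinstance(curve, VoCCCurve) else np.asarray(curve, float)
    if y.ndim != 1 or y.size < 4:
        raise ValueError("curve must be 1D with at least 4 samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("curve has non-finite values")
    freqs = np.asarray(frequencies, dtype=float)
    t = np.arange(1, y.size + 1, dtype=float)
    power = lombscargle(t, y - y.mean(), 2.0 * np.pi * freqs)
    return Spectrum(freqs, np.maximum(power, 0.0))


def inner_product_spectrum(P12: Spectrum, P23: Spectrum) -> Spectrum:
    """Elementwise product of two spectra sharing one frequency grid."""
    if len(P12) != len(P23) or not np.allclose(
        P12.frequencies, P23.frequencies, rtol=0, atol=1e-12
    ):
        raise ValueError("spectra must share an identical frequency grid")
    return Spectrum(P12.frequencies.copy(), P12.power * P23.power)


def first_peak_cut_index(power: np.ndarray) -> int:
    """Index after the low-frequency peak: everything before it is dropped.

    The first local maximum of ``power`` is located (array ends count when
    they dominate their single neighbor); the cut falls just past the first
    interior local minimum that follows it.  If no interior local minimum
    exists the leading strictly-decreasing run is dropped instead.
    """
    p = np.asarray(power, dtype=float)
    n = p.size
    if n < 5:
        raise ValueError("need at least 5 spectral points for first-peak exclusion")
    first_max = None
    for i in range(n):
        left_ok = i == 0 or p[i] >= p[i - 1]
        right_ok = i == n - 1 or p[i] >= p[i + 1]
        if left_ok and right_ok:
            first_max = i
            break
    assert first_max is not None
    for m in range(first_max + 1, n - 1):
        if p[m] <= p[m - 1] and p[m] <= p[m + 1]:
            return m + 1
    run = 0
    while run + 1 < n and p[run + 1] < p[run]:
        run += 1
    return run + 1


def exclude_first_peak(spec: Spectrum) -> Spectrum:
    """Drop the leading low-frequency peak of a spectrum.

    Both tumor classes carry a dominant low-frequency component reflecting the
    overall ROI envelope rather than texture, so it carries no class signal.
    Raises ``ValueError`` when fewer than 2 points would remain.
    """
    cut = first_peak_cut_index(spec.power)
    if len(spec) - cut < 2:
        raise ValueError("spectrum exhausted: first-peak exclusion leaves < 2 points")
    return Spectrum(spec.frequencies[cut:], spec.power[cut:])


def cutoff_frequency(spec: Spectrum, epsilon: float = 0.01) -> float:
    """Smallest frequency beyond which power stays below epsilon * max(power).

    Falls back to the largest grid frequency when the spectrum never settles
    below the threshold.
    """
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    if len(spec) == 0 or spec.power.max() <= 0:
        raise ValueError("cutoff frequency undefined for an all-zero spectrum")
    threshold = epsilon * spec.power.max()
    below = spec.power < threshold
    # suffix scan: first index from which every point stays below threshold
    idx = len(spec)
    for i in range(len(spec) - 1, -1, -1):
        if not below[i]:
            break
        idx = i
    if idx == len(spec):
        return float(spec.frequencies[-1])
    return float(spec.frequencies[idx])


def extract_features(
    P12: Spectrum,
    P23: Spectrum,
    epsilon: float = 0.01,
    subject_id: str = "",
    contrast: str = "",
    label: str = "",
    grade: str = "",
    normalize_difference: bool = True,
) -> SpectralFeatures:
    """Three features from a pair of (first-peak-excluded) periodograms.

    Energies are plain sums of power over the retained grid points; the
    cutoff frequency is measured on the inner-product spectrum.  The
    difference energy is by default divided by the two spectra's summed total
    power: the absolute difference scales with the subject's overall VoCC
    magnitude (ROI size, texture energy), which carries no across-slice
    consistency information and would otherwise swamp the contrast between
    matching and non-matching spectra.  ``normalize_difference=False`` gives
    the raw absolute difference.
    """
    inner = inner_product_spectrum(P12, P23)
    e12, e23 = float(P12.power.sum()), float(P23.power.sum())
    diff = abs(e12 - e23)
    if normalize_difference:
        diff = diff / (e12 + e23) if (e12 + e23) > 0 else 0.0
    return SpectralFeatures(
        difference_energy=diff,
        total_volumetric_energy=float(inner.power.sum()),
        cutoff_frequency=cutoff_frequency(inner, epsilon),
        subject_id=subject_id,
        contrast=contrast,
        label=label,
        grade=grade,
    )


def subject_spectral_features(
    curve12: VoCCCurve,
    curve23: VoCCCurve,
    oversample: float = 4.0,
    epsilon: float = 0.01,
    subject_id: str = "",
    contrast: str = "",
    label: str = "",
    grade: str = "",
) -> tuple[SpectralFeatures, dict[str, Spectrum]]:
    """Full spectral stage for one subject-contrast: curves -> features.

    Both pair periodograms are computed on one frequency grid; the first-peak
    cut is located on the inner-product spectrum and the identical index cut
    is applied to both periodograms, keeping the three spectra on a shared
    grid.  Returns the features plus the retained spectra (pair12, pair23,
    inner) for optional export.
    """
    if len(curve12) != len(curve23):
        raise ValueError("slice-pair curves must have the same length")
    freqs = default_frequency_grid(len(curve12), oversample)
    P12 = lombscargle_psd(curve12, freqs)
    P23 = lombscargle_psd(curve23, freqs)
    inner = inner_product_spectrum(P12, P23)
    cut = first_peak_cut_index(inner.power)
    if len(inner) - cut < 2:
        raise ValueError("spectrum exhausted: first-peak exclusion leaves < 2 points")
    P12c = Spectrum(P12.frequencies[cut:], P12.power[cut:])
    P23c = Spectrum(P23.frequencies[cut:], P23.power[cut:])
    feats = extract_features(
        P12c, P23c, epsilon,
        subject_id=subject_id, contrast=contrast, label=label, grade=grade,
    )
    spectra = {
        "pair12": P12c,
        "pair23": P23c,
        "inner": inner_product_spectrum(P12c, P23c),
    }
    return feats, spectra
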