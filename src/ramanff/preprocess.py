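"""Spectral preprocessing: background subtraction, fingerprint cropping,
vector normalization, wavelet denoising and mean-centering.

The fixed pipeline order is background-subtract -> crop -> vector-normalize,
followed by wavelet denoising (classification path only) or mean-centering
(discovery path). Vector normalization is Euclidean (L2) over the cropped
fingerprint region, so a flat spectrum on the 1,201-point 600-1800 cm^-1
grid normalizes to 1/sqrt(1201) ~ 0.0289 everywhere — the intensity scale
on which zone quantifications are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from ramanff.errors import ValidationError
from ramanff.spectra import (
    FINGERPRINT_RANGE,
    Spectrum,
    SpectrumSet,
    WavenumberGrid,
    average_replicates,
)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing pipeline.

    fingerprint : (lo, hi) crop window in cm^-1.
    wavelet_family : "haar", "db4" or "none" (no denoising).
    wavelet_level : decomposition depth of the discrete wavelet transform.
    """

    fingerprint: tuple[float, float] = FINGERPRINT_RANGE
    wavelet_family: str = "db4"
    wavelet_level: int = 4
    threshold_rule: str = "universal-soft"
    center_mode: str = "grand-mean"

    def __post_init__(self) -> None:
        if self.wavelet_family not in ("haar", "db4", "none"):
            raise ValidationError(f"unknown wavelet family {self.wavelet_family!r}")
        if self.wavelet_family != "none" and self.wavelet_level < 1:
            raise ValidationError("wavelet_level must be >= 1")
        if self.threshold_rule != "universal-soft":
            raise ValidationError(f"unknown threshold rule {self.threshold_rule!r}")


def subtract_background(spectrum: Spectrum, background: Spectrum) -> Spectrum:
    """Pointwise spectrum minus background; negatives floored at 0."""
    if spectrum.grid != background.grid:
        raise ValidationError("spectrum and background must share one grid")
    diff = np.maximum(spectrum.intensities - background.intensities, 0.0)
    return spectrum.with_intensities(diff)


def crop_fingerprint(spectrum: Spectrum, zone: tuple[float, float] | None = None) -> Spectrum:
    """Restrict a spectrum to the closed window [lo, hi] (default 600-1800)."""
    lo, hi = zone if zone is not None else FINGERPRINT_RANGE
    sl = spectrum.grid.index_range(lo, hi)
    w = spectrum.grid.wavenumbers[sl]
    grid = WavenumberGrid(float(w[0]), float(w[-1]), spectrum.grid.step)
    return Spectrum(grid, spectrum.intensities[sl])


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale intensities to unit Euclidean norm."""
    norm = float(np.linalg.norm(spectrum.intensities))
    if norm <= 0:
        raise ValidationError("cannot vector-normalize an all-zero spectrum")
    return spectrum.with_intensities(spectrum.intensities / norm)


def wavelet_denoise(spectrum: Spectrum, config: PreprocessConfig) -> Spectrum:
    """Multilevel DWT denoising with a universal soft threshold.

    Detail coefficients are soft-thresholded at sigma * sqrt(2 ln n), with
    sigma estimated from the median absolute deviation of the finest-level
    details (MAD / 0.6745). Reconstruction is truncated to the input length.
    """
    if config.wavelet_family == "none":
        return spectrum
    x = spectrum.intensities
    n = x.size
    wav = pywt.Wavelet(config.wavelet_family)
    max_level = pywt.dwt_max_level(n, wav.dec_len)
    if config.wavelet_level > max_level:
        raise ValidationError(
            f"wavelet level {config.wavelet_level} too deep for {n} points "
            f"with {config.wavelet_family} (max {max_level})"
        )
    coeffs = pywt.wavedec(x, wav, level=config.wavelet_level)
    finest = coeffs[-1]
    sigma = float(np.median(np.abs(finest - np.median(finest)))) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(n))
    if thresh == 0:  # noise-free signal: nothing to shrink
        return spectrum
    denoised = [coeffs[0]] + [pywt.threshold(c, thresh, mode="soft") for c in coeffs[1:]]
    rec = pywt.waverec(denoised, wav)[:n]
    return spectrum.with_intensities(rec)


def mean_center(dataset: SpectrumSet) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Grand-mean centering of per-sample spectra.

    Subtracts the mean spectrum over all samples from each sample spectrum
    and returns ``(centered_matrix, group_means)`` where ``group_means``
    maps each label value (for whichever label columns are non-NA) to the
    mean centered spectrum of that group — the curves a mean-centered
    group-difference plot displays.
    """
    if dataset.n_samples < 2:
        raise ValidationError("mean centering needs at least 2 samples")
    collapsed = dataset if dataset.replicates_per_sample == 1 else average_replicates(dataset)
    mat = collapsed.intensity_matrix()
    centered = mat - mat.mean(axis=0, keepdims=True)
    group_means: dict[str, np.ndarray] = {}
    for task in ("pcos", "blastocyst", "pregnancy"):
        labels = collapsed.labels(task)
        for lab in np.unique(labels):
            if lab == "NA":
                continue
            group_means[str(lab)] = centered[labels == lab].mean(axis=0)
    return centered, group_means


def preprocess_set(
    dataset: SpectrumSet,
    config: PreprocessConfig | None = None,
    *,
    background: Spectrum | None = None,
    denoise: bool = False,
    collapse_replicates: bool = True,
) -> SpectrumSet:
    """Run the fixed preprocessing chain on every replicate.

    Order: (background subtract) -> crop to fingerprint -> vector normalize
    -> (wavelet denoise, then re-normalize so downstream quantifications
    stay on the unit-norm scale) -> (average replicates per sample).
    """
    config = config or PreprocessConfig()

    def _one(sp: Spectrum) -> Spectrum:
        if background is not None:
            sp = subtract_background(sp, background)
        sp = crop_fingerprint(sp, config.fingerprint)
        sp = vector_normalize(sp)
        if denoise and config.wavelet_family != "none":
            sp = vector_normalize(wavelet_denoise(sp, config))
        return sp

    out = dataset.map_intensities(_one)
    if collapse_replicates:
        out = average_replicates(out)
    return out
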