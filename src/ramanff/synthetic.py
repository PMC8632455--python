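"""Synthetic follicular-fluid Raman cohorts with calibrated group effects.

Each replicate spectrum is built as

    baseline(w) + sum_k  a_k * g_k(class) * pseudoVoigt(w; c_k, fwhm_k)

scaled by a per-replicate multiplicative jitter and corrupted by additive
Gaussian noise, clipped at zero. Peak centers default to the bands a
follicular-fluid spectrum shows (tryptophan 758, tyrosine/proline 852,
protein backbone 936, phenylalanine 1003, C-C/C-N protein 1156, carotenoid
1516/1518, 1590, amide 1627, carbonyl 1668 cm^-1) plus broad filler bands;
the baseline is a smooth fluorescence-like decay.

Group structure enters as multiplicative amplitude gains on the peaks whose
center falls inside a target zone, applied to one class. Because the
analysis vector-normalizes each spectrum, raising one zone necessarily
lowers the rest of the spectrum — the mechanism that lets a single cohort
show one zone elevated and another depressed in the same class.
:func:`calibrate_group_gains` root-finds per-class zone gains so the
noiseless class-mean spectra reproduce, after cropping and normalization,
four printed zone-quantification means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from ramanff.errors import CalibrationError, ValidationError
from ramanff.preprocess import crop_fingerprint, vector_normalize
from ramanff.spectra import (
    NEGATIVE_CLASS,
    POSITIVE_CLASS,
    SampleMeta,
    Spectrum,
    SpectrumSet,
    TASKS,
    WavenumberGrid,
    acquisition_grid,
)
from ramanff.zones import ZONE_A, ZONE_B, Zone, quantify_zone

#: group-mean zone quantifications each task's default cohort is calibrated
#: to: (zoneA positive, zoneA negative, zoneB positive, zoneB negative)
PRINTED_ZONE_MEANS = {
    "pcos": (0.0286, 0.0274, 0.0319, 0.0337),
    "blastocyst": (0.0316, 0.0328, 0.0292, 0.0279),
    "pregnancy": (0.0316, 0.0335, 0.0289, 0.0278),
}

#: cohort sizes per task: (n positive, n negative)
DEFAULT_GROUP_SIZES = {
    "pcos": (150, 150),
    "blastocyst": (75, 75),
    "pregnancy": (85, 65),
}


@dataclass(frozen=True)
class PeakSpec:
    """One Raman band: a pseudo-Voigt line of given height.

    ``shape_mix`` is the Lorentzian fraction (1 = pure Lorentzian,
    0 = pure Gaussian); both components share the same FWHM and unit height.
    """

    center: float
    fwhm: float = 12.0
    amplitude: float = 1.0
    shape_mix: float = 0.7

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValidationError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")
        if not 0 <= self.shape_mix <= 1:
            raise ValidationError("shape_mix must be in [0, 1]")

    def profile(self, w: np.ndarray) -> np.ndarray:
        """Unit-height pseudo-Voigt evaluated on wavenumbers ``w``."""
        half = self.fwhm / 2.0
        x = (w - self.center) / half
        lor = 1.0 / (1.0 + x * x)
        gau = np.exp(-np.log(2.0) * x * x)
        return self.shape_mix * lor + (1.0 - self.shape_mix) * gau


@dataclass(frozen=True)
class BaselineSpec:
    """Smooth residual background: polynomial + exponential fluorescence tail.

    The polynomial is evaluated in the normalized coordinate
    u = (w - w_min) / (w_max - w_min); the fluorescence term is
    ``fluor_amplitude * exp(-(w - w_min) / fluor_decay)``.
    """

    poly_coeffs: tuple[float, ...] = (0.5,)
    fluor_amplitude: float = 2.0
    fluor_decay: float = 800.0

    def evaluate(self, w: np.ndarray) -> np.ndarray:
        u = (w - w[0]) / (w[-1] - w[0])
        base = np.polynomial.polynomial.polyval(u, self.poly_coeffs)
        base = base + self.fluor_amplitude * np.exp(-(w - w[0]) / self.fluor_decay)
        if np.any(base < 0):
            raise ValidationError("baseline is negative somewhere on the grid")
        return base


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative gain on peaks whose center lies inside ``zone``."""

    zone: Zone
    gain: float

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValidationError("gain must be > 0")


def _default_peaks() -> tuple[PeakSpec, ...]:
    bands = [
        # (center, fwhm, height) — sharp assigned bands
        (758, 12, 0.50), (852, 12, 0.45), (936, 14, 0.40),
        (1003, 8, 1.30), (1156, 12, 1.00),
        (1516, 14, 1.60), (1518, 14, 1.10), (1590, 12, 0.90),
        (1627, 14, 1.00), (1668, 16, 1.30),
        # broad filler bands filling the fingerprint envelope
        (700, 60, 0.30), (1080, 80, 0.35), (1260, 90, 0.40),
        (1340, 70, 0.35), (1450, 60, 0.80), (1740, 50, 0.25),
    ]
    return tuple(PeakSpec(c, f, a) for c, f, a in bands)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full recipe for one synthetic cohort.

    ``effects`` maps class labels to zone gains; classes not listed get
    unit gains. ``noise_sd`` of ``None`` resolves at generation time to
    0.5% of the tallest peak of the noiseless signal. ``sample_gain_sd``
    adds per-sample biological individuality: every peak amplitude of a
    sample is scattered by an independent log-normal factor shared across
    that sample's replicates. ``baseline_tilt_sd`` scatters the residual
    background per sample with a zero-mean linear tilt across the grid,
    emulating droplet-to-droplet fluorescence differences.
    """

    grid: WavenumberGrid = field(default_factory=acquisition_grid)
    peaks: tuple[PeakSpec, ...] = field(default_factory=_default_peaks)
    baseline: BaselineSpec = field(default_factory=BaselineSpec)
    effects: tuple[tuple[str, GroupEffect], ...] = ()
    n_per_group: int | tuple[int, int] = 150
    replicates: int = 5
    replicate_jitter_sd: float = 0.02
    noise_sd: float | None = None
    sample_gain_sd: float = 0.1
    baseline_tilt_sd: float = 0.05
    peak_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_pos, n_neg = self.group_sizes
        if min(n_pos, n_neg) < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        for name in ("replicate_jitter_sd", "sample_gain_sd", "baseline_tilt_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.peak_scale <= 0:
            raise ValidationError("peak_scale must be > 0")

    @property
    def group_sizes(self) -> tuple[int, int]:
        if isinstance(self.n_per_group, tuple):
            return self.n_per_group
        return (self.n_per_group, self.n_per_group)

    def class_gains(self, label: str) -> np.ndarray:
        """Per-peak gain vector for one class."""
        gains = np.ones(len(self.peaks))
        for lab, eff in self.effects:
            if lab != label:
                continue
            for k, p in enumerate(self.peaks):
                if eff.zone.lo <= p.center <= eff.zone.hi:
                    gains[k] *= eff.gain
        return gains

    def amplitudes(self, label: str) -> np.ndarray:
        return self.peak_scale * np.array([p.amplitude for p in self.peaks]) * self.class_gains(label)


def _profiles(config: SyntheticConfig) -> np.ndarray:
    """Peaks x gridpoints matrix of unit-height line profiles."""
    w = config.grid.wavenumbers
    return np.stack([p.profile(w) for p in config.peaks])


def class_mean_spectrum(config: SyntheticConfig, label: str) -> Spectrum:
    """Noiseless expected spectrum of one class on the acquisition grid."""
    w = config.grid.wavenumbers
    signal = config.baseline.evaluate(w) + config.amplitudes(label) @ _profiles(config)
    return Spectrum(config.grid, signal)


def _resolved_noise_sd(config: SyntheticConfig, profiles: np.ndarray) -> float:
    if config.noise_sd is not None:
        return config.noise_sd
    base_amp = config.peak_scale * np.array([p.amplitude for p in config.peaks])
    return 0.005 * float((base_amp @ profiles).max())


def generate_dataset(config: SyntheticConfig, task: str) -> SpectrumSet:
    """Generate a labeled synthetic cohort for one classification task.

    Sample ids are ``P0001..`` (positive class) and ``N0001..`` (negative);
    output is deterministic given ``config.seed``.
    """
    if task not in TASKS:
        raise ValidationError(f"unknown task {task!r}; expected one of {TASKS}")
    pos, neg = POSITIVE_CLASS[task], NEGATIVE_CLASS[task]
    n_pos, n_neg = config.group_sizes
    rng = np.random.default_rng(config.seed)
    w = config.grid.wavenumbers
    profiles = _profiles(config)
    baseline = config.baseline.evaluate(w)
    tilt_shape = (w - w[0]) / (w[-1] - w[0]) - 0.5
    noise_sd = _resolved_noise_sd(config, profiles)

    samples: list[SampleMeta] = []
    spectra: list[list[Spectrum]] = []
    for label, n, prefix in ((pos, n_pos, "P"), (neg, n_neg, "N")):
        amps = config.amplitudes(label)
        for i in range(n):
            meta_kwargs = {"pcos": "group_pcos", "blastocyst": "blastocyst", "pregnancy": "pregnancy"}
            samples.append(
                SampleMeta(sample_id=f"{prefix}{i + 1:04d}", **{meta_kwargs[task]: label})
            )
            sample_amps = amps * np.exp(rng.normal(0.0, config.sample_gain_sd, size=amps.size))
            tilt = rng.normal(0.0, config.baseline_tilt_sd)
            sample_baseline = np.maximum(baseline * (1.0 + tilt * tilt_shape), 0.0)
            clean = sample_baseline + sample_amps @ profiles
            reps = []
            for _ in range(config.replicates):
                scale = 1.0 + rng.normal(0.0, config.replicate_jitter_sd)
                y = clean * scale + rng.normal(0.0, noise_sd, size=clean.size)
                reps.append(Spectrum(config.grid, np.maximum(y, 0.0)))
            spectra.append(reps)
    return SpectrumSet(samples, spectra)


# ---------------------------------------------------------------------------
# calibration

def _noiseless_zone_means(
    config: SyntheticConfig, label: str, zoneA: Zone, zoneB: Zone
) -> tuple[float, float]:
    sp = vector_normalize(crop_fingerprint(class_mean_spectrum(config, label)))
    return quantify_zone(sp, zoneA), quantify_zone(sp, zoneB)


def _with_class_gains(
    config: SyntheticConfig, label: str, zoneA: Zone, zoneB: Zone, gA: float, gB: float
) -> SyntheticConfig:
    effects = tuple((lab, eff) for lab, eff in config.effects if lab != label)
    effects += ((label, GroupEffect(zoneA, gA)), (label, GroupEffect(zoneB, gB)))
    return replace(config, effects=effects)


def _solve_class(
    config: SyntheticConfig,
    label: str,
    zoneA: Zone,
    zoneB: Zone,
    targetA: float,
    targetB: float,
    tol: float,
    max_iter: int = 60,
) -> tuple[float, float, float]:
    """Alternating 1-D root finds on (gainA, gainB) for one class.

    Each zone's quantification is monotone increasing in its own gain
    (raising a zone's peaks raises its share of the unit-norm spectrum), so
    each coordinate is solved with Brent's method and the pair iterated to
    a joint fixed point. Returns (gainA, gainB, residual).
    """
    base = tuple((lab, eff) for lab, eff in config.effects if lab != label)
    cfg = replace(config, effects=base)
    gA, gB = 1.0, 1.0

    def mean_for(which: str, g: float, gA: float, gB: float) -> float:
        if which == "A":
            gA = g
        else:
            gB = g
        c = _with_class_gains(cfg, label, zoneA, zoneB, gA, gB)
        mA, mB = _noiseless_zone_means(c, label, zoneA, zoneB)
        return mA if which == "A" else mB

    lo, hi = 1e-3, 1e3
    residual = np.inf
    for _ in range(max_iter):
        gA = brentq(lambda g: mean_for("A", g, gA, gB) - targetA, lo, hi, xtol=1e-10)
        gB = brentq(lambda g: mean_for("B", g, gA, gB) - targetB, lo, hi, xtol=1e-10)
        mA, mB = _noiseless_zone_means(
            _with_class_gains(cfg, label, zoneA, zoneB, gA, gB), label, zoneA, zoneB
        )
        residual = max(abs(mA - targetA), abs(mB - targetB))
        if residual < tol:
            break
    return gA, gB, residual


def calibrate_group_gains(
    config: SyntheticConfig,
    zoneA: Zone | tuple[float, float],
    zoneB: Zone | tuple[float, float],
    targets: tuple[float, float, float, float],
    task: str = "pcos",
    tol: float = 1e-6,
) -> SyntheticConfig:
    """Tune per-class zone gains so noiseless class means hit four targets.

    ``targets`` is (meanA_pos, meanA_neg, meanB_pos, meanB_neg): the
    post-normalization width-averaged quantifications over ``zoneA`` and
    ``zoneB`` that the positive and negative class-mean spectra should
    produce. Raises :class:`CalibrationError` (with the best residual)
    when the targets cannot be reached with positive gains.
    """
    zoneA = zoneA if isinstance(zoneA, Zone) else Zone(*zoneA)
    zoneB = zoneB if isinstance(zoneB, Zone) else Zone(*zoneB)
    mAp, mAn, mBp, mBn = targets
    for t in targets:
        if not 0 < t < 1:
            raise ValidationError("targets must lie in (0, 1)")
    pos, neg = POSITIVE_CLASS[task], NEGATIVE_CLASS[task]
    out = config
    try:
        for label, tA, tB in ((pos, mAp, mBp), (neg, mAn, mBn)):
            gA, gB, residual = _solve_class(out, label, zoneA, zoneB, tA, tB, tol)
            if not residual < 1e-4:
                raise CalibrationError(
                    f"calibration for class {label!r} stalled at residual {residual:.3g}",
                    residual=residual,
                )
            out = _with_class_gains(out, label, zoneA, zoneB, gA, gB)
    except ValueError as exc:  # brentq bracket failure: targets unreachable
        raise CalibrationError(f"targets unreachable with positive gains: {exc}") from exc
    return out


def default_config(task: str = "pcos", seed: int = 0, **overrides) -> SyntheticConfig:
    """Uncalibrated default cohort recipe for a task (unit gains)."""
    if task not in TASKS:
        raise ValidationError(f"unknown task {task!r}")
    params = dict(n_per_group=DEFAULT_GROUP_SIZES[task], seed=seed)
    params.update(overrides)
    return SyntheticConfig(**params)


def calibrated_config(task: str = "pcos", seed: int = 0, **overrides) -> SyntheticConfig:
    """Default cohort recipe calibrated to the task's printed zone means."""
    cfg = default_config(task, seed=seed, **overrides)
    return calibrate_group_gains(cfg, Zone(*ZONE_A), Zone(*ZONE_B), PRINTED_ZONE_MEANS[task], task=task)
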