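"""PCA-guided discovery of discriminative wavenumber zones.

The discovery engine: principal-component analysis of preprocessed
per-sample spectra, extraction of candidate zone anchors from the loading
plot of the leading component, enumeration and Welch-test scoring of
anchor-pair zones, and per-zone group statistics for boxplot-style
reporting.

A zone quantification is the trapezoidal integral of the vector-normalized
intensity over the zone divided by the zone width — a width-averaged
normalized intensity, so values sit on the ~0.03 scale of a unit-norm
1,201-point spectrum rather than growing with zone width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from sklearn.decomposition import PCA

from ramanff.errors import ValidationError
from ramanff.spectra import (
    NEGATIVE_CLASS,
    POSITIVE_CLASS,
    Spectrum,
    SpectrumSet,
)

#: discriminative zones reported for follicular-fluid cohorts, cm^-1
ZONE_A = (993.0, 1165.0)
ZONE_B = (1439.0, 1678.0)


@dataclass(frozen=True)
class Zone:
    """Closed wavenumber interval [lo, hi] cm^-1."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValidationError(f"zone lo must be < hi, got [{self.lo}, {self.hi}]")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def overlaps(self, other: "Zone") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi

    def jaccard(self, other: "Zone") -> float:
        inter = max(0.0, min(self.hi, other.hi) - max(self.lo, other.lo))
        union = max(self.hi, other.hi) - min(self.lo, other.lo)
        return inter / union if union > 0 else 0.0


@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # components x wavenumbers, unit-norm rows
    explained_variance_fraction: np.ndarray
    wavenumbers: np.ndarray


@dataclass(frozen=True)
class ZoneStat:
    """Group comparison of one zone's per-sample quantifications."""

    zone: Zone
    mean_pos: float
    mean_neg: float
    sd_pos: float
    sd_neg: float
    t_stat: float
    p_value: float
    n_pos: int
    n_neg: int


def pca_decompose(matrix: np.ndarray, n_components: int, wavenumbers: np.ndarray | None = None) -> PCAResult:
    """PCA of a samples x wavenumbers matrix (column-centered internally).

    Components are ordered by decreasing explained variance. Sign
    convention: each loading row is flipped so its largest-magnitude
    element is positive, making results deterministic across solvers.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_samples, n_feat = matrix.shape
    if n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if n_components > min(n_samples - 1, n_feat):
        raise ValidationError(
            f"n_components={n_components} exceeds min(samples-1, wavenumbers)="
            f"{min(n_samples - 1, n_feat)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix)
    loadings = pca.components_.copy()
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]
    if wavenumbers is None:
        wavenumbers = np.arange(n_feat, dtype=float)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        wavenumbers=np.asarray(wavenumbers, dtype=float),
    )


def loading_extrema(pca: PCAResult, component: int = 0, min_prominence: float = 0.08) -> np.ndarray:
    """Candidate zone anchors: local extrema of |loading| on one component.

    Returns the wavenumbers of local maxima of the absolute loading whose
    prominence exceeds ``min_prominence`` times the absolute maximum,
    sorted ascending.
    """
    if not 0 <= component < pca.loadings.shape[0]:
        raise ValidationError(f"component {component} not in PCA result")
    mag = np.abs(pca.loadings[component])
    peak = float(mag.max())
    if peak <= 0:
        return np.array([])
    idx, _ = signal.find_peaks(mag, prominence=min_prominence * peak)
    return pca.wavenumbers[idx]


def quantify_zone(spectrum: Spectrum, zone: Zone | tuple[float, float]) -> float:
    """Width-averaged normalized intensity over a zone.

    Trapezoidal integral of the intensity over grid points in [lo, hi],
    divided by (hi - lo). Constant intensity v returns v exactly.
    """
    if not isinstance(zone, Zone):
        zone = Zone(*zone)
    sl = spectrum.grid.index_range(zone.lo, zone.hi)
    w = spectrum.grid.wavenumbers[sl]
    y = spectrum.intensities[sl]
    if w.size < 2:
        raise ValidationError(f"zone [{zone.lo}, {zone.hi}] covers fewer than 2 grid points")
    return float(np.trapezoid(y, w) / (w[-1] - w[0]))


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t-test for unequal variances.

    t = (mean(x) - mean(y)) / sqrt(sx^2/nx + sy^2/ny) with
    Welch-Satterthwaite degrees of freedom; two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValidationError("Welch test needs >= 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return (0.0, 1.0) if x.mean() == y.mean() else (np.inf, 0.0)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def _zone_stat(matrix_quants: np.ndarray, is_pos: np.ndarray, zone: Zone) -> ZoneStat:
    qp, qn = matrix_quants[is_pos], matrix_quants[~is_pos]
    t, p = welch_t_test(qp, qn)
    return ZoneStat(
        zone=zone,
        mean_pos=float(qp.mean()),
        mean_neg=float(qn.mean()),
        sd_pos=float(qp.std(ddof=1)),
        sd_neg=float(qn.std(ddof=1)),
        t_stat=t,
        p_value=p,
        n_pos=int(qp.size),
        n_neg=int(qn.size),
    )


def resolve_positive_class(classes: np.ndarray, positive: str | None = None) -> str:
    """Pick the positive class of a two-class label vector.

    Known task label pairs (PCOS/nonPCOS, HQ/LQ, success/failure) have a
    conventional positive class; otherwise the first class in sorted order
    is used unless ``positive`` is given explicitly.
    """
    classes = [str(c) for c in classes]
    if positive is not None:
        if positive not in classes:
            raise ValidationError(f"positive class {positive!r} not among labels {classes}")
        return positive
    for task, pos in POSITIVE_CLASS.items():
        if set(classes) == {pos, NEGATIVE_CLASS[task]}:
            return pos
    return classes[0]


def _per_sample_quants(dataset: SpectrumSet, zone: Zone) -> np.ndarray:
    if dataset.replicates_per_sample != 1:
        raise ValidationError("zone scanning expects one (replicate-averaged) spectrum per sample")
    return np.array([quantify_zone(reps[0], zone) for reps in dataset.spectra])


def scan_zones(
    dataset: SpectrumSet,
    labels: np.ndarray,
    anchors: np.ndarray,
    min_width: float = 30.0,
    max_zones: int = 2,
    positive: str | None = None,
) -> list[ZoneStat]:
    """Enumerate anchor-pair zones, score by Welch p, keep non-overlapping best.

    Candidate zones are all pairs (a_i, a_j), i < j, of the anchor
    wavenumbers with width >= min_width. Each is scored by the Welch
    p-value comparing per-sample quantifications between the two label
    groups, ranked ascending by p (ties: wider zone first, then lower lo),
    and retained greedily while discarding any zone overlapping an
    already-retained one, until ``max_zones`` are kept.
    """
    anchors = np.sort(np.asarray(anchors, dtype=float))
    if anchors.size < 2:
        raise ValidationError("zone scanning needs at least 2 anchors")
    if min_width <= 0:
        raise ValidationError("min_width must be > 0")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError(f"need exactly 2 label classes, got {classes.tolist()}")
    is_pos = labels == resolve_positive_class(classes, positive)

    candidates = [
        Zone(float(a), float(b))
        for i, a in enumerate(anchors)
        for b in anchors[i + 1 :]
        if b - a >= min_width
    ]
    if not candidates:
        warnings.warn("no anchor pair meets min_width; empty zone scan", stacklevel=2)
        return []
    scored = [_zone_stat(_per_sample_quants(dataset, z), is_pos, z) for z in candidates]
    scored.sort(key=lambda s: (s.p_value, -s.zone.width, s.zone.lo))
    kept: list[ZoneStat] = []
    for s in scored:
        if len(kept) >= max_zones:
            break
        if any(s.zone.overlaps(k.zone) for k in kept):
            continue
        kept.append(s)
    return kept


def group_difference_report(
    dataset: SpectrumSet,
    labels: np.ndarray,
    zones: list[Zone] | list[tuple[float, float]],
    positive: str | None = None,
) -> tuple[list[ZoneStat], dict[str, np.ndarray]]:
    """Per-zone group statistics plus boxplot-ready per-sample values.

    Samples with a missing ("NA") label are excluded with a warning.
    Returns ``(stats, per_sample)`` where ``per_sample`` maps
    ``"lo-hi"`` zone keys to the per-sample quantification vector (kept
    samples only, in dataset order) and ``"labels"`` to their labels.
    """
    if not zones:
        raise ValidationError("zones must be non-empty")
    zones = [z if isinstance(z, Zone) else Zone(*z) for z in zones]
    labels = np.asarray(labels)
    keep = labels != "NA"
    if not np.all(keep):
        warnings.warn(f"excluding {int((~keep).sum())} samples with missing labels", stacklevel=2)
    kept_ids = [m.sample_id for m, k in zip(dataset.samples, keep) if k]
    sub = dataset.subset(kept_ids)
    sub_labels = labels[keep]
    classes = np.unique(sub_labels)
    if classes.size != 2:
        raise ValidationError(f"need exactly 2 label classes, got {classes.tolist()}")
    is_pos = sub_labels == resolve_positive_class(classes, positive)
    stats_out: list[ZoneStat] = []
    per_sample: dict[str, np.ndarray] = {"labels": sub_labels}
    for z in zones:
        q = _per_sample_quants(sub, z)
        per_sample[f"{z.lo:g}-{z.hi:g}"] = q
        stats_out.append(_zone_stat(q, is_pos, z))
    return stats_out, per_sample
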