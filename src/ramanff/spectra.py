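"""Domain types and text I/O for Raman spectra and labeled datasets.

A single acquisition is a :class:`Spectrum` on a uniform
:class:`WavenumberGrid`; a labeled cohort is a :class:`SpectrumSet` holding,
for every biological sample, its replicate acquisitions (five per
follicular-fluid droplet by default) together with the sample's group
labels (PCOS status, blastocyst quality, pregnancy outcome).

Files are plain text: a spectrum is a two-column CSV
(``wavenumber_cm-1,intensity``), a dataset is a manifest (CSV or JSON)
mapping sample ids and labels to replicate spectrum files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from ramanff.errors import FormatError, ValidationError

#: acquisition range of the spectrometer, cm^-1
ACQUISITION_RANGE = (50.0, 2000.0)
#: fingerprint region used for all analysis, cm^-1
FINGERPRINT_RANGE = (600.0, 1800.0)

PCOS_LABELS = ("PCOS", "nonPCOS", "NA")
BLASTOCYST_LABELS = ("HQ", "LQ", "NA")
PREGNANCY_LABELS = ("success", "failure", "NA")

TASKS = ("pcos", "blastocyst", "pregnancy")
#: positive class per classification / discovery task
POSITIVE_CLASS = {"pcos": "PCOS", "blastocyst": "HQ", "pregnancy": "success"}
NEGATIVE_CLASS = {"pcos": "nonPCOS", "blastocyst": "LQ", "pregnancy": "failure"}


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform closed wavenumber grid ``start, start+step, ..., stop`` (cm^-1)."""

    start: float
    stop: float
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValidationError(f"grid start must be < stop, got [{self.start}, {self.stop}]")
        if self.step <= 0:
            raise ValidationError(f"grid step must be > 0, got {self.step}")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-6:
            raise ValidationError(
                f"stop {self.stop} is not reachable from start {self.start} in steps of {self.step}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    def contains(self, lo: float, hi: float) -> bool:
        """Whether the closed interval [lo, hi] lies within the grid."""
        return self.start <= lo and hi <= self.stop

    def index_range(self, lo: float, hi: float) -> slice:
        """Slice selecting grid points w with lo <= w <= hi (inclusive)."""
        if not self.contains(lo, hi):
            raise ValidationError(f"zone [{lo}, {hi}] outside grid [{self.start}, {self.stop}]")
        w = self.wavenumbers
        i0 = int(np.searchsorted(w, lo - 1e-9, side="left"))
        i1 = int(np.searchsorted(w, hi + 1e-9, side="right"))
        return slice(i0, i1)


def acquisition_grid(step: float = 1.0) -> WavenumberGrid:
    """Default full acquisition grid, 50-2000 cm^-1."""
    return WavenumberGrid(*ACQUISITION_RANGE, step)


def fingerprint_grid(step: float = 1.0) -> WavenumberGrid:
    """Default analysis grid, the 600-1800 cm^-1 fingerprint region."""
    return WavenumberGrid(*FINGERPRINT_RANGE, step)


@dataclass(frozen=True)
class Spectrum:
    """One acquisition: an intensity vector on a wavenumber grid."""

    grid: WavenumberGrid
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if arr.ndim != 1 or arr.size != self.grid.n_points:
            raise ValidationError(
                f"intensity vector length {arr.size} does not match grid ({self.grid.n_points} points)"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("spectrum intensities must all be finite")

    def with_intensities(self, values: np.ndarray) -> "Spectrum":
        return Spectrum(self.grid, values)


@dataclass(frozen=True)
class SampleMeta:
    """Identity and group labels of one biological sample.

    ``blastocyst`` is defined only for samples whose oocyte developed into a
    transferrable blastocyst; any label may be ``"NA"`` when the study arm
    does not apply.
    """

    sample_id: str
    group_pcos: str = "NA"
    blastocyst: str = "NA"
    pregnancy: str = "NA"

    def __post_init__(self) -> None:
        for value, allowed, name in (
            (self.group_pcos, PCOS_LABELS, "group_pcos"),
            (self.blastocyst, BLASTOCYST_LABELS, "blastocyst"),
            (self.pregnancy, PREGNANCY_LABELS, "pregnancy"),
        ):
            if value not in allowed:
                raise ValidationError(f"{name}={value!r} not one of {allowed}")

    def label_for(self, task: str) -> str:
        if task == "pcos":
            return self.group_pcos
        if task == "blastocyst":
            return self.blastocyst
        if task == "pregnancy":
            return self.pregnancy
        raise ValidationError(f"unknown task {task!r}; expected one of {TASKS}")


@dataclass
class SpectrumSet:
    """A labeled cohort: per-sample metadata plus replicate spectra.

    ``spectra[i]`` holds the replicate acquisitions of ``samples[i]``; all
    spectra in the set share one grid.
    """

    samples: list[SampleMeta]
    spectra: list[list[Spectrum]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.spectra):
            raise ValidationError("samples and spectra lists must have equal length")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_id(s): {dup}")
        grid = None
        for meta, reps in zip(self.samples, self.spectra):
            if not reps:
                raise ValidationError(f"sample {meta.sample_id!r} has no replicate spectra")
            for sp in reps:
                if grid is None:
                    grid = sp.grid
                elif sp.grid != grid:
                    raise FormatError(
                        f"sample {meta.sample_id!r} uses grid {sp.grid}, expected {grid}"
                    )

    @property
    def grid(self) -> WavenumberGrid:
        return self.spectra[0][0].grid

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def replicates_per_sample(self) -> int:
        counts = {len(r) for r in self.spectra}
        return counts.pop() if len(counts) == 1 else -1

    def labels(self, task: str) -> np.ndarray:
        return np.array([m.label_for(task) for m in self.samples])

    def intensity_matrix(self) -> np.ndarray:
        """Samples x wavenumbers matrix; requires one spectrum per sample."""
        if self.replicates_per_sample != 1:
            raise ValidationError(
                "intensity_matrix requires one spectrum per sample; call average_replicates first"
            )
        return np.stack([reps[0].intensities for reps in self.spectra])

    def subset(self, sample_ids: Iterable[str]) -> "SpectrumSet":
        wanted = set(sample_ids)
        keep = [i for i, m in enumerate(self.samples) if m.sample_id in wanted]
        missing = wanted - {self.samples[i].sample_id for i in keep}
        if missing:
            raise ValidationError(f"sample ids not in set: {sorted(missing)}")
        return SpectrumSet(
            [self.samples[i] for i in keep], [self.spectra[i] for i in keep]
        )

    def map_intensities(self, fn) -> "SpectrumSet":
        """Apply ``fn(Spectrum) -> Spectrum`` to every replicate."""
        return SpectrumSet(
            list(self.samples), [[fn(sp) for sp in reps] for reps in self.spectra]
        )


# ---------------------------------------------------------------------------
# text I/O

CSV_HEADER = "wavenumber_cm-1,intensity"


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Read a two-column wavenumber/intensity CSV (header optional).

    The wavenumber column must be ascending on a uniform grid; the grid step
    is inferred from the file.
    """
    path = Path(path)
    wavenumbers: list[float] = []
    intensities: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 comma-separated columns")
            try:
                w, x = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise FormatError(f"{path}:{lineno}: non-numeric row {line!r}") from None
            wavenumbers.append(w)
            intensities.append(x)
    if len(wavenumbers) < 2:
        raise FormatError(f"{path}: fewer than 2 data rows")
    w = np.asarray(wavenumbers)
    steps = np.diff(w)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
        raise FormatError(f"{path}: wavenumbers are not an ascending uniform grid")
    grid = WavenumberGrid(float(w[0]), float(w[-1]), float(round(steps[0], 9)))
    return Spectrum(grid, np.asarray(intensities))


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum as a two-column CSV at full float precision."""
    path = Path(path)
    lines = [CSV_HEADER]
    for w, x in zip(spectrum.grid.wavenumbers, spectrum.intensities):
        lines.append(f"{float(w)!r},{float(x)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _assemble(rows: list[dict], base: Path) -> SpectrumSet:
    samples, spectra = [], []
    seen: set[str] = set()
    for row in rows:
        sid = str(row["sample_id"])
        if sid in seen:
            raise ValidationError(f"duplicate sample_id {sid!r} in manifest")
        seen.add(sid)
        samples.append(
            SampleMeta(
                sample_id=sid,
                group_pcos=str(row.get("group_pcos", "NA") or "NA"),
                blastocyst=str(row.get("blastocyst", "NA") or "NA"),
                pregnancy=str(row.get("pregnancy", "NA") or "NA"),
            )
        )
        reps = []
        for rel in row["replicates"]:
            fp = base / rel
            if not fp.exists():
                raise FileNotFoundError(f"replicate file not found: {fp}")
            reps.append(read_spectrum_csv(fp))
        spectra.append(reps)
    return SpectrumSet(samples, spectra)


def read_dataset_manifest(path: str | Path) -> SpectrumSet:
    """Assemble a SpectrumSet from a manifest file (CSV or JSON).

    CSV columns: ``sample_id, group_pcos, blastocyst, pregnancy,
    replicate_paths`` with the replicate paths joined by semicolons; JSON is
    a list of objects with a ``replicates`` array. Paths are resolved
    relative to the manifest's directory. All referenced spectra must share
    one grid.
    """
    path = Path(path)
    base = path.parent
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        rows = [dict(r, replicates=list(r["replicates"])) for r in data]
    else:
        import csv as _csv

        with open(path, newline="") as fh:
            reader = _csv.DictReader(fh)
            rows = []
            for r in reader:
                paths = [p for p in (r.get("replicate_paths") or "").split(";") if p]
                if not paths:
                    raise FormatError(f"{path}: sample {r.get('sample_id')!r} lists no replicate paths")
                rows.append(dict(r, replicates=paths))
    if not rows:
        raise FormatError(f"{path}: empty manifest")
    return _assemble(rows, base)


def write_dataset_manifest(dataset: SpectrumSet, out_dir: str | Path) -> Path:
    """Write every replicate spectrum as CSV plus a manifest.csv index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec_dir = out_dir / "spectra"
    spec_dir.mkdir(exist_ok=True)
    lines = ["sample_id,group_pcos,blastocyst,pregnancy,replicate_paths"]
    for meta, reps in zip(dataset.samples, dataset.spectra):
        rels = []
        for k, sp in enumerate(reps):
            rel = f"spectra/{meta.sample_id}_r{k}.csv"
            write_spectrum_csv(sp, out_dir / rel)
            rels.append(rel)
        lines.append(
            f"{meta.sample_id},{meta.group_pcos},{meta.blastocyst},{meta.pregnancy},{';'.join(rels)}"
        )
    manifest = out_dir / "manifest.csv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def average_replicates(dataset: SpectrumSet) -> SpectrumSet:
    """Collapse each sample's replicates to their pointwise mean spectrum."""
    spectra = []
    for reps in dataset.spectra:
        stacked = np.stack([sp.intensities for sp in reps])
        spectra.append([Spectrum(reps[0].grid, stacked.mean(axis=0))])
    return SpectrumSet(list(dataset.samples), spectra)
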