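"""Preprocessing of MALDI-TOF profile spectra.

Raw profile spectra are turned into baseline-corrected, total-ion-count
(TIC) normalized spectra on a common m/z grid.  The fixed stage order is

    resample -> QC filter -> baseline correction -> TIC normalization
    -> replicate averaging

after which a cohort mean spectrum is formed for peak detection.  The
operators are deliberately simple and monotone: linear interpolation for
resampling, a rolling-minimum followed by a moving average of the same
width for the baseline, and scalar rescaling for TIC normalization, so
that each stage has closed-form behaviour on idealized inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d, uniform_filter1d

CASE = "case"
CONTROL = "control"
LABELS = (CASE, CONTROL)

DEFAULT_GRID_RANGE = (1000.0, 10000.0)
DEFAULT_GRID_STEP = 1.0
DEFAULT_BASELINE_WINDOW_DA = 200.0
DEFAULT_TIC_TARGET = 1.0
DEFAULT_MIN_TIC = 1e-9
DEFAULT_MIN_CORR = 0.5


class QCExclusionError(ValueError):
    """Raised when an operation hits a spectrum that QC should have removed."""


@dataclass
class Spectrum:
    """A single profile mass spectrum on a strictly ascending m/z axis.

    Intensities are arbitrary units; after baseline correction they are
    non-negative by construction.
    """

    mz: np.ndarray
    intensity: np.ndarray
    spectrum_id: str = "spectrum"
    sample_id: str = "sample"
    replicate: int = 1
    label: str | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z values must be strictly ascending")
        if not (np.all(np.isfinite(self.mz)) and np.all(np.isfinite(self.intensity))):
            raise ValueError("m/z and intensities must be finite")

    @property
    def tic(self) -> float:
        """Total ion count: the sum of all intensities."""
        return float(self.intensity.sum())

    def with_intensity(self, intensity: np.ndarray, **changes) -> "Spectrum":
        return replace(self, intensity=np.asarray(intensity, dtype=float), **changes)


@dataclass
class LabeledCohort:
    """A set of spectra with a binary case/control label per sample."""

    spectra: list[Spectrum]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lab in self.labels.values():
            if lab not in LABELS:
                raise ValueError(f"label must be one of {LABELS}, got {lab!r}")
        for spec in self.spectra:
            if spec.sample_id not in self.labels:
                raise ValueError(f"sample {spec.sample_id!r} has no label")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for spec in self.spectra:
            seen.setdefault(spec.sample_id, None)
        return list(seen)

    def label_of(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def common_grid(self) -> np.ndarray:
        """The shared m/z grid; raises if spectra are not aligned."""
        if not self.spectra:
            raise ValueError("empty cohort")
        grid = self.spectra[0].mz
        for spec in self.spectra[1:]:
            if spec.mz.shape != grid.shape or not np.array_equal(spec.mz, grid):
                raise ValueError(
                    f"spectrum {spec.spectrum_id!r} is not on the common grid"
                )
        return grid


def default_grid(
    mass_range: Sequence[float] = DEFAULT_GRID_RANGE, step: float = DEFAULT_GRID_STEP
) -> np.ndarray:
    lo, hi = float(mass_range[0]), float(mass_range[1])
    if not lo < hi:
        raise ValueError(f"mass_range must satisfy low < high, got ({lo}, {hi})")
    if step <= 0:
        raise ValueError("grid step must be positive")
    n = int(np.floor((hi - lo) / step + 0.5)) + 1
    return lo + step * np.arange(n)


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a new ascending m/z grid.

    The grid must lie within the spectrum's m/z span; values on the new
    grid always lie between the neighbouring original intensities.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be a strictly ascending 1-D array")
    lo, hi = spectrum.mz[0], spectrum.mz[-1]
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] outside spectrum span [{lo}, {hi}]"
        )
    values = np.interp(grid, spectrum.mz, spectrum.intensity)
    return replace(spectrum, mz=grid, intensity=values)


def _window_points(mz: np.ndarray, window_da: float) -> int:
    step = float(np.median(np.diff(mz)))
    if window_da <= step:
        raise ValueError(
            f"baseline window ({window_da} Da) must exceed the grid step ({step} Da)"
        )
    span = mz[-1] - mz[0]
    if window_da > span:
        raise ValueError(
            f"baseline window ({window_da} Da) exceeds the spectrum span ({span} Da)"
        )
    return max(3, int(round(window_da / step)) | 1)  # odd size, >= 3


def estimate_baseline(
    spectrum: Spectrum, window_da: float = DEFAULT_BASELINE_WINDOW_DA
) -> Spectrum:
    """Rolling-minimum baseline followed by a moving average of equal width.

    The smoothed rolling minimum is clamped from above by the signal so
    the estimate never exceeds the spectrum anywhere.
    """
    size = _window_points(spectrum.mz, window_da)
    rolled = minimum_filter1d(spectrum.intensity, size=size, mode="nearest")
    smoothed = uniform_filter1d(rolled, size=size, mode="nearest")
    baseline = np.minimum(smoothed, spectrum.intensity)
    return spectrum.with_intensity(
        baseline, spectrum_id=f"{spectrum.spectrum_id}:baseline"
    )


def subtract_baseline(spectrum: Spectrum, baseline: Spectrum) -> Spectrum:
    """Pointwise difference, clamped at zero (intensities are physical)."""
    if spectrum.mz.shape != baseline.mz.shape or not np.array_equal(
        spectrum.mz, baseline.mz
    ):
        raise ValueError("spectrum and baseline are on different grids")
    corrected = np.maximum(spectrum.intensity - baseline.intensity, 0.0)
    return spectrum.with_intensity(corrected)


def normalize_tic(spectrum: Spectrum, target_tic: float = DEFAULT_TIC_TARGET) -> Spectrum:
    """Scale intensities so their sum equals ``target_tic``."""
    if target_tic <= 0:
        raise ValueError("target_tic must be positive")
    total = spectrum.intensity.sum()
    if total <= 0:
        raise QCExclusionError(
            f"spectrum {spectrum.spectrum_id!r} has non-positive TIC ({total})"
        )
    return spectrum.with_intensity(spectrum.intensity * (target_tic / total))


def mean_spectrum(spectra: Iterable[Spectrum] | LabeledCohort) -> Spectrum:
    """Pointwise arithmetic mean over all spectra (labels are ignored)."""
    if isinstance(spectra, LabeledCohort):
        spectra = spectra.spectra
    spectra = list(spectra)
    if not spectra:
        raise ValueError("cannot average an empty set of spectra")
    grid = spectra[0].mz
    acc = np.zeros_like(grid)
    for spec in spectra:
        if spec.mz.shape != grid.shape or not np.array_equal(spec.mz, grid):
            raise ValueError(f"spectrum {spec.spectrum_id!r} not on the common grid")
        acc += spec.intensity
    return Spectrum(
        mz=grid, intensity=acc / len(spectra), spectrum_id="mean", sample_id="mean"
    )


def qc_filter(
    cohort: LabeledCohort,
    min_tic: float = DEFAULT_MIN_TIC,
    min_corr_to_mean: float = DEFAULT_MIN_CORR,
) -> tuple[LabeledCohort, pd.DataFrame]:
    """Exclude spectra with a degenerate TIC or poor correlation to the mean.

    Returns the filtered cohort and a report with one row per spectrum
    (columns: spectrum_id, sample_id, excluded, reason).  Raises if
    nothing survives.
    """
    if not cohort.spectra:
        raise ValueError("empty cohort")
    mean = mean_spectrum(cohort).intensity
    mean_centered = mean - mean.mean()
    mean_norm = np.sqrt((mean_centered**2).sum())
    rows = []
    kept: list[Spectrum] = []
    for spec in cohort.spectra:
        reason = ""
        if spec.tic < min_tic:
            reason = "tic"
        else:
            x = spec.intensity - spec.intensity.mean()
            denom = np.sqrt((x**2).sum()) * mean_norm
            corr = float((x * mean_centered).sum() / denom) if denom > 0 else 0.0
            if corr < min_corr_to_mean:
                reason = "correlation"
        if reason:
            rows.append((spec.spectrum_id, spec.sample_id, True, reason))
        else:
            rows.append((spec.spectrum_id, spec.sample_id, False, ""))
            kept.append(spec)
    report = pd.DataFrame(rows, columns=["spectrum_id", "sample_id", "excluded", "reason"])
    if not kept:
        raise ValueError("all spectra excluded by QC")
    labels = {s.sample_id: cohort.labels[s.sample_id] for s in kept}
    return LabeledCohort(spectra=kept, labels=labels), report


def average_replicates(cohort: LabeledCohort) -> LabeledCohort:
    """Average technical replicates so each sample has a single spectrum."""
    grid = cohort.common_grid()
    by_sample: dict[str, list[Spectrum]] = {}
    for spec in cohort.spectra:
        by_sample.setdefault(spec.sample_id, []).append(spec)
    merged = []
    for sample_id, specs in by_sample.items():
        mean_int = np.mean([s.intensity for s in specs], axis=0)
        merged.append(
            Spectrum(
                mz=grid,
                intensity=mean_int,
                spectrum_id=sample_id,
                sample_id=sample_id,
                replicate=1,
                label=cohort.labels[sample_id],
            )
        )
    return LabeledCohort(spectra=merged, labels=dict(cohort.labels))


@dataclass
class PreprocessParams:
    """Tunable knobs of the fixed preprocessing pipeline."""

    mass_range: tuple[float, float] = DEFAULT_GRID_RANGE
    grid_step: float = DEFAULT_GRID_STEP
    baseline_window_da: float = DEFAULT_BASELINE_WINDOW_DA
    tic_target: float = DEFAULT_TIC_TARGET
    min_tic: float = DEFAULT_MIN_TIC
    min_corr_to_mean: float = DEFAULT_MIN_CORR


@dataclass
class PreprocessResult:
    cohort: LabeledCohort  # one baseline-corrected, normalized spectrum per sample
    mean: Spectrum  # mean of the preprocessed per-sample spectra
    qc_report: pd.DataFrame


def preprocess_cohort(
    cohort: LabeledCohort, params: PreprocessParams | None = None
) -> PreprocessResult:
    """Run the full fixed-order preprocessing pipeline on a raw cohort."""
    params = params or PreprocessParams()
    grid = default_grid(params.mass_range, params.grid_step)
    resampled = LabeledCohort(
        spectra=[resample(s, grid) for s in cohort.spectra], labels=dict(cohort.labels)
    )
    filtered, report = qc_filter(resampled, params.min_tic, params.min_corr_to_mean)
    processed = []
    for spec in filtered.spectra:
        baseline = estimate_baseline(spec, params.baseline_window_da)
        corrected = subtract_baseline(spec, baseline)
        processed.append(normalize_tic(corrected, params.tic_target))
    clean = LabeledCohort(spectra=processed, labels=dict(filtered.labels))
    per_sample = average_replicates(clean)
    return PreprocessResult(
        cohort=per_sample, mean=mean_spectrum(per_sample), qc_report=report
    )
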