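"""Synthetic MALDI-TOF profile cohorts with known ground truth.

The generator emulates the structure of a linear-mode, low-molecular-weight
(1-10 kDa) CSF profiling experiment: a common m/z grid, Gaussian peaks whose
width grows proportionally with m/z, an exponentially decaying chemical
background, additive detector noise, a log-normal per-spectrum intensity
scale (what TIC normalization removes), small m/z jitter, and optional
technical replicates.  A handful of "marker" peaks carry multiplicative
case/control fold changes; everything needed to verify downstream recovery
(peak centers, amplitudes, fold changes, per-spectrum scales) is returned
as a :class:`SyntheticTruth`.

Marker base amplitudes are assigned as ``marker_delta / |FC - 1|`` so that
every marker carries a comparable absolute case-control intensity
separation.  A discovered biomarker panel is by construction a set of peaks
that were individually informative, so emulating one means giving each
marker similar discriminative power rather than letting a large-|FC-1|
marker with a large random amplitude dominate (which would make the
classification task either trivial or, for the weak markers, hopeless).
Background amplitudes are log-uniform over ``peak_height_range``.

Randomness: a single seed feeds one ``numpy.random.default_rng`` stream and
all draws happen in a fixed, documented order (centers, marker assignment,
amplitudes, then per sample: TIC scale; per replicate: jitter, noise), so
the same config and seed reproduce bit-identical cohorts.  The TIC scale is
drawn once per sample and shared by its technical replicates: the scale
models the preparation, which is why replicates cluster by sample.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mfio
from .preprocess import CASE, CONTROL, LabeledCohort, Spectrum, default_grid


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the emulated study: 35 cases vs 23 controls, profile
    spectra on a 1 Da grid over 1,000-10,000 Da, 153 detectable peaks of
    which 5 are markers with modest fold changes.
    """

    n_cases: int = 35
    n_controls: int = 23
    mass_range: tuple[float, float] = (1000.0, 10000.0)
    grid_step: float = 1.0
    n_background_peaks: int = 148
    n_marker_peaks: int = 5
    marker_fold_changes: tuple[float, ...] = (0.79, 0.90, 0.94, 0.96, 1.5)
    peak_height_range: tuple[float, float] = (5.0, 50.0)
    resolution_factor: float = 0.002  # peak sd = resolution_factor * m/z
    baseline_amplitude: float = 20.0
    baseline_decay_da: float = 1500.0
    noise_sd: float = 0.5
    tic_scale_sd: float = 0.2  # sd of log of the per-spectrum multiplicative scale
    mz_jitter_sd: float = 1.0
    n_replicates: int = 1
    marker_delta: float = 0.45  # absolute case-control separation per marker
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        lo, hi = self.mass_range
        if not lo < hi:
            raise ValueError(f"mass_range must satisfy low < high, got ({lo}, {hi})")
        if lo <= 0:
            raise ValueError("mass_range must be positive")
        if len(self.marker_fold_changes) != self.n_marker_peaks:
            raise ValueError("need one fold change per marker peak")
        if any(fc <= 0 for fc in self.marker_fold_changes):
            raise ValueError("fold changes must be positive")
        if self.n_background_peaks < 0 or self.n_marker_peaks < 0:
            raise ValueError("peak counts must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.resolution_factor < 0.25 / 4:
            raise ValueError("resolution_factor must be in (0, 0.0625)")
        if self.peak_height_range[0] <= 0 or (
            self.peak_height_range[1] < self.peak_height_range[0]
        ):
            raise ValueError("peak_height_range must be positive and ordered")
        for name in ("noise_sd", "tic_scale_sd", "mz_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for parameter-recovery tests."""

    marker_centers: list[float]
    marker_fold_changes: list[float]
    marker_amplitudes: list[float]
    background_centers: list[float]
    background_amplitudes: list[float]
    tic_scales: dict[str, float] = field(default_factory=dict)
    baseline_amplitude: float = 0.0
    baseline_decay_da: float = 1.0
    mass_range: tuple[float, float] = (1000.0, 10000.0)
    resolution_factor: float = 0.002

    def __post_init__(self) -> None:
        if len(self.marker_centers) != len(self.marker_fold_changes):
            raise ValueError("marker centers and fold changes differ in length")
        if set(self.marker_centers) & set(self.background_centers):
            raise ValueError("marker and background centers must be disjoint")

    def baseline(self, mz: np.ndarray) -> np.ndarray:
        """The true background curve b(m) = A * exp(-(m - low)/decay)."""
        return self.baseline_amplitude * np.exp(
            -(np.asarray(mz, dtype=float) - self.mass_range[0]) / self.baseline_decay_da
        )

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["mass_range"] = list(data["mass_range"])
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        data = json.loads(Path(path).read_text())
        data["mass_range"] = tuple(data["mass_range"])
        return cls(**data)


def _place_centers(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw peak centers with guaranteed pairwise separation >= 4 peak sd.

    Centers are placed in log-m/z space, where the minimum-separation
    constraint (4 sd with sd proportional to m/z) becomes a constant gap
    u = -ln(1 - 4*resolution_factor); the slack beyond the mandatory gaps
    is split Dirichlet-uniformly, which yields the exact requested count
    in one pass.
    """
    n = config.n_background_peaks + config.n_marker_peaks
    if n == 0:
        return np.empty(0)
    lo, hi = config.mass_range
    u = -np.log1p(-4.0 * config.resolution_factor)
    margin = max(2.0 * u, np.log1p(8.0 * config.grid_step / lo))
    s_min, s_max = np.log(lo) + margin, np.log(hi) - margin
    slack = (s_max - s_min) - (n - 1) * u
    if slack < 0:
        raise ValueError(
            f"cannot place {n} peaks with 4-sd separation inside {config.mass_range}"
        )
    extras = rng.dirichlet(np.ones(n + 1)) * slack
    s = s_min + np.cumsum(extras[:-1]) + u * np.arange(n)
    return np.exp(s)


def generate_cohort(config: SimConfig) -> tuple[LabeledCohort, SyntheticTruth]:
    """Generate a labeled synthetic cohort and its ground truth.

    Each spectrum is  t * ( sum_i A_i exp(-(m - c_i - j_i)^2 / (2 s_i^2))
    + b(m) + eps )  where t is the per-spectrum log-normal TIC scale,
    j_i the per-spectrum m/z jitter, s_i = resolution_factor * c_i and
    b(m) the exponential background.  Case samples have marker amplitudes
    multiplied by the configured fold change, so the case-mean amplitude
    equals fold_change times the control-mean amplitude exactly.
    """
    rng = np.random.default_rng(config.seed)
    grid = default_grid(config.mass_range, config.grid_step)

    centers = _place_centers(config, rng)
    n_total = centers.size
    marker_idx = np.sort(
        rng.choice(n_total, size=config.n_marker_peaks, replace=False)
    ) if config.n_marker_peaks else np.empty(0, dtype=int)
    is_marker = np.zeros(n_total, dtype=bool)
    is_marker[marker_idx] = True

    log_lo, log_hi = np.log(config.peak_height_range[0]), np.log(config.peak_height_range[1])
    amplitudes = np.exp(rng.uniform(log_lo, log_hi, size=n_total))
    fold = np.ones(n_total)
    for j, idx in enumerate(marker_idx):
        fc = config.marker_fold_changes[j]
        fold[idx] = fc
        if abs(fc - 1.0) > 1e-12:
            # equalized absolute separation; floor keeps the peak detectable
            amplitudes[idx] = max(
                config.marker_delta / abs(fc - 1.0), 2.0 * config.noise_sd
            )

    sigmas = config.resolution_factor * centers
    baseline = config.baseline_amplitude * np.exp(
        -(grid - config.mass_range[0]) / config.baseline_decay_da
    )

    sample_ids = [f"case{i + 1:02d}" for i in range(config.n_cases)] + [
        f"ctrl{i + 1:02d}" for i in range(config.n_controls)
    ]
    labels = {
        sid: (CASE if sid.startswith("case") else CONTROL) for sid in sample_ids
    }

    spectra: list[Spectrum] = []
    tic_scales: dict[str, float] = {}
    for sid in sample_ids:
        case_factor = fold if labels[sid] == CASE else np.ones(n_total)
        # the multiplicative scale belongs to the preparation, i.e. the
        # sample: technical replicates share it, which is what makes
        # replicates cluster by sample in raw intensity space
        scale = (
            float(np.exp(rng.normal(0.0, config.tic_scale_sd)))
            if config.tic_scale_sd > 0
            else 1.0
        )
        for rep in range(1, config.n_replicates + 1):
            jitter = (
                rng.normal(0.0, config.mz_jitter_sd, size=n_total)
                if config.mz_jitter_sd > 0
                else np.zeros(n_total)
            )
            signal = np.zeros_like(grid)
            for c, a, s, f, j in zip(centers, amplitudes, sigmas, case_factor, jitter):
                c_eff = c + j
                i0 = np.searchsorted(grid, c_eff - 5.0 * s)
                i1 = np.searchsorted(grid, c_eff + 5.0 * s)
                window = grid[i0:i1]
                signal[i0:i1] += (a * f) * np.exp(
                    -((window - c_eff) ** 2) / (2.0 * s * s)
                )
            noise = (
                rng.normal(0.0, config.noise_sd, size=grid.size)
                if config.noise_sd > 0
                else 0.0
            )
            spectrum_id = f"{sid}_r{rep}"
            tic_scales[spectrum_id] = scale
            spectra.append(
                Spectrum(
                    mz=grid,
                    intensity=scale * (signal + baseline + noise),
                    spectrum_id=spectrum_id,
                    sample_id=sid,
                    replicate=rep,
                    label=labels[sid],
                )
            )

    truth = SyntheticTruth(
        marker_centers=[float(c) for c in centers[is_marker]],
        marker_fold_changes=[float(f) for f in fold[is_marker]],
        marker_amplitudes=[float(a) for a in amplitudes[is_marker]],
        background_centers=[float(c) for c in centers[~is_marker]],
        background_amplitudes=[float(a) for a in amplitudes[~is_marker]],
        tic_scales=tic_scales,
        baseline_amplitude=config.baseline_amplitude,
        baseline_decay_da=config.baseline_decay_da,
        mass_range=config.mass_range,
        resolution_factor=config.resolution_factor,
    )
    return LabeledCohort(spectra=spectra, labels=labels), truth


def write_cohort(
    cohort: LabeledCohort,
    truth: SyntheticTruth | None,
    directory: str | Path,
    fmt: str = "text",
) -> dict[str, Path]:
    """Write spectra (text or mzML), the sample sheet and the truth JSON.

    Returns a mapping with the sample-sheet path, optional truth path and
    the list of spectrum paths under key ``"spectra"``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}
    spectrum_paths: list[Path] = []
    if fmt == "text":
        for spec in cohort.spectra:
            p = directory / f"{spec.spectrum_id}.txt"
            mfio.write_spectrum_text(spec, p)
            spectrum_paths.append(p)
    elif fmt == "mzml":
        if cohort.spectra:
            p = directory / "spectra.mzML"
            mfio.write_mzml(cohort.spectra, p)
            spectrum_paths.append(p)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'text' or 'mzml')")
    sheet = directory / "samples.csv"
    mfio.write_sample_sheet(cohort, sheet)
    paths["sample_sheet"] = sheet
    paths["spectra"] = spectrum_paths
    if truth is not None:
        tpath = directory / "truth.json"
        truth.to_json(tpath)
        paths["truth"] = tpath
    return paths


def read_cohort(directory: str | Path) -> tuple[LabeledCohort, SyntheticTruth | None]:
    """Read a cohort written by :func:`write_cohort` back into memory."""
    directory = Path(directory)
    sheet = directory / "samples.csv"
    if not sheet.exists():
        raise FileNotFoundError(f"sample sheet not found at {sheet}")
    table = pd.read_csv(sheet, dtype={"spectrum_id": str, "sample_id": str})
    mzml_path = directory / "spectra.mzML"
    by_id: dict[str, Spectrum] = {}
    if mzml_path.exists():
        for spec in mfio.read_mzml(mzml_path):
            by_id[spec.spectrum_id] = spec
    spectra = []
    labels: dict[str, str] = {}
    for row in table.itertuples(index=False):
        labels[row.sample_id] = row.label
        if row.spectrum_id in by_id:
            spec = by_id[row.spectrum_id]
        else:
            p = directory / f"{row.spectrum_id}.txt"
            if not p.exists():
                raise FileNotFoundError(f"spectrum file not found at {p}")
            spec = mfio.read_spectrum_text(p)
        spectra.append(
            Spectrum(
                mz=spec.mz,
                intensity=spec.intensity,
                spectrum_id=row.spectrum_id,
                sample_id=row.sample_id,
                replicate=int(row.replicate),
                label=row.label,
            )
        )
    truth_path = directory / "truth.json"
    truth = SyntheticTruth.from_json(truth_path) if truth_path.exists() else None
    return LabeledCohort(spectra=spectra, labels=labels), truth
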