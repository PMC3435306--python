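"""Peak detection on the cohort mean spectrum and per-sample quantification.

Peaks are found once, on the mean of the preprocessed spectra, and every
sample is then quantified at the same positions.  Detection works on a
lightly smoothed copy of the mean spectrum: a candidate is a strict local
maximum whose height above the local median trend, divided by a robust
local noise estimate (median absolute deviation of the detrended signal,
scaled to a standard deviation), reaches ``snr_min``.  Candidates closer
than ``min_separation_da`` are thinned greedily, keeping the higher peak
(ties keep the lower m/z).  Quantification takes the windowed maximum (or,
optionally, the trapezoidal area) inside each peak's window and averages
technical replicates per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d, percentile_filter, uniform_filter1d
from scipy.signal import argrelextrema

from .preprocess import CASE, LabeledCohort, Spectrum

LQ_TO_SD = 3.1388  # lower-quartile of |noise| to sd, Gaussian consistency

DEFAULT_SNR_MIN = 2.0
DEFAULT_MIN_SEPARATION_DA = 5.0
DEFAULT_NOISE_WINDOW_DA = 250.0
DEFAULT_SMOOTH_WINDOW_DA = 5.0
DEFAULT_MAX_HALFWIDTH_FRACTION = 0.003  # cap: 0.3% of the peak mass


@dataclass
class PeakSet:
    """Detected peak centers with quantification windows."""

    centers: np.ndarray  # Da, strictly ascending
    half_widths: np.ndarray  # Da
    snr: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.half_widths = np.asarray(self.half_widths, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if not (self.centers.shape == self.half_widths.shape == self.snr.shape):
            raise ValueError("centers, half_widths and snr must have equal length")
        if self.centers.size and not np.all(np.diff(self.centers) > 0):
            raise ValueError("peak centers must be strictly ascending")

    def __len__(self) -> int:
        return self.centers.size

    @property
    def peak_ids(self) -> list[str]:
        """Peak ids: mass rounded to 2 decimals; collisions get letter suffixes."""
        ids: list[str] = []
        seen: dict[str, int] = {}
        for c in self.centers:
            base = f"{c:.2f}"
            count = seen.get(base, 0)
            ids.append(base if count == 0 else f"{base}_{chr(ord('a') + count)}")
            seen[base] = count + 1
        return ids

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "peak_id": self.peak_ids,
                "center": self.centers,
                "half_width": self.half_widths,
                "snr": self.snr,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PeakSet":
        table = pd.read_csv(path)
        return cls(
            centers=table["center"].to_numpy(),
            half_widths=table["half_width"].to_numpy(),
            snr=table["snr"].to_numpy(),
        )


@dataclass
class FeatureMatrix:
    """Samples x peaks intensity table with case/control labels."""

    values: np.ndarray  # (n_samples, n_peaks), non-negative
    sample_ids: list[str]
    labels: np.ndarray  # 'case' / 'control' per sample
    peak_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.shape != (len(self.sample_ids), len(self.peak_ids)):
            raise ValueError("values shape does not match sample/peak ids")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Binary response: 1 for case, 0 for control."""
        return (self.labels == CASE).astype(int)

    def select(self, peak_ids: list[str]) -> "FeatureMatrix":
        index = {pid: j for j, pid in enumerate(self.peak_ids)}
        cols = [index[pid] for pid in peak_ids]
        return FeatureMatrix(
            values=self.values[:, cols],
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
            peak_ids=list(peak_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=self.sample_ids, columns=self.peak_ids)
        frame.insert(0, "label", self.labels)
        frame.index.name = "sample_id"
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        frame = pd.read_csv(path, index_col="sample_id")
        labels = frame.pop("label").to_numpy(dtype=object)
        return cls(
            values=frame.to_numpy(dtype=float),
            sample_ids=[str(s) for s in frame.index],
            labels=labels,
            peak_ids=[str(c) for c in frame.columns],
        )


def detect_peaks(
    mean_spec: Spectrum,
    snr_min: float = DEFAULT_SNR_MIN,
    min_separation_da: float = DEFAULT_MIN_SEPARATION_DA,
    noise_window_da: float = DEFAULT_NOISE_WINDOW_DA,
    smooth_window_da: float = DEFAULT_SMOOTH_WINDOW_DA,
    max_halfwidth_fraction: float = DEFAULT_MAX_HALFWIDTH_FRACTION,
) -> PeakSet:
    """Detect peaks on a preprocessed mean spectrum.

    An all-zero or featureless spectrum yields an empty PeakSet rather
    than an error.  Detection is scale-free: both the height and the
    noise estimate scale linearly with the spectrum.
    """
    mz, intensity = mean_spec.mz, mean_spec.intensity
    step = float(np.median(np.diff(mz)))
    if not np.any(intensity > 0):
        empty = np.empty(0)
        return PeakSet(centers=empty, half_widths=empty.copy(), snr=empty.copy())

    smooth_pts = max(1, int(round(smooth_window_da / step)) | 1)
    noise_pts = max(3, int(round(noise_window_da / step)) | 1)
    # 'reflect' padding everywhere: 'nearest' would tile a single boundary
    # value across half a window and wreck the edge noise estimate
    smoothed = uniform_filter1d(intensity, size=smooth_pts, mode="reflect")
    # local floor: smoothed rolling minimum, as in the baseline operator;
    # peak height is the prominence of the smoothed signal above it
    floor = uniform_filter1d(
        minimum_filter1d(smoothed, size=noise_pts, mode="reflect"),
        size=noise_pts,
        mode="reflect",
    )
    floor = np.minimum(floor, smoothed)
    # detrend by removing everything smooth (peaks included): what is left
    # is high-frequency noise; the local lower quartile of its magnitude is
    # a scale estimator that tolerates narrow peaks leaking into the
    # residual (unlike the MAD, which they inflate in crowded regions)
    detrended = np.abs(intensity - smoothed)
    noise = LQ_TO_SD * percentile_filter(detrended, percentile=25, size=noise_pts, mode="reflect")
    noise_floor = 1e-9 * float(np.max(smoothed))
    noise = np.maximum(noise, noise_floor)

    (candidates,) = argrelextrema(smoothed, np.greater, order=1)
    if candidates.size == 0:
        empty = np.empty(0)
        return PeakSet(centers=empty, half_widths=empty.copy(), snr=empty.copy())
    height = smoothed[candidates] - floor[candidates]
    snr = height / noise[candidates]
    keep = snr >= snr_min
    candidates, snr, height = candidates[keep], snr[keep], height[keep]

    # greedy thinning: strongest first, equal heights keep the lower m/z
    order = np.lexsort((mz[candidates], -height))
    kept_idx: list[int] = []
    kept_mz: list[float] = []
    kept_snr: list[float] = []
    for k in order:
        pos = float(mz[candidates[k]])
        if all(abs(pos - other) >= min_separation_da for other in kept_mz):
            kept_idx.append(candidates[k])
            kept_mz.append(pos)
            kept_snr.append(float(snr[k]))
    sort = np.argsort(kept_mz)
    centers = np.array(kept_mz)[sort]
    snr_out = np.array(kept_snr)[sort]

    half_widths = np.empty_like(centers)
    for i, c in enumerate(centers):
        gaps = []
        if i > 0:
            gaps.append((c - centers[i - 1]) / 2.0)
        if i < centers.size - 1:
            gaps.append((centers[i + 1] - c) / 2.0)
        neighbour = min(gaps) if gaps else np.inf
        half_widths[i] = min(neighbour, max_halfwidth_fraction * c)
    return PeakSet(centers=centers, half_widths=half_widths, snr=snr_out)


def quantify(
    cohort: LabeledCohort, peakset: PeakSet, statistic: str = "max"
) -> FeatureMatrix:
    """Quantify every sample at the detected peaks.

    ``statistic='max'`` takes the highest intensity inside each peak's
    window (robust to small m/z jitter); ``'area'`` integrates the window
    trapezoidally.  Technical replicates are averaged per sample.
    """
    if statistic not in ("max", "area"):
        raise ValueError("statistic must be 'max' or 'area'")
    grid = cohort.common_grid()
    lo_idx = np.searchsorted(grid, peakset.centers - peakset.half_widths, side="left")
    hi_idx = np.searchsorted(grid, peakset.centers + peakset.half_widths, side="right")
    for pid, c, i0, i1 in zip(peakset.peak_ids, peakset.centers, lo_idx, hi_idx):
        if c < grid[0] or c > grid[-1]:
            raise ValueError(f"peak {pid} at {c} Da lies outside the grid span")
        if i1 <= i0:
            raise ValueError(f"peak {pid} has an empty quantification window")

    by_sample: dict[str, list[Spectrum]] = {}
    for spec in cohort.spectra:
        by_sample.setdefault(spec.sample_id, []).append(spec)
    sample_ids = list(by_sample)
    values = np.zeros((len(sample_ids), len(peakset)))
    for row, sid in enumerate(sample_ids):
        per_replicate = []
        for spec in by_sample[sid]:
            if statistic == "max":
                vals = [spec.intensity[i0:i1].max() for i0, i1 in zip(lo_idx, hi_idx)]
            else:
                vals = [
                    np.trapezoid(spec.intensity[i0:i1], grid[i0:i1])
                    for i0, i1 in zip(lo_idx, hi_idx)
                ]
            per_replicate.append(vals)
        values[row] = np.mean(per_replicate, axis=0)
    labels = np.array([cohort.labels[sid] for sid in sample_ids], dtype=object)
    return FeatureMatrix(
        values=values,
        sample_ids=sample_ids,
        labels=labels,
        peak_ids=peakset.peak_ids,
    )
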