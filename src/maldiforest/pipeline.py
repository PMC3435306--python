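"""End-to-end pipeline: configuration, staged execution and the run report.

A run is fully described by one :class:`PipelineConfig` (serializable to
YAML) plus the input spectra (or the simulator settings), and is
reproducible bit-for-bit from that config and its seed: all randomness is
derived from the single recorded seed, timings are logged but kept out of
the report, and every intermediate artifact is written as text (two-column
spectra, CSV tables, JSON results) so each stage can also be run standalone
on the files of the previous one.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as mfio
from .classify import (
    derive_seeds,
    fit_forest,
    nested_performance,
    repeated_cv,
    rfe,
    roc_points,
)
from .peaks import FeatureMatrix, PeakSet, detect_peaks, quantify
from .preprocess import (
    LabeledCohort,
    PreprocessParams,
    preprocess_cohort,
)
from .simulate import SimConfig, generate_cohort, read_cohort, write_cohort
from .stats import univariate_table

log = logging.getLogger("maldiforest")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class PeakParams:
    snr_min: float = 2.0
    min_separation_da: float = 10.0
    noise_window_da: float = 250.0
    smooth_window_da: float = 5.0
    statistic: str = "max"


@dataclass
class ClassifyParams:
    n_trees: int = 500
    n_trees_importance: int = 500
    n_folds: int = 10
    n_repetitions: int = 10
    mtry: int | None = None
    run_nested: bool = True


@dataclass
class StatsParams:
    mode: str = "auto"


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run, with documented defaults."""

    outdir: str = "maldiforest_run"
    seed: int | None = 0
    input_dir: str | None = None  # read spectra from here instead of simulating
    spectrum_format: str = "text"  # 'text' or 'mzml' for simulated spectra
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    peaks: PeakParams = field(default_factory=PeakParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    stats: StatsParams = field(default_factory=StatsParams)

    def to_dict(self) -> dict:
        data = asdict(self)
        for key in ("mass_range", "marker_fold_changes", "peak_height_range"):
            data["sim"][key] = list(data["sim"][key])
        data["preprocess"]["mass_range"] = list(data["preprocess"]["mass_range"])
        return data

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = dict(data.pop("sim", {}))
        for key in ("mass_range", "marker_fold_changes", "peak_height_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        prep = dict(data.pop("preprocess", {}))
        if "mass_range" in prep:
            prep["mass_range"] = tuple(prep["mass_range"])
        return cls(
            sim=SimConfig(**sim),
            preprocess=PreprocessParams(**prep),
            peaks=PeakParams(**data.pop("peaks", {})),
            classify=ClassifyParams(**data.pop("classify", {})),
            stats=StatsParams(**data.pop("stats", {})),
            **data,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """Hash of the scientific configuration (where outputs land is not
        part of what defines a run)."""
        data = self.to_dict()
        data.pop("outdir", None)
        canonical = json.dumps(data, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            start = time.perf_counter()
            log.info("stage %s: starting", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # tag the failure with its stage
                raise PipelineError(f"stage {name}: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - start)
            return result

        return run

    return wrap


@_stage("simulate")
def stage_simulate(config: PipelineConfig, outdir: Path):
    cohort, truth = generate_cohort(config.sim)
    write_cohort(cohort, truth, outdir / "spectra", fmt=config.spectrum_format)
    return cohort, truth


@_stage("preprocess")
def stage_preprocess(config: PipelineConfig, cohort: LabeledCohort, outdir: Path):
    result = preprocess_cohort(cohort, config.preprocess)
    prep_dir = outdir / "preprocessed"
    prep_dir.mkdir(parents=True, exist_ok=True)
    for spec in result.cohort.spectra:
        mfio.write_spectrum_text(spec, prep_dir / f"{spec.spectrum_id}.txt")
    mfio.write_sample_sheet(result.cohort, prep_dir / "samples.csv")
    mfio.write_spectrum_text(result.mean, outdir / "mean_spectrum.txt")
    result.qc_report.to_csv(outdir / "qc_report.csv", index=False)
    return result


@_stage("detect")
def stage_detect(config: PipelineConfig, result, outdir: Path):
    p = config.peaks
    peakset = detect_peaks(
        result.mean,
        snr_min=p.snr_min,
        min_separation_da=p.min_separation_da,
        noise_window_da=p.noise_window_da,
        smooth_window_da=p.smooth_window_da,
    )
    peakset.to_csv(outdir / "peaks.csv")
    features = quantify(result.cohort, peakset, statistic=p.statistic)
    features.to_csv(outdir / "features.csv")
    # hand downstream stages the serialized matrix, so a staged run on the
    # same files is bit-identical to run-all (CSV text is the contract)
    return peakset, FeatureMatrix.from_csv(outdir / "features.csv")


@_stage("classify")
def stage_classify(config: PipelineConfig, features: FeatureMatrix, seed: int, outdir: Path):
    c = config.classify
    full_model = fit_forest(
        features, n_trees=c.n_trees_importance, mtry=c.mtry, seed=seed
    )
    full_model.ranked_panel().to_csv(outdir / "ranked_peaks_full.csv", index=False)
    cv_full = repeated_cv(
        features,
        n_folds=c.n_folds,
        n_repetitions=c.n_repetitions,
        n_trees=c.n_trees,
        mtry=c.mtry,
        seed=seed,
    )
    cv_full.to_json(outdir / "cv_full.json")
    trace = rfe(
        features,
        seed=seed,
        n_trees_importance=c.n_trees_importance,
        n_trees_cv=c.n_trees,
        n_folds=c.n_folds,
        n_repetitions=c.n_repetitions,
    )
    trace.to_json(outdir / "rfe_trace.json")
    selected = features.select(trace.selected_set)
    panel_model = fit_forest(
        selected, n_trees=c.n_trees_importance, mtry=c.mtry, seed=seed
    )
    panel_model.ranked_panel().to_csv(outdir / "ranked_panel.csv", index=False)
    cv_selected = trace.selected_cv
    roc = roc_points(
        cv_selected.predictions["vote_fraction"].to_numpy(),
        cv_selected.predictions["label"].to_numpy(),
    )
    roc.to_csv(outdir / "roc_selected.csv", index=False)
    panel_ranked = panel_model.ranked_panel()
    cv_nested = None
    if c.run_nested:
        cv_nested = nested_performance(
            features,
            seed=seed,
            selected_fraction=len(trace.selected_set) / features.n_features,
            n_trees_importance=c.n_trees_importance,
            n_trees_cv=c.n_trees,
            n_folds=c.n_folds,
            n_repetitions=c.n_repetitions,
        )
        cv_nested.to_json(outdir / "cv_nested.json")
    return full_model, cv_full, trace, cv_nested, panel_ranked


@_stage("stats")
def stage_stats(config: PipelineConfig, features: FeatureMatrix, outdir: Path):
    table = univariate_table(features, mode=config.stats.mode)
    table.to_csv(outdir / "univariate.csv", index=False)
    return table


@dataclass
class RunReport:
    """Every number here is recomputable from the config and the inputs."""

    payload: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute simulate (optional) -> preprocess -> peaks -> classify -> stats."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
        log.info("no seed given; drew %d", seed)
    config = PipelineConfig.from_dict({**config.to_dict(), "seed": seed})
    config.sim.seed = int(derive_seeds(seed, 1, "sim")[0])
    if config.input_dir is None:
        # simulated runs are preprocessed on the simulation grid
        config.preprocess.mass_range = config.sim.mass_range
        config.preprocess.grid_step = config.sim.grid_step
    config.to_yaml(outdir / "config.yaml")

    truth = None
    if config.input_dir is not None:
        cohort, truth = read_cohort(config.input_dir)
    else:
        cohort, truth = stage_simulate(config, outdir)
    prep = stage_preprocess(config, cohort, outdir)
    peakset, features = stage_detect(config, prep, outdir)
    full_model, cv_full, trace, cv_nested, panel_ranked = stage_classify(
        config, features, seed, outdir
    )
    table = stage_stats(config, features, outdir)

    def cv_summary(cv) -> dict:
        return {
            "auc": cv.auc,
            "accuracy_pct": cv.metrics.accuracy,
            "sensitivity_pct": cv.metrics.sensitivity,
            "specificity_pct": cv.metrics.specificity,
            "n_predictions": cv.n_predictions,
            "n_case_predictions": cv.metrics.n_cases,
            "n_control_predictions": cv.metrics.n_controls,
        }

    panel = panel_ranked
    payload = {
        "provenance": {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": seed,
            "versions": _library_versions(),
        },
        "qc": {
            "n_spectra": int(len(prep.qc_report)),
            "n_excluded": int(prep.qc_report["excluded"].sum()),
        },
        "peaks": {"n_detected": len(peakset)},
        "cv_full": cv_summary(cv_full),
        "rfe": {
            "set_sizes": trace.sizes,
            "selected_size": len(trace.selected_set),
            "selected_peaks": list(trace.selected_set),
            "aucs": [cv.auc for cv in trace.cv_results],
        },
        "cv_selected": cv_summary(trace.selected_cv),
        "cv_nested": cv_summary(cv_nested) if cv_nested is not None else None,
        "ranked_panel": {
            "peak_id": list(panel["peak_id"]),
            "mda_z_score": [float(v) for v in panel["mda_z_score"]],
        },
        "univariate": {
            "n_significant": int((table["tier"] == "significant").sum()),
            "n_trend": int((table["tier"] == "trend").sum()),
        },
    }
    if truth is not None:
        selected_centers = [
            float(pid.split("_")[0]) for pid in trace.selected_set
        ]
        recovered = _recovered_markers(truth.marker_centers, selected_centers)
        payload["truth_recovery"] = {
            "n_markers": len(truth.marker_centers),
            "n_recovered_in_panel": recovered,
        }
    report = RunReport(payload=payload)
    report.to_json(outdir / "report.json")
    return report


def _recovered_markers(
    marker_centers, selected_centers, tolerance_da: float = 5.0
) -> int:
    """How many true marker centers appear in the selected panel."""
    count = 0
    for mc in marker_centers:
        if any(abs(mc - sc) <= tolerance_da for sc in selected_centers):
            count += 1
    return count


def _library_versions() -> dict:
    import scipy
    import sklearn

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
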