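import numpy as np
import pytest

from maldiforest.peaks import detect_peaks, quantify
from maldiforest.preprocess import PreprocessParams, preprocess_cohort
from maldiforest.simulate import SimConfig, generate_cohort


def small_sim_config(**overrides) -> SimConfig:
    """A reduced cohort for fast pipeline-level tests."""
    kwargs = dict(
        n_cases=12,
        n_controls=10,
        mass_range=(1000.0, 4000.0),
        n_background_peaks=28,
        n_marker_peaks=2,
        marker_fold_changes=(0.7, 1.4),
        seed=42,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def cohort_features(config: SimConfig):
    """Generate -> preprocess -> detect -> quantify; returns all stages."""
    cohort, truth = generate_cohort(config)
    prep = preprocess_cohort(
        cohort,
        PreprocessParams(mass_range=config.mass_range, grid_step=config.grid_step),
    )
    peakset = detect_peaks(prep.mean)
    features = quantify(prep.cohort, peakset)
    return cohort, truth, prep, peakset, features


def detected_marker_ids(peakset, truth, tolerance_da: float = 3.0):
    """Peak ids matching true marker centers (None where undetected)."""
    ids = []
    for center in truth.marker_centers:
        j = int(np.argmin(np.abs(peakset.centers - center)))
        ids.append(
            peakset.peak_ids[j]
            if abs(peakset.centers[j] - center) <= tolerance_da
            else None
        )
    return ids


@pytest.fixture(scope="session")
def small_pipeline():
    """One fully processed small synthetic cohort, shared across tests."""
    config = small_sim_config()
    cohort, truth, prep, peakset, features = cohort_features(config)
    return {
        "config": config,
        "cohort": cohort,
        "truth": truth,
        "prep": prep,
        "peakset": peakset,
        "features": features,
    }
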