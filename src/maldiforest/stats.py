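"""Univariate screening: Wilcoxon rank-sum tests, fold changes, tiers.

Each feature (a detected peak, or a column of an external concentration
table such as an ELISA/MRM panel) is tested case vs control with the
two-tailed Wilcoxon rank-sum (Mann-Whitney) test and summarized by its
fold change, defined as the ratio of the case-group mean to the
control-group mean (FC < 1: downregulated, FC > 1: upregulated).

Significance tiers follow the common screening convention: p <= 0.05 is
"significant", 0.05 < p <= 0.1 a "trend", anything larger "ns".  Raw
p-values drive the tiers; a Benjamini-Hochberg adjusted column is emitted
alongside as supplementary output only.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .peaks import FeatureMatrix
from .preprocess import CASE, CONTROL

EXACT_MAX_GROUP = 8  # exact enumeration when min group size <= this and no ties

SIGNIFICANT_P = 0.05
TREND_P = 0.10


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def wilcoxon_two_sided(x, y, mode: str = "auto") -> float:
    """Two-tailed Wilcoxon rank-sum p-value for two independent samples.

    ``mode='auto'`` uses exact enumeration when the smaller group has at
    most 8 observations and the pooled values are tie-free, and otherwise
    the normal approximation with midranks, tie correction and continuity
    correction.  When the rank-sum statistic sits exactly at its null
    expectation the two-sided p is 1 by symmetry.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError("mode must be 'auto', 'exact' or 'asymptotic'")
    ties = _has_ties(x, y)
    if mode == "exact" and ties:
        raise ValueError("exact mode is undefined in the presence of ties")
    if mode == "auto":
        mode = "exact" if (min(x.size, y.size) <= EXACT_MAX_GROUP and not ties) else "asymptotic"
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # constant pooled values carry no rank information
    result = mannwhitneyu(
        x, y, alternative="two-sided", method=mode, use_continuity=True
    )
    u = float(result.statistic)
    if mode == "asymptotic" and np.isclose(u, x.size * y.size / 2.0):
        return 1.0
    return float(min(result.pvalue, 1.0))


def fold_change(case_values, control_values) -> float:
    """Ratio of case-group mean to control-group mean."""
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size == 0 or control_values.size == 0:
        raise ValueError("both groups must be non-empty")
    control_mean = control_values.mean()
    if control_mean <= 0:
        raise ValueError(
            f"fold change undefined: control mean is non-positive ({control_mean})"
        )
    return float(case_values.mean() / control_mean)


def _tier(p: float) -> str:
    if p <= SIGNIFICANT_P:
        return "significant"
    if p <= TREND_P:
        return "trend"
    return "ns"


def _direction(fc: float) -> str:
    if fc > 1.0:
        return "up"
    if fc < 1.0:
        return "down"
    return "flat"


def univariate_table(
    features: FeatureMatrix | pd.DataFrame,
    labels: np.ndarray | None = None,
    mode: str = "auto",
) -> pd.DataFrame:
    """Per-feature Wilcoxon p-value, fold change, direction and tier.

    Accepts either the pipeline's :class:`FeatureMatrix` or a wide table
    (rows = samples, columns = analytes) with ``labels`` given separately
    or as a ``label`` column.  Constant columns get p = 1.0 with a warning
    rather than an error.  The ``p_bh`` column (Benjamini-Hochberg) is
    supplementary; tiers are assigned on the raw p-values.
    """
    if isinstance(features, FeatureMatrix):
        frame = pd.DataFrame(features.values, columns=features.peak_ids)
        label_arr = np.asarray(features.labels)
    else:
        frame = features.copy()
        if labels is None:
            if "label" not in frame.columns:
                raise ValueError("need labels: pass them or include a 'label' column")
            label_arr = frame.pop("label").to_numpy()
        else:
            label_arr = np.asarray(labels)
    is_case = label_arr == CASE
    is_control = label_arr == CONTROL
    if is_case.sum() < 2 or is_control.sum() < 2:
        raise ValueError("need at least two samples per class")

    rows = []
    for column in frame.columns:
        values = frame[column].to_numpy(dtype=float)
        x, y = values[is_case], values[is_control]
        if np.ptp(values) == 0:
            warnings.warn(f"feature {column!r} is constant; p set to 1.0")
            p = 1.0
        else:
            p = wilcoxon_two_sided(x, y, mode=mode)
        fc = fold_change(x, y) if y.mean() > 0 else np.nan
        rows.append((str(column), p, fc))
    table = pd.DataFrame(rows, columns=["feature", "p_value", "fold_change"])
    table["direction"] = [
        _direction(fc) if np.isfinite(fc) else "flat" for fc in table["fold_change"]
    ]
    table["tier"] = [_tier(p) for p in table["p_value"]]
    table["p_bh"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    return table


def read_concentration_table(path: str | Path, label_column: str = "label") -> pd.DataFrame:
    """Read a wide per-sample concentration CSV (e.g. an MRM ng/ml table).

    Rows are samples, columns analytes, plus a case/control label column;
    the label column is renamed to ``label`` for :func:`univariate_table`.
    """
    frame = pd.read_csv(path, index_col=0)
    if label_column not in frame.columns:
        raise ValueError(f"{path}: no label column {label_column!r}")
    frame = frame.rename(columns={label_column: "label"})
    bad = set(frame["label"]) - {CASE, CONTROL}
    if bad:
        raise ValueError(f"{path}: unknown labels {sorted(bad)}")
    return frame
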