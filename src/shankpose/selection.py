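"""Feature scaling and pruning of quasi-constant and correlated columns.

The pruning pipeline follows the order: min-max scale each feature to
[0, 1], drop quasi-constant columns (variance below 0.01 on the scaled
values), then drop strongly correlated columns (|Pearson r| above 0.8)
by a greedy left-to-right scan in the fixed feature-registry order — a
column is removed iff it correlates too strongly with any earlier
retained column, so the survivor of a correlated pair is always the one
appearing first in the registry.  The fitted scaling parameters and drop
lists form a ``SelectionReport`` that can be re-applied to held-out
data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ValidationError, feature_columns

DEFAULT_R_THRESHOLD = 0.8
DEFAULT_VAR_THRESHOLD = 0.01


@dataclass
class SelectionReport:
    """Everything needed to replay a fitted scaling + pruning on new data."""

    feature_min: dict[str, float] = field(default_factory=dict)
    feature_max: dict[str, float] = field(default_factory=dict)
    dropped_quasi_constant: list[str] = field(default_factory=list)
    dropped_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    r_threshold: float = DEFAULT_R_THRESHOLD
    var_threshold: float = DEFAULT_VAR_THRESHOLD

    @property
    def dropped(self) -> list[str]:
        return self.dropped_quasi_constant + [d for _, d, _ in self.dropped_correlated]

    def to_dict(self) -> dict:
        return {
            "feature_min": self.feature_min,
            "feature_max": self.feature_max,
            "dropped_quasi_constant": self.dropped_quasi_constant,
            "dropped_correlated": [list(t) for t in self.dropped_correlated],
            "retained": self.retained,
            "r_threshold": self.r_threshold,
            "var_threshold": self.var_threshold,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionReport":
        return cls(
            feature_min=d["feature_min"],
            feature_max=d["feature_max"],
            dropped_quasi_constant=list(d["dropped_quasi_constant"]),
            dropped_correlated=[
                (a, b, float(r)) for a, b, r in d["dropped_correlated"]
            ],
            retained=list(d["retained"]),
            r_threshold=d["r_threshold"],
            var_threshold=d["var_threshold"],
        )

    @classmethod
    def from_json(cls, path) -> "SelectionReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _split(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    feats = feature_columns(matrix)
    meta = [c for c in matrix.columns if c not in feats]
    return matrix[feats], matrix[meta]


def minmax_scale(matrix: pd.DataFrame) -> tuple[pd.DataFrame, SelectionReport]:
    """Map each feature column to [0, 1]; constant columns map to 0."""
    feats, meta = _split(matrix)
    if len(feats) < 2:
        raise ValidationError("min-max scaling needs at least 2 rows")
    values = feats.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite value in feature matrix")
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    rng = hi - lo
    scaled = np.where(rng > 0, (values - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    report = SelectionReport(
        feature_min=dict(zip(feats.columns, lo.tolist())),
        feature_max=dict(zip(feats.columns, hi.tolist())),
        retained=list(feats.columns),
    )
    out = pd.DataFrame(scaled, columns=feats.columns, index=matrix.index)
    return pd.concat([out, meta], axis=1), report


def drop_quasi_constant(
    matrix: pd.DataFrame, var_threshold: float = DEFAULT_VAR_THRESHOLD
) -> tuple[pd.DataFrame, list[str]]:
    """Remove scaled columns whose population variance falls below threshold."""
    feats, meta = _split(matrix)
    variances = feats.to_numpy(dtype=float).var(axis=0)
    dropped = [c for c, v in zip(feats.columns, variances) if v < var_threshold]
    kept = [c for c in feats.columns if c not in dropped]
    return pd.concat([feats[kept], meta], axis=1), dropped


def drop_correlated(
    matrix: pd.DataFrame, r_threshold: float = DEFAULT_R_THRESHOLD
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Greedy left-to-right removal of strongly correlated columns.

    Returns the reduced matrix and the (kept, dropped, r) record of each
    removal.  Zero-variance columns correlate with nothing (r taken as 0).
    """
    feats, meta = _split(matrix)
    values = feats.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValidationError("correlation pruning needs at least 2 rows")
    cols = list(feats.columns)
    centered = values - values.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    retained_idx: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for j in range(len(cols)):
        culprit = None
        for i in retained_idx:
            if norms[i] == 0 or norms[j] == 0:
                continue
            r = float(centered[:, i] @ centered[:, j] / (norms[i] * norms[j]))
            if abs(r) > r_threshold:
                culprit = (cols[i], cols[j], r)
                break
        if culprit is None:
            retained_idx.append(j)
        else:
            dropped.append(culprit)
    kept = [cols[i] for i in retained_idx]
    return pd.concat([feats[kept], meta], axis=1), dropped


def fit_selection(
    matrix: pd.DataFrame,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    var_threshold: float = DEFAULT_VAR_THRESHOLD,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Scale, then prune quasi-constant and correlated features.

    The full fitted pipeline is captured in the returned report so it can
    be replayed on held-out data with :func:`apply_selection`.
    """
    scaled, report = minmax_scale(matrix)
    report.r_threshold = r_threshold
    report.var_threshold = var_threshold
    reduced, qc = drop_quasi_constant(scaled, var_threshold)
    report.dropped_quasi_constant = qc
    reduced, corr = drop_correlated(reduced, r_threshold)
    report.dropped_correlated = corr
    report.retained = feature_columns(reduced)
    return reduced, report


def apply_selection(matrix: pd.DataFrame, report: SelectionReport) -> pd.DataFrame:
    """Replay a fitted scaling + pruning on a new matrix.

    Values outside the training min/max are clipped into [0, 1].
    """
    feats, meta = _split(matrix)
    missing = [c for c in report.retained if c not in feats.columns]
    if missing:
        raise ValidationError(f"matrix is missing feature column(s) {missing}")
    out = {}
    for c in report.retained:
        lo, hi = report.feature_min[c], report.feature_max[c]
        v = feats[c].to_numpy(dtype=float)
        scaled = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
        out[c] = np.clip(scaled, 0.0, 1.0)
    reduced = pd.DataFrame(out, index=matrix.index)
    return pd.concat([reduced, meta], axis=1)
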