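"""Quantile normalization and detection filtering of expression matrices.

Quantile normalization forces every sample (column) to share the same value
distribution: each order statistic is replaced by the across-sample mean of
that order statistic. Detection filtering keeps probes whose intensity
strictly exceeds a threshold in at least one sample; the threshold is either
supplied or suggested as a percentile of the pooled intensity distribution
(mirroring the usual by-inspection choice on the pooled log-intensity
histogram, which is also written to the log).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import InputError

logger = logging.getLogger(__name__)


def quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a probes x samples DataFrame.

    Ties within a column receive the mean of the target values over their tied
    rank span, which keeps the transform idempotent on tie-free data and
    deterministic on ties.
    """
    if df.isna().any().any():
        raise InputError("cannot quantile-normalize a matrix with missing values")
    X = df.to_numpy(dtype=float)
    if X.size == 0:
        return df.copy()
    target = np.sort(X, axis=0).mean(axis=1)  # mean of order statistics
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(col)
        mapped[order] = target
        tied = pd.DataFrame({"v": col, "t": mapped})
        out[:, j] = tied.groupby("v", sort=False)["t"].transform("mean").to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize an :class:`ExpressionMatrix`; labels are unchanged."""
    return ExpressionMatrix(
        values=quantile_normalize_frame(matrix.values),
        genes=matrix.genes.copy(),
        groups=matrix.groups.copy(),
    )


@dataclass
class DetectionResult:
    """Outcome of the detection call at a given threshold."""

    threshold: float
    detected_mask: pd.Series  # bool per probe
    matrix: ExpressionMatrix  # detected probes only, order preserved

    @property
    def n_detected(self) -> int:
        return int(self.detected_mask.sum())


def detect_probes(matrix: ExpressionMatrix, threshold: float) -> DetectionResult:
    """Call probes detected when their intensity strictly exceeds ``threshold``
    in at least one sample.

    ``threshold=-inf`` keeps every probe. The detected set is monotone
    non-increasing in the threshold.
    """
    if np.isnan(threshold):
        raise InputError("detection threshold must be a number or -inf, got NaN")
    mask = (matrix.values.max(axis=1) > threshold).rename("detected")
    logger.info(
        "detection call at threshold %.4g: %d of %d probes detected",
        threshold, int(mask.sum()), matrix.n_probes,
    )
    return DetectionResult(threshold=threshold, detected_mask=mask, matrix=matrix.subset_probes(mask))


def suggest_threshold(matrix: ExpressionMatrix, percentile: float = 20.0) -> float:
    """Suggest a detection threshold as a percentile of the pooled intensities.

    Uses linear interpolation between closest order statistics (the common
    spreadsheet convention). A text histogram of the pooled log-intensity
    distribution is written to the log so the choice can be inspected.
    """
    if not 0.0 <= percentile <= 100.0:
        raise InputError(f"percentile must lie in [0, 100], got {percentile}")
    pooled = matrix.values.to_numpy(dtype=float).ravel()
    if pooled.size == 0:
        raise InputError("cannot suggest a threshold for an empty matrix")
    value = float(np.percentile(pooled, percentile))
    for line in _text_histogram(pooled, value):
        logger.info("%s", line)
    return value


def _text_histogram(pooled: np.ndarray, threshold: float, bins: int = 30, width: int = 50) -> list[str]:
    counts, edges = np.histogram(pooled, bins=bins)
    peak = max(int(counts.max()), 1)
    lines = ["pooled log2-intensity distribution (* marks the suggested threshold bin):"]
    for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
        bar = "#" * max(1 if c else 0, round(width * c / peak))
        mark = "*" if lo <= threshold <= hi else " "
        lines.append(f"{mark}[{lo:8.3f}, {hi:8.3f}) {bar} {c}")
    return lines
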