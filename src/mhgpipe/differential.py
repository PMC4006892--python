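"""SAM-style two-class differential statistics with permutation FDR.

The moderated statistic is the two-class unpaired Tusher statistic

    d_i = (mean_treated_i - mean_control_i) / (s_i + s0)

with s_i the pooled standard error

    s_i = sqrt[(1/n1 + 1/n2) * (SS1_i + SS2_i) / (n1 + n2 - 2)]

and s0 the "exchangeability factor": a percentile (default 75) of the
per-probe scatter values s_i, added to every denominator so that probes with
accidentally tiny variance do not dominate the ranking.

Significance is assessed by permuting group labels. For a grid of thresholds
delta, the called set is {probes with |d| >= delta}; the estimated FDR at
delta is the median over permutations of the number of permuted statistics
exceeding delta, divided by the number of called probes. A probe's q-value is
the smallest FDR over thresholds at which the probe is called; probes are
ranked by q ascending. Per-probe permutation p-values pool the permuted null
statistics over all probes with add-one smoothing.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import ConfigError, DesignError

logger = logging.getLogger(__name__)

#: enumerate all balanced relabelings instead of sampling when their number
#: does not exceed this
EXHAUSTIVE_LIMIT = 2000


@dataclass
class SamConfig:
    """Settings for the SAM-style analysis."""

    s0_percentile: float = 75.0
    n_permutations: int | str = 1000  # count, or "all" for exhaustive enumeration
    seed: int = 0
    delta_grid: np.ndarray | None = None  # default: 50 values from 0 to max|d|
    n_delta: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.s0_percentile <= 100.0:
            raise ConfigError(f"s0_percentile must lie in [0, 100], got {self.s0_percentile}")
        if self.n_permutations != "all":
            if not isinstance(self.n_permutations, (int, np.integer)) or self.n_permutations < 1:
                raise ConfigError(f"n_permutations must be a positive count or 'all', got {self.n_permutations!r}")


def compute_s0(scatter_values: np.ndarray | pd.Series, percentile: float = 75.0) -> float:
    """Percentile of the per-probe scatter values, with linear interpolation."""
    s = np.asarray(scatter_values, dtype=float)
    if s.size == 0:
        raise ConfigError("cannot compute s0 from an empty scatter vector")
    if (s < 0).any():
        raise ConfigError("scatter values must be non-negative")
    if not 0.0 <= percentile <= 100.0:
        raise ConfigError(f"s0 percentile must lie in [0, 100], got {percentile}")
    return float(np.percentile(s, percentile))


def _group_arrays(matrix: ExpressionMatrix, control: str | None, treated: str | None):
    control, treated = matrix.two_groups(control, treated)
    X1 = matrix.group_values(control)
    X2 = matrix.group_values(treated)
    for name, X in ((control, X1), (treated, X2)):
        if X.shape[1] < 2:
            raise DesignError(f"group {name!r} has {X.shape[1]} sample(s); need at least 2")
    return control, treated, X1, X2


def _tusher_d(X1: np.ndarray, X2: np.ndarray, s0: float):
    n1, n2 = X1.shape[1], X2.shape[1]
    m1 = X1.mean(axis=1)
    m2 = X2.mean(axis=1)
    ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + ((X2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (m2 - m1) / (s + s0)
    d[np.isnan(d)] = 0.0  # 0/0 when a probe is constant and s0 == 0
    return d, s


def sam_d(
    matrix: ExpressionMatrix,
    s0: float,
    control: str | None = None,
    treated: str | None = None,
) -> pd.DataFrame:
    """Per-probe Tusher statistic ``d`` and pooled scatter ``s``."""
    _, _, X1, X2 = _group_arrays(matrix, control, treated)
    d, s = _tusher_d(X1, X2, s0)
    return pd.DataFrame({"d": d, "s": s}, index=matrix.values.index)


def _relabelings(n: int, n1: int, config: SamConfig) -> np.ndarray:
    """Indices assigned to the first group, one row per relabeling.

    Enumerates all C(n, n1) balanced relabelings when requested or when their
    count is small; otherwise samples label permutations at the configured
    seed.
    """
    total = math.comb(n, n1)
    if config.n_permutations == "all" or total <= EXHAUSTIVE_LIMIT:
        return np.array(list(itertools.combinations(range(n), n1)), dtype=int)
    rng = np.random.default_rng(config.seed)
    out = np.empty((int(config.n_permutations), n1), dtype=int)
    for b in range(out.shape[0]):
        out[b] = rng.permutation(n)[:n1]
    return out


def permutation_fdr(
    matrix: ExpressionMatrix,
    s0: float,
    config: SamConfig,
    control: str | None = None,
    treated: str | None = None,
) -> pd.DataFrame:
    """Per-probe permutation p-values and q-values.

    Returns a DataFrame with columns ``p_perm`` and ``q`` indexed like the
    matrix. ``q`` is monotone non-decreasing in decreasing |d| by
    construction (minimum over the delta grid up to each probe's |d|).
    """
    control_name, treated_name, X1, X2 = _group_arrays(matrix, control, treated)
    cols1 = list(matrix.groups.index[matrix.groups == control_name])
    cols2 = list(matrix.groups.index[matrix.groups == treated_name])
    X = matrix.values[cols1 + cols2].to_numpy(dtype=float)
    n1, n2 = len(cols1), len(cols2)
    d_obs, _ = _tusher_d(X[:, :n1], X[:, n1:], s0)
    abs_d = np.abs(d_obs)

    labelings = _relabelings(n1 + n2, n1, config)
    B = labelings.shape[0]
    logger.info("permutation null: %d relabelings (%s)", B,
                "exhaustive" if config.n_permutations == "all" or B == math.comb(n1 + n2, n1)
                else "sampled")
    all_idx = np.arange(n1 + n2)
    abs_dstar = np.empty((B, X.shape[0]))
    for b, g1 in enumerate(labelings):
        g2 = np.setdiff1d(all_idx, g1, assume_unique=True)
        db, _ = _tusher_d(X[:, g1], X[:, g2], s0)
        abs_dstar[b] = np.abs(db)

    # pooled permutation p-values, add-one smoothed
    pooled = np.sort(abs_dstar, axis=None)
    n_pool = pooled.size
    exceed = n_pool - np.searchsorted(pooled, abs_d, side="left")
    p_perm = (exceed + 1.0) / (n_pool + 1.0)

    # median-based FDR over a delta grid; q = min FDR over deltas at which
    # the probe is called
    if config.delta_grid is not None:
        deltas = np.sort(np.asarray(config.delta_grid, dtype=float))
        if (deltas < 0).any():
            raise ConfigError("delta_grid thresholds must be non-negative")
    else:
        deltas = np.linspace(0.0, abs_d.max() if abs_d.size else 0.0, config.n_delta)
    n_called = (abs_d[None, :] >= deltas[:, None]).sum(axis=1)
    false_counts = np.empty((B, deltas.size))
    sorted_rows = np.sort(abs_dstar, axis=1)
    for b in range(B):
        false_counts[b] = abs_dstar.shape[1] - np.searchsorted(sorted_rows[b], deltas, side="left")
    median_false = np.median(false_counts, axis=0)
    fdr = np.minimum(1.0, median_false / np.maximum(1, n_called))
    prefix_min = np.minimum.accumulate(fdr)
    idx = np.searchsorted(deltas, abs_d, side="right") - 1
    idx = np.clip(idx, 0, len(deltas) - 1)
    q = prefix_min[idx]
    return pd.DataFrame({"p_perm": p_perm, "q": q}, index=matrix.values.index)


def fold_changes(
    matrix: ExpressionMatrix,
    control: str | None = None,
    treated: str | None = None,
) -> pd.DataFrame:
    """Per-probe treated/control ratio on the anti-log scale.

    ``fold_change`` is 2**(mean log2 treated - mean log2 control); the
    ``direction`` flag is "down" when the ratio is below 1, else "up".
    """
    _, _, X1, X2 = _group_arrays(matrix, control, treated)
    ratio = np.exp2(X2.mean(axis=1) - X1.mean(axis=1))
    return pd.DataFrame(
        {"fold_change": ratio, "direction": np.where(ratio < 1.0, "down", "up")},
        index=matrix.values.index,
    )


def differential_table(
    matrix: ExpressionMatrix,
    config: SamConfig | None = None,
    control: str | None = None,
    treated: str | None = None,
) -> pd.DataFrame:
    """Full per-probe differential table, sorted by q ascending.

    Columns: gene, d, s, fold_change, direction, p_perm, q; index: probe id.
    Ties in q are broken by |d| descending, then probe id.
    """
    config = config or SamConfig()
    ds = sam_d(matrix, 0.0, control, treated)  # scatter is s0-independent
    s0 = compute_s0(ds["s"], config.s0_percentile)
    ds = sam_d(matrix, s0, control, treated)
    fc = fold_changes(matrix, control, treated)
    pq = permutation_fdr(matrix, s0, config, control, treated)
    table = pd.concat([matrix.genes.rename("gene"), ds, fc, pq], axis=1)
    table.attrs["s0"] = s0
    return sort_by_q(table)


def sort_by_q(table: pd.DataFrame) -> pd.DataFrame:
    """Sort by q ascending, |d| descending, probe id lexicographic."""
    key = pd.DataFrame(
        {"q": table["q"], "neg_abs_d": -table["d"].abs(), "probe": table.index},
        index=table.index,
    )
    order = key.sort_values(["q", "neg_abs_d", "probe"], kind="mergesort").index
    return table.loc[order]


def filter_de(table: pd.DataFrame, min_fold: float = 1.2, max_p: float = 0.05) -> pd.DataFrame:
    """Keep probes altered at least ``min_fold`` in either direction with a
    permutation p-value at most ``max_p``; both bounds inclusive, order kept."""
    if table.empty:
        return table.copy()
    ratio = table["fold_change"].to_numpy(dtype=float)
    magnitude = np.maximum(ratio, 1.0 / ratio)
    keep = (magnitude >= min_fold) & (table["p_perm"].to_numpy(dtype=float) <= max_p)
    return table.loc[keep]
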