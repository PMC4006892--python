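"""Relative quantification of qPCR data by the comparative-Ct (ddCt) method.

Per sample, dCt = Ct(target) - Ct(reference endogenous control, default
GAPDH). Per target, ddCt = mean dCt(treated) - mean dCt(control) and the
relative quantity is RQ = 2**-ddCt, assuming perfect doubling per cycle.
Group differences are tested with a classical two-sided, equal-variance
Student t-test on the per-sample dCt values; dispersion is summarized as the
standard error of the mean of per-sample relative quantities (RQ scale,
anchored at the control-group mean dCt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, InputError

REQUIRED_COLUMNS = ("sample_id", "group", "target", "ct")

DEFAULT_REFERENCE = "GAPDH"


@dataclass
class QpcrResult:
    """ddCt quantification of one target against a reference gene."""

    target: str
    reference: str
    ddct: float
    rq: float
    sem_control: float
    sem_treated: float
    p_value: float
    dct_control: np.ndarray
    dct_treated: np.ndarray
    #: scale on which the SEMs are computed (output metadata)
    sem_scale: str = "rq"

    @property
    def change_text(self) -> str:
        return report_change(self.rq)


def _delta_ct(table: pd.DataFrame, target: str, reference: str) -> pd.DataFrame:
    """Per-sample dCt with group labels; errors name samples lacking wells."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise InputError(f"qPCR table lacks required column {col!r}")
    tgt = table[table["target"] == target].set_index("sample_id")
    ref = table[table["target"] == reference].set_index("sample_id")
    if tgt.empty:
        raise InputError(f"no wells for target {target!r}")
    missing = tgt.index.difference(ref.index)
    if len(missing):
        raise InputError(
            f"samples missing reference ({reference}) wells: {sorted(missing)}"
        )
    out = pd.DataFrame(
        {
            "group": tgt["group"],
            "dct": tgt["ct"].astype(float) - ref.loc[tgt.index, "ct"].astype(float),
        }
    )
    return out


def relative_quantity(
    table: pd.DataFrame,
    target: str,
    reference: str = DEFAULT_REFERENCE,
    control: str | None = None,
    treated: str | None = None,
) -> QpcrResult:
    """ddCt, RQ = 2**-ddCt, per-group SEMs and the Student t-test p-value.

    Group labels default to order of first appearance in the table
    (first = control).
    """
    dct = _delta_ct(table, target, reference)
    groups = list(dict.fromkeys(dct["group"]))
    if control is None and treated is None:
        if len(groups) != 2:
            raise DesignError(f"expected exactly two groups, found {groups}")
        control, treated = groups
    if control not in groups or treated not in groups:
        raise DesignError(f"groups {control!r}/{treated!r} not both present in {groups}")
    dct_c = dct.loc[dct["group"] == control, "dct"].to_numpy(dtype=float)
    dct_t = dct.loc[dct["group"] == treated, "dct"].to_numpy(dtype=float)
    if len(dct_c) < 2 or len(dct_t) < 2:
        raise DesignError(
            f"need >=2 samples per group for target {target!r}; "
            f"got {len(dct_c)} control, {len(dct_t)} treated"
        )
    ddct = float(dct_t.mean() - dct_c.mean())
    rq = float(2.0 ** -ddct)
    # per-sample relative quantities anchored at the control-group mean dCt
    rq_c = 2.0 ** -(dct_c - dct_c.mean())
    rq_t = 2.0 ** -(dct_t - dct_c.mean())
    if np.ptp(dct_c) == 0 and np.ptp(dct_t) == 0:
        p = 1.0 if ddct == 0 else 0.0  # degenerate noise-free input
    else:
        p = float(stats.ttest_ind(dct_t, dct_c, equal_var=True).pvalue)
    return QpcrResult(
        target=target,
        reference=reference,
        ddct=ddct,
        rq=rq,
        sem_control=float(stats.sem(rq_c)),
        sem_treated=float(stats.sem(rq_t)),
        p_value=p,
        dct_control=dct_c,
        dct_treated=dct_t,
    )


def report_change(rq: float) -> str:
    """Render a relative quantity with the mixed percent/fold convention
    used in expression figure legends.

    RQ < 1: percent decrease; 1 <= RQ < 2: percent increase; RQ >= 2:
    fold increase. RQ = 1 reads "0% change".
    """
    if not np.isfinite(rq) or rq <= 0:
        raise InputError(f"relative quantity must be positive, got {rq}")
    if rq == 1.0:
        return "0% change"
    if rq < 1.0:
        return f"{_fmt((1.0 - rq) * 100.0)}% decrease"
    if rq < 2.0:
        return f"{_fmt((rq - 1.0) * 100.0)}% increase"
    return f"{_fmt(rq)} fold increase"


def _fmt(x: float) -> str:
    """Up to three significant digits, trailing zeros trimmed (69.3, 50, 6.06)."""
    return f"{x:.3g}"


def quantify_all(
    table: pd.DataFrame,
    reference: str = DEFAULT_REFERENCE,
    control: str | None = None,
    treated: str | None = None,
) -> pd.DataFrame:
    """Quantify every non-reference target in the table; one row per target."""
    targets = [t for t in dict.fromkeys(table["target"]) if t != reference]
    rows = []
    for t in targets:
        res = relative_quantity(table, t, reference, control, treated)
        rows.append(
            {
                "target": t,
                "ddct": res.ddct,
                "rq": res.rq,
                "change_text": res.change_text,
                "sem_control": res.sem_control,
                "sem_treated": res.sem_treated,
                "sem_scale": res.sem_scale,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("target")
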