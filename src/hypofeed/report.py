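"""Percent-activity normalization, food-intake classes, summary statistics.

Because the focus of the analysis is on response *patterns*, unit
responses are expressed as percentages of their maximal responses over
the enumerated reachable set.  Food intake is binned into three classes
of its percent-of-maximum range: low (0-43%), medium (44-80%) and high
(81-100%), the break points of the distribution of food-intake values
the model produces; with real-valued percentages the bands are closed
at 43 and 81.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .statespace import ReachableSet

__all__ = ["FI_LOW", "FI_HIGH", "percent_activity", "classify_fi", "summarize_configurations"]

FI_LOW = 43.0  # inclusive upper edge of the low band
FI_HIGH = 81.0  # inclusive lower edge of the high band


def classify_fi(fi_percent: float) -> str:
    """Food-intake class of a percent-of-maximum value."""
    if not 0.0 <= fi_percent <= 100.0:
        raise ValueError(f"fi_percent must be in [0, 100], got {fi_percent}")
    if fi_percent <= FI_LOW:
        return "low"
    if fi_percent >= FI_HIGH:
        return "high"
    return "medium"


def percent_activity(reachable: ReachableSet, keys=None) -> pd.DataFrame:
    """Configuration table: rows are states, columns percent-of-max responses.

    Column maxima are taken over the *full* reachable set (not only the
    selected rows), so selections remain comparable.  All-zero columns
    are reported as zeros and listed in ``df.attrs["zero_max"]``.  The
    FI column additionally yields an ``fi_class`` column.
    """
    spec = reachable.spec
    all_keys = sorted(reachable.states)
    keys = all_keys if keys is None else list(keys)
    cols = list(spec.elements)
    M = np.array([[float(reachable.states[k].resp[e]) for e in cols] for k in all_keys])
    mx = M.max(axis=0) if len(M) else np.zeros(len(cols))
    zero_max = [c for c, m in zip(cols, mx) if m <= 0]
    denom = np.where(mx > 0, mx, 1.0)
    sel = np.array([[float(reachable.states[k].resp[e]) for e in cols] for k in keys])
    if len(sel) == 0:
        sel = np.empty((0, len(cols)))
    df = pd.DataFrame(100.0 * sel / denom, columns=cols)
    df.insert(0, "state", [str(k) for k in keys])
    if spec.fi_element is not None:
        df["fi_class"] = [classify_fi(v) for v in df[spec.fi_element]] if len(df) else []
    df.attrs["zero_max"] = zero_max
    return df


def summarize_configurations(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise mean/median/IQR/range over a configuration table
    (the box-plot summaries of the percent-activity analyses)."""
    cols = [c for c in table.columns if c not in ("state", "fi_class")]
    if len(table) == 0:
        raise ValueError("empty configuration table")
    out = {}
    for c in cols:
        v = table[c].to_numpy(dtype=float)
        q1, q3 = np.percentile(v, [25, 75])
        out[c] = {
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "iqr_low": float(q1),
            "iqr_high": float(q3),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
        }
    return pd.DataFrame(out).T[["mean", "median", "iqr_low", "iqr_high", "min", "max"]]
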