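"""Dual-luciferase reporter normalization and two-group testing.

In a dual-luciferase assay the test construct drives Renilla luciferase and
a co-transfected Firefly luciferase serves as transfection-efficiency
control, so the per-well readout is the Renilla/Firefly ratio.  Ratios are
then expressed relative to the mean ratio of a designated empty-vector
control construct, whose mean relative activity is therefore 1 by
construction.  Group comparisons use a two-tailed unpaired t-test
(Student's pooled-variance by default; Welch via ``equal_var=False``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

LUCIFERASE_COLUMNS = ("construct_id", "replicate", "renilla", "firefly")


def relative_luciferase(t: pd.DataFrame, control_id: str) -> pd.DataFrame:
    """Per-well relative luciferase activities, normalized to a control.

    Parameters
    ----------
    t : DataFrame
        Well table with columns construct_id, replicate, renilla, firefly.
    control_id : str
        Construct whose mean Renilla/Firefly ratio anchors the scale.

    Returns the input with two added columns: ``ratio`` (renilla/firefly per
    well) and ``relative_activity`` (ratio divided by the control mean ratio).
    """
    missing = set(LUCIFERASE_COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"luciferase table missing columns: {sorted(missing)}")
    if (t["renilla"] <= 0).any() or (t["firefly"] <= 0).any():
        raise ValueError("luciferase readings must be positive")
    if control_id not in set(t["construct_id"]):
        raise ValueError(f"control construct {control_id!r} not in table")
    out = t.copy()
    out["ratio"] = out["renilla"] / out["firefly"]
    control_mean = out.loc[out["construct_id"] == control_id, "ratio"].mean()
    out["relative_activity"] = out["ratio"] / control_mean
    return out


def unpaired_t_test(
    x, y, equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-tailed unpaired t-test: returns ``(t, df, p)``.

    Student's pooled-variance test by default (df = n_x + n_y - 2); set
    ``equal_var=False`` for Welch's test with Satterthwaite df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_constructs_to_control(
    rel: pd.DataFrame, control_id: str, equal_var: bool = True
) -> pd.DataFrame:
    """t-test every non-control construct's relative activity vs the control."""
    ctl = rel.loc[rel["construct_id"] == control_id, "relative_activity"]
    rows = []
    for cid, grp in rel.groupby("construct_id", sort=True):
        if cid == control_id:
            continue
        t, df, p = unpaired_t_test(
            grp["relative_activity"], ctl, equal_var=equal_var
        )
        rows.append(
            {
                "construct_id": cid,
                "mean_relative_activity": grp["relative_activity"].mean(),
                "t": t,
                "df": df,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
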