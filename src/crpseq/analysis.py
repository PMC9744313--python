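"""Descriptive and model-based diagnostics of trial streams and RTs.

All statistics run identically on measured and model-predicted RTs, so the
same code path produces both sides of a calibration comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .asrt import NA_LABEL, Pattern

ERROR_TYPES = ("pattern", "recency", "other")


def classify_error(
    t: int,
    events: np.ndarray,
    keys: np.ndarray,
    pattern: Pattern,
) -> str:
    """Categorize the incorrect response at 0-based index ``t``.

    ``pattern``: the pressed key is the pattern successor of the event two
    trials back.  ``recency`` (only if not a pattern error): the two-element
    context ``(e_{t-2}, e_{t-1})`` occurred before, and the key repeats the
    response given at its most recent occurrence.  Anything else: ``other``.
    Raises if called on a correct response or with fewer than two context
    trials.
    """
    events = np.asarray(events, dtype=int)
    keys = np.asarray(keys, dtype=int)
    if keys[t] == events[t]:
        raise ValueError("classify_error applies to incorrect responses only")
    if t < 2:
        raise ValueError("trigram undefined before the third trial")
    if pattern.successor(int(events[t - 2])) == keys[t]:
        return "pattern"
    ctx = (events[t - 2], events[t - 1])
    for s in range(t - 1, 1, -1):
        if (events[s - 2], events[s - 1]) == ctx:
            return "recency" if keys[s] == keys[t] else "other"
    return "other"


def label_errors(
    df: pd.DataFrame,
    events: np.ndarray,
    keys: np.ndarray,
    patterns: dict[int, Pattern],
    label_col: str = "label_old",
) -> pd.DataFrame:
    """Add an ``error_type`` column for incorrect responses on rL trials.

    ``patterns`` maps session number to the pattern in force there (so the
    interference sessions can be judged against the right rule).  Trials
    outside the scope (correct, non-rL, or early) get ``NA``.
    """
    events = np.asarray(events, dtype=int)
    keys = np.asarray(keys, dtype=int)
    out = np.full(len(df), NA_LABEL, dtype=object)
    labels = df[label_col].to_numpy()
    sessions = df["session"].to_numpy()
    for t in range(2, len(df)):
        if keys[t] == events[t] or labels[t] != "rL":
            continue
        out[t] = classify_error(t, events, keys, patterns[int(sessions[t])])
    df = df.copy()
    df["error_type"] = out
    return df


def trial_type_contrasts(
    df: pd.DataFrame,
    rt_col: str = "rt_ms",
    by: tuple[str, ...] = ("session",),
    label_col: str = "label_old",
) -> pd.DataFrame:
    """Per-bin mean RT by trial type, with the standard contrasts.

    Returns one row per group with columns ``mean_d, mean_rH, mean_rL,
    d_minus_r, rH_minus_rL`` (NaN where a category is empty) and, when an
    ``overlap`` column is present, the interference contrasts
    ``H_old_minus_L`` and ``H_new_minus_L`` (non-overlapping H vs L-both).
    """
    work = df[df[label_col] != NA_LABEL]
    rows = []
    for key, grp in work.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        means = grp.groupby(label_col)[rt_col].mean()
        m_d = means.get("d", np.nan)
        m_h = means.get("rH", np.nan)
        m_l = means.get("rL", np.nan)
        m_r = grp.loc[grp[label_col].isin(["rH", "rL"]), rt_col].mean()
        row = dict(zip(by, key))
        row.update(
            {
                "n": len(grp),
                "mean_d": m_d,
                "mean_rH": m_h,
                "mean_rL": m_l,
                "d_minus_r": m_d - m_r,
                "rH_minus_rL": m_h - m_l,
            }
        )
        if "overlap" in grp.columns:
            om = grp.groupby("overlap")[rt_col].mean()
            l_both = om.get("L_both", np.nan)
            row["H_old_minus_L"] = om.get("H_old_only", np.nan) - l_both
            row["H_new_minus_L"] = om.get("H_new_only", np.nan) - l_both
        rows.append(row)
    return pd.DataFrame(rows)


def higher_order_effect(
    df: pd.DataFrame,
    rt_col: str = "rt_ms",
    by: tuple[str, ...] = ("session",),
    label_col: str = "label_old",
) -> pd.DataFrame:
    """Standardized rH - d RT difference per bin (the (>2)-order effect).

    RTs are z-scored within each group before averaging; positive values
    mean d trials were faster (deeper-than-trigram knowledge), negative
    values mean rH trials were faster (recency advantage).
    """
    rows = []
    for key, grp in df.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        z = (grp[rt_col] - grp[rt_col].mean()) / grp[rt_col].std(ddof=0)
        lab = grp[label_col]
        zh = z[lab == "rH"]
        zd = z[lab == "d"]
        rows.append(
            dict(zip(by, key))
            | {"effect": zh.mean() - zd.mean(), "n_rH": len(zh), "n_d": len(zd)}
        )
    return pd.DataFrame(rows)


def error_rt_contrasts(df: pd.DataFrame, rt_col: str = "rt_ms") -> dict[str, float]:
    """Mean RT differences between error categories on rL trials.

    Positive ``other_minus_pattern`` / ``other_minus_recency`` mean that
    statistics-driven errors were committed faster than unexplained ones.
    """
    work = df[df["error_type"].isin(ERROR_TYPES)]
    means = work.groupby("error_type")[rt_col].mean()
    populated = [e for e in ERROR_TYPES if e in means.index]
    if len(populated) < 2:
        raise ValueError(f"need at least two populated error categories, got {populated}")
    out = {f"mean_{e}": float(means[e]) for e in populated}
    out["n_errors"] = int(len(work))
    if "other" in means:
        if "pattern" in means:
            out["other_minus_pattern"] = float(means["other"] - means["pattern"])
        if "recency" in means:
            out["other_minus_recency"] = float(means["other"] - means["recency"])
    return out


def correlate(
    left: pd.DataFrame,
    right: pd.DataFrame,
    on: str = "participant",
) -> pd.DataFrame:
    """Pearson correlations between every numeric column pair across tables.

    Joins the two per-participant tables on ``on`` and reports r and p for
    each (left column, right column) pair -- a generic utility for relating
    fitted parameters to external covariates.
    """
    merged = left.merge(right, on=on, suffixes=("_x", "_y"))
    lcols = [c for c in left.columns if c != on and np.issubdtype(left[c].dtype, np.number)]
    rcols = [c for c in right.columns if c != on and np.issubdtype(right[c].dtype, np.number)]
    rows = []
    for lc in lcols:
        for rc in rcols:
            lx = lc + "_x" if lc + "_x" in merged else lc
            ry = rc + "_y" if rc + "_y" in merged else rc
            r, p = pearsonr(merged[lx], merged[ry])
            rows.append({"left": lc, "right": rc, "r": float(r), "p": float(p),
                         "n": len(merged)})
    return pd.DataFrame(rows)
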