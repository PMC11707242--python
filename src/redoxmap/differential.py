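"""Differential screening rules for redox sites (and any feature matrix).

Two rule systems are implemented, mirroring common practice for
multiplexed PTM data with structured missingness:

* Three-group (ages young/middle/old): sites detected in >= 3 samples of
  every group get a one-way ANOVA (raw p < 0.05, no multiplicity
  correction by default); sites that fail the detection requirement fall
  through to a presence/absence rule — differential if undetected in one
  or two groups but detected in at least half the samples of every
  remaining group.

* Two-group (treatment/control): Student's t-test on log2 values with a
  joint cutoff p < alpha AND |log2 fold change| > 0.263 (fold change
  1.2); plus a presence rule for features detected in at least half of
  one group and none of the other.

Trends classify how group medians order with age; "up_in_M"/"down_in_M"
mark features peaking or dipping in the middle group.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

RESULT_COLUMNS = ["rule", "p_value", "statistic", "log2_fc", "trend",
                  "significant", "flag"]


def _group_columns(design: pd.DataFrame | pd.Series,
                   samples: Sequence[str],
                   group_order: Sequence[str] | None) -> tuple[list[str], dict[str, list[str]]]:
    groups = design["group"] if isinstance(design, pd.DataFrame) else design
    missing = [s for s in samples if s not in groups.index]
    if missing:
        raise ValidationError(f"samples not in design: {missing}")
    groups = groups.loc[list(samples)]
    if group_order is None:
        group_order = list(pd.unique(groups))
    by_group = {g: [s for s in samples if groups[s] == g] for g in group_order}
    empty = [g for g, ss in by_group.items() if not ss]
    if empty:
        raise ValidationError(f"group(s) without samples: {empty}")
    return list(group_order), by_group


def classify_trend(medians: Sequence[float]) -> str:
    """Trend label from group medians ordered young, middle, old.

    up_in_M / down_in_M when the middle median is strictly extreme;
    otherwise the old-vs-young comparison decides (ties -> "flat").
    With two medians only, compares last vs first.
    """
    med = [m for m in medians if m is not None and not pd.isna(m)]
    if len(med) < 2:
        raise ValidationError("need at least two group medians for a trend")
    if len(med) >= 3:
        y, m, o = med[0], med[1], med[-1]
        if m > max(y, o):
            return "up_in_M"
        if m < min(y, o):
            return "down_in_M"
    else:
        y, o = med[0], med[-1]
    if o > y:
        return "up_with_age"
    if o < y:
        return "down_with_age"
    return "flat"


def screen_anova(values: pd.DataFrame, design: pd.DataFrame | pd.Series,
                 alpha: float = 0.05, min_n: int = 3,
                 group_order: Sequence[str] | None = None
                 ) -> tuple[pd.DataFrame, pd.Index]:
    """One-way ANOVA over three age groups for adequately detected sites.

    ``values``: site x sample matrix (occupancies or levels). Returns
    (results, leftover) where ``leftover`` indexes the sites that lacked
    >= ``min_n`` detections in some group and should go to the
    presence/absence screen.
    """
    order, by_group = _group_columns(design, values.columns, group_order)
    if len(order) < 3:
        raise ValidationError("need >= 3 groups; use screen_two_group for two")

    counts = pd.DataFrame({g: values[ss].notna().sum(axis=1)
                           for g, ss in by_group.items()})
    testable = (counts >= min_n).all(axis=1)
    rows = []
    for site in values.index[testable]:
        arrays = [values.loc[site, ss].dropna().to_numpy() for ss in by_group.values()]
        if all(np.ptp(a) == 0 for a in arrays) and np.ptp(np.concatenate(arrays)) == 0:
            f, p, flag = 0.0, 1.0, "zero_variance"
        else:
            f, p = stats.f_oneway(*arrays)
            flag = ""
        medians = [np.median(a) for a in arrays]
        rows.append((site, "anova", p, f, np.nan, classify_trend(medians),
                     bool(p < alpha), flag))
    res = pd.DataFrame(rows, columns=["site_id"] + RESULT_COLUMNS).set_index("site_id")
    for g in order:
        res[f"n_{g}"] = counts.loc[res.index, g]
    return res, values.index[~testable]


def screen_presence(values: pd.DataFrame, design: pd.DataFrame | pd.Series,
                    min_frac: float = 0.5,
                    group_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Presence/absence rule for sites that escaped the ANOVA screen.

    Differential iff at least one group has zero detections and every
    group with any detection covers >= ``min_frac`` of its samples. The
    non-empty group pattern assigns the trend (only old -> up_with_age,
    only young -> down_with_age, only middle -> up_in_M, young+old only
    -> down_in_M, ...).
    """
    order, by_group = _group_columns(design, values.columns, group_order)
    counts = pd.DataFrame({g: values[ss].notna().sum(axis=1)
                           for g, ss in by_group.items()})
    sizes = {g: len(ss) for g, ss in by_group.items()}

    rows = []
    for site in values.index:
        c = counts.loc[site]
        nonempty = [g for g in order if c[g] > 0]
        empty = [g for g in order if c[g] == 0]
        if not empty or not nonempty:
            continue
        covered = all(c[g] >= min_frac * sizes[g] for g in nonempty)
        if not covered:
            continue
        trend = _presence_trend(order, nonempty)
        rows.append((site, "presence", np.nan, np.nan, np.nan, trend, True, ""))
    res = pd.DataFrame(rows, columns=["site_id"] + RESULT_COLUMNS).set_index("site_id")
    for g in order:
        res[f"n_{g}"] = counts.loc[res.index, g] if len(res) else pd.Series(dtype=int)
    return res


def _presence_trend(order: Sequence[str], nonempty: Sequence[str]) -> str:
    first, last = order[0], order[-1]
    middle = list(order[1:-1])
    ne = set(nonempty)
    if middle and ne == set(middle):
        return "up_in_M"
    if middle and ne == {first, last}:
        return "down_in_M"
    if last in ne and first not in ne:
        return "up_with_age"
    if first in ne and last not in ne:
        return "down_with_age"
    return "mixed"


def screen_three_group(values: pd.DataFrame, design: pd.DataFrame | pd.Series,
                       alpha: float = 0.05, min_n: int = 3, min_frac: float = 0.5,
                       group_order: Sequence[str] | None = None) -> pd.DataFrame:
    """ANOVA screen plus presence screen on the leftover sites.

    The two rule sets are disjoint by construction: a site either meets
    the per-group detection floor (ANOVA) or it does not (presence
    candidate).
    """
    anova_res, leftover = screen_anova(values, design, alpha, min_n, group_order)
    presence_res = screen_presence(values.loc[leftover], design, min_frac, group_order)
    parts = [r for r in (anova_res, presence_res) if len(r)]
    if not parts:
        return anova_res
    if len(parts) == 1:
        return parts[0]
    return pd.concat(parts, axis=0)


def screen_two_group(values: pd.DataFrame, design: pd.DataFrame | pd.Series,
                     group_a: str, group_b: str,
                     alpha: float = 0.05, min_abs_log2fc: float = 0.263,
                     min_n: int = 3, min_frac: float = 0.5,
                     equal_var: bool = True) -> pd.DataFrame:
    """Two-group screen on log2 values: t-test + fold-change + presence rules.

    ``log2_fc`` is mean(group_b) - mean(group_a) (treatment over
    control). Differential iff p < alpha AND |log2_fc| > min_abs_log2fc
    (both strict); features detected in >= ``min_frac`` of one group and
    none of the other are differential by presence.
    """
    groups = design["group"] if isinstance(design, pd.DataFrame) else design
    a_cols = [s for s in values.columns if groups.get(s) == group_a]
    b_cols = [s for s in values.columns if groups.get(s) == group_b]
    if not a_cols or not b_cols:
        raise ValidationError(f"groups {group_a!r}/{group_b!r} not found in design")

    rows = []
    for site in values.index:
        a = values.loc[site, a_cols].dropna().to_numpy(dtype=float)
        b = values.loc[site, b_cols].dropna().to_numpy(dtype=float)
        na, nb = len(a), len(b)
        if na >= min_n and nb >= min_n:
            lfc = float(b.mean() - a.mean())
            if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
                rows.append((site, "two_group", np.nan, np.nan, lfc, "flat",
                             False, "zero_variance", na, nb))
                continue
            t, p = stats.ttest_ind(b, a, equal_var=equal_var)
            sig = bool(p < alpha and abs(lfc) > min_abs_log2fc)
            trend = "up" if lfc > 0 else ("down" if lfc < 0 else "flat")
            rows.append((site, "two_group", p, t, lfc, trend, sig, "", na, nb))
        elif nb == 0 and na >= min_frac * len(a_cols) and na > 0:
            rows.append((site, "two_group_presence", np.nan, np.nan, np.nan,
                         "down", True, "", na, nb))
        elif na == 0 and nb >= min_frac * len(b_cols) and nb > 0:
            rows.append((site, "two_group_presence", np.nan, np.nan, np.nan,
                         "up", True, "", na, nb))
    return pd.DataFrame(
        rows, columns=["site_id"] + RESULT_COLUMNS + [f"n_{group_a}", f"n_{group_b}"]
    ).set_index("site_id")


def bh_fdr(p_values: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (optional, off by default upstream)."""
    p = p_values.dropna()
    n = len(p)
    order = np.argsort(p.to_numpy())
    ranked = p.to_numpy()[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = pd.Series(np.nan, index=p_values.index)
    out.loc[p.index[order]] = np.clip(adj, 0, 1)
    return out
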