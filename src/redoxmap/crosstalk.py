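"""Metabolite-redoxome crosstalk: Spearman pair screening and sign tallies.

For each (Cys site, metabolite) pair with enough complete observations,
a Spearman correlation between the site's total-oxidation (Sto) levels
and the metabolite's normalized abundance is retained when p < 0.05 and
|rho| > 0.6 (both strict). Per metabolite, the numbers of positively and
negatively correlated sites are tallied; an excess of negative
correlations marks a candidate suppressor of oxidative stress, an
excess of positive ones a candidate promoter.

A top-k overlap utility intersects, across omics layers, the sites with
the most significant correlations.
"""
from __future__ import annotations

import itertools
import math
import warnings
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .differential import screen_anova

EXACT_P_MAX_N = 9  # exact permutation null up to this n (no ties)


def select_age_related_features(features: pd.DataFrame,
                                design: pd.DataFrame | pd.Series,
                                alpha: float = 0.05, min_n: int = 3,
                                group_order: Sequence[str] | None = None) -> pd.Index:
    """Features with one-way ANOVA p < alpha across age groups."""
    res, _ = screen_anova(features, design, alpha=alpha, min_n=min_n,
                          group_order=group_order)
    return res.index[res["significant"]]


@lru_cache(maxsize=None)
def _exact_rho_null(n: int) -> np.ndarray:
    """Sorted |rho| null distribution over all rank permutations (no ties)."""
    base = np.arange(1, n + 1)
    denom = n * (n * n - 1)
    rhos = np.empty(math.factorial(n))
    for k, perm in enumerate(itertools.permutations(base)):
        s = int(np.sum((base - np.asarray(perm)) ** 2))
        rhos[k] = 1.0 - 6.0 * s / denom
    return np.sort(np.abs(rhos))


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and two-sided p.

    Exact permutation p for small tie-free samples, t-approximation
    otherwise.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return np.nan, np.nan
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= EXACT_P_MAX_N and not ties:
        null = _exact_rho_null(n)
        k = len(null) - np.searchsorted(null, abs(rho) - 1e-12, side="left")
        p = k / len(null)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def spearman_pairs(sto: pd.DataFrame, features: pd.DataFrame,
                   p_max: float = 0.05, rho_min: float = 0.6,
                   min_pairs: int = 8) -> pd.DataFrame:
    """Significant (site, feature) Spearman correlations.

    ``sto``: site x sample Sto levels; ``features``: feature x sample
    matrix. Pairs are computed over shared samples with pairwise-complete
    observations (>= ``min_pairs``) and retained iff p < p_max AND
    |rho| > rho_min (strict).
    """
    shared = sto.columns.intersection(features.columns)
    if len(shared) == 0:
        raise ValidationError("no shared samples between matrices")
    s = sto[shared].to_numpy(dtype=float)
    f = features[shared].to_numpy(dtype=float)

    rows = []
    for j, feat in enumerate(features.index):
        fv = f[j]
        f_ok = ~np.isnan(fv)
        for i, site in enumerate(sto.index):
            sv = s[i]
            ok = f_ok & ~np.isnan(sv)
            n = int(ok.sum())
            if n < min_pairs:
                continue
            rho, p = _spearman(sv[ok], fv[ok])
            if np.isnan(rho):
                continue
            if p < p_max and abs(rho) > rho_min:
                rows.append((site, feat, rho, p, n))
    return pd.DataFrame(rows, columns=["site_id", "feature_id", "rho",
                                       "p_value", "n_pairs"])


def tally_features(pairs: pd.DataFrame, min_total: int = 3) -> pd.DataFrame:
    """Per-feature counts of positive/negative significant pairs and call.

    direction_score = (n_neg - n_pos) / (n_neg + n_pos); the call is
    suppressor_candidate when negatives dominate, promoter_candidate when
    positives dominate, ambiguous on ties or fewer than ``min_total``
    pairs overall.
    """
    rows = []
    for feat, grp in pairs.groupby("feature_id", sort=True):
        n_pos = int((grp["rho"] > 0).sum())
        n_neg = int((grp["rho"] < 0).sum())
        total = n_pos + n_neg
        score = (n_neg - n_pos) / total if total else np.nan
        if total < min_total or n_pos == n_neg:
            call = "ambiguous"
        elif n_neg > n_pos:
            call = "suppressor_candidate"
        else:
            call = "promoter_candidate"
        rows.append((feat, n_pos, n_neg, score, call))
    return pd.DataFrame(rows, columns=["feature_id", "n_pos", "n_neg",
                                       "direction_score", "call"]).set_index("feature_id")


def top_k_overlap(counts_per_omics: Mapping[str, pd.Series],
                  k: int = 50) -> tuple[set, dict[str, set], bool]:
    """Intersection of the top-k most-correlated sites across omics layers.

    Sites tied with the k-th count are all included (order-independent);
    the returned flag marks whether any layer had such a boundary tie.
    Returns (intersection, per-layer top sets, tie_flag).
    """
    if len(counts_per_omics) < 2:
        raise ValidationError("need counts from at least two omics layers")
    tops: dict[str, set] = {}
    tie_flag = False
    for name, counts in counts_per_omics.items():
        c = counts.dropna().sort_values(ascending=False)
        if k >= len(c):
            warnings.warn(f"{name}: k={k} >= universe ({len(c)}); taking all")
            tops[name] = set(c.index)
            continue
        threshold = c.iloc[k - 1]
        chosen = c.index[c >= threshold]
        if len(chosen) > k:
            tie_flag = True
        tops[name] = set(chosen)
    inter = set.intersection(*tops.values())
    return inter, tops, tie_flag
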