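"""Redox-state occupancy, bimodal regions, transitions and contributions.

Occupancy (stoichiometry) of modification m at a site-sample is
``occ_m = I_m / (I_Sto + I_SH)`` on channel-normalized intensities; the
reference division cancels in this ratio, so either intensity scale
gives identical occupancies. Group summaries are medians over samples
with at least ``min_n`` quantifications. The distribution of total-
oxidation (Sto) occupancy is bimodal; a Gaussian KDE is fitted per age
group, the valley between the two highest peaks splits sites into a
low-occupancy region (1) and a high-occupancy region (2), and
region-label changes between young and old (Y1->O2, Y2->O1) are counted
together with the subset whose occupancy changed by more than
``delta_min`` (absolute occupancy, default 0.10).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import DegenerateValuesError, UnimodalDensityError, ValidationError
from .types import MOD_STATES, NormalizedRedoxTable, OccupancyTable, ReporterSiteTable

OCC_STATES = ("Sto", "SH") + MOD_STATES


def compute_occupancy(table: NormalizedRedoxTable | ReporterSiteTable | pd.DataFrame,
                      clamp: bool = True) -> OccupancyTable:
    """Per site x sample x state occupancy.

    Requires Sto and SH intensities for the site-sample; otherwise the
    occupancy is missing. Ratios above 1 (reporter noise) are clamped to
    1 and flagged; the raw ratio is retained.
    """
    if isinstance(table, NormalizedRedoxTable):
        intens = table.normalized
    elif isinstance(table, ReporterSiteTable):
        intens = table.intensities
    else:
        intens = table
    states = [s for s in OCC_STATES if s in intens.columns.get_level_values(0)]
    if "Sto" not in states or "SH" not in states:
        raise ValidationError("need both Sto and SH intensities for occupancy")
    denom = intens["Sto"] + intens["SH"]  # NaN if either missing
    n_zero = int((denom == 0).sum().sum())
    if n_zero:
        warnings.warn(f"{n_zero} site-sample(s) with I_Sto + I_SH == 0; occupancy missing")
    denom = denom.mask(denom == 0)

    raw = {}
    for st in states:
        raw[st] = intens[st].div(denom)
    raw_df = pd.concat(raw, axis=1, names=["state", "sample"])
    occ = raw_df.clip(upper=1.0) if clamp else raw_df.copy()
    clamped = raw_df > 1.0
    return OccupancyTable(occupancy=occ, raw=raw_df, clamped=clamped)


def group_median_occupancy(occ: OccupancyTable | pd.DataFrame,
                           design: pd.DataFrame,
                           min_n: int = 3,
                           stratify_location: bool = False
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median occupancy per (site, state, group[, location]).

    Returns ``(medians, counts)``; a median is missing wherever fewer
    than ``min_n`` samples of that group quantified the site. The
    unstratified call pools both locations ("All" analysis).
    """
    frame = occ.occupancy if isinstance(occ, OccupancyTable) else occ
    samples = frame.columns.get_level_values("sample")
    unknown = set(samples) - set(design.index)
    if unknown:
        raise ValidationError(f"samples not in design: {sorted(unknown)}")
    keys = ["group", "location"] if stratify_location else ["group"]
    group_of = design[keys].astype(str).agg("/".join, axis=1)

    cols = pd.MultiIndex.from_arrays(
        [frame.columns.get_level_values("state"), samples.map(group_of)],
        names=["state", "group"])
    tframe = frame.T
    tframe.index = cols
    med = tframe.groupby(level=["state", "group"]).median().T
    counts = tframe.notna().groupby(level=["state", "group"]).sum().T
    med = med.where(counts >= min_n)
    return med, counts


@dataclass
class RegionModel:
    """Fitted density with two peaks and the valley boundary for one group."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    peak_low: float
    peak_high: float
    valley: float
    group: str = ""


@dataclass
class DensityGrid:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def fit_density(values, bandwidth: str | float = "silverman",
                grid_size: int = 512, min_values: int = 50) -> DensityGrid:
    """Gaussian KDE of occupancies evaluated on a uniform grid over [0, 1]."""
    vals = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(vals) < min_values:
        raise DegenerateValuesError(
            f"only {len(vals)} values (< {min_values}); pool groups or locations")
    if np.ptp(vals) == 0:
        raise DegenerateValuesError("constant values; density is a point mass")
    kde = gaussian_kde(vals, bw_method=bandwidth)
    grid = np.linspace(0.0, 1.0, grid_size)
    dens = kde(grid)
    return DensityGrid(grid=grid, density=dens, bandwidth=float(kde.factor * vals.std(ddof=1)))


def find_peaks_valley(grid: DensityGrid, group: str = "") -> RegionModel:
    """Locate the two highest density peaks and the valley between them.

    Peaks are local maxima of the gridded density (grid endpoints
    included); the valley is the density argmin strictly between the two
    peaks. Fewer than two maxima raises ``UnimodalDensityError``.
    """
    d = grid.density
    x = grid.grid
    n = len(d)
    maxima = []
    for i in range(n):
        left = d[i - 1] if i > 0 else -np.inf
        right = d[i + 1] if i < n - 1 else -np.inf
        if d[i] > left and d[i] >= right:
            maxima.append(i)
    if len(maxima) < 2:
        raise UnimodalDensityError("density has fewer than two local maxima")
    top_two = sorted(sorted(maxima, key=lambda i: d[i], reverse=True)[:2])
    i_lo, i_hi = top_two
    between = slice(i_lo + 1, i_hi)
    i_valley = i_lo + 1 + int(np.argmin(d[between]))
    return RegionModel(grid=x, density=d, bandwidth=grid.bandwidth,
                       peak_low=float(x[i_lo]), peak_high=float(x[i_hi]),
                       valley=float(x[i_valley]), group=group)


def fit_region_model(values, group: str = "", **kwargs) -> RegionModel:
    """Convenience: density fit + peak/valley location in one call."""
    return find_peaks_valley(fit_density(values, **kwargs), group=group)


def assign_regions(medians: pd.Series, model: RegionModel) -> pd.Series:
    """1 for median <= valley (low-occupancy region), 2 above.

    A median exactly at the valley goes to region 1 (documented tie rule).
    """
    if model is None:
        raise ValidationError("no region model for this group")
    med = medians.dropna()
    return pd.Series(np.where(med > model.valley, 2, 1), index=med.index, name="region")


@dataclass
class TransitionReport:
    """Region-label changes between the young and old groups."""

    y1_to_o2: list
    y2_to_o1: list
    n_y1_to_o2: int
    n_y2_to_o1: int
    n_y1_to_o2_gt_delta: int
    n_y2_to_o1_gt_delta: int
    delta: pd.Series            # old median - young median, per shared site
    delta_min: float


def count_transitions(young_medians: pd.Series, young_regions: pd.Series,
                      old_medians: pd.Series, old_regions: pd.Series,
                      delta_min: float = 0.10) -> TransitionReport:
    """Count Y1->O2 and Y2->O1 sites and those with |delta occ| > delta_min.

    Only sites with a region label (hence a valid median) in both groups
    are considered; the delta filter is a strict absolute-occupancy
    threshold.
    """
    shared = young_regions.index.intersection(old_regions.index)
    yr = young_regions.loc[shared]
    orr = old_regions.loc[shared]
    delta = (old_medians.loc[shared] - young_medians.loc[shared]).rename("delta")

    up = shared[(yr == 1) & (orr == 2)]
    down = shared[(yr == 2) & (orr == 1)]
    return TransitionReport(
        y1_to_o2=list(up), y2_to_o1=list(down),
        n_y1_to_o2=len(up), n_y2_to_o1=len(down),
        n_y1_to_o2_gt_delta=int((delta.loc[up].abs() > delta_min).sum()),
        n_y2_to_o1_gt_delta=int((delta.loc[down].abs() > delta_min).sum()),
        delta=delta, delta_min=delta_min)


def modification_contribution(medians: pd.DataFrame) -> pd.DataFrame:
    """Fraction of total-oxidation occupancy carried by SSG/SOH/SNO.

    ``medians``: site x state frame (one group/stratum) containing Sto
    and the sub-modifications. fraction_m = occ_m / occ_Sto capped at 1;
    if the fractions sum above 1 (noise) they are rescaled to sum 1 and
    flagged; the residual covers states not separately measured
    (disulfides, SO2H/SO3H).
    """
    if "Sto" not in medians.columns:
        raise ValidationError("medians must include the Sto state")
    sto = medians["Sto"].mask(medians["Sto"] <= 0)
    mods = [m for m in MOD_STATES if m in medians.columns]
    frac = medians[mods].div(sto, axis=0).clip(upper=1.0)
    total = frac.fillna(0.0).sum(axis=1)
    rescaled = total > 1.0
    frac.loc[rescaled] = frac.loc[rescaled].div(total[rescaled], axis=0)
    residual = (1.0 - frac.fillna(0.0).sum(axis=1)).clip(lower=0.0)
    quantified = medians[mods].notna().any(axis=1) & sto.notna()
    out = frac.copy()
    out["residual"] = residual
    out[~quantified] = np.nan
    out["rescaled"] = rescaled & quantified
    return out
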