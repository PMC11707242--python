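"""Normalization for the three data layers and QC correlations.

Redoxome: per plex/channel "total protein ratio" from the unenriched
aliquot (channel sum over the common-reference channel sum); reporter
intensities are divided by their channel ratio, and per-site reference
ratios divide by the same site's normalized reference intensity.

Proteome: unique-peptide aggregation (>= 2 unique peptides), per-sample
total equalization, optional per-batch common-reference division, log2,
and a minimum detection-fraction filter.

Metabolome: QC coefficient-of-variation filter (CV >= 0.3 excluded),
per-sample protein-concentration division and per-mode correction
factors (sample total / mean total), then mode concatenation.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NormalizationError, ValidationError
from .types import (
    CHANNELS,
    REF_STATE,
    MetaboliteTable,
    NormalizedRedoxTable,
    ReporterSiteTable,
)


def compute_channel_ratios(protein_table: pd.DataFrame,
                           reference_channel: str = REF_STATE) -> pd.DataFrame:
    """Total protein ratio per (channel, sample plex).

    ``protein_table`` is the unenriched-aliquot quant: protein x
    (channel, sample). Each plex (= sample) contributes one ratio per
    channel: channel sum / reference-channel sum. The reference channel's
    ratio is exactly 1.
    """
    if protein_table.empty:
        raise NormalizationError("empty protein table")
    sums = protein_table.sum(axis=0, skipna=True)  # (channel, sample) totals
    sums = sums.unstack(level="sample") if isinstance(sums.index, pd.MultiIndex) else sums
    if reference_channel not in sums.index:
        raise NormalizationError(f"reference channel {reference_channel!r} absent")
    ref = sums.loc[reference_channel]
    bad = ref[(ref <= 0) | ref.isna()]
    if len(bad):
        raise NormalizationError(
            f"reference channel total is zero/missing for plex(es): {list(bad.index)}")
    ratios = sums.div(ref, axis=1)
    ratios.loc[reference_channel] = 1.0
    return ratios


def normalize_redox(sites: ReporterSiteTable | pd.DataFrame,
                    ratios: pd.DataFrame,
                    reference_channel: str = REF_STATE) -> NormalizedRedoxTable:
    """Divide reporter intensities by channel ratios; compute reference ratios.

    Missing intensities propagate; a site without a reference intensity
    keeps its normalized intensities but has missing reference ratios.
    """
    intens = sites.intensities if isinstance(sites, ReporterSiteTable) else sites
    scale = []
    for st, sm in intens.columns:
        try:
            r = ratios.loc[st, sm]
        except KeyError:
            raise NormalizationError(f"no channel ratio for (state={st!r}, sample={sm!r})")
        if pd.isna(r) or r <= 0:
            raise NormalizationError(f"non-positive ratio for (state={st!r}, sample={sm!r})")
        scale.append(r)
    normalized = intens.div(pd.Series(scale, index=intens.columns), axis=1)

    if reference_channel not in normalized.columns.get_level_values(0):
        raise NormalizationError(f"reference channel {reference_channel!r} absent from table")
    ref = normalized[reference_channel]
    blocks = {}
    for st in normalized.columns.get_level_values(0).unique():
        blocks[st] = normalized[st].div(ref.reindex(columns=normalized[st].columns), axis=0)
    reference_ratio = pd.concat(blocks, axis=1, names=["state", "sample"])
    return NormalizedRedoxTable(normalized=normalized, reference_ratio=reference_ratio)


def aggregate_unique_peptides(peptide_table: pd.DataFrame,
                              sample_columns: Sequence[str],
                              min_unique: int = 2) -> pd.DataFrame:
    """Sum unique-peptide intensities per protein; keep proteins with
    >= ``min_unique`` distinct unique peptides.

    ``peptide_table`` needs a ``protein`` column and a boolean ``unique``
    column; rows are peptides.
    """
    uniq = peptide_table[peptide_table["unique"].astype(bool)]
    if uniq.empty:
        warnings.warn("no unique peptides; returning empty protein table")
        return pd.DataFrame(columns=list(sample_columns))
    counts = uniq.groupby("protein").size()
    keep = counts[counts >= min_unique].index
    summed = uniq.groupby("protein")[list(sample_columns)].sum(min_count=1)
    return summed.loc[summed.index.intersection(keep)]


def normalize_proteome(peptide_table: pd.DataFrame,
                       batches: Mapping[str, str] | None = None,
                       reference_samples: Mapping[str, str] | None = None,
                       min_unique: int = 2,
                       min_detect_frac: float = 0.5,
                       log2: bool = True) -> pd.DataFrame:
    """Proteome matrix from a peptide table.

    Steps: unique-peptide aggregation; zeros -> missing; per-sample total
    equalization to the mean total; optional division by the per-batch
    common-reference sample; log2; drop proteins detected in fewer than
    ``min_detect_frac`` of the (non-reference) samples.
    """
    sample_columns = [c for c in peptide_table.columns
                      if c not in ("protein", "peptide", "unique", "batch")]
    prot = aggregate_unique_peptides(peptide_table, sample_columns, min_unique)
    if prot.empty:
        return prot
    prot = prot.mask(prot == 0)

    totals = prot.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        raise NormalizationError(
            f"zero total intensity in sample(s): {list(totals.index[totals <= 0])}")
    prot = prot.mul(totals.mean() / totals, axis=1)

    out_cols = list(prot.columns)
    if reference_samples is not None:
        if batches is None:
            raise NormalizationError("reference_samples given without batches")
        for s in prot.columns:
            b = batches.get(s)
            if b is None:
                raise NormalizationError(f"sample {s!r} has no batch assignment")
            if reference_samples.get(b) is None:
                raise NormalizationError(f"batch {b!r} has no reference sample")
        ref_names = set(reference_samples.values())
        scaled = {s: prot[s] / prot[reference_samples[batches[s]]]
                  for s in prot.columns if s not in ref_names}
        prot = pd.DataFrame(scaled)
        out_cols = list(prot.columns)

    if log2:
        prot = np.log2(prot)
    detect_frac = prot.notna().sum(axis=1) / len(out_cols)
    return prot[detect_frac >= min_detect_frac]


def normalize_metabolome(tables: Sequence[MetaboliteTable],
                         cv_max: float = 0.3) -> pd.DataFrame:
    """Merge ion modes into one normalized metabolite x sample matrix.

    Per mode: metabolites whose QC coefficient of variation (sd/mean,
    sample sd) is >= ``cv_max`` are excluded; each value is divided by
    its sample's protein concentration; each sample is then divided by
    its correction factor (sample total / mean of sample totals).
    """
    blocks = []
    for table in tables:
        if table.qc.shape[1] < 2:
            raise ValidationError(f"mode {table.mode!r}: need >= 2 QC replicates")
        qc_mean = table.qc.mean(axis=1)
        qc_sd = table.qc.std(axis=1, ddof=1)
        zero_mean = qc_mean == 0
        if zero_mean.any():
            warnings.warn(f"mode {table.mode!r}: excluding "
                          f"{int(zero_mean.sum())} metabolite(s) with zero QC mean")
        cv = qc_sd / qc_mean.mask(zero_mean)
        keep = (cv < cv_max) & ~zero_mean
        vals = table.values.loc[keep.index[keep]]
        vals = vals.div(table.protein_concentration[vals.columns], axis=1)
        totals = vals.sum(axis=0, skipna=True)
        factor = totals / totals.mean()
        blocks.append(vals.div(factor, axis=1))
    merged = pd.concat(blocks, axis=0)
    if merged.index.duplicated().any():
        raise ValidationError("duplicate metabolite ids across ion modes")
    return merged


def qc_correlation(matrix: pd.DataFrame, method: str = "pearson",
                   min_pairs: int = 3) -> pd.DataFrame:
    """Sample x sample correlation over pairwise-complete observations.

    ``matrix``: features x samples. Constant columns yield missing
    correlations with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown method: {method!r}")
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    constant = [c for c in matrix.columns
                if matrix[c].dropna().nunique() <= 1]
    if constant:
        warnings.warn(f"constant column(s), correlations undefined: {constant}")
    corr = matrix.corr(method=method, min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr
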