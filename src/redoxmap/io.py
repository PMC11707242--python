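"""Readers for MaxQuant-dialect site/protein tables, metabolite TSVs and FASTA.

Row-level quality filtering happens here: reverse-database and
contaminant hits (``+`` flags or REV_/CON_ accession prefixes) are
removed, site rows additionally require a localization probability
strictly above the threshold (default 0.75). Zero reporter intensities
are converted to missing on ingest — a zero reporter means the ion was
not quantified, not that it was absent at zero abundance.
"""
from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError
from .types import MetaboliteTable, ReporterSiteTable

#: Accepted header spellings, first match wins. Extendable by callers for
#: other export dialects.
SITE_DIALECT: Mapping[str, Sequence[str]] = {
    "site_id": ("Site ID", "site_id", "id"),
    "protein": ("Protein", "Proteins", "protein", "Leading proteins"),
    "position": ("Position", "position"),
    "localization_prob": ("Localization prob", "Localization probability",
                          "localization_prob"),
    "reverse": ("Reverse",),
    "contaminant": ("Potential contaminant", "Contaminant"),
}

PROTEIN_DIALECT: Mapping[str, Sequence[str]] = {
    "protein": ("Protein IDs", "Majority protein IDs", "Protein", "protein"),
    "reverse": ("Reverse",),
    "contaminant": ("Potential contaminant", "Contaminant"),
}

_INTENSITY_RE = re.compile(r"^intensity\.(?P<state>[^.]+)\.(?P<sample>.+)$")


def _resolve(columns: Sequence[str], dialect: Mapping[str, Sequence[str]],
             required: Sequence[str]) -> dict[str, str]:
    found = {}
    for key, names in dialect.items():
        for name in names:
            if name in columns:
                found[key] = name
                break
    for key in required:
        if key not in found:
            raise SchemaError(f"required column '{key}' not found "
                              f"(accepted spellings: {list(dialect[key])})")
    return found


def _intensity_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Collect `intensity.<state>.<sample>` columns into a (state, sample) frame."""
    pairs, cols = [], []
    for c in df.columns:
        m = _INTENSITY_RE.match(str(c))
        if m:
            pairs.append((m.group("state"), m.group("sample")))
            cols.append(c)
    if not pairs:
        raise SchemaError("no 'intensity.<state>.<sample>' columns found")
    intens = df[cols].apply(pd.to_numeric, errors="coerce")
    if (intens.to_numpy(dtype=float) < 0).any():
        raise ValidationError("negative reporter intensity encountered")
    intens = intens.mask(intens == 0)  # zero reporter -> not quantified
    intens.columns = pd.MultiIndex.from_tuples(pairs, names=["state", "sample"])
    return intens


def _flagged(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.strip() == "+"


def read_site_table(path: str | Path, loc_prob_threshold: float = 0.75,
                    dialect: Mapping[str, Sequence[str]] | None = None) -> ReporterSiteTable:
    """Read a redox site table and apply the row-level quality filters.

    Rows flagged as reverse or contaminant ('+', or REV_/CON_ accession
    prefixes) are dropped; surviving rows must have localization
    probability strictly greater than ``loc_prob_threshold``.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"Reverse": str, "Potential contaminant": str})
    cols = _resolve(df.columns, dialect or SITE_DIALECT,
                    required=["site_id", "protein", "position", "localization_prob"])
    n_input = len(df)
    if n_input == 0:
        warnings.warn(f"{path}: empty site table")

    acc = df[cols["protein"]].fillna("").astype(str)
    rev = acc.str.startswith("REV_")
    con = acc.str.startswith("CON_")
    if "reverse" in cols:
        rev |= _flagged(df[cols["reverse"]])
    if "contaminant" in cols:
        con |= _flagged(df[cols["contaminant"]])
    con &= ~rev  # count each row once, reverse takes precedence
    loc = pd.to_numeric(df[cols["localization_prob"]], errors="coerce")
    low_loc = ~(loc > loc_prob_threshold) & ~rev & ~con

    keep = ~(rev | con | low_loc)
    filter_log = {
        "input_rows": n_input,
        "reverse": int(rev.sum()),
        "contaminant": int(con.sum()),
        "localization": int(low_loc.sum()),
        "retained": int(keep.sum()),
    }
    kept = df[keep]
    meta = pd.DataFrame({
        "protein": kept[cols["protein"]].astype(str).to_numpy(),
        "position": pd.to_numeric(kept[cols["position"]]).astype(int).to_numpy(),
        "localization_prob": loc[keep].to_numpy(),
    }, index=pd.Index(kept[cols["site_id"]].astype(str), name="site_id"))
    intens = _intensity_frame(kept).set_axis(meta.index, axis=0)
    return ReporterSiteTable(meta=meta, intensities=intens, filter_log=filter_log)


def read_protein_table(path: str | Path,
                       dialect: Mapping[str, Sequence[str]] | None = None) -> pd.DataFrame:
    """Read an unenriched protein quant table; drop decoys and contaminants.

    Returns a protein x (state, sample) intensity frame (zeros -> missing).
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = _resolve(df.columns, dialect or PROTEIN_DIALECT, required=["protein"])
    if len(df) == 0:
        warnings.warn(f"{path}: empty protein table")
        return pd.DataFrame(columns=pd.MultiIndex.from_tuples([], names=["state", "sample"]))

    acc = df[cols["protein"]].fillna("").astype(str)
    drop = acc.str.startswith("REV_") | acc.str.startswith("CON_")
    if "reverse" in cols:
        drop |= _flagged(df[cols["reverse"]])
    if "contaminant" in cols:
        drop |= _flagged(df[cols["contaminant"]])
    kept = df[~drop]
    intens = _intensity_frame(kept)
    intens.index = pd.Index(kept[cols["protein"]].astype(str), name="protein")
    return intens


def read_metabolite_table(path: str | Path, mode: str,
                          qc_prefix: str = "QC_") -> MetaboliteTable:
    """Read one ion mode's metabolite TSV.

    Layout: metabolite rows x (sample columns + QC replicate columns),
    plus one ``protein_concentration`` row carrying each sample's tissue
    protein concentration.
    """
    if mode not in ("pos", "neg"):
        raise ValidationError(f"unknown ion mode: {mode!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if "protein_concentration" not in df.index:
        raise SchemaError("missing 'protein_concentration' row")
    conc_row = pd.to_numeric(df.loc["protein_concentration"], errors="coerce")
    body = df.drop(index="protein_concentration").apply(pd.to_numeric, errors="coerce")

    qc_cols = [c for c in body.columns if str(c).startswith(qc_prefix)]
    sample_cols = [c for c in body.columns if c not in qc_cols]
    missing_conc = [s for s in sample_cols if pd.isna(conc_row.get(s))]
    if missing_conc:
        raise ValidationError(f"missing protein_concentration for samples: {missing_conc}")
    if (body.to_numpy(dtype=float) < 0).any():
        raise ValidationError("negative metabolite intensity encountered")
    return MetaboliteTable(values=body[sample_cols], qc=body[qc_cols],
                           protein_concentration=conc_row[sample_cols], mode=mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into {accession: uppercased sequence}.

    The accession is the first whitespace-delimited token of the header.
    Duplicate accessions and residue-before-header records are rejected.
    """
    with open(path) as fh:
        first_line = None
        for i, line in enumerate(fh, start=1):
            if line.strip():
                first_line = (i, line)
                break
    if first_line is not None and not first_line[1].startswith(">"):
        raise ParseError(f"{path}: line {first_line[0]}: expected '>' header, "
                         f"got {first_line[1].strip()[:30]!r}")

    from Bio import SeqIO
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in seqs:
            raise ParseError(f"{path}: duplicate accession {acc!r}")
        seqs[acc] = str(rec.seq).upper()
    return seqs
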