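"""Sequence windows around modified Cys sites and position frequency matrices.

Windows span ``flank`` residues either side of the cysteine (default 10,
21 positions total); positions beyond the sequence termini are padded
with '_'. Per occupancy region, the relative frequency of each residue
at each flank position is tabulated — the numeric counterpart of a
sequence logo.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
PAD = "_"


def extract_windows(sequences: Mapping[str, str], sites: pd.DataFrame,
                    flank: int = 10) -> pd.DataFrame:
    """±flank residue window for each site.

    ``sites``: indexed by site id with ``protein`` and 1-based
    ``position`` columns (any extra columns, e.g. ``region``, are carried
    through). Every position must hold a cysteine.
    """
    missing = sorted(set(sites["protein"]) - set(sequences))
    if missing:
        raise ValidationError(f"accessions missing from FASTA: {missing}")
    windows = []
    for site_id, row in sites.iterrows():
        seq = sequences[row["protein"]]
        pos = int(row["position"])  # 1-based
        if not 1 <= pos <= len(seq):
            raise ValidationError(f"site {site_id}: position {pos} outside sequence")
        if seq[pos - 1] != "C":
            raise ValidationError(
                f"site {site_id}: residue at position {pos} is {seq[pos - 1]!r}, not 'C'")
        i = pos - 1
        left = seq[max(0, i - flank):i]
        right = seq[i + 1:i + 1 + flank]
        window = PAD * (flank - len(left)) + left + "C" + right + PAD * (flank - len(right))
        windows.append(window)
    out = sites.copy()
    out["window"] = windows
    return out


def position_frequencies(windows: Iterable[str], flank: int = 10) -> pd.DataFrame:
    """Relative residue frequencies per flank position.

    Rows are positions -flank..+flank, columns the 20 amino acids plus
    the terminus placeholder; each row sums to 1.
    """
    wins = [w for w in windows]
    if not wins:
        raise ValidationError("no windows")
    width = 2 * flank + 1
    if any(len(w) != width for w in wins):
        raise ValidationError(f"all windows must have length {width}")
    symbols = AMINO_ACIDS + (PAD,)
    arr = np.frombuffer("".join(wins).encode("ascii"), dtype="S1").reshape(len(wins), width)
    mat = np.zeros((width, len(symbols)))
    for j, sym in enumerate(symbols):
        mat[:, j] = (arr == sym.encode()).sum(axis=0)
    mat /= len(wins)
    return pd.DataFrame(mat, index=pd.RangeIndex(-flank, flank + 1, name="offset"),
                        columns=list(symbols))


def sites_near_peak(medians: pd.Series, peak: float, width: float = 0.10) -> pd.Index:
    """Sites whose median occupancy lies within ±width of a density peak.

    This is the neighborhood used to pick motif input sites for each
    occupancy peak.
    """
    med = medians.dropna()
    return med.index[(med - peak).abs() <= width]
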