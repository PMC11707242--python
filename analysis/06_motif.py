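#!/usr/bin/env python
"""Sequence motifs around Cys sites, stratified by occupancy region.

Extracts ±10-residue windows for sites in the low (region 1) and high
(region 2) young-group occupancy regions and writes the position
frequency matrices; the modal residue at each flank position summarizes
the motif.
"""
from pathlib import Path

import pandas as pd

from redoxmap import io, motif

FIX = Path("results/fixture")
OUT = Path("results")


def main() -> None:
    seqs = io.read_fasta(FIX / "proteins.fasta")
    sites = io.read_site_table(FIX / "redox_sites.txt").meta
    regions = pd.read_csv(OUT / "regions_transitions.tsv", sep="\t", index_col=0)

    sites = sites.join(regions["young_region"]).dropna(subset=["young_region"])
    wins = motif.extract_windows(seqs, sites)
    for region in (1, 2):
        sel = wins[wins["young_region"] == region]
        mat = motif.position_frequencies(sel["window"])
        mat.to_csv(OUT / f"motif_region{region}.tsv", sep="\t")
        aa = [c for c in mat.columns if c != "_"]
        modal = mat.loc[-1, aa].idxmax()
        print(f"region {region}: {len(sel)} windows; modal residue at -1: "
              f"{modal} ({mat.loc[-1, modal]:.1%})")


if __name__ == "__main__":
    main()
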