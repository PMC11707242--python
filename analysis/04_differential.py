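#!/usr/bin/env python
"""Differential screening of Sto levels across age groups, per stratum.

Runs the ANOVA + presence/absence rule system on the "All" (pooled),
ascending and descending strata and summarizes trends.
"""
from pathlib import Path

import pandas as pd

from redoxmap import differential as dm, io, normalize as nm

FIX = Path("results/fixture")
OUT = Path("results")
GROUPS = ["young", "middle", "old"]


def main() -> None:
    sites = io.read_site_table(FIX / "redox_sites.txt")
    proteins = io.read_protein_table(FIX / "protein_quant.txt")
    design = pd.read_csv(FIX / "design.tsv", sep="\t", index_col=0)
    levels = nm.normalize_redox(
        sites, nm.compute_channel_ratios(proteins)).level("Sto")

    frames = []
    for stratum in ("All", "A", "D"):
        if stratum == "All":
            cols, des = levels.columns, design
        else:
            des = design[design["location"] == stratum]
            cols = [c for c in levels.columns if c in des.index]
        res = dm.screen_three_group(levels[list(cols)], des, group_order=GROUPS)
        res.insert(0, "stratum", stratum)
        frames.append(res)
        sig = res[res["significant"]]
        print(f"{stratum}: {len(sig)} differential sites "
              f"({(sig['rule'] == 'presence').sum()} by presence); trends: "
              f"{sig['trend'].value_counts().to_dict()}")
    pd.concat(frames).to_csv(OUT / "differential_sto.tsv", sep="\t")


if __name__ == "__main__":
    main()
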