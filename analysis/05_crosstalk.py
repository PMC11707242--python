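#!/usr/bin/env python
"""Metabolite-redoxome crosstalk: which metabolites track oxidation?

Normalizes both ion modes, selects age-related metabolites (ANOVA
p < 0.05), correlates them (Spearman, p < 0.05 and |rho| > 0.6) against
the Sto levels of differential Cys sites, and tallies positive vs
negative partners per metabolite to call suppressor / promoter
candidates. With the ground truth available, the call accuracy on
planted metabolites is reported.
"""
from pathlib import Path

import pandas as pd

from redoxmap import crosstalk as ct, differential as dm, io, normalize as nm

FIX = Path("results/fixture")
OUT = Path("results")
GROUPS = ["young", "middle", "old"]


def main() -> None:
    sites = io.read_site_table(FIX / "redox_sites.txt")
    proteins = io.read_protein_table(FIX / "protein_quant.txt")
    design = pd.read_csv(FIX / "design.tsv", sep="\t", index_col=0)
    levels = nm.normalize_redox(
        sites, nm.compute_channel_ratios(proteins)).level("Sto")

    tables = [io.read_metabolite_table(FIX / f"metabolites_{m}.tsv", m)
              for m in ("pos", "neg")]
    metab = nm.normalize_metabolome(tables, cv_max=0.3)
    print(f"metabolome: {len(metab)} metabolites after the QC CV filter")

    age_related = ct.select_age_related_features(metab, design, group_order=GROUPS)
    print(f"age-related metabolites (ANOVA p < 0.05): {len(age_related)}")

    diff = dm.screen_three_group(levels, design, group_order=GROUPS)
    diff_sites = diff.index[diff["significant"]]
    pairs = ct.spearman_pairs(levels.loc[diff_sites], metab.loc[age_related])
    tally = ct.tally_features(pairs)
    pairs.to_csv(OUT / "crosstalk_pairs.tsv", sep="\t", index=False)
    tally.to_csv(OUT / "crosstalk_tally.tsv", sep="\t")
    print(f"{len(pairs)} significant pairs; "
          f"{(tally['call'] == 'suppressor_candidate').sum()} suppressor and "
          f"{(tally['call'] == 'promoter_candidate').sum()} promoter candidates")

    truth_path = FIX / "truth_metabolites.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col=0)
        planted = truth.index[truth["klass"] != "uncoupled"]
        calls = tally["call"].reindex(planted)
        expected = truth.loc[planted, "klass"].map(
            {"suppressor": "suppressor_candidate",
             "promoter": "promoter_candidate"})
        called = calls.notna()
        acc = (calls[called] == expected[called]).mean() if called.any() else float("nan")
        print(f"planted metabolites: {called.sum()}/{len(planted)} called, "
              f"direction accuracy {acc:.0%}")


if __name__ == "__main__":
    main()
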