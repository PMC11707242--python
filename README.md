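# redoxmap

Analysis pipeline for multiplexed cysteine redoxomics: from
reporter-ion site tables to redox-state occupancies, bimodal occupancy
regions and age transitions, differential-modification screening, and
metabolite–redoxome crosstalk.

## The problem

Protein cysteines cycle through oxidative modifications — sulfenic acid
(SOH), S-nitrosylation (SNO), S-glutathionylation (SSG) — and their
pooled total oxidation (Sto) tracks tissue oxidative stress, e.g. in
the aging gut. Multiplexed (TMT-style) assays quantify five Cys states
per sample plus a fully reduced common reference, but turning reporter
intensities into biology takes a chain of careful steps: channel
normalization against the reference plex, site **occupancy**
(stoichiometry)

    occ_m = I_m / (I_Sto + I_SH),

density-based splitting of the bimodal Sto occupancy distribution at
the valley between its two peaks (regions Y1/Y2 in young, O1/O2 in
old), counting sites whose occupancy region shifts with age,
missingness-aware differential rules (one-way ANOVA where detection
allows, presence/absence otherwise; two-group t-test + fold-change for
intervention designs), and a Spearman correlation tally that flags
metabolites as candidate suppressors or promoters of oxidative stress
by the sign balance of their correlated Cys sites.

`redoxmap` implements that chain as a tested library with a CLI, and
ships a synthetic cohort generator (3 age groups × 2 colon locations ×
4 animals, planted age effects, a latent oxidative-stress factor,
MNAR dropout) so every stage is verifiable offline against known
ground truth. It is aimed at proteomics bioinformaticians who want the
stoichiometry/region/crosstalk logic as reusable, audited components.

## Worked example

Generate a cohort and run the full pipeline:

```bash
redoxmap run --config examples/demo.yaml
```

or drive the stages as scripts (each writes TSVs under `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_normalize_qc.py
python analysis/03_stoichiometry.py
python analysis/04_differential.py
python analysis/05_crosstalk.py
python analysis/06_motif.py
```

On the default cohort (seed 1, 3000 sites) this prints:

```
young: peaks at 26.0% / 83.0%, valley at 56.8%
old: peaks at 26.2% / 84.0%, valley at 56.9%
Y1->O2: 34 sites (24 with >10% increase)
Y2->O1: 11 sites (8 with >10% decrease)
...
age-related metabolites (ANOVA p < 0.05): 23
1580 significant pairs; 10 suppressor and 13 promoter candidates
planted metabolites: 20/20 called, direction accuracy 100%
...
region 1: 1705 windows; modal residue at -1: K (41.1%)
```

Reading: the fitted Sto occupancy density peaks (26%/83–84%) recover
the generator's planted modes (25%/85%); 34 sites cross the valley from
the young low-occupancy region to the old high-occupancy region (24 of
them gaining more than 10 occupancy points); 23 of 111 metabolites are
age-related, and every planted suppressor/promoter metabolite is
direction-called correctly from the sign balance of its correlated Cys
sites; the lysine planted at flank position −1 of low-occupancy sites
is recovered as the modal residue of the region-1 motif matrix.

Library use mirrors the scripts:

```python
from redoxmap import io, normalize, stoichiometry

sites = io.read_site_table("results/fixture/redox_sites.txt")   # filters rows
ratios = normalize.compute_channel_ratios(
    io.read_protein_table("results/fixture/protein_quant.txt"))
norm = normalize.normalize_redox(sites, ratios)
occ = stoichiometry.compute_occupancy(norm)                      # in [0, 1]
```

## Layout

- `src/redoxmap/` — library: `simulate`, `io`, `normalize`,
  `stoichiometry`, `differential`, `crosstalk`, `motif`, `pipeline`,
  `cli`
- `analysis/` — numbered narrative drivers over the library
- `tests/` — unit, property and end-to-end suites
- `docs/methods.md` — model, assumptions, parameter defaults, limits
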