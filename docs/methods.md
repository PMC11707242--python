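# Methods

## Scope

`redoxmap` implements the computational arc of a multiplexed cysteine
redox profiling study of the aging primate gut: five Cys redox states
(free thiol SH, total oxidation Sto, sulfenic acid SOH,
S-nitrosylation SNO, S-glutathionylation SSG) are quantified per sample
through TMT-style reporter channels, with a fully reduced pooled
reference bridging plexes. The package consumes MaxQuant-dialect site
tables, performs the normalization and stoichiometry arithmetic,
screens for age-related changes, and scores metabolite–redoxome
crosstalk. Wet-lab chemistry, spectral search, enrichment analysis
(GO/KEGG/GSEA) and cell-type deconvolution are out of scope.

Because raw reporter data are not shipped, a synthetic cohort generator
with complete ground truth stands in for the deposited data; every
downstream claim the test suite makes is therefore a statement about
recovery of planted structure, not about any particular tissue.

## Normalization model

Each plex carries six channels of one biological sample: the five redox
states plus the common reference (REF, fully TCEP-reduced). An
unenriched aliquot of each channel provides a protein-level quant; the
**total protein ratio** of a channel is its protein-sum divided by the
reference channel's protein-sum. Reporter intensities are divided by
this ratio (channel normalization), and each site's normalized
intensity is further divided by the same site's normalized reference
intensity to give the **reference ratio** ("Sto level" for the Sto
channel) used in differential screening and crosstalk.

Occupancy of modification m at a site-sample is

    occ_m = I_m / (I_Sto + I_SH)

computed on channel-normalized intensities. The reference division
cancels in this ratio, so the two intensity scales give identical
occupancies; `occ(Sto) + occ(SH) = 1` holds identically wherever both
are quantified. Ratios above 1 (reporter noise on low signals) are
clamped to 1 and flagged, keeping site coverage while recording the
anomaly; clamping is monotone, so region labels are unaffected.

Proteome matrices (two-group mouse-style workflows) aggregate unique
peptides (≥ 2 per protein), equalize per-sample totals to their mean
(the target level is a free choice; the mean is used and configurable),
optionally divide by the per-batch reference sample, log2-transform and
drop proteins detected in under half the samples. Metabolite matrices
are filtered on QC coefficient of variation (CV ≥ 0.3 excluded, sample
standard deviation), divided by per-sample tissue protein
concentration, and divided per mode by the correction factor
(sample total / mean of sample totals) before modes are concatenated.

## Occupancy regions and transitions

The distribution of per-site group-median Sto occupancy is bimodal. Per
group, a Gaussian KDE (Silverman bandwidth, 512-point grid on [0, 1],
no boundary correction; bandwidth configurable) is fitted to the
medians; the two highest local maxima are the peaks and the grid argmin
strictly between them is the valley. Sites at or below the valley are
region 1 (low occupancy), above it region 2; a median exactly at the
valley goes to region 1 (tie rule). Fewer than two maxima raise
`UnimodalDensityError` so callers can fall back to a fixed boundary.
The valley is computed per group from that group's own density; a
shared boundary is available by passing one model to both assignments.

Group medians require ≥ 3 quantified samples per group (`min_n`).
Transitions are counted between the young and old labelings
(Y1→O2, Y2→O1), with the sub-count of sites whose absolute
occupancy change exceeds `delta_min` = 0.10 (strict; "10%" is read as
absolute occupancy points). The middle group does not enter region
assignment. Sub-modification contributions divide `occ_m` by `occ_Sto`
(capped at 1); fraction sums above 1 are rescaled to 1 and flagged, and
the residual absorbs states not separately measured (disulfides,
SO2H/SO3H).

## Differential rules

Three-group screen: sites detected in ≥ 3 samples of every age group
get a one-way ANOVA; significance is raw p < 0.05 with no multiplicity
correction by default (a BH-FDR helper exists but is off). Sites
failing the detection floor fall through to the presence/absence rule:
differential iff at least one group has zero detections and every
detected group covers ≥ half its samples. The two rule sets are
disjoint by construction. Trends order group medians
(up/down with age; up/down in the middle group when it is strictly
extreme); exact Y-vs-O ties are labeled "flat" and flagged.

Two-group screen (on log2 values): classic equal-variance Student
t-test (Welch via `equal_var=False`), significant iff p < 0.05 AND
|log2FC| > 0.263 (fold change 1.2), both strict; plus a presence rule
for features detected in ≥ half of one group and none of the other.
"Detected" always means a positive, non-missing intensity after the
ingest zero→missing conversion.

## Crosstalk

Age-related metabolites (three-group ANOVA p < 0.05 on the normalized
matrix, pooled over locations) are correlated against the Sto levels
(reference ratios, not occupancies; an occupancy mode is available) of
differential Cys sites: Spearman with average ranks, two-sided p,
retained iff p < 0.05 and |rho| > 0.6, both strict, over ≥ `min_pairs`
pairwise-complete observations (default 8 — a conservative floor for a
24-sample design). For tie-free samples of n ≤ 9 the p-value is the
exact permutation tail (cached null of all n! rank permutations);
otherwise the t approximation. Per metabolite the positive and negative
partners are tallied; `direction_score = (n_neg − n_pos)/(n_neg +
n_pos)`, and the call is suppressor candidate when negatives dominate,
promoter candidate when positives dominate, ambiguous on ties or fewer
than 3 pairs. Top-k overlap ranks sites per omics layer by significant-
correlation count, keeps the top k including boundary ties
(order-independent, flagged), and intersects the layers.

## Motifs

±10-residue windows (21 positions) around each Cys; termini are padded
with `_`, which is tracked as its own symbol and excluded from
enrichment comparisons. Matrices are plain per-position relative
frequencies (sequence-logo probabilities); a log-odds mode against the
cohort background is deliberately not the default. Motif input sites
can be restricted to medians within ±0.10 of a density peak
(`sites_near_peak`).

## Synthetic cohort

The generator emulates the study design: 3 age groups (young / middle /
old) × 2 colon locations (A = ascending, D = descending) × 4 animals,
24 samples, ~3000 Cys sites on ~800 proteins, 120 metabolites in two
ion modes with 8 pooled QC replicates.

* **True occupancy**: per-site base occupancy from a two-component Beta
  mixture parameterized by mode and concentration (modes 0.25 / 0.85,
  weight 0.6 low, concentration 18) — an interior-mode bimodal shape
  without copying any data.
* **Age effects**: 5% of sites shift up and 2% down, linearly across
  groups, by 0.15 occupancy between extreme groups.
* **Latent stress factor**: one value per sample, increasing with age
  group (group index centered, jitter sd 0.4). Forty "driven" sites add
  0.2 occupancy per unit factor; suppressor/promoter metabolites (8%
  each) couple with log2 slope ∓1.0 and residual sd 0.4, giving planted
  site–metabolite correlations of |rho| ≈ 0.7 at n = 24. Coupled
  metabolites are placed in the low-abundance tail so sample totals
  (hence correction factors) stay decoupled from the factor.
* **Intensities**: per-site base total intensity (log10 mean 6.3,
  between-site sd 0.5) with per-sample deviation (sd 0.2), so a peptide
  is persistently bright or dim across plexes; per-channel loading
  multipliers U(0.7, 1.4) per plex; unit-mean log-normal reporter noise
  with CV 0.2 (the assay's reporter noise magnitude is not published;
  this is a free parameter exposed in the config).
* **Dropout**: detection probability is logistic in log10 intensity
  (midpoint 4.3, steepness 2), i.e. missing-not-at-random; sub-
  modification channels (a few percent of the total signal) lose
  roughly a third to a half of their measurements while Sto/SH stay
  nearly complete, which is what makes the presence/absence rule
  testable.
* **Sequences**: random proteins from vertebrate residue background
  frequencies with a C at every site; low-mode sites carry a planted K
  at position −1 with probability 0.4.
* **Streams**: one pseudo-random stream per output block (design,
  sites, sequences, intensities, proteins, metabolites, dropout), all
  spawned from the master seed, so toggling one block does not shift
  the draws of another; identical config + seed is byte-identical on
  disk.

What the generator does *not* emulate: isotope impurity between
reporter channels, co-isolation interference, retention-time structure,
peptide-level (as opposed to site-level) aggregation, and correlated
biology beyond the single latent factor. Passing tests therefore show
the pipeline's arithmetic, rules and recovery behavior are correct
under the stated noise model — not that the biology of any real cohort
is reproduced.

## Numerical choices

* ANOVA calibration is assessed on log2 reference ratios: the ratios
  are log-normal-ish, and the F-test's null rate on the log scale sits
  at the nominal 5% (the raw-scale rate is mildly conservative).
* Zero reporter intensity means "not quantified" and becomes missing at
  ingest; `I_Sto + I_SH = 0` yields a missing occupancy with a warning.
* The localization-probability filter is strictly `> 0.75`
  (a site at exactly 0.75 is dropped); the threshold is configurable.
* Spearman p-values: exact permutation null for tie-free n ≤ 9,
  t-approximation otherwise; rho itself is always the average-rank
  Pearson formula and matches an independent rank-and-correlate oracle
  to 1e-12.
* Peaks/valley are reported at grid resolution (1/511 ≈ 0.002
  occupancy); tests use ±0.05 bands.
* Problem sizes in the test and acceptance runs: the full cohort at
  3000 sites for recovery checks; 2500-site null cohorts for
  calibration; 1500-site cohorts for the power curve at effects
  {0.05, 0.10, 0.15}; a 10,000-site random table for the transition
  oracle. These sizes give stable statistics on a single CPU in well
  under a minute each.

## Known limitations

* The exact-permutation Spearman path enumerates n! permutations and is
  only engaged for n ≤ 9 without ties.
* The KDE has no boundary correction; densities within one bandwidth of
  0 or 1 are biased low. The planted modes (0.25/0.85) are far enough
  from the boundary that peak recovery is unaffected.
* Presence-rule trends for patterns detected only in two non-adjacent
  groups are heuristic ("down_in_M" for young+old detection).
* The two-group presence rule requires exactly zero detections in one
  group; a single stray detection routes the site to the t-test path
  (where it will usually fail the detection floor and be dropped).
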