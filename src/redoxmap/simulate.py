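"""Synthetic redox cohort generator with known ground truth.

Emulates the study design this package targets: three age groups x two
colon locations x four animals, five cysteine redox states plus a fully
reduced common reference per sample, a bimodal distribution of true
total-oxidation occupancy, planted age-shifted sites, a per-sample latent
oxidative-stress factor that both perturbs occupancies of a subset of
"driven" sites and linearly drives coupled metabolites, per-channel
loading multipliers, multiplicative reporter noise, and intensity-
dependent (MNAR, logistic in log10 intensity) dropout.

Every downstream stage of the pipeline can therefore be tested against
the generator's truth records without any external data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .types import CHANNELS, MOD_STATES, REF_STATE, ReporterSiteTable, MetaboliteTable

# Approximate vertebrate proteome residue background (sums to 1).
AA_BACKGROUND = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.044, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.058, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.053, "W": 0.011, "Y": 0.027, "V": 0.060,
}
_AA = np.array(list(AA_BACKGROUND))
_AA_P = np.array(list(AA_BACKGROUND.values()))
_AA_P = _AA_P / _AA_P.sum()

GROUP_LABELS_3 = ("young", "middle", "old")
GROUP_SHORT_3 = ("Y", "M", "O")


def _beta_params_from_mode(mode: float, concentration: float) -> tuple[float, float]:
    """Beta(a, b) with the given mode, parameterized by concentration a+b."""
    a = 1.0 + mode * (concentration - 2.0)
    b = 1.0 + (1.0 - mode) * (concentration - 2.0)
    return a, b


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults follow the emulated study design: 3 age groups x 2 colon
    locations x 4 animals, ~3000 Cys sites on ~800 proteins, true Sto
    occupancy from a two-mode Beta mixture, 5% of sites with a planted
    monotone age increase of 0.15 occupancy between extreme groups, and
    8% of metabolites each coupled negatively (suppressors) / positively
    (promoters) to the latent oxidative-stress factor.
    """

    n_groups: int = 3
    n_locations: int = 2
    n_per_cell: int = 4
    n_sites: int = 3000
    n_proteins: int = 800
    n_metabolites: int = 120
    mixture_modes: tuple[float, float] = (0.25, 0.85)
    mixture_weight: float = 0.6          # fraction of sites in the low mode
    mixture_concentration: float = 18.0
    frac_age_up: float = 0.05
    frac_age_down: float = 0.02
    age_effect: float = 0.15             # occupancy shift between extreme groups
    n_driven_sites: int = 40             # sites coupled to the latent stress factor
    driven_effect: float = 0.2           # occupancy shift per unit latent factor
    stress_sd: float = 0.4               # sample-level jitter of the latent factor
    frac_metab_suppressor: float = 0.08
    frac_metab_promoter: float = 0.08
    metab_slope: float = 1.0             # |log2 slope| vs the latent factor
    metab_noise_sd: float = 0.4          # log2 residual noise of metabolites
    dropout_midpoint: float | None = 4.3  # log10 intensity of 50% detection; None disables
    dropout_steepness: float = 2.0
    noise_cv: float = 0.2                # multiplicative reporter noise CV
    channel_load_range: tuple[float, float] = (0.7, 1.4)
    log10_intensity_mean: float = 6.3
    log10_intensity_sd: float = 0.5   # between-site spread of base intensity
    log10_intensity_within_sd: float = 0.2  # per-sample deviation around a site's base
    n_qc: int = 8
    qc_cv: float = 0.1
    frac_qc_noisy: float = 0.05          # metabolites with irreproducible QC (CV ~ noisy_qc_cv)
    noisy_qc_cv: float = 0.5
    motif_residue: str = "K"
    motif_position: int = -1
    motif_prob: float = 0.4              # planted enrichment in low-mode sites
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mixture_weight", "frac_age_up", "frac_age_down",
                     "frac_metab_suppressor", "frac_metab_promoter",
                     "frac_qc_noisy", "motif_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(name, f"{v} not in [0, 1]")
        lo, hi = self.mixture_modes
        if not (0.0 < lo < 1.0 and 0.0 < hi < 1.0):
            raise ConfigError("mixture_modes", f"{self.mixture_modes} not strictly inside (0, 1)")
        if lo >= hi:
            raise ConfigError("mixture_modes", f"{self.mixture_modes} not strictly increasing")
        if self.n_per_cell < 3:
            raise ConfigError("n_per_cell", f"{self.n_per_cell} < 3 (group tests need >= 3)")
        for name in ("n_groups", "n_locations", "n_sites", "n_proteins",
                     "n_metabolites", "n_qc"):
            if getattr(self, name) < 0 or (name in ("n_groups", "n_locations", "n_qc")
                                           and getattr(self, name) < 1):
                raise ConfigError(name, f"{getattr(self, name)} invalid")
        if self.n_groups < 2:
            raise ConfigError("n_groups", f"{self.n_groups} < 2")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv", f"{self.noise_cv} < 0")
        lo, hi = self.channel_load_range
        if lo <= 0 or hi < lo:
            raise ConfigError("channel_load_range", f"{self.channel_load_range} invalid")
        if self.mixture_concentration <= 2:
            raise ConfigError("mixture_concentration", "must exceed 2 for an interior mode")
        if self.frac_age_up + self.frac_age_down > 1:
            raise ConfigError("frac_age_up", "frac_age_up + frac_age_down > 1")
        if self.n_driven_sites < 0:
            raise ConfigError("n_driven_sites", "negative")
        # small cohorts cannot host more driven sites than they have
        self.n_driven_sites = min(self.n_driven_sites, self.n_sites)

    @property
    def group_labels(self) -> tuple[str, ...]:
        if self.n_groups == 3:
            return GROUP_LABELS_3
        return tuple(f"g{i}" for i in range(self.n_groups))

    @property
    def group_short(self) -> tuple[str, ...]:
        if self.n_groups == 3:
            return GROUP_SHORT_3
        return tuple(f"G{i}" for i in range(self.n_groups))

    @property
    def location_labels(self) -> tuple[str, ...]:
        return tuple("AD"[i] if i < 2 else f"L{i}" for i in range(self.n_locations))


@dataclass
class CohortTruth:
    """Ground truth for every simulated entity."""

    sites: pd.DataFrame        # per site: protein, position, component, theta_base, age_class, driven
    theta: pd.DataFrame        # site x sample true Sto occupancy
    metabolites: pd.DataFrame  # per metabolite: mode, klass, slope
    samples: pd.DataFrame      # per sample: group, location, animal, stress (latent factor)


@dataclass
class CohortBundle:
    """Everything `generate_cohort` produces."""

    config: CohortConfig
    design: pd.DataFrame                   # sample -> group, location, animal
    sites: ReporterSiteTable
    proteins: pd.DataFrame                 # protein x (channel, sample) unenriched quant
    metabolites: dict[str, MetaboliteTable]
    sequences: dict[str, str]
    truth: CohortTruth


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """One independent generator per output block, all derived from `seed`.

    Separate streams keep blocks decoupled: toggling noise or dropout
    does not shift the draws of sites, sequences or metabolites.
    """
    base = np.random.SeedSequence(seed)
    names = ["design", "sites", "sequences", "intensity", "proteins",
             "metabolites", "dropout"]
    children = base.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _make_design(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for gi, g in enumerate(cfg.group_labels):
        for a in range(1, cfg.n_per_cell + 1):
            for loc in cfg.location_labels:
                sid = f"{cfg.group_short[gi]}{a}{loc}"
                rows.append((sid, g, loc, a, gi))
    df = pd.DataFrame(rows, columns=["sample", "group", "location", "animal", "group_index"])
    df = df.set_index("sample")
    center = (cfg.n_groups - 1) / 2.0
    df["stress"] = df["group_index"] - center + rng.normal(0.0, cfg.stress_sd, len(df))
    return df


def _simulate_sites(cfg: CohortConfig, rng: np.random.Generator,
                    design: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Site truth table, true theta matrix, per-site sub-mod fractions."""
    n = cfg.n_sites
    component = (rng.random(n) >= cfg.mixture_weight).astype(int)  # 0 = low mode
    theta_base = np.empty(n)
    for k, mode in enumerate(cfg.mixture_modes):
        a, b = _beta_params_from_mode(mode, cfg.mixture_concentration)
        idx = component == k
        theta_base[idx] = rng.beta(a, b, idx.sum())

    age_class = np.full(n, "none", dtype=object)
    n_up = int(round(cfg.frac_age_up * n))
    n_down = int(round(cfg.frac_age_down * n))
    order = rng.permutation(n)
    age_class[order[:n_up]] = "up"
    age_class[order[n_up:n_up + n_down]] = "down"

    driven = np.zeros(n, dtype=bool)
    none_idx = np.flatnonzero(age_class == "none")
    driven[rng.choice(none_idx, size=min(cfg.n_driven_sites, len(none_idx)),
                      replace=False)] = True

    # Sub-modification fractions of the oxidized pool; SSG dominates.
    c_ssg = rng.uniform(0.04, 0.12, n)
    c_soh = rng.uniform(0.01, 0.03, n)
    c_sno = rng.uniform(0.015, 0.04, n)

    protein_idx = rng.integers(0, cfg.n_proteins, n) if cfg.n_proteins else np.zeros(n, int)

    sites = pd.DataFrame({
        "protein": [f"P{j:05d}" for j in protein_idx],
        "component": component,
        "theta_base": theta_base,
        "age_class": age_class,
        "driven": driven,
        "c_SSG": c_ssg,
        "c_SOH": c_soh,
        "c_SNO": c_sno,
    }, index=pd.Index([f"site{i:05d}" for i in range(n)], name="site_id"))

    # True per-sample occupancy: base + monotone age shift + latent coupling.
    gidx = design["group_index"].to_numpy()
    shift_unit = gidx / max(cfg.n_groups - 1, 1)       # 0 .. 1 across groups
    sign = np.where(age_class == "up", 1.0, np.where(age_class == "down", -1.0, 0.0))
    theta = (theta_base[:, None]
             + cfg.age_effect * sign[:, None] * shift_unit[None, :]
             + cfg.driven_effect * driven[:, None].astype(float)
             * design["stress"].to_numpy()[None, :])
    theta = np.clip(theta, 0.02, 0.98)
    theta_df = pd.DataFrame(theta, index=sites.index, columns=design.index)
    return sites, theta_df, sites[["c_SSG", "c_SOH", "c_SNO"]]


def _mult_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean log-normal multiplicative noise with the given CV."""
    if cv <= 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, shape))


def _simulate_reporters(cfg: CohortConfig, rng: np.random.Generator,
                        rng_drop: np.random.Generator,
                        sites: pd.DataFrame, theta: pd.DataFrame,
                        loads: pd.DataFrame) -> pd.DataFrame:
    n, m = theta.shape
    # persistent per-site base intensity + per-sample deviation, so the
    # same peptide is bright (or dim) in every plex, as in real data
    site_base = rng.normal(cfg.log10_intensity_mean, cfg.log10_intensity_sd, n)
    total = 10.0 ** (site_base[:, None]
                     + rng.normal(0.0, cfg.log10_intensity_within_sd, (n, m)))
    th = theta.to_numpy()
    frac = {
        "Sto": th,
        "SH": 1.0 - th,
        "SSG": th * sites["c_SSG"].to_numpy()[:, None],
        "SOH": th * sites["c_SOH"].to_numpy()[:, None],
        "SNO": th * sites["c_SNO"].to_numpy()[:, None],
        REF_STATE: np.ones_like(th),
    }
    blocks = {}
    for ch in CHANNELS:
        eps = _mult_noise(rng, cfg.noise_cv, (n, m))
        intens = total * frac[ch] * loads.loc[ch].to_numpy()[None, :] * eps
        if cfg.dropout_midpoint is not None:
            with np.errstate(divide="ignore"):
                logi = np.log10(np.where(intens > 0, intens, np.nan))
            p_detect = 1.0 / (1.0 + np.exp(-cfg.dropout_steepness
                                           * (logi - cfg.dropout_midpoint)))
            detected = rng_drop.random((n, m)) < p_detect
            intens = np.where(detected, intens, np.nan)
        blocks[ch] = intens
    cols = pd.MultiIndex.from_product([list(CHANNELS), list(theta.columns)],
                                      names=["state", "sample"])
    data = np.concatenate([blocks[ch] for ch in CHANNELS], axis=1)
    return pd.DataFrame(data, index=theta.index, columns=cols)


def _simulate_protein_quant(cfg: CohortConfig, rng: np.random.Generator,
                            design: pd.DataFrame, loads: pd.DataFrame) -> pd.DataFrame:
    """Unenriched-aliquot protein quant per plex channel (for channel ratios)."""
    n = cfg.n_proteins
    base = 10.0 ** rng.normal(6.5, 0.6, n)
    cols = pd.MultiIndex.from_product([list(CHANNELS), list(design.index)],
                                      names=["state", "sample"])
    data = np.empty((n, len(cols)))
    for j, (ch, s) in enumerate(cols):
        eps = _mult_noise(rng, 0.05, n)
        data[:, j] = base * loads.loc[ch, s] * eps
    return pd.DataFrame(data, columns=cols,
                        index=pd.Index([f"P{j:05d}" for j in range(n)], name="protein"))


def _simulate_metabolites(cfg: CohortConfig, rng: np.random.Generator,
                          design: pd.DataFrame) -> tuple[dict[str, MetaboliteTable], pd.DataFrame]:
    n = cfg.n_metabolites
    n_sup = int(round(cfg.frac_metab_suppressor * n))
    n_pro = int(round(cfg.frac_metab_promoter * n))
    klass = np.full(n, "uncoupled", dtype=object)
    order = rng.permutation(n)
    klass[order[:n_sup]] = "suppressor"
    klass[order[n_sup:n_sup + n_pro]] = "promoter"
    slope = np.where(klass == "suppressor", -cfg.metab_slope,
                     np.where(klass == "promoter", cfg.metab_slope, 0.0))

    z = design["stress"].to_numpy()
    # Coupled metabolites sit in the low-abundance tail so that sample
    # totals (hence correction factors) stay decoupled from the latent
    # factor; injection variation is what the correction factor removes.
    baseline = np.where(klass == "uncoupled", rng.normal(20.0, 1.0, n),
                        rng.normal(17.0, 1.0, n))
    log2v = (baseline[:, None] + slope[:, None] * z[None, :]
             + rng.normal(0.0, cfg.metab_noise_sd, (n, len(z))))
    values = 2.0 ** log2v

    conc = pd.Series(np.clip(rng.normal(1.0, 0.05, len(design)), 0.5, None),
                     index=design.index, name="protein_concentration")
    injection = _mult_noise(rng, 0.15, len(design))
    values = values * (conc.to_numpy() * injection)[None, :]  # undone by normalization

    noisy = rng.random(n) < cfg.frac_qc_noisy
    qc_mean = 2.0 ** baseline
    qc = np.empty((n, cfg.n_qc))
    for i in range(n):
        cv = cfg.noisy_qc_cv if noisy[i] else cfg.qc_cv
        qc[i] = qc_mean[i] * _mult_noise(rng, cv, cfg.n_qc)

    mode = np.where(np.arange(n) % 2 == 0, "pos", "neg")
    ids = pd.Index([f"{mode[i]}_M{i:04d}" for i in range(n)], name="metabolite_id")
    truth = pd.DataFrame({"mode": mode, "klass": klass, "slope": slope,
                          "qc_noisy": noisy}, index=ids)

    tables = {}
    for md in ("pos", "neg"):
        mask = mode == md
        tables[md] = MetaboliteTable(
            values=pd.DataFrame(values[mask], index=ids[mask], columns=design.index),
            qc=pd.DataFrame(qc[mask], index=ids[mask],
                            columns=[f"QC_{r + 1}" for r in range(cfg.n_qc)]),
            protein_concentration=conc,
            mode=md,
        )
    return tables, truth


def _simulate_sequences(cfg: CohortConfig, rng: np.random.Generator,
                        sites: pd.DataFrame) -> tuple[dict[str, str], pd.Series]:
    """Protein sequences with a C at every site position.

    Low-mode sites optionally carry a planted residue enrichment at a
    fixed flank offset (default K at -1), which the motif stage should
    recover in the low-occupancy region.
    """
    lengths = rng.integers(200, 601, cfg.n_proteins)
    seqs = {f"P{j:05d}": rng.choice(_AA, size=L, p=_AA_P)
            for j, L in enumerate(lengths)}

    positions = pd.Series(0, index=sites.index, dtype=int)
    used: dict[str, set[int]] = {}
    for sid, row in sites.iterrows():
        acc = row["protein"]
        L = len(seqs[acc])
        taken = used.setdefault(acc, set())
        pos = int(rng.integers(2, L))  # 1-based, leave room for a -1 neighbour
        while pos in taken:
            pos = int(rng.integers(2, L))
        taken.add(pos)
        positions[sid] = pos
        seqs[acc][pos - 1] = "C"
        if (row["component"] == 0 and cfg.motif_prob > 0
                and rng.random() < cfg.motif_prob):
            off = pos - 1 + cfg.motif_position
            if 0 <= off < L and (off + 1) not in taken:
                seqs[acc][off] = cfg.motif_residue
    return {acc: "".join(s) for acc, s in seqs.items()}, positions


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate the full synthetic cohort; deterministic given the seed."""
    rngs = _streams(config.seed)
    design = _make_design(config, rngs["design"])
    sites, theta, _ = _simulate_sites(config, rngs["sites"], design)
    sequences, positions = _simulate_sequences(config, rngs["sequences"], sites)
    sites = sites.assign(position=positions)

    lo, hi = config.channel_load_range
    if lo == hi == 1.0:
        loads = pd.DataFrame(1.0, index=list(CHANNELS), columns=design.index)
    else:
        loads = pd.DataFrame(
            rngs["intensity"].uniform(lo, hi, (len(CHANNELS), len(design))),
            index=list(CHANNELS), columns=design.index)

    intens = _simulate_reporters(config, rngs["intensity"], rngs["dropout"],
                                 sites, theta, loads)
    proteins = _simulate_protein_quant(config, rngs["proteins"], design, loads)
    metabolites, metab_truth = _simulate_metabolites(config, rngs["metabolites"], design)

    meta = pd.DataFrame({
        "protein": sites["protein"],
        "position": sites["position"],
        "localization_prob": 1.0,
    }, index=sites.index)
    site_table = ReporterSiteTable(meta=meta, intensities=intens,
                                   filter_log={"input_rows": len(meta),
                                               "retained": len(meta)})
    truth = CohortTruth(sites=sites, theta=theta, metabolites=metab_truth,
                        samples=design[["group", "location", "animal", "stress"]])
    return CohortBundle(config=config, design=design, sites=site_table,
                        proteins=proteins, metabolites=metabolites,
                        sequences=sequences, truth=truth)


# --------------------------------------------------------------------------
# Fixture writing (MaxQuant-dialect TSVs + FASTA + truth tables)

SITE_COLUMNS = ["Site ID", "Protein", "Position", "Localization prob",
                "Reverse", "Potential contaminant"]


def _intensity_columns(intensities: pd.DataFrame) -> list[str]:
    return [f"intensity.{st}.{sm}" for st, sm in intensities.columns]


def write_fixture(bundle: CohortBundle, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as the plain-text files `ingest` consumes.

    Missing reporter intensities are written as 0 (the MaxQuant
    convention); ingest converts zeros back to missing, so the intensity
    matrix round-trips exactly.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sites = bundle.sites
    out = pd.DataFrame({
        "Site ID": sites.meta.index,
        "Protein": sites.meta["protein"].to_numpy() if len(sites.meta) else [],
        "Position": sites.meta["position"].to_numpy() if len(sites.meta) else [],
        "Localization prob": sites.meta["localization_prob"].to_numpy() if len(sites.meta) else [],
        "Reverse": "-",
        "Potential contaminant": "-",
    })
    intens = sites.intensities.fillna(0.0)
    intens.columns = _intensity_columns(sites.intensities)
    out = pd.concat([out.reset_index(drop=True), intens.reset_index(drop=True)], axis=1)
    if len(out) == 0:  # degenerate bundle: headers only
        out = out.reindex(columns=SITE_COLUMNS + list(intens.columns))
    paths["sites"] = d / "redox_sites.txt"
    out.to_csv(paths["sites"], sep="\t", index=False)

    prot = bundle.proteins.copy()
    prot.columns = _intensity_columns(bundle.proteins)
    prot.insert(0, "Reverse", "-")
    prot.insert(1, "Potential contaminant", "-")
    paths["proteins"] = d / "protein_quant.txt"
    prot.to_csv(paths["proteins"], sep="\t", index=True, index_label="Protein IDs")

    for mode, table in bundle.metabolites.items():
        block = pd.concat([table.values, table.qc], axis=1)
        conc_row = pd.Series(np.nan, index=block.columns, name="protein_concentration")
        conc_row[table.values.columns] = table.protein_concentration[table.values.columns]
        block = pd.concat([block, conc_row.to_frame().T])
        block.index.name = "metabolite_id"
        paths[f"metabolites_{mode}"] = d / f"metabolites_{mode}.tsv"
        block.to_csv(paths[f"metabolites_{mode}"], sep="\t")

    paths["fasta"] = d / "proteins.fasta"
    with open(paths["fasta"], "w") as fh:
        for acc, seq in bundle.sequences.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")

    paths["design"] = d / "design.tsv"
    bundle.design.to_csv(paths["design"], sep="\t")
    paths["truth_sites"] = d / "truth_sites.tsv"
    bundle.truth.sites.to_csv(paths["truth_sites"], sep="\t")
    paths["truth_theta"] = d / "truth_theta.tsv"
    bundle.truth.theta.to_csv(paths["truth_theta"], sep="\t")
    paths["truth_metabolites"] = d / "truth_metabolites.tsv"
    bundle.truth.metabolites.to_csv(paths["truth_metabolites"], sep="\t")
    paths["truth_samples"] = d / "truth_samples.tsv"
    bundle.truth.samples.to_csv(paths["truth_samples"], sep="\t")

    cfg = asdict(bundle.config)
    paths["config"] = d / "cohort_config.yaml"
    import yaml
    with open(paths["config"], "w") as fh:
        yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in cfg.items()}, fh, sort_keys=True)
    return paths
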