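"""End-to-end orchestration: simulate -> ingest -> normalize -> stoichiometry
-> differential -> crosstalk -> motif, with a provenance manifest.

The pipeline is deliberately file-based: every stage writes plain TSVs
into the output directory and the manifest records the config hash,
seed, package version and per-stage row counts, so a rerun with the
same config is byte-comparable.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, io, normalize, stoichiometry, differential, crosstalk, motif
from .errors import ConfigError
from .simulate import CohortConfig, generate_cohort, write_fixture

_THRESHOLD_RANGES = {
    "loc_prob": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "rho_min": (0.0, 1.0),
    "cv_max": (0.0, float("inf")),
    "delta_min": (0.0, 1.0),
    "min_detect_frac": (0.0, 1.0),
    "min_frac": (0.0, 1.0),
}

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "loc_prob": 0.75,
    "min_n": 3,
    "alpha": 0.05,
    "rho_min": 0.6,
    "p_max": 0.05,
    "log2fc": 0.263,
    "cv_max": 0.3,
    "delta_min": 0.10,
    "flank": 10,
    "k": 50,
    "min_frac": 0.5,
    "min_detect_frac": 0.5,
    "min_pairs": 8,
    "stratify_location": False,
    "young_group": "young",
    "old_group": "old",
    "cohort": {},          # overrides for CohortConfig when simulating
    "simulate": True,
    "input_dir": None,     # used when simulate is false
    "out_dir": "redoxmap_out",
}


@dataclasses.dataclass
class RunConfig:
    """Validated flat run configuration (one section per stage threshold)."""

    params: dict[str, Any]

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - set(_DEFAULTS)
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration key")
        params = dict(_DEFAULTS)
        params.update(raw)
        for key, (lo, hi) in _THRESHOLD_RANGES.items():
            v = params[key]
            if not (lo <= v <= hi):
                raise ConfigError(key, f"{v} outside [{lo}, {hi}]")
        for key in ("min_n", "flank", "k", "min_pairs"):
            if int(params[key]) < 1:
                raise ConfigError(key, "must be >= 1")
        return cls(params=params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def __getitem__(self, key: str) -> Any:
        return self.params[key]

    def sha256(self) -> str:
        canonical = json.dumps(self.params, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages in dependency order; returns the manifest."""
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.sha256(),
        "seed": config["seed"],
        "stages": {},
    }

    try:
        _run_stages(config, out, manifest)
    except Exception:
        (out / "manifest.failed").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str,
                                                  sort_keys=True))
    return manifest


def _run_stages(config: RunConfig, out: Path, manifest: dict[str, Any]) -> None:
    if config["simulate"]:
        cohort_kwargs = dict(config["cohort"])
        cohort_kwargs.setdefault("seed", config["seed"])
        if "mixture_modes" in cohort_kwargs:
            cohort_kwargs["mixture_modes"] = tuple(cohort_kwargs["mixture_modes"])
        if "channel_load_range" in cohort_kwargs:
            cohort_kwargs["channel_load_range"] = tuple(cohort_kwargs["channel_load_range"])
        bundle = generate_cohort(CohortConfig(**cohort_kwargs))
        input_dir = out / "fixture"
        write_fixture(bundle, input_dir)
        manifest["stages"]["simulate"] = {"n_sites": len(bundle.sites.meta),
                                          "n_samples": len(bundle.design)}
    else:
        if config["input_dir"] is None:
            raise ConfigError("input_dir", "required when simulate is false")
        input_dir = Path(config["input_dir"])
        for fname in ("redox_sites.txt", "protein_quant.txt", "design.tsv"):
            if not (input_dir / fname).exists():
                raise FileNotFoundError(f"missing input file: {input_dir / fname}")

    sites = io.read_site_table(input_dir / "redox_sites.txt",
                               loc_prob_threshold=config["loc_prob"])
    proteins = io.read_protein_table(input_dir / "protein_quant.txt")
    design = pd.read_csv(input_dir / "design.tsv", sep="\t", index_col=0)
    manifest["stages"]["ingest"] = dict(sites.filter_log)

    ratios = normalize.compute_channel_ratios(proteins)
    norm = normalize.normalize_redox(sites, ratios)
    manifest["stages"]["normalize"] = {"n_channels": int(ratios.size)}

    occ = stoichiometry.compute_occupancy(norm)
    # Pooled ("All") medians drive regions and transitions; a stratified
    # table is written alongside when requested.
    medians, counts = stoichiometry.group_median_occupancy(
        occ, design, min_n=config["min_n"], stratify_location=False)
    if config["stratify_location"]:
        strat, _ = stoichiometry.group_median_occupancy(
            occ, design, min_n=config["min_n"], stratify_location=True)
        strat.columns = [f"{st}.{g}" for st, g in strat.columns]
        strat.to_csv(out / "group_median_occupancy_by_location.tsv", sep="\t")
    med_out = medians.copy()
    med_out.columns = [f"{st}.{g}" for st, g in med_out.columns]
    med_out.to_csv(out / "group_median_occupancy.tsv", sep="\t")

    young, old = config["young_group"], config["old_group"]
    sto_med = medians["Sto"]
    models, regions = {}, {}
    for grp in (young, old):
        models[grp] = stoichiometry.fit_region_model(sto_med[grp], group=grp)
        regions[grp] = stoichiometry.assign_regions(sto_med[grp], models[grp])
    report = stoichiometry.count_transitions(
        sto_med[young], regions[young], sto_med[old], regions[old],
        delta_min=config["delta_min"])
    pd.DataFrame({
        "young_region": regions[young], "old_region": regions[old],
        "young_median": sto_med[young], "old_median": sto_med[old],
        "delta": report.delta,
    }).to_csv(out / "regions.tsv", sep="\t")
    manifest["stages"]["stoichiometry"] = {
        "peaks": {g: [models[g].peak_low, models[g].peak_high] for g in models},
        "valley": {g: models[g].valley for g in models},
        "n_y1_to_o2": report.n_y1_to_o2,
        "n_y2_to_o1": report.n_y2_to_o1,
        "n_y1_to_o2_gt_delta": report.n_y1_to_o2_gt_delta,
        "n_y2_to_o1_gt_delta": report.n_y2_to_o1_gt_delta,
    }

    contrib = stoichiometry.modification_contribution(
        medians.xs(old, level="group", axis=1))
    contrib.to_csv(out / "modification_contribution.tsv", sep="\t")

    levels = norm.level("Sto")
    diff = differential.screen_three_group(
        levels, design, alpha=config["alpha"], min_n=config["min_n"],
        min_frac=config["min_frac"], group_order=list(dict.fromkeys(design["group"])))
    diff.to_csv(out / "differential_sto.tsv", sep="\t")
    manifest["stages"]["differential"] = {
        "n_anova": int((diff["rule"] == "anova").sum()),
        "n_presence": int((diff["rule"] == "presence").sum()),
        "n_significant": int(diff["significant"].sum()),
    }

    metab_tables = []
    for mode in ("pos", "neg"):
        p = input_dir / f"metabolites_{mode}.tsv"
        if p.exists():
            metab_tables.append(io.read_metabolite_table(p, mode))
    if metab_tables:
        metab = normalize.normalize_metabolome(metab_tables, cv_max=config["cv_max"])
        metab.to_csv(out / "metabolites_normalized.tsv", sep="\t")
        age_related = crosstalk.select_age_related_features(
            metab, design, alpha=config["alpha"], min_n=config["min_n"],
            group_order=list(dict.fromkeys(design["group"])))
        diff_sites = diff.index[diff["significant"]]
        pairs = crosstalk.spearman_pairs(
            levels.loc[levels.index.intersection(diff_sites)],
            metab.loc[age_related],
            p_max=config["p_max"], rho_min=config["rho_min"],
            min_pairs=config["min_pairs"])
        tally = crosstalk.tally_features(pairs)
        pairs.to_csv(out / "crosstalk_pairs.tsv", sep="\t", index=False)
        tally.to_csv(out / "crosstalk_tally.tsv", sep="\t")
        manifest["stages"]["crosstalk"] = {
            "n_age_related_metabolites": int(len(age_related)),
            "n_pairs": int(len(pairs)),
            "n_suppressor": int((tally["call"] == "suppressor_candidate").sum()),
            "n_promoter": int((tally["call"] == "promoter_candidate").sum()),
        }

    fasta = input_dir / "proteins.fasta"
    if fasta.exists():
        seqs = io.read_fasta(fasta)
        site_meta = sites.meta.copy()
        site_meta["region"] = regions[young].reindex(site_meta.index)
        with_region = site_meta.dropna(subset=["region"])
        windows = motif.extract_windows(seqs, with_region, flank=config["flank"])
        for region in (1, 2):
            sel = windows[windows["region"] == region]
            if len(sel):
                mat = motif.position_frequencies(sel["window"], flank=config["flank"])
                mat.to_csv(out / f"motif_region{region}.tsv", sep="\t")
        manifest["stages"]["motif"] = {"n_windows": int(len(windows))}
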