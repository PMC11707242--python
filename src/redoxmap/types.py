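"""Core in-memory containers.

All tables are thin wrappers around pandas objects. Reporter intensities
live in a wide DataFrame whose columns are a (state, sample) MultiIndex;
``NaN`` always means "not quantified". Redox states follow the TMT-6plex
channel layout of the assay: five states of each biological sample plus a
fully reduced common reference (``REF``) that bridges plexes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Redox states measured per sample. ``Sto`` is total oxidation (TCEP-
#: reducible), ``SH`` the free thiol, the rest selectively reduced
#: sub-modifications (arsenite/ascorbate/Grx chemistry upstream).
STATES: tuple[str, ...] = ("Sto", "SH", "SOH", "SNO", "SSG")

#: Reversible sub-modifications contributing to total oxidation.
MOD_STATES: tuple[str, ...] = ("SSG", "SOH", "SNO")

#: The common reference channel (fully reduced pooled sample).
REF_STATE: str = "REF"

#: All reporter channels of one plex.
CHANNELS: tuple[str, ...] = STATES + (REF_STATE,)


def _check_channel_frame(intensities: pd.DataFrame) -> None:
    if not isinstance(intensities.columns, pd.MultiIndex) or intensities.columns.nlevels != 2:
        raise ValueError("intensities must have a (state, sample) column MultiIndex")


@dataclass
class ReporterSiteTable:
    """Per-Cys-site reporter intensities across samples and redox states.

    Attributes
    ----------
    meta:
        One row per site (index = site id) with ``protein``, ``position``
        (1-based within the protein sequence) and ``localization_prob``.
    intensities:
        Wide matrix indexed like ``meta`` with (state, sample) columns.
        Zero reporter intensity is represented as missing (``NaN``).
    filter_log:
        Row-accounting from ingest: input_rows, reverse, contaminant,
        localization, retained.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_channel_frame(self.intensities)
        if not self.meta.index.equals(self.intensities.index):
            raise ValueError("meta and intensities must share an index")

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns.get_level_values(1).unique())

    @property
    def states(self) -> list[str]:
        return list(self.intensities.columns.get_level_values(0).unique())

    def state(self, state: str) -> pd.DataFrame:
        """Site x sample matrix for one redox state."""
        return self.intensities[state]


@dataclass
class NormalizedRedoxTable:
    """Channel-corrected reporter intensities and per-site reference ratios.

    ``normalized`` is raw intensity divided by the plex/channel total
    protein ratio; ``reference_ratio`` additionally divides by the same
    site's normalized reference-channel intensity (the "Sto level" used
    for differential and crosstalk analyses).
    """

    normalized: pd.DataFrame
    reference_ratio: pd.DataFrame

    def __post_init__(self) -> None:
        _check_channel_frame(self.normalized)
        _check_channel_frame(self.reference_ratio)

    def state(self, state: str) -> pd.DataFrame:
        return self.normalized[state]

    def level(self, state: str) -> pd.DataFrame:
        """Reference-ratio matrix ("levels") for one state."""
        return self.reference_ratio[state]


@dataclass
class OccupancyTable:
    """Per site x sample x state occupancy in [0, 1].

    occ_m = I_m / (I_Sto + I_SH); missing wherever Sto or SH is missing.
    ``raw`` keeps the unclamped ratios; ``clamped`` marks cells where the
    ratio exceeded 1 and was clamped.
    """

    occupancy: pd.DataFrame
    raw: pd.DataFrame
    clamped: pd.DataFrame

    def __post_init__(self) -> None:
        _check_channel_frame(self.occupancy)

    def state(self, state: str) -> pd.DataFrame:
        return self.occupancy[state]


@dataclass
class MetaboliteTable:
    """Untargeted metabolomics intensities for one ion mode.

    ``values``: metabolite x sample intensities; ``qc``: metabolite x QC
    replicate intensities from the pooled QC injections;
    ``protein_concentration``: per-sample tissue protein concentration
    used for abundance normalization.
    """

    values: pd.DataFrame
    qc: pd.DataFrame
    protein_concentration: pd.Series
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("pos", "neg"):
            raise ValueError(f"unknown ion mode: {self.mode!r}")
        missing = [s for s in self.values.columns if s not in self.protein_concentration.index]
        if missing:
            raise ValueError(f"missing protein concentration for samples: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)
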