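"""Normalization identities for the three data layers and QC correlations."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from redoxmap import normalize as nm
from redoxmap.errors import NormalizationError, ValidationError
from redoxmap.types import MetaboliteTable


def _protein_frame(channel_sums, sample="s1"):
    """Single-protein table whose channel sums are the given values."""
    cols = pd.MultiIndex.from_tuples([(ch, sample) for ch in channel_sums],
                                     names=["state", "sample"])
    return pd.DataFrame([list(channel_sums.values())], columns=cols,
                        index=pd.Index(["P1"], name="protein"))


def test_channel_ratios_forced_arithmetic():
    ratios = nm.compute_channel_ratios(_protein_frame({"REF": 100.0, "A": 200.0, "B": 50.0}))
    assert ratios.loc["REF", "s1"] == 1.0
    assert ratios.loc["A", "s1"] == 2.0
    assert ratios.loc["B", "s1"] == 0.5


def test_channel_ratios_identity_and_zero_reference():
    ratios = nm.compute_channel_ratios(_protein_frame({"REF": 7.0, "A": 7.0}))
    assert (ratios == 1.0).all().all()
    with pytest.raises(NormalizationError):
        nm.compute_channel_ratios(_protein_frame({"REF": 0.0, "A": 5.0}))


def _site_frame(values, sample="s1"):
    cols = pd.MultiIndex.from_tuples([(ch, sample) for ch in values],
                                     names=["state", "sample"])
    return pd.DataFrame([list(values.values())], columns=cols,
                        index=pd.Index(["site1"], name="site_id"))


def test_normalize_redox_forced_arithmetic():
    intens = _site_frame({"Sto": 60.0, "REF": 30.0})
    ratios = pd.DataFrame({"s1": [2.0, 2.0]}, index=["Sto", "REF"])
    out = nm.normalize_redox(intens, ratios)
    assert out.normalized.loc["site1", ("Sto", "s1")] == 30.0
    assert out.normalized.loc["site1", ("REF", "s1")] == 15.0
    assert out.reference_ratio.loc["site1", ("Sto", "s1")] == 2.0
    assert out.reference_ratio.loc["site1", ("REF", "s1")] == 1.0


def test_normalize_redox_unit_ratios_identity(small_cohort):
    intens = small_cohort.sites.intensities
    samples = intens.columns.get_level_values(1).unique()
    states = intens.columns.get_level_values(0).unique()
    ratios = pd.DataFrame(1.0, index=states, columns=samples)
    out = nm.normalize_redox(intens, ratios)
    pd.testing.assert_frame_equal(out.normalized, intens, check_exact=True)


def test_missing_reference_keeps_normalized_intensity():
    intens = _site_frame({"Sto": 60.0, "REF": np.nan})
    ratios = pd.DataFrame({"s1": [1.0, 1.0]}, index=["Sto", "REF"])
    out = nm.normalize_redox(intens, ratios)
    assert out.normalized.loc["site1", ("Sto", "s1")] == 60.0
    assert pd.isna(out.reference_ratio.loc["site1", ("Sto", "s1")])


def test_unmapped_channel_errors():
    intens = _site_frame({"Sto": 60.0, "REF": 30.0})
    ratios = pd.DataFrame({"s1": [1.0]}, index=["REF"])
    with pytest.raises(NormalizationError, match="Sto"):
        nm.normalize_redox(intens, ratios)


def test_channel_normalization_equalizes_totals(small_cohort):
    """After division by channel ratios, every channel's protein total
    equals the reference total (exact on complete data)."""
    prot = small_cohort.proteins
    ratios = nm.compute_channel_ratios(prot)
    sums = prot.sum(axis=0).unstack(level="sample")
    normalized_sums = sums / ratios
    ref = normalized_sums.loc["REF"]
    for ch in normalized_sums.index:
        assert np.allclose(normalized_sums.loc[ch], ref, rtol=1e-12)


# --- proteome ---------------------------------------------------------------

def _peptide_table():
    return pd.DataFrame({
        "protein": ["A", "A", "A", "B", "C", "C"],
        "unique": [True, True, False, True, True, True],
        "s1": [10.0, 20.0, 99.0, 5.0, 8.0, 2.0],
        "s2": [12.0, 18.0, 99.0, 6.0, 10.0, 4.0],
    }, index=[f"pep{i}" for i in range(6)])


def test_min_unique_peptides_rule():
    """A protein backed by a single unique peptide is dropped."""
    agg = nm.aggregate_unique_peptides(_peptide_table(), ["s1", "s2"], min_unique=2)
    assert "B" not in agg.index           # one unique peptide
    assert agg.loc["A", "s1"] == 30.0     # 10 + 20, non-unique excluded
    assert agg.loc["C", "s2"] == 14.0


def test_proteome_totals_equalized():
    out = nm.normalize_proteome(_peptide_table(), log2=False)
    totals = out.sum(axis=0, skipna=True)
    assert np.allclose(totals, totals.mean(), rtol=1e-9)


def test_proteome_detection_fraction_filter():
    pep = _peptide_table()
    pep.loc["pep4", "s2"] = 0.0   # zero -> missing; C detected in 1/2 samples only
    pep.loc["pep5", "s2"] = 0.0
    out = nm.normalize_proteome(pep, min_detect_frac=0.6)
    assert "C" not in out.index
    assert "A" in out.index


def test_no_unique_peptides_warns_empty():
    pep = _peptide_table()
    pep["unique"] = False
    with pytest.warns(UserWarning, match="unique"):
        out = nm.normalize_proteome(pep)
    assert out.empty


# --- metabolome -------------------------------------------------------------

def _metab_table(values, qc, conc, mode="pos", ids=None):
    ids = ids or [f"m{i}" for i in range(len(values))]
    samples = [f"s{j}" for j in range(len(values[0]))]
    return MetaboliteTable(
        values=pd.DataFrame(values, index=ids, columns=samples),
        qc=pd.DataFrame(qc, index=ids,
                        columns=[f"QC_{r}" for r in range(len(qc[0]))]),
        protein_concentration=pd.Series(conc, index=samples),
        mode=mode)


def test_metabolome_cv_filter_forced_arithmetic():
    """CV 0 is kept; QC [100,200,300] has sd/mean = 0.5 >= 0.3 and is excluded."""
    t = _metab_table([[10.0, 10.0], [10.0, 10.0]],
                     [[100, 100, 100], [100, 200, 300]], [1.0, 1.0])
    out = nm.normalize_metabolome([t])
    assert list(out.index) == ["m0"]


def test_metabolome_correction_factor_forced_arithmetic():
    """Totals [100, 300] -> factors [0.5, 1.5]; post-division totals equal."""
    t = _metab_table([[100.0, 300.0]], [[50, 50, 50]], [1.0, 1.0])
    out = nm.normalize_metabolome([t])
    assert out.loc["m0", "s0"] == 200.0
    assert out.loc["m0", "s1"] == 200.0


def test_metabolome_unit_concentration_is_identity():
    vals = [[100.0, 100.0], [300.0, 300.0]]
    t = _metab_table(vals, [[1, 1, 1], [1, 1, 1]], [1.0, 1.0])
    out = nm.normalize_metabolome([t])
    # equal sample totals -> correction factors 1; conc 1 -> untouched
    assert np.allclose(out.to_numpy(), vals)


def test_metabolome_per_sample_totals_equal_within_mode(small_cohort):
    out = nm.normalize_metabolome([small_cohort.metabolites["pos"]])
    totals = out.sum(axis=0, skipna=True)
    assert np.allclose(totals, totals.mean(), rtol=1e-9)


def test_metabolome_zero_qc_mean_warns():
    t = _metab_table([[10.0, 10.0]], [[0, 0, 0]], [1.0, 1.0])
    with pytest.warns(UserWarning, match="zero QC mean"):
        out = nm.normalize_metabolome([t])
    assert out.empty


# --- QC correlation ---------------------------------------------------------

def test_qc_correlation_duplicate_and_inverted_columns():
    rng = np.random.default_rng(0)
    x = rng.normal(size=40)
    m = pd.DataFrame({"a": x, "b": x, "c": -x})
    corr = nm.qc_correlation(m, "pearson")
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert corr.loc["a", "c"] == pytest.approx(-1.0)
    assert (np.diag(corr) == 1.0).all()


def test_spearman_qc_matches_rank_brute_force():
    """Rank-transform by hand, then Pearson: must match to 1e-12."""
    rng = np.random.default_rng(42)
    m = pd.DataFrame(rng.normal(size=(50, 6)), columns=list("abcdef"))
    ours = nm.qc_correlation(m, "spearman")
    ranks = m.apply(lambda c: stats.rankdata(c))
    brute = np.corrcoef(ranks.to_numpy().T)
    assert np.allclose(ours.to_numpy(), brute, atol=1e-12)


def test_qc_correlation_constant_column_warns():
    m = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0]})
    with pytest.warns(UserWarning, match="constant"):
        corr = nm.qc_correlation(m, "pearson")
    assert pd.isna(corr.loc["a", "b"])


def test_qc_correlation_needs_two_samples():
    with pytest.raises(ValidationError):
        nm.qc_correlation(pd.DataFrame({"a": [1.0, 2.0]}), "pearson")
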