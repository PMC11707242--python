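"""Occupancy arithmetic, density regions, transitions, contributions."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from redoxmap import stoichiometry as st
from redoxmap.errors import DegenerateValuesError, UnimodalDensityError, ValidationError


def _intensity_frame(rows, sample="s1"):
    """rows: {site_id: {state: value}}"""
    states = sorted({s for v in rows.values() for s in v})
    cols = pd.MultiIndex.from_tuples([(s, sample) for s in states],
                                     names=["state", "sample"])
    return pd.DataFrame([[rows[r].get(s, np.nan) for s in states] for r in rows],
                        index=list(rows), columns=cols)


def test_occupancy_forced_arithmetic():
    intens = _intensity_frame({"a": {"Sto": 80.0, "SH": 20.0, "SSG": 25.0}})
    occ = st.compute_occupancy(intens)
    assert occ.occupancy.loc["a", ("SSG", "s1")] == pytest.approx(0.25)
    assert occ.occupancy.loc["a", ("Sto", "s1")] == pytest.approx(0.80)
    assert occ.occupancy.loc["a", ("SH", "s1")] == pytest.approx(0.20)


def test_occupancy_boundary_and_clamping():
    intens = _intensity_frame({
        "zero_ox": {"Sto": np.nan, "SH": 50.0},
        "over": {"Sto": 80.0, "SH": 20.0, "SNO": 150.0},
    })
    # missing Sto -> occupancy missing (needs both Sto and SH)
    occ = st.compute_occupancy(intens)
    assert pd.isna(occ.occupancy.loc["zero_ox", ("SH", "s1")])
    assert occ.occupancy.loc["over", ("SNO", "s1")] == 1.0
    assert occ.raw.loc["over", ("SNO", "s1")] == pytest.approx(1.5)
    assert bool(occ.clamped.loc["over", ("SNO", "s1")])


def test_occupancy_zero_denominator_warns_missing():
    intens = _intensity_frame({"a": {"Sto": 0.0, "SH": 0.0}})
    with pytest.warns(UserWarning, match="Sto \\+ I_SH"):
        occ = st.compute_occupancy(intens)
    assert occ.occupancy.isna().all().all()


def test_occupancy_invariant_to_channel_rescaling(small_cohort):
    """Multiplying all states of a site-sample by c > 0 leaves occupancy fixed."""
    intens = small_cohort.sites.intensities.iloc[:50]
    rng = np.random.default_rng(0)
    scale = pd.Series(rng.uniform(0.1, 10.0, len(intens.columns.get_level_values(1).unique())),
                      index=intens.columns.get_level_values(1).unique())
    scaled = intens.mul(intens.columns.get_level_values(1).map(scale).to_numpy(), axis=1)
    a = st.compute_occupancy(intens).occupancy
    b = st.compute_occupancy(scaled).occupancy
    pd.testing.assert_frame_equal(a, b, rtol=1e-12)


def test_group_median_min_n_rule():
    design = pd.DataFrame({"group": ["young"] * 4, "location": ["A"] * 4},
                          index=["s1", "s2", "s3", "s4"])
    cols = pd.MultiIndex.from_product([["Sto"], design.index],
                                      names=["state", "sample"])
    occ = pd.DataFrame([[0.2, 0.3, 0.4, np.nan], [0.2, 0.3, np.nan, np.nan]],
                       index=["a", "b"], columns=cols)
    med, counts = st.group_median_occupancy(occ, design, min_n=3)
    assert med.loc["a", ("Sto", "young")] == pytest.approx(0.3)
    assert pd.isna(med.loc["b", ("Sto", "young")])  # only 2 quantified
    assert counts.loc["b", ("Sto", "young")] == 2


def test_group_median_unknown_sample_errors():
    design = pd.DataFrame({"group": ["young"], "location": ["A"]}, index=["s1"])
    cols = pd.MultiIndex.from_product([["Sto"], ["s1", "sX"]],
                                      names=["state", "sample"])
    occ = pd.DataFrame([[0.1, 0.2]], index=["a"], columns=cols)
    with pytest.raises(ValidationError, match="sX"):
        st.group_median_occupancy(occ, design)


def test_density_recovers_beta_mode():
    rng = np.random.default_rng(1)
    vals = rng.beta(9, 9, 2000)  # mode 0.5
    grid = st.fit_density(vals)
    assert abs(grid.grid[np.argmax(grid.density)] - 0.5) <= 0.05
    integral = np.trapezoid(grid.density, grid.grid)
    assert 0.98 <= integral <= 1.02


def test_density_degenerate_inputs():
    with pytest.raises(DegenerateValuesError):
        st.fit_density([0.5] * 10)  # too few
    with pytest.raises(DegenerateValuesError):
        st.fit_density([0.5] * 100)  # constant


def test_peaks_valley_against_exact_mixture_density():
    """Peaks/valley from the KDE match the analytic mixture density's
    argmax/argmin on the same grid, within the KDE's resolution."""
    rng = np.random.default_rng(7)
    w, modes, conc = 0.6, (0.25, 0.85), 18.0
    n = 3000
    comp = rng.random(n) >= w
    a0 = 1 + modes[0] * (conc - 2); b0 = 1 + (1 - modes[0]) * (conc - 2)
    a1 = 1 + modes[1] * (conc - 2); b1 = 1 + (1 - modes[1]) * (conc - 2)
    vals = np.where(comp, rng.beta(a1, b1, n), rng.beta(a0, b0, n))
    model = st.fit_region_model(vals)

    x = np.linspace(0, 1, 512)
    exact = w * stats.beta.pdf(x, a0, b0) + (1 - w) * stats.beta.pdf(x, a1, b1)
    lo_exact = x[np.argmax(np.where(x < 0.5, exact, -np.inf))]
    hi_exact = x[np.argmax(np.where(x >= 0.5, exact, -np.inf))]
    mid = (x > lo_exact) & (x < hi_exact)
    valley_exact = x[mid][np.argmin(exact[mid])]
    assert abs(model.peak_low - lo_exact) <= 0.05
    assert abs(model.peak_high - hi_exact) <= 0.05
    assert abs(model.valley - valley_exact) <= 0.1
    assert model.peak_low < model.valley < model.peak_high


def test_symmetric_spikes_valley_near_half():
    vals = np.concatenate([np.full(1000, 0.2), np.full(1000, 0.8)])
    vals = vals + np.random.default_rng(0).normal(0, 0.01, 2000)  # break constancy
    model = st.fit_region_model(vals)
    assert abs(model.valley - 0.5) <= 0.05


def test_unimodal_raises():
    rng = np.random.default_rng(3)
    with pytest.raises(UnimodalDensityError):
        st.fit_region_model(rng.beta(9, 9, 3000))


def test_assign_regions_tie_rule():
    model = st.RegionModel(grid=np.linspace(0, 1, 5), density=np.ones(5),
                           bandwidth=0.1, peak_low=0.2, peak_high=0.9, valley=0.55)
    med = pd.Series({"a": 0.2, "b": 0.9, "c": 0.55})
    regions = st.assign_regions(med, model)
    assert regions["a"] == 1 and regions["b"] == 2
    assert regions["c"] == 1  # exactly at the valley -> region 1


def test_transitions_hand_example():
    ym = pd.Series({"a": 0.2, "b": 0.3, "c": 0.9})
    om = pd.Series({"a": 0.85, "b": 0.4, "c": 0.2})
    valley = 0.55
    model = st.RegionModel(grid=np.zeros(1), density=np.zeros(1), bandwidth=0.1,
                           peak_low=0.2, peak_high=0.9, valley=valley)
    yr = st.assign_regions(ym, model)
    orr = st.assign_regions(om, model)
    rep = st.count_transitions(ym, yr, om, orr, delta_min=0.10)
    assert rep.n_y1_to_o2 == 1 and rep.y1_to_o2 == ["a"]
    assert rep.n_y2_to_o1 == 1 and rep.y2_to_o1 == ["c"]
    assert rep.n_y1_to_o2_gt_delta == 1  # delta = 0.65


def test_transitions_match_brute_force():
    rng = np.random.default_rng(11)
    n = 2000
    ids = [f"s{i}" for i in range(n)]
    ym = pd.Series(rng.random(n), index=ids)
    om = pd.Series(rng.random(n), index=ids)
    vy, vo = 0.55, 0.6
    my = st.RegionModel(np.zeros(1), np.zeros(1), 0.1, 0.2, 0.9, vy)
    mo = st.RegionModel(np.zeros(1), np.zeros(1), 0.1, 0.2, 0.9, vo)
    rep = st.count_transitions(ym, st.assign_regions(ym, my),
                               om, st.assign_regions(om, mo))
    # independent per-site loop
    up = down = up_d = down_d = 0
    for i in ids:
        ry = 1 if ym[i] <= vy else 2
        ro = 1 if om[i] <= vo else 2
        d = om[i] - ym[i]
        if ry == 1 and ro == 2:
            up += 1
            up_d += abs(d) > 0.10
        if ry == 2 and ro == 1:
            down += 1
            down_d += abs(d) > 0.10
    assert (rep.n_y1_to_o2, rep.n_y2_to_o1) == (up, down)
    assert (rep.n_y1_to_o2_gt_delta, rep.n_y2_to_o1_gt_delta) == (up_d, down_d)


def test_contribution_forced_arithmetic():
    med = pd.DataFrame({"Sto": [0.25], "SSG": [0.10], "SOH": [0.02], "SNO": [0.03]},
                       index=["a"])
    out = st.modification_contribution(med)
    assert out.loc["a", "SSG"] == pytest.approx(0.40)
    assert out.loc["a", "SOH"] == pytest.approx(0.08)
    assert out.loc["a", "SNO"] == pytest.approx(0.12)
    assert out.loc["a", "residual"] == pytest.approx(0.40)


def test_contribution_boundary_and_overshoot():
    med = pd.DataFrame({"Sto": [0.25, 0.2], "SSG": [0.25, 0.3],
                        "SOH": [np.nan, 0.1], "SNO": [np.nan, np.nan]},
                       index=["full", "over"])
    out = st.modification_contribution(med)
    assert out.loc["full", "SSG"] == pytest.approx(1.0)
    assert out.loc["full", "residual"] == pytest.approx(0.0)
    # overshoot: capped fractions 1.0 + 0.5 rescaled to sum 1
    assert out.loc["over", "SSG"] + out.loc["over", "SOH"] == pytest.approx(1.0)
    assert bool(out.loc["over", "rescaled"])
    assert out.loc["over", "residual"] == pytest.approx(0.0)


def test_planted_age_sites_enriched_in_upward_transitions(default_cohort):
    """Sites with a planted age increase dominate Y1->O2, delta > 0.10
    transitions at least 10-fold over sites with no planted structure."""
    from redoxmap import normalize as nm
    b = default_cohort
    norm = nm.normalize_redox(b.sites, nm.compute_channel_ratios(b.proteins))
    med, _ = st.group_median_occupancy(st.compute_occupancy(norm), b.design)
    sto = med["Sto"]
    models = {g: st.fit_region_model(sto[g], group=g) for g in ("young", "old")}
    regions = {g: st.assign_regions(sto[g], models[g]) for g in models}
    rep = st.count_transitions(sto["young"], regions["young"],
                               sto["old"], regions["old"])
    up_big = {s for s in rep.y1_to_o2 if abs(rep.delta[s]) > 0.10}
    truth = b.truth.sites
    planted = set(truth.index[truth["age_class"] == "up"])
    # latent-factor-driven sites carry real age structure; the null set
    # is sites with no planted effect at all
    null = set(truth.index[(truth["age_class"] == "none") & ~truth["driven"]])
    rate_planted = len(up_big & planted) / len(planted)
    rate_null = max(len(up_big & null) / len(null), 1 / len(null))
    assert rate_planted / rate_null >= 10


def test_conservation_on_cohort(small_cohort):
    occ = st.compute_occupancy(small_cohort.sites.intensities)
    s = occ.occupancy["Sto"] + occ.occupancy["SH"]
    assert float((s - 1).abs().max().max()) < 1e-9
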