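import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from insertscan.ensemble_stats import (MutantEnsemble, cohens_d,
                                       hbc_by_pair_grid,
                                       helix_group_comparison,
                                       normalized_size_outlier_rates,
                                       outliers, pair_frequency_matrix,
                                       position_frequency, residue_frequency,
                                       top_pairs, two_sample_t)
from insertscan.synthetic_data import (PlantedEffect, SyntheticEnsembleConfig,
                                       ideal_helix_structure,
                                       simulate_metric_ensemble)


def _tiny_ensemble(rows):
    """rows: list of (mutant_id, aa1, aa2, pos1, pos2, rop)."""
    df = pd.DataFrame(rows, columns=["mutant_id", "aa1", "aa2",
                                     "pos1", "pos2", "rop"])
    df["gap1"] = df["pos1"] - 1
    df["gap2"] = df["pos2"] - 2
    df["hbc"] = 5
    df["cce"] = 0.5
    df["helix_group"] = "I_XX"
    df["size_group"] = "VSVS"
    return MutantEnsemble(df)


@pytest.fixture(scope="module")
def sim_ensemble():
    st_ = ideal_helix_structure(12)
    st_.helix_ranges = [(3, 10)]
    st_.__post_init__()
    cfg = SyntheticEnsembleConfig(seed=42)
    return simulate_metric_ensemble(cfg, st_), st_


def test_constant_metric_yields_empty_outlier_set():
    ens = _tiny_ensemble([(f"m{i}", "A", "A", 1, 2, 0.5) for i in range(5)])
    with pytest.warns(UserWarning):
        oset = outliers(ens, "rop")
    assert oset.member_ids == set()


def test_single_extreme_value_is_outlier():
    """99 zeros and one 100: mean 1, population sd ~9.95, the 100 qualifies."""
    rows = [(f"m{i}", "A", "A", 1, 2, 1e-9) for i in range(99)]
    rows.append(("big", "A", "A", 1, 2, 1.0))
    df = _tiny_ensemble(rows).records.copy()
    df["hbc"] = [0] * 99 + [100]
    ens = MutantEnsemble(df)
    oset = outliers(ens, "hbc")
    assert oset.mean == pytest.approx(1.0)
    assert oset.sd == pytest.approx(9.94987, abs=1e-4)
    assert oset.member_ids == {"big"}


def test_outlier_set_affine_invariance(sim_ensemble):
    ens, _ = sim_ensemble
    base = outliers(ens, "cce").member_ids
    df = ens.records.copy()
    df["cce"] = 0.3 * df["cce"] + 0.2  # stays within [0, 1]
    assert outliers(MutantEnsemble(df), "cce").member_ids == base
    df2 = ens.records.copy()
    df2["hbc"] = -2 * df2["hbc"]  # negative scale flips sides, not the set
    df2["hbc"] -= df2["hbc"].min()  # keep validation happy
    assert outliers(MutantEnsemble(df2), "hbc").member_ids == \
        outliers(ens, "hbc").member_ids


def test_residue_frequency_counting_rules():
    ens = _tiny_ensemble([("a", "P", "W", 1, 2, 0.1),
                          ("b", "C", "C", 1, 3, 0.2),
                          ("c", "A", "G", 2, 3, 0.3)])
    oset = outliers(ens, "rop", k=0.0)  # everything qualifies at k=0
    freq = residue_frequency(ens, oset)
    assert freq["P"] == 1 and freq["W"] == 1
    assert freq["C"] == 2  # homotypic pair counts twice
    assert sum(freq.values()) == 2 * len(oset)


def test_pair_frequency_matrix_symmetry():
    ens = _tiny_ensemble([("a", "R", "R", 1, 2, 0.1),
                          ("b", "H", "W", 1, 3, 0.9)])
    oset = outliers(ens, "rop", k=0.0)
    mat = pair_frequency_matrix(ens, oset)
    assert mat.loc["R", "R"] == 1
    assert mat.loc["H", "W"] == 1 and mat.loc["W", "H"] == 1
    assert (mat.values == mat.values.T).all()
    off_diag = mat.values.sum() - np.trace(mat.values)
    assert off_diag % 2 == 0


def test_position_frequency_with_helix_flags():
    st_ = ideal_helix_structure(25)
    st_.helix_ranges = [(5, 10)]
    st_.__post_init__()
    # gaps 6 and 8: pos1 = 7, pos2 = 10
    ens = _tiny_ensemble([("a", "A", "A", 7, 10, 0.1)])
    oset = outliers(_tiny_ensemble([("a", "A", "A", 7, 10, 0.1),
                                    ("b", "A", "A", 1, 2, 0.9)]),
                    "rop", k=0.0)
    ens2 = _tiny_ensemble([("a", "A", "A", 7, 10, 0.1),
                           ("b", "A", "A", 1, 2, 0.9)])
    table = position_frequency(ens2, oset, st_)
    counts = dict(zip(table["gap"], table["count"]))
    assert counts[6] == 1 and counts[8] == 1
    helix_flags = dict(zip(table["gap"], table["in_helix"]))
    assert helix_flags[6] and helix_flags[8]
    assert table["count"].sum() == 2 * len(oset)


def test_empty_outlier_set_gives_zero_positions():
    st_ = ideal_helix_structure(10)
    ens = _tiny_ensemble([("a", "A", "A", 1, 2, 0.4),
                          ("b", "A", "A", 1, 3, 0.6)])
    oset = outliers(ens, "rop", k=50.0)
    table = position_frequency(ens, oset, st_)
    assert table["count"].sum() == 0


def test_top_pairs_tie_break_and_breakdown():
    freq = {("P", "W"): 19, ("M", "P"): 7, ("F", "P"): 7}
    pairs, top5 = top_pairs(freq, k=2)
    assert pairs == [("P", "W"), ("F", "P")]  # FP beats MP lexicographically
    assert top5["P"] == 26  # P appears in both selected pairs
    with pytest.warns(UserWarning):
        all_pairs, _ = top_pairs(freq, k=10)
    assert len(all_pairs) == 3


def test_cohens_d_worked_example():
    """M1-M2 = 2, sd1 = 3, sd2 = 4 gives d = 2 / sqrt(12.5)."""
    g1 = np.array([2.0 - 3 / np.sqrt(2), 2.0 + 3 / np.sqrt(2)])
    g2 = np.array([-4 / np.sqrt(2), 4 / np.sqrt(2)])
    r = cohens_d(g1, g2)
    assert r.sd1 == pytest.approx(3.0)
    assert r.sd2 == pytest.approx(4.0)
    assert r.sd_pooled == pytest.approx(np.sqrt(12.5))
    assert r.d == pytest.approx(2 / np.sqrt(12.5))


def test_cohens_d_identical_groups():
    g = [1.0, 2.0, 3.0]
    r = cohens_d(g, g)
    assert r.d == 0.0
    assert r.t == pytest.approx(0.0)
    assert r.p == pytest.approx(1.0)


def test_cohens_d_unit_example():
    g1 = np.array([1 - 1 / np.sqrt(2), 1 + 1 / np.sqrt(2)])
    g2 = np.array([-1 / np.sqrt(2), 1 / np.sqrt(2)])
    assert cohens_d(g1, g2).d == pytest.approx(1.0)


@given(st.lists(st.floats(-50, 50), min_size=3, max_size=12),
       st.lists(st.floats(-50, 50), min_size=3, max_size=12),
       st.floats(0.1, 9.0))
def test_cohens_d_antisymmetry_and_scale_invariance(a, b, c):
    a, b = np.asarray(a), np.asarray(b)
    if a.std(ddof=1) < 1e-6 or b.std(ddof=1) < 1e-6:
        return
    d_ab = cohens_d(a, b).d
    assert cohens_d(b, a).d == pytest.approx(-d_ab, rel=1e-9, abs=1e-12)
    assert cohens_d(c * a, c * b).d == pytest.approx(d_ab, rel=1e-6, abs=1e-9)


def test_two_sample_t_validations():
    with pytest.raises(ValueError):
        two_sample_t([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        two_sample_t([1.0, 1.0], [2.0, 2.0])


def test_helix_group_comparison_planted_recovery():
    """A planted standardized shift between helix groups is recovered."""
    st_ = ideal_helix_structure(12)
    st_.helix_ranges = [(3, 10)]
    st_.__post_init__()
    cfg = SyntheticEnsembleConfig(
        seed=7,
        planted_effects=[PlantedEffect(("helix_group", "I_XH"), "cce", -0.40),
                         PlantedEffect(("helix_group", "I_HH"), "cce", -0.80)])
    ens = simulate_metric_ensemble(cfg, st_)
    res = helix_group_comparison(ens, "cce")
    assert set(res) == {"I_XX_vs_I_XH", "I_XX_vs_I_HH", "I_XH_vs_I_HH"}
    assert res["I_XX_vs_I_XH"]["effect"].d == pytest.approx(0.40, abs=0.05)
    assert res["I_XX_vs_I_HH"]["effect"].d == pytest.approx(0.80, abs=0.05)
    for name, entry in res.items():
        for g in name.split("_vs_"):
            assert entry[g]["hi"] - entry[g]["lo"] == pytest.approx(
                2 * entry[g]["sd"])


def test_helix_group_comparison_without_helices():
    st_ = ideal_helix_structure(8)
    st_.helix_ranges = []
    st_.__post_init__()
    ens = simulate_metric_ensemble(SyntheticEnsembleConfig(seed=1), st_)
    assert helix_group_comparison(ens, "cce") == {}


def test_size_rates_all_outliers():
    st_ = ideal_helix_structure(6)
    sim = simulate_metric_ensemble(SyntheticEnsembleConfig(seed=5), st_)
    table = normalized_size_outlier_rates(sim, "cce", k=0.0)
    defined = table[table["n_group"] > 0]
    assert (defined["rate"] == 1.0).all()


def test_size_rates_planted_group_flagged_max(sim_ensemble):
    ens, st_ = sim_ensemble
    cfg = SyntheticEnsembleConfig(
        seed=9, planted_effects=[PlantedEffect(("size_group", "VLVL"),
                                               "rop", -1.2)])
    planted = simulate_metric_ensemble(cfg, st_)
    table = normalized_size_outlier_rates(planted, "rop")
    pairs = table[table["block"] == "pair"].set_index("group")
    assert pairs.loc["VLVL", "flag"] == "max"
    singles = table[table["block"] == "single"].set_index("group")
    assert singles.loc["VL", "flag"] == "max"


def test_size_rates_null_uniformity(sim_ensemble):
    ens, _ = sim_ensemble
    table = normalized_size_outlier_rates(ens, "cce")
    defined = table[table["n_group"] > 0]
    assert ((defined["rate"] - 0.0455).abs() < 0.01).all()


def test_hbc_grid_ordering_and_conservation(sim_ensemble):
    ens, _ = sim_ensemble
    grid, counts = hbc_by_pair_grid(ens, with_counts=True)
    assert grid.index[0] == "GG"
    assert grid.index[-1] == "WW"
    assert len(grid.index) == 210
    vals = grid.values
    # count-weighted grid mean equals the ensemble HBC mean
    weighted = np.nansum(vals * counts.values) / counts.values.sum()
    assert weighted == pytest.approx(ens.records["hbc"].mean())
    # full-space simulation: no missing mutants
    assert not np.isnan(vals).any()
    assert counts.values.sum() == len(ens)


def test_hbc_grid_marks_missing_mutants(sim_ensemble):
    ens, _ = sim_ensemble
    df = ens.records
    dropped = MutantEnsemble(df[df["mutant_id"] != df["mutant_id"].iloc[0]])
    grid = hbc_by_pair_grid(dropped)
    assert np.isnan(grid.values).sum() == 1


def test_ensemble_validation():
    df = _tiny_ensemble([("a", "A", "A", 1, 2, 0.5)]).records.copy()
    dup = pd.concat([df, df])
    with pytest.raises(ValueError):
        MutantEnsemble(dup)
    bad = df.copy()
    bad["cce"] = 1.5
    with pytest.raises(ValueError):
        MutantEnsemble(bad)
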