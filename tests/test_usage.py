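"""Usage profiles, Z-normalisation, clustering, ARI and the separability protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from xcompare.errors import EmptyResultError, XCompareError
from xcompare.usage import (
    HEAVY,
    LIGHT,
    UsageProfile,
    adjusted_rand,
    cluster_profiles,
    kappa_lambda_ratio,
    linkage_to_newick,
    richness_at_depth,
    separability_test,
    usage_difference_tests,
    usage_profile,
    z_normalise,
)
from tests.conftest import make_repertoire


def _heavy_rep(v_calls, subject_id="s1"):
    return make_repertoire(
        [dict(v_call=v, j_call="IGHJ4*01", junction="TGTGCGTGG", junction_aa="CAW")
         for v in v_calls], subject_id=subject_id)


def test_usage_profile_subgroup_level():
    rep = _heavy_rep(["IGHV3-23*01", "IGHV1-2*01"])
    prof = usage_profile(rep, segment="V", level="subgroup")
    assert dict(zip(prof.axis, prof.frequencies)) == {"IGHV1": 0.5, "IGHV3": 0.5}


def test_usage_profile_single_gene_and_reference_axis():
    rep = _heavy_rep(["IGHV3-23*01"] * 4)
    prof = usage_profile(rep, level="gene", reference_labels=["IGHV1-2", "IGHV3-23"])
    assert dict(zip(prof.axis, prof.frequencies)) == {"IGHV1-2": 0.0, "IGHV3-23": 1.0}
    assert prof.frequencies.sum() == pytest.approx(1.0)


def test_usage_profile_no_segment_errors():
    rep = _heavy_rep(["IGHV3-23*01"])
    with pytest.raises(EmptyResultError):
        usage_profile(rep, segment="D")  # no d_call column


def test_kappa_lambda_ratio():
    rep = make_repertoire([
        dict(v_call=v, j_call=j, junction="TGTCAATTC", junction_aa="CQF")
        for v, j in [("IGKV1-39", "IGKJ1")] * 3 + [("IGLV1-44", "IGLJ2")]
    ])
    assert kappa_lambda_ratio(rep) == pytest.approx((75.0, 25.0))
    all_k = make_repertoire([dict(v_call="IGKV1-39", j_call="IGKJ1",
                                  junction="TGTCAATTC", junction_aa="CQF")])
    assert kappa_lambda_ratio(all_k) == pytest.approx((100.0, 0.0))
    heavy_only = _heavy_rep(["IGHV3-23"])
    with pytest.raises(EmptyResultError):
        kappa_lambda_ratio(heavy_only)


def test_z_normalise_two_subjects_hand_value():
    """Frequencies 0.4/0.6 on one category give Z = -/+ 1/sqrt(2) (sample sd)."""
    profs = [UsageProfile("a", ["g1", "g2"], [0.4, 0.6], 10),
             UsageProfile("b", ["g1", "g2"], [0.6, 0.4], 10)]
    z = z_normalise(profs)
    assert z.loc["a", "g1"] == pytest.approx(-1 / np.sqrt(2))
    assert z.loc["b", "g1"] == pytest.approx(+1 / np.sqrt(2))


def test_z_normalise_identical_profiles_all_zero():
    profs = [UsageProfile(s, ["g1", "g2"], [0.3, 0.7], 10) for s in "abc"]
    z = z_normalise(profs)
    assert (z.values == 0).all()


def test_z_normalise_column_means_zero():
    rng = np.random.default_rng(0)
    rows = rng.dirichlet(np.ones(6), size=5)
    profs = [UsageProfile(f"s{i}", [f"g{j}" for j in range(6)], rows[i], 100)
             for i in range(5)]
    z = z_normalise(profs)
    assert np.abs(z.mean(axis=0).values).max() < 1e-9


def test_cluster_profiles_trivial_cases():
    m = pd.DataFrame([[0.0, 0.0], [5.0, 5.0]], index=["a", "b"])
    _, cut = cluster_profiles(m)
    assert cut["a"] != cut["b"]  # 2 subjects -> each its own cluster
    m3 = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]], index=["a", "b", "c"])
    Z, cut3 = cluster_profiles(m3)
    assert cut3["a"] == cut3["b"] != cut3["c"]
    assert Z[0, 2] == 0.0  # duplicated rows merge first at distance zero
    with pytest.raises(XCompareError):
        cluster_profiles(pd.DataFrame([[np.nan, 0.0], [1.0, 1.0]]))


def test_cluster_profiles_recovers_blobs():
    rng = np.random.default_rng(3)
    blob_a = rng.normal(0, 0.2, size=(4, 5))
    blob_b = rng.normal(4, 0.2, size=(4, 5))
    m = pd.DataFrame(np.vstack([blob_a, blob_b]),
                     index=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
    _, cut = cluster_profiles(m)
    truth = ["A"] * 4 + ["B"] * 4
    assert adjusted_rand(truth, cut.values) == 1.0
    newick = linkage_to_newick(*cluster_profiles(m)[:1], leaf_names=list(m.index))
    assert newick.endswith(";") and "a0" in newick


def _ari_contingency_oracle(a, b):
    """Adjusted Rand from the contingency-table formula, written out by hand."""
    cats_a, cats_b = sorted(set(a)), sorted(set(b))
    n = len(a)
    table = np.zeros((len(cats_a), len(cats_b)))
    for x, y in zip(a, b):
        table[cats_a.index(x), cats_b.index(y)] += 1
    sum_comb = comb(table, 2).sum()
    comb_a = comb(table.sum(axis=1), 2).sum()
    comb_b = comb(table.sum(axis=0), 2).sum()
    expected = comb_a * comb_b / comb(n, 2)
    max_index = (comb_a + comb_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)


@pytest.mark.parametrize("a,b,expected", [
    (["x", "x", "y", "y"], ["x", "x", "y", "y"], 1.0),
    (["x", "x", "y", "y"], ["p", "p", "q", "q"], 1.0),   # relabelling
    (["x", "x", "x", "x"], ["p", "p", "q", "q"], 0.0),   # all-in-one vs split
])
def test_adjusted_rand_known_values(a, b, expected):
    assert adjusted_rand(a, b) == pytest.approx(expected)
    assert adjusted_rand(a, b) == pytest.approx(_ari_contingency_oracle(a, b))


@given(st.lists(st.integers(0, 3), min_size=4, max_size=12))
@settings(max_examples=40, derandomize=True)
def test_adjusted_rand_matches_oracle_and_is_symmetric(labels):
    rng = np.random.default_rng(len(labels))
    other = rng.integers(0, 3, size=len(labels)).tolist()
    assert adjusted_rand(labels, other) == pytest.approx(_ari_contingency_oracle(labels, other))
    assert adjusted_rand(labels, other) == pytest.approx(adjusted_rand(other, labels))
    assert adjusted_rand(labels, other) <= 1.0 + 1e-12


def test_adjusted_rand_errors():
    with pytest.raises(XCompareError):
        adjusted_rand([1, 2], [1, 2, 3])
    with pytest.raises(XCompareError):
        adjusted_rand([1], [1])


def _species_rep(rng, subject_id, probs):
    genes = [f"IGHV{k}-1*01" for k in range(1, len(probs) + 1)]
    draws = rng.choice(genes, size=300, p=probs)
    return _heavy_rep(draws, subject_id=subject_id)


def test_separability_disjoint_usage_is_perfect():
    """Two simulated species with disjoint gene usage separate in all repeats."""
    rng = np.random.default_rng(11)
    reps = [_species_rep(rng, f"a{i}", [0.5, 0.5, 0.0, 0.0]) for i in range(3)] + \
           [_species_rep(rng, f"b{i}", [0.0, 0.0, 0.5, 0.5]) for i in range(3)]
    labels = {r.subject_id: r.subject_id[0] for r in reps}
    res = separability_test(reps, labels, subsample_n=105, n_repeats=100, seed=5)
    assert res.fraction_perfect == 1.0


def test_separability_monotone_in_usage_gap():
    """fraction_perfect does not decrease as the between-group usage gap grows."""
    fractions = []
    for gap in (0.02, 0.10, 0.30):
        rng = np.random.default_rng(17)
        pa = np.array([0.25 + gap / 2, 0.25 - gap / 2, 0.25, 0.25])
        pb = np.array([0.25 - gap / 2, 0.25 + gap / 2, 0.25, 0.25])
        reps = [_species_rep(rng, f"a{i}", pa) for i in range(3)] + \
               [_species_rep(rng, f"b{i}", pb) for i in range(3)]
        labels = {r.subject_id: r.subject_id[0] for r in reps}
        res = separability_test(reps, labels, subsample_n=105, n_repeats=40, seed=5)
        fractions.append(res.fraction_perfect)
    assert fractions[0] <= fractions[1] <= fractions[2]
    assert fractions[2] > fractions[0]


def test_separability_deterministic_and_validates_depth():
    rng = np.random.default_rng(2)
    reps = [_species_rep(rng, f"s{i}", [0.5, 0.5, 0.0, 0.0]) for i in range(2)]
    labels = {r.subject_id: "x" for r in reps}
    one = separability_test(reps, labels, subsample_n=50, n_repeats=1, seed=9)
    two = separability_test(reps, labels, subsample_n=50, n_repeats=1, seed=9)
    assert one.ari_values == two.ari_values
    with pytest.raises(XCompareError, match="s0"):
        separability_test(reps, labels, subsample_n=10_000)


def test_usage_difference_tests_identical_groups():
    profs = [UsageProfile(f"s{i}", ["g1", "g2"], [0.4, 0.6], 10) for i in range(6)]
    out = usage_difference_tests(profs[:3], profs[3:])
    assert (out["p_adj"] >= 0.99).all()


def test_usage_difference_tests_disjoint_supports_exact_p():
    """Disjoint 5-vs-5 supports reach the smallest achievable rank-sum p.

    Oracle: with all group-A values above all group-B values, the exact
    two-sided Mann-Whitney p is 2 * 1/C(10,5) = 2/252.
    """
    a = [UsageProfile(f"a{i}", ["g1", "g2"], [0.8 + 0.01 * i, 0.2 - 0.01 * i], 10)
         for i in range(5)]
    b = [UsageProfile(f"b{i}", ["g1", "g2"], [0.2 + 0.01 * i, 0.8 - 0.01 * i], 10)
         for i in range(5)]
    out = usage_difference_tests(a, b).set_index("category")
    assert out.loc["g1", "p"] == pytest.approx(2 / comb(10, 5), rel=1e-6)


def test_usage_difference_tests_flags_simulated_subgroup_gap(human_reps, kymouse_reps):
    """The configured IGHD subgroup gap between presets is detected."""
    from xcompare.usage import usage_profile as up

    pa = [up(r, segment="D", level="subgroup") for r in human_reps]
    pb = [up(r, segment="D", level="subgroup") for r in kymouse_reps]
    out = usage_difference_tests(pa, pb).set_index("category")
    # human IGHD2 usage is ~3x the kymouse preset's: the groups should be
    # perfectly ranked, reaching the smallest p achievable with 3 vs 3
    # subjects (2 / C(6,3) = 0.1), and in the right direction
    assert out.loc["IGHD2", "p"] == pytest.approx(0.1, abs=1e-9)
    mean_a = np.mean([dict(zip(p.axis, p.frequencies)).get("IGHD2", 0) for p in pa])
    mean_b = np.mean([dict(zip(p.axis, p.frequencies)).get("IGHD2", 0) for p in pb])
    assert mean_a > mean_b


def test_richness_at_depth_closed_form():
    """Uniform 10-gene repertoire at depth 105: E[distinct] ~ 10(1-(9/10)^105).

    The without-replacement oracle on a finite pool of 300 is even closer to
    10 than the coupon-collector bound, so the bound acts as a floor.
    """
    rng = np.random.default_rng(1)
    genes = [f"IGHV{k}-1*01" for k in range(1, 11)]
    rep = _heavy_rep(rng.choice(genes, size=300).tolist())
    mean = richness_at_depth(rep, depth=105, n_repeats=50, seed=3)
    assert 10 * (1 - 0.9 ** 105) - 0.2 <= mean <= 10.0


def test_richness_at_depth_edge_cases():
    rep = _heavy_rep(["IGHV1-1*01"] * 20)
    assert richness_at_depth(rep, depth=5, n_repeats=5, seed=0) == 1.0
    multi = _heavy_rep(["IGHV1-1*01", "IGHV2-1*01", "IGHV3-1*01"] * 4)
    assert richness_at_depth(multi, depth=12, n_repeats=3, seed=0) == 3.0  # full depth
    with pytest.raises(XCompareError):
        richness_at_depth(multi, depth=100)


def test_richness_vj_combinations():
    rep = make_repertoire([
        dict(v_call=v, j_call=j, junction="TGTGCGTGG", junction_aa="CAW")
        for v, j in [("IGHV1-1", "IGHJ4"), ("IGHV1-1", "IGHJ6"),
                     ("IGHV2-1", "IGHJ4"), ("IGHV2-1", "IGHJ6")] * 3
    ])
    assert richness_at_depth(rep, depth=12, n_repeats=2, seed=0, segment="VJ") == 4.0
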