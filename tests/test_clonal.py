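"""Clonotype assignment against brute-force oracles, overlap, downsampling."""

import itertools

import numpy as np
import pytest

from xcompare.clonal import (
    assign_clonotypes,
    exact_cdrh3_set,
    pairwise_overlap,
    stratified_downsample,
)
from xcompare.errors import XCompareError
from tests.conftest import make_repertoire


def _rep_from_cdr3s(entries, subject_id="s1"):
    """entries: list of (v_gene, j_gene, cdr3_aa)."""
    return make_repertoire(
        [dict(v_call=v + "*01", j_call=j + "*01",
              junction="TGT" + "GCA" * len(c) + "TGG", junction_aa="C" + c + "W")
         for v, j, c in entries], subject_id=subject_id)


def _brute_force_clones(entries, threshold):
    """Oracle: transitive closure of the pairwise linkage relation."""
    n = len(entries)
    def linked(a, b):
        va, ja, ca = a
        vb, jb, cb = b
        if va != vb or ja != jb or len(ca) != len(cb):
            return False
        ident = sum(x == y for x, y in zip(ca, cb)) / len(ca)
        return ident >= threshold - 1e-12
    parent = list(range(n))
    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x
    for i, j in itertools.combinations(range(n), 2):
        if linked(entries[i], entries[j]):
            parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    return {r: frozenset(i for i in range(n) if find(i) == r) for r in set(roots)}


def _partition_of(assign):
    clones = {}
    for i, cid in enumerate(assign.members["clone_id"]):
        clones.setdefault(cid, set()).add(i)
    return {frozenset(v) for v in clones.values()}


def test_identity_boundary_inclusive():
    """Length-10 CDR3s differing at one position: identity exactly 0.90 links."""
    entries = [("IGHV3-23", "IGHJ4", "ARDYWGQGTL"), ("IGHV3-23", "IGHJ4", "ARDYWGQGTV")]
    assign = assign_clonotypes(_rep_from_cdr3s(entries), identity_threshold=0.90)
    assert assign.n_clones == 1


def test_different_j_gene_separates():
    entries = [("IGHV3-23", "IGHJ4", "ARDYW"), ("IGHV3-23", "IGHJ6", "ARDYW")]
    assert assign_clonotypes(_rep_from_cdr3s(entries)).n_clones == 2


def test_single_linkage_chains_transitively():
    """A-B and B-C at 0.9 but A-C at 0.8: one clone under single linkage."""
    entries = [("IGHV1-2", "IGHJ4", "AAAAAAAAAA"),
               ("IGHV1-2", "IGHJ4", "AAAAAAAAAB"),
               ("IGHV1-2", "IGHJ4", "AAAAAAAABB")]
    rep = _rep_from_cdr3s(entries)
    assign = assign_clonotypes(rep, identity_threshold=0.90, method="single")
    assert assign.n_clones == 1
    assert _partition_of(assign) == set(_brute_force_clones(entries, 0.90).values())
    # complete linkage refuses the 0.8-identity pair in one cluster
    complete = assign_clonotypes(rep, identity_threshold=0.90, method="complete")
    assert complete.n_clones == 2


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_clonotypes_match_brute_force_oracle(seed):
    """Random <=200-sequence fixtures: partition equals transitive closure."""
    rng = np.random.default_rng(seed)
    alphabet = list("ARNDC")
    entries = []
    for _ in range(rng.integers(100, 200)):
        v = f"IGHV{rng.integers(1, 4)}-1"
        j = f"IGHJ{rng.integers(4, 7)}"
        length = int(rng.choice([8, 10]))
        base = "".join(rng.choice(alphabet, size=length))
        entries.append((v, j, base))
        # seed near-duplicates to exercise linking
        if rng.random() < 0.4:
            mutated = list(base)
            mutated[rng.integers(length)] = rng.choice(alphabet)
            entries.append((v, j, "".join(mutated)))
    entries = entries[:200]
    assign = assign_clonotypes(_rep_from_cdr3s(entries), identity_threshold=0.90)
    assert _partition_of(assign) == set(_brute_force_clones(entries, 0.90).values())


def test_threshold_one_equals_exact_grouping(kymouse_reps):
    """At threshold 1.0 clonotyping degenerates to grouping by (V, J, CDR3)."""
    rep = kymouse_reps[0]
    assign = assign_clonotypes(rep, identity_threshold=1.0)
    heavy = rep.df[rep.df["locus"] == "IGH"]
    exact = heavy.groupby(
        [heavy["v_call"].str.split("*").str[0],
         heavy["j_call"].str.split("*").str[0],
         heavy["junction_aa"]]).ngroups
    assert assign.n_clones == exact


def test_clone_count_monotone_in_threshold(human_reps):
    rep = human_reps[0]
    counts = [assign_clonotypes(rep, t).n_clones for t in (1.0, 0.9, 0.8)]
    assert counts[0] >= counts[1] >= counts[2]


def test_clone_members_share_keys(kymouse_reps):
    assign = assign_clonotypes(kymouse_reps[1])
    merged = assign.members.merge(assign.clones, on="clone_id")
    assert (merged.groupby("clone_id")["v_gene"].nunique() == 1).all()
    assert (assign.members["clone_id"] >= 0).all()
    assert assign.clones["n_members"].sum() == len(assign.members)


def test_exact_cdrh3_set():
    entries = [("IGHV1-2", "IGHJ4", c) for c in ["AAA", "AAA", "BBB", "CCC", "BBB"]]
    assert exact_cdrh3_set(_rep_from_cdr3s(entries)) == {"AAA", "BBB", "CCC"}


def test_exact_cdrh3_set_smaller_than_reads(kymouse_reps):
    rep = kymouse_reps[0]
    n_heavy = (rep.df["locus"] == "IGH").sum()
    assert len(exact_cdrh3_set(rep)) < n_heavy  # clonal redundancy duplicates


def test_overlap_hand_computed_conventions():
    a = _rep_from_cdr3s([("IGHV1-2", "IGHJ4", c) for c in "ABC"], subject_id="a")
    b = _rep_from_cdr3s([("IGHV1-2", "IGHJ4", c) for c in "BCD"], subject_id="b")
    mean = pairwise_overlap([a, b], unit="cdrh3", convention="mean").values
    assert mean.loc["a", "b"] == pytest.approx(100 * (2 / 3 + 2 / 3) / 2)
    jac = pairwise_overlap([a, b], unit="cdrh3", convention="jaccard").values
    assert jac.loc["a", "b"] == pytest.approx(100 * 2 / 4)
    mn = pairwise_overlap([a, b], unit="cdrh3", convention="min").values
    assert mn.loc["a", "b"] == pytest.approx(100 * 2 / 3)


def test_overlap_identical_and_disjoint():
    a = _rep_from_cdr3s([("IGHV1-2", "IGHJ4", c) for c in ["AAA", "BBB"]], "a")
    b = _rep_from_cdr3s([("IGHV1-2", "IGHJ4", c) for c in ["AAA", "BBB"]], "b")
    c = _rep_from_cdr3s([("IGHV1-2", "IGHJ4", x) for x in ["CCC", "DDD"]], "c")
    for conv in ("mean", "min", "jaccard"):
        m = pairwise_overlap([a, b, c], unit="cdrh3", convention=conv).values
        assert m.loc["a", "b"] == pytest.approx(100.0)
        assert m.loc["a", "c"] == 0.0
        assert np.allclose(m.values, m.values.T)
        assert (np.diag(m.values) == 100.0).all()


def test_overlap_clonotype_counts_near_identical_cross_subject():
    """Joint pooled clustering: CDR3s at >=90% identity across subjects share a clone."""
    a = _rep_from_cdr3s([("IGHV1-2", "IGHJ4", "AAAAAAAAAA")], "a")
    b = _rep_from_cdr3s([("IGHV1-2", "IGHJ4", "AAAAAAAAAB")], "b")
    m = pairwise_overlap([a, b], unit="clonotype", convention="mean").values
    assert m.loc["a", "b"] == pytest.approx(100.0)
    # exact-string sharing sees nothing
    e = pairwise_overlap([a, b], unit="cdrh3", convention="mean").values
    assert e.loc["a", "b"] == 0.0


def test_overlap_monotone_under_shared_addition():
    base_a = [("IGHV1-2", "IGHJ4", c) for c in ["AAAA", "CCCC"]]
    base_b = [("IGHV1-2", "IGHJ4", c) for c in ["AAAA", "DDDD"]]
    before = pairwise_overlap([_rep_from_cdr3s(base_a, "a"), _rep_from_cdr3s(base_b, "b")],
                              unit="cdrh3").values.loc["a", "b"]
    after = pairwise_overlap(
        [_rep_from_cdr3s(base_a + [("IGHV1-2", "IGHJ4", "EEEE")], "a"),
         _rep_from_cdr3s(base_b + [("IGHV1-2", "IGHJ4", "EEEE")], "b")],
        unit="cdrh3").values.loc["a", "b"]
    assert after >= before


def test_stratified_downsample_identity_at_full_size(kymouse_reps):
    rep = kymouse_reps[2]
    heavy_n = int((rep.df["locus"] == "IGH").sum())
    down = stratified_downsample(rep, heavy_n, seed=0)
    assert sorted(down.df["sequence_id"]) == sorted(
        rep.df.loc[rep.df["locus"] == "IGH", "sequence_id"])
    with pytest.raises(XCompareError):
        stratified_downsample(rep, len(rep.df) + 1)


def test_stratified_downsample_preserves_clone_size_spectrum():
    """Chi-square distance of the clone-size composition, pre vs post, is
    smaller under stratified sampling than uniform record sampling (20 seeds)."""
    from xcompare import SimulationConfig, simulate_repertoire

    rep = simulate_repertoire(SimulationConfig(preset="mouse", n_subjects=1,
                                               n_sequences=2000, seed=77, paired=False))[0]
    assign = assign_clonotypes(rep)
    sizes = assign.members.set_index("sequence_id")["clone_id"].map(
        assign.clones.set_index("clone_id")["n_members"])
    bins = [1, 2, 3, 5, 9, np.inf]

    def comp(ids):
        s = sizes.loc[ids]
        hist = np.histogram(s, bins=bins)[0].astype(float)
        return hist / hist.sum()

    ref = comp(rep.df["sequence_id"])
    n_target = 400
    chi_strat, chi_unif = [], []
    for seed in range(20):
        down = stratified_downsample(rep, n_target, seed=seed)
        chi_strat.append(((comp(down.df["sequence_id"]) - ref) ** 2 / (ref + 1e-12)).sum())
        rng = np.random.default_rng(1000 + seed)
        ids = rep.df["sequence_id"].sample(n_target, random_state=seed)
        chi_unif.append(((comp(ids) - ref) ** 2 / (ref + 1e-12)).sum())
    assert np.mean(chi_strat) < np.mean(chi_unif)
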