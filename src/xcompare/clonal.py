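"""Clonotype assignment, CDRH3 sets, pairwise sharing, and downsampling.

A clonotype groups heavy-chain sequences inferred to descend from one
recombination event: common IGHV and IGHJ genes (allele-stripped) and at
least 90% amino-acid identity across length-matched CDRH3s.  Within each
(V, J, CDR3-length) partition, clustering is single-linkage by default, so
two sequences share a clone if they are connected by a chain of pairwise
links at or above the identity threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as _linkage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from xcompare.airr_io import Repertoire, strip_allele
from xcompare.errors import XCompareError

logger = logging.getLogger(__name__)


@dataclass
class ClonotypeAssignment:
    """Partition of records into clones.

    ``members`` has one row per assigned record (sequence_id, subject_id,
    clone_id); ``clones`` one row per clone with its defining V/J genes,
    CDR3 length, member count, subject count, and a representative CDR3.
    """

    members: pd.DataFrame
    clones: pd.DataFrame
    identity_threshold: float
    n_dropped: int = 0

    @property
    def n_clones(self) -> int:
        return len(self.clones)


@dataclass
class OverlapMatrix:
    """Subject x subject shared-percentage matrix."""

    values: pd.DataFrame
    unit: str
    convention: str

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v.values, v.values.T):
            raise ValueError("overlap matrix must be symmetric")


def _cdr3(series: pd.Series) -> pd.Series:
    """Junction interior: drop the two anchor residues."""
    return series.str[1:-1]


def _identity_clusters(cdr3s: list[str], threshold: float, method: str) -> np.ndarray:
    """Cluster equal-length CDR3 strings by Hamming identity >= threshold."""
    n = len(cdr3s)
    if n == 1:
        return np.zeros(1, dtype=int)
    L = len(cdr3s[0])
    arr = np.frombuffer("".join(cdr3s).encode(), dtype=np.uint8).reshape(n, L)
    # max mismatches allowed for identity >= threshold
    max_mm = int(np.floor((1.0 - threshold) * L + 1e-9))
    if method == "single":
        rows, cols = [], []
        chunk = max(1, int(2e7) // max(n * L, 1))
        for start in range(0, n, chunk):
            block = arr[start:start + chunk]
            mm = (block[:, None, :] != arr[None, :, :]).sum(axis=2)
            r, c = np.nonzero(mm <= max_mm)
            rows.extend((r + start).tolist())
            cols.extend(c.tolist())
        graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        _, labels = connected_components(graph, directed=False)
        return labels
    if method == "complete":
        mm = (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(float)
        Z = _linkage(squareform(mm, checks=False), method="complete")
        return fcluster(Z, t=max_mm, criterion="distance") - 1
    raise XCompareError(f"unknown clonotype linkage {method!r}")


def assign_clonotypes(reps: Repertoire | list[Repertoire],
                      identity_threshold: float = 0.90,
                      method: str = "single") -> ClonotypeAssignment:
    """Assign heavy-chain records (pooled across repertoires) to clonotypes.

    Records missing v_call, j_call or junction_aa are dropped with a logged
    count.  Clone IDs are deterministic given input order (numbered by first
    member occurrence).
    """
    if isinstance(reps, Repertoire):
        reps = [reps]
    frames = []
    for rep in reps:
        df = rep.df
        heavy = df[df["locus"] == "IGH"] if "locus" in df.columns else df
        frames.append(pd.DataFrame({
            "sequence_id": heavy["sequence_id"],
            "subject_id": rep.subject_id,
            "v_gene": heavy["v_call"].map(strip_allele, na_action="ignore"),
            "j_gene": heavy["j_call"].map(strip_allele, na_action="ignore"),
            "junction_aa": heavy["junction_aa"],
        }))
    pooled = pd.concat(frames, ignore_index=True)
    ok = pooled[["v_gene", "j_gene", "junction_aa"]].notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("assign_clonotypes: dropped %d records missing key fields", n_dropped)
    pooled = pooled[ok].reset_index(drop=True)
    pooled["cdr3"] = _cdr3(pooled["junction_aa"])
    pooled["cdr3_aa_length"] = pooled["cdr3"].str.len()

    clone_of = np.full(len(pooled), -1, dtype=int)
    next_id = 0
    clone_rows = []
    # groupby(sort=False) keeps first-occurrence partition order -> stable IDs
    for (v, j, length), idx in pooled.groupby(
            ["v_gene", "j_gene", "cdr3_aa_length"], sort=False).groups.items():
        idx = np.asarray(idx)
        sub = pooled.loc[idx]
        uniq = sub["cdr3"].drop_duplicates().tolist()
        labels = _identity_clusters(uniq, identity_threshold, method)
        label_of = dict(zip(uniq, labels))
        local = sub["cdr3"].map(label_of).to_numpy()
        for lab in pd.unique(local):
            members = idx[local == lab]
            clone_of[members] = next_id
            clone_rows.append({
                "clone_id": next_id, "v_gene": v, "j_gene": j,
                "cdr3_aa_length": int(length), "n_members": len(members),
                "n_subjects": pooled.loc[members, "subject_id"].nunique(),
                "representative": pooled.loc[members[0], "junction_aa"],
            })
            next_id += 1
    members = pooled[["sequence_id", "subject_id"]].copy()
    members["clone_id"] = clone_of
    clones = pd.DataFrame(clone_rows)
    return ClonotypeAssignment(members=members, clones=clones,
                               identity_threshold=identity_threshold, n_dropped=n_dropped)


def exact_cdrh3_set(rep: Repertoire) -> set[str]:
    """Deduplicated CDR3 amino-acid strings (junction minus anchors) of heavy records."""
    df = rep.df
    heavy = df[df["locus"] == "IGH"] if "locus" in df.columns else df
    junctions = heavy["junction_aa"].dropna()
    return set(_cdr3(junctions))


def pairwise_overlap(reps: list[Repertoire], unit: str = "cdrh3",
                     convention: str = "mean",
                     identity_threshold: float = 0.90) -> OverlapMatrix:
    """Pairwise shared-percentage matrix between repertoires.

    ``unit='cdrh3'`` counts exact amino-acid CDR3 matches; ``unit='clonotype'``
    jointly clusters each pooled pair so near-identical cross-subject CDR3s
    count as shared.  ``convention`` names the denominator: ``mean`` of the
    two directional fractions (default), ``min`` (the larger fraction of the
    smaller set... i.e. shared / min set size), or ``jaccard``.
    """
    if len(reps) < 2:
        raise XCompareError("pairwise_overlap needs at least 2 repertoires")
    if convention not in {"mean", "min", "jaccard"}:
        raise XCompareError(f"unknown overlap convention {convention!r}")
    subjects = [r.subject_id for r in reps]
    n = len(reps)
    mat = np.full((n, n), 100.0)

    if unit == "cdrh3":
        sets = [exact_cdrh3_set(r) for r in reps]
        for i in range(n):
            for j in range(i + 1, n):
                shared = len(sets[i] & sets[j])
                na, nb = len(sets[i]), len(sets[j])
                mat[i, j] = mat[j, i] = _percent(shared, na, nb, convention)
    elif unit == "clonotype":
        for rep in reps:
            df = rep.df
            if "locus" in df.columns and (df["locus"] != "IGH").any():
                has_heavy = (df["locus"] == "IGH").any()
                if not has_heavy:
                    raise XCompareError(
                        f"clonotype overlap undefined for light-chain-only repertoire {rep.subject_id}")
        for i in range(n):
            for j in range(i + 1, n):
                assign = assign_clonotypes([reps[i], reps[j]], identity_threshold)
                per_clone = assign.members.groupby("clone_id")["subject_id"].agg(frozenset)
                a, b = reps[i].subject_id, reps[j].subject_id
                in_a = per_clone.map(lambda s: a in s)
                in_b = per_clone.map(lambda s: b in s)
                shared = int((in_a & in_b).sum())
                mat[i, j] = mat[j, i] = _percent(shared, int(in_a.sum()), int(in_b.sum()), convention)
    else:
        raise XCompareError(f"unknown overlap unit {unit!r}")
    values = pd.DataFrame(mat, index=subjects, columns=subjects)
    return OverlapMatrix(values=values, unit=unit, convention=convention)


def _percent(shared: int, na: int, nb: int, convention: str) -> float:
    if na == 0 or nb == 0:
        return 0.0
    if convention == "mean":
        return 100.0 * 0.5 * (shared / na + shared / nb)
    if convention == "min":
        return 100.0 * shared / min(na, nb)
    return 100.0 * shared / (na + nb - shared)  # jaccard


def stratified_downsample(rep: Repertoire, n_target: int, seed: int = 0,
                          identity_threshold: float = 0.90) -> Repertoire:
    """Downsample preserving the clonal structure.

    Records are stratified by the size of the clone they belong to; each
    stratum contributes records in proportion to its share of the full
    repertoire (largest-remainder rounding), so the post-sample clone-size
    composition matches the pre-sample one in expectation with lower
    variance than uniform record sampling.
    """
    if n_target > len(rep.df):
        raise XCompareError(f"n_target {n_target} exceeds repertoire size {len(rep.df)}")
    assign = assign_clonotypes(rep, identity_threshold)
    sizes = assign.members["clone_id"].map(assign.clones.set_index("clone_id")["n_members"])
    heavy_ids = assign.members["sequence_id"]
    stratum_of = pd.Series(sizes.values, index=heavy_ids.values)

    df = rep.df
    heavy_mask = df["locus"] == "IGH" if "locus" in df.columns else pd.Series(True, index=df.index)
    pool = df[heavy_mask & df["sequence_id"].isin(stratum_of.index)].reset_index(drop=True)
    strata = pool["sequence_id"].map(stratum_of)

    rng = np.random.default_rng(seed)
    counts = strata.value_counts().sort_index()
    exact = counts / counts.sum() * n_target
    base = np.floor(exact).astype(int)
    remainder = n_target - int(base.sum())
    if remainder > 0:
        order = (exact - base).sort_values(ascending=False).index[:remainder]
        base.loc[order] += 1
    chosen = []
    for stratum, k in base.items():
        if k == 0:
            continue
        members = np.flatnonzero(strata.values == stratum)
        chosen.extend(rng.choice(members, size=int(k), replace=False).tolist())
    out = pool.iloc[sorted(chosen)]
    return rep.with_df(out, note=f"stratified downsample to {n_target}")
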