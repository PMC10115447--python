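"""Comparison of repertoires by categorical structural annotations.

Each sequence carries a categorical annotation — a CDRH3 structural-cluster
ID (the best-matching backbone template from a clustered database) or a
canonical class — together with the species of origin of that template.
Repertoires are compared by their usage profiles over these categories:
Euclidean distance in Z-normalised proportions, hierarchical clustering,
species-origin bias of the clusters used, and length-stratified enrichment
of origin-specific templates against the database background.

Structure prediction itself is out of scope: this module consumes
annotation tables (TSV with columns subject_id, species, cdr3_aa_length,
category_id, category_origin) and provides a synthetic generator that
emulates them with species-biased category mixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import binomtest

from xcompare.errors import XCompareError
from xcompare.usage import (
    UsageProfile,
    adjusted_rand,
    align_profiles,
    cluster_profiles,
    linkage_to_newick,
    z_normalise,
)

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("subject_id", "species", "cdr3_aa_length", "category_id", "category_origin")

#: Default CDRH3 length window (aa) for structural analyses.
LENGTH_WINDOW = (4, 16)


def read_annotation_table(path) -> pd.DataFrame:
    """Read an annotation TSV, checking the column contract."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS[:4] if c not in table.columns]
    if missing:
        raise XCompareError(f"annotation table missing columns: {missing}")
    return table


def apply_length_window(table: pd.DataFrame,
                        window: tuple[int, int] = LENGTH_WINDOW) -> pd.DataFrame:
    lo, hi = window
    return table[(table["cdr3_aa_length"] >= lo) & (table["cdr3_aa_length"] <= hi)]


def category_usage_profile(table: pd.DataFrame, subject: str) -> UsageProfile:
    """Proportions over category_id for one subject (shared UsageProfile type)."""
    sub = table[table["subject_id"] == subject]
    if len(sub) == 0:
        raise XCompareError(f"unknown subject {subject!r}")
    counts = sub["category_id"].value_counts()
    axis = sorted(counts.index.astype(str))
    freqs = np.array([counts[a] for a in axis], dtype=float)
    freqs /= freqs.sum()
    return UsageProfile(subject_id=subject, axis=axis, frequencies=freqs,
                        n_sequences=int(counts.sum()))


@dataclass
class UsageDistanceResult:
    """Pairwise distances, tree, 2-cut ARI and comparison-type distributions."""

    distances: pd.DataFrame
    linkage: np.ndarray
    newick: str
    cut: pd.Series
    ari: float
    comparisons: pd.DataFrame


def usage_distance_analysis(table: pd.DataFrame, true_labels: dict[str, str],
                            linkage: str = "average") -> UsageDistanceResult:
    """The structural usage-distance analysis.

    Z-normalises per-subject category proportions, measures pairwise
    Euclidean distances, clusters hierarchically, scores the 2-cluster cut
    against ``true_labels`` with the ARI, and tabulates the distance
    distributions stratified by comparison type (within-label vs between).
    """
    subjects = sorted(table["subject_id"].unique())
    if len(subjects) < 3 or len(set(true_labels[s] for s in subjects)) < 2:
        raise XCompareError("usage_distance_analysis needs >=3 subjects spanning >=2 labels")
    profiles = [category_usage_profile(table, s) for s in subjects]
    frame = align_profiles(profiles)
    if frame.shape[1] == 0:
        raise XCompareError("shared category axis is empty")
    z = z_normalise(frame)
    dist = pd.DataFrame(squareform(pdist(z.values, metric="euclidean")),
                        index=subjects, columns=subjects)
    Z, cut = cluster_profiles(z, linkage=linkage)
    truth = [true_labels[s] for s in subjects]
    ari = adjusted_rand(truth, cut.values)
    rows = []
    for i, a in enumerate(subjects):
        for b in subjects[i + 1:]:
            la, lb = true_labels[a], true_labels[b]
            kind = f"{la} vs {la}" if la == lb else f"{min(la, lb)} vs {max(la, lb)}"
            rows.append((a, b, kind, float(dist.loc[a, b])))
    comparisons = pd.DataFrame(rows, columns=["subject_a", "subject_b", "comparison", "distance"])
    return UsageDistanceResult(distances=dist, linkage=Z,
                               newick=linkage_to_newick(Z, subjects),
                               cut=cut, ari=ari, comparisons=comparisons)


def species_origin_bias(table: pd.DataFrame, subjects: list[str] | None = None,
                        weighted: bool = False) -> pd.Series:
    """Proportion of used categories by template species of origin.

    Default counts *distinct* categories used by the subject group; the
    ``weighted`` flag switches to sequence-weighted usage.  Categories with
    missing origin are excluded from the denominator (warned above 10%).
    """
    sub = table if subjects is None else table[table["subject_id"].isin(subjects)]
    if "category_origin" not in sub.columns:
        raise XCompareError("annotation table has no category_origin column")
    n_all = sub["category_id"].nunique()
    known = sub[sub["category_origin"].notna()]
    n_missing = n_all - known["category_id"].nunique()
    if n_all and n_missing / n_all > 0.10:
        logger.warning("species_origin_bias: %d/%d categories lack an origin", n_missing, n_all)
    if weighted:
        props = known["category_origin"].value_counts(normalize=True)
    else:
        origin_of = known.drop_duplicates("category_id").set_index("category_id")["category_origin"]
        props = origin_of.value_counts(normalize=True)
    return props.sort_index()


def enrichment_by_length(table: pd.DataFrame, background: pd.DataFrame, origin: str,
                         alpha: float = 0.01) -> pd.DataFrame:
    """Length-stratified enrichment of origin-specific template usage.

    ``background`` has columns (category_id, origin, cdr3_aa_length,
    frequency) with frequencies summing to 1 within each length stratum.
    Per observed length: ratio = observed origin proportion / background
    origin proportion, with a two-sided exact binomial test against the
    background proportion; ``significant`` flags p < alpha (1% default).
    """
    bg_prop = (background.groupby("cdr3_aa_length")
               .apply(lambda g: g.loc[g["origin"] == origin, "frequency"].sum(),
                      include_groups=False))
    rows = []
    for length, group in table.groupby("cdr3_aa_length"):
        if length not in bg_prop.index:
            raise XCompareError(f"background does not cover CDRH3 length {length}")
        n = len(group)
        k = int((group["category_origin"] == origin).sum())
        p_bg = float(bg_prop.loc[length])
        observed = k / n
        if p_bg == 0:
            ratio, p = (float("inf") if k else float("nan")), 1.0 if k == 0 else 0.0
        else:
            ratio = observed / p_bg
            p = binomtest(k, n, min(p_bg, 1.0), alternative="two-sided").pvalue
        rows.append((int(length), n, k, observed, p_bg, ratio, float(p), p < alpha))
    return pd.DataFrame(rows, columns=["cdr3_aa_length", "n", "k", "observed",
                                       "background", "ratio", "p", "significant"])


def greedy_cluster(distances: pd.DataFrame | np.ndarray, cutoff: float) -> np.ndarray:
    """Greedy leader clustering of items under a distance cutoff.

    Items are visited in input order; an item joins the first existing
    cluster whose *representative* (founder) is within ``cutoff``, else it
    founds a new cluster.  Deterministic given input order — callers should
    fix the order (e.g. sort by item ID) for reproducibility.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise XCompareError("greedy_cluster needs a square matrix")
    if np.abs(D - D.T).max() > 1e-9:
        raise XCompareError("greedy_cluster: matrix is not symmetric")
    if (D < 0).any() or np.abs(np.diag(D)).max() > 1e-12:
        raise XCompareError("greedy_cluster: need non-negative distances with zero diagonal")
    n = D.shape[0]
    labels = np.full(n, -1, dtype=int)
    representatives: list[int] = []
    for i in range(n):
        for ci, rep in enumerate(representatives):
            if D[i, rep] <= cutoff:
                labels[i] = ci
                break
        else:
            labels[i] = len(representatives)
            representatives.append(i)
    return labels


def length_balanced_subsample(table: pd.DataFrame, n_per_length: int,
                              n_subsamples: int = 100, seed: int = 0,
                              window: tuple[int, int] = LENGTH_WINDOW,
                              retain: str = "all") -> list[pd.DataFrame]:
    """Equal-count-per-length subsamples of an annotation table.

    With ``retain='all'`` every length inside ``window`` observed in any
    subject is retained and every subject must have at least
    ``n_per_length`` sequences at each (else an error names the limiting
    subject/length).  With ``retain='feasible'`` the retained window is
    narrowed to the lengths at which all subjects meet the count (logged).
    Returns ``n_subsamples`` sub-tables, deterministic under ``seed``.
    """
    tab = apply_length_window(table, window)
    subjects = sorted(tab["subject_id"].unique())
    per = tab.groupby(["subject_id", "cdr3_aa_length"]).size().unstack(fill_value=0)
    if retain == "feasible":
        retained = [l for l in per.columns if (per[l] >= n_per_length).all()]
        if not retained:
            raise XCompareError(f"no CDRH3 length has >= {n_per_length} sequences in every subject")
        logger.info("length_balanced_subsample: retained lengths %s", retained)
    elif retain == "all":
        retained = [l for l in per.columns if (per[l] > 0).all()]
        if not retained:
            raise XCompareError("no CDRH3 length is observed in every subject")
        for subject in subjects:
            for length in retained:
                if per.loc[subject, length] < n_per_length:
                    raise XCompareError(
                        f"subject {subject} has only {per.loc[subject, length]} sequences at "
                        f"length {length} (< n_per_length={n_per_length})")
    else:
        raise XCompareError(f"retain must be 'all' or 'feasible', got {retain!r}")
    rng = np.random.default_rng(seed)
    groups = {k: v for k, v in tab.groupby(["subject_id", "cdr3_aa_length"]).groups.items()}
    out = []
    for _ in range(n_subsamples):
        picks = []
        for subject in subjects:
            for length in retained:
                idx = np.asarray(groups[(subject, length)])
                picks.extend(rng.choice(idx, size=n_per_length, replace=False).tolist())
        out.append(tab.loc[sorted(picks)])
    return out


# ---------------------------------------------------------------------------
# synthetic annotation generator

_ORIGIN_PROPS = {"human": 0.37, "mouse": 0.41, "other": 0.22}

#: Origin-bias multipliers applied to template background weights when a
#: species samples its structural space: each species prefers (but is not
#: confined to) templates derived from its own kind of antibody; the
#: humanised transgenic preset inherits a human-like preference.
_SPECIES_BIAS = {
    "human": {"human": 3.0, "mouse": 0.8, "other": 1.0},
    "kymouse": {"human": 2.6, "mouse": 0.9, "other": 1.0},
    "mouse": {"human": 0.7, "mouse": 3.5, "other": 1.0},
}

_LENGTH_MEAN = {"human": 12.6, "kymouse": 12.0, "mouse": 11.2}


def simulate_annotation_tables(n_subjects: dict[str, int], n_per_subject: int = 2000,
                               n_clusters: int = 1000, seed: int = 0,
                               window: tuple[int, int] = LENGTH_WINDOW
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic annotation table + background composition emulating the
    structural-cluster usage scenario.

    A pool of ``n_clusters`` templates is drawn with origins in the database
    proportions (41% murine, 37% human) and lengths spread over the window;
    each subject samples sequences whose length follows its species'
    distribution and whose cluster is drawn from the background at that
    length re-weighted by the species' origin bias.  Returns
    ``(annotation_table, background)``; background frequencies sum to 1
    within each length stratum.
    """
    rng = np.random.default_rng(seed)
    lo, hi = window
    lengths = np.arange(lo, hi + 1)
    origins = rng.choice(list(_ORIGIN_PROPS), size=n_clusters,
                         p=list(_ORIGIN_PROPS.values()))
    cl_lengths = rng.choice(lengths, size=n_clusters)
    # heavy-tailed template popularity: most templates are rarely matched,
    # so a repertoire of a few thousand sequences does not saturate the pool
    weights = rng.dirichlet(np.full(n_clusters, 0.5))
    pool = pd.DataFrame({
        "category_id": [f"C{i:04d}" for i in range(n_clusters)],
        "origin": origins,
        "cdr3_aa_length": cl_lengths,
        "weight": weights,
    })
    background = pool.copy()
    background["frequency"] = background.groupby("cdr3_aa_length")["weight"].transform(
        lambda w: w / w.sum())
    background = background[["category_id", "origin", "cdr3_aa_length", "frequency"]]

    rows = []
    for species, n_sub in n_subjects.items():
        bias = _SPECIES_BIAS[species]
        mu = _LENGTH_MEAN[species]
        length_w = np.exp(-0.5 * ((lengths - mu) / 2.5) ** 2)
        length_w /= length_w.sum()
        for si in range(n_sub):
            subject = f"{species}_{si + 1}"
            # per-subject jitter so subjects of one species are similar, not identical
            subj_bias = {o: b * rng.lognormal(0.0, 0.10) for o, b in bias.items()}
            drawn_lengths = rng.choice(lengths, size=n_per_subject, p=length_w)
            for length, count in zip(*np.unique(drawn_lengths, return_counts=True)):
                avail = pool[pool["cdr3_aa_length"] == length]
                if len(avail) == 0:
                    continue
                w = avail["weight"].values * avail["origin"].map(subj_bias).values
                picks = rng.choice(len(avail), size=int(count), p=w / w.sum())
                for k in picks:
                    rows.append((subject, species, int(length),
                                 avail.iloc[k]["category_id"], avail.iloc[k]["origin"]))
    table = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    return table, background
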