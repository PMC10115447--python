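"""Gene-usage profiles, separability under subsampling, and per-gene testing.

The central comparison in this package asks whether repertoires from two
populations can be told apart from their germline gene usage alone.  The
protocol: subsample every repertoire to a common depth, compute per-subject
usage frequency vectors, Z-normalise each gene across subjects, cluster the
subjects hierarchically (Euclidean distance), cut the tree into two groups
and score the cut against the true population labels with the adjusted Rand
index (ARI); the fraction of subsampling repeats with ARI = 1.0 measures
separability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from xcompare.airr_io import Repertoire, parse_gene_call, strip_allele
from xcompare.errors import EmptyResultError, XCompareError

logger = logging.getLogger(__name__)

HEAVY = ("IGH",)
LIGHT = ("IGK", "IGL")


@dataclass
class UsageProfile:
    """Per-subject frequency vector over an ordered category axis."""

    subject_id: str
    axis: list[str]
    frequencies: np.ndarray
    n_sequences: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.axis) != len(self.frequencies):
            raise ValueError("axis and frequencies differ in length")
        if len(set(self.axis)) != len(self.axis):
            raise ValueError("axis labels must be unique")
        if (self.frequencies < -1e-12).any() or abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be non-negative and sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.frequencies, index=self.axis, name=self.subject_id)


@dataclass
class SeparabilityResult:
    """Outcome of the repeated-subsampling separability protocol."""

    fraction_perfect: float
    ari_values: list[float]
    n_repeats: int
    subsample_n: int
    seed: int

    def __post_init__(self) -> None:
        expect = float(np.mean([a >= 1.0 - 1e-12 for a in self.ari_values]))
        if abs(expect - self.fraction_perfect) > 1e-9:
            raise ValueError("fraction_perfect inconsistent with per-repeat ARI values")


def _segment_labels(rep: Repertoire, segment: str, level: str, loci: tuple[str, ...]) -> pd.Series:
    """Allele-stripped gene (or subgroup) labels of all records carrying the call."""
    if segment not in {"V", "D", "J"}:
        raise XCompareError(f"segment must be V, D or J, got {segment!r}")
    col = {"V": "v_call", "D": "d_call", "J": "j_call"}[segment]
    df = rep.df
    mask = df["locus"].isin(loci) if "locus" in df.columns else pd.Series(True, index=df.index)
    calls = df.loc[mask, col] if col in df.columns else pd.Series(dtype=str)
    calls = calls.dropna().astype(str)
    calls = calls[calls.str.len() > 0]
    if calls.empty:
        raise EmptyResultError(
            f"{rep.subject_id}: no records with a {segment} call on loci {loci}")
    genes = calls.map(strip_allele)
    if level == "gene":
        return genes
    if level == "subgroup":
        return genes.map(lambda g: parse_gene_call(g).subgroup)
    raise XCompareError(f"level must be 'gene' or 'subgroup', got {level!r}")


def usage_profile(rep: Repertoire, segment: str = "V", level: str = "gene",
                  loci: tuple[str, ...] = HEAVY,
                  reference_labels: list[str] | None = None) -> UsageProfile:
    """Frequency of each gene (or subgroup) among records carrying the call.

    Frequencies are per record row, i.e. per unique sequence once the
    repertoire has been collapsed.  ``reference_labels`` extends the axis
    with zero-frequency entries so profiles from different subjects share
    an axis.
    """
    labels = _segment_labels(rep, segment, level, loci)
    counts = labels.value_counts()
    axis = sorted(set(counts.index) | set(reference_labels or []))
    freqs = np.array([counts.get(a, 0) for a in axis], dtype=float)
    freqs /= freqs.sum()
    return UsageProfile(subject_id=rep.subject_id, axis=axis, frequencies=freqs,
                        n_sequences=int(counts.sum()))


def kappa_lambda_ratio(rep: Repertoire) -> tuple[float, float]:
    """Percentage of light-chain records on the kappa vs lambda locus."""
    df = rep.df
    light = df[df["locus"].isin(LIGHT)] if "locus" in df.columns else df.iloc[0:0]
    if len(light) == 0:
        raise EmptyResultError(f"{rep.subject_id}: no light-chain records")
    kappa = float((light["locus"] == "IGK").mean()) * 100.0
    return kappa, 100.0 - kappa


def align_profiles(profiles: list[UsageProfile]) -> pd.DataFrame:
    """Stack profiles into a subjects x categories frequency matrix (0-filled)."""
    frame = pd.DataFrame([p.as_series() for p in profiles]).fillna(0.0)
    frame.index = [p.subject_id for p in profiles]
    return frame


def z_normalise(profiles: list[UsageProfile] | pd.DataFrame) -> pd.DataFrame:
    """Z-normalise each category across subjects (sample sd, ddof=1).

    Zero-variance categories are set to all-zero (logged), so they carry no
    weight in downstream distances.
    """
    frame = profiles if isinstance(profiles, pd.DataFrame) else align_profiles(profiles)
    if len(frame) < 2:
        raise XCompareError("z_normalise needs at least 2 profiles")
    mean = frame.mean(axis=0)
    sd = frame.std(axis=0, ddof=1)
    flat = sd <= 1e-12  # tolerance: identical columns can leave sd ~ 1e-17
    if flat.any():
        logger.info("z_normalise: %d zero-variance categories set to 0", int(flat.sum()))
    z = (frame - mean).div(sd.where(~flat, 1.0), axis=1)
    z.loc[:, flat] = 0.0
    return z


def cluster_profiles(matrix: pd.DataFrame, linkage: str = "average") -> tuple[np.ndarray, pd.Series]:
    """Agglomerative clustering of subjects on Euclidean distance.

    Returns the scipy linkage matrix and the 2-cluster cut labels (Series
    indexed by subject).  Average linkage (UPGMA) is the default; ``complete``
    and ``ward`` are accepted.
    """
    if len(matrix) < 2:
        raise XCompareError("cluster_profiles needs at least 2 rows")
    values = np.asarray(matrix, dtype=float)
    if np.isnan(values).any():
        raise XCompareError("cluster_profiles: NaN in input matrix")
    Z = hierarchy.linkage(values, method=linkage, metric="euclidean")
    cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return Z, pd.Series(cut, index=matrix.index, name="cluster")


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def _rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = _rec(node.get_left(), node.dist)
        right = _rec(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return _rec(tree, tree.dist) + ";"


def adjusted_rand(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (1.0 = identical)."""
    labels_a, labels_b = list(labels_a), list(labels_b)
    if len(labels_a) != len(labels_b):
        raise XCompareError("adjusted_rand: label vectors differ in length")
    if len(labels_a) < 2:
        raise XCompareError("adjusted_rand needs at least 2 items")
    return float(adjusted_rand_score(labels_a, labels_b))


def separability_test(reps: list[Repertoire], true_labels: dict[str, str],
                      subsample_n: int = 105, n_repeats: int = 100, seed: int = 0,
                      segment: str = "V", level: str = "gene",
                      loci: tuple[str, ...] = HEAVY,
                      linkage: str = "average") -> SeparabilityResult:
    """Repeated-subsampling separability of repertoire groups by gene usage.

    Per repeat: subsample each repertoire (without replacement) to
    ``subsample_n`` records carrying the segment call, recompute usage
    profiles on the shared axis, Z-normalise, cluster, and score the
    2-cluster cut against ``true_labels`` with the ARI.  Reports the
    fraction of repeats achieving ARI = 1.0.
    """
    all_labels = [_segment_labels(r, segment, level, loci) for r in reps]
    for rep, lab in zip(reps, all_labels):
        if len(lab) < subsample_n:
            raise XCompareError(
                f"subsample_n={subsample_n} exceeds {rep.subject_id} "
                f"({len(lab)} records with a {segment} call)")
    truth = [true_labels[r.subject_id] for r in reps]
    axis = sorted(set().union(*[set(l.unique()) for l in all_labels]))
    rng = np.random.default_rng(seed)
    aris = []
    for _ in range(n_repeats):
        rows = []
        for lab in all_labels:
            take = lab.iloc[rng.choice(len(lab), size=subsample_n, replace=False)]
            counts = take.value_counts()
            rows.append([counts.get(a, 0) / subsample_n for a in axis])
        frame = pd.DataFrame(rows, index=[r.subject_id for r in reps], columns=axis)
        z = z_normalise(frame)
        _, cut = cluster_profiles(z, linkage=linkage)
        aris.append(adjusted_rand(truth, cut.values))
    frac = float(np.mean([a >= 1.0 - 1e-12 for a in aris]))
    return SeparabilityResult(fraction_perfect=frac, ari_values=aris,
                              n_repeats=n_repeats, subsample_n=subsample_n, seed=seed)


def usage_difference_tests(group_a: list[UsageProfile], group_b: list[UsageProfile],
                           method: str = "mannwhitney") -> pd.DataFrame:
    """Per-category two-sided rank-sum tests between two subject groups.

    Returns a DataFrame (category, statistic, p, p_adj) with Benjamini-
    Hochberg adjustment across categories.  The choice of test is a
    convention (the comparison design only fixes 'a two-sided test across
    subjects'); Mann-Whitney U is the default.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise XCompareError("usage_difference_tests needs >=2 subjects per group")
    if len(group_a) < 3 or len(group_b) < 3:
        logger.warning("usage_difference_tests: fewer than 3 subjects per group")
    if method != "mannwhitney":
        raise XCompareError(f"unknown test method {method!r}")
    fa, fb = align_profiles(group_a), align_profiles(group_b)
    axis = sorted(set(fa.columns) | set(fb.columns))
    fa = fa.reindex(columns=axis, fill_value=0.0)
    fb = fb.reindex(columns=axis, fill_value=0.0)
    rows = []
    for cat in axis:
        a, b = fa[cat].values, fb[cat].values
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = len(a) * len(b) / 2.0, 1.0
        else:
            stat, p = mannwhitneyu(a, b, alternative="two-sided")
        rows.append((cat, float(stat), float(p)))
    out = pd.DataFrame(rows, columns=["category", "statistic", "p"])
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def richness_at_depth(rep: Repertoire, depth: int, n_repeats: int = 100, seed: int = 0,
                      segment: str = "V", level: str = "gene",
                      loci: tuple[str, ...] = HEAVY) -> float:
    """Mean distinct-category count in without-replacement subsamples.

    ``segment='VJ'`` counts distinct V x J gene combinations (combinatorial
    diversity); otherwise distinct genes/subgroups of one segment.
    """
    if segment == "VJ":
        v = _segment_labels(rep, "V", level, loci)
        j = _segment_labels(rep, "J", level, loci)
        common = v.index.intersection(j.index)
        labels = (v.loc[common] + "|" + j.loc[common]).reset_index(drop=True)
    else:
        labels = _segment_labels(rep, segment, level, loci).reset_index(drop=True)
    if depth > len(labels):
        raise XCompareError(f"depth {depth} exceeds repertoire size {len(labels)}")
    rng = np.random.default_rng(seed)
    counts = [labels.iloc[rng.choice(len(labels), size=depth, replace=False)].nunique()
              for _ in range(n_repeats)]
    return float(np.mean(counts))
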