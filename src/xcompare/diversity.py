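"""Shannon diversity of CDRH3 and clonotype abundance distributions.

Diversity is computed over unique sequences (not read counts): the abundance
of a CDRH3 is the number of unique sequences carrying it, and likewise for
clonotypes.  H = -sum p_i ln p_i in nats, so a uniform distribution over s
categories gives exactly ln s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from xcompare.airr_io import Repertoire
from xcompare.clonal import assign_clonotypes
from xcompare.errors import XCompareError


@dataclass
class DiversityResult:
    """Shannon entropy of one abundance distribution."""

    H: float
    s: int
    p: np.ndarray
    stratum: str = "all"


def shannon_entropy(abundances) -> float:
    """Shannon entropy (natural log) of counts or proportions.

    Input is normalised to proportions; zero entries contribute nothing
    (0 ln 0 = 0).  Raises on empty, all-zero, or negative input.
    """
    a = np.asarray(list(abundances) if not isinstance(abundances, np.ndarray) else abundances,
                   dtype=float)
    if a.size == 0 or (a < 0).any() or a.sum() <= 0:
        raise XCompareError("shannon_entropy needs non-negative input with a positive sum")
    return float(_scipy_entropy(a))


def _unit_counts(rep: Repertoire, unit: str):
    """Per-record unit label and CDR3 length for heavy records."""
    df = rep.df
    heavy = df[df["locus"] == "IGH"] if "locus" in df.columns else df
    heavy = heavy[heavy["junction_aa"].notna()]
    cdr3 = heavy["junction_aa"].str[1:-1]
    lengths = cdr3.str.len()
    if unit == "cdrh3":
        labels = cdr3
    elif unit == "clonotype":
        assign = assign_clonotypes(rep)
        clone_of = assign.members.set_index("sequence_id")["clone_id"]
        labels = heavy["sequence_id"].map(clone_of)
        keep = labels.notna()
        labels, lengths = labels[keep], lengths[keep]
    else:
        raise XCompareError(f"unknown diversity unit {unit!r}")
    return labels, lengths


def per_length_diversity(rep: Repertoire, unit: str = "cdrh3") -> dict[int, DiversityResult]:
    """Shannon entropy of unit abundances within each CDR3 aa-length stratum.

    Strata with fewer than two distinct units report H = 0 (single-category
    distribution); empty strata are absent from the map.
    """
    labels, lengths = _unit_counts(rep, unit)
    out: dict[int, DiversityResult] = {}
    for length, group in labels.groupby(lengths):
        counts = group.value_counts().to_numpy(dtype=float)
        p = counts / counts.sum()
        out[int(length)] = DiversityResult(
            H=shannon_entropy(counts), s=len(counts), p=p, stratum=str(int(length)))
    return out


def repertoire_diversity(rep: Repertoire, unit: str = "cdrh3") -> DiversityResult:
    """Shannon entropy of the whole-repertoire unit abundance distribution."""
    labels, _ = _unit_counts(rep, unit)
    counts = labels.value_counts().to_numpy(dtype=float)
    return DiversityResult(H=shannon_entropy(counts), s=len(counts),
                           p=counts / counts.sum(), stratum="all")


def unique_per_sequence_ratio(rep: Repertoire, unit: str = "cdrh3") -> float:
    """Distinct units divided by the number of (unique) sequences."""
    labels, _ = _unit_counts(rep, unit)
    if len(labels) == 0:
        raise XCompareError(f"{rep.subject_id}: no heavy records with junctions")
    return float(labels.nunique() / len(labels))
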