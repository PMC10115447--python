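"""Domain model and I/O for AIRR Rearrangement tables.

A :class:`Repertoire` wraps a pandas DataFrame whose columns follow the AIRR
Rearrangement schema names (``sequence_id``, ``v_call``, ``junction_aa``,
``np1_length`` ...) plus a few extension columns used by the junction
decomposition (``v_cdr3_nt``, ``d_align_nt``, ``j_cdr3_nt``).  All analysis
functions in the package consume and return this type.

The filtering conventions implemented here define the *naive* repertoire as
IgM sequences carrying zero nucleotide mutations relative to their assigned
germline, and deduplicate on the full available nucleotide sequence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from xcompare.errors import EmptyInputError, EmptyResultError, FormatError, ParseError

logger = logging.getLogger(__name__)

#: Columns that must be present in any readable rearrangement table.
MANDATORY_COLUMNS = ("sequence_id", "v_call", "j_call", "junction_aa")

#: Columns written out for every repertoire (missing ones are filled with NA).
OUTPUT_COLUMNS = (
    "sequence_id",
    "locus",
    "isotype",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "np1_length",
    "np2_length",
    "v_cdr3_nt",
    "d_align_nt",
    "j_cdr3_nt",
    "mutation_count",
    "duplicate_count",
    "v_call_ambiguous",
)

_GENE_RE = re.compile(r"^(IGH|IGK|IGL)([VDJ])(\d+)")


@dataclass(frozen=True)
class GeneCall:
    """A parsed germline gene call, e.g. ``IGHV3-23*01``.

    ``subgroup`` is the gene family (leading letters plus the first numeral
    block, e.g. ``IGHV3``); ``gene`` drops the allele suffix; ``allele`` is
    the two-digit allele designation or ``None``.
    """

    locus: str
    segment: str
    subgroup: str
    gene: str
    allele: str | None = None

    def __post_init__(self) -> None:
        if not self.gene.startswith(self.subgroup):
            raise ValueError(f"subgroup {self.subgroup!r} is not a prefix of gene {self.gene!r}")
        if not self.gene.startswith(self.locus):
            raise ValueError(f"locus {self.locus!r} inconsistent with gene {self.gene!r}")


def parse_gene_call(call_string: str) -> GeneCall:
    """Parse a single IMGT-style gene call into its nomenclature parts.

    Multi-hit strings (``"IGHV3-23*01,IGHV3-23*04"``) must be split by the
    caller first; this function handles exactly one designation.
    """
    if not call_string or not isinstance(call_string, str):
        raise ParseError(f"empty or non-string gene call: {call_string!r}")
    call_string = call_string.strip()
    m = _GENE_RE.match(call_string)
    if m is None:
        raise ParseError(f"unparseable gene call (expected IGH/IGK/IGL prefix): {call_string!r}")
    locus = m.group(1)
    segment = m.group(2)
    subgroup = locus + segment + m.group(3)
    if "*" in call_string:
        gene, allele = call_string.split("*", 1)
    else:
        gene, allele = call_string, None
    return GeneCall(locus=locus, segment=segment, subgroup=subgroup, gene=gene, allele=allele)


def strip_allele(call_string: str) -> str:
    """Drop the ``*NN`` allele suffix from a gene designation."""
    return call_string.split("*", 1)[0]


@dataclass
class Repertoire:
    """A subject-labelled collection of annotated rearrangements.

    ``df`` holds one row per record with AIRR-named columns.  Frequencies
    reported by downstream analyses are per row (i.e. per unique sequence once
    :func:`collapse_unique` has been applied).
    """

    subject_id: str
    species: str
    df: pd.DataFrame
    provenance: str = ""
    dropped: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cdr3_aa_lengths(self) -> pd.Series:
        """Amino-acid CDR3 lengths (junction minus the two anchor residues)."""
        return self.df["junction_aa"].str.len() - 2

    def with_df(self, df: pd.DataFrame, note: str = "") -> "Repertoire":
        prov = self.provenance + ("; " + note if note else "")
        return replace(self, df=df.reset_index(drop=True), provenance=prov)


def _first_call(series: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Split multi-hit gene calls, returning (first call, ambiguity flag)."""
    s = series.fillna("").astype(str)
    ambiguous = s.str.contains(",")
    first = s.str.split(",").str[0].str.strip()
    return first.where(first != "", other=pd.NA), ambiguous


def read_rearrangements(path: str | Path, species: str = "other", subject_id: str | None = None) -> Repertoire:
    """Read an AIRR Rearrangement TSV into a :class:`Repertoire`.

    Multi-gene ambiguous calls keep the first listed designation and set the
    ``v_call_ambiguous`` flag.  Rows missing ``junction_aa`` or with
    unparseable ``v_call``/``j_call`` are dropped; their counts are recorded
    in ``Repertoire.dropped`` and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    dropped: dict[str, int] = {}

    for seg in ("v_call", "d_call", "j_call"):
        if seg in df.columns:
            first, amb = _first_call(df[seg])
            df[seg] = first
            if seg == "v_call":
                df["v_call_ambiguous"] = amb

    # drop rows unusable for any CDR3-based analysis
    missing_junction = df["junction_aa"].isna() | (df["junction_aa"].astype(str).str.len() < 3)
    bad_call = pd.Series(False, index=df.index)
    for seg in ("v_call", "j_call"):
        vals = df[seg].fillna("")
        bad_call |= ~vals.str.match(_GENE_RE.pattern.replace("^", ""))
    keep = ~(missing_junction | bad_call)
    dropped["missing_junction_aa"] = int(missing_junction.sum())
    dropped["unparseable_gene_call"] = int((bad_call & ~missing_junction).sum())
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d malformed rows (%s)", path, n_dropped, dropped)
    df = df[keep].reset_index(drop=True)
    if len(df) == 0:
        raise EmptyResultError(f"{path}: all rows malformed ({dropped})")

    for col in ("np1_length", "np2_length", "v_cdr3_nt", "d_align_nt", "j_cdr3_nt", "mutation_count"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "duplicate_count" in df.columns:
        df["duplicate_count"] = pd.to_numeric(df["duplicate_count"], errors="coerce").fillna(1).astype(int)
    else:
        df["duplicate_count"] = 1
    if "locus" not in df.columns:
        df["locus"] = df["v_call"].str[:3]
    if "v_call_ambiguous" not in df.columns:
        df["v_call_ambiguous"] = False

    sid = subject_id if subject_id is not None else path.stem
    return Repertoire(subject_id=sid, species=species, df=df, provenance=f"read from {path}", dropped=dropped)


def write_rearrangements(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire back to AIRR Rearrangement TSV (UTF-8, tab-separated)."""
    path = Path(path)
    out = rep.df.copy()
    for col in OUTPUT_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    out = out[[c for c in OUTPUT_COLUMNS]]
    out.to_csv(path, sep="\t", index=False)


def filter_naive(rep: Repertoire) -> Repertoire:
    """Restrict to the naive compartment: IgM isotype with zero mutations.

    Order is preserved.  Raises :class:`EmptyResultError` with per-reason
    rejection counts if nothing survives.
    """
    df = rep.df
    if "isotype" not in df.columns or "mutation_count" not in df.columns:
        raise FormatError("filter_naive requires isotype and mutation_count columns")
    is_igm = df["isotype"].astype(str).str.upper().isin({"IGM", "M"})
    zero_mut = pd.to_numeric(df["mutation_count"], errors="coerce") == 0
    keep = is_igm & zero_mut
    if not keep.any():
        raise EmptyResultError(
            "no naive records: "
            f"{int((~is_igm).sum())} non-IgM, {int((~zero_mut).sum())} with mutations"
        )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_naive(%s): removed %d records", rep.subject_id, n_drop)
    return rep.with_df(df[keep], note=f"naive filter kept {int(keep.sum())}/{len(df)}")


def collapse_unique(rep: Repertoire) -> Repertoire:
    """Collapse to unique nucleotide sequences, accumulating duplicate_count.

    Deduplication uses the full available nucleotide sequence: the
    ``sequence`` column if present, otherwise ``junction`` (nucleotides).
    The first occurrence of each sequence is retained; total
    ``duplicate_count`` mass is conserved.
    """
    df = rep.df
    key_col = "sequence" if "sequence" in df.columns and df["sequence"].notna().all() else "junction"
    if key_col not in df.columns:
        raise FormatError("collapse_unique requires a 'sequence' or 'junction' column")
    counts = df.groupby(key_col, sort=False)["duplicate_count"].transform("sum")
    first = ~df.duplicated(subset=key_col, keep="first")
    out = df[first].copy()
    out["duplicate_count"] = counts[first].astype(int)
    return rep.with_df(out, note=f"collapsed {len(df)} reads to {len(out)} unique")
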