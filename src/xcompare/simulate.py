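"""Naive V(D)J repertoire simulator with human / mouse / Kymouse presets.

The simulator emulates the distributional structure of naive (IgM,
zero-mutation) B-cell receptor repertoires as printed for the three study
populations: species-specific V/D/J usage, Igkappa/Iglambda ratios,
zero-inflated VD/DJ N-insertion length distributions, D-segment trimming,
and clonal redundancy.  It produces :class:`~xcompare.airr_io.Repertoire`
objects (optionally written as AIRR Rearrangement TSV) so that every
downstream analysis is testable without sequencing data.

Calibration anchors (overall insertion mean, zero-insertion fraction,
kappa fraction) are carried per preset:

===========  ==========  ==========  ==============
preset       VD mean/z0  DJ mean/z0  kappa fraction
===========  ==========  ==========  ==============
human        7.30/0.082  6.77/0.045  0.62
kymouse      3.35/0.191  2.91/0.141  0.51
mouse        1.80/0.400  1.40/0.450  0.90
===========  ==========  ==========  ==============

Junction nucleotide length is forced to a multiple of three by choosing the
V-segment 3' trim (marginally uniform on {0,1,2}); stop codons are removed
by resampling the random N-region nucleotide *content* at fixed lengths.
Both choices keep the realised insertion-length distributions exactly equal
to the configured ones — a whole-draw rejection scheme would shorten the
accepted insertions, because longer junctions carry more random codons and
hence more stop codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from xcompare.airr_io import Repertoire, write_rearrangements
from xcompare.errors import SimulationError, XCompareError
from xcompare.germlines import GERMLINE_TABLES

_NT = np.array(list("ACGT"))

PRESET_NAMES = ("human", "mouse", "kymouse")


@dataclass(frozen=True)
class ZeroInflatedGeometric:
    """Insertion-length model: P(0) = zero_prob, else 1 + Geometric.

    ``mean`` is the *overall* mean (including zeros); the positive part is
    geometric on {1, 2, ...} with mean ``mean / (1 - zero_prob)``.  Geometric
    is the minimal one-parameter choice given that only means and zero
    fractions are calibrated.
    """

    zero_prob: float
    mean: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_prob <= 1.0:
            raise ValueError("zero_prob must be in [0, 1]")
        if self.mean < 0:
            raise ValueError("mean must be >= 0")
        if self.positive_mean < 1.0:
            raise ValueError("positive-part mean must be >= 1 nt")

    @property
    def positive_mean(self) -> float:
        return self.mean / (1.0 - self.zero_prob)

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | int:
        p = 1.0 / self.positive_mean
        if size is None:
            return 0 if rng.random() < self.zero_prob else int(rng.geometric(p))
        out = rng.geometric(p, size=size)
        out[rng.random(size) < self.zero_prob] = 0
        return out


@dataclass
class SpeciesPreset:
    """Parameter bundle describing one species' naive repertoire."""

    name: str
    heavy_v: dict[str, dict]
    heavy_d: dict[str, dict]
    heavy_j: dict[str, dict]
    kappa_v: dict[str, dict]
    lambda_v: dict[str, dict]
    kappa_j: dict[str, dict]
    lambda_j: dict[str, dict]
    kappa_fraction: float
    vd_insertion: ZeroInflatedGeometric
    dj_insertion: ZeroInflatedGeometric
    light_insertion: ZeroInflatedGeometric
    d_trim_max: int = 5       # per D end, uniform {0..d_trim_max}
    j_trim_max: int = 3       # J 5' end
    light_j_trim_max: int = 3
    clonal_redundancy: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa_fraction <= 1.0:
            raise ValueError("kappa_fraction must be in [0, 1]")
        if self.clonal_redundancy < 1.0:
            raise ValueError("clonal_redundancy must be >= 1")
        for label in ("heavy_v", "heavy_d", "heavy_j", "kappa_v", "lambda_v", "kappa_j", "lambda_j"):
            table = getattr(self, label)
            total = sum(g["usage"] for g in table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{label} usage sums to {total}, not 1")

    def usage(self, table_name: str) -> dict[str, float]:
        """Gene usage frequencies of one segment table."""
        return {g: e["usage"] for g, e in getattr(self, table_name).items()}


_PRESET_SCALARS = {
    "human": dict(vd=(0.082, 7.30), dj=(0.045, 6.77), light=(0.25, 2.0), kappa=0.62),
    "kymouse": dict(vd=(0.191, 3.35), dj=(0.141, 2.91), light=(0.25, 2.0), kappa=0.51),
    "mouse": dict(vd=(0.400, 1.80), dj=(0.450, 1.40), light=(0.35, 1.5), kappa=0.90),
}


def preset(name: str) -> SpeciesPreset:
    """Return the fully populated preset for ``human``, ``mouse`` or ``kymouse``."""
    if name not in PRESET_NAMES:
        raise XCompareError(f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}")
    tables = GERMLINE_TABLES[name]
    s = _PRESET_SCALARS[name]
    return SpeciesPreset(
        name=name,
        heavy_v={g: dict(e) for g, e in tables["heavy_v"].items()},
        heavy_d={g: dict(e) for g, e in tables["heavy_d"].items()},
        heavy_j={g: dict(e) for g, e in tables["heavy_j"].items()},
        kappa_v={g: dict(e) for g, e in tables["kappa_v"].items()},
        lambda_v={g: dict(e) for g, e in tables["lambda_v"].items()},
        kappa_j={g: dict(e) for g, e in tables["kappa_j"].items()},
        lambda_j={g: dict(e) for g, e in tables["lambda_j"].items()},
        kappa_fraction=s["kappa"],
        vd_insertion=ZeroInflatedGeometric(*s["vd"]),
        dj_insertion=ZeroInflatedGeometric(*s["dj"]),
        light_insertion=ZeroInflatedGeometric(*s["light"]),
    )


@dataclass
class SimulationConfig:
    """Configuration for one simulation run.

    ``jitter_concentration`` controls inter-subject variability: per-subject
    gene usage is drawn from Dirichlet(concentration x preset usage), so
    larger values give subjects closer to the preset frequencies.
    """

    preset: str | SpeciesPreset = "human"
    n_subjects: int = 1
    n_sequences: int = 1000
    seed: int = 0
    jitter_concentration: float = 500.0
    paired: bool = True  # emit a light-chain record alongside each heavy one

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_sequences < 1:
            raise ValueError("n_subjects and n_sequences must be >= 1")

    def resolve_preset(self) -> SpeciesPreset:
        return preset(self.preset) if isinstance(self.preset, str) else self.preset


_STOPS = ("TAA", "TAG", "TGA")


def _translate(nt: str) -> str:
    return str(Seq(nt).translate())


def _random_nt(rng: np.random.Generator, n: int) -> str:
    if n == 0:
        return ""
    return "".join(_NT[rng.integers(0, 4, size=n)])


def sample_junction(pre: SpeciesPreset, rng: np.random.Generator,
                    usage: dict[str, dict[str, float]] | None = None,
                    max_tries: int = 1000) -> dict:
    """Draw one heavy-chain junction with full anatomy.

    Returns a dict with gene calls, the five junction components in nt
    (``v_cdr3_nt``, ``np1``, ``d_align_nt``, ``np2``, ``j_cdr3_nt``; V and J
    contributions are measured from/to the conserved anchor codons, so the
    five components sum to the junction nucleotide length exactly), the
    assembled in-frame stop-free ``junction`` and its translation.
    """
    usage = usage or {}

    def _draw(table: dict[str, dict], key: str) -> str:
        freqs = usage.get(key) or {g: e["usage"] for g, e in table.items()}
        genes = list(freqs)
        return genes[rng.choice(len(genes), p=np.asarray([freqs[g] for g in genes]))]

    v_gene = _draw(pre.heavy_v, "heavy_v")
    d_gene = _draw(pre.heavy_d, "heavy_d")
    j_gene = _draw(pre.heavy_j, "heavy_j")
    v_entry, d_entry, j_entry = pre.heavy_v[v_gene], pre.heavy_d[d_gene], pre.heavy_j[j_gene]

    np1 = int(pre.vd_insertion.sample(rng))
    np2 = int(pre.dj_insertion.sample(rng))

    for attempt in range(max_tries):
        d5 = int(rng.integers(0, pre.d_trim_max + 1))
        d3 = int(rng.integers(0, pre.d_trim_max + 1))
        d_align = max(0, d_entry["length"] - d5 - d3)
        jt = int(rng.integers(0, pre.j_trim_max + 1))
        j_contrib = j_entry["length"] - jt
        # V 3' trim takes the unique value in {0,1,2} that makes the total a
        # multiple of 3; marginally uniform, so no length bias is introduced.
        rest = np1 + d_align + np2 + j_contrib
        vt = (v_entry["length"] + rest) % 3
        v_contrib = v_entry["length"] - vt

        v_part = v_entry["seq"][:v_contrib]
        d_part = d_entry["seq"][d5:d_entry["length"] - d3]
        j_part = j_entry["seq"][jt:]
        # resample only the random N content until the frame is stop-free
        for _ in range(100):
            junction = v_part + _random_nt(rng, np1) + d_part + _random_nt(rng, np2) + j_part
            aa = _translate(junction)
            if "*" not in aa:
                return {
                    "v_call": v_gene + "*01",
                    "d_call": d_gene + "*01",
                    "j_call": j_gene + "*01",
                    "locus": "IGH",
                    "v_cdr3_nt": v_contrib,
                    "np1_length": np1,
                    "d_align_nt": d_align,
                    "np2_length": np2,
                    "j_cdr3_nt": j_contrib,
                    "junction": junction,
                    "junction_aa": aa,
                }
            if np1 == 0 and np2 == 0:
                break  # stop spans germline-only nucleotides: redraw trims
    raise SimulationError(f"no productive junction within {max_tries} tries")


def sample_light_junction(pre: SpeciesPreset, rng: np.random.Generator,
                          usage: dict[str, dict[str, float]] | None = None,
                          max_tries: int = 1000) -> dict:
    """Draw one light-chain (kappa or lambda) junction."""
    usage = usage or {}
    locus = "IGK" if rng.random() < pre.kappa_fraction else "IGL"
    v_table = pre.kappa_v if locus == "IGK" else pre.lambda_v
    j_table = pre.kappa_j if locus == "IGK" else pre.lambda_j

    def _draw(table: dict[str, dict], key: str) -> str:
        freqs = usage.get(key) or {g: e["usage"] for g, e in table.items()}
        genes = list(freqs)
        return genes[rng.choice(len(genes), p=np.asarray([freqs[g] for g in genes]))]

    v_gene = _draw(v_table, f"{'kappa' if locus == 'IGK' else 'lambda'}_v")
    j_gene = _draw(j_table, f"{'kappa' if locus == 'IGK' else 'lambda'}_j")
    v_entry, j_entry = v_table[v_gene], j_table[j_gene]

    n_ins = int(pre.light_insertion.sample(rng))
    for _ in range(max_tries):
        jt = int(rng.integers(0, pre.light_j_trim_max + 1))
        j_contrib = j_entry["length"] - jt
        vt = (v_entry["length"] + n_ins + j_contrib) % 3
        v_contrib = v_entry["length"] - vt
        for _ in range(100):
            junction = v_entry["seq"][:v_contrib] + _random_nt(rng, n_ins) + j_entry["seq"][jt:]
            aa = _translate(junction)
            if "*" not in aa:
                return {
                    "v_call": v_gene + "*01",
                    "d_call": None,
                    "j_call": j_gene + "*01",
                    "locus": locus,
                    "v_cdr3_nt": v_contrib,
                    "np1_length": n_ins,
                    "d_align_nt": None,
                    "np2_length": None,
                    "j_cdr3_nt": j_contrib,
                    "junction": junction,
                    "junction_aa": aa,
                }
            if n_ins == 0:
                break
    raise SimulationError(f"no productive light junction within {max_tries} tries")


def _jitter_usage(pre: SpeciesPreset, rng: np.random.Generator, concentration: float) -> dict:
    """Per-subject usage: Dirichlet jitter around the preset frequencies."""
    out = {}
    for key in ("heavy_v", "heavy_d", "heavy_j", "kappa_v", "lambda_v", "kappa_j", "lambda_j"):
        freqs = pre.usage(key)
        genes = list(freqs)
        alpha = np.maximum(concentration * np.asarray([freqs[g] for g in genes]), 1e-3)
        drawn = rng.dirichlet(alpha)
        out[key] = dict(zip(genes, drawn))
    return out


def _clone_sizes(n_reads: int, redundancy: float, rng: np.random.Generator) -> np.ndarray:
    """Clone sizes: every clone appears once, extra reads go to clones with
    heavy-tailed weights, giving ~n_reads/redundancy unique rearrangements."""
    n_unique = max(1, int(round(n_reads / redundancy)))
    sizes = np.ones(n_unique, dtype=int)
    extra = n_reads - n_unique
    if extra > 0:
        weights = rng.pareto(1.5, size=n_unique) + 1.0
        sizes += rng.multinomial(extra, weights / weights.sum())
    return sizes


def simulate_repertoire(config: SimulationConfig, out_dir: str | Path | None = None) -> list[Repertoire]:
    """Simulate ``n_subjects`` repertoires under one species preset.

    Each repertoire holds ``n_sequences`` heavy-chain reads (plus paired
    light-chain reads when ``config.paired``); reads within a clone share
    the same rearrangement.  Deterministic under ``config.seed``.  When
    ``out_dir`` is given, one AIRR TSV per subject plus a ``manifest.yaml``
    of the true generating parameters are written.
    """
    pre = config.resolve_preset()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    reps = []
    for si, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        subject = f"{pre.name}_{si + 1}"
        usage = _jitter_usage(pre, rng, config.jitter_concentration)
        sizes = _clone_sizes(config.n_sequences, pre.clonal_redundancy, rng)
        rows = []
        seq_i = 0
        for clone_i, size in enumerate(sizes):
            heavy = sample_junction(pre, rng, usage)
            light = sample_light_junction(pre, rng, usage) if config.paired else None
            for _ in range(int(size)):
                seq_i += 1
                cell = f"{subject}_cell{seq_i}"
                rows.append(dict(heavy, sequence_id=f"{subject}_H{seq_i}", cell_id=cell))
                if light is not None:
                    rows.append(dict(light, sequence_id=f"{subject}_L{seq_i}", cell_id=cell))
        df = pd.DataFrame(rows)
        df["isotype"] = "IgM"
        df["mutation_count"] = 0
        df["duplicate_count"] = 1
        df["v_call_ambiguous"] = False
        rep = Repertoire(subject_id=subject, species=pre.name, df=df,
                         provenance=f"simulated preset={pre.name} seed={config.seed} subject={si}")
        reps.append(rep)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rep in reps:
            write_rearrangements(rep, out_dir / f"{rep.subject_id}.tsv")
        manifest = {
            "preset": pre.name,
            "seed": config.seed,
            "n_subjects": config.n_subjects,
            "n_sequences": config.n_sequences,
            "kappa_fraction": pre.kappa_fraction,
            "vd_insertion": {"zero_prob": pre.vd_insertion.zero_prob, "mean": pre.vd_insertion.mean},
            "dj_insertion": {"zero_prob": pre.dj_insertion.zero_prob, "mean": pre.dj_insertion.mean},
            "clonal_redundancy": pre.clonal_redundancy,
            "heavy_v_usage": pre.usage("heavy_v"),
            "heavy_d_usage": pre.usage("heavy_d"),
            "heavy_j_usage": pre.usage("heavy_j"),
        }
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return reps
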