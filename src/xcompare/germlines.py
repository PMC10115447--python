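"""Bundled synthetic germline gene tables for the repertoire simulator.

These are small, deterministic stand-ins for real germline databases
(synthetic: the nucleotide content is generated, not downloaded from IMGT).
Gene labels follow real IMGT nomenclature so that parsing code paths are
exercised; only the CDR3-proximal region of each gene is modelled, since
nothing downstream of the junction is analysed.

Per gene we store the nucleotide sequence of its junction contribution:
V genes start at the conserved Cys codon (TGT), heavy J genes end at the
conserved Trp codon (TGG), light J genes end at the conserved Phe codon
(TTC).  All sequences are generated free of stop trinucleotides at every
frame offset, which keeps the simulator's stop-avoidance loop cheap.
"""

from __future__ import annotations

import numpy as np

_STOPS = ("TAA", "TAG", "TGA")
_NT = np.array(list("ACGT"))


def _has_stop(seq: str) -> bool:
    return any(s in seq for s in _STOPS)


def _make_seq(rng: np.random.Generator, length: int, prefix: str = "", suffix: str = "") -> str:
    """Random nucleotide string of `length` with fixed ends and no stop substring."""
    core_len = length - len(prefix) - len(suffix)
    if core_len < 0:
        raise ValueError("length shorter than prefix+suffix")
    for _ in range(10_000):
        core = "".join(rng.choice(_NT, size=core_len))
        seq = prefix + core + suffix
        if not _has_stop(seq):
            return seq
    raise RuntimeError("could not generate stop-free germline segment")


def _build_table(rng: np.random.Generator, spec: list[tuple[str, int, float]],
                 prefix: str = "", suffix: str = "") -> dict[str, dict]:
    table = {}
    for name, length, usage in spec:
        table[name] = {
            "seq": _make_seq(rng, length, prefix=prefix, suffix=suffix),
            "length": length,
            "usage": usage,
        }
    total = sum(g["usage"] for g in table.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"usage does not sum to 1: {total}")
    return table


# (gene, junction-contribution length in nt, usage frequency)
# Usage frequencies are calibrated per species; where a printed subgroup
# frequency exists it is split across the subgroup's genes.

_HUMAN_V = [
    ("IGHV1-2", 11, 0.100), ("IGHV1-69", 11, 0.094),
    ("IGHV2-5", 10, 0.040),
    ("IGHV3-23", 11, 0.200), ("IGHV3-30", 11, 0.150), ("IGHV3-7", 12, 0.098),
    ("IGHV4-34", 11, 0.150), ("IGHV4-59", 11, 0.111),
    ("IGHV5-51", 10, 0.030),
    ("IGHV6-1", 12, 0.007),
    ("IGHV7-4-1", 11, 0.020),
]
_KYMOUSE_V = [
    ("IGHV1-2", 11, 0.055), ("IGHV1-69", 11, 0.050),
    ("IGHV2-5", 10, 0.020),
    ("IGHV3-23", 11, 0.300), ("IGHV3-30", 11, 0.220), ("IGHV3-7", 12, 0.144),
    ("IGHV4-34", 11, 0.090), ("IGHV4-59", 11, 0.068),
    ("IGHV5-51", 10, 0.012),
    ("IGHV6-1", 12, 0.040),
    ("IGHV7-4-1", 11, 0.001),
]
_MOUSE_V = [
    ("IGHV1-12", 10, 0.300), ("IGHV1-64", 11, 0.250),
    ("IGHV2-3", 10, 0.100),
    ("IGHV3-2", 11, 0.050),
    ("IGHV5-9", 11, 0.150),
    ("IGHV6-7", 10, 0.050),
    ("IGHV8-8", 11, 0.050),
    ("IGHV14-3", 10, 0.050),
]

# D lengths are tuned so that usage-weighted mean germline length differs
# between the human and Kymouse presets by ~2.3 nt (shorter in Kymouse),
# emulating the transgenic preference for shorter IGHD genes.
_HUMAN_D = [
    ("IGHD1-26", 13, 0.093),
    ("IGHD2-2", 19, 0.161),
    ("IGHD3-10", 22, 0.110), ("IGHD3-22", 22, 0.090),
    ("IGHD4-17", 22, 0.150),
    ("IGHD5-12", 21, 0.096),
    ("IGHD6-19", 14, 0.096),
    ("IGHD7-27", 15, 0.204),
]
_KYMOUSE_D = [
    ("IGHD1-26", 13, 0.247),
    ("IGHD2-2", 19, 0.052),
    ("IGHD3-10", 22, 0.090), ("IGHD3-22", 22, 0.060),
    ("IGHD4-17", 22, 0.075),
    ("IGHD5-12", 21, 0.040),
    ("IGHD6-19", 14, 0.150),
    ("IGHD7-27", 15, 0.286),
]
_MOUSE_D = [
    ("IGHD1-1", 15, 0.300),
    ("IGHD2-4", 17, 0.350),
    ("IGHD3-3", 16, 0.200),
    ("IGHD4-1", 16, 0.150),
]

_HUMAN_J = [
    ("IGHJ1", 18, 0.010), ("IGHJ2", 19, 0.015), ("IGHJ3", 18, 0.096),
    ("IGHJ4", 19, 0.442), ("IGHJ5", 19, 0.151), ("IGHJ6", 22, 0.286),
]
_KYMOUSE_J = [
    ("IGHJ1", 18, 0.005), ("IGHJ2", 19, 0.010), ("IGHJ3", 18, 0.073),
    ("IGHJ4", 19, 0.473), ("IGHJ5", 19, 0.111), ("IGHJ6", 22, 0.328),
]
_MOUSE_J = [
    ("IGHJ1", 20, 0.150), ("IGHJ2", 21, 0.300),
    ("IGHJ3", 21, 0.250), ("IGHJ4", 22, 0.300),
]

# Light chains: human and Kymouse share (human) genes with different usage;
# the wild-type mouse uses its own kappa-dominated locus.
_HUMAN_KV = [("IGKV1-39", 23, 0.33), ("IGKV2-28", 23, 0.18),
             ("IGKV3-20", 23, 0.30), ("IGKV4-1", 23, 0.19)]
_HUMAN_LV = [("IGLV1-44", 23, 0.40), ("IGLV2-14", 23, 0.30), ("IGLV3-21", 23, 0.30)]
_KYMOUSE_KV = [("IGKV1-39", 23, 0.45), ("IGKV2-28", 23, 0.25),
               ("IGKV3-20", 23, 0.12), ("IGKV4-1", 23, 0.18)]
_KYMOUSE_LV = [("IGLV1-44", 23, 0.30), ("IGLV2-14", 23, 0.45), ("IGLV3-21", 23, 0.25)]
_MOUSE_KV = [("IGKV1-110", 23, 0.40), ("IGKV4-55", 23, 0.30), ("IGKV6-15", 23, 0.30)]
_MOUSE_LV = [("IGLV1-1", 23, 1.00)]

_HUMAN_KJ = [("IGKJ1", 13, 0.30), ("IGKJ2", 13, 0.163), ("IGKJ3", 13, 0.24),
             ("IGKJ4", 13, 0.20), ("IGKJ5", 13, 0.097)]
_HUMAN_LJ = [("IGLJ1", 13, 0.30), ("IGLJ2", 13, 0.40), ("IGLJ3", 13, 0.30)]
_KYMOUSE_KJ = [("IGKJ1", 13, 0.35), ("IGKJ2", 13, 0.054), ("IGKJ3", 13, 0.25),
               ("IGKJ4", 13, 0.25), ("IGKJ5", 13, 0.096)]
_KYMOUSE_LJ = [("IGLJ1", 13, 0.25), ("IGLJ2", 13, 0.35), ("IGLJ3", 13, 0.40)]
_MOUSE_KJ = [("IGKJ1", 13, 0.30), ("IGKJ2", 13, 0.30), ("IGKJ4", 13, 0.40)]
_MOUSE_LJ = [("IGLJ1", 13, 1.00)]


def _build_all() -> dict[str, dict[str, dict]]:
    # one fixed stream; table content is deterministic across sessions
    rng = np.random.Generator(np.random.PCG64(20230327))
    tables: dict[str, dict[str, dict]] = {}
    for species, v, d, j, kv, lv, kj, lj in [
        ("human", _HUMAN_V, _HUMAN_D, _HUMAN_J, _HUMAN_KV, _HUMAN_LV, _HUMAN_KJ, _HUMAN_LJ),
        ("kymouse", _KYMOUSE_V, _KYMOUSE_D, _KYMOUSE_J, _KYMOUSE_KV, _KYMOUSE_LV, _KYMOUSE_KJ, _KYMOUSE_LJ),
        ("mouse", _MOUSE_V, _MOUSE_D, _MOUSE_J, _MOUSE_KV, _MOUSE_LV, _MOUSE_KJ, _MOUSE_LJ),
    ]:
        tables[species] = {
            "heavy_v": _build_table(rng, v, prefix="TGT"),
            "heavy_d": _build_table(rng, d),
            "heavy_j": _build_table(rng, j, suffix="TGG"),
            "kappa_v": _build_table(rng, kv, prefix="TGT"),
            "lambda_v": _build_table(rng, lv, prefix="TGT"),
            "kappa_j": _build_table(rng, kj, suffix="TTC"),
            "lambda_j": _build_table(rng, lj, suffix="TTC"),
        }
    # human and Kymouse presets share the same (human) germline sequences,
    # only usage differs: copy sequence content across
    for seg in ("heavy_v", "heavy_d", "heavy_j", "kappa_v", "lambda_v", "kappa_j", "lambda_j"):
        for gene, entry in tables["kymouse"][seg].items():
            if gene in tables["human"][seg]:
                entry["seq"] = tables["human"][seg][gene]["seq"]
    return tables


GERMLINE_TABLES = _build_all()
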