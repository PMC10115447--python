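# xcompare

Cross-species comparison of naive B-cell receptor (BCR) repertoires.

`xcompare` is a Python library for asking how similar the antigen-inexperienced
antibody repertoire of one population is to another's — the question that
arises when evaluating humanised transgenic animal platforms (mice carrying
human immunoglobulin variable-gene loci) against the human and wild-type mouse
repertoires they sit between. It implements the four comparison axes used in
that setting:

- **Germline gene usage** — per-subject V/D/J gene (or subgroup) frequency
  profiles, Igκ/Igλ ratios, Z-normalised hierarchical clustering, and a
  repeated-subsampling *separability* protocol scored with the adjusted Rand
  index (ARI);
- **Junction anatomy** — the heavy-chain junction decomposes exactly into five
  nucleotide components (V contribution, VD N-insertions, D segment, DJ
  N-insertions, J contribution); differences in mean CDRH3 length between
  populations are attributed to each factor by bootstrap estimation
  statistics (mean difference, percentile 95% CI, p-value);
- **Clonal structure** — clonotype assignment (shared IGHV/IGHJ genes plus
  ≥ 90% amino-acid identity across length-matched CDRH3s, single linkage),
  Shannon diversity H = −Σ pᵢ ln pᵢ overall and per CDRH3 length, and
  pairwise CDRH3/clonotype sharing matrices under explicit denominator
  conventions;
- **Structural-cluster usage** — comparison of repertoires by per-sequence
  categorical annotations (CDRH3 structural clusters, canonical classes):
  usage-distance analysis, species-origin bias, length-stratified enrichment
  against a database background, and greedy leader clustering.

A built-in V(D)J simulator with `human`, `mouse` and `kymouse` (humanised
transgenic) presets generates naive AIRR-format repertoires whose
distributional structure matches each population's printed statistics —
species-specific gene usage, κ/λ ratios (≈62:38 human, ≈90:10 mouse, ≈51:49
humanised), zero-inflated VD/DJ insertion models (human means 7.30/6.77 nt
with 8.2%/4.5% zero; humanised 3.35/2.91 nt with 19.1%/14.1% zero), D
trimming and clonal redundancy — so the entire analysis stack is runnable
and testable without sequencing data. Real data in AIRR Rearrangement TSV
format is read with `read_rearrangements`.

## Worked example

```python
from xcompare import (SimulationConfig, simulate_repertoire,
                      decompose_length_difference)
from xcompare.airr_io import collapse_unique

def unique_heavy(preset, seed):
    rep = simulate_repertoire(SimulationConfig(preset=preset, n_subjects=1,
                                               n_sequences=8000, seed=seed))[0]
    heavy = rep.df[rep.df["locus"] == "IGH"]
    return collapse_unique(rep.with_df(heavy))

human, kymouse = unique_heavy("human", 21), unique_heavy("kymouse", 22)
decomp = decompose_length_difference([human], [kymouse], n_reps=2000, seed=7)
for factor, est in decomp.items():
    print(f"{factor:12s} {est.estimate:+6.2f} {est.units} "
          f"(95% CI {est.ci_low:+.2f}, {est.ci_high:+.2f})")
```

prints

```
v_cdr3_nt     -0.11 nt (95% CI -0.15, -0.07)
np1_length    +3.69 nt (95% CI +3.47, +3.91)
d_align_nt    +1.83 nt (95% CI +1.67, +1.99)
np2_length    +3.87 nt (95% CI +3.66, +4.06)
j_cdr3_nt     -0.08 nt (95% CI -0.14, -0.01)
total_aa      +3.07 aa (95% CI +2.96, +3.18)
```

Positive values mean *longer in the first group* (human). The VD and DJ
insertion factors dominate the CDRH3 length gap — the humanised preset
inserts ~3.9 nt fewer at each junction (its configured gaps are
7.30 − 3.35 and 6.77 − 2.91 nt) — with a smaller D-segment contribution and
near-zero V/J effects; the five nucleotide factors sum to three times the
amino-acid difference, as the junction arithmetic requires.

The `examples/` directory holds one short narrative script per capability
(simulation, separability, clonotypes and sharing, junction decomposition,
diversity, structural usage, full pipeline). A thin CLI covers the two
shell-level entry points:

```bash
xcompare simulate --preset kymouse --subjects 7 --n 20000 --seed 13 --out sims/
xcompare run --seed 1 --out run1/
```

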