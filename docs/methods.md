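# Methods

This note records the models, conventions and numerical choices behind
`xcompare`, in the order the data flows through the package.

## Domain model and filtering conventions

A repertoire is a subject-labelled table of annotated V(D)J rearrangements
with AIRR-schema column names. Three conventions are applied consistently:

- **Naive filter** — the naive compartment is operationalised as IgM
  sequences with zero nucleotide mutations from the assigned germline.
  The filter is idempotent and reports per-reason rejection counts.
- **Deduplication** — analyses of usage, diversity, junction anatomy and
  sharing are run per *unique nucleotide sequence* (the `sequence` column if
  present, else the junction), with read multiplicity accumulated in
  `duplicate_count`. This matters statistically: clonally replicated reads
  are not independent draws, and collapsing first restores the i.i.d.
  sampling that bootstrap CIs assume.
- **CDR3 convention** — IMGT CDR3 = junction minus the two anchor residues
  (the conserved Cys and Trp/Phe); all "CDRH3 length" statistics are
  amino-acid CDR3 lengths. Multi-hit gene calls keep the first listed
  designation (flagged); alleles are stripped before any frequency
  computation, which is reported at gene or subgroup level only.

## The V(D)J simulator

The simulator is first-class, tested code: it defines the study conditions
under which every downstream method is exercised.

**Junction assembly.** A heavy-chain junction is drawn as
V-contribution + np1 + D-segment + np2 + J-contribution, where the V and J
contributions are measured from/to the conserved anchor codons, so the five
components sum *exactly* to the junction nucleotide length. Gene tables are
small bundled synthetic germline sets (labelled synthetic; nucleotide
content is generated, not downloaded) whose labels follow real IMGT
nomenclature so parsing paths are exercised. The human and humanised presets
share gene sequences and differ only in usage frequencies, mirroring a
transgenic platform carrying the human loci.

**Insertion model.** N-insertion lengths are zero-inflated geometric: P(0)
= z, else 1 + Geometric matched to the overall mean m. Only means and zero
fractions are calibrated quantities, so the one-parameter geometric
positive part is the minimal choice; it is isolated behind
`ZeroInflatedGeometric` and swappable. Calibration anchors:

| preset  | VD mean (z₀)  | DJ mean (z₀)  | κ fraction | mean CDRH3 |
|---------|---------------|---------------|------------|------------|
| human   | 7.30 (0.082)  | 6.77 (0.045)  | 0.62       | ≈16.6 aa   |
| kymouse | 3.35 (0.191)  | 2.91 (0.141)  | 0.51       | ≈13.4 aa   |
| mouse   | 1.80 (0.400)  | 1.40 (0.450)  | 0.90       | ≈12.4 aa   |

The mouse insertion parameters are not separately published for this
setting; they were chosen once so that the mouse preset's mean CDRH3 length
is ≈12.4 aa with the high zero-insertion rates typical of wild-type mice.
np1 and np2 are drawn independently; real repertoires show mild positive
dependence between the two junctions' zero events, which is deliberately
not modelled. D-segment trimming is uniform 0–5 nt per end (uncalibrated —
no published trimming distribution constrains it); J 5′ trimming is uniform
0–3 nt. The D gene lengths and usage were set so the usage-weighted mean
D contribution is ~2.3 nt shorter in the humanised preset, reproducing the
preference for shorter D genes.

**Frame and stop handling — a deliberate deviation from naive rejection.**
The junction must translate in frame without stops. Rejecting whole draws
until this holds would bias the realised insertion lengths downward by
roughly 1 nt, because longer junctions carry more random codons and hence
more stop codons — violating the calibration the simulator exists to
provide. Instead (a) the V 3′ trim takes the unique value in {0, 1, 2}
making the total a multiple of three (marginally uniform, so no length
bias), and (b) stop codons are removed by resampling the *content* of the
random N nucleotides at fixed lengths, falling back to redrawing trims only
in the rare all-germline-junction case. The realised length distributions
therefore equal the configured ones exactly, which the recovery tests
verify at n = 20,000 within 3–4 standard errors.

**Cohort structure.** Per-subject gene usage is jittered by a Dirichlet
draw with concentration 500 × preset frequencies, giving realistic
within-species spread for the separability protocol. Clonal redundancy 1.5
is implemented by giving every unique rearrangement at least one read and
distributing the extra reads with heavy-tailed (Pareto) weights, so
collapsing n reads yields ≈ n/1.5 unique sequences with a non-trivial
clone-size spectrum. Paired mode emits one light-chain record per cell
(κ with probability `kappa_fraction`). Everything is deterministic under
the config seed; identical configs produce byte-identical TSVs.

## Gene usage and separability

Usage profiles are per-record frequencies over allele-stripped genes or
subgroups. Z-normalisation is per category across subjects with the sample
(n−1) standard deviation; zero-variance categories (tolerance 1e-12) are
set to zero so they carry no distance weight. Clustering is agglomerative
on Euclidean distance, average linkage (UPGMA) by default — the protocol's
linkage is a convention, so `complete`/`ward` are accepted flags. The
separability protocol subsamples every repertoire without replacement to a
common depth (default 105, the minimum subject size in the motivating
study design), recomputes profiles, Z-normalises, clusters, cuts at two
groups and scores against the true labels with the adjusted Rand index;
`fraction_perfect` is the share of (default 100) repeats at ARI = 1.0.
Per-gene group testing uses two-sided Mann–Whitney U across subjects with
Benjamini–Hochberg adjustment across categories; the underlying test is a
convention-dependent choice surfaced as a parameter. Note the exact-test
floor: with 3 vs 3 subjects the smallest achievable two-sided p is 0.1.

## Clonotypes, sharing, downsampling

Clonotypes partition heavy-chain records by (V gene, J gene, CDR3 length)
and then cluster within partitions by Hamming identity on the CDR3 with
threshold ≥ 0.90 *inclusive* ("90% or more"), single linkage by default
(complete linkage by flag). At threshold 1.0 the partition provably equals
exact (V, J, CDR3) grouping, and the implementation is tested against a
brute-force transitive-closure oracle on random fixtures.

Sharing between two subjects counts exact CDRH3 string matches, or — for
clonotypes — clusters of the jointly re-clustered pooled pair containing
members of both subjects, so near-identical cross-subject CDR3s count as
shared. The "% shared" denominator is not standardised; three conventions
are implemented (`mean` of the two directional fractions — the default —
`min`, and `jaccard`) and the convention is recorded on the result object.

Stratified downsampling preserves clonal structure by stratifying records
on the size of their clone and sampling each stratum proportionally
(largest-remainder rounding), which matches the pre-sample clone-size
composition in expectation with lower variance than uniform record
sampling (verified by χ² comparison over 20 seeds).

## Diversity

Shannon entropy H = −Σ pᵢ ln pᵢ (natural log, 0·ln 0 = 0) over unit
abundance distributions, where a unit is an exact CDRH3 or a clonotype and
abundance counts unique sequences. Per-length profiles stratify by CDR3
amino-acid length; single-unit strata report H = 0 and empty strata are
absent. In the simulated cohorts the peak-diversity length orders mouse ≤
humanised ≤ human, tracking the insertion rates.

## Junction decomposition

Anatomy prefers explicit AIRR fields and otherwise derives insertions from
1-based inclusive alignment coordinates (np1 = d_sequence_start −
v_sequence_end − 1). Records without a D call get d_align = 0, the single
combined insertion assigned to np1 (preserving the conservation identity)
and a `no_d` flag; `exclude_no_d` drops them instead, since published
practice is silent on this point. On simulated data the conservation
identity holds exactly for every record; on parsed data violations are the
caller's to inspect — they are never silently repaired.

`bootstrap_mean_difference` resamples each group with replacement
(default 5000 replicates, chunked for memory), reports the percentile
2.5/97.5 CI and a two-sided sign-proportion p floored at 1/n_reps. The two
resampling streams are assigned to the groups in a canonical content-derived
order, making the estimator exactly antisymmetric under swapping the
groups at the same seed. Coverage is property-tested: ≥ 90% of 200
replicated 95% CIs contain a known mean gap. Factor samples are pooled per
group (sequence-level n), not per-subject means.

## Categorical (structural) usage

The structural comparison consumes annotation tables — structure prediction
is out of scope — and reuses the gene-usage machinery (shared
`UsageProfile` type, same Z-normalisation and clustering), so the two entry
points cannot drift apart. Origin bias counts *distinct* clusters used by
a subject group (sequence-weighted counting by flag). Length-stratified
enrichment compares the observed origin proportion at each CDRH3 length
with the database background via an exact two-sided binomial test,
flagging significance at the 1% level; a zero background with non-zero
observation yields an infinite-ratio flag. The default length window for
structural analyses is 4–16 aa. Greedy leader clustering visits items in
input order and joins the first cluster whose *founder* is within the
cutoff; the result is order-dependent by construction, so callers fix the
order (sorted IDs) for determinism.

The synthetic annotation generator draws a pool of 1000 templates with
origins at the database composition (37% human, 41% murine, 22% other) and
heavy-tailed popularity weights (Dirichlet 0.5, so a few-thousand-sequence
repertoire does not saturate the pool), then samples each subject's
sequences from a species-specific length distribution and an origin-biased
re-weighting of the background at that length. Human and humanised subjects
receive human-tilted bias, murine subjects mouse-tilted, with mild
per-subject log-normal jitter. By construction the murine group separates
from the human/humanised groups at ARI 1.0 and each group's most-used
origin matches its bias.

## What the synthetic data does and does not show

The simulator reproduces marginal usage frequencies, insertion-length and
zero-insertion statistics, κ/λ balance, clonal redundancy and
between-subject jitter. It does not model somatic hypermutation, class
switching, selection, P-nucleotides as distinct from N-insertions,
VD/DJ insertion dependence, allele-level variation, or sequencing error.
Passing tests therefore demonstrate that the *methods* recover known truths
under realistic distributional structure — not that any particular
biological population has those parameter values. Sharing percentages in
particular scale strongly with sequencing depth, so synthetic values at
desk-scale depths are smaller than published deep-repertoire values.

## Problem sizes and budgets

Deep calibration checks use single subjects at n = 20,000; cohort
protocols use 3 subjects × 5,000 sequences per species; the structural
scenario uses 3 × 1,500 annotations per species; the acceptance study runs
in well under a minute and the full test suite in a few minutes on one CPU.
These sizes were chosen so every statistical tolerance (3–4 standard
errors, bootstrap CI widths) is meaningful at desk scale.

## Known limitations

- The humanised preset's mean CDRH3 length (~13.4 aa) follows from
  honouring the insertion/D-segment calibration plus the exact junction
  conservation identity; published per-factor and total-length statistics
  are not mutually consistent under that identity, and the insertion
  calibration was given priority.
- Greedy clustering quality depends on input order; only determinism, not
  optimality, is guaranteed.
- The Mann–Whitney option is the only implemented per-gene test; with very
  few subjects its discreteness limits attainable significance.
- Light-chain simulation is simpler than heavy (single insertion segment,
  no D), sufficient for κ/λ ratios and light-V usage analyses only.
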