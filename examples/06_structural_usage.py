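"""Compare repertoires by CDRH3 structural-cluster usage.

Sequences annotated with a structural cluster (a backbone-shape template
from a clustered database) are compared between subjects via Euclidean
distance in Z-normalised cluster-usage proportions, with hierarchical
clustering and an adjusted Rand index against species labels.
"""

from xcompare import (
    enrichment_by_length,
    length_balanced_subsample,
    simulate_annotation_tables,
    species_origin_bias,
    usage_distance_analysis,
)

table, background = simulate_annotation_tables(
    {"human": 3, "kymouse": 3, "mouse": 3}, n_per_subject=1500, seed=6)
labels = {s: ("murine" if s.startswith("mouse") else "human-like")
          for s in table["subject_id"].unique()}

res = usage_distance_analysis(table, labels)
print(f"2-cut adjusted Rand index (murine vs human-like): {res.ari:.2f}")
print(res.comparisons.groupby("comparison")["distance"].mean().round(2))

for species in ("human", "kymouse", "mouse"):
    group = [s for s in labels if s.startswith(species)]
    bias = species_origin_bias(table, group)
    print(f"{species}: origin of distinct clusters used ->",
          {k: f"{100 * v:.1f}%" for k, v in bias.items()})

enr = enrichment_by_length(table[table["species"] == "human"], background, "human")
print(f"human-origin template enrichment significant (1% level) at "
      f"{int(enr['significant'].sum())}/{len(enr)} CDRH3 lengths")

subs = length_balanced_subsample(table, n_per_length=15, n_subsamples=10,
                                 seed=8, retain="feasible")
aris = [usage_distance_analysis(s, labels).ari for s in subs]
print(f"length-balanced subsamples with ARI 1.0: {sum(a == 1.0 for a in aris)}/10")

# The humanised repertoires cluster with the humans (ARI 1.0) and prefer
# human-origin templates; the split survives in nearly all length-balanced
# subsamples, so it is not simply a CDRH3-length artefact.
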