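"""Why are humanised-mouse CDRH3s shorter than human ones?

The junction length is the exact sum of five components (V contribution,
VD insertions, D segment, DJ insertions, J contribution).  Bootstrapping
the mean difference of each factor separately attributes the overall
length gap to its mechanistic sources.
"""

from xcompare import SimulationConfig, decompose_length_difference, simulate_repertoire
from xcompare.airr_io import collapse_unique


def unique_heavy(preset, seed):
    rep = simulate_repertoire(SimulationConfig(preset=preset, n_subjects=1,
                                               n_sequences=8000, seed=seed))[0]
    heavy = rep.df[rep.df["locus"] == "IGH"]
    return collapse_unique(rep.with_df(heavy))


human, kymouse = unique_heavy("human", 21), unique_heavy("kymouse", 22)
decomp = decompose_length_difference([human], [kymouse], n_reps=2000, seed=7)

print("factor contributions to human-minus-kymouse CDRH3 length:")
for factor, est in decomp.items():
    print(f"  {factor:12s} {est.estimate:+6.2f} {est.units}  "
          f"(95% CI {est.ci_low:+.2f}, {est.ci_high:+.2f}; p={est.p:.3g})")

# The VD and DJ insertion factors dominate (~3.9 nt each, the configured
# 7.30-3.35 and 6.77-2.91 gaps), with a smaller D-segment effect; the five
# nucleotide factors sum to three times the total amino-acid difference.
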