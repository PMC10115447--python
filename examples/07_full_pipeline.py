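"""Run the whole comparison end to end and inspect the report bundle.

One RunConfig fixes every seed and convention flag; the pipeline simulates
the three cohorts, applies the naive filter, collapses to unique sequences
and writes tidy TSV/JSON reports plus a run log.
"""

import json
from pathlib import Path

from xcompare import RunConfig, run_pipeline

out = Path("scratch/example_run")
cfg = RunConfig(n_subjects=3, n_sequences=1000, n_repeats=20, bootstrap_reps=500,
                structural_n_per_subject=600, seed=1, out_dir=str(out))
report = run_pipeline(cfg)
print("report:", report)
print("files:", sorted(p.name for p in out.iterdir()))

sep = json.loads((out / "separability.json").read_text())
print(f"usage separability: perfect in {100 * sep['fraction_perfect']:.0f}% "
      f"of {sep['n_repeats']} repeats at depth {sep['subsample_n']}")
decomp = json.loads((out / "decomp.json").read_text())
vd = decomp["factors"]["np1_length"]
print(f"VD insertion factor: {vd['estimate']:+.2f} nt (CI {vd['ci'][0]:+.2f}, {vd['ci'][1]:+.2f})")

# Re-running with the same config writes byte-identical reports; change the
# seed (or any convention flag such as overlap_convention) to explore.
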