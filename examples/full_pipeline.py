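"""End-to-end run: phantom cohort -> LC-I -> NBM -> VOIs -> statistics.

Generates a small two-group image cohort, measures every subject with the
actual image pipeline (not the generating numbers), and prints the group
means of the extracted markers together with the provenance hash that makes
the run reproducible.
"""

import tempfile

from lcnbm import PhantomDesign, RunConfig, run_pipeline

design = PhantomDesign(
    n_per_group=(5, 5), group_labels=("Control", "AD"), missing_lc_i={}, seed=42
)
with tempfile.TemporaryDirectory() as tmp:
    results = run_pipeline(RunConfig(out_dir=tmp, design=design))
    cohort = results.cohort

print(cohort.groupby("group")[["lc_i", "nbm_vol_norm", "hippocampus_vol"]].mean().round(4))
print(f"\nfailures: {results.failures}")
print(f"seed {results.provenance['seed']}, config hash {results.provenance['config_hash'][:12]}")
print("Extracted LC-I sits at the built-in contrasts (1.30 control, 1.18 AD);")
print("NBM per-mil volume reflects the 0.85 atrophy scale (0.85^3 = 0.61 of control).")
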