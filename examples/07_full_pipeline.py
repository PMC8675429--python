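"""Run the complete analysis end to end and inspect the manifest.

Equivalent to `lifespanvol run-all --out <dir>`: simulate (or read) a cohort,
QC, ICV-adjust, harmonize, fit trajectories, test variability, fit centiles,
and write every artefact with a reproducibility manifest.
"""

import lifespanvol as lv

config = lv.PipelineConfig(seed=0, sim_scale=0.2, output_dir="scratch/example_run")
result = lv.run_pipeline(config)

m = result.manifest
print(f"rows analyzed:      {m['n_rows_analyzed']}")
print(f"trajectory fits:    {m['n_fp_fits']}")
print(f"variance reports:   {m['n_variance_reports']}  "
      f"(corrected alpha {m['corrected_alpha']:.6f})")
print(f"centile strata:     {m['n_centile_tables']}")
print(f"config hash:        {m['config_hash']}  (rerun with the same config "
      f"and seed regenerates every file bit-identically)")
print("outputs:", ", ".join(m["outputs"]))
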