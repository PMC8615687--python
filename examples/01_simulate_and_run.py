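"""Simulate a two-group lipidomics experiment and run the full pipeline.

Injects a 5% elevation into the diacyl-PC class (the scale of change a
mild vitamin-D deficit produces in neuroblastoma cells) and shows how
the class-summary bar-chart numbers recover it.
"""

from pathlib import Path

from mrmlipid import (
    LipidClass,
    PipelineConfig,
    SimulationConfig,
    format_p,
    run_pipeline,
    simulate,
)

cfg = SimulationConfig(seed=42, class_effects={LipidClass.PC_AA: 1.05})
records, truth = simulate(cfg)
print(f"simulated {len(records)} intensity records "
      f"({len(cfg.panel)} analytes, 2 x {cfg.n_per_group} samples, "
      f"{cfg.n_technical} technical replicates)")

result = run_pipeline(records, PipelineConfig(
    reference_group="control", out_dir=Path("scratch/example_run")))

print("\nclass summaries (percent of reference, mean ± SEM over species):")
for _, row in result.class_summary.iterrows():
    print(f"  {row['lipid_class']:>6}: {row['mean_percent']:6.1f} ± "
          f"{row['sem_percent']:.1f}%  (p = {format_p(row['p'])}, "
          f"n = {row['n_species']})")
print("\n100% means unchanged relative to the control group; the PC_AA row "
      "should sit near the injected 105%.")
print(f"matrix-effect QC: mean |standard change| = "
      f"{result.matrix_report.mean_abs_change:.2f}% "
      "(spiked standards should not differ between groups)")
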