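"""Drive the whole analysis end to end with one config.

simulate -> respond -> encode -> reconstruct -> analyze -> report, with a
resolved-config copy and a structured log (thresholds and survivor counts)
written next to the CSV outputs.  Equivalent shell command:

    neurorecon run --seed 11 --out pipeline_out
"""

from neurorecon.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=11,
    out_dir="scratch/pipeline_demo",
    n_cells=60,
    n_images=40,
    n_trials=6,
    recon_mode="all_cell",  # skip per-cell encoding models for speed
    stages=("simulate", "respond", "reconstruct", "analyze", "report"),
)
result = run_pipeline(config)
print(f"outputs in {result.out_dir}:")
for entry in result.log:
    print(" ", entry)
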