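"""The orchestrated pipeline: simulate -> process -> compare -> screen -> enrich.

Runs every stage with a reduced copy of the default planted design,
writes all artifacts into ./scratch_run and prints the recovery report
(precision/recall of each called set against its planted class).

Equivalent shell command:
    dgetag run-all --outdir scratch_run --seed 11
"""

from dgetag import run_pipeline
from dgetag.config import PipelineConfig, SimulationConfig

cfg = PipelineConfig(
    seed=11,
    simulation=SimulationConfig(
        n_genes=400, depth=40_000, length_min=150, length_max=600,
        planted_abundance_floor=1e-3,
        class_sizes={"normal_up": 10, "microcycle_up": 15,
                     "sucrose_specific": 6, "nitrate_specific": 6,
                     "phosphate_specific": 6},
    ),
)
result = run_pipeline(cfg, "scratch_run")

print("per-library statistics:")
print(result.library_stats.to_string(index=False))
print("\nrecovery of the planted classes:")
print(result.recovery.to_string(index=False))
print(f"\nartifacts written to {result.outdir}/ (see manifest.json)")
# precision/recall of 1.0 means every planted gene and nothing else
# survived the exact-test screens and the subtractive set logic
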