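"""Subtractive set screens: pattern intersections and nutrient specificity.

Runs the simulate/process/compare stages, then derives the two
four-way pattern intersections and the three nutrient-specific sets,
and prints each against the planted truth.
"""

from dgetag import evaluate_recovery, venn_partition
from dgetag.config import PipelineConfig, SimulationConfig
from dgetag.pipeline import stage_compare, stage_process, stage_screen, stage_simulate

cfg = PipelineConfig(
    seed=5,
    simulation=SimulationConfig(
        n_genes=500, depth=60_000, length_min=150, length_max=600,
        planted_abundance_floor=6e-4,
        class_sizes={"normal_up": 10, "microcycle_up": 20,
                     "sucrose_specific": 8, "nitrate_specific": 8,
                     "phosphate_specific": 8},
    ),
)
catalog, truth, raw_libs, _ = stage_simulate(cfg)
clean, table, _ = stage_process(cfg, catalog, raw_libs)
comparisons = stage_compare(cfg, table)
pattern, nutrient_sets, _ = stage_screen(cfg, table, comparisons)

print("set sizes and recovery against the planted truth:")
for name, called in [("normal_up", pattern.normal_up),
                     ("microcycle_up", pattern.microcycle_up)]:
    p, r = evaluate_recovery(called, truth.class_members(name))
    print(f"  {name:<20} {len(called):>4} genes  precision={p:.2f} recall={r:.2f}")
for cls, ns in nutrient_sets.items():
    p, r = evaluate_recovery(ns.genes, truth.class_members(cls))
    print(f"  {cls:<20} {len(ns.members):>4} genes  precision={p:.2f} recall={r:.2f}"
          f"  ({len(ns.removed)} DEG candidates removed as expressed elsewhere)")

regions = venn_partition({
    f"SYA_vs_{c}": comparisons[c].genes_with_call("up_in_A")
    for c in ("SR", "NR", "PR", "SDAY")
})
print("\nVenn regions of the four up-in-SYA DEG sets (region: size):")
for sig, members in sorted(regions.items(), key=lambda kv: -len(kv[1])):
    print(f"  {sig}: {len(members)}")
# the full four-way region is the microcycle_up pattern set
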