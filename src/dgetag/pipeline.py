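"""End-to-end orchestration: simulate -> process -> compare -> screen -> enrich.

Each stage is a pure function of its inputs; ``run_pipeline`` chains
them, writes every artifact into an output directory and records a
manifest with the resolved config, seed and content digests, so two runs
with the same config and seed produce byte-identical artifacts.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as dio
from .config import PipelineConfig
from .de import SubtractiveLibrary, compare_libraries
from .enrich import AnnotationMap, EnrichmentResult, enrich
from .screen import (
    NutrientSpecificSet,
    PatternSets,
    derive_pattern_sets,
    expressed_genes,
    nutrient_specific,
    venn_partition,
)
from .simulate import (
    BASELINE,
    CONDITIONS,
    NUTRIENT_CLASSES,
    PLANTED_CLASSES,
    ReferenceCatalog,
    SimTruth,
    evaluate_recovery,
    generate_annotations,
    generate_reference,
    plan_truth,
    simulate_libraries,
)
from .tags import (
    DEFAULT_ANCHOR,
    CleanLibrary,
    GeneCountTable,
    TagLibrary,
    build_count_table,
    clean_tags,
    extract_reference_tags,
    library_statistics,
)
from .simulate import DEFAULT_ADAPTOR_PREFIX

__all__ = [
    "PipelineResult",
    "stage_simulate",
    "stage_process",
    "stage_compare",
    "stage_screen",
    "stage_enrich",
    "recovery_report",
    "run_pipeline",
]

#: order of the four canonical baseline-vs-other comparisons
COMPARISON_CONDITIONS = ("SR", "NR", "PR", "SDAY")


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    catalog: ReferenceCatalog
    truth: SimTruth | None
    raw_libs: dict[str, TagLibrary]
    clean_libs: dict[str, CleanLibrary]
    table: GeneCountTable
    library_stats: pd.DataFrame
    comparisons: dict[str, SubtractiveLibrary]
    pattern_sets: PatternSets
    nutrient_sets: dict[str, NutrientSpecificSet]
    enrichment: dict[str, EnrichmentResult] = field(default_factory=dict)
    recovery: pd.DataFrame | None = None
    outdir: Path | None = None


def stage_simulate(
    config: PipelineConfig, seed: int | None = None
) -> tuple[ReferenceCatalog, SimTruth, dict[str, TagLibrary], AnnotationMap]:
    """Generate catalogue, truth, raw libraries and a synthetic annotation map."""
    sim = config.simulation
    seed = config.seed if seed is None else seed
    catalog = generate_reference(
        n_genes=sim.n_genes,
        length_range=(sim.length_min, sim.length_max),
        seed=seed,
        anchor=config.tag.anchor,
        body_length=config.tag.body_length,
    )
    truth = plan_truth(
        catalog,
        class_sizes=sim.class_sizes,
        fold_change=sim.fold_change,
        abundance_location=sim.abundance_location,
        abundance_scale=sim.abundance_scale,
        depths=sim.condition_depths(),
        seed=seed,
        nutrient_sya_factor=sim.nutrient_sya_factor,
        planted_abundance_floor=sim.planted_abundance_floor,
    )
    raw_libs = simulate_libraries(
        catalog,
        truth,
        error_rate=sim.error_rate,
        adaptor_rate=sim.adaptor_rate,
        seed=seed,
        anchor=config.tag.anchor,
        body_length=config.tag.body_length,
    )
    planted_genes = None
    planted_term = None
    if sim.planted_enriched_class is not None:
        members = sorted(truth.class_members(sim.planted_enriched_class))
        if members:
            planted_term = f"TERM:planted_{sim.planted_enriched_class}"
            planted_genes = set(members[: sim.planted_term_size])
    annotation = generate_annotations(
        catalog.gene_ids,
        n_terms=sim.annotation_terms,
        mean_term_size=sim.annotation_mean_term_size,
        seed=seed + 1,
        planted_term=planted_term,
        planted_genes=planted_genes,
    )
    return catalog, truth, raw_libs, annotation


def stage_process(
    config: PipelineConfig,
    catalog: ReferenceCatalog,
    raw_libs: dict[str, TagLibrary],
) -> tuple[dict[str, CleanLibrary], GeneCountTable, pd.DataFrame]:
    """Clean every library, map tags and assemble the count table."""
    index = extract_reference_tags(
        catalog, anchor=config.tag.anchor, body_length=config.tag.body_length
    )
    clean_libs = {
        cond: clean_tags(
            lib,
            adaptor=DEFAULT_ADAPTOR_PREFIX,
            min_copies=config.thresholds.min_copies,
        )
        for cond, lib in raw_libs.items()
    }
    table = build_count_table(
        clean_libs, index, catalog, max_mismatch=config.tag.max_mismatch
    )
    stats = library_statistics(raw_libs, clean_libs, table)
    return clean_libs, table, stats


def stage_compare(
    config: PipelineConfig, table: GeneCountTable
) -> dict[str, SubtractiveLibrary]:
    """The four canonical SYA-vs-other subtractive libraries."""
    th = config.thresholds
    return {
        cond: compare_libraries(
            table,
            BASELINE,
            cond,
            alpha=th.alpha_fdr,
            lfc_min=th.lfc_min,
            zero_floor=th.zero_floor,
        )
        for cond in COMPARISON_CONDITIONS
    }


def stage_screen(
    config: PipelineConfig,
    table: GeneCountTable,
    comparisons: dict[str, SubtractiveLibrary],
) -> tuple[PatternSets, dict[str, NutrientSpecificSet], dict[str, pd.DataFrame]]:
    """Pattern intersections, nutrient-specific screens and Venn tables."""
    libs = [comparisons[c] for c in COMPARISON_CONDITIONS]
    pattern = derive_pattern_sets(libs)

    min_count = config.thresholds.min_expressed_count
    expressed = {
        cond: expressed_genes(table, cond, min_count=min_count)
        for cond in COMPARISON_CONDITIONS
    }
    nutrient_sets = {}
    for cls, cond in NUTRIENT_CLASSES.items():
        others = {c: expressed[c] for c in COMPARISON_CONDITIONS if c != cond}
        nutrient_sets[cls] = nutrient_specific(comparisons[cond], others)

    venns = {
        "normal_up": _venn_df(
            {
                f"{BASELINE}_vs_{c}": comparisons[c].genes_with_call("up_in_B")
                for c in COMPARISON_CONDITIONS
            }
        ),
        "microcycle_up": _venn_df(
            {
                f"{BASELINE}_vs_{c}": comparisons[c].genes_with_call("up_in_A")
                for c in COMPARISON_CONDITIONS
            }
        ),
    }
    for cls, cond in NUTRIENT_CLASSES.items():
        venns[cls] = _venn_df(
            {
                f"DEG_{cond}": comparisons[cond].genes,
                **{
                    f"expr_{c}": expressed[c]
                    for c in COMPARISON_CONDITIONS
                    if c != cond
                },
            }
        )
    return pattern, nutrient_sets, venns


def _venn_df(sets: dict[str, set]) -> pd.DataFrame:
    regions = venn_partition(sets)
    rows = [
        {
            "region": sig,
            "size": len(members),
            "members": ",".join(sorted(members)),
        }
        for sig, members in sorted(regions.items())
    ]
    return pd.DataFrame(rows, columns=["region", "size", "members"])


def stage_enrich(
    config: PipelineConfig,
    gene_sets: dict[str, set[str]],
    annotation: AnnotationMap,
) -> dict[str, EnrichmentResult]:
    return {
        name: enrich(genes, annotation, q_threshold=config.thresholds.q_enrich)
        for name, genes in gene_sets.items()
    }


def recovery_report(
    truth: SimTruth,
    pattern: PatternSets,
    nutrient_sets: dict[str, NutrientSpecificSet],
) -> pd.DataFrame:
    """Precision/recall of each called set against its planted class."""
    called = {
        "normal_up": pattern.normal_up,
        "microcycle_up": pattern.microcycle_up,
        **{cls: ns.genes for cls, ns in nutrient_sets.items()},
    }
    rows = []
    for cls in PLANTED_CLASSES:
        planted = truth.class_members(cls)
        precision, recall = evaluate_recovery(called.get(cls, set()), planted)
        rows.append(
            {
                "class": cls,
                "planted": len(planted),
                "called": len(called.get(cls, set())),
                "precision": precision,
                "recall": recall,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    seed: int | None = None,
    log=None,
) -> PipelineResult:
    """Run every stage in simulation mode and write all artifacts.

    ``seed`` overrides the config seed.  Artifacts (all TSV/FASTA/JSON)
    are deterministic for a fixed config+seed; the manifest records the
    config and a sha256 digest of every file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    log_lines: list[str] = []

    def _log(msg: str) -> None:
        log_lines.append(msg)
        if log is not None:
            print(msg, file=log)

    _log(f"stage simulate: seed={seed}")
    catalog, truth, raw_libs, annotation = stage_simulate(config, seed=seed)
    dio.write_fasta(catalog, outdir / "reference.fasta")
    dio.write_truth(truth, outdir / "truth.json")
    dio.write_annotation_tsv(annotation, outdir / "annotations.tsv")
    for cond, lib in raw_libs.items():
        dio.write_tag_library(lib, outdir / f"tags_raw_{cond}.tsv")

    _log("stage process: cleaning and mapping")
    clean_libs, table, lib_stats = stage_process(config, catalog, raw_libs)
    for cond, lib in clean_libs.items():
        dio.write_tag_library(lib, outdir / f"tags_clean_{cond}.tsv")
    dio.write_count_table(table, outdir / "counts.tsv")
    dio.write_tsv(lib_stats, outdir / "library_stats.tsv")

    _log("stage compare: four subtractive libraries")
    comparisons = stage_compare(config, table)
    for cond, sub in comparisons.items():
        dio.write_comparison(sub, outdir / f"de_{BASELINE}_vs_{cond}.tsv")
        _log(f"  {BASELINE} vs {cond}: {len(sub.records)} significant genes")

    _log("stage screen: pattern and nutrient-specific sets")
    pattern, nutrient_sets, venns = stage_screen(config, table, comparisons)
    dio.write_gene_set_tsv(
        {g: "up_in_other" for g in pattern.normal_up},
        outdir / "pattern_normal_up.tsv",
    )
    dio.write_gene_set_tsv(
        {g: "up_in_SYA" for g in pattern.microcycle_up},
        outdir / "pattern_microcycle_up.tsv",
    )
    for cls, ns in nutrient_sets.items():
        dio.write_gene_set_tsv(
            ns.members,
            outdir / f"nutrient_{ns.nutrient}.tsv",
            comments=[
                f"condition={ns.condition}",
                f"removed={len(ns.removed)}",
            ],
        )
        _log(f"  {cls}: {len(ns.members)} genes ({len(ns.removed)} removed)")
    for name, df in venns.items():
        dio.write_tsv(df, outdir / f"venn_{name}.tsv")

    _log("stage enrich: hypergeometric enrichment of screened sets")
    gene_sets = {
        "normal_up": pattern.normal_up,
        "microcycle_up": pattern.microcycle_up,
        **{cls: ns.genes for cls, ns in nutrient_sets.items()},
    }
    enrichment = stage_enrich(config, gene_sets, annotation)
    for name, result in enrichment.items():
        dio.write_tsv(
            result.records,
            outdir / f"enrichment_{name}.tsv",
            comments=[
                f"namespace={result.namespace}",
                f"query={result.n_query}",
                f"dropped={result.n_dropped}",
            ],
        )

    recovery = recovery_report(truth, pattern, nutrient_sets)
    dio.write_tsv(recovery, outdir / "recovery.tsv")
    _log("recovery report written")

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n", newline="\n")

    manifest = {
        "seed": seed,
        "conditions": list(CONDITIONS),
        "baseline": BASELINE,
        "config": config.model_dump(),
        "artifacts": {
            p.name: dio.sha256_file(p)
            for p in sorted(outdir.iterdir())
            if p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n", newline="\n"
    )

    return PipelineResult(
        config=config,
        catalog=catalog,
        truth=truth,
        raw_libs=raw_libs,
        clean_libs=clean_libs,
        table=table,
        library_stats=lib_stats,
        comparisons=comparisons,
        pattern_sets=pattern,
        nutrient_sets=nutrient_sets,
        enrichment=enrichment,
        recovery=recovery,
        outdir=outdir,
    )
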