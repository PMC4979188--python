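"""Subtractive set screens across the five-condition design.

Two screens operate on the four baseline-vs-other subtractive libraries
(SYA vs SR, NR, PR, SDAY):

* the *pattern* screen intersects the four libraries in one direction,
  yielding genes consistently up on all four normal-conidiation media
  (``up_in_other``) or consistently up on the microcycle medium
  (``up_in_SYA``);
* the *nutrient* screen takes one SYA-vs-nutrient subtractive library
  and removes every gene expressed on quarter-strength SDAY or on the
  other two nutrient media, leaving genes whose differential expression
  is specific to that nutrient.

``venn_partition`` provides the generic region accounting used to
summarize how 2-4 named gene sets overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .de import CALL_UP_A, CALL_UP_B, SubtractiveLibrary
from .simulate import BASELINE, NUTRIENT_CLASSES

__all__ = [
    "DIRECTION_UP_SYA",
    "DIRECTION_UP_OTHER",
    "PatternSets",
    "NutrientSpecificSet",
    "expressed_genes",
    "pattern_intersection",
    "derive_pattern_sets",
    "nutrient_specific",
    "venn_partition",
]

DIRECTION_UP_SYA = "up_in_SYA"
DIRECTION_UP_OTHER = "up_in_other"

#: condition -> nutrient name for the three enriched media
CONDITION_NUTRIENT = {cond: cls.split("_")[0] for cls, cond in NUTRIENT_CLASSES.items()}


@dataclass
class PatternSets:
    """The two four-way intersections with per-gene provenance.

    ``provenance`` maps each member gene to its call in each of the four
    comparisons (column per pair); the two sets are disjoint by
    construction since they require opposite directions.
    """

    normal_up: set[str]
    microcycle_up: set[str]
    provenance: pd.DataFrame


@dataclass
class NutrientSpecificSet:
    """Genes specific to one nutrient medium relative to the SYA baseline.

    ``members`` maps gene -> direction ("up" = higher on the nutrient
    medium than on SYA); ``removed`` maps each excluded candidate to the
    conditions whose expression disqualified it.
    """

    nutrient: str
    condition: str
    members: dict[str, str]
    removed: dict[str, tuple[str, ...]]

    @property
    def genes(self) -> set[str]:
        return set(self.members)


def expressed_genes(table, condition: str, min_count: int = 1) -> set[str]:
    """Genes with unambiguous count >= ``min_count`` on ``condition``."""
    if condition not in table.conditions:
        raise KeyError(f"unknown condition {condition!r}; have {table.conditions}")
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    col = table.counts[condition]
    return set(col.index[col >= min_count])


def _check_four_baseline(libs: list[SubtractiveLibrary]) -> None:
    if len(libs) != 4:
        raise ValueError(f"expected exactly four subtractive libraries, got {len(libs)}")
    for lib in libs:
        if lib.pair[0] != BASELINE:
            raise ValueError(
                f"library {lib.pair} does not use {BASELINE} as its baseline"
            )
    others = [lib.pair[1] for lib in libs]
    if len(set(others)) != 4:
        raise ValueError(f"duplicate comparison conditions: {others}")


def pattern_intersection(
    libs: list[SubtractiveLibrary], direction: str
) -> tuple[set[str], pd.DataFrame]:
    """Genes carrying ``direction`` in all four subtractive libraries.

    ``direction`` is ``up_in_SYA`` (up on the baseline) or
    ``up_in_other`` (up on the non-baseline side).  Returns the gene set
    and a provenance frame of the four calls per member.
    """
    if direction not in (DIRECTION_UP_SYA, DIRECTION_UP_OTHER):
        raise ValueError(f"unknown direction {direction!r}")
    _check_four_baseline(libs)
    call = CALL_UP_A if direction == DIRECTION_UP_SYA else CALL_UP_B
    per_lib = [lib.genes_with_call(call) for lib in libs]
    members = set.intersection(*per_lib)
    provenance = pd.DataFrame(
        {
            f"{lib.pair[0]}_vs_{lib.pair[1]}": pd.Series(
                {g: lib.direction_of(g) for g in members}
            )
            for lib in libs
        }
    )
    provenance.index.name = "gene_id"
    return members, provenance.sort_index()


def derive_pattern_sets(libs: list[SubtractiveLibrary]) -> PatternSets:
    """Both four-way intersections in one pass."""
    normal, prov_n = pattern_intersection(libs, DIRECTION_UP_OTHER)
    micro, prov_m = pattern_intersection(libs, DIRECTION_UP_SYA)
    provenance = pd.concat([prov_n, prov_m]).sort_index()
    return PatternSets(normal_up=normal, microcycle_up=micro, provenance=provenance)


def nutrient_specific(
    sub: SubtractiveLibrary,
    expressed_other: dict[str, set[str]],
) -> NutrientSpecificSet:
    """Remove from a SYA-vs-nutrient library every gene expressed elsewhere.

    ``expressed_other`` maps each of the three other non-baseline
    conditions (SDAY and the two remaining nutrient media) to its
    expressed-gene set.  Direction labels follow the subtractive
    library: "up" means higher on the nutrient medium than on SYA.
    """
    if sub.pair[0] != BASELINE:
        raise ValueError(f"subtractive library {sub.pair} must be baselined on {BASELINE}")
    cond = sub.pair[1]
    if cond not in CONDITION_NUTRIENT:
        raise ValueError(f"{cond!r} is not a nutrient-enriched condition")
    if cond in expressed_other:
        raise ValueError(
            f"expression set for the screened condition {cond!r} must not be supplied"
        )
    members: dict[str, str] = {}
    removed: dict[str, tuple[str, ...]] = {}
    for _, row in sub.records.iterrows():
        gene = row["gene_id"]
        blockers = tuple(
            sorted(c for c, genes in expressed_other.items() if gene in genes)
        )
        if blockers:
            removed[gene] = blockers
        else:
            members[gene] = "up" if row["call"] == CALL_UP_B else "down"
    return NutrientSpecificSet(
        nutrient=CONDITION_NUTRIENT[cond],
        condition=cond,
        members=members,
        removed=removed,
    )


def venn_partition(sets: dict[str, set]) -> dict[str, set]:
    """Partition 2-4 named sets into disjoint membership regions.

    Region keys join member-set names with ``&`` in input order; only
    non-empty regions are returned.  Regions are pairwise disjoint and
    their union equals the union of the inputs.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError(f"need between 2 and 4 sets, got {len(sets)}")
    names = list(sets)
    regions: dict[str, set] = {}
    for element in set.union(*sets.values()):
        signature = "&".join(n for n in names if element in sets[n])
        regions.setdefault(signature, set()).add(element)
    return regions
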