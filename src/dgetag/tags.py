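"""Tag extraction, cleaning, mapping and normalization for DGE libraries.

NlaIII-style DGE chemistry sequences a short tag downstream of the
3'-most anchor site (``CATG`` by default) of each transcript.  This
module derives the expected tag catalogue from a transcript reference,
filters raw sequenced tags into "clean" tags, maps clean tags back to
genes, and produces the gene x condition count/TPM table that every
downstream stage consumes.

Cleaning applies three rules, in order and with per-rule accounting:
drop sequences with non-ACGT characters, drop adaptor-prefixed
sequences, and drop distinct tags below a copy-number threshold
(singleton removal by default).  Mapping counts a gene only from tags
that reach it unambiguously; ambiguous and unmapped copies are
accounted so that copies are conserved exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TagLibrary",
    "CleanLibrary",
    "ReferenceTagIndex",
    "GeneCountTable",
    "DEFAULT_ANCHOR",
    "DEFAULT_BODY_LENGTH",
    "extract_reference_tags",
    "clean_tags",
    "map_tags",
    "build_count_table",
    "normalize_tpm",
    "copy_number_distribution",
    "library_statistics",
]

DEFAULT_ANCHOR = "CATG"
DEFAULT_BODY_LENGTH = 17

_ACGT = frozenset("ACGT")


@dataclass
class TagLibrary:
    """Raw sequenced tags of one condition: distinct sequence -> copy number."""

    condition: str
    tags: dict[str, int]

    def __post_init__(self) -> None:
        for seq, copies in self.tags.items():
            if copies <= 0:
                raise ValueError(
                    f"tag {seq!r} has non-positive copy number {copies}"
                )

    @property
    def total_raw(self) -> int:
        return sum(self.tags.values())

    @property
    def distinct_raw(self) -> int:
        return len(self.tags)


@dataclass
class CleanLibrary:
    """Filtered tags of one condition plus per-rule removal accounting."""

    condition: str
    tags: dict[str, int]
    #: rule -> {"distinct": n removed distinct tags, "copies": n removed copies}
    filter_log: dict[str, dict[str, int]]

    @property
    def total_clean(self) -> int:
        return sum(self.tags.values())

    @property
    def distinct_clean(self) -> int:
        return len(self.tags)


@dataclass
class ReferenceTagIndex:
    """Every anchored tag of the reference with its gene associations.

    ``signature_tags`` records each gene's 3'-most anchored tag, the tag
    that carries the gene's expression under standard DGE chemistry.
    """

    anchor: str
    body_length: int
    tag_to_genes: dict[str, tuple[str, ...]]
    signature_tags: dict[str, str]

    @property
    def tag_length(self) -> int:
        return len(self.anchor) + self.body_length

    def is_ambiguous(self, tag: str) -> bool:
        return len(self.tag_to_genes[tag]) > 1

    def __len__(self) -> int:
        return len(self.tag_to_genes)


@dataclass
class GeneCountTable:
    """Gene x condition unambiguous counts with clean-library sizes.

    ``counts`` is a genes-by-conditions integer DataFrame; ``library_sizes``
    the per-condition clean totals used for TPM; ``mapping_stats`` an
    optional per-condition summary (mapped fraction, genes detected, ...).
    """

    counts: pd.DataFrame
    library_sizes: pd.Series
    mapping_stats: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for cond in self.counts.columns:
            if cond not in self.library_sizes.index:
                raise ValueError(f"missing library size for condition {cond!r}")
            size = self.library_sizes[cond]
            if size <= 0 and self.counts[cond].sum() > 0:
                raise ValueError(
                    f"condition {cond!r} has zero library size but non-zero counts"
                )

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.counts.index)

    @property
    def tpm(self) -> pd.DataFrame:
        sizes = self.library_sizes[list(self.counts.columns)].astype(float)
        sizes = sizes.replace(0, np.nan)
        return (self.counts / sizes * 1e6).fillna(0.0)


def extract_reference_tags(
    catalog,
    anchor: str = DEFAULT_ANCHOR,
    body_length: int = DEFAULT_BODY_LENGTH,
) -> ReferenceTagIndex:
    """Index every ``anchor + body_length`` tag of each transcript.

    Each occurrence of the anchor followed by at least ``body_length``
    bases yields one tag; a gene's 3'-most such tag is its signature tag.
    Tags shared by more than one gene are flagged ambiguous via their
    gene multiplicity.  Genes with no eligible site contribute nothing.
    """
    if body_length < 1:
        raise ValueError(f"body_length must be >= 1, got {body_length}")
    if not anchor or not set(anchor) <= _ACGT:
        raise ValueError(f"anchor must be a non-empty ACGT motif, got {anchor!r}")
    tag_len = len(anchor) + body_length
    tag_genes: dict[str, set[str]] = {}
    signature: dict[str, str] = {}
    for gene_id, seq in catalog.records:
        pos = seq.find(anchor)
        last_tag = None
        while pos != -1:
            if pos + tag_len <= len(seq):
                tag = seq[pos : pos + tag_len]
                tag_genes.setdefault(tag, set()).add(gene_id)
                last_tag = tag
            pos = seq.find(anchor, pos + 1)
        if last_tag is not None:
            signature[gene_id] = last_tag
    return ReferenceTagIndex(
        anchor=anchor,
        body_length=body_length,
        tag_to_genes={t: tuple(sorted(g)) for t, g in tag_genes.items()},
        signature_tags=signature,
    )


_RULE_NON_ACGT = "non_acgt"
_RULE_ADAPTOR = "adaptor_prefix"
_RULE_LOW_COPY = "low_copy"


def clean_tags(raw: TagLibrary, adaptor: str, min_copies: int = 2) -> CleanLibrary:
    """Filter a raw library: non-ACGT, adaptor-prefixed, then low-copy tags."""
    if min_copies < 1:
        raise ValueError(f"min_copies must be >= 1, got {min_copies}")
    log = {
        rule: {"distinct": 0, "copies": 0}
        for rule in (_RULE_NON_ACGT, _RULE_ADAPTOR, _RULE_LOW_COPY)
    }
    kept: dict[str, int] = {}
    for seq, copies in raw.tags.items():
        if copies <= 0:
            raise ValueError(f"tag {seq!r} has non-positive copy number {copies}")
        if not set(seq) <= _ACGT:
            rule = _RULE_NON_ACGT
        elif adaptor and seq.startswith(adaptor):
            rule = _RULE_ADAPTOR
        elif copies < min_copies:
            rule = _RULE_LOW_COPY
        else:
            kept[seq] = copies
            continue
        log[rule]["distinct"] += 1
        log[rule]["copies"] += copies
    return CleanLibrary(condition=raw.condition, tags=kept, filter_log=log)


def _hamming1_neighbors(tag: str) -> list[str]:
    out = []
    for i, base in enumerate(tag):
        for other in "ACGT":
            if other != base:
                out.append(tag[:i] + other + tag[i + 1 :])
    return out


def map_tags(
    clean: CleanLibrary,
    index: ReferenceTagIndex,
    max_mismatch: int = 0,
) -> tuple[pd.Series, dict[str, float]]:
    """Map clean tags to genes; return per-gene counts and mapping statistics.

    A tag maps exactly when present in the index.  With
    ``max_mismatch=1`` an unmatched tag is rescued only when exactly one
    indexed tag lies within Hamming distance 1 and that tag is itself
    unambiguous; any other reachable configuration counts as
    mapped-ambiguous.  Copies are conserved:
    mapped_unambiguous + mapped_ambiguous + unmapped == total_clean.
    """
    if max_mismatch not in (0, 1):
        raise ValueError(f"max_mismatch must be 0 or 1, got {max_mismatch}")
    tag_len = index.tag_length
    for seq in clean.tags:
        if len(seq) != tag_len:
            raise ValueError(
                f"clean tag length {len(seq)} != index tag length {tag_len}"
            )
    gene_counts: Counter[str] = Counter()
    unambig = ambig = unmapped = 0
    for seq, copies in clean.tags.items():
        genes = index.tag_to_genes.get(seq)
        if genes is None and max_mismatch == 1:
            hits = [v for v in _hamming1_neighbors(seq) if v in index.tag_to_genes]
            if len(hits) == 1:
                genes = index.tag_to_genes[hits[0]]
            elif len(hits) > 1:
                ambig += copies
                continue
        if genes is None:
            unmapped += copies
        elif len(genes) == 1:
            gene_counts[genes[0]] += copies
            unambig += copies
        else:
            ambig += copies
    total = clean.total_clean
    stats = {
        "total_clean": total,
        "mapped_unambiguous": unambig,
        "mapped_ambiguous": ambig,
        "unmapped": unmapped,
        "mapped_fraction": (unambig + ambig) / total if total else 0.0,
        "genes_detected": sum(1 for c in gene_counts.values() if c >= 1),
    }
    return pd.Series(gene_counts, dtype=int), stats


def build_count_table(
    clean_libs: dict[str, CleanLibrary],
    index: ReferenceTagIndex,
    catalog,
    max_mismatch: int = 0,
) -> GeneCountTable:
    """Map every condition's clean library and assemble the count table."""
    gene_ids = [g for g, _ in catalog.records]
    counts = pd.DataFrame(0, index=pd.Index(gene_ids, name="gene_id"),
                          columns=list(clean_libs), dtype=int)
    sizes = {}
    stat_rows = {}
    n_ref = len(gene_ids)
    for cond, lib in clean_libs.items():
        per_gene, stats = map_tags(lib, index, max_mismatch=max_mismatch)
        counts.loc[per_gene.index, cond] = per_gene.astype(int)
        sizes[cond] = lib.total_clean
        stats["pct_reference_genes"] = 100.0 * stats["genes_detected"] / n_ref
        stat_rows[cond] = stats
    return normalize_tpm(
        counts,
        pd.Series(sizes),
        mapping_stats=pd.DataFrame(stat_rows).T.loc[list(clean_libs)],
    )


def normalize_tpm(
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    mapping_stats: pd.DataFrame | None = None,
) -> GeneCountTable:
    """Wrap counts and clean-library sizes; TPM = count / N * 1e6 per cell."""
    return GeneCountTable(
        counts=counts, library_sizes=library_sizes, mapping_stats=mapping_stats
    )


def copy_number_distribution(
    clean: CleanLibrary, bin_edges: list[int]
) -> pd.DataFrame:
    """Fractions of distinct and total clean tags per copy-number bin.

    ``bin_edges`` are strictly ascending integers starting at the
    singleton threshold; bin i covers [edge_i, edge_{i+1}) and the final
    bin is open-ended.  Both fraction columns sum to 1.
    """
    if not clean.tags:
        raise ValueError("cannot bin an empty clean library")
    edges = list(bin_edges)
    if len(edges) < 1 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError(f"bin edges must be strictly ascending, got {bin_edges}")
    copies = np.array(list(clean.tags.values()))
    if copies.min() < edges[0]:
        raise ValueError(
            f"copy number {copies.min()} below first bin edge {edges[0]}"
        )
    bounds = edges + [np.inf]
    labels, distinct_frac, total_frac = [], [], []
    n_distinct = len(copies)
    n_total = copies.sum()
    for lo, hi in zip(bounds, bounds[1:]):
        mask = (copies >= lo) & (copies < hi)
        labels.append(f"[{lo},{'inf' if np.isinf(hi) else int(hi) - 1}]")
        distinct_frac.append(mask.sum() / n_distinct)
        total_frac.append(copies[mask].sum() / n_total)
    return pd.DataFrame(
        {
            "bin": labels,
            "distinct_fraction": distinct_frac,
            "total_fraction": total_frac,
        }
    )


def library_statistics(
    raw_libs: dict[str, TagLibrary],
    clean_libs: dict[str, CleanLibrary],
    table: GeneCountTable,
) -> pd.DataFrame:
    """Per-library summary: raw/clean tag totals and gene-detection rates."""
    rows = []
    for cond in raw_libs:
        stats = (
            table.mapping_stats.loc[cond].to_dict()
            if table.mapping_stats is not None
            else {}
        )
        rows.append(
            {
                "condition": cond,
                "raw_total": raw_libs[cond].total_raw,
                "raw_distinct": raw_libs[cond].distinct_raw,
                "clean_total": clean_libs[cond].total_clean,
                "clean_distinct": clean_libs[cond].distinct_clean,
                "mapped_fraction": stats.get("mapped_fraction", float("nan")),
                "genes_detected": stats.get("genes_detected", float("nan")),
                "pct_reference_genes": stats.get(
                    "pct_reference_genes", float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
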