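"""Synthetic transcript catalogues and five-condition DGE tag libraries.

The study design emulated here contrasts a microcycle-conidiation
baseline medium (SYA) with four normal-conidiation media: quarter
strength SDAY and SYA enriched in sucrose (SR), nitrate (NR) or
phosphate (PR).  No raw reads are available for the original libraries,
so every downstream stage is exercised against simulated libraries with
known planted structure:

* ``background`` genes share the same relative abundance everywhere;
* ``normal_up`` genes are ``fold_change``-times more abundant on the
  four normal-conidiation media than on SYA;
* ``microcycle_up`` genes are ``fold_change``-times more abundant on SYA;
* each nutrient-specific class is expressed only on its own nutrient
  medium (abundance zero on SDAY and the other two nutrient media, and a
  reduced SYA abundance, ``1/fold_change`` of baseline by default).

Baseline abundances follow a log-normal renormalized onto the simplex,
so a few transcripts are highly abundant while most are rare, matching
the heavy-tailed copy-number spectra typical of DGE libraries.  Planted
genes receive an abundance floor so their effects are detectable at test
depths.  Sequencing is modelled as multinomial sampling of each gene's
signature tag followed by independent per-base substitution errors and
adaptor replacement; libraries are byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .tags import TagLibrary, extract_reference_tags

__all__ = [
    "CONDITIONS",
    "BASELINE",
    "CLASS_BACKGROUND",
    "CLASS_NORMAL_UP",
    "CLASS_MICROCYCLE_UP",
    "NUTRIENT_CLASSES",
    "PLANTED_CLASSES",
    "ReferenceCatalog",
    "SimTruth",
    "generate_reference",
    "plan_truth",
    "simulate_libraries",
    "simulate_null_counts",
    "evaluate_recovery",
    "adaptor_tag",
    "DEFAULT_ADAPTOR_PREFIX",
]

CONDITIONS = ("SYA", "SR", "NR", "PR", "SDAY")
BASELINE = "SYA"

CLASS_BACKGROUND = "background"
CLASS_NORMAL_UP = "normal_up"
CLASS_MICROCYCLE_UP = "microcycle_up"
#: nutrient-specific class -> the only condition on which it is expressed
NUTRIENT_CLASSES = {
    "sucrose_specific": "SR",
    "nitrate_specific": "NR",
    "phosphate_specific": "PR",
}
PLANTED_CLASSES = (
    CLASS_NORMAL_UP,
    CLASS_MICROCYCLE_UP,
    *NUTRIENT_CLASSES,
)

DEFAULT_ADAPTOR_PREFIX = "GATCGGAAG"
_ADAPTOR_FILLER = "AGCGTCGTGTAGGGAAAGAGTGTA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def adaptor_tag(tag_length: int) -> str:
    """The fixed adaptor-prefixed sequence used for contaminated tags."""
    seq = DEFAULT_ADAPTOR_PREFIX + _ADAPTOR_FILLER
    if tag_length > len(seq):
        raise ValueError(f"tag length {tag_length} exceeds adaptor template")
    return seq[:tag_length]


@dataclass(frozen=True)
class ReferenceCatalog:
    """Ordered (gene_id, sequence) records over the ACGT alphabet."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        for gene_id, seq in self.records:
            if not seq:
                raise ValueError(f"gene {gene_id!r} has an empty sequence")
            if not set(seq) <= set("ACGT"):
                raise ValueError(f"gene {gene_id!r} has non-ACGT characters")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth: abundances, memberships and per-gene effects.

    ``abundance`` is the baseline relative abundance (sums to 1 across
    genes); ``membership`` assigns each gene to background or one of the
    five planted classes; ``fold_change`` holds the planted effect per
    planted gene; ``condition_depths`` the intended clean-tag count per
    condition.  ``expected_weights`` returns the *unnormalized*
    per-condition expression weights, so planted ratios are exact.
    """

    gene_ids: tuple[str, ...]
    abundance: dict[str, float]
    membership: dict[str, str]
    fold_change: dict[str, float]
    seed: int
    condition_depths: dict[str, int]
    nutrient_sya_factor: float

    def __post_init__(self) -> None:
        total = sum(self.abundance.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1, got {total}")
        if any(a < 0 for a in self.abundance.values()):
            raise ValueError("abundances must be non-negative")
        for gene, fc in self.fold_change.items():
            if fc < 1:
                raise ValueError(f"fold change for {gene!r} must be >= 1, got {fc}")

    def class_members(self, cls: str) -> set[str]:
        return {g for g, m in self.membership.items() if m == cls}

    def expected_weights(self, condition: str) -> dict[str, float]:
        """Unnormalized expected expression of every gene on ``condition``."""
        if condition not in CONDITIONS:
            raise KeyError(f"unknown condition {condition!r}")
        weights = {}
        for gene in self.gene_ids:
            a = self.abundance[gene]
            cls = self.membership[gene]
            fc = self.fold_change.get(gene, 1.0)
            if cls == CLASS_NORMAL_UP:
                w = a if condition == BASELINE else a * fc
            elif cls == CLASS_MICROCYCLE_UP:
                w = a * fc if condition == BASELINE else a
            elif cls in NUTRIENT_CLASSES:
                home = NUTRIENT_CLASSES[cls]
                if condition == home:
                    w = a
                elif condition == BASELINE:
                    w = a * self.nutrient_sya_factor
                else:
                    w = 0.0
            else:
                w = a
            weights[gene] = w
        return weights

    def to_json(self) -> str:
        payload = {
            "gene_ids": list(self.gene_ids),
            "abundance": self.abundance,
            "membership": self.membership,
            "fold_change": self.fold_change,
            "seed": self.seed,
            "condition_depths": self.condition_depths,
            "nutrient_sya_factor": self.nutrient_sya_factor,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            gene_ids=tuple(d["gene_ids"]),
            abundance=d["abundance"],
            membership=d["membership"],
            fold_change=d["fold_change"],
            seed=int(d["seed"]),
            condition_depths={k: int(v) for k, v in d["condition_depths"].items()},
            nutrient_sya_factor=float(d["nutrient_sya_factor"]),
        )


def generate_reference(
    n_genes: int,
    length_range: tuple[int, int] = (200, 1200),
    seed: int = 0,
    anchor: str = "CATG",
    body_length: int = 17,
) -> ReferenceCatalog:
    """Random transcript catalogue in which every gene hosts >= 1 full tag.

    Each sequence gets one anchor implanted at a position leaving at
    least ``body_length`` trailing bases; additional anchor sites may
    occur by chance.  Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    lmin, lmax = length_range
    if lmin > lmax:
        raise ValueError(f"invalid length range {length_range}")
    if lmin < len(anchor) + body_length:
        raise ValueError(
            f"minimum length {lmin} cannot host anchor ({len(anchor)}) "
            f"plus tag body ({body_length})"
        )
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    records = []
    for i in range(n_genes):
        length = int(rng.integers(lmin, lmax + 1))
        codes = rng.integers(0, 4, size=length)
        seq = bytes(_BASES[codes]).decode()
        pos = int(rng.integers(0, length - len(anchor) - body_length + 1))
        seq = seq[:pos] + anchor + seq[pos + len(anchor) :]
        records.append((f"gene{i:0{width}d}", seq))
    return ReferenceCatalog(records=tuple(records))


def plan_truth(
    catalog: ReferenceCatalog,
    class_sizes: dict[str, int] | None = None,
    fold_change: float = 8.0,
    abundance_location: float = 1.0,
    abundance_scale: float = 1.5,
    depths: dict[str, int] | int = 300_000,
    seed: int = 0,
    nutrient_sya_factor: float | None = None,
    planted_abundance_floor: float = 1.25e-4,
) -> SimTruth:
    """Assign planted classes, abundances and depths for a simulation run.

    Baseline abundances are log-normal(location, scale) renormalized to
    the simplex; planted genes are floored at ``planted_abundance_floor``
    (before a final renormalization) so their effects are visible at the
    intended depths.  Class members are drawn disjointly at random.
    """
    if class_sizes is None:
        class_sizes = {}
    unknown = set(class_sizes) - set(PLANTED_CLASSES)
    if unknown:
        raise ValueError(f"unknown planted classes: {sorted(unknown)}")
    if any(v < 0 for v in class_sizes.values()):
        raise ValueError("class sizes must be non-negative")
    n_planted = sum(class_sizes.values())
    if n_planted > len(catalog):
        raise ValueError(
            f"planted classes ({n_planted}) exceed catalogue size ({len(catalog)})"
        )
    if n_planted and fold_change <= 1:
        raise ValueError(f"fold_change must be > 1, got {fold_change}")
    if abundance_scale <= 0:
        raise ValueError(f"abundance_scale must be positive, got {abundance_scale}")
    if isinstance(depths, int):
        depths = {c: depths for c in CONDITIONS}
    for cond, depth in depths.items():
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r} in depths")
        if depth < 0:
            raise ValueError(f"depth for {cond!r} must be >= 0, got {depth}")

    rng = np.random.default_rng(seed)
    gene_ids = catalog.gene_ids
    raw = rng.lognormal(mean=abundance_location, sigma=abundance_scale,
                        size=len(gene_ids))
    abundance = raw / raw.sum()

    membership = {g: CLASS_BACKGROUND for g in gene_ids}
    fold = {}
    chosen = rng.choice(len(gene_ids), size=n_planted, replace=False)
    offset = 0
    for cls in PLANTED_CLASSES:
        for idx in chosen[offset : offset + class_sizes.get(cls, 0)]:
            membership[gene_ids[idx]] = cls
            fold[gene_ids[idx]] = float(fold_change)
        offset += class_sizes.get(cls, 0)

    if n_planted and planted_abundance_floor > 0:
        planted_idx = chosen[:n_planted]
        abundance[planted_idx] = np.maximum(
            abundance[planted_idx], planted_abundance_floor
        )
        abundance = abundance / abundance.sum()

    return SimTruth(
        gene_ids=gene_ids,
        abundance={g: float(a) for g, a in zip(gene_ids, abundance)},
        membership=membership,
        fold_change=fold,
        seed=int(seed),
        condition_depths={c: int(depths.get(c, 0)) for c in CONDITIONS},
        nutrient_sya_factor=float(
            nutrient_sya_factor if nutrient_sya_factor is not None
            else 1.0 / fold_change
        ),
    )


def _condition_seed(seed: int, condition: str) -> int:
    """Stable per-condition stream seed from the master seed."""
    digest = hashlib.sha256(f"{seed}|{condition}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def simulate_libraries(
    catalog: ReferenceCatalog,
    truth: SimTruth,
    error_rate: float = 0.001,
    adaptor_rate: float = 0.0,
    seed: int | None = None,
    anchor: str = "CATG",
    body_length: int = 17,
) -> dict[str, TagLibrary]:
    """Draw one raw TagLibrary per condition from the planted truth.

    Copies are multinomial over gene signature tags weighted by the
    renormalized per-condition expected weights; each copy is then
    independently corrupted base-by-base with probability ``error_rate``
    and a fraction ``adaptor_rate`` of copies is replaced by the fixed
    adaptor-prefixed tag.  Per-condition random streams are derived by
    stable hashing of (seed, condition).
    """
    if not 0 <= error_rate < 1:
        raise ValueError(f"error_rate must lie in [0, 1), got {error_rate}")
    if not 0 <= adaptor_rate < 1:
        raise ValueError(f"adaptor_rate must lie in [0, 1), got {adaptor_rate}")
    if set(catalog.gene_ids) != set(truth.gene_ids):
        raise ValueError("catalogue and truth gene ids differ")
    master = truth.seed if seed is None else seed

    index = extract_reference_tags(catalog, anchor=anchor, body_length=body_length)
    tag_len = index.tag_length
    genes = [g for g in truth.gene_ids if g in index.signature_tags]
    sig_tags = [index.signature_tags[g] for g in genes]
    tag_codes = np.array(
        [np.frombuffer(t.encode(), dtype=np.uint8) for t in sig_tags]
    )
    lut = np.zeros(256, dtype=np.uint8)
    for v, b in enumerate(b"ACGT"):
        lut[b] = v
    tag_codes = lut[tag_codes]
    adaptor_seq = adaptor_tag(tag_len)

    libraries = {}
    for cond in CONDITIONS:
        depth = truth.condition_depths.get(cond, 0)
        rng = np.random.default_rng(_condition_seed(master, cond))
        if depth == 0:
            libraries[cond] = TagLibrary(condition=cond, tags={})
            continue
        weights = truth.expected_weights(cond)
        w = np.array([weights[g] for g in genes], dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"no positive expression weight on {cond!r}")
        gene_counts = rng.multinomial(depth, w / w.sum())
        copy_gene = np.repeat(np.arange(len(genes)), gene_counts)

        is_adaptor = rng.random(depth) < adaptor_rate
        err = rng.random((depth, tag_len)) < error_rate
        err[is_adaptor] = False
        has_err = err.any(axis=1)

        tags: Counter[str] = Counter()
        intact = ~is_adaptor & ~has_err
        intact_counts = np.bincount(copy_gene[intact], minlength=len(genes))
        for gi in np.nonzero(intact_counts)[0]:
            tags[sig_tags[gi]] += int(intact_counts[gi])

        mutated_rows = np.nonzero(~is_adaptor & has_err)[0]
        if mutated_rows.size:
            codes = tag_codes[copy_gene[mutated_rows]].copy()
            mask = err[mutated_rows]
            shifts = rng.integers(1, 4, size=int(mask.sum()))
            codes[mask] = (codes[mask] + shifts) % 4
            seqs = _BASES[codes]
            for row in seqs:
                tags[bytes(row).decode()] += 1

        n_adaptor = int(is_adaptor.sum())
        if n_adaptor:
            tags[adaptor_seq] += n_adaptor
        libraries[cond] = TagLibrary(condition=cond, tags=dict(tags))
    return libraries


def generate_annotations(
    gene_ids,
    n_terms: int = 40,
    mean_term_size: float = 15.0,
    seed: int = 0,
    planted_term: str | None = None,
    planted_genes: set[str] | None = None,
    namespace: str = "GO",
):
    """Random flat annotation map, optionally with one planted term.

    Each of ``n_terms`` random terms annotates a Poisson-sized draw of
    genes; ``planted_term`` (if given) annotates exactly
    ``planted_genes``, letting enrichment recovery be tested against a
    known signal.
    """
    from .enrich import AnnotationMap

    gene_ids = list(gene_ids)
    rng = np.random.default_rng(seed)
    pairs = []
    for t in range(n_terms):
        size = max(1, int(rng.poisson(mean_term_size)))
        size = min(size, len(gene_ids))
        for idx in rng.choice(len(gene_ids), size=size, replace=False):
            pairs.append((gene_ids[idx], f"TERM:{t:04d}"))
    if planted_term is not None:
        if not planted_genes:
            raise ValueError("planted_term requires non-empty planted_genes")
        for gene in sorted(planted_genes):
            pairs.append((gene, planted_term))
    return AnnotationMap.from_pairs(pairs, namespace=namespace)


def simulate_null_counts(
    n_genes: int, depth: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two multinomial count vectors over equally abundant genes."""
    rng = np.random.default_rng(seed)
    probs = np.full(n_genes, 1.0 / n_genes)
    return rng.multinomial(depth, probs), rng.multinomial(depth, probs)


def evaluate_recovery(called: set[str], truth_set: set[str]) -> tuple[float, float]:
    """(precision, recall) of a called gene set against a planted set.

    Empty ``called`` with non-empty truth gives precision 0; empty truth
    gives recall 1 (and precision 1 when both are empty).
    """
    called = set(called)
    truth_set = set(truth_set)
    hits = len(called & truth_set)
    if not called:
        precision = 1.0 if not truth_set else 0.0
    else:
        precision = hits / len(called)
    recall = 1.0 if not truth_set else hits / len(truth_set)
    return precision, recall
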