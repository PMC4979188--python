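"""Readers and writers for every pipeline artifact.

Formats: FASTA for the transcript reference (via Biopython), JSON for
configs/truth/manifest, and a fixed TSV dialect everywhere else:
tab-separated, UTF-8, '#'-prefixed header comments, no quoting.  All
writers are deterministic (sorted rows, fixed float formatting) so that
identical runs produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .de import SubtractiveLibrary
from .simulate import ReferenceCatalog, SimTruth
from .tags import CleanLibrary, GeneCountTable, TagLibrary

__all__ = [
    "write_fasta", "read_fasta",
    "write_tag_library", "read_tag_library",
    "write_truth", "read_truth",
    "write_count_table", "read_count_table",
    "write_comparison", "read_comparison",
    "write_tsv", "read_tsv",
    "write_gene_set_tsv",
    "write_annotation_tsv", "read_annotation_tsv",
    "sha256_file",
]

_FLOAT_FMT = "%.10g"


def write_fasta(catalog: ReferenceCatalog, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="")
        for gene_id, seq in catalog.records
    ]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> ReferenceCatalog:
    records = tuple(
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    )
    return ReferenceCatalog(records=records)


def _write_tags(condition: str, tags: dict[str, int], path: str | Path,
                extra_comments: list[str] | None = None) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# condition={condition}\n")
        for line in extra_comments or []:
            fh.write(f"# {line}\n")
        fh.write("tag_sequence\tcopies\n")
        for seq in sorted(tags, key=lambda s: (-tags[s], s)):
            fh.write(f"{seq}\t{tags[seq]}\n")


def write_tag_library(lib: TagLibrary | CleanLibrary, path: str | Path) -> None:
    extra = None
    if isinstance(lib, CleanLibrary):
        extra = [
            f"removed {rule} distinct={v['distinct']} copies={v['copies']}"
            for rule, v in lib.filter_log.items()
        ]
    _write_tags(lib.condition, lib.tags, path, extra)


def read_tag_library(path: str | Path) -> TagLibrary:
    condition = None
    tags: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if line.startswith("# condition="):
                    condition = line.split("=", 1)[1]
                continue
            if line == "tag_sequence\tcopies" or not line:
                continue
            seq, copies = line.split("\t")
            tags[seq] = int(copies)
    if condition is None:
        raise ValueError(f"{path}: missing '# condition=' header")
    return TagLibrary(condition=condition, tags=tags)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json() + "\n")


def read_truth(path: str | Path) -> SimTruth:
    return SimTruth.from_json(Path(path).read_text())


def write_count_table(table: GeneCountTable, path: str | Path) -> None:
    """Counts + TPM per condition; library sizes in '#' header comments."""
    conds = list(table.conditions)
    tpm = table.tpm
    out = pd.DataFrame(index=table.counts.index)
    for cond in conds:
        out[f"{cond}_count"] = table.counts[cond]
    for cond in conds:
        out[f"{cond}_tpm"] = tpm[cond]
    buf = _io.StringIO()
    for cond in conds:
        buf.write(f"# library_size\t{cond}\t{int(table.library_sizes[cond])}\n")
    out.sort_index().to_csv(buf, sep="\t", float_format=_FLOAT_FMT)
    Path(path).write_text(buf.getvalue(), newline="\n")


def read_count_table(path: str | Path) -> GeneCountTable:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# library_size"):
            _, cond, size = line.rstrip("\n").split("\t")
            sizes[cond] = int(size)
        elif not line.startswith("#"):
            body_start = i
            break
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep="\t",
                     index_col="gene_id")
    conds = [c[: -len("_count")] for c in df.columns if c.endswith("_count")]
    counts = df[[f"{c}_count" for c in conds]]
    counts.columns = conds
    return GeneCountTable(
        counts=counts.astype(int), library_sizes=pd.Series(sizes)
    )


def write_comparison(sub: SubtractiveLibrary, path: str | Path) -> None:
    buf = _io.StringIO()
    buf.write(f"# pair\t{sub.pair[0]}\t{sub.pair[1]}\n")
    sub.table.sort_values("gene_id").to_csv(
        buf, sep="\t", index=False, float_format=_FLOAT_FMT
    )
    Path(path).write_text(buf.getvalue(), newline="\n")


def read_comparison(path: str | Path) -> SubtractiveLibrary:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("# pair\t"):
            raise ValueError(f"{path}: missing '# pair' header")
        _, a, b = header.split("\t")
        table = pd.read_csv(fh, sep="\t")
    records = table[table["call"] != "not_significant"].reset_index(drop=True)
    return SubtractiveLibrary(pair=(a, b), records=records, table=table)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False,
              comments: list[str] | None = None) -> None:
    buf = _io.StringIO()
    for line in comments or []:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=index, float_format=_FLOAT_FMT)
    Path(path).write_text(buf.getvalue(), newline="\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_gene_set_tsv(members: dict[str, str], path: str | Path,
                       comments: list[str] | None = None) -> None:
    """gene_id -> direction/provenance label, sorted by gene id."""
    df = pd.DataFrame(
        sorted(members.items()), columns=["gene_id", "direction"]
    )
    write_tsv(df, path, comments=comments)


def write_annotation_tsv(annotation, path: str | Path) -> None:
    rows = [
        (gene, term)
        for gene in sorted(annotation.gene_to_terms)
        for term in sorted(annotation.gene_to_terms[gene])
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "term_id"])
    write_tsv(df, path, comments=[f"namespace={annotation.namespace}"])


def read_annotation_tsv(path: str | Path, namespace: str | None = None):
    from .enrich import AnnotationMap

    if namespace is None:
        namespace = "GO"
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("# namespace="):
            namespace = first.rstrip("\n").split("=", 1)[1]
    df = read_tsv(path)
    return AnnotationMap.from_pairs(
        zip(df["gene_id"], df["term_id"]), namespace=namespace
    )


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
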