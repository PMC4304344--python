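"""File-format boundary: FASTA/FASTQ via Biopython, GFF3 via gffutils, TSV via pandas.

Coordinates are 0-based half-open in memory and converted to/from the 1-based
inclusive GFF3 convention here and nowhere else.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRUCTURAL_TYPES = frozenset({"tRNA", "rRNA", "snoRNA", "snRNA"})
KNOWN_FEATURE_TYPES = STRUCTURAL_TYPES | {"gene"}


@dataclass(frozen=True)
class Feature:
    """A genomic interval annotation (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    ftype: str
    feature_id: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered {id: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(counts: Mapping[str, int], path: str | Path, prefix: str = "read") -> None:
    """Expand collapsed (sequence -> count) reads into a Phred+33 FASTQ.

    Qualities are dummy 'I' (Q40); ordering is deterministic (sequence-sorted,
    copies consecutive) so identical inputs give byte-identical files.
    """
    i = 0
    with open(path, "w") as fh:
        for seq in sorted(counts):
            for _ in range(counts[seq]):
                fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")
                i += 1


def read_fastq_counts(path: str | Path) -> Counter:
    """Collapse a FASTQ (or FASTA) file to distinct-sequence counts."""
    fmt = "fasta" if str(path).endswith((".fa", ".fasta")) else "fastq"
    counts: Counter = Counter()
    for rec in SeqIO.parse(str(path), fmt):
        counts[str(rec.seq).upper()] += 1
    return counts


def write_gff3(features: Iterable[Feature], path: str | Path, source: str = "senescmir") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        source,
                        f.ftype,
                        str(f.start + 1),  # GFF3 is 1-based inclusive
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.feature_id}",
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    feats = []
    for f in db.all_features():
        fid = f.attributes.get("ID", [f.id])[0]
        feats.append(
            Feature(
                chrom=f.seqid,
                start=f.start - 1,  # back to 0-based half-open
                end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
                ftype=f.featuretype,
                feature_id=fid,
            )
        )
    return feats


def structural_features(features: Iterable[Feature]) -> list[Feature]:
    """Keep t/r/sn/snoRNA intervals; warn on (and drop) unknown feature types."""
    kept = []
    for f in features:
        if f.ftype in STRUCTURAL_TYPES:
            kept.append(f)
        elif f.ftype not in KNOWN_FEATURE_TYPES:
            warnings.warn(f"ignoring interval with unknown feature type {f.ftype!r}")
    return kept


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
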