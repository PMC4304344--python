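"""Nucleotide-alphabet helpers shared across the package.

All sequences are handled internally as uppercase DNA (``ACGTN``); RNA input
(miRBase-style mature sequences, the locus report) is converted at the I/O
boundary with :func:`rna_to_dna` / :func:`dna_to_rna`.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Watson-Crick pairs plus the G:U (G:T in DNA letters) wobble, as
#: (strand_a_base, strand_b_base) read antiparallel.
WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def is_wc(a: str, b: str) -> bool:
    return (a, b) in WC_PAIRS


def is_wobble(a: str, b: str) -> bool:
    return (a, b) in WOBBLE_PAIRS


def can_pair(a: str, b: str) -> bool:
    """True if the two bases can pair in an RNA helix (WC or G:U wobble)."""
    return (a, b) in WC_PAIRS or (a, b) in WOBBLE_PAIRS


_ACGT = frozenset("ACGT")
_ACGTN = frozenset("ACGTN")


def check_alphabet(seq: str, allow_n: bool = False) -> bool:
    return set(seq) <= (_ACGTN if allow_n else _ACGT)
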