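"""Stem-loop pairing score for candidate sRNA precursors.

A miRNA-like precursor is a single hairpin: one stem (with bulges and internal
loops) closed by a terminal loop.  We score a window by the maximum number of
bases it can pair in such a structure — pairs (i1,j1) ⊃ (i2,j2) ⊃ ... nested
around a single loop, Watson-Crick or G:U, terminal loop of at least
``min_loop`` unpaired bases — counting only pairs that sit in helices of at
least ``min_helix`` consecutive stacked pairs.  The helix constraint is what
separates real inverted repeats from the incidental pairing any random
sequence can scrape together; unconstrained maximum matching saturates on
random sequence and discriminates nothing.

Score = 2 * paired_bases_credited / window_length, in [0, 1].  Because G:U
pairing is not symmetric under reverse complement, the reported score is the
maximum over the window and its reverse complement, making it independent of
which genomic strand the window was read from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqtools import revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}

# pairable[a,b]: WC or G:U wobble (N pairs nothing)
_PAIRABLE = np.zeros((5, 5), dtype=bool)
for a, b in [(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)]:
    _PAIRABLE[a, b] = True


def _codes(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.int8)


def stem_pairs(seq: str, min_loop: int = 3, min_helix: int = 5) -> tuple[int, list[tuple[int, int]]]:
    """Maximum credited pairs of a single stem-loop structure on one strand.

    Returns (credited pair count, the pair list of one optimal structure,
    including the short uncredited helices it may contain).
    """
    n = len(seq)
    H = max(min_helix, 1)
    codes = _codes(seq)
    if n == 0:
        return 0, []
    pairable = _PAIRABLE[codes[:, None], codes[None, :]]

    # G[L][k, i] = best credited pairs in seq[i : i+L] entered with a run of k
    # consecutive stacked pairs immediately outside (k capped at H).
    G: list[np.ndarray | None] = [None] * (n + 1)
    G[0] = np.zeros((H + 1, n + 1), dtype=np.int32)
    for L in range(1, n + 1):
        m = n - L + 1
        cur = np.zeros((H + 1, m), dtype=np.int32)
        if L >= min_loop + 2:
            prev1 = G[L - 1]
            skip = np.maximum(prev1[0, 1: m + 1], prev1[0, :m])
            i_idx = np.arange(m)
            diag = pairable[i_idx, i_idx + L - 1]
            prev2 = G[L - 2]
            inner = prev2[:, 1: m + 1] if prev2.shape[1] >= m + 1 else prev2[:, 1:]
            for k in range(H + 1):
                k2 = min(k + 1, H)
                gain = H if k + 1 == H else (1 if k + 1 > H else 0)
                paired = np.where(diag, gain + inner[k2], -1)
                cur[k] = np.maximum(skip, paired)
        G[L] = cur

    best = int(G[n][0, 0])

    # traceback of one optimal structure
    pairs: list[tuple[int, int]] = []
    i, j, k = 0, n - 1, 0
    while j - i + 1 >= min_loop + 2:
        L = j - i + 1
        val = int(G[L][k, i])
        if val == int(G[L - 1][0, i + 1]):
            i += 1
            k = 0
            continue
        if val == int(G[L - 1][0, i]):
            j -= 1
            k = 0
            continue
        # must be a pair
        pairs.append((i, j))
        k = min(k + 1, H)
        i, j = i + 1, j - 1
    return best, pairs


@dataclass
class HairpinReport:
    """Folding verdict for a candidate precursor window."""

    sequence: str
    score: float  # fraction of bases paired in credited helices
    passes: bool
    threshold: float
    strand: str  # '+' if the window itself scored best, '-' for its revcomp
    pairs: list[tuple[int, int]]  # pair list in window coordinates
    loop_center: float  # window coordinate of the terminal loop midpoint

    def arm_of(self, position: float) -> str:
        """'5p' or '3p' arm assignment of a window position."""
        return "5p" if position < self.loop_center else "3p"


def fold_hairpin(
    sequence: str,
    min_loop: int = 3,
    min_helix: int = 5,
    threshold: float = 0.6,
    both_strands: bool = True,
) -> HairpinReport:
    """Score a candidate precursor window (>= 50 nt) for stem-loop character."""
    n = len(sequence)
    if n < 50:
        raise ValueError("hairpin folding requires a window of at least 50 nt")
    fwd_pairs, fwd_list = stem_pairs(sequence, min_loop, min_helix)
    strand, npairs, plist = "+", fwd_pairs, fwd_list
    if both_strands:
        rev_pairs, rev_list = stem_pairs(revcomp(sequence), min_loop, min_helix)
        if rev_pairs > fwd_pairs:
            strand, npairs = "-", rev_pairs
            # map pairs back to window coordinates
            plist = [(n - 1 - j, n - 1 - i) for i, j in rev_list]
    score = 2.0 * npairs / n
    if plist:
        inner = max(plist, key=lambda p: p[0])
        loop_center = (inner[0] + inner[1]) / 2.0
    else:
        loop_center = n / 2.0
    return HairpinReport(
        sequence=sequence,
        score=score,
        passes=score >= threshold,
        threshold=threshold,
        strand=strand,
        pairs=sorted(plist),
        loop_center=loop_center,
    )
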