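"""Plant small-RNA target scoring (Allen-scheme penalties).

An sRNA is aligned antisense to a candidate target window and charged
penalties per sRNA position: 1.0 for a mismatch, 0.5 for a G:U wobble, 2.0
per bulged nucleotide, all doubled within the 5'-core (sRNA positions 2-13).
The minimum-penalty alignment is found by dynamic programming with a bulge
budget; bulges are forbidden opposite sRNA positions 10-11 so the cleavage
register stays unambiguous.  Targets scoring at or below the cutoff (4.0,
inclusive — reported targets sit exactly at 4.0) are candidate cleavage
targets; the predicted cleavage site is the target position paired to sRNA
position 10, the 5' end of the downstream cleavage fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqtools import is_wc, is_wobble, revcomp

INF = float("inf")


@dataclass(frozen=True)
class ScoreScheme:
    """Penalty constants of the scoring scheme (configurable for calibration
    against a served predictor's settings)."""

    mismatch: float = 1.0
    wobble: float = 0.5
    bulge: float = 2.0  # per bulged nucleotide
    core: tuple[int, int] = (2, 13)  # 1-based sRNA positions with doubling
    core_multiplier: float = 2.0
    max_bulges: int = 2
    no_bulge_positions: tuple[int, int] = (10, 11)

    def position_multiplier(self, pos: int) -> float:
        return self.core_multiplier if self.core[0] <= pos <= self.core[1] else 1.0

    def pair_penalty(self, srna_base: str, target_base: str, pos: int) -> float:
        """Penalty for pairing sRNA position ``pos`` (1-based from the 5' end)
        to a target base (both read 5'->3' on their own strands)."""
        if is_wc(srna_base, target_base):
            p = 0.0
        elif is_wobble(srna_base, target_base):
            p = self.wobble
        else:
            p = self.mismatch
        return p * self.position_multiplier(pos)


@dataclass
class TargetAlignment:
    """An sRNA:transcript antisense pairing with its penalty score."""

    srna_id: str
    srna_sequence: str
    transcript_id: str
    window_start: int  # 0-based half-open, transcript coordinates
    window_end: int
    score: float
    pairing: str  # per sRNA position 5'->3': '|' WC, 'o' G:U, '.' mismatch, '-' bulged
    target_bulges: int
    cleavage_site: int  # 1-based transcript position paired to sRNA position 10

    @property
    def window(self) -> tuple[int, int]:
        return (self.window_start + 1, self.window_end)  # 1-based inclusive


def score_pairing(
    srna: str,
    target_window: str,
    scheme: ScoreScheme | None = None,
    srna_id: str = "srna",
    transcript_id: str = "window",
    window_start: int = 0,
) -> TargetAlignment:
    """Minimum-penalty global antisense alignment of an sRNA to a window.

    The window is given 5'->3' in transcript orientation; its 3' end pairs the
    sRNA 5' end.  Window length must be within ``max_bulges`` of the sRNA
    length.  Score 0 means perfect complementarity.
    """
    scheme = scheme or ScoreScheme()
    m, w = len(srna), len(target_window)
    if abs(m - w) > scheme.max_bulges:
        raise ValueError("window length outside sRNA length +- max_bulges")
    s = srna.upper()
    # reverse the window so index j pairs sRNA index j under a gapless alignment
    t = target_window.upper()[::-1]
    G = scheme.max_bulges

    # D[i][j][g]: min penalty aligning sRNA[:i] to reversed-window[:j] with g bulges
    D = np.full((m + 1, w + 1, G + 1), INF)
    D[0, 0, 0] = 0.0
    back: dict[tuple[int, int, int], tuple[int, int, int, str]] = {}
    for i in range(m + 1):
        for j in range(w + 1):
            for g in range(G + 1):
                base = D[i, j, g]
                if base == INF:
                    continue
                if i < m and j < w:  # pair (possibly mismatched)
                    pos = i + 1
                    c = base + scheme.pair_penalty(s[i], t[j], pos)
                    if c < D[i + 1, j + 1, g]:
                        D[i + 1, j + 1, g] = c
                        back[(i + 1, j + 1, g)] = (i, j, g, "pair")
                if g < G:
                    if i < m:  # sRNA nucleotide bulged
                        pos = i + 1
                        if pos not in scheme.no_bulge_positions:
                            c = base + scheme.bulge * scheme.position_multiplier(pos)
                            if c < D[i + 1, j, g + 1]:
                                D[i + 1, j, g + 1] = c
                                back[(i + 1, j, g + 1)] = (i, j, g, "sbulge")
                    if j < w:  # target nucleotide bulged (between sRNA pos i, i+1)
                        if not (i == scheme.no_bulge_positions[0] == scheme.no_bulge_positions[1] - 1):
                            pos = min(i + 1, m)
                            c = base + scheme.bulge * scheme.position_multiplier(pos)
                            if c < D[i, j + 1, g + 1]:
                                D[i, j + 1, g + 1] = c
                                back[(i, j + 1, g + 1)] = (i, j, g, "tbulge")
    gbest = int(np.argmin(D[m, w]))
    score = float(D[m, w, gbest])
    if score == INF:
        raise ValueError("no alignment within the bulge budget")

    # traceback: pairing string per sRNA position and the position-10 partner
    state = (m, w, gbest)
    pairing = [""] * m
    partner: dict[int, int] = {}  # sRNA pos (1-based) -> reversed-window index
    tbulges = 0
    while state != (0, 0, 0):
        i, j, g = state
        pi, pj, pg, move = back[state]
        if move == "pair":
            a, b = s[pi], t[pj]
            pairing[pi] = "|" if is_wc(a, b) else ("o" if is_wobble(a, b) else ".")
            partner[pi + 1] = pj
        elif move == "sbulge":
            pairing[pi] = "-"
        else:
            tbulges += 1
        state = (pi, pj, pg)

    cleavage = -1
    if 10 in partner:
        # reversed-window index -> transcript coordinate (1-based)
        cleavage = window_start + (w - 1 - partner[10]) + 1
    return TargetAlignment(
        srna_id=srna_id,
        srna_sequence=s,
        transcript_id=transcript_id,
        window_start=window_start,
        window_end=window_start + w,
        score=score,
        pairing="".join(pairing),
        target_bulges=tbulges,
        cleavage_site=cleavage,
    )


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def _pen_matrix(scheme: ScoreScheme) -> np.ndarray:
    """penalty[a, b] for sRNA base a paired to target base b (no doubling)."""
    bases = "ACGT"
    P = np.full((4, 4), scheme.mismatch)
    for ai, a in enumerate(bases):
        for bi, b in enumerate(bases):
            if is_wc(a, b):
                P[ai, bi] = 0.0
            elif is_wobble(a, b):
                P[ai, bi] = scheme.wobble
    return P


def _scan_min_scores(srna: str, transcript: str, scheme: ScoreScheme) -> np.ndarray:
    """Vectorized DP: minimum alignment score for every window END position.

    Entry e is the best score over alignments whose target window ends at
    transcript position e (exclusive); the sRNA is consumed 3'->5' while the
    transcript is consumed 5'->3', matching the antisense geometry.
    """
    m = len(srna)
    L = len(transcript)
    G = scheme.max_bulges
    s = np.array([_CODE[c] for c in srna.upper()])
    t = np.array([_CODE.get(c, 0) for c in transcript.upper()])
    P = _pen_matrix(scheme)

    D = np.full((G + 1, L + 1), INF)
    D[0, :] = 0.0  # window may start anywhere
    for i in range(1, m + 1):
        pos = m - i + 1  # sRNA position consumed at this row (1-based)
        mult = scheme.position_multiplier(pos)
        col = P[s[pos - 1], t] * mult  # penalty vs each transcript base
        newD = np.full((G + 1, L + 1), INF)
        for g in range(G + 1):
            diag = np.full(L + 1, INF)
            diag[1:] = D[g, :-1] + col
            best = diag
            if g > 0 and pos not in scheme.no_bulge_positions:
                best = np.minimum(best, D[g - 1] + scheme.bulge * mult)
            newD[g] = best
        # target bulges (between sRNA positions pos-1 and pos)
        bond_banned = (pos - 1) == scheme.no_bulge_positions[0]
        if not bond_banned:
            bmult = scheme.position_multiplier(min(pos, m))
            for g in range(1, G + 1):
                shifted = np.full(L + 1, INF)
                shifted[1:] = newD[g - 1, :-1] + scheme.bulge * bmult
                newD[g] = np.minimum(newD[g], shifted)
        D = newD
    return D.min(axis=0)  # per end position


def predict_targets(
    srna: str,
    transcripts: dict[str, str],
    cutoff: float = 4.0,
    scheme: ScoreScheme | None = None,
    srna_id: str = "srna",
) -> list[TargetAlignment]:
    """Scan every transcript for minimum-score antisense windows.

    Returns alignments with score <= cutoff (inclusive: reported targets sit
    exactly at the cutoff), sorted by ascending score, one per non-overlapping
    site, each with its predicted cleavage position.
    """
    scheme = scheme or ScoreScheme()
    if not transcripts:
        raise ValueError("empty transcriptome")
    m = len(srna)
    hits: list[TargetAlignment] = []
    for tx_id, seq in transcripts.items():
        if len(seq) < m - scheme.max_bulges:
            continue
        ends = _scan_min_scores(srna, seq, scheme)
        for e in np.nonzero(ends <= cutoff + 1e-9)[0]:
            e = int(e)
            best: TargetAlignment | None = None
            for wl in range(m - scheme.max_bulges, m + scheme.max_bulges + 1):
                s0 = e - wl
                if s0 < 0:
                    continue
                aln = score_pairing(
                    srna, seq[s0:e], scheme, srna_id=srna_id,
                    transcript_id=tx_id, window_start=s0,
                )
                if best is None or aln.score < best.score:
                    best = aln
            if best is not None and best.score <= cutoff + 1e-9:
                hits.append(best)
    # greedy non-overlap selection per transcript, best scores first
    hits.sort(key=lambda a: (a.score, a.transcript_id, a.window_start))
    kept: list[TargetAlignment] = []
    for aln in hits:
        clash = any(
            k.transcript_id == aln.transcript_id
            and aln.window_start < k.window_end
            and k.window_start < aln.window_end
            for k in kept
        )
        if not clash:
            kept.append(aln)
    return kept


def perfect_site(srna: str) -> str:
    """The perfect-complement target window of an sRNA (score 0 by definition)."""
    return revcomp(srna)
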