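"""Independent brute-force oracles used to validate the package's DPs and
index structures.  Everything here is deliberately naive — exhaustive
enumeration and linear scans — and shares no code path with the
implementations it checks."""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_scan(genome: dict[str, str], query: str) -> list[tuple[str, int, str]]:
    """All exact occurrences of query on both strands by linear scan."""
    out = []
    for strand, q in (("+", query), ("-", rc(query))):
        for chrom in genome:
            seq = genome[chrom]
            start = 0
            while True:
                i = seq.find(q, start)
                if i < 0:
                    break
                out.append((chrom, i, strand))
                start = i + 1
    return sorted(out)


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def exhaustive_stem_pairs(seq: str, min_loop: int = 3, min_helix: int = 5) -> int:
    """Maximum credited pairs over ALL single stem-loop structures, by
    exhaustive recursion over nested pair chains.

    A chain is (i1,j1) ⊃ (i2,j2) ⊃ ...; a pair is 'stacked' iff it is exactly
    (prev_i+1, prev_j-1); runs of >= min_helix stacked pairs are credited in
    full, shorter runs score nothing.
    """
    s = seq.upper()
    H = min_helix

    def rec(i: int, j: int, run: int) -> int:
        best = 0  # stop here; pending short run scores nothing
        for a in range(i, j):
            for b in range(a + min_loop + 1, j + 1):
                if (s[a], s[b]) not in _PAIRS:
                    continue
                stacked = (a == i and b == j and run > 0)
                newrun = run + 1 if stacked else 1
                if newrun == H:
                    gain = H
                elif newrun > H:
                    gain = 1
                    newrun = H
                else:
                    gain = 0
                best = max(best, gain + rec(a + 1, b - 1, newrun))
        return best

    n = len(s)
    if n == 0:
        return 0
    # outermost pair has no enclosing pair: run starts at 0 (nothing stacked yet)
    return rec(0, n - 1, 0)


def brute_min_alignment_score(
    srna: str,
    window: str,
    mismatch: float = 1.0,
    wobble: float = 0.5,
    bulge: float = 2.0,
    core: tuple[int, int] = (2, 13),
    core_mult: float = 2.0,
    max_bulges: int = 2,
    no_bulge: tuple[int, int] = (10, 11),
) -> float:
    """Minimum penalty over ALL global antisense alignments, by enumeration.

    The sRNA is consumed 5'->3' against the window 3'->5'; position-dependent
    penalties mirror the documented scoring scheme.
    """
    s = srna.upper()
    t = window.upper()[::-1]
    m, w = len(s), len(t)

    def mult(pos: int) -> float:
        return core_mult if core[0] <= pos <= core[1] else 1.0

    def pen(a: str, b: str, pos: int) -> float:
        if (a, b) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}:
            return 0.0
        if (a, b) in {("G", "T"), ("T", "G")}:
            return wobble * mult(pos)
        return mismatch * mult(pos)

    best = [float("inf")]

    def rec(i: int, j: int, gaps: int, score: float) -> None:
        if score >= best[0]:
            return
        if i == m and j == w:
            best[0] = score
            return
        if i < m and j < w:
            rec(i + 1, j + 1, gaps, score + pen(s[i], t[j], i + 1))
        if gaps < max_bulges:
            if i < m and (i + 1) not in no_bulge:
                rec(i + 1, j, gaps + 1, score + bulge * mult(i + 1))
            if j < w and i != no_bulge[0]:
                rec(i, j + 1, gaps + 1, score + bulge * mult(min(i + 1, m)))
        return

    rec(0, 0, 0, 0.0)
    return best[0]
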