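"""Independent reference implementations used only as test oracles.

These deliberately share no code path with the package: plain-Python
dynamic programming, quadratic string scans and direct enumeration.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def full_nw_affine(q: str, t: str, score_fn, gap_open: int, gap_extend: int) -> float:
    """Unbanded global Needleman-Wunsch with affine gaps.

    A gap of length g costs ``gap_open + g * gap_extend``.
    """
    m, n = len(q), len(t)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for i in range(1, m + 1):
        Ix[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, n + 1):
        Iy[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = score_fn(q[i - 1], t[j - 1])
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] - gap_open - gap_extend, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open - gap_extend, Iy[i][j - 1] - gap_extend)
    return max(M[m][n], Ix[m][n], Iy[m][n])


def brute_suffix_array(text: str) -> list[int]:
    return sorted(range(len(text)), key=lambda i: text[i:])


def brute_lcp(text: str, sa: list[int]) -> list[int]:
    out = [0] * len(sa)
    for r in range(1, len(sa)):
        a, b = text[sa[r - 1]:], text[sa[r]:]
        h = 0
        while h < len(a) and h < len(b) and a[h] == b[h]:
            h += 1
        out[r] = h
    return out


def mes_overlaps(source: str, others: dict, min_overlap: int, direction: str = "right") -> set:
    """Direct enumeration of maximal extension overlaps.

    ``others`` maps id -> sequence (source excluded).  Returns the set of
    (id, overlap) surviving removal of candidates whose extension is a
    substring of a strictly longer extension.
    """
    if direction == "left":
        source = source[::-1]
        others = {k: v[::-1] for k, v in others.items()}
    cands = {}
    for oid, t in others.items():
        for L in range(min(len(source), len(t) - 1), min_overlap - 1, -1):
            if source[len(source) - L:] == t[:L]:
                cands[oid] = (L, t[L:])
                break
    out = set()
    for oid, (L, ext) in cands.items():
        if not any(len(oext) > len(ext) and ext in oext
                   for o2, (L2, oext) in cands.items() if o2 != oid):
            out.add((oid, L))
    return out


def postmap_placements(read: str, contig: str, min_fraction: float = 0.6, max_subs: int = 3):
    """All qualifying ungapped placements of a read on a contig."""
    hits = []
    for off in range(-(len(read) - 1), len(contig)):
        aligned = 0
        subs = 0
        for i, ch in enumerate(read):
            p = off + i
            if 0 <= p < len(contig):
                aligned += 1
                if contig[p] != ch:
                    subs += 1
        if aligned > 0 and aligned >= min_fraction * len(read) - 1e-9 and subs <= max_subs:
            hits.append((off, aligned, subs))
    return hits


def trapezoid_auc(points) -> float:
    """Trapezoid integral of recall against the precision decrement."""
    r = np.array([p[0] for p in points], dtype=float)
    p = np.array([p[1] for p in points], dtype=float)
    return float(np.sum((r[1:] + r[:-1]) * (p[:-1] - p[1:])) / 2.0)


def random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=length))


def sampled_read_db(rng, n_reads: int, source_len: int = 120,
                    min_len: int = 15, max_len: int = 40):
    """Reads sampled as substrings of one random source, so overlaps occur."""
    import pepgrasp as pg

    source = random_protein(rng, source_len)
    reads = []
    for _ in range(n_reads):
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, source_len - length + 1))
        reads.append(source[start:start + length])
    return pg.PeptideDatabase(reads)
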