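"""Recalibration (greedy contig re-merging) and post-mapping of reads.

Local assembly caps each seed extension at a fixed link depth, so one
long homologous region usually surfaces as several overlapping contig
pieces.  :func:`recalibrate` greedily re-merges pieces by descending
exact suffix/prefix overlap (diagonal-compatible only), re-scores the
merged contigs and applies the E-value cutoff.  :func:`post_map` then
recruits every database read whose best ungapped placement on a final
contig aligns at least 60 % of the read with at most 3 substitutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .search import Contig, _score_state
from .seqcore import ScoringMatrix, ScoringStatistics

__all__ = [
    "ContigSet",
    "ReadAssignment",
    "recalibrate",
    "post_map",
    "collect_homologs",
]


@dataclass
class ContigSet:
    """Final contigs for one query."""

    query_id: str
    contigs: list
    db_fingerprint: str = ""


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    contig_id: str
    offset: int  # placement of read start on the contig (may be negative)
    aligned_fraction: float
    substitutions: int


def _max_merge_overlap(a: Contig, b: Contig, min_overlap: int, band: int):
    """Longest exact suffix(a)/prefix(b) overlap with compatible diagonals.

    Only overlaps whose implied placement of ``b`` lies within ``band``
    of ``b``'s own diagonal can qualify, which bounds the search window.
    """
    limit = min(len(a.sequence), len(b.sequence))
    # |a.diag + len(a) - ov - b.diag| <= band  =>  ov in [target-band, target+band]
    target = a.diag + len(a.sequence) - b.diag
    hi = min(limit, target + band)
    lo = max(min_overlap, target - band)
    for ov in range(hi, lo - 1, -1):
        if a.sequence[-1] == b.sequence[ov - 1] and a.sequence[-ov:] == b.sequence[:ov]:
            return ov
    return 0


def _merge(a: Contig, b: Contig, overlap: int) -> Contig:
    shift = len(a.sequence) - overlap
    seq = a.sequence + b.sequence[overlap:]
    chain = list(a.chain) + [replace(s, offset=s.offset + shift) for s in b.chain]
    chain = sorted(set(chain), key=lambda s: (s.offset, s.read_id))
    return Contig(sequence=seq, chain=tuple(chain), diag=a.diag, seed=a.seed)


def _drop_contained(contigs: list, band: int) -> list:
    """Remove contigs whose sequence sits inside another at a compatible diagonal."""
    keep = []
    for i, c in enumerate(contigs):
        contained = False
        for j, other in enumerate(contigs):
            if i == j:
                continue
            if other.sequence == c.sequence and other.diag == c.diag:
                if j < i:  # exact duplicate: keep first occurrence
                    contained = True
                    break
                continue
            if len(other.sequence) <= len(c.sequence):
                continue
            pos = other.sequence.find(c.sequence)
            while pos != -1:
                if abs(other.diag + pos - c.diag) <= band:
                    contained = True
                    break
                pos = other.sequence.find(c.sequence, pos + 1)
            if contained:
                break
        if not contained:
            keep.append(c)
    return keep


def _contained_in(c: Contig, other: Contig, band: int) -> bool:
    if other.sequence == c.sequence and other.diag == c.diag:
        return False  # handled separately as an exact duplicate
    if len(other.sequence) <= len(c.sequence):
        return False
    pos = other.sequence.find(c.sequence)
    while pos != -1:
        if abs(other.diag + pos - c.diag) <= band:
            return True
        pos = other.sequence.find(c.sequence, pos + 1)
    return False


def _merge_to_fixpoint(contigs: list, min_overlap: int, band: int) -> list:
    """Greedy merging by descending overlap with cached pairwise overlaps."""
    items: dict[int, Contig] = {}
    seen_keys = set()
    for c in _drop_contained(list(contigs), band):
        key = (c.sequence, c.diag)
        if key not in seen_keys:
            seen_keys.add(key)
            items[len(items)] = c

    ov_cache: dict[tuple, int] = {}

    def pair_ov(i: int, j: int) -> int:
        key = (i, j)
        if key not in ov_cache:
            ov_cache[key] = _max_merge_overlap(items[i], items[j], min_overlap, band)
        return ov_cache[key]

    next_id = len(items)
    while True:
        best = None  # (overlap, i, j) with i, j ascending for determinism
        for i in sorted(items):
            for j in sorted(items):
                if i != j:
                    ov = pair_ov(i, j)
                    if ov and (best is None or ov > best[0]):
                        best = (ov, i, j)
        if best is None:
            break
        ov, i, j = best
        merged = _merge(items[i], items[j], ov)
        for k in (i, j):
            del items[k]
            for other in list(ov_cache):
                if k in other:
                    del ov_cache[other]
        # drop pieces absorbed by the merged contig (and stale duplicates)
        for k in sorted(items):
            c = items[k]
            if (c.sequence, c.diag) == (merged.sequence, merged.diag) or _contained_in(c, merged, band):
                del items[k]
                for other in list(ov_cache):
                    if k in other:
                        del ov_cache[other]
        if not any(_contained_in(merged, c, band) for c in items.values()):
            items[next_id] = merged
            next_id += 1
    return [items[k] for k in sorted(items)]


def recalibrate(
    contigs: list,
    query: str,
    matrix: ScoringMatrix,
    stats: ScoringStatistics,
    min_merge_overlap: int = 10,
    band: int = 40,
    evalue_cutoff: float | None = None,
    merge: bool = True,
) -> list:
    """Greedy overlap merging to fixpoint, then fresh scores and E-values.

    Pairs are merged in order of descending exact overlap length; a merge
    additionally requires the two pieces to sit on compatible diagonals
    (within ``band``), preventing chimeras between distinct hit regions.
    With ``merge=False`` (the direct-alignment special case, used when
    ``max_depth == 0``) only re-scoring and filtering are performed.
    """
    work = list(contigs)
    if merge:
        work = _merge_to_fixpoint(work, min_merge_overlap, band)

    out = []
    for c in work:
        raw, bits, interval = _score_state(c.sequence, c.diag, query, matrix, stats, band)
        c = replace(c, raw_score=raw, bits=bits, evalue=stats.e_value(bits), query_interval=interval)
        if evalue_cutoff is not None and c.evalue > evalue_cutoff:
            continue
        out.append(c)
    out.sort(key=lambda c: (-c.bits, c.sequence, c.diag))
    return out


_PAD = 255  # sentinel code outside the contig


def _encode_plain(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _best_placement(read_arr: np.ndarray, contig_arr: np.ndarray, min_fraction: float, max_substitutions: int):
    """Best qualifying ungapped placement of a read on a contig, or None.

    All start offsets from ``-(len(read)-1)`` to ``len(contig)-1`` are
    evaluated at once via a padded sliding window; positions hanging off
    the contig count as unaligned.
    """
    lr = len(read_arr)
    padded = np.concatenate([
        np.full(lr - 1, _PAD, np.uint8), contig_arr, np.full(lr - 1, _PAD, np.uint8)])
    windows = sliding_window_view(padded, lr)  # row r = offset r - (lr - 1)
    inside = windows != _PAD
    aligned = inside.sum(axis=1)
    mismatches = ((windows != read_arr[None, :]) & inside).sum(axis=1)
    # aligned / lr >= min_fraction, in exact integer arithmetic
    ok = (aligned >= min_fraction * lr - 1e-9) & (mismatches <= max_substitutions) & (aligned > 0)
    if not ok.any():
        return None
    idx = np.flatnonzero(ok)
    order = sorted(idx, key=lambda r: (-int(aligned[r]), int(mismatches[r]), r))
    r = order[0]
    return int(r) - (lr - 1), int(aligned[r]), int(mismatches[r])


_MIN_ANCHOR_K = 4


def _anchor_k(read_len: int, min_fraction: float, max_subs: int) -> int:
    """Shortest exact run every qualifying placement must contain.

    A qualifying placement aligns a contiguous block of at least
    ``ceil(min_fraction * L)`` residues with at most ``max_subs``
    mismatches, so by pigeonhole it contains an exact match of length
    ``ceil((aligned_min - max_subs) / (max_subs + 1))``.
    """
    a_min = math.ceil(min_fraction * read_len - 1e-9)
    return max(1, math.ceil((a_min - max_subs) / (max_subs + 1)))


def _verify_offset(read_arr: np.ndarray, contig_arr: np.ndarray, off: int):
    lr = read_arr.shape[0]
    s = max(0, -off)
    e = min(lr, contig_arr.shape[0] - off)
    aligned = e - s
    if aligned <= 0:
        return None
    mism = int(np.count_nonzero(read_arr[s:e] != contig_arr[off + s:off + e]))
    return aligned, mism


def post_map(
    db,
    contigs: ContigSet,
    min_fraction: float = 0.6,
    max_substitutions: int = 3,
) -> list[ReadAssignment]:
    """Ungapped recruitment of all database reads onto the final contigs.

    A read is assigned to a contig iff some gap-free placement aligns at
    least ``min_fraction`` of the read's residues within the contig with
    at most ``max_substitutions`` mismatches; every qualifying
    (read, contig) pair is reported with its best placement (most
    aligned residues, then fewest substitutions, then smallest offset).

    Long enough reads are located through shared exact k-mers (an exact
    prefilter: every qualifying placement must contain such an anchor);
    short reads fall back to a full sliding scan.
    """
    contig_items = []
    for ci, contig in enumerate(contigs.contigs):
        contig_items.append((f"{contigs.query_id}_contig_{ci}", contig.sequence,
                             _encode_plain(contig.sequence)))

    anchor_of = {L: _anchor_k(L, min_fraction, max_substitutions) for L in {len(s) for s in db.reads}}
    needed_ks = sorted({k for k in anchor_of.values() if k >= _MIN_ANCHOR_K})
    kmer_map: dict[int, dict] = {k: {} for k in needed_ks}
    for ci, (_, cseq, _) in enumerate(contig_items):
        for k in needed_ks:
            table = kmer_map[k]
            for pos in range(len(cseq) - k + 1):
                table.setdefault(cseq[pos:pos + k], []).append((ci, pos))

    assignments = []
    for rid, seq in zip(db.read_ids, db.reads):
        read_arr = _encode_plain(seq)
        lr = len(seq)
        k = anchor_of[lr]
        best_per_contig: dict[int, tuple] = {}
        if k >= _MIN_ANCHOR_K:
            table = kmer_map[k]
            candidates: dict[int, set] = {}
            for p in range(lr - k + 1):
                for ci, cpos in table.get(seq[p:p + k], ()):
                    candidates.setdefault(ci, set()).add(cpos - p)
            for ci, offsets in candidates.items():
                carr = contig_items[ci][2]
                for off in sorted(offsets):
                    r = _verify_offset(read_arr, carr, off)
                    if r is None:
                        continue
                    aligned, mism = r
                    if aligned >= min_fraction * lr - 1e-9 and mism <= max_substitutions:
                        cand = (-aligned, mism, off)
                        if ci not in best_per_contig or cand < best_per_contig[ci]:
                            best_per_contig[ci] = cand
        else:
            for ci, (_, _, carr) in enumerate(contig_items):
                hit = _best_placement(read_arr, carr, min_fraction, max_substitutions)
                if hit is not None:
                    off, aligned, mism = hit
                    best_per_contig[ci] = (-aligned, mism, off)
        for ci in sorted(best_per_contig):
            neg_aligned, mism, off = best_per_contig[ci]
            assignments.append(ReadAssignment(
                read_id=rid, contig_id=contig_items[ci][0], offset=off,
                aligned_fraction=-neg_aligned / lr, substitutions=mism))
    return assignments


def collect_homologs(assignments: list) -> set:
    """Union of assigned read ids: the homolog read set of the query."""
    return {a.read_id for a in assignments}
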