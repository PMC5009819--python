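"""Simultaneous alignment and assembly: seeding plus link-guided extension.

For each query, exact reduced-alphabet k-mer matches passing a
full-alphabet score filter become seeds; each seed read is grown right
then left by following pre-built extension links, re-scoring the grown
contig against the query window with a banded affine-gap DP after every
link traversal, pruning paths that fall a fixed number of bits below the
best score seen on that path, and capping the link depth per direction.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, replace

import numpy as np

from .index import IndexBundle, SeedIndex
from .seqcore import (
    ReducedAlphabet,
    ScoringMatrix,
    ScoringStatistics,
    blosum62,
    gbmr10,
    reduce_sequence,
)

__all__ = [
    "SearchParams",
    "SeedPair",
    "ChainStep",
    "Contig",
    "FingerprintMismatchError",
    "find_seeds",
    "banded_align",
    "extend_seed",
    "search_query",
    "search_queries",
]

_NEG = -(1 << 30)


class FingerprintMismatchError(RuntimeError):
    """Search parameters incompatible with the index they are used against."""


@dataclass
class SearchParams:
    """Tunables of the search stage; defaults follow the shipped configuration."""

    k: int = 6
    seed_score_factor: float = 0.7
    band: int = 40
    dropoff_bits: float = 25.0
    max_depth: int = 20
    evalue_cutoff: float = 10.0
    min_merge_overlap: int = 10

    def __post_init__(self):
        if self.k < 1 or self.band < 1 or self.seed_score_factor <= 0:
            raise ValueError("k, band and seed_score_factor must be positive")
        if self.dropoff_bits <= 0 or self.max_depth < 0:
            raise ValueError("dropoff_bits must be positive and max_depth >= 0")

    def min_seed_score(self, matrix: ScoringMatrix) -> float:
        """Seed acceptance threshold ``k * factor * a`` for the matrix in use."""
        return self.k * self.seed_score_factor * matrix.mean_diagonal


@dataclass(frozen=True)
class SeedPair:
    """A reduced-alphabet exact k-mer match plus its full-alphabet score."""

    query_pos: int
    read_id: str
    read_pos: int
    raw_score: int

    @property
    def diagonal(self) -> int:
        return self.query_pos - self.read_pos


@dataclass(frozen=True)
class ChainStep:
    read_id: str
    offset: int  # start of the read within the contig
    overlap: int  # overlap with the neighbour it was joined through


@dataclass
class Contig:
    """An assembled peptide with its read chain and alignment statistics."""

    sequence: str
    chain: tuple
    diag: int  # query position of contig coordinate 0 (may be negative)
    raw_score: int = 0
    bits: float = 0.0
    evalue: float = float("inf")
    query_interval: tuple = (0, 0)
    seed: SeedPair | None = None

    def spelled_by_chain(self, db) -> bool:
        """Every chain read must appear verbatim at its recorded offset."""
        for step in self.chain:
            seq = db.sequence(step.read_id)
            if self.sequence[step.offset:step.offset + len(seq)] != seq:
                return False
        covered = 0
        for step in sorted(self.chain, key=lambda s: s.offset):
            if step.offset > covered:
                return False
            covered = max(covered, step.offset + len(db.sequence(step.read_id)))
        return covered == len(self.sequence)


def find_seeds(
    query: str,
    seed_index: SeedIndex,
    matrix: ScoringMatrix,
    params: SearchParams,
    alphabet: ReducedAlphabet | None = None,
    db=None,
) -> list[SeedPair]:
    """All reduced-k-mer matches whose full-alphabet score passes threshold."""
    k = params.k
    if len(query) < k:
        return []
    alphabet = alphabet or gbmr10()
    if seed_index.k != k or seed_index.alphabet_name != alphabet.name:
        raise FingerprintMismatchError(
            f"seed index built with k={seed_index.k}/{seed_index.alphabet_name}, "
            f"search wants k={k}/{alphabet.name}")
    threshold = params.min_seed_score(matrix)
    reduced = reduce_sequence(query, alphabet)
    wc = alphabet.wildcard_letter
    out = []
    for qpos in range(len(query) - k + 1):
        kmer = reduced[qpos:qpos + k]
        if wc in kmer:
            continue
        occs = seed_index.lookup(kmer)
        if not occs:
            continue
        qk = query[qpos:qpos + k]
        for rid, rpos in occs:
            rk = db.sequence(rid)[rpos:rpos + k] if db is not None else None
            if rk is None:
                raise ValueError("find_seeds requires the database for rescoring")
            score = matrix.pair_score(qk, rk)
            if score >= threshold:
                out.append(SeedPair(query_pos=qpos, read_id=rid, read_pos=rpos, raw_score=score))
    out.sort(key=lambda s: (s.query_pos, s.read_id, s.read_pos))
    return out


# ---------------------------------------------------------------------------
# banded global alignment with affine gaps
# ---------------------------------------------------------------------------

def _banded_kernel(q, t, smat, band, gopen, gext):
    m = q.shape[0]
    n = t.shape[0]
    b = band
    d = m - n if m > n else n - m
    if b < d:
        b = d
    M = np.full(n + 1, _NEG, np.int64)
    Ix = np.full(n + 1, _NEG, np.int64)  # gap in target (consumes query)
    Iy = np.full(n + 1, _NEG, np.int64)  # gap in query (consumes target)
    nM = np.full(n + 1, _NEG, np.int64)
    nIx = np.full(n + 1, _NEG, np.int64)
    nIy = np.full(n + 1, _NEG, np.int64)
    M[0] = 0
    hi0 = n if n < b else b
    for j in range(1, hi0 + 1):
        Iy[j] = -(gopen + gext * j)
    for i in range(1, m + 1):
        lo = i - b if i - b > 1 else 1
        hi = i + b if i + b < n else n
        # reset only the window the next row can read
        r0 = lo - 1 if lo > 1 else 0
        r1 = hi + 1 if hi < n else n
        for j in range(r0, r1 + 1):
            nM[j] = _NEG
            nIx[j] = _NEG
            nIy[j] = _NEG
        if i <= b:
            nIx[0] = -(gopen + gext * i)
        qi = q[i - 1]
        for j in range(lo, hi + 1):
            diag = M[j - 1]
            if Ix[j - 1] > diag:
                diag = Ix[j - 1]
            if Iy[j - 1] > diag:
                diag = Iy[j - 1]
            if diag > _NEG:
                nM[j] = diag + smat[qi, t[j - 1]]
            a = M[j] - (gopen + gext)
            c = Ix[j] - gext
            nIx[j] = a if a > c else c
            a = nM[j - 1] - (gopen + gext)
            c = nIy[j - 1] - gext
            nIy[j] = a if a > c else c
        M, nM = nM, M
        Ix, nIx = nIx, Ix
        Iy, nIy = nIy, Iy
    best = M[n]
    if Ix[n] > best:
        best = Ix[n]
    if Iy[n] > best:
        best = Iy[n]
    return best


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _banded_kernel_fast = njit(cache=True, nogil=True)(_banded_kernel)
except Exception:  # pragma: no cover
    _banded_kernel_fast = _banded_kernel


def banded_align(query_segment: str, target: str, matrix: ScoringMatrix, band: int) -> int:
    """Optimal global alignment score restricted to the diagonal band.

    Cells ``(i, j)`` with ``|i - j| <= b`` participate, where ``b`` is
    the band widened to ``|len(q) - len(t)|`` when needed so the global
    end cell stays reachable.  With ``band >= max(len(q), len(t))`` the
    result equals unbanded Needleman-Wunsch with affine gaps.
    """
    if band < 1:
        raise ValueError("band must be >= 1")
    m, n = len(query_segment), len(target)
    go, ge = matrix.gap_open, matrix.gap_extend
    if m == 0 and n == 0:
        return 0
    if m == 0:
        return -(go + ge * n)
    if n == 0:
        return -(go + ge * m)
    q = matrix.encode(query_segment)
    t = matrix.encode(target)
    return int(_banded_kernel_fast(q, t, matrix.array.astype(np.int64), band, go, ge))


# ---------------------------------------------------------------------------
# seed extension
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _State:
    sequence: str
    chain: tuple
    diag: int
    raw: int
    bits: float


def _score_state(sequence: str, diag: int, query: str, matrix, stats, band: int):
    qs = max(0, min(diag, len(query)))
    qe = max(0, min(diag + len(sequence), len(query)))
    if qe <= qs:
        raw = -(matrix.gap_open + matrix.gap_extend * len(sequence))
    else:
        raw = banded_align(query[qs:qe], sequence, matrix, band)
    return raw, stats.bit_score(raw), (qs, qe)


def _grow_right(state: _State, sink_seq: str, sink_id: str, overlap: int) -> tuple[str, tuple, int]:
    seq = state.sequence + sink_seq[overlap:]
    chain = state.chain + (ChainStep(sink_id, len(state.sequence) - overlap, overlap),)
    return seq, chain, state.diag


def _grow_left(state: _State, sink_seq: str, sink_id: str, overlap: int) -> tuple[str, tuple, int]:
    ext = sink_seq[:len(sink_seq) - overlap]
    seq = ext + state.sequence
    shifted = tuple(replace(s, offset=s.offset + len(ext)) for s in state.chain)
    chain = (ChainStep(sink_id, 0, overlap),) + shifted
    return seq, chain, state.diag - len(ext)


def _extend_direction(start: _State, direction: str, links, db, query, matrix, stats, params) -> list[_State]:
    """Depth-first traversal of one direction's link tree with X-drop pruning.

    A branch is cut when its bit score falls more than ``dropoff_bits``
    below the best score seen on its own path; every path surviving to
    termination (no links, all children pruned, or the depth cap)
    contributes its terminal state.
    """
    results: dict[tuple, _State] = {}
    stack = [(start, 0, start.bits)]
    while stack:
        state, depth, best_bits = stack.pop()
        children = []
        if depth < params.max_depth:
            edge = state.chain[-1].read_id if direction == "right" else state.chain[0].read_id
            for sid, ov in links.sinks(edge):
                sink_seq = db.sequence(sid)
                if direction == "right":
                    seq, chain, diag = _grow_right(state, sink_seq, sid, ov)
                else:
                    seq, chain, diag = _grow_left(state, sink_seq, sid, ov)
                raw, bits, _ = _score_state(seq, diag, query, matrix, stats, params.band)
                if best_bits - bits > params.dropoff_bits:
                    continue
                children.append(_State(seq, chain, diag, raw, bits))
        if children:
            for child in children:
                stack.append((child, depth + 1, max(best_bits, child.bits)))
        else:
            key = (state.sequence, state.diag)
            prev = results.get(key)
            if prev is None or state.bits > prev.bits:
                results[key] = state
    return [results[k] for k in sorted(results)]


def extend_seed(
    seed: SeedPair,
    query: str,
    db,
    links_right,
    links_left,
    matrix: ScoringMatrix,
    stats: ScoringStatistics,
    params: SearchParams,
) -> list[Contig]:
    """Grow the seed read right then left along extension links."""
    read_seq = db.sequence(seed.read_id)
    diag = seed.query_pos - seed.read_pos
    raw, bits, _ = _score_state(read_seq, diag, query, matrix, stats, params.band)
    start = _State(read_seq, (ChainStep(seed.read_id, 0, 0),), diag, raw, bits)

    out: dict[tuple, Contig] = {}
    for right_state in _extend_direction(start, "right", links_right, db, query, matrix, stats, params):
        for final in _extend_direction(right_state, "left", links_left, db, query, matrix, stats, params):
            raw, bits, interval = _score_state(final.sequence, final.diag, query, matrix, stats, params.band)
            contig = Contig(
                sequence=final.sequence,
                chain=tuple(sorted(final.chain, key=lambda s: s.offset)),
                diag=final.diag,
                raw_score=raw,
                bits=bits,
                evalue=stats.e_value(bits),
                query_interval=interval,
                seed=seed,
            )
            key = (contig.sequence, contig.diag)
            prev = out.get(key)
            if prev is None or contig.bits > prev.bits:
                out[key] = contig
    return [out[k] for k in sorted(out)]


def _check_compatible(bundle: IndexBundle, params: SearchParams, alphabet: ReducedAlphabet):
    if bundle.params.get("k") != params.k or bundle.params.get("alphabet") != alphabet.name:
        raise FingerprintMismatchError(
            f"index parameters {bundle.params} incompatible with search (k={params.k}, "
            f"alphabet={alphabet.name})")


def search_query(
    query: str,
    bundle: IndexBundle,
    params: SearchParams | None = None,
    matrix: ScoringMatrix | None = None,
    alphabet: ReducedAlphabet | None = None,
    stats: ScoringStatistics | None = None,
) -> list[Contig]:
    """All pre-recalibration contigs for one query, deterministically ordered.

    A per-query visited set keyed by ``(read id, diagonal)`` suppresses
    re-derivation of contigs from seeds that fall inside an already
    assembled region on the same diagonal.
    """
    params = params or SearchParams()
    matrix = matrix or blosum62()
    alphabet = alphabet or gbmr10()
    _check_compatible(bundle, params, alphabet)
    if stats is None:
        stats = ScoringStatistics(search_space_m=max(1, len(query)),
                                  search_space_n=max(1, bundle.db.total_residues))
    seeds = find_seeds(query, bundle.seeds, matrix, params, alphabet, db=bundle.db)
    visited: set[tuple] = set()
    collected: dict[tuple, Contig] = {}
    for seed in seeds:
        if (seed.read_id, seed.diagonal) in visited:
            continue
        contigs = extend_seed(seed, query, bundle.db, bundle.links_right, bundle.links_left,
                              matrix, stats, params)
        for contig in contigs:
            for step in contig.chain:
                visited.add((step.read_id, contig.diag + step.offset))
            if len(contig.sequence) < params.k:
                continue
            key = (contig.sequence, contig.diag)
            prev = collected.get(key)
            if prev is None or contig.bits > prev.bits:
                collected[key] = contig
    result = list(collected.values())
    result.sort(key=lambda c: (-c.bits, c.sequence, c.diag))
    return result


def search_queries(queries, bundle, params=None, matrix=None, alphabet=None, workers: int = 1) -> dict:
    """Search many queries; results are keyed by query id and independent
    of the worker count (query-level parallelism only)."""
    items = list(queries.items() if isinstance(queries, dict) else queries)
    params = params or SearchParams()
    matrix = matrix or blosum62()
    alphabet = alphabet or gbmr10()

    def one(item):
        qid, seq = item
        return qid, search_query(seq, bundle, params, matrix, alphabet)

    if workers <= 1:
        pairs = [one(it) for it in items]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            pairs = list(pool.map(one, items))
    return dict(pairs)
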