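"""Database indexing: suffix/LCP arrays, extension links and the seed index.

The searchable form of a peptide read database consists of

* a suffix array + LCP array over the sentinel-separated concatenation,
* two :class:`ExtensionLinkTable` instances (right and left) recording,
  for every read, which other reads extend it through an exact
  suffix/prefix overlap and survive maximal-extension filtering,
* a reduced-alphabet k-mer :class:`SeedIndex`.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqcore import AA20, WILDCARD, ReducedAlphabet, gbmr10, reduce_sequence

__all__ = [
    "SENTINEL",
    "EmptyDatabaseError",
    "IndexFormatError",
    "Provenance",
    "PeptideDatabase",
    "SuffixIndex",
    "ExtensionLinkTable",
    "SeedIndex",
    "IndexBundle",
    "build_suffix_index",
    "build_extension_links",
    "brute_force_mes",
    "build_seed_index",
    "build_index",
    "save_index",
    "load_index",
]

#: Separator between reads in the concatenated text; lexicographically
#: below every residue letter and never matched by any operation.
SENTINEL = "$"

INDEX_FORMAT_VERSION = 2

_VALID_RESIDUES = frozenset(AA20 + WILDCARD)


class EmptyDatabaseError(ValueError):
    pass


class IndexFormatError(RuntimeError):
    """Version mismatch or corrupt index artifact."""


@dataclass(frozen=True)
class Provenance:
    """Where a (simulated) read came from: source id plus interval."""

    source_id: str
    start: int
    end: int
    sampled_fraction: float = 1.0


class PeptideDatabase:
    """The read set: ordered peptide strings with stable identifiers."""

    def __init__(self, reads, read_ids=None, provenance=None):
        reads = list(reads)
        if read_ids is None:
            read_ids = [f"read_{i}" for i in range(len(reads))]
        read_ids = list(read_ids)
        if len(read_ids) != len(reads):
            raise ValueError("read_ids length must match reads")
        if len(set(read_ids)) != len(read_ids):
            raise ValueError("read ids must be unique")
        for rid, seq in zip(read_ids, reads):
            if len(seq) < 1:
                raise ValueError(f"read {rid} is empty")
            bad = set(seq) - _VALID_RESIDUES
            if bad:
                raise ValueError(f"read {rid} contains unsupported residues {sorted(bad)}")
        self.reads = reads
        self.read_ids = read_ids
        self.provenance = dict(provenance or {})
        self._id_to_pos = {rid: i for i, rid in enumerate(read_ids)}
        offsets = []
        pos = 0
        for seq in reads:
            offsets.append(pos)
            pos += len(seq) + 1  # trailing sentinel
        self.offsets = offsets
        self.text = SENTINEL.join(reads) + SENTINEL if reads else ""

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def total_residues(self) -> int:
        return sum(len(r) for r in self.reads)

    def sequence(self, read_id: str) -> str:
        return self.reads[self._id_to_pos[read_id]]

    def read_at_text_pos(self, pos: int) -> tuple[str, int]:
        """Return (read_id, offset within read) for a concatenated-text position."""
        idx = int(np.searchsorted(np.asarray(self.offsets), pos, side="right")) - 1
        off = pos - self.offsets[idx]
        if off >= len(self.reads[idx]):
            raise ValueError(f"text position {pos} falls on a sentinel")
        return self.read_ids[idx], off

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for rid, seq in zip(self.read_ids, self.reads):
            h.update(rid.encode())
            h.update(b"\x00")
            h.update(seq.encode())
            h.update(b"\x01")
        return h.hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "read_ids": self.read_ids,
            "reads": self.reads,
            "provenance": {
                rid: [p.source_id, p.start, p.end, p.sampled_fraction]
                for rid, p in sorted(self.provenance.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PeptideDatabase":
        prov = {rid: Provenance(v[0], int(v[1]), int(v[2]), float(v[3])) for rid, v in d.get("provenance", {}).items()}
        return cls(d["reads"], d["read_ids"], prov)


@dataclass
class SuffixIndex:
    """Suffix array and LCP array over the concatenated sentinel text."""

    suffix_array: np.ndarray
    lcp_array: np.ndarray
    text_length: int


def _suffix_array_doubling(codes: np.ndarray) -> np.ndarray:
    """Prefix-doubling suffix array (O(n log^2 n), numpy-vectorized)."""
    n = len(codes)
    rank = np.searchsorted(np.unique(codes), codes).astype(np.int64)
    k = 1
    sa = np.argsort(rank, kind="stable")
    tmp = np.empty(n, dtype=np.int64)
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        tmp[sa[0]] = 0
        prev = sa[:-1]
        cur = sa[1:]
        newer = (rank[cur] != rank[prev]) | (key2[cur] != key2[prev])
        tmp[cur] = np.cumsum(newer)
        rank, tmp = tmp.copy(), rank
        if rank[sa[-1]] == n - 1:
            break
        k *= 2
    return sa.astype(np.int64)


def _kasai_lcp(text: str, sa: np.ndarray) -> np.ndarray:
    n = len(text)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = int(sa[r - 1])
            while i + h < n and j + h < n and text[i + h] == text[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def build_suffix_index(db: PeptideDatabase) -> SuffixIndex:
    """Build the suffix array and LCP array of ``db``'s concatenated text."""
    if len(db) == 0:
        raise EmptyDatabaseError("cannot index an empty database")
    codes = np.frombuffer(db.text.encode("ascii"), dtype=np.uint8)
    sa = _suffix_array_doubling(codes)
    lcp = _kasai_lcp(db.text, sa)
    return SuffixIndex(suffix_array=sa, lcp_array=lcp, text_length=len(db.text))


@dataclass
class ExtensionLinkTable:
    """Directed source -> sink overlap links, fan-out capped per source.

    ``links[source_id]`` is an ordered list of ``(sink_id, overlap)``;
    for the ``right`` direction the last ``overlap`` residues of the
    source equal the first ``overlap`` residues of the sink (mirrored for
    ``left``).  Each retained sink is a maximal extension of its source.
    """

    direction: str
    links: dict = field(default_factory=dict)
    min_overlap: int = 10
    max_links: int = 20
    ops: int = 0  # traversal operation counter, for scaling checks

    def sinks(self, source_id: str):
        return self.links.get(source_id, [])

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "min_overlap": self.min_overlap,
            "max_links": self.max_links,
            "links": {src: [[sid, ov] for sid, ov in lst] for src, lst in sorted(self.links.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExtensionLinkTable":
        return cls(
            direction=d["direction"],
            min_overlap=int(d["min_overlap"]),
            max_links=int(d["max_links"]),
            links={src: [(sid, int(ov)) for sid, ov in lst] for src, lst in d["links"].items()},
        )


def _link_eligible_ids(db: PeptideDatabase, min_overlap: int) -> list[str]:
    """Reads taking part in link construction.

    Policy: drop reads shorter than ``min_overlap``, collapse exact
    duplicate sequences onto the first id, and drop reads fully
    contained in another (longer) read; post-mapping recovers them.
    """
    seen_seq: dict[str, str] = {}
    candidates = []
    for rid, seq in zip(db.read_ids, db.reads):
        if len(seq) < min_overlap:
            continue
        if seq in seen_seq:
            continue
        seen_seq[seq] = rid
        candidates.append((rid, seq))
    out = []
    for rid, seq in candidates:
        contained = any(seq in other and len(other) > len(seq) for orid, other in candidates if orid != rid)
        if not contained:
            out.append(rid)
    return out


def _mes_filter(cands: dict[str, tuple[int, str]]) -> list[tuple[str, int]]:
    """Drop candidates whose extension is a substring of a strictly longer one.

    ``cands`` maps sink id -> (overlap, extension string).  Equal-length
    extensions are all retained (mutual containment would otherwise
    delete valid paths).
    """
    kept = []
    items = list(cands.items())
    for sid, (ov, ext) in items:
        dominated = any(
            len(oext) > len(ext) and ext in oext for osid, (oov, oext) in items if osid != sid
        )
        if not dominated:
            kept.append((sid, ov))
    return kept


def _truncate_fanout(pairs: list[tuple[str, int]], max_links: int | None) -> list[tuple[str, int]]:
    pairs = sorted(pairs, key=lambda p: (-p[1], p[0]))
    if max_links is not None:
        pairs = pairs[:max_links]
    return pairs


def build_extension_links(
    db: PeptideDatabase,
    index: SuffixIndex | None = None,
    min_overlap: int = 10,
    max_links: int | None = 20,
    direction: str = "right",
) -> ExtensionLinkTable:
    """Compute the capped maximal-extension link table for one direction.

    The left direction is derived by running the right-direction
    construction on residue-reversed reads.  ``index`` is accepted for
    interface symmetry; construction uses a hash join over read
    prefixes, which is linear in total residues for bounded read length.
    """
    if len(db) == 0:
        raise EmptyDatabaseError("cannot build links on an empty database")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if direction not in ("right", "left"):
        raise ValueError("direction must be 'right' or 'left'")

    eligible = _link_eligible_ids(db, min_overlap)
    seqs = {rid: db.sequence(rid) for rid in eligible}
    if direction == "left":
        seqs = {rid: s[::-1] for rid, s in seqs.items()}

    table = ExtensionLinkTable(direction=direction, min_overlap=min_overlap,
                               max_links=max_links if max_links is not None else 0)
    if max_links is None:
        table.max_links = -1  # sentinel for "unlimited"

    # prefix -> sink ids, for every prefix length in [min_overlap, len-1]
    prefix_map: dict[str, list[str]] = {}
    ops = 0
    for rid in eligible:
        s = seqs[rid]
        for L in range(min_overlap, len(s)):
            prefix_map.setdefault(s[:L], []).append(rid)
            ops += 1

    for rid in eligible:
        s = seqs[rid]
        cands: dict[str, tuple[int, str]] = {}
        for L in range(min_overlap, len(s) + 1):
            suffix = s[-L:]
            for sid in prefix_map.get(suffix, ()):
                ops += 1
                if sid == rid:
                    continue
                # keep the maximal overlap per (source, sink) pair
                cands[sid] = (L, seqs[sid][L:])
        if not cands:
            continue
        kept = _mes_filter(cands)
        kept = _truncate_fanout(kept, max_links)
        if kept:
            table.links[rid] = kept
    table.ops = ops
    return table


def brute_force_mes(
    source_id: str,
    db: PeptideDatabase,
    min_overlap: int = 10,
    direction: str = "right",
) -> set[tuple[str, int]]:
    """Independent direct-comparison oracle for the maximal-extension set.

    Enumerates all suffix/prefix overlaps >= ``min_overlap`` by direct
    string comparison, then discards any sink whose extension sequence is
    contained in a strictly longer extension of another sink.  Shares
    only the read-eligibility policy with :func:`build_extension_links`.
    """
    eligible = _link_eligible_ids(db, min_overlap)
    if source_id not in eligible:
        return set()
    src = db.sequence(source_id)
    if direction == "left":
        src = src[::-1]
    cands: dict[str, tuple[int, str]] = {}
    for sid in eligible:
        if sid == source_id:
            continue
        t = db.sequence(sid)
        if direction == "left":
            t = t[::-1]
        for L in range(min(len(src), len(t) - 1), min_overlap - 1, -1):
            if src[len(src) - L:] == t[:L]:
                cands[sid] = (L, t[L:])
                break
    result = set()
    for sid, (ov, ext) in cands.items():
        dominated = False
        for osid, (oov, oext) in cands.items():
            if osid != sid and len(oext) > len(ext) and ext in oext:
                dominated = True
                break
        if not dominated:
            result.add((sid, ov))
    return result


@dataclass
class SeedIndex:
    """Reduced-alphabet k-mer -> list of (read id, offset) occurrences."""

    k: int
    alphabet_name: str
    table: dict = field(default_factory=dict)

    def lookup(self, reduced_kmer: str):
        return self.table.get(reduced_kmer, [])

    @property
    def n_occurrences(self) -> int:
        return sum(len(v) for v in self.table.values())

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "alphabet": self.alphabet_name,
            "table": {key: [[rid, off] for rid, off in occs] for key, occs in sorted(self.table.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SeedIndex":
        return cls(
            k=int(d["k"]),
            alphabet_name=d["alphabet"],
            table={key: [(rid, int(off)) for rid, off in occs] for key, occs in d["table"].items()},
        )


def build_seed_index(db: PeptideDatabase, alphabet: ReducedAlphabet | None = None, k: int = 6) -> SeedIndex:
    """Index every k-length window of every read by its reduced k-mer.

    Windows containing the wildcard letter are skipped: the wildcard can
    never participate in a seed match.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    alphabet = alphabet or gbmr10()
    wc = alphabet.wildcard_letter
    idx = SeedIndex(k=k, alphabet_name=alphabet.name)
    for rid, seq in zip(db.read_ids, db.reads):
        if len(seq) < k:
            continue
        red = reduce_sequence(seq, alphabet)
        for off in range(len(seq) - k + 1):
            kmer = red[off:off + k]
            if wc in kmer:
                continue
            idx.table.setdefault(kmer, []).append((rid, off))
    return idx


@dataclass
class IndexBundle:
    """All artifacts needed by the search stage, plus a parameter fingerprint."""

    db: PeptideDatabase
    suffix: SuffixIndex
    links_right: ExtensionLinkTable
    links_left: ExtensionLinkTable
    seeds: SeedIndex
    params: dict

    def fingerprint(self) -> str:
        payload = json.dumps({"params": self.params, "db": self.db.fingerprint()}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_index(
    db: PeptideDatabase,
    alphabet: ReducedAlphabet | None = None,
    k: int = 6,
    min_overlap: int = 10,
    max_links: int = 20,
) -> IndexBundle:
    """One-shot construction of every index artifact for ``db``."""
    alphabet = alphabet or gbmr10()
    suffix = build_suffix_index(db)
    right = build_extension_links(db, suffix, min_overlap=min_overlap, max_links=max_links, direction="right")
    left = build_extension_links(db, suffix, min_overlap=min_overlap, max_links=max_links, direction="left")
    seeds = build_seed_index(db, alphabet, k=k)
    params = {
        "k": k,
        "alphabet": alphabet.name,
        "min_overlap": min_overlap,
        "max_links": max_links,
    }
    return IndexBundle(db=db, suffix=suffix, links_right=right, links_left=left, seeds=seeds, params=params)


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def save_index(bundle: IndexBundle, path) -> Path:
    """Serialize an index bundle to ``<path>/index.json`` (versioned, checksummed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    payload = {
        "format_version": INDEX_FORMAT_VERSION,
        "params": bundle.params,
        "fingerprint": bundle.fingerprint(),
        "db": bundle.db.to_dict(),
        "suffix_array": bundle.suffix.suffix_array.tolist(),
        "lcp_array": bundle.suffix.lcp_array.tolist(),
        "links_right": bundle.links_right.to_dict(),
        "links_left": bundle.links_left.to_dict(),
        "seed_index": bundle.seeds.to_dict(),
    }
    body = _canonical_json(payload)
    checksum = hashlib.sha256(body.encode()).hexdigest()
    out = path / "index.json"
    out.write_text(_canonical_json({"checksum": checksum, "payload": payload}))
    return out


def load_index(path) -> IndexBundle:
    """Load and verify an index bundle written by :func:`save_index`."""
    path = Path(path)
    f = path / "index.json" if path.is_dir() else path
    try:
        wrapper = json.loads(f.read_text())
        payload = wrapper["payload"]
        checksum = wrapper["checksum"]
    except (OSError, ValueError, KeyError) as exc:
        raise IndexFormatError(f"corrupt index file {f}: {exc}") from exc
    body = _canonical_json(payload)
    if hashlib.sha256(body.encode()).hexdigest() != checksum:
        raise IndexFormatError(f"checksum mismatch in {f}")
    if payload.get("format_version") != INDEX_FORMAT_VERSION:
        raise IndexFormatError(
            f"index format version {payload.get('format_version')} != {INDEX_FORMAT_VERSION}")
    db = PeptideDatabase.from_dict(payload["db"])
    suffix = SuffixIndex(
        suffix_array=np.asarray(payload["suffix_array"], dtype=np.int64),
        lcp_array=np.asarray(payload["lcp_array"], dtype=np.int64),
        text_length=len(db.text),
    )
    bundle = IndexBundle(
        db=db,
        suffix=suffix,
        links_right=ExtensionLinkTable.from_dict(payload["links_right"]),
        links_left=ExtensionLinkTable.from_dict(payload["links_left"]),
        seeds=SeedIndex.from_dict(payload["seed_index"]),
        params=payload["params"],
    )
    if bundle.fingerprint() != payload["fingerprint"]:
        raise IndexFormatError("fingerprint mismatch: index inconsistent with its parameters")
    return bundle
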