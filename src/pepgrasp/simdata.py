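"""Synthetic peptide read databases with exact per-read provenance.

Reads are sampled directly in peptide space: uniform start positions on
the source proteins (weighted by relative abundance), fixed expected
read length, and i.i.d. per-residue substitution errors.  Every read
records the exact source interval it came from, which downstream
evaluation uses as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .index import PeptideDatabase, Provenance
from .seqcore import AA20

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "random_protein",
    "simulate_reads",
    "truth_homolog_reads",
]


@dataclass
class SimulationConfig:
    """Sampling model: coverage, expected read length and error rate."""

    source_proteins: dict  # source id -> amino-acid string
    coverage: float = 10.0
    read_length_aa: int = 33
    error_rate: float = 0.01
    abundance_weights: dict | None = None  # source id -> positive weight
    rng_seed: int = 0
    length_jitter: bool = False  # geometric jitter around the expected length

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must lie in [0, 1)")
        if self.read_length_aa < 1:
            raise ValueError("read_length_aa must be >= 1")
        if self.abundance_weights is not None:
            for sid, w in self.abundance_weights.items():
                if not (w > 0 and math.isfinite(w)):
                    raise ValueError(f"abundance weight for {sid} must be positive and finite")


@dataclass
class GroundTruth:
    """Provenance-based truth: per-read source intervals and homolog intervals."""

    sources: dict  # source id -> length
    read_provenance: dict  # read id -> Provenance
    homolog_intervals: dict = field(default_factory=dict)  # query id -> [(source, start, end)]
    mode: str = "planted"  # how homolog intervals were defined

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "sources": dict(sorted(self.sources.items())),
            "read_provenance": {
                rid: [p.source_id, p.start, p.end, p.sampled_fraction]
                for rid, p in sorted(self.read_provenance.items())
            },
            "homolog_intervals": {
                qid: [[s, a, b] for s, a, b in ivs]
                for qid, ivs in sorted(self.homolog_intervals.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            sources={k: int(v) for k, v in d["sources"].items()},
            read_provenance={
                rid: Provenance(v[0], int(v[1]), int(v[2]), float(v[3]))
                for rid, v in d["read_provenance"].items()
            },
            homolog_intervals={
                qid: [(s, int(a), int(b)) for s, a, b in ivs]
                for qid, ivs in d["homolog_intervals"].items()
            },
            mode=d.get("mode", "planted"),
        )


def random_protein(rng: np.random.Generator, length: int) -> str:
    """A uniform random protein over the 20 standard residues."""
    return "".join(rng.choice(list(AA20), size=length))


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate == 0.0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    for i in hits:
        alternatives = [a for a in AA20 if a != out[i]]
        out[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


def simulate_reads(config: SimulationConfig) -> tuple[PeptideDatabase, GroundTruth]:
    """Sample a peptide read database and its provenance scaffold.

    The total read count is ``round(coverage * total_source_length /
    read_length)``; each read's source is drawn with probability
    proportional to ``weight * length``, its start uniform over valid
    positions.  Substitutions are applied i.i.d. per residue, uniformly
    over the 19 alternative residues.  Fully deterministic for a fixed
    ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    sids = sorted(config.source_proteins)
    lengths = {s: len(config.source_proteins[s]) for s in sids}
    weights = config.abundance_weights or {s: 1.0 for s in sids}
    missing = set(sids) - set(weights)
    if missing:
        raise ValueError(f"missing abundance weights for {sorted(missing)}")

    ell = config.read_length_aa
    total = sum(lengths[s] for s in sids)
    n_reads = int(round(config.coverage * total / ell))
    probs = np.array([weights[s] * lengths[s] for s in sids], dtype=float)
    probs /= probs.sum()

    reads, read_ids, provenance = [], [], {}
    for i in range(n_reads):
        sid = sids[int(rng.choice(len(sids), p=probs))]
        source = config.source_proteins[sid]
        length = ell
        if config.length_jitter:
            length = max(1, 1 + int(rng.geometric(1.0 / ell)) - 1)
        if length > len(source):
            length = len(source)  # short source: truncated read
        start = int(rng.integers(0, len(source) - length + 1))
        fragment = source[start:start + length]
        read = _mutate(fragment, rng, config.error_rate)
        rid = f"sim_{i}"
        reads.append(read)
        read_ids.append(rid)
        provenance[rid] = Provenance(sid, start, start + length, 1.0)

    db = PeptideDatabase(reads, read_ids, provenance)
    truth = GroundTruth(sources=lengths, read_provenance=dict(provenance))
    # default homolog intervals: each source planted verbatim as a query
    for sid in sids:
        truth.homolog_intervals[sid] = [(sid, 0, lengths[sid])]
    return db, truth


def truth_homolog_reads(query_id: str, truth: GroundTruth, db: PeptideDatabase | None = None) -> set:
    """Reads with strictly more than 60 % of their residues sampled from
    the query's homolog intervals."""
    if query_id not in truth.homolog_intervals:
        raise KeyError(f"no homolog intervals recorded for query {query_id!r}")
    intervals = truth.homolog_intervals[query_id]
    out = set()
    for rid, p in truth.read_provenance.items():
        read_len = p.end - p.start
        if read_len <= 0:
            continue
        covered = 0
        for sid, a, b in intervals:
            if sid != p.source_id:
                continue
            covered += max(0, min(p.end, b) - max(p.start, a))
        # strict > 60 %, exact at the boundary (integer arithmetic when possible)
        if p.sampled_fraction == 1.0:
            if covered * 5 > read_len * 3:
                out.add(rid)
        elif covered * p.sampled_fraction * 5 > read_len * 3:
            out.add(rid)
    return out
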