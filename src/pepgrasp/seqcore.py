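"""Amino-acid alphabets, substitution matrices and alignment statistics.

Everything downstream (seeding, banded alignment, contig scoring,
E-value reporting) is expressed in terms of the three objects defined
here: :class:`ScoringMatrix`, :class:`ReducedAlphabet` and
:class:`ScoringStatistics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "AA20",
    "WILDCARD",
    "InvalidSequenceError",
    "ScoringMatrix",
    "ReducedAlphabet",
    "ScoringStatistics",
    "reduce_sequence",
    "mean_diagonal",
    "bit_score",
    "e_value",
    "blosum62",
    "gbmr10",
    "identity_alphabet",
]

#: The 20 standard residues, in the conventional NCBI matrix order.
AA20 = "ARNDCQEGHILKMFPSTWYV"

#: Wildcard residue.  Scores 0 against everything and owns a private
#: reduced-alphabet letter, so seeds never form across it.
WILDCARD = "X"

_ALPHABET = AA20 + WILDCARD


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains a residue outside the supported set."""


class ScoringMatrix:
    """A symmetric 20x20 substitution matrix with affine gap penalties.

    ``gap_open`` and ``gap_extend`` are stored as positive magnitudes and
    applied subtractively; a gap of length ``g`` costs
    ``gap_open + g * gap_extend`` (NCBI convention for -11/-1).
    """

    def __init__(self, name: str, scores: dict, gap_open: int = 11, gap_extend: int = 1):
        if gap_open <= 0 or gap_extend <= 0:
            raise ValueError("gap penalties must be strictly positive magnitudes")
        self.name = name
        self.gap_open = int(gap_open)
        self.gap_extend = int(gap_extend)
        self._index = {aa: i for i, aa in enumerate(_ALPHABET)}
        n = len(_ALPHABET)
        arr = np.zeros((n, n), dtype=np.int32)
        for a in AA20:
            for b in AA20:
                try:
                    s = scores[a, b]
                except KeyError:
                    s = scores[b, a]
                arr[self._index[a], self._index[b]] = int(s)
        # wildcard row/column stays 0
        if not np.array_equal(arr, arr.T):
            raise ValueError("substitution matrix must be symmetric")
        self._arr = arr

    @property
    def array(self) -> np.ndarray:
        """Integer score lookup indexed by :meth:`encode` codes."""
        return self._arr

    def score(self, a: str, b: str) -> int:
        try:
            return int(self._arr[self._index[a], self._index[b]])
        except KeyError as exc:
            raise InvalidSequenceError(f"unsupported residue in pair ({a!r}, {b!r})") from exc

    def encode(self, seq: str) -> np.ndarray:
        """Encode a residue string to uint8 codes usable with :attr:`array`."""
        try:
            return np.array([self._index[c] for c in seq], dtype=np.uint8)
        except KeyError as exc:
            raise InvalidSequenceError(f"unsupported residue in {seq!r}") from exc

    @property
    def mean_diagonal(self) -> float:
        diag = [self.score(a, a) for a in AA20]
        return sum(diag) / len(diag)

    def pair_score(self, s: str, t: str) -> int:
        """Ungapped score of two equal-length strings."""
        if len(s) != len(t):
            raise ValueError("pair_score requires equal-length strings")
        return sum(self.score(a, b) for a, b in zip(s, t))

    @classmethod
    def from_ncbi_file(cls, path, name: str | None = None, gap_open: int = 11, gap_extend: int = 1) -> "ScoringMatrix":
        """Load a matrix from an NCBI-format text file (e.g. ``BLOSUM62``)."""
        mat = substitution_matrices.read(str(path))
        scores = {(a, b): mat[a, b] for a in AA20 for b in AA20}
        return cls(name or "custom", scores, gap_open=gap_open, gap_extend=gap_extend)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ScoringMatrix({self.name!r}, gap={self.gap_open}/{self.gap_extend})"


def blosum62(gap_open: int = 11, gap_extend: int = 1) -> ScoringMatrix:
    """The default BLOSUM62 matrix with -11/-1 affine gap penalties."""
    mat = substitution_matrices.load("BLOSUM62")
    scores = {(a, b): mat[a, b] for a in AA20 for b in AA20}
    return ScoringMatrix("BLOSUM62", scores, gap_open=gap_open, gap_extend=gap_extend)


@dataclass(frozen=True)
class ReducedAlphabet:
    """A total mapping from the 20 standard residues onto group letters."""

    name: str
    mapping: dict = field(repr=False)

    def __post_init__(self):
        missing = set(AA20) - set(self.mapping)
        if missing:
            raise ValueError(f"reduced alphabet {self.name} misses residues {sorted(missing)}")

    @property
    def n_groups(self) -> int:
        return len({self.mapping[a] for a in AA20})

    @property
    def wildcard_letter(self) -> str:
        return self.mapping.get(WILDCARD, "x")

    def reduce(self, seq: str) -> str:
        return reduce_sequence(seq, self)


# 10-group reduced alphabet used for seeding.  Each group is written as
# its first member's letter; the wildcard maps to a private lowercase
# letter so that reduced k-mers containing it never match anything.
_GBMR10_GROUPS = ["G", "P", "IV", "FYW", "A", "LM", "EQRK", "ND", "TS", "HC"]


def gbmr10() -> ReducedAlphabet:
    mapping = {}
    for group in _GBMR10_GROUPS:
        for aa in group:
            mapping[aa] = group[0]
    mapping[WILDCARD] = "x"
    return ReducedAlphabet("gbmr10", mapping)


def identity_alphabet() -> ReducedAlphabet:
    """20-group identity mapping (useful for tests)."""
    mapping = {a: a for a in AA20}
    mapping[WILDCARD] = "x"
    return ReducedAlphabet("identity", mapping)


def reduce_sequence(seq: str, alphabet: ReducedAlphabet) -> str:
    """Map a residue string into reduced-alphabet space, length preserved."""
    try:
        return "".join(alphabet.mapping[c] for c in seq)
    except KeyError as exc:
        raise InvalidSequenceError(f"residue {exc.args[0]!r} not covered by alphabet {alphabet.name}") from exc


def mean_diagonal(matrix: ScoringMatrix) -> float:
    """Arithmetic mean of the 20 standard diagonal entries."""
    return matrix.mean_diagonal


@dataclass
class ScoringStatistics:
    """Karlin-Altschul parameters plus the search-space dimensions.

    Defaults are the standard NCBI gapped BLOSUM62(11,1) constants.
    ``search_space_m`` is the query length; ``search_space_n`` the total
    residue count of the read database, fixed per search so E-values are
    comparable across contigs.
    """

    lambda_: float = 0.267
    k_const: float = 0.041
    search_space_m: int = 1
    search_space_n: int = 1

    def __post_init__(self):
        if self.lambda_ <= 0 or self.k_const <= 0:
            raise ValueError("lambda and K must be positive")

    def bit_score(self, raw: float) -> float:
        return bit_score(raw, self)

    def e_value(self, bits: float) -> float:
        return e_value(bits, self)


def bit_score(raw: float, stats: ScoringStatistics) -> float:
    """Normalized bit score ``(lambda * raw - ln K) / ln 2``."""
    return (stats.lambda_ * raw - math.log(stats.k_const)) / math.log(2.0)


def e_value(bits: float, stats: ScoringStatistics) -> float:
    """Expected chance hits ``m * n * 2**(-bits)``."""
    if stats.search_space_m <= 0 or stats.search_space_n <= 0:
        raise ValueError("search space dimensions must be positive")
    return float(stats.search_space_m) * float(stats.search_space_n) * math.pow(2.0, -bits)
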