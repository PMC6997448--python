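"""IUPAC degenerate DNA motifs and matching primitives.

A motif is a short word (typically 3-8 nt) over the IUPAC nucleotide code,
where each letter denotes a subset of {A, C, G, T}: ``R`` = {A, G},
``M`` = {A, C}, ``N`` = {A, C, G, T}, and so on.  A motif matches a window of
a concrete DNA sequence when every base of the window lies in the allowed
set of the corresponding motif position.  ``N`` in a *sequence* marks a
masked base and matches nothing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

#: IUPAC letter -> allowed-base set.  All 15 non-empty subsets of {A,C,G,T}.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: allowed-base set -> IUPAC letter (inverse of :data:`IUPAC_SETS`).
SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class Motif:
    """An IUPAC consensus word with per-position allowed-base sets."""

    position_sets: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.position_sets:
            raise ValueError("motif must have at least one position")
        for s in self.position_sets:
            if s not in SET_TO_IUPAC:
                raise ValueError(f"invalid position set {set(s)!r}")

    @classmethod
    def from_consensus(cls, word: str) -> "Motif":
        try:
            sets = tuple(IUPAC_SETS[c] for c in word.upper())
        except KeyError as exc:
            raise ValueError(f"invalid IUPAC letter {exc.args[0]!r} in {word!r}") from exc
        return cls(sets)

    @property
    def consensus(self) -> str:
        return "".join(SET_TO_IUPAC[s] for s in self.position_sets)

    def __len__(self) -> int:
        return len(self.position_sets)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.consensus

    def expansions(self) -> list[str]:
        """All concrete A/C/G/T words the motif matches."""
        return [
            "".join(bases)
            for bases in itertools.product(*(sorted(s) for s in self.position_sets))
        ]

    def n_expansions(self) -> int:
        n = 1
        for s in self.position_sets:
            n *= len(s)
        return n

    def reverse_complement(self) -> "Motif":
        sets = tuple(
            frozenset(_COMPLEMENT[b] for b in s) for s in reversed(self.position_sets)
        )
        return Motif(sets)

    def allowed_table(self) -> np.ndarray:
        """Boolean (len, 5) lookup: position x encoded base (A,C,G,T,N).

        Column 4 (``N`` in a sequence) is always False: masked bases match
        nothing.
        """
        tab = np.zeros((len(self), 5), dtype=bool)
        for i, s in enumerate(self.position_sets):
            for b in s:
                tab[i, BASE_INDEX[b]] = True
        return tab


def match_positions(motif: Motif, sequence: str) -> list[int]:
    """0-based offsets of every window of ``sequence`` matched by ``motif``.

    ``sequence`` is over {A,C,G,T,N}; ``N`` matches nothing.  A motif longer
    than the sequence yields an empty list.
    """
    m = len(motif)
    seq = sequence.upper()
    n = len(seq)
    if m > n:
        return []
    sets = motif.position_sets
    out = []
    for off in range(n - m + 1):
        for j in range(m):
            if seq[off + j] not in sets[j]:
                break
        else:
            out.append(off)
    return out


def count_containing(motif: Motif, sequences) -> int:
    """Number of sequences with at least one match (zero-or-one counting).

    This is the discriminative-discovery convention: each sequence
    contributes at most 1 regardless of how many windows match.
    """
    return sum(1 for s in sequences if match_positions(motif, s))


def motif_to_pfm(motif: Motif) -> np.ndarray:
    """Position frequency matrix (len, 4): uniform over each allowed set."""
    pfm = np.zeros((len(motif), 4))
    for i, s in enumerate(motif.position_sets):
        for b in s:
            pfm[i, BASE_INDEX[b]] = 1.0 / len(s)
    return pfm


def encode_sequences(sequences: list[str]) -> np.ndarray:
    """Encode equal-length sequences as a (n, L) uint8 array (A,C,G,T,N -> 0..4)."""
    if not sequences:
        return np.zeros((0, 0), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    arrs = [lut[np.frombuffer(s.encode(), dtype=np.uint8)] for s in sequences]
    return np.vstack(arrs)


def matches_encoded(motif: Motif, encoded: np.ndarray) -> np.ndarray:
    """Boolean vector: which encoded sequences contain >=1 match.

    Vectorized counterpart of :func:`match_positions` for equal-length
    sequence collections.
    """
    n, L = encoded.shape
    m = len(motif)
    if m > L or n == 0:
        return np.zeros(n, dtype=bool)
    tab = motif.allowed_table()
    hit = np.zeros(n, dtype=bool)
    pos_idx = np.arange(m)
    for off in range(L - m + 1):
        window_ok = tab[pos_idx, encoded[:, off : off + m]].all(axis=1)
        hit |= window_ok
    return hit
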