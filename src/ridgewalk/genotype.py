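"""Genotype representation and hypercube geometry.

A genotype is a fixed-length sequence of biallelic loci, encoded as a tuple
of 0/1 integers: 0 is the ancestral (lowercase) allele, 1 the derived
(uppercase) allele. Genotypes live on the vertices of the L-dimensional
hypercube; two genotypes are mutational neighbors iff their Hamming
distance is 1. Locus indices are 0-based throughout, and bitstring
serialization is most-significant locus first (``"010"`` means locus 1
carries the derived allele for L = 3).

The :class:`Quadruple` type holds the four genotypes {ab, Ab, aB, AB}
spanned by two focal loci, together with their fitnesses — the unit on
which pairwise epistasis is defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: A genotype: an immutable tuple of 0/1 allele states, one per locus.
Genotype = tuple

__all__ = [
    "Genotype",
    "Quadruple",
    "as_genotype",
    "validate_genotype",
    "to_bitstring",
    "from_bitstring",
    "genotype_index",
    "index_to_genotype",
    "hamming_distance",
    "flip_locus",
    "hamming_neighbors",
    "complement_genotype",
    "enumerate_genotypes",
]


def as_genotype(alleles: Iterable[int]) -> Genotype:
    """Coerce an iterable of 0/1 allele states into a Genotype tuple."""
    g = tuple(int(a) for a in alleles)
    validate_genotype(g)
    return g


def validate_genotype(g: Sequence[int], L: int | None = None) -> None:
    """Raise ValueError unless ``g`` is a valid genotype (of length L, if given)."""
    if L is not None and len(g) != L:
        raise ValueError(f"genotype has {len(g)} loci, expected {L}")
    if not all(a in (0, 1) for a in g):
        raise ValueError(f"genotype entries must be 0 or 1, got {g!r}")


def to_bitstring(g: Sequence[int]) -> str:
    """Serialize a genotype as a bitstring, most-significant locus first."""
    return "".join(str(int(a)) for a in g)


def from_bitstring(s: str) -> Genotype:
    """Parse a bitstring (e.g. ``"0110"``) into a Genotype."""
    if not s or any(c not in "01" for c in s):
        raise ValueError(f"not a bitstring: {s!r}")
    return tuple(int(c) for c in s)


def genotype_index(g: Sequence[int]) -> int:
    """Integer index of a genotype, consistent with bitstring order.

    Locus 0 is the most significant bit, so the index of ``"100"`` is 4.
    Used to address rows of a tabulated fitness landscape.
    """
    idx = 0
    for a in g:
        idx = (idx << 1) | int(a)
    return idx


def index_to_genotype(idx: int, L: int) -> Genotype:
    """Inverse of :func:`genotype_index`."""
    if not 0 <= idx < (1 << L):
        raise ValueError(f"index {idx} out of range for L={L}")
    return tuple((idx >> (L - 1 - i)) & 1 for i in range(L))


def hamming_distance(a: Sequence[int], b: Sequence[int]) -> int:
    """Number of loci at which two genotypes differ."""
    if len(a) != len(b):
        raise ValueError("genotypes have different locus counts")
    return sum(x != y for x, y in zip(a, b))


def flip_locus(g: Sequence[int], i: int) -> Genotype:
    """Return the genotype obtained by flipping the allele at locus ``i``."""
    if not 0 <= i < len(g):
        raise ValueError(f"locus {i} out of range for L={len(g)}")
    return tuple(1 - a if k == i else a for k, a in enumerate(g))


def hamming_neighbors(g: Sequence[int]) -> list[Genotype]:
    """All L mutational neighbors of ``g``, ordered by flipped-locus index."""
    return [flip_locus(g, i) for i in range(len(g))]


def complement_genotype(ab: Sequence[int], Ab: Sequence[int], AB: Sequence[int]) -> Genotype:
    """Fourth genotype completing the quadruple spanned by a two-step path.

    Given three genotypes traversed by two successive single-locus
    substitutions (ab -> Ab at locus i, Ab -> AB at locus j, i != j), return
    the remaining genotype aB of the quadruple, i.e. ab with locus j
    flipped. Equivalent to the allele-wise XOR ab ^ Ab ^ AB.

    Raises ValueError if the steps are not single-locus or flip the same
    locus twice (an invalid walk triple).
    """
    if not (len(ab) == len(Ab) == len(AB)):
        raise ValueError("genotypes have different locus counts")
    diff1 = [k for k in range(len(ab)) if ab[k] != Ab[k]]
    diff2 = [k for k in range(len(ab)) if Ab[k] != AB[k]]
    if len(diff1) != 1 or len(diff2) != 1:
        raise ValueError("each step must flip exactly one locus")
    if diff1 == diff2:
        raise ValueError("the two steps flip the same locus")
    return tuple(a ^ b ^ c for a, b, c in zip(ab, Ab, AB))


def enumerate_genotypes(L: int) -> np.ndarray:
    """All 2^L genotypes as a (2^L, L) uint8 matrix, row r = genotype with index r."""
    n = 1 << L
    idx = np.arange(n, dtype=np.uint32)
    shifts = np.arange(L - 1, -1, -1, dtype=np.uint32)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(np.uint8)


@dataclass(frozen=True)
class Quadruple:
    """Four genotypes spanned by two focal loci, with their fitnesses.

    The genotypes satisfy the XOR closure ab ^ AB = Ab ^ aB at every locus:
    ab and AB differ exactly at the two focal loci, and Ab, aB each carry
    one of the two derived substitutions. Walk-derived quadruples
    additionally satisfy w_ab < w_Ab < w_AB, but that ordering is checked
    by the classifier, not here.
    """

    ab: Genotype
    Ab: Genotype
    aB: Genotype
    AB: Genotype
    w_ab: float
    w_Ab: float
    w_aB: float
    w_AB: float
    focal_loci: tuple[int, int]

    def __post_init__(self) -> None:
        i, j = self.focal_loci
        if i == j:
            raise ValueError("focal loci must be distinct")
        L = len(self.ab)
        for g in (self.Ab, self.aB, self.AB):
            if len(g) != L:
                raise ValueError("genotypes have different locus counts")
        diff = [k for k in range(L) if self.ab[k] != self.AB[k]]
        if sorted(diff) != sorted((i, j)):
            raise ValueError("ab and AB must differ exactly at the focal loci")
        if any((a ^ d) != (b ^ c) for a, b, c, d in zip(self.ab, self.Ab, self.aB, self.AB)):
            raise ValueError("XOR closure violated: ab ^ AB != Ab ^ aB")
        if hamming_distance(self.ab, self.Ab) != 1 or hamming_distance(self.ab, self.aB) != 1:
            raise ValueError("Ab and aB must each be single mutants of ab")
        for w in (self.w_ab, self.w_Ab, self.w_aB, self.w_AB):
            if not w > 0:
                raise ValueError("fitnesses must be strictly positive")

    @property
    def fitnesses(self) -> tuple[float, float, float, float]:
        """Fitnesses in (ab, Ab, aB, AB) order."""
        return (self.w_ab, self.w_Ab, self.w_aB, self.w_AB)
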