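"""Base alphabet utilities and the transition/transversion classifier.

A transition (Ts) exchanges a purine for the other purine (A<->G) or a
pyrimidine for the other pyrimidine (C<->T); every other substitution
crosses the ring-number boundary and is a transversion (Tv).  Of the 12
ordered single-base substitutions, 4 are transitions, so uniform mutation
yields a 1:2 Ts:Tv ratio.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SubstitutionClass(enum.Enum):
    """Chemical class of a single-nucleotide substitution."""

    TS = "Ts"
    TV = "Tv"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class InvalidSubstitutionError(ValueError):
    """Raised for malformed variant records (non-ACGT base or ref == alt)."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside A/C/G/T."""


@dataclass(frozen=True)
class Substitution:
    """An ordered (ref, alt) base pair with its Ts/Tv class.

    The class is symmetric in the two bases and invariant under
    complementing both, so magnitude statistics downstream treat the pair
    as unordered.
    """

    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_base", _check_base(self.ref_base))
        object.__setattr__(self, "alt_base", _check_base(self.alt_base))
        if self.ref_base == self.alt_base:
            raise InvalidSubstitutionError(
                f"ref and alt are identical: {self.ref_base!r}"
            )

    @property
    def klass(self) -> SubstitutionClass:
        return classify_substitution(self.ref_base, self.alt_base)


def _check_base(base: str) -> str:
    b = str(base).upper()
    if len(b) != 1 or b not in BASES:
        raise InvalidSubstitutionError(
            f"invalid base {base!r}: expected one of A, C, G, T "
            "(ambiguity codes and indels are not supported)"
        )
    return b


def classify_substitution(ref_base: str, alt_base: str) -> SubstitutionClass:
    """Classify a single-nucleotide substitution as transition or transversion.

    Parameters
    ----------
    ref_base, alt_base
        Single bases in {A, C, G, T}, case-insensitive, and distinct.

    Returns
    -------
    SubstitutionClass
        ``TS`` for A<->G and C<->T; ``TV`` otherwise.
    """
    ref = _check_base(ref_base)
    alt = _check_base(alt_base)
    if ref == alt:
        raise InvalidSubstitutionError(f"ref and alt are identical: {ref!r}")
    pair = {ref, alt}
    if pair <= PURINES or pair <= PYRIMIDINES:
        return SubstitutionClass.TS
    return SubstitutionClass.TV


def is_transversion(ref_base: str, alt_base: str) -> bool:
    """True iff (ref, alt) is a transversion."""
    return classify_substitution(ref_base, alt_base) is SubstitutionClass.TV


def _check_sequence(seq: str) -> str:
    s = str(seq).upper()
    if set(s) - set(BASES):
        bad = sorted(set(s) - set(BASES))
        raise AlphabetError(f"sequence contains non-ACGT characters: {bad}")
    return s


def complement(seq: str) -> str:
    """Watson-Crick complement (no reversal)."""
    return _check_sequence(seq).translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; an involution."""
    return _check_sequence(seq).translate(_COMPLEMENT)[::-1]


def random_sequence(length: int, seed: int | np.random.Generator) -> str:
    """Generate an i.i.d.-uniform random DNA sequence.

    Parameters
    ----------
    length
        Sequence length in bp; must be >= 1.
    seed
        Integer seed or a ``numpy.random.Generator`` (drawn from, for use
        inside larger seeded experiments).
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    idx = rng.integers(0, 4, size=length)
    return "".join(BASES[i] for i in idx)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int8 array with A=0, C=1, G=2, T=3."""
    s = _check_sequence(seq)
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    out = np.empty(len(s), dtype=np.int8)
    for i, b in enumerate(BASES):
        out[arr == ord(b)] = i
    return out


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return "".join(BASES[int(i)] for i in codes)
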