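"""IUPAC nucleotide ambiguity-code algebra.

A degenerate oligonucleotide is a string over the 15 IUPAC nucleotide codes;
synthesising it yields an equimolar mixture of every concrete sequence obtained
by choosing one base per position ("expansion").  All primer matching in this
package reduces to position-wise base-set intersection: two codes *mismatch*
iff their base sets are disjoint, so ``N`` matches everything and the mismatch
count between two patterns equals the minimum Hamming distance over all pairs
of expanded variants (positions are independent).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import reduce
from typing import Iterator

__all__ = [
    "IUPAC_CODES",
    "COMPLEMENT",
    "IupacPattern",
    "code_bases",
    "expand",
    "revcomp",
    "pattern_mismatches",
    "degeneracy",
]

#: base set for each of the 15 IUPAC nucleotide codes
IUPAC_CODES: dict[str, frozenset[str]] = {
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

#: ambiguity-aware complement (A<->T, C<->G, R<->Y, K<->M, B<->V, D<->H; S,W,N fixed)
COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

#: base set -> canonical IUPAC code (inverse of IUPAC_CODES)
CODE_FOR_BASES: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}

DEFAULT_EXPANSION_CAP = 4096


def normalize(bases: str) -> str:
    """Uppercase a raw oligo string and map RNA-style U to T.

    Raises ``ValueError`` naming the first offending position if any character
    is not an IUPAC code after normalization (gap characters are illegal here;
    gaps belong to alignments, not primers).
    """
    out = bases.upper().replace("U", "T")
    for i, ch in enumerate(out):
        if ch not in IUPAC_CODES:
            raise ValueError(
                f"invalid IUPAC character {ch!r} at position {i} in {bases!r}"
            )
    return out


def code_bases(code: str) -> frozenset[str]:
    """Return the concrete base set of a single IUPAC code (e.g. Y -> {C,T})."""
    if len(code) != 1:
        raise ValueError(f"expected a single character, got {code!r}")
    c = code.upper().replace("U", "T")
    try:
        return IUPAC_CODES[c]
    except KeyError:
        raise ValueError(f"invalid IUPAC character {code!r} at position 0") from None


@dataclass(frozen=True)
class IupacPattern:
    """A 5'->3' oligonucleotide over the IUPAC alphabet.

    Parameters
    ----------
    bases:
        Pattern string; lowercase and U are normalized on construction.
    name:
        Optional short label (e.g. ``comaA-244F``).
    """

    bases: str
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        norm = normalize(self.bases)
        if not norm:
            raise ValueError("empty pattern")
        object.__setattr__(self, "bases", norm)

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    @property
    def degeneracy(self) -> int:
        """Number of concrete variants (product of per-position set sizes)."""
        return reduce(
            lambda acc, ch: acc * len(IUPAC_CODES[ch]), self.bases, 1
        )

    @property
    def degenerate_positions(self) -> tuple[int, ...]:
        """0-based indices of positions with more than one allowed base."""
        return tuple(
            i for i, ch in enumerate(self.bases) if len(IUPAC_CODES[ch]) > 1
        )

    def is_concrete(self) -> bool:
        return self.degeneracy == 1


def _as_pattern(p: IupacPattern | str) -> IupacPattern:
    return p if isinstance(p, IupacPattern) else IupacPattern(p)


def degeneracy(p: IupacPattern | str) -> int:
    return _as_pattern(p).degeneracy


def expand(
    p: IupacPattern | str, cap: int = DEFAULT_EXPANSION_CAP
) -> set[str]:
    """All concrete sequences obtainable from the pattern.

    Refuses patterns whose degeneracy exceeds ``cap`` (default 4096) so that a
    stray poly-N cannot blow up downstream set arithmetic; pass a larger cap
    explicitly to override.
    """
    pat = _as_pattern(p)
    d = pat.degeneracy
    if d > cap:
        raise ValueError(
            f"degeneracy {d} of {pat.bases!r} exceeds expansion cap {cap}"
        )
    return {
        "".join(t)
        for t in itertools.product(*(sorted(IUPAC_CODES[c]) for c in pat.bases))
    }


def iter_expand(p: IupacPattern | str) -> Iterator[str]:
    """Lazily iterate expanded variants (no cap; caller beware)."""
    pat = _as_pattern(p)
    for t in itertools.product(*(sorted(IUPAC_CODES[c]) for c in pat.bases)):
        yield "".join(t)


def revcomp(p: IupacPattern | str) -> IupacPattern:
    """Reverse complement with ambiguity-aware code complementation.

    An involution: ``revcomp(revcomp(x)) == x``.
    """
    pat = _as_pattern(p)
    rc = "".join(COMPLEMENT[c] for c in reversed(pat.bases))
    name = f"{pat.name}_rc" if pat.name else None
    return IupacPattern(rc, name=name)


def pattern_mismatches(a: IupacPattern | str, b: IupacPattern | str) -> int:
    """Count positions where the two codes' base sets are disjoint.

    Equals the minimum Hamming distance between any expanded variant of ``a``
    and any expanded variant of ``b``.  Requires equal lengths: primers are
    matched without indels.
    """
    pa, pb = _as_pattern(a), _as_pattern(b)
    if len(pa) != len(pb):
        raise ValueError(
            f"length mismatch: {len(pa)} vs {len(pb)} "
            f"({pa.bases!r} vs {pb.bases!r})"
        )
    return sum(
        1
        for x, y in zip(pa.bases, pb.bases)
        if IUPAC_CODES[x].isdisjoint(IUPAC_CODES[y])
    )


def union_code(bases: set[str] | frozenset[str]) -> str:
    """IUPAC code whose base set is exactly the given set of concrete bases."""
    fs = frozenset(bases)
    try:
        return CODE_FOR_BASES[fs]
    except KeyError:
        raise ValueError(f"not a valid base set: {sorted(bases)}") from None
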