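"""Primer catalog, binding-window selection, equimolar mixture design, Tm.

The built-in catalog holds the published comammox *Nitrospira* amoA primer
sets: two degenerate pairs (comaA-244F/659R for clade A, comaB-244F/659R for
clade B) and, for each clade, a defined equimolar mixture of 6 forward + 6
reverse low-degeneracy oligonucleotides.  Primer names carry canonical
reference coordinates (244 forward, 659 reverse) implying the 415 bp amplicon.

Equimolar mixtures exist because a highly degenerate synthesis inevitably
contains variants that match no real target gene and can prime off-target;
``design_equimolar_mix`` rebuilds such mixtures from observed binding-site
k-mers by greedy weighted set cover under a no-phantom constraint: every
returned oligo's expansion is a subset of the observed k-mer set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from math import log10
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .iupac import (
    IUPAC_CODES,
    IupacPattern,
    expand,
    union_code,
)

__all__ = [
    "PrimerSet",
    "BindingWindow",
    "ThermoParams",
    "TmSummary",
    "builtin_catalog",
    "candidate_windows",
    "design_equimolar_mix",
    "melt_temp",
    "read_primer_tsv",
    "write_primer_tsv",
]


@dataclass(frozen=True)
class PrimerSet:
    """A forward/reverse primer pair or equimolar oligo mixture.

    ``reverse`` members are stored as synthesized: 5'->3' on the antisense
    strand.  ``expected_amplicon_length`` follows the coordinate convention of
    the primer names: the forward footprint starts at reference position
    ``forward_coord`` (1-based) and the amplicon ends at ``reverse_coord - 1``
    inclusive, so length = reverse_coord - forward_coord.
    """

    set_name: str
    forward: tuple[IupacPattern, ...]
    reverse: tuple[IupacPattern, ...]
    forward_coord: int
    reverse_coord: int
    target_group: str

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primer set needs >=1 forward and >=1 reverse member")
        if len({len(p) for p in self.forward}) != 1:
            raise ValueError("forward members must share one length")
        if len({len(p) for p in self.reverse}) != 1:
            raise ValueError("reverse members must share one length")
        amp = self.expected_amplicon_length
        if amp <= len(self.forward[0]) + len(self.reverse[0]):
            raise ValueError(
                f"amplicon length {amp} does not exceed combined primer length"
            )

    @property
    def expected_amplicon_length(self) -> int:
        return self.reverse_coord - self.forward_coord

    @property
    def is_mixture(self) -> bool:
        return len(self.forward) > 1 or len(self.reverse) > 1


@dataclass(frozen=True)
class BindingWindow:
    """An alignment-column window eligible for primer placement."""

    start_column: int  # 0-based, half-open [start, start+width)
    width: int
    nongap_fraction: float

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if not 0.0 <= self.nongap_fraction <= 1.0:
            raise ValueError("nongap_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ThermoParams:
    """Melting-temperature model selection.

    ``basic``  : Tm = 64.9 + 41*(GC - 16.4)/L
    ``salt_adjusted`` : Tm = 100.5 + 41*GC/L - 820/L + 16.6*log10([Na+])
    with [Na+] in mol/L (default 50 mM).
    """

    method: Literal["basic", "salt_adjusted"] = "salt_adjusted"
    sodium_molar: float = 0.05

    def __post_init__(self) -> None:
        if self.method not in ("basic", "salt_adjusted"):
            raise ValueError(f"unknown Tm method {self.method!r}")
        if self.method == "salt_adjusted" and self.sodium_molar <= 0:
            raise ValueError("sodium_molar must be > 0 for salt_adjusted")


@dataclass(frozen=True)
class TmSummary:
    min: float
    mean: float
    max: float


# --- built-in catalog ------------------------------------------------------

_CLADE_A = "comammox clade A"
_CLADE_B = "comammox clade B"

_TABLE = {
    "comaA-244F": "TAYAAYTGGGTSAAYTA",
    "comaA-659R": "ARATCATSGTGCTRTG",
    "comaB-244F": "TAYTTCTGGACRTTYTA",
    "comaB-659R": "ARATCCARACDGTGTG",
    "comaA-244f_a": "TACAACTGGGTGAACTA",
    "comaA-244f_b": "TATAACTGGGTGAACTA",
    "comaA-244f_c": "TACAATTGGGTGAACTA",
    "comaA-244f_d": "TACAACTGGGTCAACTA",
    "comaA-244f_e": "TACAACTGGGTCAATTA",
    "comaA-244f_f": "TATAACTGGGTCAATTA",
    "comaA-659r_a": "AGATCATGGTGCTATG",
    "comaA-659r_b": "AAATCATGGTGCTATG",
    "comaA-659r_c": "AGATCATGGTGCTGTG",
    "comaA-659r_d": "AAATCATGGTGCTGTG",
    "comaA-659r_e": "AGATCATCGTGCTGTG",
    "comaA-659r_f": "AAATCATCGTGCTGTG",
    "comaB-244f_a": "TAYTTCTGGACGTTCTA",
    "comaB-244f_b": "TAYTTCTGGACATTCTA",
    "comaB-244f_c": "TACTTCTGGACTTTCTA",
    "comaB-244f_d": "TAYTTCTGGACGTTTTA",
    "comaB-244f_e": "TAYTTCTGGACATTTTA",
    "comaB-244f_f": "TACTTCTGGACCTTCTA",
    "comaB-659r_a": "ARATCCAGACGGTGTG",
    "comaB-659r_b": "ARATCCAAACGGTGTG",
    "comaB-659r_c": "ARATCCAGACAGTGTG",
    "comaB-659r_d": "ARATCCAAACAGTGTG",
    "comaB-659r_e": "AGATCCAGACTGTGTG",
    "comaB-659r_f": "AGATCCAAACAGTGTG",
}


def _pat(name: str) -> IupacPattern:
    return IupacPattern(_TABLE[name], name=name)


def builtin_catalog() -> list[PrimerSet]:
    """The four published comammox amoA primer sets.

    Returns the clade-A and clade-B degenerate pairs plus the clade-A and
    clade-B equimolar mixtures (6 forward + 6 reverse oligos each), with
    sequences byte-identical to the published table and the canonical
    coordinates 244/659 (expected amplicon 415 bp).
    """
    mk = lambda fs, rs: (tuple(_pat(n) for n in fs), tuple(_pat(n) for n in rs))
    a_deg = mk(["comaA-244F"], ["comaA-659R"])
    b_deg = mk(["comaB-244F"], ["comaB-659R"])
    a_mix = mk(
        [f"comaA-244f_{c}" for c in "abcdef"],
        [f"comaA-659r_{c}" for c in "abcdef"],
    )
    b_mix = mk(
        [f"comaB-244f_{c}" for c in "abcdef"],
        [f"comaB-659r_{c}" for c in "abcdef"],
    )
    return [
        PrimerSet("comaA degenerate", *a_deg, 244, 659, _CLADE_A),
        PrimerSet("comaB degenerate", *b_deg, 244, 659, _CLADE_B),
        PrimerSet("comaA equimolar mix", *a_mix, 244, 659, _CLADE_A),
        PrimerSet("comaB equimolar mix", *b_mix, 244, 659, _CLADE_B),
    ]


def catalog_set(name: str) -> PrimerSet:
    """Look up a built-in primer set by its ``set_name``."""
    for ps in builtin_catalog():
        if ps.set_name == name:
            return ps
    raise KeyError(
        f"unknown primer set {name!r}; available: "
        f"{[p.set_name for p in builtin_catalog()]}"
    )


# --- candidate binding windows ---------------------------------------------

_GAPS = {"-", "."}


def _row_concrete(row: str) -> bool:
    return not any(c in _GAPS for c in row)


def candidate_windows(
    alignment: Sequence[str],
    width: int,
    min_fraction: float = 0.8,
) -> list[BindingWindow]:
    """Windows of ``width`` columns where enough sequences are fully concrete.

    A sequence counts toward a window's ``nongap_fraction`` only if *every*
    column of the window holds a concrete base (no alignment gap ``-``, no
    missing-data ``.``).  Windows with fraction >= ``min_fraction`` are
    returned sorted by start column.  This implements the design rule of
    restricting primer placement to regions where sequence information exists
    in at least a given share (80% by default) of the database.
    """
    if not alignment:
        raise ValueError("empty alignment")
    L = len(alignment[0])
    if any(len(s) != L for s in alignment):
        raise ValueError("aligned sequences must share one length")
    if width > L:
        raise ValueError(f"window width {width} exceeds alignment length {L}")
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")

    n = len(alignment)
    # prefix counts of gap characters per row for O(1) window concreteness
    out = []
    gap_prefix = []
    for s in alignment:
        pref = [0] * (L + 1)
        for i, c in enumerate(s):
            pref[i + 1] = pref[i] + (1 if c in _GAPS else 0)
        gap_prefix.append(pref)
    for start in range(L - width + 1):
        covered = sum(
            1 for pref in gap_prefix if pref[start + width] - pref[start] == 0
        )
        frac = covered / n
        if frac >= min_fraction:
            out.append(BindingWindow(start, width, frac))
    return out


# --- equimolar mixture design ----------------------------------------------

@dataclass(frozen=True)
class MixDesign:
    oligos: tuple[IupacPattern, ...]
    covered_observations: int
    total_observations: int

    @property
    def coverage(self) -> float:
        return self.covered_observations / self.total_observations


def _candidate_patterns(
    distinct: list[str], max_ambiguities: int
) -> list[str]:
    """Phantom-free candidate oligos built from observed k-mers.

    For each observed k-mer and each choice of <= ``max_ambiguities`` columns,
    the candidate takes the union of bases seen among observed k-mers that
    agree everywhere else; it is kept only if its full expansion is a subset
    of the observed k-mer set (no co-synthesised variant may match nothing).
    Ambiguities are only ever placed at columns where >=2 distinct bases occur.
    """
    k = len(distinct[0])
    observed = set(distinct)
    variable_cols = [
        i for i in range(k) if len({s[i] for s in distinct}) > 1
    ]
    cands: set[str] = set(observed)
    for r in range(1, max_ambiguities + 1):
        for cols in combinations(variable_cols, r):
            groups: dict[str, set[str]] = {}
            for s in distinct:
                key = "".join(c for i, c in enumerate(s) if i not in cols)
                groups.setdefault(key, set()).add(s)
            for members in groups.values():
                if len(members) < 2:
                    continue
                rep = next(iter(members))
                pat = list(rep)
                for i in cols:
                    pat[i] = union_code({m[i] for m in members})
                p = "".join(pat)
                if expand(p) <= observed:
                    cands.add(p)
    return sorted(cands)


_EXACT_COMBO_BUDGET = 200_000


def design_equimolar_mix(
    observed_kmers: Mapping[str, int] | Iterable[str],
    max_oligos: int,
    max_ambiguities: int = 1,
) -> MixDesign:
    """Weighted maximum-coverage mixture design over observed k-mers.

    Candidates have <= ``max_ambiguities`` degenerate positions (only at
    columns where >=2 distinct bases occur) and an expansion that is a subset
    of the observed k-mers, so no co-synthesised oligo variant is a phantom.
    Small instances are solved exactly (enumerating all mixtures of up to
    ``max_oligos`` candidates); instances beyond an enumeration budget fall
    back to greedy selection of the candidate covering the most yet-uncovered
    observations.  Ties always break to fewer oligos, then lower total
    degeneracy, then lexicographic order, making the output deterministic.
    Reports covered/total k-mer observations.
    """
    counts = (
        Counter(dict(observed_kmers))
        if isinstance(observed_kmers, Mapping)
        else Counter(observed_kmers)
    )
    if not counts:
        raise ValueError("empty k-mer set")
    if max_oligos < 1:
        raise ValueError("max_oligos must be >= 1")
    if max_ambiguities < 0:
        raise ValueError("max_ambiguities must be >= 0")
    lengths = {len(s) for s in counts}
    if len(lengths) != 1:
        raise ValueError(f"k-mers must share one length, got {sorted(lengths)}")

    distinct = sorted(counts)
    candidates = _candidate_patterns(distinct, max_ambiguities)
    bit = {s: 1 << i for i, s in enumerate(distinct)}
    weight = [counts[s] for s in distinct]
    cand_mask = {
        c: sum(bit[s] for s in expand(c) & set(distinct)) for c in candidates
    }
    total = sum(counts.values())
    full = (1 << len(distinct)) - 1

    def mask_weight(mask: int) -> int:
        return sum(w for i, w in enumerate(weight) if mask >> i & 1)

    n = len(candidates)
    r_max = min(max_oligos, n)
    n_combos = sum(
        _ncr(n, r) for r in range(1, r_max + 1)
    )
    if n_combos <= _EXACT_COMBO_BUDGET:
        chosen_names = _exact_cover(candidates, cand_mask, mask_weight, full, r_max)
    else:
        chosen_names = _greedy_cover(
            candidates, cand_mask, mask_weight, full, max_oligos
        )
    covered_mask = 0
    for c in chosen_names:
        covered_mask |= cand_mask[c]
    return MixDesign(
        tuple(IupacPattern(c) for c in chosen_names),
        mask_weight(covered_mask),
        total,
    )


def _ncr(n: int, r: int) -> int:
    from math import comb

    return comb(n, r)


def _exact_cover(candidates, cand_mask, mask_weight, full, r_max) -> list[str]:
    """Best mixture by exhaustive enumeration, smallest size first."""
    best: tuple[int, int, int, tuple[str, ...]] | None = None
    for r in range(1, r_max + 1):
        for combo in combinations(candidates, r):
            m = 0
            for c in combo:
                m |= cand_mask[c]
            cov = mask_weight(m)
            totdeg = sum(IupacPattern(c).degeneracy for c in combo)
            key = (-cov, r, totdeg, combo)  # max coverage, then fewest oligos
            if best is None or key < best:
                best = key
        if best is not None and -best[0] == mask_weight(full):
            break  # full coverage with r oligos: no larger mix can beat it
    assert best is not None
    return list(best[3])


def _greedy_cover(candidates, cand_mask, mask_weight, full, max_oligos) -> list[str]:
    chosen: list[str] = []
    covered = 0
    while covered != full and len(chosen) < max_oligos:
        best = max(
            candidates,
            key=lambda c: (
                mask_weight(cand_mask[c] & ~covered),
                -IupacPattern(c).degeneracy,
                [-ord(ch) for ch in c],
            ),
        )
        if mask_weight(cand_mask[best] & ~covered) == 0:
            break
        chosen.append(best)
        covered |= cand_mask[best]
    return chosen


# --- melting temperature ----------------------------------------------------

def _tm_one(seq: str, params: ThermoParams) -> float:
    gc = sum(c in "GC" for c in seq)
    L = len(seq)
    if params.method == "basic":
        return 64.9 + 41.0 * (gc - 16.4) / L
    return 100.5 + 41.0 * gc / L - 820.0 / L + 16.6 * log10(params.sodium_molar)


def melt_temp(
    p: IupacPattern | str,
    params: ThermoParams = ThermoParams(),
    cap: int = 4096,
) -> TmSummary:
    """Melting-temperature summary over all expanded variants of a primer.

    Degenerate primers are synthesized as mixtures, so Tm is reported as
    {min, mean, max} across the expansion; concrete oligos collapse all three
    to one value.  Requires length >= 8 (the formulas are meaningless for
    very short oligos).
    """
    pat = p if isinstance(p, IupacPattern) else IupacPattern(p)
    if len(pat) < 8:
        raise ValueError("melt_temp requires length >= 8")
    tms = sorted(_tm_one(v, params) for v in expand(pat, cap=cap))
    return TmSummary(tms[0], sum(tms) / len(tms), tms[-1])


# --- primer TSV round-trip --------------------------------------------------

def write_primer_tsv(path: str | Path, sets: Iterable[PrimerSet]) -> None:
    """Write primer sets as TSV (set_name, orientation, clade, name, sequence)."""
    lines = ["set_name\torientation\tclade\tname\tsequence"]
    for ps in sets:
        for orient, members in (("forward", ps.forward), ("reverse", ps.reverse)):
            for m in members:
                lines.append(
                    f"{ps.set_name}\t{orient}\t{ps.target_group}\t"
                    f"{m.name or ''}\t{m.bases}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_primer_tsv(
    path: str | Path,
    forward_coord: int = 244,
    reverse_coord: int = 659,
) -> list[PrimerSet]:
    """Read primer sets back from the TSV written by :func:`write_primer_tsv`.

    Coordinates are not stored in the TSV; they default to the canonical
    244/659 layout and can be overridden.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != [
        "set_name", "orientation", "clade", "name", "sequence",
    ]:
        raise ValueError(f"{path}: missing or malformed primer TSV header")
    acc: dict[str, dict] = {}
    for ln in lines[1:]:
        if not ln.strip():
            continue
        set_name, orient, clade, name, seq = ln.split("\t")
        d = acc.setdefault(
            set_name, {"clade": clade, "forward": [], "reverse": []}
        )
        d[orient].append(IupacPattern(seq, name=name or None))
    return [
        PrimerSet(
            sn,
            tuple(d["forward"]),
            tuple(d["reverse"]),
            forward_coord,
            reverse_coord,
            d["clade"],
        )
        for sn, d in acc.items()
    ]
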