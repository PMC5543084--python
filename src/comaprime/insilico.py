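"""Binding-site search, in-silico PCR, coverage and specificity reports.

All matching is position-wise IUPAC base-set intersection (see
:mod:`comaprime.iupac`): a primer code and a template character mismatch iff
their base sets are disjoint.  Gap characters (``-``) and missing data (``.``)
have an empty base set — they mismatch everything and mark a window
non-concrete, which drives binding-site eligibility: a sequence only counts
toward coverage/specificity denominators if it holds concrete sequence
information across both primer binding windows.

Coordinates are 0-based half-open throughout.  Reverse primers are stored
5'->3' on the antisense strand and are matched on the sense strand as their
reverse complement; an amplicon spans both primer footprints inclusively.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .iupac import IUPAC_CODES, IupacPattern, revcomp

__all__ = [
    "SeqRec",
    "ReferenceDatabase",
    "MatchHit",
    "Amplicon",
    "CoverageReport",
    "SpecificityReport",
    "site_eligibility",
    "find_sites",
    "insilico_pcr",
    "coverage",
    "specificity",
]

_GAPS = frozenset("-.")


@dataclass(frozen=True)
class SeqRec:
    """One database record: id, (possibly gap-aligned) sequence, group label."""

    id: str
    seq: str
    group: str = "unlabeled"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper().replace("U", "T"))

    @property
    def degapped(self) -> str:
        return "".join(c for c in self.seq if c not in _GAPS)


@dataclass
class ReferenceDatabase:
    """Group-labeled sequence collection, optionally gap-aligned."""

    records: list[SeqRec]
    aligned: bool = False

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate sequence ids: {dupes}")
        if self.aligned:
            lens = {len(r.seq) for r in self.records}
            if len(lens) > 1:
                raise ValueError(
                    f"aligned database has ragged lengths: {sorted(lens)}"
                )

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.group, None)
        return list(seen)

    def group_records(self, group: str) -> list[SeqRec]:
        return [r for r in self.records if r.group == group]


@dataclass(frozen=True)
class MatchHit:
    sequence_id: str
    primer_name: str
    strand: Literal["sense", "antisense"]
    start: int  # 0-based on the sense strand, half-open [start, start+length)
    length: int
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class Amplicon:
    """Predicted PCR product, inclusive of both primer footprints."""

    template_id: str
    start: int
    end: int
    forward_hit: MatchHit
    reverse_hit: MatchHit

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GroupCoverage:
    group: str
    eligible: int
    matched: int

    @property
    def percent(self) -> float | None:
        """Exact percentage, or None when no sequence is eligible."""
        return None if self.eligible == 0 else 100.0 * self.matched / self.eligible

    @property
    def percent_display(self) -> int | None:
        """Half-up integer rounding for table-style display (e.g. 95)."""
        p = self.percent
        return None if p is None else int(p + 0.5)


@dataclass(frozen=True)
class CoverageReport:
    primer_set: str
    per_group: tuple[GroupCoverage, ...]

    def for_group(self, group: str) -> GroupCoverage:
        for g in self.per_group:
            if g.group == group:
                return g
        raise KeyError(group)


@dataclass(frozen=True)
class GroupSpecificity:
    """Per-sequence minimum-mismatch histogram for one off-target group.

    A sequence's value is the max over the two primers of the per-primer
    minimum mismatch count (best member at the best position): the pair "has
    k mismatches" only when neither primer does better than k.
    """

    group: str
    histogram: Mapping[int, int]  # mismatch count -> number of sequences
    eligible: int

    def count_at_or_below(self, k: int) -> int:
        return sum(n for mm, n in self.histogram.items() if mm <= k)


@dataclass(frozen=True)
class SpecificityReport:
    primer_set: str
    per_group: tuple[GroupSpecificity, ...]
    combination_rule: str = "max over the two primers of per-primer minima"

    def for_group(self, group: str) -> GroupSpecificity:
        for g in self.per_group:
            if g.group == group:
                return g
        raise KeyError(group)


# --- low-level scanning -----------------------------------------------------

def _window_stats(template: str, pos: int, pattern: str) -> tuple[int, bool]:
    """(mismatches, concrete) for pattern laid on template[pos:pos+len]."""
    mm = 0
    concrete = True
    for off, pc in enumerate(pattern):
        tc = template[pos + off]
        if tc in _GAPS:
            mm += 1
            concrete = False
            continue
        ts = IUPAC_CODES.get(tc)
        if ts is None or ts.isdisjoint(IUPAC_CODES[pc]):
            mm += 1
    return mm, concrete


def find_sites(
    template: str,
    primers: Sequence[IupacPattern] | IupacPattern,
    orientation: Literal["sense", "antisense"] = "sense",
    max_mismatches: int = 0,
    sequence_id: str = "",
) -> list[MatchHit]:
    """Scan a sense-strand template for primer binding sites.

    ``orientation="antisense"`` means the primer anneals to the antisense
    strand (a reverse primer): its members are matched on the sense strand as
    their reverse complements.  At each position the minimum mismatch count
    over all members is reported; positions above ``max_mismatches`` and
    windows containing gap/missing characters are dropped.  A template shorter
    than the primer yields no hits.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    members = [primers] if isinstance(primers, IupacPattern) else list(primers)
    if not members:
        return []
    template = template.upper().replace("U", "T")
    scan = [
        (m.name or m.bases, revcomp(m).bases if orientation == "antisense" else m.bases)
        for m in members
    ]
    plen = len(scan[0][1])
    hits: list[MatchHit] = []
    for pos in range(len(template) - plen + 1):
        best_mm: int | None = None
        best_name = ""
        concrete_any = False
        for name, pat in scan:
            mm, concrete = _window_stats(template, pos, pat)
            if best_mm is None or mm < best_mm:
                best_mm, best_name = mm, name
            concrete_any = concrete_any or concrete
        if best_mm is not None and best_mm <= max_mismatches and concrete_any:
            hits.append(
                MatchHit(sequence_id, best_name, orientation, pos, plen, best_mm)
            )
    return hits


def _best_site(
    template: str,
    members: Sequence[IupacPattern],
    orientation: Literal["sense", "antisense"],
) -> tuple[int, int, bool] | None:
    """(min mismatches, start, window concrete) of the best-matching position.

    The best position minimises the mismatch count (gaps counting as
    mismatches), tie-broken leftmost.  None when the template is too short.
    """
    scan = [
        revcomp(m).bases if orientation == "antisense" else m.bases
        for m in members
    ]
    plen = len(scan[0])
    best: tuple[int, int, bool] | None = None
    for pos in range(len(template) - plen + 1):
        mm_here: int | None = None
        concrete_here = False
        for pat in scan:
            mm, concrete = _window_stats(template, pos, pat)
            if mm_here is None or mm < mm_here:
                mm_here = mm
            concrete_here = concrete_here or concrete
        assert mm_here is not None
        if best is None or mm_here < best[0]:
            best = (mm_here, pos, concrete_here)
    return best


# --- eligibility ------------------------------------------------------------

@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    reason: str | None = None  # "gap", "truncated", "no_site"
    forward: tuple[int, int, bool] | None = None  # (mismatches, start, concrete)
    reverse: tuple[int, int, bool] | None = None


def site_eligibility(
    record: SeqRec,
    primer_set,
    max_mismatches_ceiling: int | None = None,
) -> Eligibility:
    """Decide whether a record has sequence information at both binding sites.

    The two binding windows are located by a best-hit scan on the record
    (minimum mismatches over members and positions; reverse window must start
    at or after the forward window's end).  The record is eligible iff both
    windows are fully concrete — no alignment gap, no missing data — and the
    record extends far enough past the forward site to hold the expected
    amplicon (otherwise it is ``truncated``).  With ``max_mismatches_ceiling``
    set, a best window above the ceiling counts as absent (``no_site``).
    """
    seq = record.seq
    fw = _best_site(seq, primer_set.forward, "sense")
    if fw is None:
        return Eligibility(False, "truncated")
    if fw[1] + primer_set.expected_amplicon_length > len(seq):
        return Eligibility(False, "truncated", forward=fw)
    flen = len(primer_set.forward[0])
    downstream = seq[fw[1] + flen:]
    rv = _best_site(downstream, primer_set.reverse, "antisense")
    if rv is None:
        return Eligibility(False, "truncated", forward=fw)
    rv = (rv[0], rv[1] + fw[1] + flen, rv[2])
    if max_mismatches_ceiling is not None and (
        fw[0] > max_mismatches_ceiling or rv[0] > max_mismatches_ceiling
    ):
        return Eligibility(False, "no_site", forward=fw, reverse=rv)
    if not (fw[2] and rv[2]):
        return Eligibility(False, "gap", forward=fw, reverse=rv)
    return Eligibility(True, None, forward=fw, reverse=rv)


# --- in-silico PCR ----------------------------------------------------------

def _pcr_one_orientation(
    template: str,
    pair,
    max_mismatches: int,
    min_len: int,
    max_len: int,
    template_id: str,
) -> list[tuple[MatchHit, MatchHit]]:
    """Forward/reverse hit pairs on one template orientation.

    Pairing is a symmetric nearest-partner rule: a product is kept when the
    reverse hit is the nearest downstream partner of the forward hit *or*
    the forward hit is the nearest upstream partner of the reverse hit,
    subject to ``min_len <= length <= max_len``.
    """
    fhits = find_sites(template, pair.forward, "sense", max_mismatches, template_id)
    rhits = find_sites(template, pair.reverse, "antisense", max_mismatches, template_id)
    pairs: set[tuple[MatchHit, MatchHit]] = set()

    def ok(f: MatchHit, r: MatchHit) -> bool:
        return f.start < r.start and min_len <= r.end - f.start <= max_len

    for f in fhits:
        cands = [r for r in rhits if ok(f, r)]
        if cands:
            pairs.add((f, min(cands, key=lambda r: r.start)))
    for r in rhits:
        cands = [f for f in fhits if ok(f, r)]
        if cands:
            pairs.add((max(cands, key=lambda f: f.start), r))
    return sorted(pairs, key=lambda fr: (fr[0].start, fr[1].end))


def insilico_pcr(
    template: str,
    pair,
    max_mismatches: int = 0,
    min_len: int = 50,
    max_len: int = 5000,
    template_id: str = "",
) -> list[Amplicon]:
    """Predict PCR products of a primer set on a template.

    Both template orientations are scanned — PCR amplifies the same
    double-stranded region whichever strand is supplied — so scanning the
    reverse-complemented template yields the identical product set after
    coordinate mapping.  Product coordinates are on the supplied strand and
    include both primer footprints; for a product whose forward primer
    anneals to the supplied strand's complement, ``forward_hit`` is the
    right-hand footprint (its ``strand`` field says so).
    """
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    template = template.upper().replace("U", "T")
    out: dict[tuple[int, int], Amplicon] = {}
    for f, r in _pcr_one_orientation(
        template, pair, max_mismatches, min_len, max_len, template_id
    ):
        out[(f.start, r.end)] = Amplicon(template_id, f.start, r.end, f, r)
    rc = _revcomp_seq(template)
    L = len(template)
    for f, r in _pcr_one_orientation(
        rc, pair, max_mismatches, min_len, max_len, template_id
    ):
        start, end = L - r.end, L - f.start
        key = (start, end)
        if key in out:
            continue  # palindromic product already found on the plus scan
        fwd = MatchHit(
            template_id, f.primer_name, "antisense", end - f.length,
            f.length, f.mismatches,
        )
        rev = MatchHit(
            template_id, r.primer_name, "sense", start, r.length, r.mismatches
        )
        out[key] = Amplicon(template_id, start, end, fwd, rev)
    return sorted(out.values(), key=lambda a: (a.start, a.end))


_RC = str.maketrans("ACGTRYSWKMBDHVN.-", "TGCAYRSWMKVHDBN.-")


def _revcomp_seq(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# --- aligned-database window location ---------------------------------------

def _locate_aligned_windows(
    db: ReferenceDatabase, primer_set, target_group: str
) -> tuple[int, int]:
    """Alignment column starts of the forward and reverse binding windows.

    Chooses, among all column offsets, the window minimising the mean mismatch
    count over target-group rows that are fully concrete there (reverse window
    constrained downstream of the forward one).
    """
    rows = [r.seq for r in db.group_records(target_group)]
    if not rows:
        raise ValueError(f"group {target_group!r} absent from database")
    L = len(rows[0])

    def best_col(patterns: list[str], lo: int) -> int:
        plen = len(patterns[0])
        best_score, best_c = None, lo
        for c in range(lo, L - plen + 1):
            tot, n = 0, 0
            for s in rows:
                mm = None
                concrete = False
                for pat in patterns:
                    m, conc = _window_stats(s, c, pat)
                    if mm is None or m < mm:
                        mm = m
                    concrete = concrete or conc
                if concrete:
                    tot += mm
                    n += 1
            if n == 0:
                continue
            score = tot / n
            if best_score is None or score < best_score:
                best_score, best_c = score, c
        return best_c

    fcol = best_col([m.bases for m in primer_set.forward], 0)
    flen = len(primer_set.forward[0])
    rcol = best_col([revcomp(m).bases for m in primer_set.reverse], fcol + flen)
    return fcol, rcol


def _record_match(
    record: SeqRec,
    primer_set,
    db_aligned: bool,
    windows: tuple[int, int] | None,
) -> tuple[bool, str | None, int | None, int | None]:
    """(eligible, reason, fwd mismatches, rev mismatches) for one record."""
    if db_aligned and windows is not None:
        fcol, rcol = windows
        flen = len(primer_set.forward[0])
        rlen = len(primer_set.reverse[0])
        seq = record.seq
        if rcol + rlen > len(seq):
            return False, "truncated", None, None
        fstats = [
            _window_stats(seq, fcol, m.bases) for m in primer_set.forward
        ]
        rstats = [
            _window_stats(seq, rcol, revcomp(m).bases) for m in primer_set.reverse
        ]
        if not (any(c for _, c in fstats) and any(c for _, c in rstats)):
            return False, "gap", None, None
        return (
            True,
            None,
            min(m for m, _ in fstats),
            min(m for m, _ in rstats),
        )
    elig = site_eligibility(record, primer_set)
    if not elig.eligible:
        return False, elig.reason, None, None
    assert elig.forward is not None and elig.reverse is not None
    return True, None, elig.forward[0], elig.reverse[0]


# --- coverage ---------------------------------------------------------------

def coverage(
    db: ReferenceDatabase,
    primer_set,
    target_group: str | None = None,
) -> CoverageReport:
    """Fraction of eligible target sequences perfectly matched by the set.

    A sequence is *eligible* when it carries concrete sequence information at
    both binding windows; it is *matched* when at least one forward member and
    at least one reverse member bind with zero mismatches ("fully match").
    """
    groups = [target_group] if target_group else db.groups
    if target_group and target_group not in db.groups:
        raise ValueError(f"group {target_group!r} absent from database")
    per = []
    for g in groups:
        windows = (
            _locate_aligned_windows(db, primer_set, g) if db.aligned else None
        )
        eligible = matched = 0
        for rec in db.group_records(g):
            ok, _reason, fmm, rmm = _record_match(rec, primer_set, db.aligned, windows)
            if not ok:
                continue
            eligible += 1
            if fmm == 0 and rmm == 0:
                matched += 1
        per.append(GroupCoverage(g, eligible, matched))
    return CoverageReport(primer_set.set_name, tuple(per))


# --- specificity ------------------------------------------------------------

def specificity(
    db: ReferenceDatabase,
    primer_set,
    offtarget_groups: Sequence[str] | None = None,
) -> SpecificityReport:
    """Minimum-mismatch histograms of a primer set against off-target groups.

    Per eligible off-target sequence: for each primer, the minimum mismatch
    count over members at the best-matching position; the sequence's reported
    value is the maximum of the two per-primer minima (neither primer does
    better).  Histograms sum to each group's eligible sequence count.
    """
    groups = list(offtarget_groups) if offtarget_groups else db.groups
    missing = [g for g in groups if g not in db.groups]
    if missing:
        raise ValueError(f"groups absent from database: {missing}")
    per = []
    for g in groups:
        windows = (
            _locate_aligned_windows(db, primer_set, g) if db.aligned else None
        )
        hist: Counter[int] = Counter()
        eligible = 0
        for rec in db.group_records(g):
            ok, _reason, fmm, rmm = _record_match(rec, primer_set, db.aligned, windows)
            if not ok:
                continue
            eligible += 1
            assert fmm is not None and rmm is not None
            hist[max(fmm, rmm)] += 1
        per.append(GroupSpecificity(g, dict(sorted(hist.items())), eligible))
    return SpecificityReport(primer_set.set_name, tuple(per))
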