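"""Seeded generators for every input the toolkit consumes.

Three generators emulate the study's data shapes with known ground truth:

* :func:`gen_reference_db` — a group-labeled sequence database with planted
  per-primer binding-site mismatch counts and optional gapped records, so
  coverage and specificity reports can be checked against an exact truth
  table;
* :func:`gen_template` — an amplifiable template with primer binding sites at
  the canonical reference coordinates (forward 244, reverse 659; 1-based),
  giving the expected 415 bp product by construction;
* :func:`gen_qpcr` — tenfold dilution-series standard tables with known
  amplification efficiency plus unknown-sample dilution tables with optional
  planted PCR inhibition at the lowest dilutions.

Every generator is a pure function of its spec and seed.  Planted mismatches
are placed only at primer positions that are non-degenerate across all
members, mutating to a base outside the allowed set, so planted counts equal
measured counts exactly; backgrounds are resampled (bounded, deterministic)
until a scan of the finished sequence reproduces the planted truth, ruling
out accidental better-matching sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .insilico import ReferenceDatabase, SeqRec, insilico_pcr, site_eligibility
from .iupac import IUPAC_CODES, IupacPattern, expand, revcomp
from .primers import PrimerSet, builtin_catalog
from .qpcr import slope_from_efficiency

__all__ = [
    "GroupSpec",
    "DbSpec",
    "TemplateSpec",
    "gen_reference_db",
    "gen_template",
    "gen_qpcr",
]

_BASES = "ACGT"
_MAX_RESAMPLE = 200


def _clade_a_pair() -> PrimerSet:
    return builtin_catalog()[0]


@dataclass(frozen=True)
class GroupSpec:
    """Per-group recipe for :func:`gen_reference_db`.

    ``forward_mismatches``/``reverse_mismatches`` give the planted mismatch
    count per sequence (an int applies to all sequences; a sequence cycles).
    ``gap_rate`` is the per-record probability of carrying an alignment gap
    inside one binding window, which makes the record ineligible.
    """

    n_sequences: int
    forward_mismatches: int | Sequence[int] = 0
    reverse_mismatches: int | Sequence[int] = 0
    gap_rate: float = 0.0
    length: int = 600

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if not 0.0 <= self.gap_rate <= 1.0:
            raise ValueError("gap_rate must lie in [0, 1]")

    def planted(self, which: str, i: int) -> int:
        v = getattr(self, f"{which}_mismatches")
        if isinstance(v, int):
            return v
        return int(v[i % len(v)])


@dataclass(frozen=True)
class DbSpec:
    groups: Mapping[str, GroupSpec]
    seed: int = 0
    forward_start: int = 100  # 0-based start of the forward footprint


def _nondegenerate_positions(members: Sequence[IupacPattern]) -> list[tuple[int, str]]:
    """Positions where every member allows the same single base; (pos, base)."""
    L = len(members[0])
    out = []
    for i in range(L):
        union = frozenset().union(*(IUPAC_CODES[m.bases[i]] for m in members))
        if len(union) == 1:
            out.append((i, next(iter(union))))
    return out


def _plant_site(
    rng: np.random.Generator,
    members: Sequence[IupacPattern],
    n_mismatches: int,
) -> str:
    """A concrete binding site with exactly ``n_mismatches`` to the best member."""
    fixed = _nondegenerate_positions(members)
    if n_mismatches > len(fixed):
        raise ValueError(
            f"cannot plant {n_mismatches} mismatches: only {len(fixed)} "
            "non-degenerate primer positions"
        )
    member = members[rng.integers(len(members))]
    variants = sorted(expand(member))
    site = list(variants[rng.integers(len(variants))])
    idx = rng.choice(len(fixed), size=n_mismatches, replace=False)
    for j in idx:
        pos, base = fixed[j]
        alternatives = [b for b in _BASES if b != base]
        site[pos] = alternatives[rng.integers(3)]
    return "".join(site)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(4, size=n))


def _measured(rec: SeqRec, pair: PrimerSet) -> tuple[bool, int | None, int | None]:
    elig = site_eligibility(rec, pair)
    if not elig.eligible:
        return False, None, None
    assert elig.forward and elig.reverse
    return True, elig.forward[0], elig.reverse[0]


def gen_reference_db(
    spec: DbSpec,
    primer_set: PrimerSet | None = None,
) -> tuple[ReferenceDatabase, pd.DataFrame]:
    """Generate a labeled database plus its exact truth table.

    Truth columns: id, group, eligible, forward_mismatches, reverse_mismatches
    (mismatch columns hold pandas NA for ineligible records).  Each record is
    verified by scanning it with the primer set; backgrounds producing an
    accidental better-matching site are deterministically resampled.
    """
    pair = primer_set or _clade_a_pair()
    rng = np.random.default_rng(spec.seed)
    flen = len(pair.forward[0])
    rlen = len(pair.reverse[0])
    f0 = spec.forward_start
    records: list[SeqRec] = []
    truth_rows = []
    for group, gs in spec.groups.items():
        amp = pair.expected_amplicon_length
        r0 = f0 + amp - rlen  # reverse footprint start
        if r0 + rlen + 20 > gs.length:
            raise ValueError(
                f"group {group!r}: length {gs.length} too short for the "
                f"{amp} bp site layout"
            )
        for i in range(gs.n_sequences):
            fmm = gs.planted("forward", i)
            rmm = gs.planted("reverse", i)
            gapped = bool(rng.random() < gs.gap_rate)
            fsite = _plant_site(rng, pair.forward, fmm)
            rsite_sense = revcomp(
                IupacPattern(_plant_site(rng, pair.reverse, rmm))
            ).bases
            rec = None
            for _attempt in range(_MAX_RESAMPLE):
                bg = list(_rand_seq(rng, gs.length))
                bg[f0:f0 + flen] = fsite
                bg[r0:r0 + rlen] = rsite_sense
                if gapped:
                    w0, wlen = (f0, flen) if rng.random() < 0.5 else (r0, rlen)
                    bg[w0 + int(rng.integers(wlen))] = "-"
                cand = SeqRec(f"{group}_{i}".replace(" ", "_"), "".join(bg), group)
                ok, m_f, m_r = _measured(cand, pair)
                if gapped:
                    if not ok:
                        rec = cand
                        break
                elif ok and m_f == fmm and m_r == rmm:
                    rec = cand
                    break
            if rec is None:
                raise RuntimeError(
                    f"could not realise planted truth for {group!r} seq {i} "
                    f"within {_MAX_RESAMPLE} resamples"
                )
            records.append(rec)
            truth_rows.append(
                {
                    "id": rec.id,
                    "group": group,
                    "eligible": not gapped,
                    "forward_mismatches": pd.NA if gapped else fmm,
                    "reverse_mismatches": pd.NA if gapped else rmm,
                }
            )
    return ReferenceDatabase(records), pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class TemplateSpec:
    """Layout of a synthetic amplifiable template.

    The forward footprint starts at 1-based reference position
    ``forward_coord``; the amplicon ends (inclusive) at ``reverse_coord - 1``,
    reproducing the coordinate convention of the primer names (244/659 gives
    a 415 bp product).  ``extra_forward_coords`` plant additional upstream
    forward sites; ``include_reverse=False`` omits the reverse site.
    """

    length: int = 1000
    forward_coord: int = 244
    reverse_coord: int = 659
    extra_forward_coords: tuple[int, ...] = ()
    include_reverse: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.forward_coord < 1:
            raise ValueError("forward_coord must be >= 1 (1-based)")
        if self.reverse_coord <= self.forward_coord:
            raise ValueError("reverse_coord must exceed forward_coord")


def gen_template(
    spec: TemplateSpec = TemplateSpec(),
    primer_set: PrimerSet | None = None,
) -> SeqRec:
    """A template whose in-silico PCR product has the coordinate-implied length.

    With the default layout this is a single 415 bp product.  When no primer
    set is given, sites are planted from the clade-A *equimolar mix* members —
    all of which lie inside the degenerate expansions — so the default
    template amplifies identically under both clade-A primer representations.
    Generation is verified by running :func:`insilico_pcr` on the candidate
    (against every verification set) and deterministically resampling the
    background until exactly the expected products (one per planted forward
    site) appear.
    """
    if primer_set is None:
        cat = builtin_catalog()
        pair = cat[2]  # clade-A equimolar mix
        verify_sets = [cat[0], cat[2]]
    else:
        pair = primer_set
        verify_sets = [primer_set]
    rng = np.random.default_rng(spec.seed)
    flen = len(pair.forward[0])
    rlen = len(pair.reverse[0])
    fstarts = sorted(
        {spec.forward_coord - 1, *(c - 1 for c in spec.extra_forward_coords)}
    )
    amp_end = spec.reverse_coord - 1  # 0-based half-open end of the amplicon
    r0 = amp_end - rlen
    if fstarts[0] < 0 or (spec.include_reverse and amp_end > spec.length):
        raise ValueError("site layout outside template bounds")
    for a, b in zip(fstarts, fstarts[1:]):
        if a + flen > b:
            raise ValueError("overlapping forward sites")
    if spec.include_reverse and fstarts[-1] + flen > r0:
        raise ValueError("forward site overlaps the reverse site")

    expected = len(fstarts) if spec.include_reverse else 0
    for _attempt in range(_MAX_RESAMPLE):
        seq = list(_rand_seq(rng, spec.length))
        for f0 in fstarts:
            seq[f0:f0 + flen] = _plant_site(rng, pair.forward, 0)
        if spec.include_reverse:
            seq[r0:r0 + rlen] = revcomp(
                IupacPattern(_plant_site(rng, pair.reverse, 0))
            ).bases
        rec = SeqRec("synthetic_template", "".join(seq))
        want = fstarts if expected else []
        if all(
            sorted(p.start for p in insilico_pcr(rec.seq, vs, max_mismatches=0))
            == want
            for vs in verify_sets
        ):
            return rec
    raise RuntimeError(
        f"could not realise template layout within {_MAX_RESAMPLE} resamples"
    )


def gen_qpcr(
    levels: int = 8,
    replicates: int = 3,
    efficiency: float = 0.885,
    intercept: float = 38.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    unknown_copies: Mapping[str, float] | None = None,
    dilution_factors: Sequence[float] = (10.0, 100.0, 1000.0, 10000.0),
    inhibition_shift: float = 0.0,
    inhibition_dilutions: Sequence[float] = (),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Dilution-series standard and unknown Cq tables with known truth.

    Standards span ``levels`` tenfold steps from 10^1 copies (the study used
    10^1–10^8), ``replicates`` Cq values each, generated as
    ``Cq = intercept + slope*log10(copies) + N(0, noise_sd)`` with
    ``slope = -1/log10(1 + efficiency)`` (efficiency as a fraction,
    0 < E <= 1.2).  Unknown samples are measured at the given template
    dilution factors; ``inhibition_shift`` adds a Cq delay at the listed
    (low) dilution factors to emulate PCR inhibition by excess extract.

    Returns (standards table, unknowns table, truth dict).  Same seed, same
    arguments — identical output.
    """
    if levels < 3:
        raise ValueError("need >= 3 dilution levels")
    if replicates < 1:
        raise ValueError("need >= 1 replicate")
    if not 0.0 < efficiency <= 1.2:
        raise ValueError("efficiency (fraction) must lie in (0, 1.2]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    slope = slope_from_efficiency(efficiency)

    std_rows = []
    for lvl in range(1, levels + 1):
        for rep in range(1, replicates + 1):
            cq = intercept + slope * lvl + (
                rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            )
            std_rows.append(
                {"assay": "synthetic", "log10_copies": float(lvl),
                 "replicate": rep, "Cq": cq}
            )
    standards = pd.DataFrame(std_rows)

    unknowns_map = unknown_copies or {"sample_1": 2.0e5}
    unk_rows = []
    inhibited = set(float(d) for d in inhibition_dilutions)
    for sample, copies in unknowns_map.items():
        if copies <= 0:
            raise ValueError(f"unknown copies must be > 0 ({sample})")
        for d in dilution_factors:
            in_reaction = copies / d
            for rep in range(1, replicates + 1):
                cq = intercept + slope * np.log10(in_reaction)
                if float(d) in inhibited:
                    cq += inhibition_shift
                if noise_sd > 0:
                    cq += rng.normal(0.0, noise_sd)
                unk_rows.append(
                    {"sample": sample, "assay": "synthetic",
                     "dilution_factor": float(d), "replicate": rep, "Cq": cq}
                )
    unknowns = pd.DataFrame(unk_rows)
    truth = {
        "slope": slope,
        "intercept": intercept,
        "efficiency_percent": efficiency * 100.0,
        "unknown_copies": dict(unknowns_map),
    }
    return standards, unknowns, truth
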