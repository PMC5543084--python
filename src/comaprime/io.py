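"""File I/O: FASTA (plain and aligned), group TSV, qPCR CSV, run configs.

FASTA handling goes through Biopython's SeqIO; record ids take the header up
to the first whitespace, wrapped and unwrapped input are both accepted, and
output is wrapped at 70 columns.  Tables are UTF-8 with a mandatory header
row: group and primer files are tab-separated, qPCR tables comma-separated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .insilico import ReferenceDatabase, SeqRec
from .iupac import IUPAC_CODES

logger = logging.getLogger("comaprime")

__all__ = [
    "read_sequences",
    "write_sequences",
    "read_groups",
    "merge_groups",
    "write_groups",
    "read_standards_csv",
    "read_unknowns_csv",
    "RunConfig",
]

_LEGAL = set(IUPAC_CODES) | {"-", ".", "U"}


def read_sequences(path: str | Path, expect_aligned: bool = False) -> ReferenceDatabase:
    """Read a FASTA file into an unlabeled :class:`ReferenceDatabase`.

    Validates ids for uniqueness and characters against IUPAC codes plus gap
    symbols (``-``, ``.``); U is normalized to T (logged).  With
    ``expect_aligned`` the sequences must share one length.
    """
    records: list[SeqRec] = []
    seen: set[str] = set()
    n_u = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq).upper()
        bad = [(i, c) for i, c in enumerate(raw) if c not in _LEGAL]
        if bad:
            i, c = bad[0]
            raise ValueError(
                f"{path}: illegal character {c!r} at position {i} in record "
                f"{rec.id!r}"
            )
        n_u += raw.count("U")
        records.append(SeqRec(rec.id, raw, "unlabeled"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if n_u:
        logger.info("%s: normalized %d U characters to T", path, n_u)
    if expect_aligned:
        lens = sorted({len(r.seq) for r in records})
        if len(lens) > 1:
            raise ValueError(
                f"{path}: ragged alignment, sequence lengths {lens}"
            )
    return ReferenceDatabase(records, aligned=expect_aligned)


def write_sequences(path: str | Path, db: ReferenceDatabase | Iterable[SeqRec]) -> None:
    recs = db.records if isinstance(db, ReferenceDatabase) else list(db)
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.id, description="") for r in recs),
        str(path),
        "fasta",
    )


def read_groups(path: str | Path) -> dict[str, str]:
    """Read an (id, group) TSV with a mandatory header row."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows = [ln for ln in lines if ln.strip()]
    if not rows:
        raise ValueError(f"{path}: empty group TSV")
    header = rows[0].split("\t")
    if header[:2] != ["id", "group"]:
        raise ValueError(
            f"{path}: expected header 'id<TAB>group', got {rows[0]!r}"
        )
    if len(rows) == 1:
        raise ValueError(f"{path}: group TSV has a header but no rows")
    out: dict[str, str] = {}
    for ln in rows[1:]:
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: malformed TSV row {ln!r}")
        out[parts[0]] = parts[1]
    return out


def merge_groups(db: ReferenceDatabase, groups: Mapping[str, str] | str | Path) -> ReferenceDatabase:
    """Attach group labels to a database; unlabeled records stay 'unlabeled'.

    Group-table ids that match no database record are reported as a warning
    (they are usually a sign of mismatched exports, not fatal).
    """
    mapping = (
        dict(groups) if isinstance(groups, Mapping) else read_groups(groups)
    )
    known = {r.id for r in db.records}
    unknown = sorted(set(mapping) - known)
    if unknown:
        logger.warning(
            "group table lists %d unknown ids (first: %s)",
            len(unknown), unknown[:5],
        )
    return ReferenceDatabase(
        [
            SeqRec(r.id, r.seq, mapping.get(r.id, "unlabeled"))
            for r in db.records
        ],
        aligned=db.aligned,
    )


def write_groups(path: str | Path, db: ReferenceDatabase) -> None:
    lines = ["id\tgroup"] + [f"{r.id}\t{r.group}" for r in db.records]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_standards_csv(path: str | Path) -> pd.DataFrame:
    """Standards table: columns (assay, log10_copies, replicate, Cq)."""
    df = pd.read_csv(path)
    need = {"assay", "log10_copies", "replicate", "Cq"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: standards CSV needs columns {sorted(need)}")
    return df


def read_unknowns_csv(path: str | Path) -> pd.DataFrame:
    """Unknowns table: columns (sample, assay, dilution_factor, replicate, Cq)."""
    df = pd.read_csv(path)
    need = {"sample", "assay", "dilution_factor", "replicate", "Cq"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: unknowns CSV needs columns {sorted(need)}")
    return df


@dataclass
class RunConfig:
    """Serializable record of one CLI invocation, echoed into the output dir."""

    subcommand: str
    inputs: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    output_dir: str = "."
    tool_version: str = ""

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        p = out / "run_config.json"
        p.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return p
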