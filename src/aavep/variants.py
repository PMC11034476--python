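"""Protein sequences, variant notation, and point-mutation application.

Positions are 1-based inclusive everywhere, matching the ``K4R`` missense
convention (lysine 4 replaced by arginine). Only single-residue missense
substitutions are supported; anything else fails at parse time. Applying a
variant verifies that the annotated wild-type residue matches the sequence —
a mismatch is an error, never a silent skip, so batch drivers can drop and
count such records explicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .descriptors import STANDARD_RESIDUES

__all__ = [
    "ProteinSequence",
    "VariantRecord",
    "VariantParseError",
    "WildTypeMismatchError",
    "parse_variant",
    "format_variant",
    "apply_variant",
    "read_fasta",
    "write_fasta",
    "read_variant_table",
    "write_variant_table",
]

Label = Literal["pathogenic", "benign", "unknown"]

_VARIANT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")
_STANDARD = set(STANDARD_RESIDUES)


class VariantParseError(ValueError):
    """Variant notation does not match <wt><position><alt>."""


class WildTypeMismatchError(ValueError):
    """Annotated wild-type residue disagrees with the sequence."""


@dataclass(frozen=True)
class ProteinSequence:
    seq_id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.seq_id!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class VariantRecord:
    """One protein point mutation with provenance."""

    seq_id: str
    position: int
    wt_residue: str
    alt_residue: str
    label: Label = "unknown"
    source: str = ""
    occurrence_count: int | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be 1-based positive, got {self.position}")
        if self.wt_residue == self.alt_residue:
            raise ValueError(f"not a missense record: {self.notation} is synonymous")

    @property
    def notation(self) -> str:
        return f"{self.wt_residue}{self.position}{self.alt_residue}"


def parse_variant(notation: str) -> tuple[str, int, str]:
    """Parse ``"K4R"``-style notation into ``(wt, position, alt)``.

    Indels, stop gains and frame notations are rejected; residues must be
    standard one-letter codes (case-folded to upper).
    """
    m = _VARIANT_RE.match(notation.strip())
    if not m:
        raise VariantParseError(f"malformed variant notation {notation!r}; expected e.g. 'K4R'")
    wt, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if wt not in _STANDARD or alt not in _STANDARD:
        raise VariantParseError(f"non-standard residue in variant {notation!r}")
    if pos < 1:
        raise VariantParseError(f"position must be >= 1 in {notation!r}")
    return wt, pos, alt


def format_variant(wt: str, position: int, alt: str) -> str:
    return f"{wt.upper()}{position}{alt.upper()}"


def apply_variant(seq: ProteinSequence, v: VariantRecord) -> ProteinSequence:
    """Return the mutated copy of ``seq``; the input is never modified.

    Raises
    ------
    IndexError
        Position outside ``1..len(seq)``.
    WildTypeMismatchError
        Sequence residue at the annotated position differs from the
        record's wild-type residue (callers typically drop the record).
    """
    if not (1 <= v.position <= len(seq)):
        raise IndexError(
            f"variant position {v.position} out of range for {seq.seq_id!r} (length {len(seq)})"
        )
    observed = seq.residues[v.position - 1]
    if observed != v.wt_residue.upper():
        raise WildTypeMismatchError(
            f"{seq.seq_id}: variant {v.notation} expects {v.wt_residue!r} at "
            f"position {v.position} but sequence has {observed!r}"
        )
    mutated = seq.residues[: v.position - 1] + v.alt_residue.upper() + seq.residues[v.position :]
    return replace(seq, residues=mutated)


def read_fasta(path: str | Path, gaps: Literal["error", "strip"] = "error") -> list[ProteinSequence]:
    """Read a multi-record protein FASTA; order preserved, IDs must be unique."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seqs: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq)
        if "-" in residues or "." in residues:
            if gaps == "strip":
                residues = residues.replace("-", "").replace(".", "")
            else:
                raise ValueError(
                    f"record {rec.id!r} contains gap characters; pass gaps='strip' to remove"
                )
        seqs.append(ProteinSequence(rec.id, residues, rec.description))
    return seqs


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.seq_id, description=s.description) for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


_TABLE_COLUMNS = ["seq_id", "variant", "label", "source", "count"]


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read the delimited variant-table format (columns: seq_id, variant,
    label, source, count)."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "variant": str})
    missing = [c for c in _TABLE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} missing columns {missing}")
    out: list[VariantRecord] = []
    for row in df.itertuples(index=False):
        wt, pos, alt = parse_variant(row.variant)
        count = getattr(row, "count", None)
        count = None if count is None or pd.isna(count) else int(count)
        out.append(
            VariantRecord(
                seq_id=row.seq_id, position=pos, wt_residue=wt, alt_residue=alt,
                label=str(row.label), source=str(getattr(row, "source", "") or ""),
                occurrence_count=count,
            )
        )
    return out


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [
        {
            "seq_id": r.seq_id,
            "variant": r.notation,
            "label": r.label,
            "source": r.source,
            "count": r.occurrence_count,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
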