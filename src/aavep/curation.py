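"""Harmonization of pathogenicity labels from heterogeneous database exports.

Variant exports from UniProt (humsavar), ClinVar and literature-mined
sources disagree in label vocabulary ("Likely pathogenic", "benign",
"risk factor", ...) and overlap in content. The cascade applied here, in
order:

1. drop rows without any label text;
2. drop literature-mined (litvar) rows whose occurrence count is not
   strictly greater than the threshold (default 15), as low-count text
   mining hits are unreliable;
3. classify by case-insensitive substring: "pathogenic" without "benign"
   -> pathogenic, "benign" without "pathogenic" -> benign, both or
   neither -> unclassifiable, dropped;
4. group by (seq_id, variant): conflicting surviving labels across
   sources drop the whole group; agreeing duplicates merge to one record
   keeping the lexicographically first source and the maximum count.

Every exclusion is counted per rule in the returned drop log; the cascade
is idempotent on its own output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .variants import VariantRecord, parse_variant, VariantParseError

__all__ = ["RawVariantRow", "harmonize", "read_raw_rows"]


@dataclass(frozen=True)
class RawVariantRow:
    """One unprocessed row from a source export."""

    seq_id: str
    variant: str
    label_text: str | None
    source: str = "other"
    occurrence_count: int | None = None


def _classify(label_text: str) -> str | None:
    low = label_text.lower()
    has_p = "pathogenic" in low
    has_b = "benign" in low
    if has_p and not has_b:
        return "pathogenic"
    if has_b and not has_p:
        return "benign"
    return None


def harmonize(
    rows: Iterable[RawVariantRow], litvar_min_count: int = 15
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the label-harmonization cascade; returns (records, drop_log).

    The drop log counts exclusions by rule: ``no_label``, ``low_count``,
    ``unclassifiable``, ``conflict`` plus ``merged`` for redundant rows
    collapsed into a kept record, so that
    ``len(input) == len(output) + sum(drop_log.values())``.
    """
    log = {"no_label": 0, "low_count": 0, "unclassifiable": 0, "conflict": 0, "merged": 0}
    survivors: list[tuple[RawVariantRow, str]] = []
    for row in rows:
        if isinstance(row, VariantRecord):  # accept harmonized output (idempotence)
            row = RawVariantRow(
                row.seq_id, row.notation, row.label, row.source, row.occurrence_count
            )
        if row.label_text is None or not str(row.label_text).strip():
            log["no_label"] += 1
            continue
        if row.source.lower() == "litvar" and (
            row.occurrence_count is None or row.occurrence_count <= litvar_min_count
        ):
            log["low_count"] += 1
            continue
        label = _classify(str(row.label_text))
        if label is None:
            log["unclassifiable"] += 1
            continue
        survivors.append((row, label))

    groups: dict[tuple[str, str], list[tuple[RawVariantRow, str]]] = {}
    for row, label in survivors:
        try:
            wt, pos, alt = parse_variant(row.variant)
        except VariantParseError:
            raise
        groups.setdefault((row.seq_id, f"{wt}{pos}{alt}"), []).append((row, label))

    records: list[VariantRecord] = []
    for (seq_id, notation), members in groups.items():
        labels = {label for _, label in members}
        if len(labels) > 1:
            log["conflict"] += len(members)
            continue
        log["merged"] += len(members) - 1
        wt, pos, alt = parse_variant(notation)
        counts = [r.occurrence_count for r, _ in members if r.occurrence_count is not None]
        records.append(
            VariantRecord(
                seq_id=seq_id,
                position=pos,
                wt_residue=wt,
                alt_residue=alt,
                label=labels.pop(),
                source=min(r.source for r, _ in members),
                occurrence_count=max(counts) if counts else None,
            )
        )
    return records, log


def read_raw_rows(path: str | Path, source: str | None = None) -> list[RawVariantRow]:
    """Read a delimited source export with columns seq_id, variant, label
    (optionally source, count)."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "variant": str})
    rows: list[RawVariantRow] = []
    for r in df.itertuples(index=False):
        label = getattr(r, "label", None)
        label = None if label is None or pd.isna(label) else str(label)
        count = getattr(r, "count", None)
        count = None if count is None or pd.isna(count) else int(count)
        rows.append(
            RawVariantRow(
                seq_id=r.seq_id,
                variant=r.variant,
                label_text=label,
                source=source or str(getattr(r, "source", "other") or "other"),
                occurrence_count=count,
            )
        )
    return rows
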