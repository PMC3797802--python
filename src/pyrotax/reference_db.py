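"""Curated reference database construction.

A functional-group reference is kept only if a genus-level classifier,
trained on the database's own taxonomy, reproduces the record's label at the
configured confidence threshold (self-consistency). Candidate-genus records
are exempt — no formal classifier can emit their names — and are kept
unconditionally. The curated set is then merged with a pre-cleaned base
database, and per-genus retention is tabulated as "retained/downloaded(pct%)".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional, Sequence

import pandas as pd

from .records import ReferenceRecord

#: classifier signature for curation: sequence -> genus name at threshold, or None
GenusCaller = Callable[[str], Optional[str]]


def self_consistency_filter(
        records: Sequence[ReferenceRecord], classifier: GenusCaller,
        confidence_threshold: float = 0.8,
) -> tuple[list[ReferenceRecord], list[ReferenceRecord]]:
    """Partition records into (retained, eliminated) by label self-consistency.

    A record is retained iff the classifier's genus call equals its label;
    candidate-genus records are exempt and retained unconditionally (status
    "exempt"). The threshold is enforced by the classifier itself and is
    carried here only for the run manifest.
    """
    if not (0.0 < confidence_threshold <= 1.0):
        raise ValueError("confidence_threshold must be in (0, 1]")
    retained, eliminated = [], []
    for rec in records:
        if rec.candidate:
            rec.status = "exempt"
            retained.append(rec)
            continue
        call = classifier(rec.sequence)
        if call is not None and call == rec.genus:
            rec.status = "retained"
            retained.append(rec)
        else:
            rec.status = "eliminated"
            eliminated.append(rec)
    return retained, eliminated


class MergeConflictError(ValueError):
    pass


def merge_databases(base: Sequence[ReferenceRecord],
                    curated: Sequence[ReferenceRecord]) -> list[ReferenceRecord]:
    """Union by record id. Identical duplicate ids are collapsed; the same id
    with conflicting lineages raises. Size = |base| + |curated| when the id
    sets are disjoint."""
    merged: dict[str, ReferenceRecord] = {}
    for rec in list(base) + list(curated):
        prev = merged.get(rec.id)
        if prev is None:
            merged[rec.id] = rec
        elif prev.lineage != rec.lineage:
            raise MergeConflictError(
                f"id {rec.id} carries conflicting lineages: "
                f"{prev.lineage} vs {rec.lineage}")
    return list(merged.values())


def _round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_retention(retained: int, downloaded: int) -> str:
    """Display convention: ``48/78(61.5%)`` — half-up to one decimal, with
    trailing ``.0`` dropped (``100%``, ``0%``)."""
    pct = _round_half_up(100.0 * retained / downloaded) if downloaded else 0.0
    text = f"{pct:.1f}".removesuffix(".0")
    return f"{retained:,}/{downloaded:,}({text}%)"


@dataclass
class RetentionRow:
    genus: str
    retained: int
    downloaded: int

    @property
    def percentage(self) -> float:
        return _round_half_up(100.0 * self.retained / self.downloaded) if self.downloaded else 0.0

    @property
    def display(self) -> str:
        return format_retention(self.retained, self.downloaded)


def retention_table(records: Sequence[ReferenceRecord]) -> list[RetentionRow]:
    """Per-genus curation bookkeeping plus a Total row.

    ``downloaded`` counts every functional-group record labeled with the
    genus; ``retained`` counts those the classifier reproduced ("retained"
    status). Candidate genera therefore show 0 classifier-consistent records
    even though their sequences stay in the final database (status "exempt").
    """
    by_genus: dict[str, list[ReferenceRecord]] = {}
    for rec in records:
        if rec.source != "functional-group":
            continue
        if rec.status is None:
            raise ValueError(f"record {rec.id} has no curation status")
        by_genus.setdefault(rec.genus, []).append(rec)
    rows = []
    for genus in sorted(by_genus):
        recs = by_genus[genus]
        rows.append(RetentionRow(
            genus=genus,
            retained=sum(1 for r in recs if r.status == "retained"),
            downloaded=len(recs)))
    rows.append(RetentionRow(
        genus="Total",
        retained=sum(r.retained for r in rows),
        downloaded=sum(r.downloaded for r in rows)))
    return rows


def retention_frame(rows: Sequence[RetentionRow]) -> pd.DataFrame:
    return pd.DataFrame({
        "genus": [r.genus for r in rows],
        "retained": [r.retained for r in rows],
        "downloaded": [r.downloaded for r in rows],
        "percentage": [r.percentage for r in rows],
        "display": [r.display for r in rows],
    })
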