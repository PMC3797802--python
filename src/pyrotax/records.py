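"""Shared record types: full-length references and processed amplicon tags."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .taxonomy import Lineage


@dataclass
class ReferenceRecord:
    """A near-full-length 16S reference with its labeled lineage.

    ``lineage`` is the label the database carries (what curation judges);
    ``true_lineage`` is the simulation truth and equals ``lineage`` unless
    label noise was injected. ``status`` is set by the self-consistency
    filter: retained / eliminated / exempt (candidate genera).
    """

    id: str
    sequence: str
    lineage: Lineage
    source: str = "functional-group"   # or "base"
    candidate: bool = False
    status: Optional[str] = None
    true_lineage: Optional[Lineage] = None

    @property
    def genus(self) -> str:
        return self.lineage[-1]

    @property
    def mislabeled(self) -> bool:
        return self.true_lineage is not None and self.true_lineage != self.lineage

    def relabeled(self, lineage: Lineage) -> "ReferenceRecord":
        true = self.true_lineage if self.true_lineage is not None else self.lineage
        return replace(self, lineage=lineage, true_lineage=true)


@dataclass
class Pyrotag:
    """One amplicon read, before or after primer trimming.

    ``direction`` is the sequencing direction relative to the amplicon
    (forward = from the forward primer). After trimming, reverse tags are
    stored reverse-complemented so every classifier sees the forward strand.
    """

    id: str
    sequence: str
    region: str
    direction: str = "forward"
    truth_genus: Optional[str] = None
    count: int = 1
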