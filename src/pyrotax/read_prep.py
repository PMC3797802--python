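"""Quality filter, primer trimming, length filter, dereplication, depth
normalization for directional amplicon reads.

Reads are processed in a fixed drop order — ambiguous bases, then primer
match, then minimum length — so the per-read reason codes are deterministic
and the conservation identity input = kept + dropped(ambiguous) +
dropped(primer) + dropped(length) holds at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .records import Pyrotag
from .seqs import is_unambiguous, iupac_mismatches, reverse_complement, validate_iupac

#: primer must start within the first PRIMER_WINDOW bases of a read
PRIMER_WINDOW = 3


@dataclass
class RegionPrep:
    """Per-region trimming settings: primer pair, single-primer mode, minimum
    trimmed length. In single-primer mode only the primer at the start of
    sequencing is located and removed (used for amplicons longer than the
    read, where requiring the far primer would bias retention)."""

    region: str
    forward_primer: str
    reverse_primer: str
    min_length: int
    single_primer: bool = False


@dataclass
class PrepParams:
    max_mismatches: int = 2
    depth: int = 32_000
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        if self.max_mismatches < 0:
            problems.append("max_mismatches must be >= 0")
        if self.depth <= 0:
            problems.append("depth must be positive")
        return problems


@dataclass
class DropReport:
    """Read ids dropped at each stage, with reason codes."""

    ambiguous: list[str] = field(default_factory=list)
    primer: list[str] = field(default_factory=list)
    length: list[str] = field(default_factory=list)

    def rows(self) -> list[tuple[str, str]]:
        return ([(i, "ambiguous") for i in self.ambiguous]
                + [(i, "primer") for i in self.primer]
                + [(i, "length") for i in self.length])

    @property
    def total(self) -> int:
        return len(self.ambiguous) + len(self.primer) + len(self.length)


def quality_filter(reads: Sequence[Pyrotag]) -> tuple[list[Pyrotag], list[str]]:
    """Keep exactly the reads whose sequences use only A/C/G/T."""
    kept: list[Pyrotag] = []
    dropped: list[str] = []
    for r in reads:
        if is_unambiguous(r.sequence):
            kept.append(r)
        else:
            dropped.append(r.id)
    return kept, dropped


def match_primer(sequence: str, primer: str, max_mismatches: int,
                 window: int = PRIMER_WINDOW) -> Optional[int]:
    """Leftmost start offset (within ``window`` of the read start) where the
    IUPAC-class mismatch count against ``primer`` is <= ``max_mismatches``."""
    validate_iupac(primer)
    span = len(primer)
    for off in range(0, window + 1):
        if off + span > len(sequence):
            break
        if iupac_mismatches(sequence[off:off + span], primer) <= max_mismatches:
            return off
    return None


def _match_primer_end(sequence: str, primer_rc: str, max_mismatches: int,
                      window: int = PRIMER_WINDOW) -> Optional[int]:
    """Start of the rightmost window, ending within ``window`` of the read end,
    matching ``primer_rc`` with <= max_mismatches (for far-primer trimming)."""
    span = len(primer_rc)
    for off in range(0, window + 1):
        start = len(sequence) - span - off
        if start < 0:
            break
        if iupac_mismatches(sequence[start:start + span], primer_rc) <= max_mismatches:
            return start
    return None


def trim_reads(reads: Sequence[Pyrotag], region: RegionPrep,
               params: PrepParams) -> tuple[list[Pyrotag], DropReport]:
    """Primer-trim and length-filter quality-checked reads of one region.

    Forward reads start with the forward primer; reverse reads start with the
    reverse primer and are reverse-complemented to forward orientation after
    trimming so all classifiers see a single strand. In dual-primer mode the
    far primer (as its reverse complement, at the read end) must also be found
    and is removed; in single-primer mode only the leading primer is removed.
    """
    report = DropReport()
    kept: list[Pyrotag] = []
    for r in reads:
        if not is_unambiguous(r.sequence):
            report.ambiguous.append(r.id)
            continue
        lead = region.forward_primer if r.direction == "forward" else region.reverse_primer
        far = region.reverse_primer if r.direction == "forward" else region.forward_primer
        start = match_primer(r.sequence, lead, params.max_mismatches)
        if start is None:
            report.primer.append(r.id)
            continue
        insert_start = start + len(lead)
        if region.single_primer:
            insert_end = len(r.sequence)
        else:
            end = _match_primer_end(r.sequence, reverse_complement(far),
                                    params.max_mismatches)
            if end is None or end <= insert_start:
                report.primer.append(r.id)
                continue
            insert_end = end
        tag_seq = r.sequence[insert_start:insert_end]
        if r.direction == "reverse":
            tag_seq = reverse_complement(tag_seq)
        if len(tag_seq) <= region.min_length:
            report.length.append(r.id)
            continue
        kept.append(replace(r, sequence=tag_seq))
    assert len(kept) + report.total == len(reads)
    return kept, report


def normalize_depth(tags: Sequence[Pyrotag], depth: int, seed: int) -> list[Pyrotag]:
    """Uniform subsample without replacement to exactly ``depth`` tags,
    preserving input order; deterministic given the seed."""
    if len(tags) < depth:
        raise ValueError(
            f"cannot normalize: {len(tags)} tags available, {depth} requested "
            f"(short by {depth - len(tags)})")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(tags), size=depth, replace=False))
    return [tags[int(i)] for i in idx]


def dereplicate(tags: Sequence[Pyrotag]) -> list[Pyrotag]:
    """Group tags by exact sequence; one representative per type with the
    duplicate count set. Counts sum to the input size."""
    groups: dict[str, Pyrotag] = {}
    for t in tags:
        if t.sequence in groups:
            groups[t.sequence].count += t.count
        else:
            groups[t.sequence] = replace(t)
    return list(groups.values())
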