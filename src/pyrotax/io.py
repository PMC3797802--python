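"""Reading and writing the pipeline's on-disk formats.

References travel as FASTA plus a Greengenes-style taxonomy TSV
(record-id TAB ``k__X;p__X;c__X;o__X;f__X;g__X``). Reads travel as FASTA
with reserved ``key=value`` tokens in the description (region, direction,
truth genus) so simulation truth survives round-trips through standard
files. Every run writes a JSON manifest echoing parameters, seeds, and
sha256 digests of each output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import Pyrotag, ReferenceRecord
from .taxonomy import format_greengenes, parse_greengenes


# ---------------------------------------------------------------------------
# References


def write_references(records: Sequence[ReferenceRecord], fasta_path: Path,
                     taxonomy_path: Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    with open(taxonomy_path, "w") as fh:
        for r in records:
            fh.write(f"{r.id}\t{format_greengenes(r.lineage)}\n")


def read_references(fasta_path: Path, taxonomy_path: Path,
                    candidate_genera: Iterable[str] = (),
                    source: str = "functional-group") -> list[ReferenceRecord]:
    lineages = {}
    with open(taxonomy_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rid, lineage = line.rstrip("\n").split("\t")
            lineages[rid] = parse_greengenes(lineage)
    cand = set(candidate_genera)
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in lineages:
            raise ValueError(f"no taxonomy row for sequence {rec.id}")
        lin = lineages[rec.id]
        out.append(ReferenceRecord(id=rec.id, sequence=str(rec.seq).upper(),
                                   lineage=lin, source=source,
                                   candidate=lin[-1] in cand))
    return out


# ---------------------------------------------------------------------------
# Reads / tags


def _tag_description(tag: Pyrotag) -> str:
    parts = [f"region={tag.region}", f"direction={tag.direction}"]
    if tag.truth_genus:
        parts.append(f"truth_genus={tag.truth_genus}")
    if tag.count != 1:
        parts.append(f"count={tag.count}")
    return " ".join(parts)


def write_tags(tags: Sequence[Pyrotag], path: Path) -> None:
    seqs = [SeqRecord(Seq(t.sequence), id=t.id, description=_tag_description(t))
            for t in tags]
    SeqIO.write(seqs, str(path), "fasta")


def read_tags(path: Path) -> list[Pyrotag]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(tok.split("=", 1) for tok in rec.description.split()
                      if "=" in tok)
        out.append(Pyrotag(
            id=rec.id, sequence=str(rec.seq).upper(),
            region=fields.get("region", ""),
            direction=fields.get("direction", "forward"),
            truth_genus=fields.get("truth_genus"),
            count=int(fields.get("count", 1))))
    return out


# ---------------------------------------------------------------------------
# Manifest


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: Path, params: dict, outputs: Sequence[Path],
                   extra: Optional[dict] = None) -> dict:
    manifest = {
        "parameters": params,
        "outputs": {str(p.name): sha256_of(p) for p in sorted(outputs)},
    }
    if extra:
        manifest.update(extra)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
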