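"""Synthetic 16S-like data with known truth.

The generator emulates the structure that makes hypervariable-region taxonomy
hard: a ~1.5 kb gene of alternating conserved and hypervariable segments
(C1, V1, C2, ..., V9, C10), sequences evolved down a ranked taxonomy under a
Jukes-Cantor substitution model (variable segments mutate faster than
conserved ones, primer sites not at all), degenerate primers anchored in the
conserved segments, and directional pyrosequencing-style reads with i.i.d.
substitution and ambiguity errors. Every read and reference carries its true
genus so downstream curation and classification are testable end to end.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import Pyrotag, ReferenceRecord
from .seqs import IUPAC, iupac_mismatches, reverse_complement, validate_iupac
from .taxonomy import RANKS, Lineage, TaxonNode, TaxonomyTree

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Region architecture


@dataclass(frozen=True)
class Segment:
    label: str
    kind: str        # "conserved" | "variable"
    length: int
    rate: float      # relative substitution rate (>= 0)


@dataclass
class RegionArchitecture:
    """Segment layout of the simulated gene plus primer anchor points.

    Primers are ``primer_length`` bp long; for a region spanning conserved
    segments (left, right), the forward primer covers the last primer_length
    bases of *left* and the reverse primer binds the first primer_length bases
    of *right* (its sequence is the reverse complement of that site).
    """

    segments: Sequence[Segment]
    primer_anchors: dict[str, tuple[str, str]]
    primer_length: int = 20

    def __post_init__(self) -> None:
        starts, pos = {}, 0
        for seg in self.segments:
            if seg.length <= 0:
                raise ValueError(f"segment {seg.label} has nonpositive length")
            if seg.rate < 0:
                raise ValueError(f"segment {seg.label} has negative rate")
            starts[seg.label] = pos
            pos += seg.length
        self._starts = starts
        self._length = pos
        cons = min((s.rate for s in self.segments if s.kind == "conserved"), default=0.0)
        var = min((s.rate for s in self.segments if s.kind == "variable"), default=None)
        if var is not None and var < cons:
            raise ValueError("variable-segment rate must be >= conserved-segment rate")
        for region, (left, right) in self.primer_anchors.items():
            for lbl in (left, right):
                seg = self._segment(lbl)
                if seg.kind != "conserved":
                    raise ValueError(f"primer anchor {lbl} for {region} is not conserved")
                if seg.length < self.primer_length:
                    raise ValueError(f"segment {lbl} shorter than a primer")

    def _segment(self, label: str) -> Segment:
        for s in self.segments:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def total_length(self) -> int:
        return self._length

    def segment_span(self, label: str) -> tuple[int, int]:
        start = self._starts[label]
        return start, start + self._segment(label).length

    def primer_sites(self, region: str) -> tuple[tuple[int, int], tuple[int, int]]:
        """(forward site, reverse site) as 0-based half-open template spans."""
        left, right = self.primer_anchors[region]
        ls, le = self.segment_span(left)
        rs, re = self.segment_span(right)
        return (le - self.primer_length, le), (rs, rs + self.primer_length)

    def amplicon_span(self, region: str) -> tuple[int, int]:
        (fs, _), (_, re) = self.primer_sites(region)
        return fs, re

    def rate_array(self) -> np.ndarray:
        """Per-position relative rate; primer sites are held invariant (rate 0)."""
        rates = np.empty(self._length, dtype=float)
        for seg in self.segments:
            s, e = self.segment_span(seg.label)
            rates[s:e] = seg.rate
        for region in self.primer_anchors:
            for s, e in self.primer_sites(region):
                rates[s:e] = 0.0
        return rates


def default_architecture() -> RegionArchitecture:
    """Default ~1.5 kb layout whose amplicons match common pyrosequencing sizes:
    V1&V2 350 bp, V3&V4 455 bp, V5&V6 300 bp, V7&V8&V9 420 bp (primers included).
    """
    c, v = "conserved", "variable"
    lengths = {"V1": 135, "V2": 145, "V3": 190, "V4": 195, "V5": 110,
               "V6": 120, "V7": 100, "V8": 110, "V9": 110}
    segs = []
    for i in range(1, 10):
        segs.append(Segment(f"C{i}", c, 30, 0.1))
        segs.append(Segment(f"V{i}", v, lengths[f"V{i}"], 1.0))
    segs.append(Segment("C10", c, 30, 0.1))
    anchors = {"V12": ("C1", "C3"), "V34": ("C3", "C5"),
               "V56": ("C5", "C7"), "V789": ("C7", "C10")}
    return RegionArchitecture(segments=segs, primer_anchors=anchors)


# ---------------------------------------------------------------------------
# Simulation config


@dataclass
class SimulationConfig:
    """Knobs for the whole generator; one seed fixes every draw."""

    n_phyla: int = 4
    n_genera: int = 20
    n_candidates: int = 1
    references_per_genus: int = 3
    divergences: dict[str, float] = field(default_factory=lambda: {
        "phylum": 0.12, "class": 0.06, "order": 0.05,
        "family": 0.04, "genus": 0.05, "reference": 0.005})
    error_rate: float = 0.005
    ambiguity_rate: float = 0.0005
    mislabel_fraction: float = 0.0
    abundance_sigma: float = 1.0   # lognormal spread of genus abundances
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        if not (1 <= self.n_phyla <= self.n_genera):
            problems.append("need n_genera >= n_phyla >= 1")
        if self.n_candidates < 0 or self.n_candidates > self.n_genera:
            problems.append("n_candidates out of range")
        if self.references_per_genus < 1:
            problems.append("references_per_genus must be >= 1")
        for name, rate in [("error_rate", self.error_rate),
                           ("ambiguity_rate", self.ambiguity_rate),
                           ("mislabel_fraction", self.mislabel_fraction),
                           *self.divergences.items()]:
            if not (0.0 <= rate < 1.0) and name != "mislabel_fraction":
                problems.append(f"{name} must be in [0, 1)")
            if name == "mislabel_fraction" and not (0.0 <= rate <= 1.0):
                problems.append("mislabel_fraction must be in [0, 1]")
        return problems

    def require_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("; ".join(problems))


# ---------------------------------------------------------------------------
# Taxonomy simulation


def simulate_taxonomy(n_phyla: int, n_genera: int, seed: int,
                      n_candidates: int = 0) -> TaxonomyTree:
    """Random ranked taxonomy with ``n_genera`` genus leaves over ``n_phyla`` phyla.

    Genera are distributed over phyla as evenly as possible and grouped into
    families/orders/classes of bounded size, so every genus has exactly one
    ancestor per rank. ``n_candidates`` genera are flagged as candidate taxa.
    """
    if n_phyla < 1 or n_genera < n_phyla:
        raise ValueError("need n_genera >= n_phyla >= 1")
    if not (0 <= n_candidates <= n_genera):
        raise ValueError("n_candidates out of range")
    rng = np.random.default_rng(seed)
    nodes = [TaxonNode(0, "Bacteria", "domain", None)]
    next_id = 1
    genus_ids: list[int] = []

    def _group(items: list[int], size: int) -> list[list[int]]:
        return [items[i:i + size] for i in range(0, len(items), size)]

    # genus indices per phylum, round-robin so counts differ by at most one
    per_phylum: list[list[int]] = [[] for _ in range(n_phyla)]
    for g in range(n_genera):
        per_phylum[g % n_phyla].append(g)

    for p, genera in enumerate(per_phylum):
        phylum = TaxonNode(next_id, f"Phylum{p + 1:02d}", "phylum", 0)
        nodes.append(phylum)
        next_id += 1
        families = _group(genera, 3)
        orders = _group(list(range(len(families))), 3)
        classes = _group(list(range(len(orders))), 3)
        order_parent: dict[int, int] = {}
        family_parent: dict[int, int] = {}
        for ci, order_idxs in enumerate(classes):
            cls = TaxonNode(next_id, f"Class{p + 1:02d}{ci + 1:02d}", "class", phylum.id)
            nodes.append(cls)
            next_id += 1
            for oi in order_idxs:
                order = TaxonNode(next_id, f"Order{p + 1:02d}{oi + 1:02d}", "order", cls.id)
                nodes.append(order)
                next_id += 1
                order_parent[oi] = order.id
        for oi, fam_idxs in enumerate(orders):
            for fi in fam_idxs:
                fam = TaxonNode(next_id, f"Family{p + 1:02d}{fi + 1:02d}", "family",
                                order_parent[oi])
                nodes.append(fam)
                next_id += 1
                family_parent[fi] = fam.id
        for fi, fam_genera in enumerate(families):
            for g in fam_genera:
                genus = TaxonNode(next_id, f"Genus{g + 1:03d}", "genus", family_parent[fi])
                nodes.append(genus)
                genus_ids.append(next_id)
                next_id += 1

    for idx in rng.choice(len(genus_ids), size=n_candidates, replace=False):
        node = nodes[genus_ids[int(idx)]]
        node.candidate = True
        node.name = f"Ca_{node.name}"
    return TaxonomyTree(nodes)


# ---------------------------------------------------------------------------
# Sequence evolution (Jukes-Cantor)


def _jc_evolve(parent: np.ndarray, divergence: float, rates: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """One JC69 branch: per-site substitution probability from the exact
    transition kernel, P(change) = 3/4 * (1 - exp(-4*d*r/3)), so divergences
    are additive along paths and closed-form identity expectations hold."""
    p_change = 0.75 * (1.0 - np.exp(-4.0 * divergence * rates / 3.0))
    hit = rng.random(parent.size) < p_change
    child = parent.copy()
    if hit.any():
        # map to base index, shift by 1..3, map back: uniform over other bases
        idx = np.searchsorted(_BASES, child[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        child[hit] = _BASES[(idx + shift) % 4]
    return child


def root_sequence(arch: RegionArchitecture, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return _decode(_BASES[rng.integers(0, 4, size=arch.total_length)])


def simulate_references(tree: TaxonomyTree, arch: RegionArchitecture,
                        cfg: SimulationConfig) -> list[ReferenceRecord]:
    """Evolve one sequence per node down the taxonomy, then emit
    ``references_per_genus`` records per genus with within-genus divergence.
    Conserved primer sites are invariant, so every record is amplifiable."""
    cfg.require_valid()
    rng = np.random.default_rng(cfg.seed)
    rates = arch.rate_array()
    root = _encode(root_sequence(arch, cfg.seed))
    node_seq: dict[int, np.ndarray] = {tree.root.id: root}
    records: list[ReferenceRecord] = []

    def visit(node: TaxonNode) -> None:
        for child in sorted(tree.children(node.id), key=lambda n: n.id):
            d = cfg.divergences.get(child.rank, 0.0)
            node_seq[child.id] = _jc_evolve(node_seq[node.id], d, rates, rng)
            if child.rank == "genus":
                lineage = tree.lineage_of(child)
                for i in range(cfg.references_per_genus):
                    seq = _jc_evolve(node_seq[child.id],
                                     cfg.divergences.get("reference", 0.0), rates, rng)
                    records.append(ReferenceRecord(
                        id=f"REF_{child.name}_{i + 1:03d}", sequence=_decode(seq),
                        lineage=lineage, candidate=child.candidate))
            else:
                visit(child)

    visit(tree.root)
    return records


# ---------------------------------------------------------------------------
# Label noise


def inject_label_noise(records: Sequence[ReferenceRecord], fraction: float,
                       seed: int) -> list[ReferenceRecord]:
    """Relabel exactly round(fraction * n) records with a genus from another
    family; originals keep their truth in ``true_lineage``."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    n = len(records)
    k = int(math.floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n, size=k, replace=False).tolist()) if k else set()
    lineages = sorted({r.lineage for r in records})
    out = []
    for i, rec in enumerate(records):
        if i in chosen:
            others = [lin for lin in lineages if lin[:5] != rec.lineage[:5]]
            if not others:
                raise ValueError("cannot relabel: no genus outside the record's family")
            new = others[int(rng.integers(0, len(others)))]
            out.append(rec.relabeled(new))
        else:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Primers and reads


@dataclass(frozen=True)
class PrimerPair:
    """Degenerate primer pair for one region, written 5'->3' on each strand."""

    region: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        validate_iupac(self.forward)
        validate_iupac(self.reverse)


def make_primer_set(arch: RegionArchitecture, root: str,
                    degenerate_except: Sequence[str] = ("V12",),
                    n_degenerate: int = 2, seed: int = 0) -> dict[str, PrimerPair]:
    """Primer pairs read off the root's conserved anchor sites.

    All regions except those in ``degenerate_except`` get ``n_degenerate``
    positions widened to a two-fold IUPAC code covering the root base,
    mirroring real primer sets where only one region's pair is non-degenerate.
    """
    two_fold = {"A": "R", "G": "R", "C": "Y", "T": "Y"}
    rng = np.random.default_rng(seed)
    pairs = {}
    for region in sorted(arch.primer_anchors):
        (fs, fe), (rs, re) = arch.primer_sites(region)
        fwd = root[fs:fe]
        rev = reverse_complement(root[rs:re])
        if region not in degenerate_except:
            for primer_idx in (0, 1):
                primer = list((fwd, rev)[primer_idx])
                pos = rng.choice(len(primer), size=n_degenerate, replace=False)
                for p in pos:
                    primer[int(p)] = two_fold[primer[int(p)]]
                if primer_idx == 0:
                    fwd = "".join(primer)
                else:
                    rev = "".join(primer)
        pairs[region] = PrimerPair(region, fwd, rev)
    return pairs


def _find_site(template: str, primer: str) -> Optional[int]:
    """Leftmost exact IUPAC-class occurrence of ``primer`` in ``template``."""
    span = len(primer)
    for pos in range(len(template) - span + 1):
        if iupac_mismatches(template[pos:pos + span], primer) == 0:
            return pos
    return None


def _instantiate(primer: str, rng: np.random.Generator) -> str:
    """Expand degenerate letters by uniform choice (PCR-style synthesis)."""
    out = []
    for p in primer:
        options = sorted(IUPAC[p])
        out.append(options[int(rng.integers(0, len(options)))] if len(options) > 1 else p)
    return "".join(out)


def _read_stream_seed(cfg_seed: int, pair: PrimerPair, direction: str) -> int:
    tag = f"{pair.region}|{direction}|{pair.forward}".encode()
    return (int(cfg_seed) * 1_000_003 + zlib.crc32(tag)) % (2**31 - 1)


def simulate_reads(records: Sequence[ReferenceRecord], primer_pair: PrimerPair,
                   direction: str, read_length: int,
                   cfg: SimulationConfig) -> list[Pyrotag]:
    """In-silico PCR + directional sequencing of every template.

    Per template: locate both primer sites, excise the amplicon (primer bases
    are re-synthesised, expanding degenerate letters uniformly), read
    ``read_length`` bases from the chosen end (reverse reads are the reverse
    complement of the amplicon), then apply substitution errors and ambiguous
    bases i.i.d. per position. Templates missing a primer site yield no read.
    """
    cfg.require_valid()
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    if read_length <= len(primer_pair.forward):
        raise ValueError("read_length must exceed the primer length")
    rng = np.random.default_rng(_read_stream_seed(cfg.seed, primer_pair, direction))
    rev_site = reverse_complement(primer_pair.reverse)
    reads: list[Pyrotag] = []
    for i, rec in enumerate(records):
        f0 = _find_site(rec.sequence, primer_pair.forward)
        if f0 is None:
            log.info("no forward primer site on %s; skipped", rec.id)
            continue
        r0 = _find_site(rec.sequence[f0 + len(primer_pair.forward):], rev_site)
        if r0 is None:
            log.info("no reverse primer site on %s; skipped", rec.id)
            continue
        r0 += f0 + len(primer_pair.forward)
        amplicon = (_instantiate(primer_pair.forward, rng)
                    + rec.sequence[f0 + len(primer_pair.forward):r0]
                    + reverse_complement(_instantiate(primer_pair.reverse, rng)))
        template = amplicon if direction == "forward" else reverse_complement(amplicon)
        arr = _encode(template[:read_length]).copy()
        if cfg.error_rate > 0:
            hit = rng.random(arr.size) < cfg.error_rate
            if hit.any():
                idx = np.searchsorted(_BASES, arr[hit])
                shift = rng.integers(1, 4, size=int(hit.sum()))
                arr[hit] = _BASES[(idx + shift) % 4]
        if cfg.ambiguity_rate > 0:
            amb = rng.random(arr.size) < cfg.ambiguity_rate
            arr[amb] = ord("N")
        truth = rec.true_lineage[-1] if rec.true_lineage else rec.lineage[-1]
        reads.append(Pyrotag(
            id=f"{primer_pair.region}_{direction[0].upper()}_{i:05d}_{rec.id}",
            sequence=_decode(arr), region=primer_pair.region,
            direction=direction, truth_genus=truth))
    return reads


def genus_abundances(genera: Sequence[str], sigma: float, seed: int) -> dict[str, float]:
    """Lognormal relative abundances, normalised to sum to 1 (uneven community)."""
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=len(genera))
    raw /= raw.sum()
    return {g: float(w) for g, w in zip(sorted(genera), raw)}


def sample_library(records: Sequence[ReferenceRecord], abundances: dict[str, float],
                   n_templates: int, seed: int) -> list[ReferenceRecord]:
    """Draw an amplicon library: templates sampled with replacement, genus
    probabilities from ``abundances``, references within a genus uniform."""
    rng = np.random.default_rng(seed)
    by_genus: dict[str, list[ReferenceRecord]] = {}
    for rec in records:
        truth = rec.true_lineage[-1] if rec.true_lineage else rec.lineage[-1]
        by_genus.setdefault(truth, []).append(rec)
    genera = sorted(g for g in by_genus if g in abundances)
    probs = np.array([abundances[g] for g in genera])
    probs /= probs.sum()
    picks = rng.choice(len(genera), size=n_templates, p=probs)
    out = []
    for gi in picks:
        pool = by_genus[genera[int(gi)]]
        out.append(pool[int(rng.integers(0, len(pool)))])
    return out
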