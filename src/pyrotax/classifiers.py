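"""The three genus-level assignment methods on one interface.

* NBC — an 8-mer naive-Bayes classifier with bootstrap confidence, in the
  canonical rRNA-classifier formulation: word prior Pr(w) = (n(w)+0.5)/(N+1),
  genus conditional (m(w)+Pr(w))/(M+1), confidence = fraction of 100 bootstrap
  trials (each scoring a random eighth of the query's distinct words) won by
  the full-data genus, propagated up the ranks.
* BH — best-hit: the top-ranked alignment hit above an identity cutoff
  (default 97%) donates its genus; candidate genera are reachable here.
* LCA — lowest common ancestor of all hits above an identity cutoff (default
  95%) within a top-score window (default 10%) of the best bit score;
  conflicting hits push the call above genus rank.

Alignment search uses a shared exact 11-mer prefilter, then a query-global /
reference-infix edit-distance alignment (edlib) rescored with blastn-like
constants to produce bit scores and Karlin-Altschul e-values. Hits are ranked
(bit score desc, identity desc, reference id asc) for determinism.
"""

from __future__ import annotations

import math
import re
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .records import Pyrotag, ReferenceRecord
from .taxonomy import (RANKS, Lineage, TaxonomyTree, lowest_common_ancestor)

METHODS = ("NBC", "BH", "LCA")


@dataclass
class ClassifierParams:
    word_size: int = 8
    bootstrap_trials: int = 100
    confidence_threshold: float = 0.80
    sweep_thresholds: tuple[float, ...] = (0.50, 0.80, 0.95, 1.00)
    bh_identity: float = 97.0
    lca_identity: float = 95.0
    lca_top_window: float = 0.10
    lca_min_support: int = 1
    max_hits: int = 50
    min_identity: float = 85.0        # desk-scale surrogate for the e-value ceiling
    evalue_ceiling: Optional[float] = None
    seed_word: int = 11
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    ka_lambda: float = 0.625
    ka_k: float = 0.41
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        if not (0.0 < self.confidence_threshold <= 1.0):
            problems.append("confidence_threshold must be in (0, 1]")
        for name, v in [("bh_identity", self.bh_identity),
                        ("lca_identity", self.lca_identity),
                        ("min_identity", self.min_identity)]:
            if not (0.0 < v <= 100.0):
                problems.append(f"{name} must be in (0, 100]")
        if not (0.0 <= self.lca_top_window < 1.0):
            problems.append("lca_top_window must be in [0, 1)")
        if self.max_hits < 1:
            problems.append("max_hits must be >= 1")
        if self.word_size < 1 or self.seed_word < 1:
            problems.append("word sizes must be positive")
        if self.bootstrap_trials < 1:
            problems.append("bootstrap_trials must be >= 1")
        if self.lca_min_support < 1:
            problems.append("lca_min_support must be >= 1")
        return problems


@dataclass
class Assignment:
    """One method's call for one tag. ``lineage`` may stop above genus rank;
    the genus flag is true only when the lineage reaches genus and passes the
    method's acceptance rule."""

    tag_id: str
    method: str
    lineage: Lineage = ()
    confidences: dict[str, float] = field(default_factory=dict)
    best_identity: Optional[float] = None
    genus_assigned: bool = False
    reason: Optional[str] = None
    # full-depth NBC call and its genus confidence, kept so confidence-threshold
    # sweeps can re-threshold without re-running the bootstrap
    genus_call: Optional[str] = None
    genus_confidence: Optional[float] = None

    @property
    def genus(self) -> Optional[str]:
        return self.lineage[-1] if self.genus_assigned else None

    def at_threshold(self, threshold: float) -> Optional[str]:
        """NBC genus call re-thresholded from the stored bootstrap confidence."""
        if self.genus_call is None or self.genus_confidence is None:
            return None
        return self.genus_call if self.genus_confidence >= threshold else None


# ---------------------------------------------------------------------------
# Naive-Bayes classifier


def _distinct_words(seq: str, k: int) -> list[str]:
    return sorted({seq[i:i + k] for i in range(len(seq) - k + 1)})


class NbcModel:
    """Trained word model: per-genus log conditionals over the training
    vocabulary plus a per-genus default for unseen words."""

    def __init__(self, genera: list[str], lineages: dict[str, Lineage],
                 vocab: dict[str, int], log_cond: np.ndarray,
                 log_unseen: np.ndarray, word_size: int,
                 skipped_genera: list[str]):
        self.genera = genera
        self.lineages = lineages
        self.vocab = vocab
        self.log_cond = log_cond          # (n_genera, n_words)
        self.log_unseen = log_unseen      # (n_genera,)
        self.word_size = word_size
        self.skipped_genera = skipped_genera


def train_nbc(references: Sequence[ReferenceRecord], taxonomy: TaxonomyTree,
              params: ClassifierParams) -> NbcModel:
    """Tally, per genus and per overlapping word, how many training sequences
    contain the word. Candidate-genus records are excluded — the model can
    only ever emit formally recognised genera."""
    k = params.word_size
    usable = [r for r in references if not r.candidate]
    for rec in usable:
        if taxonomy.find("genus", rec.genus) is None:
            raise ValueError(f"training record {rec.id} labeled with genus "
                             f"{rec.genus!r} absent from the taxonomy")
    by_genus: dict[str, list[ReferenceRecord]] = {}
    for rec in usable:
        by_genus.setdefault(rec.genus, []).append(rec)
    skipped = [g.name for g in taxonomy.genera(include_candidates=False)
               if g.name not in by_genus]

    record_words = [frozenset(_distinct_words(r.sequence, k)) for r in usable]
    n_total = len(usable)
    doc_freq: dict[str, int] = {}
    for words in record_words:
        for w in words:
            doc_freq[w] = doc_freq.get(w, 0) + 1
    vocab = {w: i for i, w in enumerate(sorted(doc_freq))}
    n_words = len(vocab)
    prior = np.empty(n_words)
    for w, i in vocab.items():
        prior[i] = (doc_freq[w] + 0.5) / (n_total + 1)

    genera = sorted(by_genus)
    lineages = {g: taxonomy.genus_lineage(g) for g in genera}
    log_cond = np.empty((len(genera), n_words))
    log_unseen = np.empty(len(genera))
    prior_unseen = 0.5 / (n_total + 1)
    for gi, genus in enumerate(genera):
        members = [record_words[i] for i, r in enumerate(usable) if r.genus == genus]
        m = np.zeros(n_words)
        for words in members:
            for w in words:
                m[vocab[w]] += 1
        M = len(members)
        log_cond[gi] = np.log((m + prior) / (M + 1))
        log_unseen[gi] = math.log(prior_unseen / (M + 1))
    return NbcModel(genera, lineages, vocab, log_cond, log_unseen, k, skipped)


def _bootstrap_seed(global_seed: int, tag_id: str) -> int:
    return (int(global_seed) * 1_000_003 + zlib.crc32(tag_id.encode())) % (2**31 - 1)


def classify_nbc(tag: Pyrotag, model: NbcModel,
                 params: ClassifierParams) -> Assignment:
    """Score the tag's distinct words against every genus; confidence at each
    rank is the fraction of bootstrap trials whose winner lies under that
    rank's node on the full-data winner's lineage. The reported lineage is
    truncated to the deepest rank meeting the confidence threshold."""
    if len(tag.sequence) < model.word_size:
        return Assignment(tag.id, "NBC", reason="shorter than word size")
    words = _distinct_words(tag.sequence, model.word_size)
    cols = np.array([model.vocab.get(w, -1) for w in words])
    n_genera = len(model.genera)
    L = np.where(cols[None, :] >= 0,
                 model.log_cond[:, np.clip(cols, 0, None)],
                 model.log_unseen[:, None])
    full_scores = L.sum(axis=1)
    winner_idx = int(np.argmax(full_scores))   # genera sorted by name: stable ties
    winner = model.genera[winner_idx]
    lineage = model.lineages[winner]

    W = len(words)
    subset = max(1, W // 8)
    rng = np.random.default_rng(_bootstrap_seed(params.seed, tag.id))
    idx = rng.integers(0, W, size=(params.bootstrap_trials, subset))
    trial_scores = L[:, idx.ravel()].reshape(n_genera, params.bootstrap_trials, subset).sum(axis=2)
    trial_winners = trial_scores.argmax(axis=0)

    # fraction of trials whose winning genus shares the ancestor at each rank
    trial_lineages = [model.lineages[model.genera[int(t)]] for t in trial_winners]
    confidences = {}
    for ri, rank in enumerate(RANKS):
        agree = sum(1 for lin in trial_lineages if lin[ri] == lineage[ri])
        confidences[rank] = agree / params.bootstrap_trials

    depth = 0
    for ri, rank in enumerate(RANKS):
        if confidences[rank] >= params.confidence_threshold:
            depth = ri + 1
        else:
            break
    genus_conf = confidences["genus"]
    return Assignment(
        tag_id=tag.id, method="NBC", lineage=lineage[:depth],
        confidences=confidences, genus_assigned=(depth == len(RANKS)),
        genus_call=winner, genus_confidence=genus_conf)


# ---------------------------------------------------------------------------
# Alignment search


@dataclass
class Hit:
    query_id: str
    ref_id: str
    identity: float       # percent over alignment columns
    length: int           # alignment columns
    score: int            # raw alignment score under the configured constants
    bitscore: float
    evalue: float


class ReferenceDb:
    """Searchable reference set: records, lineage lookup, and an inverted
    exact seed-word index used as the alignment prefilter."""

    def __init__(self, records: Sequence[ReferenceRecord], seed_word: int = 11):
        self.records = {r.id: r for r in records}
        if len(self.records) != len(records):
            raise ValueError("duplicate reference ids")
        self.seed_word = seed_word
        self.total_length = sum(len(r.sequence) for r in records)
        self._index: dict[str, set[str]] = {}
        for r in records:
            for i in range(len(r.sequence) - seed_word + 1):
                self._index.setdefault(r.sequence[i:i + seed_word], set()).add(r.id)

    def candidates_for(self, seq: str) -> list[str]:
        k = self.seed_word
        found: set[str] = set()
        for i in range(len(seq) - k + 1):
            found |= self._index.get(seq[i:i + k], set())
        return sorted(found)

    def lineage(self, ref_id: str) -> Lineage:
        return self.records[ref_id].lineage

    def is_candidate_genus(self, ref_id: str) -> bool:
        return self.records[ref_id].candidate


_CIGAR = re.compile(r"(\d+)([=XIDM])")


def _align_and_score(query: str, ref: str, params: ClassifierParams
                     ) -> Optional[tuple[float, int, int]]:
    """(identity %, alignment columns, raw score) of the query-global /
    reference-infix minimum-edit alignment, rescored with the configured
    match/mismatch/affine-gap constants. None when edlib finds no alignment."""
    res = edlib.align(query, ref, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    matches = mismatches = gaps = opens = 0
    for num, op in _CIGAR.findall(res["cigar"]):
        n = int(num)
        if op == "=":
            matches += n
        elif op in ("X", "M"):
            mismatches += n
        else:
            gaps += n
            opens += 1
    columns = matches + mismatches + gaps
    score = (params.match * matches + params.mismatch * mismatches
             - opens * params.gap_open - gaps * params.gap_extend)
    identity = 100.0 * matches / columns if columns else 0.0
    return identity, columns, score


def _bitscore(score: int, params: ClassifierParams) -> float:
    return (params.ka_lambda * score - math.log(params.ka_k)) / math.log(2.0)


def search_hits(tag: Pyrotag, db: ReferenceDb,
                params: ClassifierParams) -> list[Hit]:
    """Align the tag against every reference sharing an exact seed word,
    filter (identity surrogate for the e-value ceiling), rank, and truncate
    to the configured maximum number of hits."""
    hits: list[Hit] = []
    for ref_id in db.candidates_for(tag.sequence):
        ref = db.records[ref_id]
        scored = _align_and_score(tag.sequence, ref.sequence, params)
        if scored is None:
            continue
        identity, columns, score = scored
        if identity < params.min_identity:
            continue
        bits = _bitscore(score, params)
        evalue = len(tag.sequence) * db.total_length * math.pow(2.0, -bits)
        if params.evalue_ceiling is not None and evalue > params.evalue_ceiling:
            continue
        hits.append(Hit(tag.id, ref_id, identity, columns, score, bits, evalue))
    hits.sort(key=lambda h: (-h.bitscore, -h.identity, h.ref_id))
    return hits[:params.max_hits]


# ---------------------------------------------------------------------------
# Best-hit and LCA assignment


def assign_best_hit(tag: Pyrotag, hits: Sequence[Hit], db: ReferenceDb,
                    params: ClassifierParams) -> Assignment:
    """Genus of the first (highest bit score) hit at or above the identity
    cutoff; candidate genera are allowed. No qualifying hit -> unassigned."""
    for h in hits:
        if h.identity >= params.bh_identity:
            lineage = db.lineage(h.ref_id)
            return Assignment(tag.id, "BH", lineage=lineage, best_identity=h.identity,
                              genus_assigned=len(lineage) == len(RANKS))
    return Assignment(tag.id, "BH", reason="no hit above identity cutoff")


def assign_lca(tag: Pyrotag, hits: Sequence[Hit], taxonomy: TaxonomyTree,
               db: ReferenceDb, params: ClassifierParams) -> Assignment:
    """Lowest common ancestor of the hits within the identity cutoff and the
    top-score window. Hits to candidate-genus references are skipped (their
    names do not resolve in the formal taxonomy)."""
    qualified = [h for h in hits
                 if h.identity >= params.lca_identity
                 and not db.is_candidate_genus(h.ref_id)]
    if not qualified:
        return Assignment(tag.id, "LCA", reason="no qualifying hits")
    top = max(h.bitscore for h in qualified)
    kept = [h for h in qualified if h.bitscore >= (1.0 - params.lca_top_window) * top]
    if len(kept) < params.lca_min_support:
        return Assignment(tag.id, "LCA", reason="below min support")
    lineage = lowest_common_ancestor([db.lineage(h.ref_id) for h in kept])
    best_identity = max(h.identity for h in kept)
    return Assignment(tag.id, "LCA", lineage=lineage, best_identity=best_identity,
                      genus_assigned=len(lineage) == len(RANKS))


def classify_corpus(tags: Sequence[Pyrotag], model: NbcModel, db: ReferenceDb,
                    taxonomy: TaxonomyTree, params: ClassifierParams
                    ) -> dict[str, dict[str, Assignment]]:
    """Run all three methods over a tag set, caching alignment searches per
    unique sequence. Returns {method: {tag_id: Assignment}}."""
    out: dict[str, dict[str, Assignment]] = {m: {} for m in METHODS}
    hit_cache: dict[str, list[Hit]] = {}
    for tag in tags:
        out["NBC"][tag.id] = classify_nbc(tag, model, params)
        if tag.sequence not in hit_cache:
            hit_cache[tag.sequence] = search_hits(tag, db, params)
        hits = [Hit(tag.id, h.ref_id, h.identity, h.length, h.score,
                    h.bitscore, h.evalue) for h in hit_cache[tag.sequence]]
        out["BH"][tag.id] = assign_best_hit(tag, hits, db, params)
        out["LCA"][tag.id] = assign_lca(tag, hits, taxonomy, db, params)
    return out
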