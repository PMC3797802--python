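"""Naive-Bayes training/classification, alignment search, best-hit and LCA
assignment — each checked against an independent oracle."""

import math
import random

import numpy as np
import pytest

from pyrotax.classifiers import (ClassifierParams, Hit, ReferenceDb,
                                 _align_and_score, assign_best_hit,
                                 assign_lca, classify_nbc, search_hits,
                                 train_nbc)
from pyrotax.records import Pyrotag, ReferenceRecord
from pyrotax.taxonomy import TaxonomyTree, lowest_common_ancestor

PARAMS = ClassifierParams(seed=0)


def _lin(family, genus):
    return ("Bacteria", "P1", "C1", "O1", family, genus)


def _tree(*genus_specs, candidates=()):
    return TaxonomyTree.from_lineages([_lin(f, g) for f, g in genus_specs],
                                      candidates=candidates)


def _rec(rid, seq, family, genus, candidate=False):
    return ReferenceRecord(id=rid, sequence=seq, lineage=_lin(family, genus),
                           candidate=candidate)


def _tag(seq, tid="q"):
    return Pyrotag(id=tid, sequence=seq, region="VX")


# ---------------------------------------------------------------------------
# train_nbc


def test_training_vocabulary_is_the_set_of_overlapping_words():
    tree = _tree(("FamA", "GA"))
    params = ClassifierParams(word_size=4, seed=0)
    model = train_nbc([_rec("r1", "ACGTACGT", "FamA", "GA")], tree, params)
    overlapping = {"ACGTACGT"[i:i + 4] for i in range(5)}
    assert set(model.vocab) == overlapping
    assert len(overlapping) == 4    # ACGT occurs at two positions


def test_conditional_probabilities_match_hand_tally():
    """(m + Pr)/(M + 1) with Pr = (n + 0.5)/(N + 1), tallied independently."""
    tree = _tree(("FamA", "GA"), ("FamA", "GB"))
    refs = [_rec("a1", "AAAACCCC", "FamA", "GA"),
            _rec("a2", "AAAACGCC", "FamA", "GA"),
            _rec("b1", "GGGGTTTT", "FamA", "GB")]
    k = 4
    params = ClassifierParams(word_size=k, seed=0)
    model = train_nbc(refs, tree, params)

    words_of = [{r.sequence[i:i + k] for i in range(len(r.sequence) - k + 1)}
                for r in refs]
    N = len(refs)
    genus_members = {"GA": [0, 1], "GB": [2]}
    for word, col in model.vocab.items():
        n_w = sum(word in w for w in words_of)
        prior = (n_w + 0.5) / (N + 1)
        for gi, genus in enumerate(model.genera):
            m_w = sum(word in words_of[i] for i in genus_members[genus])
            M = len(genus_members[genus])
            expected = (m_w + prior) / (M + 1)
            assert math.isclose(math.exp(model.log_cond[gi, col]), expected)


def test_candidate_references_are_excluded_from_training():
    tree = _tree(("FamA", "GA"), ("FamB", "CandX"), candidates=["CandX"])
    refs = [_rec("a", "ACGTACGTACGT", "FamA", "GA"),
            _rec("c", "TTTTGGGGCCCC", "FamB", "CandX", candidate=True)]
    model = train_nbc(refs, tree, ClassifierParams(word_size=4, seed=0))
    assert model.genera == ["GA"]


def test_empty_genus_is_recorded_not_fatal():
    tree = _tree(("FamA", "GA"), ("FamA", "GB"))
    model = train_nbc([_rec("a", "ACGTACGTAC", "FamA", "GA")], tree,
                      ClassifierParams(word_size=4, seed=0))
    assert model.skipped_genera == ["GB"]


def test_unknown_training_label_raises():
    tree = _tree(("FamA", "GA"))
    with pytest.raises(ValueError, match="GZ"):
        train_nbc([_rec("a", "ACGTACGT", "FamA", "GZ")], tree, PARAMS)


# ---------------------------------------------------------------------------
# classify_nbc


def _disjoint_corpus():
    """Two genera with disjoint word sets (different alphabets of 2-mers)."""
    tree = _tree(("FamA", "GA"), ("FamB", "GB"))
    refs = [_rec("a1", "ACACACACACACACAC", "FamA", "GA"),
            _rec("a2", "ACACACACACACACAA", "FamA", "GA"),
            _rec("b1", "GTGTGTGTGTGTGTGT", "FamB", "GB"),
            _rec("b2", "GTGTGTGTGTGTGTGG", "FamB", "GB")]
    return tree, refs


def test_separable_training_sequence_classifies_to_own_genus_with_full_confidence():
    tree, refs = _disjoint_corpus()
    params = ClassifierParams(word_size=4, seed=0)
    model = train_nbc(refs, tree, params)
    a = classify_nbc(_tag(refs[0].sequence), model, params)
    assert a.genus == "GA"
    assert a.confidences["genus"] == 1.0
    assert a.lineage == refs[0].lineage


def test_invalid_confidence_threshold_is_flagged():
    params = ClassifierParams(word_size=4, seed=0, confidence_threshold=1.01)
    assert any("confidence_threshold" in p for p in params.validate())


def test_raising_threshold_shrinks_genus_assigned_set():
    """Assigned-set inclusion across 0.5/0.8/0.95/1.0 on a mixed corpus."""
    tree, refs = _disjoint_corpus()
    params = ClassifierParams(word_size=4, seed=0)
    model = train_nbc(refs, tree, params)
    rng = random.Random(0)
    tags = []
    for i in range(40):   # random blends of both genera's material
        cut = rng.randint(2, 14)
        seq = refs[0].sequence[:cut] + refs[2].sequence[cut:]
        tags.append(_tag(seq, f"t{i}"))
    assignments = [classify_nbc(t, model, params) for t in tags]
    previous = None
    for threshold in (0.5, 0.8, 0.95, 1.0):
        current = {a.tag_id for a in assignments
                   if a.at_threshold(threshold) is not None}
        if previous is not None:
            assert current <= previous
        previous = current


def test_winner_matches_exhaustive_posterior_enumeration():
    """Full-data winner equals brute-force scoring computed from scratch."""
    tree = _tree(("FamA", "GA"), ("FamA", "GB"))
    refs = [_rec("a1", "AAAACCCCGGGG", "FamA", "GA"),
            _rec("a2", "AAAACCCCGGTT", "FamA", "GA"),
            _rec("b1", "AAAATTTTGGGG", "FamA", "GB"),
            _rec("b2", "AAAATTTTGGTA", "FamA", "GB")]
    k = 4
    params = ClassifierParams(word_size=k, seed=0)
    model = train_nbc(refs, tree, params)
    words_of = [{r.sequence[i:i + k] for i in range(len(r.sequence) - k + 1)}
                for r in refs]
    N = len(refs)
    members = {"GA": [0, 1], "GB": [2, 3]}

    def brute_score(tag_seq, genus):
        words = {tag_seq[i:i + k] for i in range(len(tag_seq) - k + 1)}
        total = 0.0
        for w in words:
            n_w = sum(w in ws for ws in words_of)
            prior = (n_w + 0.5) / (N + 1)
            m_w = sum(w in words_of[i] for i in members[genus])
            total += math.log((m_w + prior) / (len(members[genus]) + 1))
        return total

    rng = random.Random(1)
    for i in range(30):
        donor = refs[rng.randrange(4)].sequence
        cut = rng.randint(4, 8)
        seq = donor[:cut] + refs[rng.randrange(4)].sequence[cut:]
        a = classify_nbc(_tag(seq, f"q{i}"), model, params)
        scores = {g: brute_score(seq, g) for g in ("GA", "GB")}
        best = max(sorted(scores), key=lambda g: scores[g])
        if not math.isclose(scores["GA"], scores["GB"]):
            assert a.genus_call == best


def test_tag_shorter_than_word_size_is_unassigned_with_reason():
    tree, refs = _disjoint_corpus()
    params = ClassifierParams(word_size=8, seed=0)
    model = train_nbc(refs, tree, params)
    a = classify_nbc(_tag("ACGT"), model, params)
    assert a.lineage == () and "word size" in a.reason


# ---------------------------------------------------------------------------
# search_hits


def _similar_family(n=10, L=400, seed=3):
    """References all derived from one base sequence (shared seeds
    guaranteed), split over two genera."""
    rng = random.Random(seed)
    base = "".join(rng.choice("ACGT") for _ in range(L))
    refs = []
    for i in range(n):
        seq = list(base)
        for _ in range(rng.randint(0, 25)):
            p = rng.randrange(L)
            seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
        genus = "GA" if i < n // 2 else "GB"
        refs.append(_rec(f"r{i:02d}", "".join(seq), "FamA", genus))
    return base, refs


def test_self_match_ranks_first_with_full_identity():
    base, refs = _similar_family()
    db = ReferenceDb(refs, seed_word=11)
    query = refs[4].sequence[50:350]
    hits = search_hits(_tag(query), db, PARAMS)
    assert hits[0].ref_id == "r04"
    assert hits[0].identity == 100.0
    assert hits[0].evalue < 1e-30


def test_no_shared_seed_gives_empty_hit_list():
    _, refs = _similar_family()
    db = ReferenceDb(refs, seed_word=11)
    assert search_hits(_tag("A" * 120), db, PARAMS) == []


def test_ranking_equals_brute_force_all_pairs_alignment():
    """On a small database, prefiltered search must reproduce the exhaustive
    alignment ranking under the same scoring and tie rules."""
    base, refs = _similar_family(n=10)
    db = ReferenceDb(refs, seed_word=11)
    rng = random.Random(7)
    for trial in range(5):
        start = rng.randrange(0, 80)
        query = refs[rng.randrange(10)].sequence[start:start + 300]
        got = search_hits(_tag(query), db, PARAMS)
        brute = []
        for ref in refs:   # oracle: no prefilter, align everything
            scored = _align_and_score(query, ref.sequence, PARAMS)
            identity, columns, score = scored
            if identity < PARAMS.min_identity:
                continue
            brute.append((ref.id, identity, score))
        brute.sort(key=lambda t: (-t[2], -t[1], t[0]))
        assert [(h.ref_id, h.identity, h.score) for h in got] == brute


def test_identity_cross_checked_against_affine_local_aligner():
    """Substitution-only queries: our rescored infix alignment and an
    independent local affine aligner must count the same matches."""
    from Bio import Align
    rng = random.Random(11)
    ref = "".join(rng.choice("ACGT") for _ in range(400))
    query = list(ref[100:300])
    for p in (10, 57, 120, 180):    # interior substitutions only
        query[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[query[p]]
    query = "".join(query)
    identity, columns, score = _align_and_score(query, ref, PARAMS)
    aligner = Align.PairwiseAligner(mode="local", match_score=2,
                                    mismatch_score=-3, open_gap_score=-7,
                                    extend_gap_score=-2)
    aln = aligner.align(query, ref)[0]
    matches = sum(
        sum(a == b for a, b in zip(query[qs:qe], ref[ts:te]))
        for (ts, te), (qs, qe) in zip(aln.aligned[1], aln.aligned[0]))
    assert columns == 200
    assert identity == pytest.approx(100.0 * matches / 200)


def test_max_hits_truncation():
    _, refs = _similar_family(n=10)
    db = ReferenceDb(refs, seed_word=11)
    params = ClassifierParams(max_hits=3, seed=0)
    hits = search_hits(_tag(refs[0].sequence[:300]), db, params)
    assert len(hits) == 3


# ---------------------------------------------------------------------------
# assign_best_hit / assign_lca


def _hit(ref_id, identity, bitscore):
    return Hit("q", ref_id, identity, 300, int(bitscore), float(bitscore), 1e-50)


def _assignment_db():
    refs = [_rec("rA", "A" * 40, "FamA", "GA"),
            _rec("rB", "C" * 40, "FamA", "GB"),
            _rec("rC", "G" * 40, "FamB", "GC"),
            _rec("rX", "T" * 40, "FamB", "CandX", candidate=True)]
    tree = _tree(("FamA", "GA"), ("FamA", "GB"), ("FamB", "GC"),
                 ("FamB", "CandX"), candidates=["CandX"])
    return ReferenceDb(refs, seed_word=11), tree


def test_best_hit_rules():
    db, _ = _assignment_db()
    a = assign_best_hit(_tag("x"), [_hit("rA", 98.0, 500)], db, PARAMS)
    assert a.genus == "GA" and a.best_identity == 98.0
    a = assign_best_hit(_tag("x"), [_hit("rA", 96.9, 500),
                                    _hit("rB", 96.0, 490)], db, PARAMS)
    assert a.genus is None and not a.genus_assigned
    # candidate genera are reachable through best-hit
    a = assign_best_hit(_tag("x"), [_hit("rX", 99.0, 500)], db, PARAMS)
    assert a.genus == "CandX"


def test_best_hit_tie_break_is_lexicographic_on_reference_id():
    db, _ = _assignment_db()
    tied = [_hit("rB", 98.0, 500), _hit("rA", 98.0, 500)]
    tied.sort(key=lambda h: (-h.bitscore, -h.identity, h.ref_id))
    a = assign_best_hit(_tag("x"), tied, db, PARAMS)
    assert a.genus == "GA"      # rA < rB lexicographically


def test_lca_rules():
    db, tree = _assignment_db()
    # all kept hits in one genus
    a = assign_lca(_tag("x"), [_hit("rA", 99, 500), _hit("rA", 98, 470)],
                   tree, db, PARAMS)
    assert a.genus == "GA"
    # two genera of one family: family-level call, genus flag false
    a = assign_lca(_tag("x"), [_hit("rA", 99, 500), _hit("rB", 98, 480)],
                   tree, db, PARAMS)
    assert a.lineage[-1] == "FamA" and not a.genus_assigned
    # below the identity cutoff: unassigned
    a = assign_lca(_tag("x"), [_hit("rA", 94.9, 500)], tree, db, PARAMS)
    assert a.lineage == ()
    # outside the top-score window: far hit ignored
    a = assign_lca(_tag("x"), [_hit("rA", 99, 500), _hit("rC", 96, 400)],
                   tree, db, PARAMS)
    assert a.genus == "GA"
    # candidate hits are skipped entirely
    a = assign_lca(_tag("x"), [_hit("rX", 99, 500), _hit("rA", 98, 495)],
                   tree, db, PARAMS)
    assert a.genus == "GA"


def test_lca_matches_deepest_common_prefix_oracle_on_random_hit_lists():
    db, tree = _assignment_db()
    rng = random.Random(5)
    formal = ["rA", "rB", "rC"]
    for _ in range(40):
        hits = [_hit(rng.choice(formal), rng.uniform(95, 100), rng.uniform(450, 500))
                for _ in range(6)]
        a = assign_lca(_tag("x"), hits, tree, db, PARAMS)
        top = max(h.bitscore for h in hits)
        kept = [h for h in hits if h.bitscore >= 0.9 * top]
        expected = lowest_common_ancestor([db.lineage(h.ref_id) for h in kept])
        assert a.lineage == expected


def test_lca_is_ancestor_of_best_hit_when_best_hit_qualifies():
    db, tree = _assignment_db()
    rng = random.Random(8)
    for _ in range(30):
        hits = sorted((_hit(rng.choice(["rA", "rB", "rC"]),
                            rng.uniform(97.1, 100), rng.uniform(450, 500))
                       for _ in range(5)),
                      key=lambda h: (-h.bitscore, -h.identity, h.ref_id))
        bh = assign_best_hit(_tag("x"), hits, db, PARAMS)
        lca = assign_lca(_tag("x"), hits, tree, db, PARAMS)
        assert lca.lineage == bh.lineage[:len(lca.lineage)]


def test_min_support_gate():
    db, tree = _assignment_db()
    params = ClassifierParams(lca_min_support=3, seed=0)
    a = assign_lca(_tag("x"), [_hit("rA", 99, 500)], tree, db, params)
    assert a.lineage == () and "support" in a.reason
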