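"""Shared fixtures: toy taxonomies and two desk-scale pipeline runs
(noisy defaults and a noiseless variant) computed once per session."""

from __future__ import annotations

import pytest

from pyrotax.config import demo_config
from pyrotax.pipeline import STAGES, PipelineState
from pyrotax.taxonomy import TaxonomyTree


def _run_through_classify(cfg):
    state = PipelineState()
    for name, stage in STAGES:
        state = stage(cfg, state)
        if name == "classify":
            break
    return state


@pytest.fixture(scope="session")
def demo_state(tmp_path_factory):
    """Default demo run (read errors, ambiguity, one candidate genus)
    through classification."""
    cfg = demo_config(seed=1, outdir=str(tmp_path_factory.mktemp("demo")))
    return cfg, _run_through_classify(cfg)


@pytest.fixture(scope="session")
def clean_state(tmp_path_factory):
    """Noiseless full-coverage run (no errors, no ambiguity, no candidate
    genera) through classification — the separable clean-data conditions."""
    cfg = demo_config(seed=1, outdir=str(tmp_path_factory.mktemp("clean")),
                      noiseless=True)
    return cfg, _run_through_classify(cfg)


@pytest.fixture()
def toy_taxonomy() -> TaxonomyTree:
    """Two families in one order: genera GA, GB under FamA; GC under FamB;
    plus candidate genus 'CandX' under FamB."""
    lineages = [
        ("Bacteria", "P1", "C1", "O1", "FamA", "GA"),
        ("Bacteria", "P1", "C1", "O1", "FamA", "GB"),
        ("Bacteria", "P1", "C1", "O1", "FamB", "GC"),
        ("Bacteria", "P1", "C1", "O1", "FamB", "CandX"),
    ]
    return TaxonomyTree.from_lineages(lineages, candidates=["CandX"])
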