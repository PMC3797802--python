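"""Stage orchestration: simulate -> prep -> curate -> classify (x3) -> concordance.

Each stage is an importable function taking the RunConfig plus the previous
stage's in-memory state, writing its tables under the run directory, and
logging counts in/out so the read-conservation invariant is visible. The
driver ``run_pipeline`` executes all stages, collects sha256 digests of every
output in a JSON manifest, and reruns byte-identically for a fixed config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as pio
from .classifiers import (Assignment, METHODS, NbcModel, ReferenceDb,
                          classify_corpus, classify_nbc, train_nbc)
from .config import DATASET_NAMES, RunConfig, validate_config
from .consistency import (bray_curtis_matrix, genus_profiles,
                          partition_agreement, partitions_frame,
                          profile_matrix, threshold_sweep, upgma_newick,
                          region_variation_summary)
from .read_prep import RegionPrep, dereplicate, normalize_depth, quality_filter, trim_reads
from .records import Pyrotag, ReferenceRecord
from .reference_db import (merge_databases, retention_frame, retention_table,
                           self_consistency_filter)
from .simulate import (PrimerPair, default_architecture, genus_abundances,
                       inject_label_noise, make_primer_set, sample_library,
                       simulate_reads, simulate_references, simulate_taxonomy)
from .taxonomy import TaxonomyTree

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, reason: str):
        super().__init__(f"stage {stage!r} failed: {reason}")
        self.stage = stage


@dataclass
class PipelineState:
    """Everything later stages need from earlier ones."""

    taxonomy: Optional[TaxonomyTree] = None
    primers: dict[str, PrimerPair] = field(default_factory=dict)
    references: list[ReferenceRecord] = field(default_factory=list)   # as "downloaded"
    raw_reads: dict[str, list[Pyrotag]] = field(default_factory=dict)  # dataset -> reads
    tags: dict[str, list[Pyrotag]] = field(default_factory=dict)       # normalized
    curated: list[ReferenceRecord] = field(default_factory=list)
    assignments: dict[str, dict[str, dict[str, Assignment]]] = field(
        default_factory=dict)  # dataset -> method -> tag id -> Assignment
    model: Optional[NbcModel] = None
    db: Optional[ReferenceDb] = None
    outputs: list[Path] = field(default_factory=list)


def _outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig, state: PipelineState) -> PipelineState:
    """Taxonomy, references (with optional label noise), and directional
    reads for every region from one shared amplicon library per region."""
    sim = config.simulation
    out = _outdir(config)
    arch = default_architecture()
    tree = simulate_taxonomy(sim.n_phyla, sim.n_genera, sim.seed,
                             n_candidates=sim.n_candidates)
    from .simulate import root_sequence
    root = root_sequence(arch, sim.seed)
    primers = make_primer_set(arch, root, seed=sim.seed)
    clean = simulate_references(tree, arch, sim)
    references = (inject_label_noise(clean, sim.mislabel_fraction, sim.seed + 1)
                  if sim.mislabel_fraction > 0 else clean)
    abundances = genus_abundances([g.name for g in tree.genera()],
                                  sim.abundance_sigma, sim.seed + 2)
    state.taxonomy, state.primers, state.references = tree, primers, references
    pio.write_references(references, out / "references.fasta",
                         out / "references_taxonomy.tsv")
    state.outputs += [out / "references.fasta", out / "references_taxonomy.tsv"]
    for ri, region in enumerate(sorted(config.regions)):
        library = sample_library(references, abundances, config.library_size,
                                 seed=sim.seed + 10 + ri)
        for direction in ("forward", "reverse"):
            dataset = DATASET_NAMES[(region, direction)]
            reads = simulate_reads(library, primers[region], direction,
                                   config.read_length, sim)
            state.raw_reads[dataset] = reads
            path = out / f"reads_{dataset}.fasta"
            pio.write_tags(reads, path)
            state.outputs.append(path)
            log.info("simulate: %s -> %d reads", dataset, len(reads))
    return state


def stage_prep(config: RunConfig, state: PipelineState) -> PipelineState:
    """Quality filter, primer trim, length filter, depth-normalize each
    region x direction dataset; drop reasons written per dataset."""
    out = _outdir(config)
    drop_rows = []
    for ri, region in enumerate(sorted(config.regions)):
        settings = config.regions[region]
        primer = state.primers[region]
        prep = RegionPrep(region=region, forward_primer=primer.forward,
                          reverse_primer=primer.reverse,
                          min_length=settings.min_length,
                          single_primer=settings.single_primer)
        for di, direction in enumerate(("forward", "reverse")):
            dataset = DATASET_NAMES[(region, direction)]
            reads = state.raw_reads[dataset]
            trimmed, report = trim_reads(reads, prep, config.prep)
            depth = config.dataset_depth(region, direction)
            if len(trimmed) < depth:
                raise StageError("prep", f"{dataset}: {len(trimmed)} tags "
                                 f"< depth {depth}")
            tags = normalize_depth(trimmed, depth,
                                   seed=config.prep.seed + 100 + 10 * ri + di)
            state.tags[dataset] = tags
            drop_rows += [(dataset, rid, reason) for rid, reason in report.rows()]
            log.info("prep: %s in=%d ambiguous=%d primer=%d length=%d kept=%d "
                     "normalized=%d", dataset, len(reads), len(report.ambiguous),
                     len(report.primer), len(report.length), len(trimmed), depth)
            path = out / f"tags_{dataset}.fasta"
            pio.write_tags(tags, path)
            state.outputs.append(path)
    drop_path = out / "drop_report.tsv"
    pd.DataFrame(drop_rows, columns=["dataset", "read_id", "reason"]).to_csv(
        drop_path, sep="\t", index=False)
    state.outputs.append(drop_path)
    return state


def curation_classifier(references, taxonomy, params):
    """Genus caller for self-consistency curation: an NBC model trained on
    the database's own (possibly noisy) labels, applied at the configured
    confidence threshold."""
    model = train_nbc(references, taxonomy, params)

    def call(sequence: str) -> Optional[str]:
        tag = Pyrotag(id=f"curate_{hash(sequence) & 0xffffffff:x}",
                      sequence=sequence, region="")
        a = classify_nbc(tag, model, params)
        return a.genus

    return call


def stage_curate(config: RunConfig, state: PipelineState,
                 base: Optional[list[ReferenceRecord]] = None) -> PipelineState:
    """Self-consistency filter over the downloaded references, merge with the
    (pre-cleaned) base database, and write the retention table."""
    out = _outdir(config)
    caller = curation_classifier(state.references, state.taxonomy,
                                 config.classifier)
    retained, eliminated = self_consistency_filter(
        state.references, caller, config.classifier.confidence_threshold)
    log.info("curate: retained=%d eliminated=%d", len(retained), len(eliminated))
    state.curated = merge_databases(base or [], retained)
    rows = retention_table(state.references)
    frame = retention_frame(rows)
    path = out / "retention_table.tsv"
    frame.to_csv(path, sep="\t", index=False)
    pio.write_references(state.curated, out / "curated.fasta",
                         out / "curated_taxonomy.tsv")
    state.outputs += [path, out / "curated.fasta", out / "curated_taxonomy.tsv"]
    return state


def stage_classify(config: RunConfig, state: PipelineState) -> PipelineState:
    """All three methods over every normalized dataset, against the curated
    database; assignments written one TSV per dataset."""
    out = _outdir(config)
    params = config.classifier
    state.model = train_nbc(state.curated, state.taxonomy, params)
    state.db = ReferenceDb(state.curated, seed_word=params.seed_word)
    for dataset in sorted(state.tags):
        tags = state.tags[dataset]
        assignments = classify_corpus(tags, state.model, state.db,
                                      state.taxonomy, params)
        state.assignments[dataset] = assignments
        rows = []
        for method in METHODS:
            for tid, a in sorted(assignments[method].items()):
                rows.append({
                    "tag_id": tid, "method": method,
                    "lineage": ";".join(a.lineage),
                    "confidence": a.genus_confidence if method == "NBC" else None,
                    "identity": a.best_identity,
                    "genus_assigned": a.genus_assigned,
                })
        path = out / f"assignments_{dataset}.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        state.outputs.append(path)
        n_genus = {m: sum(a.genus_assigned for a in assignments[m].values())
                   for m in METHODS}
        log.info("classify: %s genus-assigned %s", dataset, n_genus)
    return state


def stage_concordance(config: RunConfig, state: PipelineState) -> PipelineState:
    """Agreement partitions and indices per dataset, genus profiles and their
    Bray-Curtis/UPGMA structure, the confidence-threshold sweep, and the
    across-region variation summary."""
    out = _outdir(config)
    candidates = [g.name for g in state.taxonomy.genera() if g.candidate]
    all_parts = []
    parts_by_dataset = {}
    profiles = []
    sweeps = []
    for dataset in sorted(state.assignments):
        assignments = state.assignments[dataset]
        parts = partition_agreement(assignments, dataset,
                                    exclude_genera=candidates)
        parts_by_dataset[dataset] = parts
        all_parts += parts
        depth = len(assignments["NBC"])
        for method in METHODS:
            profiles.append(genus_profiles(assignments[method], depth,
                                           dataset, method))
        sweep = threshold_sweep(assignments["NBC"], assignments["BH"],
                                assignments["LCA"],
                                config.classifier.sweep_thresholds)
        sweep.insert(0, "dataset", dataset)
        sweeps.append(sweep)
    parts_path = out / "agreement_partitions.tsv"
    partitions_frame(all_parts).to_csv(parts_path, sep="\t", index=False)
    matrix = profile_matrix(profiles)
    matrix_path = out / "genus_profiles.tsv"
    matrix.to_csv(matrix_path, sep="\t", index_label="genus")
    bc = bray_curtis_matrix(matrix)
    bc_path = out / "bray_curtis.tsv"
    bc.to_csv(bc_path, sep="\t", index_label="dataset")
    newick_path = out / "upgma.nwk"
    newick_path.write_text(upgma_newick(bc) + "\n")
    sweep_path = out / "threshold_sweep.tsv"
    pd.concat(sweeps, ignore_index=True).to_csv(sweep_path, sep="\t", index=False)
    variation_path = out / "region_variation.tsv"
    region_variation_summary(parts_by_dataset).to_csv(variation_path, sep="\t",
                                                      index=False)
    state.outputs += [parts_path, matrix_path, bc_path, newick_path,
                      sweep_path, variation_path]
    return state


STAGES = (("simulate", stage_simulate), ("prep", stage_prep),
          ("curate", stage_curate), ("classify", stage_classify),
          ("concordance", stage_concordance))


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in order; returns the manifest dict. Any stage failure
    raises StageError after writing a FAILED marker next to partial outputs."""
    problems = validate_config(config)
    if problems:
        raise StageError("validate", "; ".join(problems))
    out = _outdir(config)
    state = PipelineState()
    for name, stage in STAGES:
        try:
            state = stage(config, state)
        except StageError:
            (out / "FAILED").write_text(f"stage {name}\n")
            raise
        except Exception as exc:   # noqa: BLE001 - re-raised with stage context
            (out / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise StageError(name, str(exc)) from exc
    config.save(out / "config.yaml")
    state.outputs.append(out / "config.yaml")
    manifest = pio.write_manifest(out / "manifest.json", config.to_dict(),
                                  state.outputs)
    return manifest
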