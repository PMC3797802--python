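"""Run configuration: one serializable object covering every stage.

Defaults mirror the protocol constants (80% confidence, 97%/95% identity
cutoffs, top 50 hits, min support 1, 2 primer mismatches, per-region length
minima, depth 32,000 with 24,000 for the V7&V8&V9 reverse set). The demo
configuration scales the community and depth down so a full simulate ->
prep -> curate -> classify -> concordance run completes on a laptop; the
structure of the analysis is unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .classifiers import ClassifierParams
from .read_prep import PrepParams
from .simulate import SimulationConfig

#: per-region minimum trimmed tag lengths (strictly-greater-than)
DEFAULT_MIN_LENGTH = {"V12": 250, "V34": 300, "V56": 200, "V789": 300}
#: regions trimmed with the sequencing-start primer only
DEFAULT_SINGLE_PRIMER = ("V34", "V789")
#: normalization depth per dataset (region x direction); reverse V789 lower
DEFAULT_DEPTH = {"V987": 24_000}
DEFAULT_DEPTH_OTHER = 32_000

#: dataset naming: forward keeps the region name order, reverse flips it
DATASET_NAMES = {
    ("V12", "forward"): "V12", ("V12", "reverse"): "V21",
    ("V34", "forward"): "V34", ("V34", "reverse"): "V43",
    ("V56", "forward"): "V56", ("V56", "reverse"): "V65",
    ("V789", "forward"): "V789", ("V789", "reverse"): "V987",
}


@dataclass
class RegionSettings:
    min_length: int
    depth: int
    single_primer: bool = False

    def validate(self, region: str) -> list[str]:
        out = []
        if self.min_length <= 0:
            out.append(f"regions[{region}].min_length must be positive")
        if self.depth <= 0:
            out.append(f"regions[{region}].depth must be positive")
        return out


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    prep: PrepParams = field(default_factory=PrepParams)
    regions: dict[str, RegionSettings] = field(default_factory=dict)
    read_length: int = 420
    library_size: int = 160
    outdir: str = "runs/demo"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            self.regions = {
                r: RegionSettings(min_length=DEFAULT_MIN_LENGTH[r],
                                  depth=DEFAULT_DEPTH_OTHER,
                                  single_primer=r in DEFAULT_SINGLE_PRIMER)
                for r in DEFAULT_MIN_LENGTH
            }

    def dataset_depth(self, region: str, direction: str) -> int:
        name = DATASET_NAMES[(region, direction)]
        base = self.regions[region].depth
        if base == DEFAULT_DEPTH_OTHER and name in DEFAULT_DEPTH:
            return DEFAULT_DEPTH[name]
        # scaled-down runs keep the 32k:24k depth ratio for the V987 set
        return int(base * DEFAULT_DEPTH.get(name, DEFAULT_DEPTH_OTHER)
                   / DEFAULT_DEPTH_OTHER)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifier"]["sweep_thresholds"] = list(
            self.classifier.sweep_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = SimulationConfig(**d.pop("simulation", {}))
        clf = d.pop("classifier", {})
        clf["sweep_thresholds"] = tuple(clf.get("sweep_thresholds",
                                                (0.50, 0.80, 0.95, 1.00)))
        classifier = ClassifierParams(**clf)
        prep = PrepParams(**d.pop("prep", {}))
        regions = {name: RegionSettings(**r)
                   for name, r in d.pop("regions", {}).items()}
        return cls(simulation=sim, classifier=classifier, prep=prep,
                   regions=regions, **d)

    def save(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def validate_config(config: RunConfig) -> list[str]:
    """All invariant violations, as human-readable strings; never raises."""
    problems: list[str] = []
    problems += config.simulation.validate()
    problems += config.classifier.validate()
    problems += config.prep.validate()
    if not config.regions:
        problems.append("no regions defined")
    for region, settings in config.regions.items():
        if (region, "forward") not in DATASET_NAMES:
            problems.append(f"unknown region {region!r}")
            continue
        problems += settings.validate(region)
    if config.read_length <= 0:
        problems.append("read_length must be positive")
    if config.library_size <= 0:
        problems.append("library_size must be positive")
    return problems


def demo_config(seed: int = 0, outdir: str = "runs/demo",
                noiseless: bool = False) -> RunConfig:
    """Desk-scale run: 20 genera over 4 phyla, 3 references each, 4 regions x
    2 directions at depth 100 (75 for V987). ``noiseless`` zeroes the read
    error/ambiguity rates and lengthens reads to cover every amplicon, the
    configuration used for the clean-data concordance checks."""
    sim = SimulationConfig(seed=seed)
    if noiseless:
        sim.error_rate = 0.0
        sim.ambiguity_rate = 0.0
        sim.n_candidates = 0
    cfg = RunConfig(
        simulation=sim,
        classifier=ClassifierParams(seed=seed),
        prep=PrepParams(seed=seed, depth=100),
        regions={r: RegionSettings(min_length=DEFAULT_MIN_LENGTH[r], depth=100,
                                   single_primer=r in DEFAULT_SINGLE_PRIMER)
                 for r in DEFAULT_MIN_LENGTH},
        read_length=470 if noiseless else 420,
        library_size=160,
        outdir=outdir,
        seed=seed,
    )
    return cfg
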