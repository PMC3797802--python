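"""Shared setup for the numbered analysis scripts: one demo-scale study
configuration (seed 1) and a helper that replays the deterministic pipeline
up to a named stage so each script can run standalone.

Bulky per-run artifacts (FASTAs, per-tag assignment tables) live under
scratch/; the scripts copy their small summary tables into results/.
"""

import shutil
from pathlib import Path

from pyrotax.config import demo_config
from pyrotax.pipeline import STAGES, PipelineState

_ROOT = Path(__file__).resolve().parent.parent
RESULTS = _ROOT / "results"
RUN_DIR = _ROOT / "scratch" / "demo_run"
SEED = 1


def study_config(noiseless: bool = False):
    outdir = RUN_DIR if not noiseless else RUN_DIR.parent / "demo_run_noiseless"
    return demo_config(seed=SEED, outdir=str(outdir), noiseless=noiseless)


def run_until(cfg, last_stage: str) -> PipelineState:
    state = PipelineState()
    for name, stage in STAGES:
        state = stage(cfg, state)
        if name == last_stage:
            break
    return state


def publish(cfg, *filenames: str) -> None:
    """Copy small summary tables from the run directory into results/."""
    RESULTS.mkdir(exist_ok=True)
    for fname in filenames:
        src = Path(cfg.outdir) / fname
        if src.exists():
            shutil.copy(src, RESULTS / fname)
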