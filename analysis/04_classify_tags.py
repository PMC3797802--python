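"""Classify every normalized dataset with the three methods — the 8-mer
naive-Bayes classifier at 80% bootstrap confidence, best-hit at 97%
identity, and the lowest common ancestor at 95% identity within a 10%
bit-score window — against the curated reference database.

Prints per-dataset genus-assignment counts (the Fig 1-style view) and
writes one assignment TSV per dataset.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import run_until, study_config  # noqa: E402

from pyrotax.classifiers import METHODS  # noqa: E402


def main() -> None:
    cfg = study_config()
    state = run_until(cfg, "classify")
    print("fraction of tags assigned at genus level:")
    print("dataset  " + "  ".join(f"{m:>5s}" for m in METHODS))
    for dataset in sorted(state.assignments):
        assignments = state.assignments[dataset]
        n = len(assignments["NBC"])
        fracs = [sum(a.genus_assigned for a in assignments[m].values()) / n
                 for m in METHODS]
        print(f"  {dataset:5s}  " + "  ".join(f"{f:5.1%}" for f in fracs))
    print(f"assignment tables under {cfg.outdir}")


if __name__ == "__main__":
    main()
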