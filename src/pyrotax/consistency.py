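"""Agreement among the three assignment methods, per region and genus.

The central object is the per-(region, genus) partition of tags by *which
subset of methods* assigned the tag to that genus: all three (n3), exactly
one pair (n2, three pairs), or exactly one method (n1, three methods). The
denominator is every tag any method assigned to the genus, so
n3 + sum(n2) + sum(n1) = denominator by construction. Two derived indices
quantify classifier bias per genus: potential overestimation (tags only the
naive-Bayes method assigned, as a share of the denominator) and potential
underestimation (tags only BH and/or LCA assigned).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .classifiers import Assignment, METHODS, NbcModel, ClassifierParams, classify_nbc
from .records import Pyrotag
from .taxonomy import RANK_INDEX, TaxonomyTree

_PAIRS = (("BH", "LCA"), ("BH", "NBC"), ("LCA", "NBC"))


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class AgreementPartition:
    region: str
    genus: str
    n3: int = 0
    n2: dict[tuple[str, str], int] = field(
        default_factory=lambda: {p: 0 for p in _PAIRS})
    n1: dict[str, int] = field(default_factory=lambda: {m: 0 for m in METHODS})

    @property
    def denominator(self) -> int:
        return self.n3 + sum(self.n2.values()) + sum(self.n1.values())


def genus_calls(assignments: Mapping[str, Assignment]) -> dict[str, Optional[str]]:
    """tag id -> genus name (None when unassigned or above genus rank)."""
    return {tid: a.genus for tid, a in assignments.items()}


def partition_agreement(assignments_by_method: Mapping[str, Mapping[str, Assignment]],
                        region: str,
                        exclude_genera: Sequence[str] = (),
                        ) -> list[AgreementPartition]:
    """Count, per genus, tags by the subset of methods that assigned them.

    A tag given three different genera contributes one n1 count to each of the
    three genera. Genera in ``exclude_genera`` (candidate genera, which are
    structurally BH-only) are left out of the three-method partition.
    """
    universes = {m: set(assignments_by_method[m]) for m in METHODS}
    ref = universes[METHODS[0]]
    for m, u in universes.items():
        if u != ref:
            diff = sorted(u ^ ref)
            raise ValueError(f"tag universes differ between methods "
                             f"({m} vs {METHODS[0]}): {diff[:10]}")
    calls = {m: genus_calls(assignments_by_method[m]) for m in METHODS}
    excluded = set(exclude_genera)
    partitions: dict[str, AgreementPartition] = {}
    for tid in ref:
        per_method = {m: calls[m][tid] for m in METHODS}
        for genus in {g for g in per_method.values() if g is not None}:
            if genus in excluded:
                continue
            supporters = tuple(sorted(m for m, g in per_method.items() if g == genus))
            part = partitions.setdefault(genus, AgreementPartition(region, genus))
            if len(supporters) == 3:
                part.n3 += 1
            elif len(supporters) == 2:
                part.n2[supporters] += 1
            else:
                part.n1[supporters[0]] += 1
    return [partitions[g] for g in sorted(partitions)]


def overestimation_index(p: AgreementPartition) -> Optional[float]:
    """Percent of the genus's tags assigned exclusively by the naive-Bayes
    method; None (not detected) when no method assigned any tag."""
    if p.denominator == 0:
        return None
    return _round1(100.0 * p.n1["NBC"] / p.denominator)


def underestimation_index(p: AgreementPartition) -> Optional[float]:
    """Percent of the genus's tags assigned exclusively by BH and/or LCA."""
    if p.denominator == 0:
        return None
    n = p.n2[("BH", "LCA")] + p.n1["BH"] + p.n1["LCA"]
    return _round1(100.0 * n / p.denominator)


def partitions_frame(partitions: Sequence[AgreementPartition]) -> pd.DataFrame:
    rows = []
    for p in partitions:
        rows.append({
            "region": p.region, "genus": p.genus, "n3": p.n3,
            "n2_BH_LCA": p.n2[("BH", "LCA")],
            "n2_BH_NBC": p.n2[("BH", "NBC")],
            "n2_LCA_NBC": p.n2[("LCA", "NBC")],
            "n1_BH": p.n1["BH"], "n1_LCA": p.n1["LCA"], "n1_NBC": p.n1["NBC"],
            "denominator": p.denominator,
            "overestimation_pct": overestimation_index(p),
            "underestimation_pct": underestimation_index(p),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Profiles and distances


@dataclass
class GenusProfile:
    """Per-genus percent of total tags for one (region, method) dataset.
    Genera with zero tags are absent; the smallest representable abundance
    is one tag, i.e. 100/depth percent."""

    region: str
    method: str
    percentages: dict[str, float]

    def display(self) -> dict[str, float]:
        return {g: _round1(v) for g, v in self.percentages.items()}


def detection_limit_pct(depth: int, decimals: int = 3) -> float:
    """Smallest nonzero relative abundance at the normalization depth
    (one tag), as a percentage rounded half-up."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(100.0 / depth)).quantize(q, rounding=ROUND_HALF_UP))


def genus_profiles(assignments: Mapping[str, Assignment], depth: int,
                   region: str, method: str) -> GenusProfile:
    counts: dict[str, int] = {}
    for a in assignments.values():
        g = a.genus
        if g is not None:
            counts[g] = counts.get(g, 0) + 1
    return GenusProfile(region, method,
                        {g: 100.0 * c / depth for g, c in sorted(counts.items())})


def profile_matrix(profiles: Sequence[GenusProfile]) -> pd.DataFrame:
    """Genus x dataset percent matrix (absent genus = 0) with
    'region/method' column labels."""
    cols = {}
    genera: set[str] = set()
    for p in profiles:
        genera |= set(p.percentages)
    index = sorted(genera)
    for p in profiles:
        cols[f"{p.region}/{p.method}"] = [p.percentages.get(g, 0.0) for g in index]
    return pd.DataFrame(cols, index=index)


def bray_curtis_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between dataset columns:
    BC(x, y) = sum|x-y| / sum(x+y); two all-zero profiles get distance 0."""
    cols = list(matrix.columns)
    n = len(cols)
    out = np.zeros((n, n))
    arr = matrix.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = arr[:, i], arr[:, j]
            denom = float((x + y).sum())
            if denom == 0.0:
                warnings.warn(f"all-zero profiles {cols[i]} vs {cols[j]}; distance 0")
                d = 0.0
            else:
                d = float(np.abs(x - y).sum() / denom)
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=cols, columns=cols)


def upgma_newick(distances: pd.DataFrame) -> str:
    """Average-linkage (UPGMA) dendrogram over the distance matrix columns,
    serialized as Newick with ultrametric branch lengths."""
    arr = distances.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T) or not np.allclose(np.diag(arr), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    labels = list(distances.columns)
    if len(labels) == 1:
        return f"{labels[0]}:0;"
    link = hierarchy.linkage(squareform(arr, checks=False), method="average")
    tree = hierarchy.to_tree(link)

    def emit(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        length = parent_height - node.dist / 2.0
        left = emit(node.left, node.dist / 2.0)
        right = emit(node.right, node.dist / 2.0)
        return f"({left},{right}):{length:.6g}"

    root_height = tree.dist / 2.0
    left = emit(tree.left, root_height)
    right = emit(tree.right, root_height)
    return f"({left},{right});"


# ---------------------------------------------------------------------------
# Threshold sweep


def threshold_sweep(nbc_assignments: Mapping[str, Assignment],
                    bh_assignments: Mapping[str, Assignment],
                    lca_assignments: Mapping[str, Assignment],
                    thresholds: Sequence[float] = (0.50, 0.80, 0.95, 1.00),
                    ) -> pd.DataFrame:
    """Re-threshold the stored NBC bootstrap confidences and tabulate, per
    threshold: fraction of tags genus-assigned by NBC, fraction solely NBC
    (no other method assigned the same genus), and fraction shared with BH or
    LCA. The solely-NBC fraction of total tags is non-increasing in the
    threshold (asserted); the ratio of solely-NBC to currently-assigned tags
    is also reported but its denominator shrinks with the threshold.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    tags = sorted(nbc_assignments)
    n = len(tags)
    bh = genus_calls(bh_assignments)
    lca = genus_calls(lca_assignments)
    rows = []
    prev_solely = None
    for t in thresholds:
        assigned = solely = shared = 0
        for tid in tags:
            g = nbc_assignments[tid].at_threshold(t)
            if g is None:
                continue
            assigned += 1
            if bh.get(tid) == g or lca.get(tid) == g:
                shared += 1
            else:
                solely += 1
        frac_solely = solely / n if n else 0.0
        rows.append({
            "threshold": t,
            "assigned_fraction": assigned / n if n else 0.0,
            "solely_nbc_fraction": frac_solely,
            "shared_fraction": shared / n if n else 0.0,
            "solely_nbc_of_assigned": solely / assigned if assigned else 0.0,
        })
        assert prev_solely is None or frac_solely <= prev_solely + 1e-12, \
            "solely-NBC fraction must be non-increasing in the threshold"
        prev_solely = frac_solely
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Region variation and rank escalation


def region_variation_summary(partitions_by_region: Mapping[str, Sequence[AgreementPartition]],
                             ) -> pd.DataFrame:
    """Per genus: max/min fold (and log10) of three-method-consistent counts
    across regions. Genera with a zero-count region are flagged instead of
    ratioed; genera absent everywhere are flagged not-detected."""
    regions = sorted(partitions_by_region)
    genera: set[str] = set()
    counts: dict[tuple[str, str], int] = {}
    for region, parts in partitions_by_region.items():
        for p in parts:
            genera.add(p.genus)
            counts[(region, p.genus)] = p.n3
    rows = []
    for genus in sorted(genera):
        n3s = [counts.get((r, genus), 0) for r in regions]
        row = {"genus": genus}
        row.update({f"n3_{r}": c for r, c in zip(regions, n3s)})
        if all(c == 0 for c in n3s):
            row.update(fold=None, log10_fold=None, flag="not-detected")
        elif any(c == 0 for c in n3s):
            row.update(fold=None, log10_fold=None, flag="zero-count-region")
        else:
            fold = max(n3s) / min(n3s)
            row.update(fold=fold, log10_fold=math.log10(fold), flag="")
        rows.append(row)
    return pd.DataFrame(rows)


def rank_escalation_check(tags: Sequence[Pyrotag], genus: str,
                          model: NbcModel, taxonomy: TaxonomyTree,
                          params: ClassifierParams,
                          ranks: Sequence[str] = ("family", "order"),
                          ) -> dict[str, float]:
    """For tags solely assigned to ``genus`` by BH or LCA: the fraction whose
    naive-Bayes call, at the configured confidence threshold, matches the
    genus's expected ancestor at each higher rank."""
    expected = taxonomy.genus_lineage(genus)
    if not tags:
        return {r: float("nan") for r in ranks}
    agree = {r: 0 for r in ranks}
    for tag in tags:
        a = classify_nbc(tag, model, params)
        for rank in ranks:
            ri = RANK_INDEX[rank]
            if len(a.lineage) > ri and a.lineage[ri] == expected[ri]:
                agree[rank] += 1
    return {r: agree[r] / len(tags) for r in ranks}
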