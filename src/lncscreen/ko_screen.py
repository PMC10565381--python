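"""Knockout-vs-wildtype induction-ratio screen for regulated genes.

The screen compares how a stimulus induces each gene in knockout (KO) versus
wildtype (WT) animals, using group-mean FPKM at baseline (0 h) and after
stimulation (4 h).  Two ratio statistics are computed per gene:

induction difference ratio
    ``r_diff = (FPKM_KO4h - FPKM_KO0h) / (FPKM_WT4h - FPKM_WT0h)``
relative fold-change ratio
    ``r_fc = (FPKM_KO4h / FPKM_KO0h) / (FPKM_WT4h / FPKM_WT0h)``

A gene is called regulated when BOTH statistics fall outside [0.5, 2]
(each must be > 2 or < 0.5).  Before the ratios, genes with fewer than five
total reads in every one of the four groups are removed as unexpressed.
Survivors are hierarchically clustered (complete linkage, Euclidean, on the
log10(FPKM + 1e-6) row-z transform) into three expression-profile classes
named I, II and III by descending cluster size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .diffexpr import cluster_transform

__all__ = [
    "GROUPS",
    "ScreenRecord",
    "ScreenConfig",
    "RegulatedGeneSet",
    "low_count_filter",
    "induction_difference_ratio",
    "relative_foldchange_ratio",
    "select_regulated",
    "cluster_classes",
    "run_screen",
]

GROUPS = ("WT0h", "WT4h", "KO0h", "KO4h")
CLASS_LABELS = ("I", "II", "III")


@dataclass(frozen=True)
class ScreenRecord:
    """Group-mean FPKM and group-total read counts for one gene."""

    gene_id: str
    fpkm: dict[str, float]
    reads: dict[str, int]

    def __post_init__(self) -> None:
        for table, kind in ((self.fpkm, "fpkm"), (self.reads, "reads")):
            missing = set(GROUPS) - set(table)
            if missing:
                raise ValueError(f"{self.gene_id}: missing {kind} for {missing}")
        if any(v < 0 for v in self.fpkm.values()):
            raise ValueError(f"{self.gene_id}: negative FPKM")
        if any(v < 0 for v in self.reads.values()):
            raise ValueError(f"{self.gene_id}: negative read total")


@dataclass(frozen=True)
class ScreenConfig:
    """Ratio thresholds, low-count cutoff and the FPKM pseudocount.

    ``low_in_all_groups=True`` removes a gene only when its reads are below
    ``min_reads`` in every group (the literal "in each group" reading); set
    False for the stricter any-group variant.
    """

    ratio_hi: float = 2.0
    ratio_lo: float = 0.5
    min_reads: int = 5
    epsilon: float = 0.01
    low_in_all_groups: bool = True

    def __post_init__(self) -> None:
        if not self.ratio_lo < 1 < self.ratio_hi:
            raise ValueError("need ratio_lo < 1 < ratio_hi")
        if self.min_reads < 0 or self.epsilon < 0:
            raise ValueError("min_reads and epsilon must be >= 0")


@dataclass
class RegulatedGeneSet:
    """Screen output: selected genes with their ratios and profile classes."""

    selected: list[str]
    ratios: pd.DataFrame  # index: all screened genes; columns r_diff, r_fc, selected
    classes: dict[str, str] = field(default_factory=dict)


def low_count_filter(
    records: list[ScreenRecord], config: ScreenConfig = ScreenConfig()
) -> tuple[list[ScreenRecord], list[str]]:
    """Remove unexpressed genes; returns (retained, removed_ids)."""
    retained: list[ScreenRecord] = []
    removed: list[str] = []
    for r in records:
        low = [r.reads[g] < config.min_reads for g in GROUPS]
        drop = all(low) if config.low_in_all_groups else any(low)
        if drop:
            removed.append(r.gene_id)
        else:
            retained.append(r)
    return retained, removed


def induction_difference_ratio(r: ScreenRecord, epsilon: float = 0.0) -> float:
    """Ratio of FPKM induction differences, KO over WT.

    The pseudocount cancels in each difference, so it only matters through
    the degenerate-denominator convention: a WT difference of exactly 0 gives
    a signed-infinity sentinel (NaN when the KO difference is also 0).
    """
    num = (r.fpkm["KO4h"] + epsilon) - (r.fpkm["KO0h"] + epsilon)
    den = (r.fpkm["WT4h"] + epsilon) - (r.fpkm["WT0h"] + epsilon)
    if den == 0:
        if num == 0:
            return math.nan
        return math.copysign(math.inf, num)
    return num / den


def relative_foldchange_ratio(r: ScreenRecord, epsilon: float = 0.01) -> float:
    """Ratio of FPKM fold changes, KO over WT, with pseudocount ``epsilon``
    added to every FPKM (required nonzero when any FPKM is 0)."""
    vals = {g: r.fpkm[g] + epsilon for g in GROUPS}
    if vals["KO0h"] == 0 or vals["WT0h"] == 0 or vals["WT4h"] == 0:
        raise ValueError(
            f"{r.gene_id}: zero FPKM with epsilon=0; use a nonzero epsilon"
        )
    return (vals["KO4h"] / vals["KO0h"]) / (vals["WT4h"] / vals["WT0h"])


def _outside_band(x: float, lo: float, hi: float) -> bool:
    if math.isnan(x):
        return False
    return x > hi or x < lo


def select_regulated(
    records: list[ScreenRecord], config: ScreenConfig = ScreenConfig()
) -> RegulatedGeneSet:
    """Call regulated genes: both ratio statistics outside [ratio_lo, ratio_hi].

    A negative or -inf ``r_diff`` satisfies the "< 0.5" arm; +inf satisfies
    "> 2"; NaN (0/0) satisfies neither.
    """
    rows = []
    for r in records:
        r_diff = induction_difference_ratio(r)
        r_fc = relative_foldchange_ratio(r, epsilon=config.epsilon)
        sel = _outside_band(r_diff, config.ratio_lo, config.ratio_hi) and _outside_band(
            r_fc, config.ratio_lo, config.ratio_hi
        )
        rows.append((r.gene_id, r_diff, r_fc, sel))
    ratios = pd.DataFrame(
        rows, columns=["gene_id", "r_diff", "r_fc", "selected"]
    ).set_index("gene_id")
    selected = ratios.index[ratios["selected"]].tolist()
    return RegulatedGeneSet(selected=selected, ratios=ratios)


def cluster_classes(fpkm_rows: pd.DataFrame, k: int = 3) -> dict[str, str]:
    """Cut a complete-linkage tree at ``k`` expression-profile classes.

    Rows (genes, over the per-sample FPKM columns) are first passed through
    the heatmap transform (log10 + pseudocount, row z-score), then clustered
    with Euclidean distance and complete linkage.  Cluster labels I, II, ...
    are assigned by descending cluster size; ties broken by the
    lexicographically smallest member gene id.  All-identical rows cannot be
    split and raise a ValueError.
    """
    if len(fpkm_rows) < k:
        raise ValueError(f"need >= {k} genes to cut {k} classes, got {len(fpkm_rows)}")
    z = cluster_transform(fpkm_rows)
    d = pdist(z.to_numpy(), metric="euclidean")
    if np.all(d == 0):
        raise ValueError("all expression profiles identical; cannot cut classes")
    tree = linkage(d, method="complete")
    assignments = fcluster(tree, t=k, criterion="maxclust")
    members: dict[int, list[str]] = {}
    for gene, c in zip(fpkm_rows.index, assignments):
        members.setdefault(int(c), []).append(gene)
    order = sorted(members, key=lambda c: (-len(members[c]), min(members[c])))
    labels = {}
    for rank, c in enumerate(order):
        name = CLASS_LABELS[rank] if rank < len(CLASS_LABELS) else str(rank + 1)
        for gene in members[c]:
            labels[gene] = name
    return labels


def run_screen(
    records: list[ScreenRecord],
    fpkm_matrix: pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
    k: int = 3,
) -> tuple[RegulatedGeneSet, list[str]]:
    """Full screen: low-count removal, ratio selection, profile clustering.

    ``fpkm_matrix`` holds per-sample FPKM rows used for clustering the
    selected genes.  Returns the regulated set (with classes filled in when
    >= k genes are selected) and the low-count-removed gene ids.
    """
    retained, removed = low_count_filter(records, config)
    result = select_regulated(retained, config)
    if len(result.selected) >= k:
        result.classes = cluster_classes(fpkm_matrix.loc[result.selected], k=k)
    return result, removed
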