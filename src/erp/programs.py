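"""Clustering of regulated genes into the three ER-stress expression programs.

Regulated genes separate into an early-induction program (maximal at
1-2 h, relaxing later), a late-induction program (ramping to 5-8 h) and a
repression program (down at all timepoints). Genes are clustered by
average-linkage agglomerative clustering on 1 - Spearman rho of their TPM
profiles, the tree is cut at k = 3, and clusters are mapped to program
names from their mean WT LFC profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .expression import ExpressionMatrix, LfcTable

log = logging.getLogger(__name__)

PROGRAMS = ("early", "late", "repression")


@dataclass
class ClusterResult:
    linkage: np.ndarray            # scipy merge history (heights non-decreasing)
    labels: pd.Series              # gene_id -> cluster index (1..k)
    distance_metric: str
    linkage_method: str
    k: int


@dataclass
class ProgramAssignment:
    """gene -> (cluster index, program name); programs partition the genes."""

    table: pd.DataFrame            # columns: cluster, program
    cluster_profiles: pd.DataFrame  # cluster mean LFC per timepoint

    def genes(self, program: str) -> set[str]:
        return set(self.table.index[self.table["program"] == program])

    @property
    def sizes(self) -> dict[str, int]:
        return {p: int((self.table["program"] == p).sum()) for p in PROGRAMS}


def spearman_distance(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Spearman rho between gene rows.

    Constant rows have undefined rank correlation; their distances to all
    other genes are set to 1 (uninformative) with a logged warning.
    """
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    ranks = np.apply_along_axis(rankdata, 1, values.to_numpy(float))
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.warning("%d constant profile(s); distances set to 1", int(constant.sum()))
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * ranks.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (centered @ centered.T) / denom
    d = 1.0 - rho
    d[constant, :] = 1.0
    d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=values.index, columns=values.index)


def hierarchical_cluster(
    distance: pd.DataFrame, k: int = 3, method: str = "average"
) -> ClusterResult:
    """Agglomerative clustering of a precomputed distance matrix cut to k."""
    n = distance.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes ({n})")
    condensed = squareform(distance.to_numpy(float), checks=False)
    linkage = hierarchy.linkage(condensed, method=method)
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return ClusterResult(
        linkage=linkage,
        labels=pd.Series(labels, index=distance.index, name="cluster"),
        distance_metric="1-spearman",
        linkage_method=method,
        k=k,
    )


def _label_cluster(profile: pd.Series) -> str:
    """Map a cluster mean LFC time profile onto a program name.

    early: the early timepoints (first half, e.g. 1-2 h) carry the maximal
    positive mean; late: the late timepoints (5-8 h) do; repression:
    overall mean negative.
    """
    if profile.mean() < 0:
        return "repression"
    times = sorted(profile.index)
    half = len(times) // 2
    early_mean = profile[times[:half]].mean()
    late_mean = profile[times[half:]].mean()
    return "early" if early_mean >= late_mean else "late"


def assign_program_labels(clusters: ClusterResult, lfc_wt: pd.DataFrame) -> ProgramAssignment:
    """Label k = 3 clusters as early / late / repression from WT LFC means.

    ``lfc_wt`` is a gene x timepoint frame (the WT block of an LfcTable).
    Raises if two clusters map to the same program, which signals a wrong
    k or degenerate input.
    """
    if clusters.k != 3:
        raise ValueError("program labeling requires exactly 3 clusters")
    common = clusters.labels.index.intersection(lfc_wt.index)
    if len(common) < len(clusters.labels):
        raise ValueError("LFC table does not cover all clustered genes")
    profiles = lfc_wt.loc[clusters.labels.index].groupby(clusters.labels).mean()
    # deterministic tie-break: process clusters by descending |mean LFC|
    order = profiles.mean(axis=1).abs().sort_values(ascending=False).index
    labels: dict[int, str] = {}
    for cluster_idx in order:
        labels[cluster_idx] = _label_cluster(profiles.loc[cluster_idx])
    if len(set(labels.values())) != 3:
        raise ValueError(
            "clusters do not map to distinct programs; cluster mean profiles:\n"
            f"{profiles.round(3)}"
        )
    table = pd.DataFrame(
        {
            "cluster": clusters.labels,
            "program": clusters.labels.map(labels),
        }
    )
    return ProgramAssignment(table=table, cluster_profiles=profiles)


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores (population SD), used only for heatmap display.

    Zero-variance rows come back all-zero with a warning rather than NaN.
    """
    arr = values.to_numpy(float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        log.warning("%d zero-variance row(s) z-scored to 0", int(flat.sum()))
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mean) / sd, index=values.index, columns=values.columns)


def program_medians(
    lfc: pd.DataFrame, genes: set[str], timepoint: float, direction: str = "induction"
) -> float:
    """Median percent change of a gene set at one timepoint.

    Works on linear fold changes: induction is 100*(median(2^lfc) - 1),
    repression is 100*(1 - median(2^lfc)).
    """
    if not genes:
        raise ValueError("empty gene set")
    present = lfc.index.intersection(list(genes))
    fold = np.exp2(lfc.loc[present, timepoint])
    med = float(fold.median())
    if direction == "induction":
        return 100.0 * (med - 1.0)
    if direction == "repression":
        return 100.0 * (1.0 - med)
    raise ValueError(f"direction must be induction or repression, got {direction!r}")
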