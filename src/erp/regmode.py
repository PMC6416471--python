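"""Translation-only vs mRNA+translation repression classification.

Paired RNA-seq and Ribo-seq log2 fold changes decompose repression into a
translational component and an mRNA-level component. The repressed
universe is gated on translational repression of at least the fold
cutoff; a gene is "mRNA and translation" repressed when the RNA-level LFC
also clears the cutoff, "translation only" when it does not. A threshold
scan over a cutoff grid checks robustness of the mode fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MODES = ("mrna_and_translation", "translation_only", "not_repressed")


@dataclass(frozen=True)
class RegModeCall:
    gene_id: str
    lfc_rna: float
    lfc_ribo: float
    delta_lfc: float  # ribo - rna: the translation-specific component
    mode: str
    mrna_only: bool = False  # repressed at mRNA level but not translationally


@dataclass
class ThresholdScan:
    cutoffs: list[float]
    counts: pd.DataFrame          # cutoff x mode counts
    mrna_fraction: pd.Series      # fraction of repressed genes with mRNA-level repression

    def repressed_counts(self) -> pd.Series:
        return self.counts["mrna_and_translation"] + self.counts["translation_only"]


def classify_mode(
    gene_id: str, lfc_rna: float, lfc_ribo: float, fold_cutoff: float = 1.5
) -> RegModeCall:
    """Classify one gene's repression mode at a linear fold cutoff.

    With c = log2(fold_cutoff): translational repression "or more" is
    inclusive (lfc_ribo <= -c); mRNA repression "less than" the cutoff is
    strict (lfc_rna > -c). Genes failing the translational gate are
    not_repressed regardless of their RNA level (flagged ``mrna_only``
    when the RNA level alone clears the cutoff).
    """
    if fold_cutoff <= 1:
        raise ValueError("fold_cutoff must exceed 1")
    if not (np.isfinite(lfc_rna) and np.isfinite(lfc_ribo)):
        raise ValueError(f"non-finite LFC for gene {gene_id!r}")
    c = np.log2(fold_cutoff)
    if lfc_ribo <= -c:
        mode = "mrna_and_translation" if lfc_rna <= -c else "translation_only"
        mrna_only = False
    else:
        mode = "not_repressed"
        mrna_only = bool(lfc_rna <= -c)
    return RegModeCall(
        gene_id=gene_id,
        lfc_rna=float(lfc_rna),
        lfc_ribo=float(lfc_ribo),
        delta_lfc=float(lfc_ribo - lfc_rna),
        mode=mode,
        mrna_only=mrna_only,
    )


def classify_table(paired: pd.DataFrame, fold_cutoff: float = 1.5) -> pd.DataFrame:
    """Vectorized classification of a paired-LFC table.

    ``paired`` must have columns lfc_rna and lfc_ribo indexed by gene id;
    returns the same index with delta_lfc, mode and the mrna_only flag.
    """
    if fold_cutoff <= 1:
        raise ValueError("fold_cutoff must exceed 1")
    missing = {"lfc_rna", "lfc_ribo"} - set(paired.columns)
    if missing:
        raise ValueError(f"paired table missing columns: {sorted(missing)}")
    rna = paired["lfc_rna"].to_numpy(float)
    ribo = paired["lfc_ribo"].to_numpy(float)
    if not (np.isfinite(rna).all() and np.isfinite(ribo).all()):
        raise ValueError("non-finite LFCs in paired table")
    c = np.log2(fold_cutoff)
    ribo_rep = ribo <= -c
    rna_rep = rna <= -c
    mode = np.where(
        ribo_rep, np.where(rna_rep, "mrna_and_translation", "translation_only"), "not_repressed"
    )
    return pd.DataFrame(
        {
            "lfc_rna": rna,
            "lfc_ribo": ribo,
            "delta_lfc": ribo - rna,
            "mode": mode,
            "mrna_only": ~ribo_rep & rna_rep,
        },
        index=paired.index,
    )


def scan_cutoffs(paired: pd.DataFrame, cutoffs=(1.3, 1.5, 1.7, 1.9, 2.1)) -> ThresholdScan:
    """Re-run the mode classification over a grid of fold cutoffs.

    The repressed universe is recomputed at each cutoff. Reports per-mode
    counts and the fraction of repressed genes that are also mRNA-level
    repressed; that fraction being stable across the grid is the
    robustness check.
    """
    cutoffs = list(cutoffs)
    if len(cutoffs) < 2:
        raise ValueError("need at least 2 cutoffs to scan")
    if cutoffs != sorted(cutoffs):
        log.warning("cutoff grid not sorted; sorting")
        cutoffs = sorted(cutoffs)
    rows, fracs = [], []
    for cut in cutoffs:
        calls = classify_table(paired, fold_cutoff=cut)
        counts = calls["mode"].value_counts()
        row = {m: int(counts.get(m, 0)) for m in MODES}
        rows.append(row)
        n_rep = row["mrna_and_translation"] + row["translation_only"]
        fracs.append(row["mrna_and_translation"] / n_rep if n_rep else np.nan)
    return ThresholdScan(
        cutoffs=cutoffs,
        counts=pd.DataFrame(rows, index=pd.Index(cutoffs, name="fold_cutoff")),
        mrna_fraction=pd.Series(fracs, index=pd.Index(cutoffs, name="fold_cutoff")),
    )


def delta_lfc_distribution(calls: pd.DataFrame) -> np.ndarray:
    """delta LFC (ribo - rna) values of the repressed genes, for ECDF plots."""
    repressed = calls["mode"] != "not_repressed"
    return calls.loc[repressed, "delta_lfc"].to_numpy(float)
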