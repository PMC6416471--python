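"""Partition of XBP1/ATF6 transcriptional target lists by PERK dependence.

Externally defined UPR target lists (from targeted XBP1/ATF6 activation
experiments) are first restricted to genes expressed in the profiled
cells, then split at the late (8 h) timepoint into PERK-independent
targets (induced in both WT and PERK-null cells) and PERK-attenuated
targets (induced in PERK-null but repressed in WT); everything else is
unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .expression import ExpressionMatrix
from .setstats import GeneSet

log = logging.getLogger(__name__)


@dataclass
class TargetPartition:
    """Disjoint target subsets; their union is the expressed target set.

    Subsets are plain frozensets (unlike GeneSet they may be empty — an
    empty attenuated class is a legitimate biological outcome).
    """

    name: str
    independent: frozenset[str]
    attenuated: frozenset[str]
    unclassified: frozenset[str]
    timepoint_h: float
    n_missing: int = 0  # targets absent from an LFC table, excluded

    @property
    def counts(self) -> dict[str, int]:
        return {
            "independent": len(self.independent),
            "attenuated": len(self.attenuated),
            "unclassified": len(self.unclassified),
        }


def read_gmt(path) -> dict[str, GeneSet]:
    """Read GMT gene sets: name <tab> description <tab> gene ids..."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if genes:
                sets[name] = GeneSet(name, frozenset(genes))
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(sets, path, description: str = "") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *sorted(s.gene_ids)]) + "\n")


def filter_expressed_targets(
    targets: GeneSet, m: ExpressionMatrix, min_tpm: float = 2.0
) -> GeneSet:
    """Keep targets whose average TPM in the matrix is at least ``min_tpm``."""
    present = [g for g in targets.gene_ids if g in m.gene_ids]
    if not present:
        raise ValueError(
            f"no target of {targets.name!r} maps into the expression matrix; "
            f"unmapped ids e.g. {sorted(targets.gene_ids)[:5]}"
        )
    means = m.values.loc[present].mean(axis=1)
    kept = frozenset(means.index[means >= min_tpm])
    if not kept:
        raise ValueError(f"all targets of {targets.name!r} below TPM {min_tpm}")
    return GeneSet(targets.name, kept)


def partition_targets(
    targets: GeneSet,
    lfc_wt: pd.Series,
    lfc_ko: pd.Series,
    timepoint_h: float = 8.0,
    min_lfc: float = 0.0,
) -> TargetPartition:
    """Split targets into PERK-independent / PERK-attenuated / unclassified.

    ``lfc_wt`` and ``lfc_ko`` are per-gene LFC series at the chosen
    timepoint. "Up" means LFC > min_lfc and "down" LFC < -min_lfc
    (min_lfc = 0 classifies by quadrant; genes exactly at 0 are
    unclassified). Independent: up in both genotypes. Attenuated: up in
    KO and down in WT. Targets missing from either table are excluded and
    counted.
    """
    independent, attenuated, unclassified = set(), set(), set()
    n_missing = 0
    for gene in targets.gene_ids:
        if gene not in lfc_wt.index or gene not in lfc_ko.index:
            n_missing += 1
            continue
        wt, ko = float(lfc_wt[gene]), float(lfc_ko[gene])
        if wt > min_lfc and ko > min_lfc:
            independent.add(gene)
        elif ko > min_lfc and wt < -min_lfc:
            attenuated.add(gene)
        else:
            unclassified.add(gene)
    if n_missing:
        log.warning("%d target(s) of %s missing from LFC tables", n_missing, targets.name)
    return TargetPartition(
        name=targets.name,
        independent=frozenset(independent),
        attenuated=frozenset(attenuated),
        unclassified=frozenset(unclassified),
        timepoint_h=timepoint_h,
        n_missing=n_missing,
    )
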