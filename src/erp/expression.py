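"""TPM table loading, filtering/flooring, fold changes and the regulated set.

The expression layer establishes the gene universe every downstream
statistic uses: genes whose average TPM across all samples is below a
minimum are dropped, remaining values are floored to damp ratio noise at
low expression, and log2 fold changes are taken for each stress condition
against the matched genotype/assay control (timepoint 0). "Regulated"
genes are those changing at least ``fold_cutoff``-fold in some timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "KO")
ASSAYS = ("ribo", "rna")

META_COLUMNS = ("sample_id", "genotype", "timepoint_h", "assay", "replicate")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one (averaged) sample column.

    timepoint_h = 0 marks the unstressed control of its (genotype, assay)
    group; every group must contain exactly one control condition.
    """

    sample_id: str
    genotype: str
    timepoint_h: float
    assay: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r} for sample {self.sample_id!r}")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r} for sample {self.sample_id!r}")
        if self.timepoint_h < 0:
            raise ValueError(f"negative timepoint for sample {self.sample_id!r}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1 for sample {self.sample_id!r}")

    @property
    def condition(self) -> tuple[str, float, str]:
        return (self.genotype, self.timepoint_h, self.assay)


@dataclass
class ExpressionMatrix:
    """Gene x sample TPM matrix with per-column sample metadata.

    ``values`` is a DataFrame indexed by gene id with one column per
    (replicate-averaged) sample; ``samples`` aligns with its columns.
    """

    values: pd.DataFrame
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("sample metadata does not align with matrix columns")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if (self.values.values < 0).any():
            bad = self.values.lt(0).any(axis=1)
            raise ValueError(f"negative TPM for gene {self.values.index[bad][0]!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def subset(self, assay: str | None = None, genotype: str | None = None) -> "ExpressionMatrix":
        keep = [
            s
            for s in self.samples
            if (assay is None or s.assay == assay) and (genotype is None or s.genotype == genotype)
        ]
        return ExpressionMatrix(self.values[[s.sample_id for s in keep]], keep)

    def sample(self, genotype: str, timepoint_h: float, assay: str) -> SampleMeta:
        for s in self.samples:
            if s.condition == (genotype, timepoint_h, assay):
                return s
        raise KeyError(f"no sample for ({genotype}, {timepoint_h}, {assay})")


@dataclass
class LfcTable:
    """Gene x condition log2 fold changes vs the matched control.

    One assay per table (ribo and rna are never mixed); columns are a
    MultiIndex of (genotype, timepoint_h), control columns excluded.
    """

    lfc: pd.DataFrame
    assay: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.lfc.values).all():
            raise ValueError("non-finite LFC values; was the matrix floored?")

    @property
    def gene_ids(self) -> pd.Index:
        return self.lfc.index

    def timepoints(self, genotype: str) -> list[float]:
        return sorted(t for g, t in self.lfc.columns if g == genotype)

    def genotype_frame(self, genotype: str) -> pd.DataFrame:
        if genotype not in {g for g, _ in self.lfc.columns}:
            raise KeyError(f"unknown genotype {genotype!r}")
        sub = self.lfc[genotype]
        return sub[sorted(sub.columns)]

    def to_tsv(self, path) -> None:
        out = self.lfc.copy()
        out.columns = [f"{g}_{t:g}h" for g, t in out.columns]
        out.to_csv(path, sep="\t", index_label="gene_id")


def _validate_numeric(values: pd.DataFrame) -> None:
    for col in values.columns:
        series = pd.to_numeric(values[col], errors="coerce")
        if series.isna().any():
            gene = values.index[series.isna()][0]
            raise ValueError(f"non-numeric TPM for gene {gene!r} in sample {col!r}")
        values[col] = series.astype(float)


def load_expression(path, meta_path) -> ExpressionMatrix:
    """Read a TPM TSV plus a sample-metadata TSV into an ExpressionMatrix.

    The TPM file has gene ids in the first column and one column per
    sequencing sample; metadata must cover every sample column. Replicate
    columns of the same (genotype, timepoint, assay) are averaged into a
    single condition column at load time.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    missing_cols = set(META_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        raise ValueError(f"duplicate sample_id {meta.index[meta.index.duplicated()][0]!r} in metadata")
    uncovered = [c for c in values.columns if c not in meta.index]
    if uncovered:
        raise ValueError(f"no metadata for sample column(s): {uncovered}")
    _validate_numeric(values)
    metas = [
        SampleMeta(
            sample_id=str(sid),
            genotype=str(meta.at[sid, "genotype"]),
            timepoint_h=float(meta.at[sid, "timepoint_h"]),
            assay=str(meta.at[sid, "assay"]),
            replicate=int(meta.at[sid, "replicate"]),
        )
        for sid in values.columns
    ]
    return build_matrix(values, metas)


def build_matrix(values: pd.DataFrame, metas: Sequence[SampleMeta]) -> ExpressionMatrix:
    """Average replicate columns per condition and validate the result."""
    if (values.values < 0).any():
        bad = values.lt(0).any(axis=1)
        raise ValueError(f"negative TPM for gene {values.index[bad][0]!r}")
    groups: dict[tuple, list[SampleMeta]] = {}
    for s in metas:
        groups.setdefault(s.condition, []).append(s)
    cols, out_meta = {}, []
    for condition, members in groups.items():
        genotype, timepoint, assay = condition
        name = f"{genotype}_{assay}_{timepoint:g}h"
        cols[name] = values[[m.sample_id for m in members]].mean(axis=1)
        out_meta.append(SampleMeta(name, genotype, timepoint, assay))
    merged = pd.DataFrame(cols, index=values.index)
    matrix = ExpressionMatrix(merged, out_meta)
    _check_controls(matrix)
    return matrix


def _check_controls(m: ExpressionMatrix) -> None:
    seen: dict[tuple[str, str], int] = {}
    for s in m.samples:
        if s.timepoint_h == 0:
            key = (s.genotype, s.assay)
            seen[key] = seen.get(key, 0) + 1
    for s in m.samples:
        key = (s.genotype, s.assay)
        if seen.get(key, 0) != 1:
            raise ValueError(f"expected exactly one control (0 h) for {key}, found {seen.get(key, 0)}")


def filter_and_floor(
    m: ExpressionMatrix, min_avg_tpm: float = 2.0, floor_tpm: float = 4.0
) -> ExpressionMatrix:
    """Drop genes with mean TPM < ``min_avg_tpm`` across all samples, then
    floor every remaining value to ``floor_tpm``.

    The filter uses the raw (pre-floor) values; the surviving gene set is
    the "expressed genes" background for every downstream statistic.
    """
    keep = m.values.mean(axis=1) >= min_avg_tpm
    if not keep.any():
        raise ValueError("all genes filtered out; check TPM scale")
    floored = m.values.loc[keep].clip(lower=floor_tpm)
    return ExpressionMatrix(floored, list(m.samples))


def compute_lfc(m: ExpressionMatrix, assay: str) -> LfcTable:
    """log2(TPM condition / TPM control) per gene for one assay.

    The control is the genotype's own 0 h column; control columns are not
    reported. The matrix must already be floored so ratios are finite.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}")
    sub = m.subset(assay=assay)
    cols: dict[tuple[str, float], pd.Series] = {}
    for genotype in sorted({s.genotype for s in sub.samples}):
        try:
            control = sub.sample(genotype, 0.0, assay)
        except KeyError:
            raise ValueError(f"missing control (0 h) column for ({genotype}, {assay})") from None
        ctrl = sub.values[control.sample_id]
        for s in sub.samples:
            if s.genotype == genotype and s.timepoint_h > 0:
                cols[(genotype, s.timepoint_h)] = np.log2(sub.values[s.sample_id] / ctrl)
    lfc = pd.DataFrame(cols, index=m.gene_ids)
    lfc.columns = pd.MultiIndex.from_tuples(lfc.columns, names=["genotype", "timepoint_h"])
    return LfcTable(lfc, assay)


def select_regulated(lfc: LfcTable, genotype: str, fold_cutoff: float = 2.0) -> set[str]:
    """Genes whose |LFC| reaches log2(fold_cutoff) in any stress timepoint."""
    if fold_cutoff <= 0:
        raise ValueError("fold_cutoff must be positive")
    frame = lfc.genotype_frame(genotype)
    cut = np.log2(fold_cutoff)
    hit = frame.abs().max(axis=1) >= cut
    return set(frame.index[hit])
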