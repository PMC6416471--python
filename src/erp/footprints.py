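"""Ribosome footprint filtering, CDS clipping and the 5'-end pausing statistic.

Footprint reads are assigned by their 5' end in AUG-anchored transcript
coordinates (position 1 = A of the start codon; no P/A-site offset is
applied). Reads are trimmed to at most 34 nt after stripping the polyA
run added during library tailing, and only lengths 22-34 nt are kept.
Transcripts with CDS shorter than 100 nt are excluded and 30 nt are
clipped from each CDS end before densities are computed, so neither the
initiation nor the termination peak contributes to any statistic.

The pausing score of a gene is the ratio of its mean footprint density
over clipped positions up to a window boundary (default 140 nt from the
AUG) to its mean density beyond it; a stress-induced 5' ramp raises the
score. Conditions are compared by a two-sample KS test on the per-gene
score distributions and by the percent change in median score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .setstats import ks_two_sample

log = logging.getLogger(__name__)

CLIP_NT = 30
MIN_CDS_NT = 100
MIN_LEN, MAX_LEN = 22, 34


@dataclass(frozen=True)
class ReadRecord:
    """One footprint read in transcript coordinates (1-based 5' end)."""

    transcript_id: str
    five_prime_pos: int
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.five_prime_pos < 1:
            raise ValueError(f"five_prime_pos must be >= 1 ({self.transcript_id})")
        if self.length <= 0:
            raise ValueError(f"length must be positive ({self.transcript_id})")


@dataclass
class PositionalProfile:
    """Footprint counts over the clipped CDS window of one transcript.

    ``counts[i]`` is the number of read 5' ends at AUG-anchored position
    CLIP_NT + 1 + i; the window spans positions 31 .. cds_length - 30.
    """

    transcript_id: str
    cds_length: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.cds_length < MIN_CDS_NT:
            raise ValueError(f"CDS shorter than {MIN_CDS_NT} nt: {self.transcript_id}")
        if len(self.counts) != self.cds_length - 2 * CLIP_NT:
            raise ValueError(
                f"profile length {len(self.counts)} != cds_length - {2 * CLIP_NT} "
                f"for {self.transcript_id}"
            )
        if (self.counts < 0).any():
            raise ValueError(f"negative counts in {self.transcript_id}")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(CLIP_NT + 1, self.cds_length - CLIP_NT + 1)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class FilterStats:
    n_input: int = 0
    n_kept: int = 0
    n_too_short: int = 0
    n_too_long: int = 0  # longer than MAX_LEN even after trimming (cannot occur) — kept for audit
    discarded_by_reason: dict = field(default_factory=dict)


def _strip_polya(seq: str, min_run: int = 3) -> str:
    """Remove a trailing run of >= min_run A's (the polyA tailing artifact)."""
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] in "Aa":
        i -= 1
    return seq[:i] if n - i >= min_run else seq


def preprocess_reads(
    reads: list[ReadRecord], polya_min_run: int = 3
) -> tuple[list[ReadRecord], FilterStats]:
    """PolyA-strip, trim to 34 nt, and keep only lengths 22-34 nt.

    Reads without a sequence skip the polyA step (their stored length is
    taken as already stripped). Returns the kept reads and an accounting
    of discards so kept + discarded = input.
    """
    stats_ = FilterStats(n_input=len(reads))
    kept: list[ReadRecord] = []
    for read in reads:
        length = read.length
        seq = read.sequence
        if seq is not None:
            seq = _strip_polya(seq, min_run=polya_min_run)
            length = len(seq)
        if length > MAX_LEN:
            length = MAX_LEN
            seq = seq[:MAX_LEN] if seq is not None else None
        if length < MIN_LEN:
            stats_.n_too_short += 1
            continue
        kept.append(ReadRecord(read.transcript_id, read.five_prime_pos, length, seq))
    stats_.n_kept = len(kept)
    stats_.discarded_by_reason = {"too_short": stats_.n_too_short}
    return kept, stats_


def clip_and_profile(
    reads: list[ReadRecord], cds_lengths: dict[str, int]
) -> dict[str, PositionalProfile]:
    """Accumulate read 5' ends into clipped positional profiles.

    Transcripts with CDS < 100 nt are excluded; reads landing inside the
    clipped 30 nt at either end, beyond the CDS, or on excluded/unknown
    transcripts are dropped (counted in the log).
    """
    profiles: dict[str, PositionalProfile] = {}
    counts: dict[str, np.ndarray] = {}
    dropped = {"short_cds": 0, "clipped": 0, "beyond_cds": 0, "unknown_transcript": 0}
    for tid, cds_len in cds_lengths.items():
        if cds_len >= MIN_CDS_NT:
            counts[tid] = np.zeros(cds_len - 2 * CLIP_NT)
    for read in reads:
        cds_len = cds_lengths.get(read.transcript_id)
        if cds_len is None:
            dropped["unknown_transcript"] += 1
            continue
        if cds_len < MIN_CDS_NT:
            dropped["short_cds"] += 1
            continue
        pos = read.five_prime_pos
        if pos > cds_len:
            dropped["beyond_cds"] += 1
            continue
        if pos <= CLIP_NT or pos > cds_len - CLIP_NT:
            dropped["clipped"] += 1
            continue
        counts[read.transcript_id][pos - CLIP_NT - 1] += 1
    if any(dropped.values()):
        log.info("reads dropped while profiling: %s", dropped)
    for tid, vec in counts.items():
        profiles[tid] = PositionalProfile(tid, cds_lengths[tid], vec)
    return profiles


def pausing_score(
    profiles: dict[str, PositionalProfile],
    window_end: int = 140,
    min_counts: float = 64,
) -> pd.Series:
    """Per-gene 5' pausing ratio: mean density <= window_end over mean beyond.

    Both means are over clipped positions only (the window boundary is
    inclusive). Genes with fewer than ``min_counts`` footprints, no
    positions on one side of the boundary, or zero downstream density are
    excluded — the ratio would be unstable or undefined.
    """
    if window_end <= CLIP_NT:
        raise ValueError(f"window_end must exceed the {CLIP_NT} nt clip")
    scores = {}
    for tid, prof in profiles.items():
        if prof.total < min_counts:
            continue
        in_window = prof.positions <= window_end
        if not in_window.any() or in_window.all():
            continue
        five = prof.counts[in_window].mean()
        rest = prof.counts[~in_window].mean()
        if rest == 0:
            continue
        scores[tid] = five / rest
    return pd.Series(scores, name="pausing_ratio", dtype=float)


@dataclass
class PausingResult:
    control_ratios: pd.Series
    stress_ratios: pd.Series
    median_control: float
    median_stress: float
    percent_increase: float
    ks_statistic: float
    ks_p: float


def compare_pausing(control: pd.Series, stress: pd.Series) -> PausingResult:
    """Two-sample KS test on pausing-ratio distributions plus median shift.

    percent_increase = 100 * (median_stress / median_control - 1).
    The gene universes need not coincide; mismatches are logged.
    """
    if len(control) < 30 or len(stress) < 30:
        raise ValueError("need at least 30 genes per condition for a stable comparison")
    overlap = control.index.intersection(stress.index)
    if len(overlap) < min(len(control), len(stress)):
        log.info(
            "pausing comparison on partially overlapping universes (%d common)", len(overlap)
        )
    ks_stat, ks_p = ks_two_sample(control.to_numpy(), stress.to_numpy())
    med_c = float(control.median())
    med_s = float(stress.median())
    return PausingResult(
        control_ratios=control,
        stress_ratios=stress,
        median_control=med_c,
        median_stress=med_s,
        percent_increase=100.0 * (med_s / med_c - 1.0),
        ks_statistic=ks_stat,
        ks_p=ks_p,
    )


def pooled_position_ks(
    profiles_control: dict[str, PositionalProfile],
    profiles_stress: dict[str, PositionalProfile],
    window_end: int = 140,
) -> tuple[float, float]:
    """Secondary statistic: KS on pooled per-position metagene densities.

    Each transcript's profile is normalized to unit mean, densities at
    positions <= window_end are pooled per condition, and the two pooled
    samples are KS-compared. Reported alongside the per-gene-ratio test.
    """
    def _pool(profiles: dict[str, PositionalProfile]) -> np.ndarray:
        chunks = []
        for prof in profiles.values():
            if prof.total == 0:
                continue
            dens = prof.counts / prof.counts.mean()
            chunks.append(dens[prof.positions <= window_end])
        return np.concatenate(chunks)

    return ks_two_sample(_pool(profiles_control), _pool(profiles_stress))


def read_records_tsv(path) -> list[ReadRecord]:
    """Read footprint records from TSV: transcript_id, pos, length[, seq]."""
    df = pd.read_csv(path, sep="\t")
    need = {"transcript_id", "pos", "length"}
    if not need.issubset(df.columns):
        raise ValueError(f"reads TSV must have columns {sorted(need)}")
    has_seq = "seq" in df.columns
    return [
        ReadRecord(
            str(r.transcript_id),
            int(r.pos),
            int(r.length),
            (str(r.seq) if has_seq and pd.notna(r.seq) else None),
        )
        for r in df.itertuples()
    ]
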