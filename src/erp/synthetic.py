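"""Synthetic data generators with planted ground truth.

Every analysis stage can be exercised without downloads: a two-genotype
(WT / PERK-null) five-timepoint TPM matrix with planted early-induction,
late-induction and repression programs; paired RNA/Ribo tables encoding
translation-only vs mRNA+translation repression; positional footprint
profiles with a 5' ramp confined to the first ~140 nt; and polysome
traces built as Gaussian peak mixtures whose monosome/polysome areas are
known in closed form.

Planted effect sizes default to the ER-stress study conditions: WT
program medians of roughly 80/89% (early at 5/8 h), 128/136% (late) and
50/51% repression, attenuated in the knockout to 12/11%, 9/26% and
18/12%; an mRNA-level component in ~15% of repressed genes; a 1.3x
pausing ramp; and trace P/M targets like 5.97 (unstressed) and 2.38
(8 h stress). All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleMeta
from .footprints import CLIP_NT, PositionalProfile
from .polysome import PolysomeTrace

TIMEPOINTS = (0.0, 1.0, 2.0, 5.0, 8.0)

# fold-change (linear, vs 0 h) profiles per program at 1, 2, 5, 8 h;
# 5/8 h entries pinned to the study's reported medians
WT_FOLDS = {
    "early": {1.0: 3.0, 2.0: 3.2, 5.0: 1.80, 8.0: 1.89},
    "late": {1.0: 1.10, 2.0: 1.35, 5.0: 2.28, 8.0: 2.36},
    "repression": {1.0: 0.45, 2.0: 0.42, 5.0: 0.50, 8.0: 0.49},
}
KO_FOLDS = {
    "early": {1.0: 1.00, 2.0: 1.00, 5.0: 1.12, 8.0: 1.11},
    "late": {1.0: 0.95, 2.0: 0.98, 5.0: 1.09, 8.0: 1.26},
    "repression": {1.0: 1.00, 2.0: 0.98, 5.0: 0.82, 8.0: 0.88},
}
# XBP1-ATF6 target behaviors at the late timepoints
TARGET_FOLDS = {
    "independent": {"WT": {1.0: 1.05, 2.0: 1.1, 5.0: 1.8, 8.0: 2.0},
                    "KO": {1.0: 1.05, 2.0: 1.1, 5.0: 1.8, 8.0: 2.0}},
    "attenuated": {"WT": {1.0: 1.0, 2.0: 0.95, 5.0: 0.80, 8.0: 0.72},
                   "KO": {1.0: 1.05, 2.0: 1.1, 5.0: 1.7, 8.0: 1.9}},
}


@dataclass
class ExpressionConfig:
    """Study conditions for the synthetic TPM matrix."""

    n_background: int = 1000
    n_early: int = 150
    n_late: int = 150
    n_repression: int = 200
    n_target_independent: int = 60
    n_target_attenuated: int = 40
    frac_mrna_mode: float = 0.15      # repressed genes with an mRNA-level component
    frac_er_target: float = 0.40      # repression-program genes flagged as ER targets
    noise_sd: float = 0.25            # lognormal sigma (natural log), multiplicative
    baseline_log_mean: float = np.log(50.0)
    baseline_log_sd: float = 1.0
    seed: int = 42

    @property
    def n_genes(self) -> int:
        return (
            self.n_background + self.n_early + self.n_late + self.n_repression
            + self.n_target_independent + self.n_target_attenuated
        )


def _fold(profile: dict[float, float], t: float) -> float:
    return 1.0 if t == 0 else profile[t]


def generate_expression(config: ExpressionConfig | None = None) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate the full WT/KO x ribo/rna x 5-timepoint TPM matrix.

    Returns the matrix (20 condition columns) and a per-gene truth table
    with columns program, mode, er_target, xbp1_atf6_class. Effects are
    multiplicative on a shared lognormal baseline; translation-only
    repressed genes keep a flat RNA profile while their ribo profile
    drops; noise is multiplicative lognormal per cell.
    """
    cfg = config or ExpressionConfig()
    rng = np.random.default_rng(cfg.seed)

    labels = (
        ["background"] * cfg.n_background
        + ["early"] * cfg.n_early
        + ["late"] * cfg.n_late
        + ["repression"] * cfg.n_repression
        + ["target_independent"] * cfg.n_target_independent
        + ["target_attenuated"] * cfg.n_target_attenuated
    )
    n = len(labels)
    if n != cfg.n_genes:
        raise ValueError("inconsistent class counts")
    gene_ids = [f"G{i:05d}" for i in range(n)]
    truth = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    truth["program"] = [
        lab if lab in ("early", "late", "repression") else "background" for lab in labels
    ]
    truth["xbp1_atf6_class"] = [
        lab.removeprefix("target_") if lab.startswith("target_") else "none" for lab in labels
    ]
    # regulatory mode: a fixed fraction of repression genes also drop at mRNA level
    modes = np.array(["none"] * n, dtype=object)
    rep_idx = [i for i, lab in enumerate(labels) if lab == "repression"]
    n_mrna = int(round(cfg.frac_mrna_mode * len(rep_idx)))
    mrna_members = rng.choice(rep_idx, size=n_mrna, replace=False)
    modes[rep_idx] = "translation_only"
    modes[mrna_members] = "mrna_and_translation"
    truth["mode"] = modes
    er = np.zeros(n, dtype=bool)
    n_er = int(round(cfg.frac_er_target * len(rep_idx)))
    er[rng.choice(rep_idx, size=n_er, replace=False)] = True
    truth["er_target"] = er

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n)

    cols: dict[str, np.ndarray] = {}
    metas: list[SampleMeta] = []
    for genotype in ("WT", "KO"):
        for assay in ("ribo", "rna"):
            for t in TIMEPOINTS:
                folds = np.ones(n)
                for i, lab in enumerate(labels):
                    if lab in WT_FOLDS:
                        profile = (WT_FOLDS if genotype == "WT" else KO_FOLDS)[lab]
                        f = _fold(profile, t)
                        if (
                            assay == "rna"
                            and lab == "repression"
                            and modes[i] == "translation_only"
                        ):
                            f = 1.0  # no mRNA-level change for translation-only genes
                    elif lab.startswith("target_"):
                        f = _fold(TARGET_FOLDS[lab.removeprefix("target_")][genotype], t)
                    else:
                        f = 1.0
                    folds[i] = f
                values = baseline * folds
                if cfg.noise_sd > 0:
                    values = values * rng.lognormal(0.0, cfg.noise_sd, size=n)
                name = f"{genotype}_{assay}_{t:g}h"
                cols[name] = values
                metas.append(SampleMeta(name, genotype, t, assay))
    matrix = ExpressionMatrix(pd.DataFrame(cols, index=truth.index), metas)
    return matrix, truth


@dataclass
class ProfileConfig:
    """Conditions for synthetic footprint positional profiles."""

    n_genes: int = 2000
    reads_per_gene: int = 2000
    cds_length_range: tuple[int, int] = (400, 2400)
    ramp_factor: float = 1.3      # density multiplier on clipped positions <= ramp_end
    ramp_end: int = 140           # nt downstream of the AUG
    seed: int = 42

    def __post_init__(self) -> None:
        if self.cds_length_range[0] < 100:
            raise ValueError("CDS lengths below 100 nt are filtered by the analysis")
        if self.cds_length_range[0] <= self.ramp_end + CLIP_NT:
            raise ValueError("shortest CDS leaves no positions beyond the ramp window")


def generate_profiles(
    config: ProfileConfig | None = None,
) -> tuple[dict[str, PositionalProfile], dict[str, PositionalProfile]]:
    """Control and stress positional profiles for the same transcript set.

    Control reads are multinomial-uniform over each clipped CDS; under
    stress the per-position weights at clipped positions <= ramp_end are
    multiplied by the ramp factor before renormalization, so the true
    5' pausing ratio equals the ramp factor.
    """
    cfg = config or ProfileConfig()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.cds_length_range
    control: dict[str, PositionalProfile] = {}
    stress: dict[str, PositionalProfile] = {}
    for i in range(cfg.n_genes):
        tid = f"T{i:05d}"
        cds_len = int(rng.integers(lo, hi + 1))
        n_pos = cds_len - 2 * CLIP_NT
        positions = np.arange(CLIP_NT + 1, cds_len - CLIP_NT + 1)
        uniform = np.full(n_pos, 1.0 / n_pos)
        weights = np.where(positions <= cfg.ramp_end, cfg.ramp_factor, 1.0)
        weights = weights / weights.sum()
        control[tid] = PositionalProfile(
            tid, cds_len, rng.multinomial(cfg.reads_per_gene, uniform)
        )
        stress[tid] = PositionalProfile(
            tid, cds_len, rng.multinomial(cfg.reads_per_gene, weights)
        )
    return control, stress


@dataclass
class TraceConfig:
    """Gaussian peak-mixture polysome trace with a known true P/M ratio."""

    target_pm: float = 5.97
    n_samples: int = 1400
    span: float = 70.0
    peak_sigma: float = 1.2
    subunit_peaks: tuple = ((6.0, 0.25, 0.9), (10.0, 0.35, 0.9))  # 40S, 60S (center, amp, sigma)
    mono_center: float = 16.0
    mono_amp: float = 1.0
    disome_trisome: tuple = ((26.0, 0.45), (33.0, 0.35))
    poly_centers: tuple = (40.0, 46.0, 51.0, 55.0, 58.0)
    poly_rel_amps: tuple = (1.0, 0.8, 0.6, 0.45, 0.3)
    baseline: float = 0.02
    noise_sd: float = 0.0
    seed: int = 0


def generate_trace(config: TraceConfig | None = None) -> tuple[PolysomeTrace, dict]:
    """Sum-of-Gaussians trace whose true polysome/monosome area ratio
    equals ``target_pm``.

    Gaussian areas are amp * sigma * sqrt(2*pi), so the polysome peak
    amplitudes are scaled analytically against the monosome amplitude.
    Returns the trace and the truth (areas, true_pm, peak centers).
    """
    cfg = config or TraceConfig()
    rng = np.random.default_rng(cfg.seed)
    x = np.linspace(0.0, cfg.span, cfg.n_samples)
    s = cfg.peak_sigma

    def gauss(center: float, amp: float, sigma: float) -> np.ndarray:
        return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)

    y = np.full_like(x, cfg.baseline)
    for center, amp, sigma in cfg.subunit_peaks:
        y += gauss(center, amp, sigma)
    y += gauss(cfg.mono_center, cfg.mono_amp, s)
    for center, amp in cfg.disome_trisome:
        y += gauss(center, amp, s)
    mono_area = cfg.mono_amp * s * np.sqrt(2 * np.pi)
    rel_area = sum(cfg.poly_rel_amps) * s * np.sqrt(2 * np.pi)
    scale = cfg.target_pm * mono_area / rel_area
    for center, rel in zip(cfg.poly_centers, cfg.poly_rel_amps):
        y += gauss(center, rel * scale, s)
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=y.shape)
    truth = {
        "true_pm": cfg.target_pm,
        "mono_area": mono_area,
        "poly_area": cfg.target_pm * mono_area,
        "mono_center": cfg.mono_center,
        "poly_centers": list(cfg.poly_centers),
    }
    return PolysomeTrace(x, y), truth
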