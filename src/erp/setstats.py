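"""Gene-set distribution statistics: ECDFs, set-vs-background t-tests,
induced fractions.

These are the primitives behind CDF-panel comparisons: the LFC
distribution of a gene set is compared against the background of all
expressed genes with a classical two-sample Student t-test (pooled
variance, two-sided), and summarized by its median LFC and the fraction
of genes induced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GeneSet:
    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GroupComparison:
    set_name: str
    condition: str
    n_set: int
    n_background: int
    t_statistic: float
    p_value: float
    median_lfc_set: float
    fraction_induced: float


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: sorted values and cumulative fractions.

    The returned fractions reach exactly 1 at the largest value.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("ECDF of empty sample")
    x = np.sort(arr)
    f = np.arange(1, arr.size + 1) / arr.size
    return x, f


def fraction_induced(lfc_values, min_lfc: float = 0.0) -> float:
    """Fraction of genes with LFC strictly above ``min_lfc``."""
    arr = np.asarray(lfc_values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty LFC sample")
    return float((arr > min_lfc).mean())


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and two-sided p-value.

    Exact p for small samples, asymptotic otherwise (scipy's auto rule).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def group_vs_background(
    set_lfc,
    background_lfc,
    set_name: str = "set",
    condition: str = "",
    welch: bool = False,
) -> GroupComparison:
    """Two-sided two-sample Student t-test of a set against the background.

    The background is the LFC distribution of all expressed genes for the
    condition, including the set itself (no exclusion). Pooled-variance
    Student by default; Welch behind a flag.
    """
    set_arr = np.asarray(set_lfc, dtype=float)
    bg_arr = np.asarray(background_lfc, dtype=float)
    if set_arr.size == 0 or bg_arr.size == 0:
        raise ValueError("empty sample")
    if set_arr.size > bg_arr.size:
        raise ValueError("set larger than background")
    t, p = stats.ttest_ind(set_arr, bg_arr, equal_var=not welch)
    return GroupComparison(
        set_name=set_name,
        condition=condition,
        n_set=int(set_arr.size),
        n_background=int(bg_arr.size),
        t_statistic=float(t),
        p_value=float(p),
        median_lfc_set=float(np.median(set_arr)),
        fraction_induced=fraction_induced(set_arr),
    )
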