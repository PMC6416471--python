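"""Overrepresentation analysis with Benjamini-Hochberg control.

One-sided Fisher exact tests of a gene set against annotation categories
over the expressed-gene background, BH-adjusted across the tested
categories; a category is enriched when its adjusted p falls below 0.05.
An optional EASE variant (DAVID's conservative k-1 score) is provided
for comparability with web-tool output, but the unmodified Fisher test
is the default statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .setstats import GeneSet

ALPHA = 0.05


def fisher_greater_p(k, n, K, N):
    """One-sided (greater) Fisher exact p for 2x2 table(s).

    The p-value is the upper hypergeometric tail P(X >= k) with X ~
    Hypergeom(N, K, n) — identical to Fisher's one-sided test and
    vectorizable over arrays of tables.
    """
    k = np.asarray(k)
    return stats.hypergeom.sf(k - 1, np.asarray(N), np.asarray(K), np.asarray(n))


@dataclass
class EnrichmentRow:
    category: str
    k: int  # set ∩ category
    n: int  # set size (within background)
    K: int  # category size in background
    N: int  # background size
    odds_ratio: float
    p: float
    p_adjusted: float = float("nan")
    enriched: bool = False


def _fisher_greater(k: int, n: int, K: int, N: int, ease: bool = False) -> tuple[float, float]:
    """Odds ratio and one-sided Fisher p for one 2x2 table.

    EASE mode scores k-1 successes (DAVID's conservative variant;
    k = 0 gives p = 1).
    """
    kk = max(k - 1, 0) if ease else k
    p = float(fisher_greater_p(kk, n, K, N))
    a, b, c, d = k, n - k, K - k, N - n - (K - k)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return odds, p


def fisher_enrichment(
    gene_set: GeneSet,
    categories: dict[str, GeneSet],
    background: GeneSet,
    alpha: float = ALPHA,
    ease: bool = False,
) -> pd.DataFrame:
    """Test a gene set for overrepresentation in each category.

    The set is intersected with the background (genes outside it cannot
    be tested); categories are likewise restricted to the background.
    Returns one row per category sorted by adjusted p.
    """
    bg = set(background.gene_ids)
    if not bg:
        raise ValueError("empty background")
    members = set(gene_set.gene_ids) & bg
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the background")
    rows = []
    for name, cat in categories.items():
        cat_bg = set(cat.gene_ids) & bg
        if not cat_bg:
            continue
        k = len(members & cat_bg)
        odds, p = _fisher_greater(k, len(members), len(cat_bg), len(bg), ease=ease)
        rows.append(
            EnrichmentRow(
                category=name, k=k, n=len(members), K=len(cat_bg), N=len(bg),
                odds_ratio=odds, p=p,
            )
        )
    if not rows:
        raise ValueError("no category overlaps the background")
    df = pd.DataFrame([vars(r) for r in rows]).set_index("category")
    reject, p_adj, _, _ = multipletests(df["p"].fillna(1.0), alpha=alpha, method="fdr_bh")
    df["p_adjusted"] = p_adj
    df["enriched"] = df["p_adjusted"] < alpha
    return df.sort_values("p_adjusted")


def exclude_and_retest(
    gene_set: GeneSet,
    exclusion: GeneSet,
    categories: dict[str, GeneSet],
    background: GeneSet,
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Re-run enrichment on the set minus an exclusion list.

    Used to ask what a program is enriched for once a dominant annotation
    class (e.g. ER targets) is removed. Returns the enrichment table and
    the sizes involved.
    """
    residual = set(gene_set.gene_ids) - set(exclusion.gene_ids)
    if not residual:
        raise ValueError("exclusion removes the entire set")
    sizes = {
        "set": len(gene_set),
        "excluded": len(set(gene_set.gene_ids) & set(exclusion.gene_ids)),
        "residual": len(residual),
    }
    residual_set = GeneSet(f"{gene_set.name}_minus_{exclusion.name}", frozenset(residual))
    return fisher_enrichment(residual_set, categories, background, alpha=alpha), sizes
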