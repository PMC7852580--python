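"""Hypergeometric protein-domain enrichment of a gene subset vs a background.

For each domain present in the background, the number of subset genes
carrying it is compared against sampling without replacement: with N
background genes of which K carry the domain, and a subset of n genes of
which k carry it, the enrichment p-value is the upper tail
P(X >= k), X ~ Hypergeometric(N, K, n).  P-values are BH-adjusted across all
tested domains; results report log2 enrichment fold log2((k/n)/(K/N)) and
the subset ratio 100*k/n.  A gene contributes at most once per domain
(presence/absence); the test is one-sided for enrichment only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust

__all__ = ["EnrichmentResult", "hypergeom_tail", "domain_enrichment"]


@dataclass(frozen=True)
class EnrichmentResult:
    domain_id: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    adjusted_p: float
    enrichment_fold_log2: float
    subset_ratio_percent: float


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Evaluated through log-gamma based survival functions, so large counts
    stay numerically stable.  k = 0 returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def domain_enrichment(
    subset: Iterable[str],
    background: Iterable[str],
    annotations: pd.DataFrame,
    adjusted_p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Test every background domain for enrichment in ``subset``.

    ``annotations`` has columns ``gene_id`` and ``domain_id`` (extra columns
    such as ``description`` are carried through).  The subset must be a
    subset of the background; annotations on genes outside the background are
    ignored.  Returns a DataFrame sorted by adjusted p then domain id with
    columns k, n, K, N, p_value, adjusted_p, enrichment_fold_log2 (``-inf``
    when k = 0), subset_ratio_percent and a boolean ``enriched`` flag at
    ``adjusted_p <= adjusted_p_cutoff``.
    """
    subset = set(subset)
    background = set(background)
    stray = subset - background
    if stray:
        raise ValueError(f"subset genes absent from background: {sorted(stray)[:5]}")
    if not background:
        raise ValueError("background is empty")
    ann = annotations[["gene_id", "domain_id"]].drop_duplicates()
    ann = ann[ann["gene_id"].isin(background)]
    N, n = len(background), len(subset)

    rows = []
    for domain, grp in ann.groupby("domain_id", sort=True):
        carriers = set(grp["gene_id"])
        K = len(carriers)
        k = len(carriers & subset)
        p = hypergeom_tail(k, K, n, N)
        fold = -math.inf if k == 0 else math.log2((k / n) / (K / N))
        rows.append((domain, k, n, K, N, p, fold, 100.0 * k / n))
    if not rows:
        return pd.DataFrame(
            columns=["domain_id", "k", "n", "K", "N", "p_value", "adjusted_p",
                     "enrichment_fold_log2", "subset_ratio_percent", "enriched"]
        )
    df = pd.DataFrame(
        rows,
        columns=["domain_id", "k", "n", "K", "N", "p_value",
                 "enrichment_fold_log2", "subset_ratio_percent"],
    )
    df["adjusted_p"] = bh_adjust(df["p_value"])
    df["enriched"] = df["adjusted_p"] <= adjusted_p_cutoff
    descr = annotations.drop(columns=["gene_id"]).drop_duplicates("domain_id")
    if "description" in descr.columns:
        df = df.merge(descr[["domain_id", "description"]], on="domain_id", how="left")
    return df.sort_values(["adjusted_p", "domain_id"], kind="mergesort").reset_index(drop=True)
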