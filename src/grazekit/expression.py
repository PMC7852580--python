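"""Differential- and high-expression classification with functional aggregation.

The experimental design is an ordered series of culture phases (exponential,
three starvation-by-dilution states, stationary), each sampled with replicate
bottles/filters that behave as exchangeable replicates.  This module

* tests per-gene differential expression between two phases with a
  negative-binomial two-sample score test sharing a common dispersion across
  genes (a deliberately simple, documented engine; externally produced
  (logFC, FDR) tables are accepted everywhere downstream),
* applies the classification thresholds (|logFC| > 2, BH FDR < 1e-3, both
  strict) and counts calls per direction,
* selects highly expressed genes (phase-mean TPM > 500 in any phase, strict),
  partitions them by DE direction, and
* aggregates phase-mean TPM over manually assigned functional categories,
  scaling each category row to percent-of-maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "de_test",
    "bh_adjust",
    "de_classify",
    "phase_mean",
    "highly_expressed_select",
    "partition_heg",
    "functional_aggregate",
    "sample_correlation",
    "estimate_common_dispersion",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample expression values plus the sample -> phase design."""

    values: pd.DataFrame
    design: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.design]
        if missing:
            raise ValueError(f"samples without a phase assignment: {missing}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def phases(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            ph = self.design[s]
            if ph not in seen:
                seen.append(ph)
        return seen

    def samples_of(self, phase: str) -> list[str]:
        return [s for s in self.values.columns if self.design[s] == phase]


def estimate_common_dispersion(groups: Sequence[np.ndarray]) -> float:
    """Method-of-moments common NB dispersion across genes.

    Each element of ``groups`` is a gene x replicate array for one condition.
    Under NB(mu, alpha), E[s^2] = mu + alpha mu^2, and m^2 - s^2/n is an
    unbiased estimate of mu^2, so a pooled ratio estimator of alpha is
    sum(s^2 - m) / sum(m^2 - s^2/n), clipped at 0.
    """
    num = 0.0
    den = 0.0
    for arr in groups:
        n = arr.shape[1]
        m = arr.mean(axis=1)
        s2 = arr.var(axis=1, ddof=1)
        num += float(np.sum(s2 - m))
        den += float(np.sum(m * m - s2 / n))
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def de_test(
    matrix: ExpressionMatrix,
    phase_a: str,
    phase_b: str,
    dispersion: float | str = "estimate",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB score test of phase_a vs phase_b with a common dispersion.

    Columns are library-size normalized to their median total.  For each gene
    the statistic is the identity-link score test of equal means,

        Z = (mean_A - mean_B) / sqrt((mu0 + alpha mu0^2) (1/nA + 1/nB)),

    with ``mu0`` the pooled null mean, referred to a standard normal: the
    null variance comes from the mean-variance relation with a dispersion
    shared across thousands of genes, not from a per-gene sample variance,
    so no small-sample t correction is warranted.  logFC is
    log2((mean_A + pc) / (mean_B + pc)).  BH-adjusted FDR spans all tested
    genes.  Returns a DataFrame indexed by gene with columns
    ``log2_fold_change``, ``p_value``, ``fdr``.
    """
    if matrix.values.empty:
        raise ValueError("empty expression matrix")
    cols_a = matrix.samples_of(phase_a)
    cols_b = matrix.samples_of(phase_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("DE testing needs >= 2 replicates per phase")
    values = matrix.values[cols_a + cols_b].to_numpy(float)
    libsize = values.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("a sample has zero total signal")
    scale = np.median(libsize) / libsize
    values = values * scale
    a = values[:, : len(cols_a)]
    b = values[:, len(cols_a):]

    if dispersion == "estimate":
        alpha = estimate_common_dispersion([a, b])
    else:
        alpha = float(dispersion)
        if alpha < 0:
            raise ValueError("dispersion must be nonnegative")

    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    mu0 = (a.sum(axis=1) + b.sum(axis=1)) / (na + nb)
    var0 = mu0 + alpha * mu0**2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (ma - mb) / np.sqrt(var0 * (1.0 / na + 1.0 / nb))
    z = np.where(var0 > 0, z, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    logfc = np.log2((ma + pseudocount) / (mb + pseudocount))
    fdr = bh_adjust(p)
    return pd.DataFrame(
        {"log2_fold_change": logfc, "p_value": p, "fdr": fdr},
        index=matrix.values.index,
    )


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_classify(
    results: pd.DataFrame,
    logfc_threshold: float = 2.0,
    fdr_threshold: float = 1e-3,
) -> tuple[pd.Series, dict[str, int]]:
    """Label each gene up_A / up_B / not_DE at strict thresholds.

    A gene is differentially expressed iff |logFC| > logfc_threshold AND
    fdr < fdr_threshold (both strict, as the thresholds are printed).
    Accepts any table carrying ``log2_fold_change`` and ``fdr`` columns, so
    external DE engines plug in directly.  Returns (labels, counts) with
    counts keyed up_A, up_B, not_DE, total_de.
    """
    lfc = results["log2_fold_change"].to_numpy(float)
    fdr = results["fdr"].to_numpy(float)
    is_de = (np.abs(lfc) > logfc_threshold) & (fdr < fdr_threshold)
    labels = np.where(is_de & (lfc > 0), "up_A", np.where(is_de, "up_B", "not_DE"))
    series = pd.Series(labels, index=results.index, name="direction")
    counts = {
        "up_A": int(np.sum(labels == "up_A")),
        "up_B": int(np.sum(labels == "up_B")),
        "not_DE": int(np.sum(labels == "not_DE")),
        "total_de": int(np.sum(is_de)),
    }
    return series, counts


def phase_mean(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean expression per gene and phase (all replicates pooled)."""
    out = {}
    for phase in matrix.phases:
        cols = matrix.samples_of(phase)
        if not cols:
            raise ValueError(f"phase {phase!r} has no samples")
        out[phase] = matrix.values[cols].mean(axis=1)
    return pd.DataFrame(out)


def highly_expressed_select(phase_means: pd.DataFrame, threshold: float = 500.0) -> list[str]:
    """Genes whose mean TPM strictly exceeds ``threshold`` in any phase."""
    mask = (phase_means > threshold).any(axis=1)
    return list(phase_means.index[mask])


def partition_heg(
    heg_set: Iterable[str],
    de_results: pd.DataFrame,
    logfc_threshold: float = 2.0,
    fdr_threshold: float = 1e-3,
) -> dict[str, list[str]]:
    """Partition highly expressed genes by their DE direction between the two
    compared phases (A = the phase favored by positive logFC).

    Returns disjoint, exhaustive classes ``up_A``, ``up_B``, ``similar``.
    ``de_results`` may carry a precomputed ``direction`` column; otherwise
    directions are derived at the stated thresholds.
    """
    heg = list(heg_set)
    missing = [g for g in heg if g not in de_results.index]
    if missing:
        raise ValueError(f"genes missing from DE results: {missing[:5]}")
    if "direction" in de_results.columns:
        directions = de_results["direction"]
    else:
        directions, _ = de_classify(de_results, logfc_threshold, fdr_threshold)
    out: dict[str, list[str]] = {"up_A": [], "up_B": [], "similar": []}
    for g in heg:
        d = directions.loc[g]
        out[d if d in ("up_A", "up_B") else "similar"].append(g)
    return out


def functional_aggregate(
    phase_means: pd.DataFrame,
    category_map: pd.DataFrame,
    genes: Iterable[str] | None = None,
    level: str = "cellular_function",
) -> pd.DataFrame:
    """Sum phase-mean TPM over functional categories and scale rows to
    percent-of-maximum.

    ``category_map`` has columns ``gene_id``, ``general_process``,
    ``cellular_function`` (at most one assignment per gene).  ``genes``
    restricts the aggregation (typically to the highly expressed set); every
    aggregated gene must carry a category.  Returns a category x phase table
    with a ``<phase>`` column per phase (TPM sums), matching ``<phase>_pct``
    columns (row percent of max), ``max_tpm`` (the row's highest cell) and
    ``n_genes``.
    """
    if level not in ("cellular_function", "general_process"):
        raise ValueError("level must be 'cellular_function' or 'general_process'")
    cmap = category_map.drop_duplicates("gene_id").set_index("gene_id")
    use = list(genes) if genes is not None else list(phase_means.index)
    missing = [g for g in use if g not in cmap.index]
    if missing:
        raise ValueError(f"genes without a category assignment: {missing[:5]}")
    sub = phase_means.loc[use]
    cats = cmap.loc[use, level]
    sums = sub.groupby(cats.to_numpy()).sum()
    sums = sums[sums.sum(axis=1) > 0]  # an all-zero category has no profile to scale
    row_max = sums.max(axis=1)
    pct = sums.div(row_max, axis=0) * 100.0
    out = sums.copy()
    for ph in sums.columns:
        out[f"{ph}_pct"] = pct[ph]
    out["max_tpm"] = row_max
    out["n_genes"] = pd.Series(cats.to_numpy()).value_counts().reindex(out.index).astype(int)
    out.index.name = level
    return out


def sample_correlation(values: pd.DataFrame, genes: Iterable[str] | None = None) -> pd.DataFrame:
    """Sample x sample Pearson correlation over the given genes (typically the
    DE set).  Zero-variance samples yield missing (NaN) correlations rather
    than 0."""
    sub = values.loc[list(genes)] if genes is not None else values
    if len(sub) < 2:
        raise ValueError("correlation needs >= 2 genes")
    return sub.corr(method="pearson", min_periods=2)
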