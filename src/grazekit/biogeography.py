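"""Relative-abundance summaries for ocean survey tables.

Marker-gene (ASV) relative abundances are computed per sample after removing
excluded read groups (e.g. metazoan and plant reads), then summarized as the
percentage of samples falling in occupancy bins — absent (exactly zero),
(0, 0.1), [0.1, 1), [1, 10) and [10, inf) percent — together with the mean
and median, the pattern that exposes patchy distributions (mean far above
median).  Metagenomic recruitment is normalized as reads per million (RPM).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["relative_abundance", "abundance_bins", "rpm", "layer_summary"]

BIN_LABELS = ("absent", "<0.1", "0.1-1", "1-10", ">10")


def relative_abundance(
    counts: pd.DataFrame,
    target: str,
    exclude: Sequence[str] = (),
) -> pd.Series:
    """Percent of retained reads belonging to ``target``, per sample.

    ``counts`` is a sample x read-group table.  Groups named in ``exclude``
    are removed from the denominator (the target itself is always retained).
    """
    if target not in counts.columns:
        raise ValueError(f"target group {target!r} not in table")
    if target in exclude:
        raise ValueError("target group cannot be excluded")
    keep = [c for c in counts.columns if c not in set(exclude)]
    retained = counts[keep].sum(axis=1)
    if (retained <= 0).any():
        bad = list(retained.index[retained <= 0])[:5]
        raise ValueError(f"zero retained reads in samples {bad}")
    return 100.0 * counts[target] / retained


def abundance_bins(values: Iterable[float]) -> dict[str, float]:
    """Distribution of per-sample percentages over occupancy bins.

    Bins: exactly 0 ("absent"), (0, 0.1), [0.1, 1), [1, 10), [10, inf);
    edges are closed on the left, so a value of exactly 0.1 falls in "0.1-1".
    Returns bin percentages (summing to 100), plus mean, median and n.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no values to bin")
    if (v < 0).any():
        raise ValueError("abundances must be nonnegative")
    n = v.size
    bins = {
        "absent": np.sum(v == 0),
        "<0.1": np.sum((v > 0) & (v < 0.1)),
        "0.1-1": np.sum((v >= 0.1) & (v < 1.0)),
        "1-10": np.sum((v >= 1.0) & (v < 10.0)),
        ">10": np.sum(v >= 10.0),
    }
    out = {label: 100.0 * count / n for label, count in bins.items()}
    out["mean"] = float(v.mean())
    out["median"] = float(np.median(v))
    out["n"] = n
    return out


def rpm(mapped_reads: float, total_reads: float) -> float:
    """Reads per million: 1e6 * mapped / total."""
    if total_reads <= 0:
        raise ValueError("total reads must be positive")
    if mapped_reads < 0:
        raise ValueError("mapped reads must be nonnegative")
    return 1e6 * mapped_reads / total_reads


def layer_summary(table: pd.DataFrame, value_column: str = "percent") -> pd.DataFrame:
    """Bin the per-sample values of ``value_column`` within each depth layer.

    ``table`` needs a ``layer`` column; returns one row per layer with the
    occupancy-bin percentages, mean, median and sample count.
    """
    if "layer" not in table.columns:
        raise ValueError("table needs a 'layer' column")
    rows = {}
    for layer, grp in table.groupby("layer", sort=True):
        rows[layer] = abundance_bins(grp[value_column])
    out = pd.DataFrame(rows).T
    out.index.name = "layer"
    return out
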