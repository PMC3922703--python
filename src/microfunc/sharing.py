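"""Gene sharing between hosts and the shared-gene saturation curve.

Quantifies how many detected genes two hosts have in common, the fraction
of a host group's gene pool shared by all of its members (the group
functional core), and how the shared-gene count decays and saturates as
hosts are added one by one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "pairwise_shared_fraction",
    "pairwise_sharing_matrix",
    "shared_percentage",
    "group_core_fraction",
    "GroupCoreFraction",
    "saturation_curve",
]


def pairwise_shared_fraction(
    detected: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    denominator: str = "union",
) -> float:
    """Percentage of genes shared between two samples.

    ``denominator`` selects the reference pool: ``"union"`` (default,
    |A∪B|), ``"mean"`` ((|A|+|B|)/2) or ``"min"`` (min(|A|,|B|)).
    """
    a = np.asarray(detected[sample_a], dtype=bool)
    b = np.asarray(detected[sample_b], dtype=bool)
    inter = int((a & b).sum())
    union = int((a | b).sum())
    if union == 0:
        raise ValueError(f"samples {sample_a} and {sample_b} share an empty union")
    if denominator == "union":
        denom = union
    elif denominator == "mean":
        denom = (int(a.sum()) + int(b.sum())) / 2
    elif denominator == "min":
        denom = min(int(a.sum()), int(b.sum()))
    else:
        raise ValueError(f"unknown denominator convention: {denominator!r}")
    return 100.0 * inter / denom


def pairwise_sharing_matrix(
    detected: pd.DataFrame, samples=None, denominator: str = "union"
) -> pd.DataFrame:
    """Symmetric sample-by-sample matrix of pairwise shared percentages.

    The diagonal is 100 by definition.
    """
    if samples is None:
        samples = list(detected.columns)
    out = pd.DataFrame(100.0, index=samples, columns=samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            v = pairwise_shared_fraction(detected, a, b, denominator)
            out.loc[a, b] = out.loc[b, a] = v
    return out


def shared_percentage(n_shared: int, n_total: int) -> float:
    """Shared percentage 100*n_shared/n_total rounded to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_shared / n_total, 1)


class GroupCoreFraction(NamedTuple):
    n_shared: int
    n_total: int
    percentage: float


def group_core_fraction(detected: pd.DataFrame, sample_subset) -> GroupCoreFraction:
    """Size of a sample subset's functional core relative to its gene pool.

    ``n_shared`` counts genes detected in *every* subset sample, ``n_total``
    genes detected in at least one, and ``percentage`` their ratio to one
    decimal place.
    """
    sample_subset = list(sample_subset)
    if not sample_subset:
        raise ValueError("sample subset is empty")
    sub = np.asarray(detected[sample_subset], dtype=bool)
    n_shared = int(sub.all(axis=1).sum())
    n_total = int(sub.any(axis=1).sum())
    return GroupCoreFraction(n_shared, n_total, shared_percentage(n_shared, n_total))


@dataclass
class SaturationCurve:
    """Mean ± sd of the shared-gene count among k hosts, for k = 1..n."""

    table: pd.DataFrame  # columns: k, mean_shared, sd_shared
    n_iter: int

    def anchor(self) -> float:
        """Shared-gene count at k = n (the subset core size, sd 0)."""
        return float(self.table["mean_shared"].iloc[-1])


def saturation_curve(
    detected: pd.DataFrame,
    sample_pool=None,
    n_iter: int = 100,
    seed: int | None = None,
) -> SaturationCurve:
    """Shared-gene saturation curve over random host orderings.

    Each of ``n_iter`` iterations draws a random ordering of the pool and,
    for every prefix length k, counts the genes detected in all first k
    hosts.  A prefix of a uniform random ordering is a uniform random
    k-subset, so the per-k means estimate the subset-average shared count,
    while the within-iteration nesting makes every iteration (and hence the
    mean curve) monotone non-increasing.  k = n is identical in every
    iteration, so the curve is anchored exactly at the pool core size with
    zero standard deviation.
    """
    if sample_pool is None:
        sample_pool = list(detected.columns)
    sample_pool = list(sample_pool)
    n = len(sample_pool)
    if n < 1:
        raise ValueError("sample pool is empty")
    rng = np.random.default_rng(seed)
    M = np.asarray(detected[sample_pool], dtype=bool)
    counts = np.empty((n_iter, n), dtype=int)
    for it in range(n_iter):
        order = rng.permutation(n)
        running = np.ones(M.shape[0], dtype=bool)
        for k, j in enumerate(order):
            running &= M[:, j]
            counts[it, k] = int(running.sum())
    table = pd.DataFrame(
        {
            "k": np.arange(1, n + 1),
            "mean_shared": counts.mean(axis=0),
            "sd_shared": counts.std(axis=0, ddof=0),
        }
    )
    return SaturationCurve(table=table, n_iter=n_iter)
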