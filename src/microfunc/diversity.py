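"""Per-sample diversity indices and permutation-based group comparisons.

Shannon diversity is reported in nats (natural log) and "Simpson" as the
inverse Simpson index 1/sum(p^2), the effective number of equally abundant
genes — the conventions under which values of ~7.5 and several hundred to a
couple of thousand, respectively, arise for samples of ~2,500 genes.

Group comparisons use permutation t-tests: the observed statistic is a
Welch (unequal-variance) t, and its null distribution is obtained by
permuting the group labels — exhaustively when the number of label
assignments is small, otherwise by seeded Monte Carlo with the standard +1
correction.  Significance tiers follow the strict-inequality convention
NS / * (p<0.1) / ** (p<0.05) / *** (p<0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "diversity_indices",
    "permutation_t_test",
    "significance_tier",
    "core_variability_ranking",
    "compare_groups_rowwise",
    "PermutationTestResult",
]

#: Label assignments at or below this count are enumerated exhaustively.
EXHAUSTIVE_LIMIT = 20_000


def diversity_indices(normalized: pd.DataFrame) -> pd.DataFrame:
    """Richness, Shannon (nats) and inverse Simpson per sample.

    ``normalized`` is a gene-by-sample relative-abundance matrix whose
    columns sum to 1 (undetected genes 0).  Richness counts the nonzero
    entries; Shannon is -sum(p ln p) over nonzero p; inverse Simpson is
    1/sum(p^2).
    """
    X = np.asarray(normalized, dtype=float)
    if (X.sum(axis=0) <= 0).any():
        bad = normalized.columns[X.sum(axis=0) <= 0]
        raise ValueError(f"all-zero sample column(s): {list(bad)}")
    richness = (X > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(X > 0, X * np.log(X), 0.0)
    shannon = -plogp.sum(axis=0)
    inv_simpson = 1.0 / (X**2).sum(axis=0)
    return pd.DataFrame(
        {
            "richness": richness,
            "shannon": shannon,
            "inverse_simpson": inv_simpson,
        },
        index=normalized.columns,
    )


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    tier: str
    n_perm: int
    exhaustive: bool


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    va = a.var(ddof=1) / na
    vb = b.var(ddof=1) / nb
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0  # both groups constant; equal means => t := 0
    return float((a.mean() - b.mean()) / denom)


def permutation_t_test(
    values,
    labels,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Two-sided permutation t-test of a two-group difference in means.

    The statistic is Welch's t on the observed labels.  The null is built
    by reassigning group labels: all C(n, n1) assignments when that count
    is <= 20,000, else ``n_perm`` Monte Carlo draws (seeded).  The
    two-sided p is the fraction of permuted |t| >= observed |t| (with the
    +1 correction in the Monte Carlo case, so p is never 0).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two groups, got {list(uniq)}")
    mask_a = labels == uniq[0]
    na, nb = int(mask_a.sum()), int((~mask_a).sum())
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two samples")
    t_obs = _welch_t(values[mask_a], values[~mask_a])

    n = len(values)
    n_assign = comb(n, na)
    if n_assign <= EXHAUSTIVE_LIMIT:
        count = 0
        for idx in combinations(range(n), na):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            if abs(_welch_t(values[sel], values[~sel])) >= abs(t_obs) - 1e-12:
                count += 1
        p = count / n_assign
        return PermutationTestResult(t_obs, p, significance_tier(p), n_assign, True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        sel = np.zeros(n, dtype=bool)
        sel[perm[:na]] = True
        if abs(_welch_t(values[sel], values[~sel])) >= abs(t_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationTestResult(t_obs, p, significance_tier(p), n_perm, False)


def significance_tier(p: float) -> str:
    """Map a p-value to the NS / * / ** / *** tiers (strict inequalities)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value out of range: {p}")
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return "NS"


def core_variability_ranking(
    normalized: pd.DataFrame, core_genes
) -> pd.DataFrame:
    """Rank core genes by the sample standard deviation of their abundance.

    Returns a table sorted by descending sd with boolean ``most_varied`` /
    ``least_varied`` flags on the two extremes (ties broken by gene id for
    determinism).
    """
    core_genes = pd.Index(core_genes)
    if len(core_genes) == 0:
        raise ValueError("core gene set is empty")
    sub = normalized.loc[core_genes]
    sd = sub.std(axis=1, ddof=1)
    table = (
        pd.DataFrame({"sd": sd})
        .rename_axis("gene")
        .sort_values(["sd", "gene"], ascending=[False, True], kind="stable")
    )
    table["rank"] = np.arange(1, len(table) + 1)
    table["most_varied"] = False
    table["least_varied"] = False
    table.iloc[0, table.columns.get_loc("most_varied")] = True
    table.iloc[-1, table.columns.get_loc("least_varied")] = True
    return table


def _welch_t_rows(X: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Vectorized Welch t for every row of X under one label assignment."""
    A = X[:, mask_a]
    B = X[:, ~mask_a]
    na, nb = A.shape[1], B.shape[1]
    va = A.var(axis=1, ddof=1) / na
    vb = B.var(axis=1, ddof=1) / nb
    denom = np.sqrt(va + vb)
    diff = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def compare_groups_rowwise(
    table: pd.DataFrame,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation t-test of every row (gene or category) between two groups.

    All rows share the same set of label permutations, which keeps the test
    exact per row while making thousands of rows tractable.  Returns a
    table with the Welch statistic, permutation p, significance tier and a
    Benjamini-Hochberg adjusted p column (reported for reference; tiers
    follow the raw p).
    """
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two groups, got {list(uniq)}")
    X = np.asarray(table, dtype=float)
    mask_a = labels == uniq[0]
    t_obs = _welch_t_rows(X, mask_a)

    rng = np.random.default_rng(seed)
    n = X.shape[1]
    na = int(mask_a.sum())
    exceed = np.zeros(X.shape[0], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        sel = np.zeros(n, dtype=bool)
        sel[perm[:na]] = True
        exceed += np.abs(_welch_t_rows(X, sel)) >= np.abs(t_obs) - 1e-12
    p = (exceed + 1) / (n_perm + 1)
    out = pd.DataFrame(
        {
            "statistic": t_obs,
            "p_value": p,
            "tier": [significance_tier(v) for v in p],
            "p_bh": multipletests(p, method="fdr_bh")[1],
        },
        index=table.index,
    )
    return out
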