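"""Presence-pattern triplet biomarkers for host-group discrimination.

The discriminative unit is a *triplet feature*: three non-core genes whose
joint 0/1 presence pattern separates the two host groups.  Each group's
samples are split into training and testing subsets in every possible way
(10 samples split 7/3 gives 120 groupings per group).  A bootstrap loop
draws one split per group, ranks genes by their training-set presence
difference between groups (the "feature selection" step), forms candidate
triplets from the most discriminative genes, scores each triplet on the
training samples, and classifies the held-out samples by Hamming-nearest
group consensus (the "classification" step).  Triplets whose mean held-out
accuracy across all splits in which they were evaluated reaches the
threshold (default 80%) are selected; genes appearing in the selected
triplets of exactly one group are flagged as *exclusive-pattern* genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "GroupingSplit",
    "BiomarkerReport",
    "enumerate_groupings",
    "evaluate_triplet",
    "select_triplets",
    "detect_exclusive_genes",
]


@dataclass(frozen=True)
class GroupingSplit:
    """One train/test split of a host group's samples."""

    train: tuple
    test: tuple
    index: int  # 1-based position in the lexicographic enumeration

    def __post_init__(self):
        if set(self.train) & set(self.test):
            raise ValueError("train and test sets overlap")


def enumerate_groupings(group_samples, n_test: int = 3) -> list[GroupingSplit]:
    """All C(n, n_test) train/test splits in deterministic order.

    The test subsets are enumerated lexicographically over sample
    positions, so 10 samples with ``n_test=3`` yield exactly 120 splits.
    """
    group_samples = list(group_samples)
    n = len(group_samples)
    if not 0 < n_test < n:
        raise ValueError(f"n_test must be in (0, {n}), got {n_test}")
    splits = []
    for i, test_idx in enumerate(combinations(range(n), n_test), start=1):
        test = tuple(group_samples[j] for j in test_idx)
        train = tuple(s for s in group_samples if s not in test)
        splits.append(GroupingSplit(train=train, test=test, index=i))
    assert len(splits) == comb(n, n_test)
    return splits


def _consensus(block: np.ndarray) -> np.ndarray:
    """Majority 0/1 per gene over training samples; ties become 0.5.

    The 0.5 encoding makes an ambiguous bit equidistant from presence and
    absence, so it pushes samples toward ties — which are counted against
    the triplet — rather than silently favoring either group.
    """
    freq = block.mean(axis=-1)
    cons = np.where(freq > 0.5, 1.0, 0.0)
    return np.where(np.isclose(freq, 0.5), 0.5, cons)


def evaluate_triplet(
    triplet_genes,
    noncore_binary: pd.DataFrame,
    split_a: GroupingSplit,
    split_b: GroupingSplit,
) -> tuple[float, float]:
    """Training discrimination score and held-out accuracy of one triplet.

    Group consensus patterns are the per-gene training majorities.  The
    training score is the fraction of training samples whose 3-bit profile
    is strictly closer (Hamming) to their own group's consensus than to the
    other's.  Each test sample is assigned to the group with the nearer
    consensus; ties are unclassified and counted incorrect.  Accuracy is
    the fraction of correctly assigned test samples.
    """
    triplet_genes = list(triplet_genes)
    if len(set(triplet_genes)) != 3:
        raise ValueError("a triplet needs three distinct genes")
    missing = [g for g in triplet_genes if g not in noncore_binary.index]
    if missing:
        raise ValueError(
            f"genes not in the non-core binary matrix (core or unknown): {missing}"
        )
    B = noncore_binary.loc[triplet_genes]
    cons_a = _consensus(np.asarray(B[list(split_a.train)], dtype=float))
    cons_b = _consensus(np.asarray(B[list(split_b.train)], dtype=float))

    def dist(sample: str, cons: np.ndarray) -> float:
        return float(np.abs(np.asarray(B[sample], dtype=float) - cons).sum())

    correct_train = 0
    for s in split_a.train:
        correct_train += dist(s, cons_a) < dist(s, cons_b)
    for s in split_b.train:
        correct_train += dist(s, cons_b) < dist(s, cons_a)
    n_train = len(split_a.train) + len(split_b.train)
    score = correct_train / n_train

    correct_test = 0
    for s in split_a.test:
        correct_test += dist(s, cons_a) < dist(s, cons_b)
    for s in split_b.test:
        correct_test += dist(s, cons_b) < dist(s, cons_a)
    n_test = len(split_a.test) + len(split_b.test)
    accuracy = correct_test / n_test
    return score, accuracy


def _evaluate_many(
    B: np.ndarray,
    triplets: np.ndarray,
    train_a: np.ndarray,
    train_b: np.ndarray,
    test_a: np.ndarray,
    test_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (score, accuracy) for many triplets at once.

    ``B`` is the gene-by-sample 0/1 matrix, ``triplets`` an (m, 3) array of
    row indices, the remaining arguments column-index arrays.  Semantics
    match :func:`evaluate_triplet` exactly.
    """
    cons_a = _consensus(B[:, train_a])  # per gene
    cons_b = _consensus(B[:, train_b])
    d_a = np.abs(B - cons_a[:, None])  # gene x sample distance contribution
    d_b = np.abs(B - cons_b[:, None])
    # triplet x sample distances
    D_a = d_a[triplets].sum(axis=1)
    D_b = d_b[triplets].sum(axis=1)
    train = np.concatenate([train_a, train_b])
    own_train = np.concatenate(
        [D_a[:, train_a], D_b[:, train_b]], axis=1
    )
    other_train = np.concatenate(
        [D_b[:, train_a], D_a[:, train_b]], axis=1
    )
    scores = (own_train < other_train).mean(axis=1)
    own_test = np.concatenate([D_a[:, test_a], D_b[:, test_b]], axis=1)
    other_test = np.concatenate([D_b[:, test_a], D_a[:, test_b]], axis=1)
    acc = (own_test < other_test).mean(axis=1)
    assert len(train) == own_train.shape[1]
    return scores, acc


@dataclass
class BiomarkerReport:
    """Selected triplet features, gene frequencies and exclusive genes."""

    triplets: pd.DataFrame  # genes, group, mean_score, mean_accuracy, n_splits, rank
    gene_frequencies: pd.DataFrame  # gene, group, count
    exclusive_genes: dict  # gene -> group
    provenance: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return len(self.triplets)

    def triplets_for(self, group: str) -> pd.DataFrame:
        return self.triplets[self.triplets["group"] == group]


def _assign_group(cons_a: np.ndarray, cons_b: np.ndarray, freq_a, freq_b,
                  names: tuple[str, str]) -> str:
    """Group whose consensus pattern is predominantly 'present'."""
    ones_a = float((cons_a == 1).sum())
    ones_b = float((cons_b == 1).sum())
    if ones_a != ones_b:
        return names[0] if ones_a > ones_b else names[1]
    if freq_a != freq_b:
        return names[0] if freq_a > freq_b else names[1]
    return names[0]


def select_triplets(
    noncore_binary: pd.DataFrame,
    groups: dict,
    accuracy_threshold: float = 0.8,
    n_bootstrap: int = 50,
    n_top_genes: int = 25,
    n_candidates_per_split: int = 50_000,
    n_test: int = 3,
    seed: int | None = None,
) -> BiomarkerReport:
    """Bootstrap triplet-feature selection over the train/test split grid.

    Parameters
    ----------
    noncore_binary
        0/1 presence matrix of the non-core genes (genes x samples).
    groups
        Mapping of exactly two group labels to their sample-id lists.
    accuracy_threshold
        A triplet is selected when its mean held-out accuracy over every
        split in which it was evaluated reaches this value (0.8 by
        default; 0 returns everything evaluated).
    n_bootstrap
        Number of bootstrap iterations; each draws one split per group
        uniformly from the full enumeration (e.g. the 120 x 120 grid for
        10+10 samples split 7/3).
    n_top_genes
        Feature-selection width: candidate triplets are formed from the
        genes with the largest training-set presence difference between
        the groups.  All C(n_top_genes, 3) triplets are evaluated unless
        that exceeds ``n_candidates_per_split``, in which case a random
        subset of that size is drawn.
    """
    if not 0 <= accuracy_threshold <= 1:
        raise ValueError("accuracy_threshold must lie in [0, 1]")
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    if len(noncore_binary) < 3:
        raise ValueError("need at least three non-core genes")
    names = tuple(groups)
    samples_a, samples_b = (list(groups[g]) for g in names)
    rng = np.random.default_rng(seed)

    cols = list(noncore_binary.columns)
    col_pos = {s: i for i, s in enumerate(cols)}
    B = np.asarray(noncore_binary, dtype=float)
    genes = np.asarray(noncore_binary.index)
    splits_a = enumerate_groupings(samples_a, n_test)
    splits_b = enumerate_groupings(samples_b, n_test)

    # accumulate per-triplet statistics across bootstrap iterations
    stats: dict[tuple, list] = {}
    for _ in range(n_bootstrap):
        sa = splits_a[rng.integers(len(splits_a))]
        sb = splits_b[rng.integers(len(splits_b))]
        train_a = np.array([col_pos[s] for s in sa.train])
        train_b = np.array([col_pos[s] for s in sb.train])
        test_a = np.array([col_pos[s] for s in sa.test])
        test_b = np.array([col_pos[s] for s in sb.test])

        # feature selection: training presence-frequency gap per gene
        gap = np.abs(B[:, train_a].mean(axis=1) - B[:, train_b].mean(axis=1))
        k = min(n_top_genes, len(genes))
        top = np.argsort(-gap, kind="stable")[:k]
        if comb(k, 3) <= n_candidates_per_split:
            cand = np.array(list(combinations(sorted(top), 3)))
        else:
            cand = np.sort(
                np.array(
                    [rng.choice(top, size=3, replace=False) for _ in range(n_candidates_per_split)]
                ),
                axis=1,
            )
            cand = np.unique(cand, axis=0)
        scores, acc = _evaluate_many(B, cand, train_a, train_b, test_a, test_b)
        for t, sc, ac in zip(map(tuple, cand), scores, acc):
            rec = stats.setdefault(t, [0.0, 0.0, 0])
            rec[0] += sc
            rec[1] += ac
            rec[2] += 1

    freq_a = B[:, [col_pos[s] for s in samples_a]].mean(axis=1)
    freq_b = B[:, [col_pos[s] for s in samples_b]].mean(axis=1)
    cons_full_a = _consensus(B[:, [col_pos[s] for s in samples_a]])
    cons_full_b = _consensus(B[:, [col_pos[s] for s in samples_b]])

    rows = []
    for t, (sum_sc, sum_ac, n) in stats.items():
        mean_ac = sum_ac / n
        if mean_ac + 1e-12 < accuracy_threshold:
            continue
        idx = np.array(t)
        grp = _assign_group(
            cons_full_a[idx], cons_full_b[idx],
            float(freq_a[idx].sum()), float(freq_b[idx].sum()), names,
        )
        cons_own = cons_full_a[idx] if grp == names[0] else cons_full_b[idx]
        rows.append(
            {
                "genes": tuple(genes[idx]),
                "group": grp,
                "mean_score": sum_sc / n,
                "mean_accuracy": mean_ac,
                "n_splits": n,
                "n_present_bits": int((cons_own == 1).sum()),
                "mean_gene_gap": float(np.abs(freq_a[idx] - freq_b[idx]).mean()),
            }
        )
    triplet_df = pd.DataFrame(
        rows,
        columns=["genes", "group", "mean_score", "mean_accuracy", "n_splits",
                 "n_present_bits", "mean_gene_gap"],
    )
    if len(triplet_df):
        # equally accurate triplets are ordered by the marginal group
        # contrast of their member genes, then by how fully "present" the
        # pattern is in the assigned group: among observationally tied
        # features, the one built from individually sharper, group-present
        # genes is the more interpretable biomarker
        triplet_df = triplet_df.sort_values(
            ["mean_accuracy", "n_splits", "mean_score", "mean_gene_gap",
             "n_present_bits", "genes"],
            ascending=[False, False, False, False, False, True],
            kind="stable",
        ).reset_index(drop=True)
        triplet_df["rank"] = (
            triplet_df.groupby("group").cumcount() + 1
        )
    else:
        triplet_df["rank"] = pd.Series(dtype=int)

    freq_rows = []
    for grp in names:
        sub = triplet_df[triplet_df["group"] == grp]
        counts: dict = {}
        for t in sub["genes"]:
            for g in t:
                counts[g] = counts.get(g, 0) + 1
        for g, c in sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0]))):
            freq_rows.append({"gene": g, "group": grp, "count": c})
    freq_df = pd.DataFrame(freq_rows, columns=["gene", "group", "count"])

    report = BiomarkerReport(
        triplets=triplet_df,
        gene_frequencies=freq_df,
        exclusive_genes={},
        provenance={
            "seed": seed,
            "n_bootstrap": n_bootstrap,
            "accuracy_threshold": accuracy_threshold,
            "n_top_genes": n_top_genes,
            "n_candidates_per_split": n_candidates_per_split,
            "n_test": n_test,
            "groups": {g: list(groups[g]) for g in names},
        },
    )
    report.exclusive_genes = detect_exclusive_genes(report)
    if report.n_selected == 0:
        import warnings

        warnings.warn("no triplet passed the accuracy threshold", stacklevel=2)
    return report


def detect_exclusive_genes(report: BiomarkerReport, top_n: int | None = None) -> dict:
    """Genes appearing in the selected triplets of exactly one group.

    With ``top_n`` set, only each group's ``top_n`` best-ranked triplets are
    considered — the exclusive pattern is a property of a shortlist of
    markers, and over an exhaustively large selection almost every frequent
    gene eventually appears in both groups' lists.  Returns a mapping
    gene -> group label (e.g. ``{"gene_0042": "H"}``).
    """
    by_group: dict[str, set] = {}
    for _, row in report.triplets.iterrows():
        if top_n is not None and "rank" in row and row["rank"] > top_n:
            continue
        by_group.setdefault(row["group"], set()).update(row["genes"])
    groups = list(by_group)
    exclusive = {}
    for grp in groups:
        others = set().union(*(by_group[g] for g in groups if g != grp)) if len(groups) > 1 else set()
        for gene in sorted(by_group[grp] - others, key=str):
            exclusive[gene] = grp
    return exclusive
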