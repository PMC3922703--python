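"""Community ordination and dissimilarity testing.

Correspondence analysis (CA) decomposes the chi-square standardized
residuals of a nonnegative gene-by-sample table by SVD; detrended
correspondence analysis (DCA) removes the arch effect by segment-wise
centering of the second axis along the first (no nonlinear rescaling).
The multi-response permutation procedure (MRPP) tests whether within-group
sample distances are smaller than expected under random relabeling,
reporting the weighted mean within-group distance delta, the
chance-corrected effect size A = 1 - delta_obs/delta_exp, and a
permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "OrdinationResult",
    "MrppResult",
    "correspondence_analysis",
    "detrended_ca",
    "mrpp",
]


@dataclass
class OrdinationResult:
    """Sample and gene scores on the first two ordination axes."""

    sample_scores: pd.DataFrame  # columns axis1, axis2
    gene_scores: pd.DataFrame
    eigenvalues: np.ndarray
    n_segments: int | None = None  # set when detrended


def _ca_decomposition(abundance: pd.DataFrame):
    X = np.asarray(abundance, dtype=float)
    if (X < 0).any():
        raise ValueError("abundance matrix must be nonnegative")
    zero_rows = abundance.index[X.sum(axis=1) == 0]
    zero_cols = abundance.columns[X.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        raise ValueError(
            f"all-zero rows {list(zero_rows[:5])} / columns {list(zero_cols[:5])}"
        )
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    return r, c, U, s, Vt


def correspondence_analysis(abundance: pd.DataFrame) -> OrdinationResult:
    """Classical correspondence analysis of a gene-by-sample table.

    Rows are genes, columns samples.  Scores are principal coordinates
    (weighted standard coordinates scaled by the singular values); the
    eigenvalues are the squared singular values, each in [0, 1].
    """
    r, c, U, s, Vt = _ca_decomposition(abundance)
    n_axes = min(2, len(s))
    gene_scores = (U[:, :n_axes] / np.sqrt(r)[:, None]) * s[:n_axes]
    sample_scores = (Vt[:n_axes].T / np.sqrt(c)[:, None]) * s[:n_axes]
    cols = [f"axis{i + 1}" for i in range(n_axes)]
    return OrdinationResult(
        sample_scores=pd.DataFrame(sample_scores, index=abundance.columns, columns=cols),
        gene_scores=pd.DataFrame(gene_scores, index=abundance.index, columns=cols),
        eigenvalues=s[:n_axes] ** 2,
    )


def _detrend(axis1: np.ndarray, axis2: np.ndarray, n_segments: int) -> np.ndarray:
    lo, hi = axis1.min(), axis1.max()
    if hi - lo <= 1e-12 * max(1.0, abs(hi), abs(lo)):
        raise ValueError("degenerate axis-1 range; cannot detrend")
    # right-closed equal-width bins over the axis-1 range
    edges = np.linspace(lo, hi, n_segments + 1)
    which = np.clip(np.searchsorted(edges, axis1, side="right") - 1, 0, n_segments - 1)
    out = axis2.astype(float).copy()
    for b in range(n_segments):
        m = which == b
        if m.any():
            out[m] -= out[m].mean()
    return out


def detrended_ca(abundance: pd.DataFrame, n_segments: int = 26) -> OrdinationResult:
    """Detrending-by-segments DCA of a gene-by-sample table.

    Axis 1 is the CA first axis unchanged.  Sample (and gene) axis-2 scores
    are centered within each of ``n_segments`` equal-width bins of the
    respective axis-1 range, which flattens the quadratic arch that CA
    produces on gradient-structured data.  Hill's nonlinear rescaling is
    deliberately not applied.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    res = correspondence_analysis(abundance)
    if res.sample_scores.shape[1] < 2:
        raise ValueError("need at least two axes to detrend")
    for scores in (res.sample_scores, res.gene_scores):
        scores["axis2"] = _detrend(
            scores["axis1"].to_numpy(), scores["axis2"].to_numpy(), n_segments
        )
    res.n_segments = n_segments
    return res


@dataclass
class MrppResult:
    delta: float
    expected_delta: float
    A: float
    p_value: float
    n_perm: int
    metric: str


def _weighted_delta(D: np.ndarray, labels: np.ndarray, uniq, weights) -> float:
    delta = 0.0
    for g, w in zip(uniq, weights):
        idx = np.flatnonzero(labels == g)
        sub = D[np.ix_(idx, idx)]
        m = len(idx)
        delta += w * sub[np.triu_indices(m, k=1)].mean()
    return delta


def mrpp(
    data,
    labels,
    metric: str = "braycurtis",
    n_perm: int = 999,
    seed: int | None = None,
) -> MrppResult:
    """Multi-response permutation procedure on sample distances.

    ``data`` is either a gene-by-sample abundance DataFrame (distances are
    computed between sample columns with ``metric``, default Bray-Curtis)
    or an already-square sample distance matrix (``metric`` ignored, pass
    ``metric="precomputed"`` for clarity).  Groups are weighted by their
    relative size n_i/N (the classical choice).  The p-value is
    (#{delta_perm <= delta_obs} + 1)/(n_perm + 1).
    """
    labels = np.asarray(labels)
    if isinstance(data, pd.DataFrame) and data.shape[0] == data.shape[1] and np.allclose(
        np.asarray(data), np.asarray(data).T
    ) and metric == "precomputed":
        D = np.asarray(data, dtype=float)
    elif metric == "precomputed":
        D = np.asarray(data, dtype=float)
        if D.shape[0] != D.shape[1]:
            raise ValueError("precomputed distance matrix must be square")
    else:
        X = np.asarray(data, dtype=float).T  # samples become rows
        try:
            D = squareform(pdist(X, metric=metric))
        except ValueError as exc:
            raise ValueError(f"unknown distance metric {metric!r}") from exc
    n = D.shape[0]
    if len(labels) != n:
        raise ValueError("label length does not match the number of samples")
    uniq = pd.unique(labels)
    counts = np.array([(labels == g).sum() for g in uniq])
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >=2 groups with >=2 samples each")
    weights = counts / n

    delta_obs = _weighted_delta(D, labels, uniq, weights)
    rng = np.random.default_rng(seed)
    perm_deltas = np.empty(n_perm)
    for i in range(n_perm):
        perm_deltas[i] = _weighted_delta(D, labels[rng.permutation(n)], uniq, weights)
    expected = float(perm_deltas.mean())
    p = (int((perm_deltas <= delta_obs + 1e-12).sum()) + 1) / (n_perm + 1)
    A = 1.0 - delta_obs / expected if expected > 0 else 0.0
    return MrppResult(
        delta=float(delta_obs),
        expected_delta=expected,
        A=float(A),
        p_value=p,
        n_perm=n_perm,
        metric=metric,
    )
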