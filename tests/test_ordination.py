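"""Correspondence analysis, detrending and MRPP."""

import json
import shutil
import subprocess
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from microfunc import correspondence_analysis, detrended_ca, mrpp, simulate_dataset
from microfunc.ordination import _weighted_delta

from conftest import small_config


def _frame(values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))], columns=samples)


def _gradient_community(n_genes=40, n_samples=15, seed=0):
    """Unimodal gene responses along a sample gradient (classic arch data)."""
    rng = np.random.default_rng(seed)
    grad = np.linspace(0, 10, n_samples)
    optima = rng.uniform(0, 10, n_genes)
    X = np.exp(-((grad[None, :] - optima[:, None]) ** 2) / 4.0) * rng.uniform(
        0.5, 2.0, (n_genes, 1)
    )
    return _frame(X + 1e-6)


class TestCorrespondenceAnalysis:
    def test_identical_samples_get_identical_scores(self):
        rng = np.random.default_rng(1)
        X = rng.random((20, 5))
        X[:, 4] = X[:, 3]
        res = correspondence_analysis(_frame(X))
        assert np.allclose(
            res.sample_scores.loc["s3"], res.sample_scores.loc["s4"], atol=1e-9
        )

    def test_block_diagonal_separates_on_axis_one(self):
        X = np.zeros((6, 6))
        X[:3, :3] = 1.0
        X[3:, 3:] = 1.0
        res = correspondence_analysis(_frame(X))
        a1 = res.sample_scores["axis1"].to_numpy()
        assert np.ptp(np.sign(a1[:3])) == 0 and np.ptp(np.sign(a1[3:])) == 0
        assert np.sign(a1[0]) == -np.sign(a1[3])

    def test_axis_one_matches_reciprocal_averaging_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.random((5, 4)) + 0.1
        frame = _frame(X)
        res = correspondence_analysis(frame)

        # reciprocal averaging: alternate row/column weighted averages,
        # projecting out the trivial constant solution
        P = X / X.sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        x = rng.standard_normal(4)
        for _ in range(5000):
            y = (P @ x) / r
            x_new = (P.T @ y) / c
            x_new = x_new - (c * x_new).sum()  # remove trivial component
            x = x_new / np.sqrt((c * x_new**2).sum())
        ours = res.sample_scores["axis1"].to_numpy()
        ours = ours / np.sqrt((c * ours**2).sum())
        assert min(
            np.abs(ours - x).max(), np.abs(ours + x).max()
        ) < 1e-6

    def test_eigenvalues_bounded_and_sorted(self):
        res = correspondence_analysis(_gradient_community())
        ev = res.eigenvalues
        assert (ev >= -1e-12).all() and (ev <= 1 + 1e-12).all()
        assert ev[0] >= ev[1]

    def test_zero_row_rejected(self):
        X = np.ones((3, 3))
        X[1] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            correspondence_analysis(_frame(X))


class TestDetrendedCA:
    def test_axis_one_untouched_by_detrending(self):
        frame = _gradient_community()
        ca = correspondence_analysis(frame)
        dca = detrended_ca(frame, n_segments=10)
        assert np.allclose(
            ca.sample_scores["axis1"], dca.sample_scores["axis1"], atol=1e-12
        )

    def test_detrending_flattens_the_arch(self):
        frame = _gradient_community(n_genes=60, n_samples=25, seed=2)
        ca = correspondence_analysis(frame)
        dca = detrended_ca(frame, n_segments=8)
        assert dca.sample_scores["axis2"].var() < ca.sample_scores["axis2"].var()

    def test_single_segment_is_global_centering(self):
        frame = _gradient_community(seed=5)
        ca = correspondence_analysis(frame)
        dca = detrended_ca(frame, n_segments=1)
        expected = ca.sample_scores["axis2"] - ca.sample_scores["axis2"].mean()
        assert np.allclose(dca.sample_scores["axis2"], expected, atol=1e-12)

    def test_degenerate_axis_range_rejected(self):
        # a structureless table has no axis-1 gradient to detrend along
        with pytest.raises(ValueError):
            detrended_ca(_frame(np.ones((4, 4))))

    def test_group_separation_recovered_from_simulations(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            dataset, _ = simulate_dataset(
                small_config(
                    n_genes=600, n_samples_per_group=10, group_effect=1.5, seed=seed
                )
            )
            from microfunc import build_profile

            profile = build_profile(dataset)
            dca = detrended_ca(profile.normalized)
            scores = dca.sample_scores[["axis1", "axis2"]].to_numpy()
            groups = np.array([s[0] for s in dca.sample_scores.index])
            cen_h = scores[groups == "H"].mean(axis=0)
            cen_c = scores[groups == "C"].mean(axis=0)
            between = np.linalg.norm(cen_h - cen_c)
            within = np.mean(
                [
                    np.linalg.norm(scores[groups == g] - cen, axis=1).mean()
                    for g, cen in (("H", cen_h), ("C", cen_c))
                ]
            )
            wins += between > within
        assert wins >= 0.9 * n_seeds


class TestMrpp:
    def test_tight_distinct_clusters_give_minimal_p(self):
        X = np.zeros((5, 6))
        X[:, :3] = [[1], [1], [0], [0], [0]]
        X[:, 3:] = [[0], [0], [1], [1], [1]]
        res = mrpp(_frame(X + 1e-9), ["a"] * 3 + ["b"] * 3, n_perm=999, seed=0)
        assert res.delta == pytest.approx(0.0, abs=1e-9)
        # only label permutations reproducing the 3|3 partition (or its
        # mirror) reach delta 0, so the attainable minimum p is ~0.1
        assert res.p_value < 0.15
        assert res.A > 0

    def test_monte_carlo_p_within_3_se_of_exhaustive(self):
        rng = np.random.default_rng(10)
        for trial in range(3):
            X = rng.random((8, 6))
            X[:, 3:] += trial * 0.3
            frame = _frame(X)
            labels = np.array(["a"] * 3 + ["b"] * 3)
            D = squareform(pdist(X.T, metric="braycurtis"))
            delta_obs = _weighted_delta(D, labels, ["a", "b"], [0.5, 0.5])
            deltas = []
            for pos in combinations(range(6), 3):
                lab = np.array(["b"] * 6)
                lab[list(pos)] = "a"
                deltas.append(_weighted_delta(D, lab, ["a", "b"], [0.5, 0.5]))
            exact_p = np.mean([d <= delta_obs + 1e-12 for d in deltas])
            n_perm = 4999
            res = mrpp(frame, labels, n_perm=n_perm, seed=trial)
            se = np.sqrt(exact_p * (1 - exact_p) / n_perm)
            assert abs(res.p_value - exact_p) <= 3 * se + 1 / (n_perm + 1)

    def test_a_statistic_identity(self):
        rng = np.random.default_rng(3)
        frame = _frame(rng.random((10, 8)))
        res = mrpp(frame, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=1)
        assert res.A == pytest.approx(1 - res.delta / res.expected_delta, abs=1e-12)
        assert 0 < res.p_value <= 1

    def test_unknown_metric_rejected(self):
        frame = _frame(np.random.default_rng(0).random((4, 4)))
        with pytest.raises(ValueError, match="metric"):
            mrpp(frame, ["a", "a", "b", "b"], metric="nonsense")


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestVeganCrossCheck:
    """Independent R/vegan implementations as oracles on a small matrix."""

    def _run_r(self, script: str) -> dict:
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        return json.loads(proc.stdout.strip().splitlines()[-1])

    def test_ca_eigenvalues_match_vegan(self, tmp_path):
        rng = np.random.default_rng(11)
        frame = _frame(rng.random((12, 7)) + 0.05)
        path = tmp_path / "mat.tsv"
        frame.to_csv(path, sep="\t")
        res = correspondence_analysis(frame)
        out = self._run_r(
            f"""
            suppressMessages(library(vegan)); suppressMessages(library(jsonlite))
            x <- read.delim("{path}", row.names=1)
            ev <- cca(t(x))$CA$eig
            cat(toJSON(list(eig=unname(ev[1:2])), digits=I(12)))
            """
        )
        assert np.allclose(res.eigenvalues, out["eig"], rtol=1e-6)

    def test_mrpp_delta_and_a_match_vegan(self, tmp_path):
        rng = np.random.default_rng(12)
        X = rng.random((15, 10))
        X[:, 5:] += 0.4
        frame = _frame(X)
        path = tmp_path / "mat.tsv"
        frame.to_csv(path, sep="\t")
        labels = ["a"] * 5 + ["b"] * 5
        res = mrpp(frame, labels, n_perm=999, seed=3)
        out = self._run_r(
            f"""
            suppressMessages(library(vegan)); suppressMessages(library(jsonlite))
            x <- read.delim("{path}", row.names=1)
            g <- factor(c(rep("a",5), rep("b",5)))
            set.seed(1)
            m <- mrpp(t(x), g, permutations=999, distance="bray", weight.type=1)
            cat(toJSON(list(delta=m$delta, A=m$A, p=m$Pvalue), digits=I(12)))
            """
        )
        assert res.delta == pytest.approx(out["delta"][0], abs=1e-9)
        assert res.A == pytest.approx(out["A"][0], abs=0.05)
        assert abs(res.p_value - out["p"][0]) < 0.1
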