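"""SGCCA: scaling, sparsification, ascent, deflation, AVE, full fit."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crosstalknet import (
    CohortConfig,
    DataError,
    SgccaConfig,
    compute_ave,
    deflate_blocks,
    fit_component,
    fit_sgcca,
    generate_blocks,
    generate_latent_cohort,
    scale_blocks,
    soft_threshold_sparsify,
)
from crosstalknet.sgcca import ComponentFit
from tests.conftest import make_block


def standardized_blocks(rng, shapes):
    """Random blocks already in the scaled form fit_component expects."""
    out = []
    for n, p in shapes:
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0, ddof=1) / np.sqrt(p)
        out.append(X)
    return out


def brute_force_keepcount1(X_list):
    """Exhaustive search over all single-feature supports (centroid scheme).

    With keep-count 1 the weight is +-e_i, and |cov| is sign-free, so the
    optimum is the support triple maximizing the sum of pairwise |cov|.
    """
    n = X_list[0].shape[0]
    K = len(X_list)
    best = -np.inf
    for idx in itertools.product(*[range(X.shape[1]) for X in X_list]):
        cols = [X[:, i] for X, i in zip(X_list, idx)]
        obj = sum(
            abs(cols[k] @ cols[l]) / (n - 1)
            for k in range(K)
            for l in range(k + 1, K)
        )
        best = max(best, obj)
    return best


class TestScaleBlocks:
    def test_features_centered_and_block_scaled(self):
        rng = np.random.default_rng(0)
        block = make_block(rng.normal(5, 3, size=(30, 4)))
        scaled = scale_blocks({"fecal": block})["fecal"]
        assert np.abs(scaled.mean(axis=0)).max() < 1e-10
        Z = (block.values - block.values.mean(0)) / block.values.std(0, ddof=1)
        assert np.isclose(
            np.linalg.norm(scaled.to_numpy()), np.linalg.norm(Z) / 2.0
        )

    def test_single_standardized_feature_unchanged(self):
        x = np.random.default_rng(1).normal(size=30)
        x = (x - x.mean()) / x.std(ddof=1)
        scaled = scale_blocks({"fecal": make_block(x[:, None])})["fecal"]
        np.testing.assert_allclose(scaled.to_numpy().ravel(), x, atol=1e-12)

    def test_zero_variance_feature_rejected(self):
        with pytest.raises(DataError):
            scale_blocks({"fecal": make_block(np.ones((5, 2)))})


class TestSoftThresholdSparsify:
    def test_soft_threshold_then_normalize(self):
        # S_0.15 of (0.5, -0.2, 0.1) = (0.35, -0.05, 0); L2 = sqrt(0.125)
        expected = np.array([0.35, -0.05, 0.0]) / np.sqrt(0.125)
        bound = float(np.abs(expected).sum())
        out = soft_threshold_sparsify(np.array([0.5, -0.2, 0.1]), bound)
        np.testing.assert_allclose(out, [0.98995, -0.14142, 0.0], atol=1e-5)

    def test_no_bound_is_l2_normalization(self):
        w = np.array([3.0, -4.0])
        np.testing.assert_allclose(soft_threshold_sparsify(w), [0.6, -0.8])

    def test_keepcount_one_keeps_largest(self):
        out = soft_threshold_sparsify(np.array([0.5, -0.2, 0.1]), 1)
        np.testing.assert_allclose(out, [1.0, 0.0, 0.0])

    def test_keepcount_tie_prefers_earlier_feature(self):
        out = soft_threshold_sparsify(np.array([0.5, -0.5, 0.5]), 2)
        np.testing.assert_allclose(out, [np.sqrt(0.5), -np.sqrt(0.5), 0.0])

    def test_unit_norm_and_sparsity_always_hold(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            w = rng.normal(size=8)
            m = int(rng.integers(1, 8))
            out = soft_threshold_sparsify(w, m)
            assert np.isclose(np.linalg.norm(out), 1.0)
            assert np.count_nonzero(out) <= m


class TestFitComponent:
    def test_two_single_feature_blocks_reach_covariance(self):
        rng = np.random.default_rng(4)
        X_list = standardized_blocks(rng, [(40, 1), (40, 1)])
        fit = fit_component(X_list, SgccaConfig(seed=0))
        cov = float(X_list[0][:, 0] @ X_list[1][:, 0]) / 39
        assert np.isclose(fit.objective_trace[-1], abs(cov))
        assert {abs(fit.weights[0][0]), abs(fit.weights[1][0])} == {1.0}

    def test_objective_trace_non_decreasing(self):
        rng = np.random.default_rng(5)
        X_list = standardized_blocks(rng, [(30, 6), (30, 5), (30, 4)])
        fit = fit_component(X_list, SgccaConfig(seed=0), bounds=[2, 2, 2])
        trace = np.array(fit.objective_trace)
        assert (np.diff(trace) >= -1e-10).all()

    def test_matches_exhaustive_support_oracle(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X_list = standardized_blocks(rng, [(30, 3), (30, 3), (30, 3)])
            fit = fit_component(X_list, SgccaConfig(seed=seed), bounds=[1, 1, 1])
            oracle = brute_force_keepcount1(X_list)
            hits += fit.objective_trace[-1] >= (1 - 1e-6) * oracle
        assert hits >= 9

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        X_list = standardized_blocks(rng, [(30, 5), (30, 4)])
        perm = np.array([3, 0, 4, 1, 2])
        fit = fit_component(X_list, SgccaConfig(seed=0), bounds=[2, 2])
        X_perm = [X_list[0][:, perm], X_list[1]]
        fit_p = fit_component(X_perm, SgccaConfig(seed=0), bounds=[2, 2])
        # the centroid objective is invariant to a joint sign flip of a
        # block's weights, so compare after aligning the global sign
        expected = fit.weights[0][perm]
        flip = np.sign(fit_p.weights[0] @ expected)
        np.testing.assert_allclose(flip * fit_p.weights[0], expected, atol=1e-8)


class TestDeflation:
    def _fitted(self):
        rng = np.random.default_rng(7)
        X_list = standardized_blocks(rng, [(25, 4), (25, 3)])
        fit = fit_component(X_list, SgccaConfig(seed=0))
        return X_list, fit

    def test_deflation_is_idempotent(self):
        X_list, fit = self._fitted()
        once = deflate_blocks(X_list, fit.scores)
        twice = deflate_blocks(once, fit.scores)
        for a, b in zip(once, twice):
            assert np.linalg.norm(a - b) < 1e-10

    def test_deflated_columns_orthogonal_to_score(self):
        X_list, fit = self._fitted()
        for X, t in zip(deflate_blocks(X_list, fit.scores), fit.scores):
            assert np.abs(t @ X).max() < 1e-10

    def test_rank_drops_by_one(self):
        X_list, fit = self._fitted()
        X, t = X_list[0], fit.scores[0]
        deflated = deflate_blocks([X], [t])[0]
        assert np.linalg.matrix_rank(deflated) == np.linalg.matrix_rank(X) - 1


class TestAve:
    def test_perfectly_explained_single_feature(self):
        x = np.random.default_rng(8).normal(size=30)
        assert np.isclose(compute_ave(x[:, None], 2.5 * x), 1.0)

    def test_orthogonal_component_gives_zero(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        t = rng.normal(size=30)
        t -= t.mean() + 0  # center
        x -= x.mean()
        t -= (t @ x) / (x @ x) * x  # exactly orthogonal
        assert compute_ave(x[:, None], t) < 1e-20

    def test_constructed_correlations_average(self):
        rng = np.random.default_rng(10)
        n = 50
        t = rng.normal(size=n)
        t = (t - t.mean()) / np.linalg.norm(t - t.mean())
        e1, e2 = rng.normal(size=n), rng.normal(size=n)
        for e in (e1, e2):
            e -= e.mean()
        e1 -= (e1 @ t) * t
        e1 /= np.linalg.norm(e1)
        e2 -= (e2 @ t) * t + (e2 @ e1) * e1
        e2 /= np.linalg.norm(e2)
        x1 = 0.6 * t + 0.8 * e1
        x2 = 0.8 * t + 0.6 * e2
        ave = compute_ave(np.column_stack([x1, x2]), t)
        assert np.isclose(ave, 0.5, atol=1e-10)


class TestFitSgcca:
    def test_single_component_reduces_to_fit_component(self, small_cohort):
        from crosstalknet import preprocess_genus_block, rank_inverse_normal

        blocks = {
            "fecal": rank_inverse_normal(
                small_cohort.blocks["fecal"].with_data(
                    small_cohort.blocks["fecal"].data.fillna(0.0)
                )
            ),
            "genus": preprocess_genus_block(small_cohort.blocks["genus"])[0],
        }
        config = SgccaConfig(n_components=1, sparsity={"fecal": 3, "genus": 3}, seed=0)
        model = fit_sgcca(blocks, config)
        scaled = scale_blocks(blocks)
        fit = fit_component(
            [scaled["fecal"].to_numpy(), scaled["genus"].to_numpy()], config, [3, 3]
        )
        np.testing.assert_allclose(
            model.weights["fecal"]["comp_1"].to_numpy(), fit.weights[0], atol=1e-10
        )
        assert model.objective_trace[0][-1] == pytest.approx(fit.objective_trace[-1])

    def test_weights_unit_norm_and_sparsity_respected(self, recovery_cohort):
        model = self._recovery_model(recovery_cohort)
        for lab, W in model.weights.items():
            norms = np.linalg.norm(W.to_numpy(), axis=0)
            np.testing.assert_allclose(norms, 1.0, atol=1e-8)

    @staticmethod
    def _recovery_model(recovery_cohort, seed=0):
        from crosstalknet import preprocess_genus_block, preprocess_metabolite_block

        config, cohort = recovery_cohort
        processed = {"genus": preprocess_genus_block(cohort.blocks["genus"])[0]}
        for lab in ("fecal", "plasma"):
            processed[lab] = preprocess_metabolite_block(cohort.blocks[lab])[0]
        counts = {
            lab: config.loaded_per_factor(cohort.blocks[lab].n_features)
            for lab in processed
        }
        return fit_sgcca(
            processed, SgccaConfig(n_components=5, sparsity=counts, seed=seed)
        )

    def test_planted_features_recovered(self, recovery_cohort):
        _, cohort = recovery_cohort
        model = self._recovery_model(recovery_cohort)
        selected = model.selected_features()
        for lab in ("genus", "fecal", "plasma"):
            sel, planted = set(selected[lab]), set(cohort.truth[lab])
            assert len(sel & planted) / len(planted) >= 0.8
            assert len(sel - planted) / max(len(sel), 1) < 0.2

    def test_selection_stable_across_initialization_seeds(self, recovery_cohort):
        reference = self._recovery_model(recovery_cohort, seed=0).selected_features()
        for seed in range(1, 5):
            assert (
                self._recovery_model(recovery_cohort, seed=seed).selected_features()
                == reference
            )

    def test_ave_in_unit_interval(self, recovery_cohort):
        model = self._recovery_model(recovery_cohort)
        for values in model.ave.values():
            assert all(0.0 <= v <= 1.0 for v in values)

    def test_sample_mismatch_raises_with_ids(self):
        a = make_block(np.random.default_rng(0).normal(size=(5, 2)))
        b_data = pd.DataFrame(
            np.random.default_rng(1).normal(size=(5, 2)),
            index=["s0", "s1", "s2", "s3", "zz"],
            columns=["g0", "g1"],
        )
        from crosstalknet import OmicsBlock

        b = OmicsBlock(b_data, "plasma")
        with pytest.raises(DataError, match="zz"):
            fit_sgcca({"fecal": a, "plasma": b}, SgccaConfig(n_components=1))
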