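import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirbact import synth
from mirbact.assoc import (
    ClrMatrix,
    bh_adjust,
    cim_matrix,
    clr_transform,
    component_correlations,
    correlate,
    permutation_pvalues,
    spls_fit,
)
from mirbact.formats import CountMatrix


def _counts(array):
    array = np.asarray(array)
    return CountMatrix(
        [f"S{i}" for i in range(array.shape[0])],
        [f"f{j}" for j in range(array.shape[1])],
        array,
    )


def _clr_from(values):
    values = np.asarray(values, dtype=float)
    values = values - values.mean(axis=1, keepdims=True)
    return ClrMatrix(
        values,
        [f"S{i}" for i in range(values.shape[0])],
        [f"f{j}" for j in range(values.shape[1])],
    )


class TestClr:
    def test_equal_parts_map_to_zero(self):
        clr = clr_transform(_counts([[1, 1, 1, 1]]))
        assert np.allclose(clr.values, 0)

    def test_all_zero_row_with_pseudocount(self):
        clr = clr_transform(_counts([[0, 0, 0]]), pseudocount=1)
        assert np.allclose(clr.values, 0)

    def test_direct_formula_on_1_3(self):
        clr = clr_transform(_counts([[1, 3]]), pseudocount=1)
        mean = (np.log(2) + np.log(4)) / 2
        assert clr.values[0] == pytest.approx(
            [np.log(2) - mean, np.log(4) - mean]
        )

    def test_zero_pseudocount_with_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            clr_transform(_counts([[0, 1]]), pseudocount=0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.5, 20.0),
    )
    def test_rows_sum_to_zero_and_scale_invariance(self, seed, factor):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 100, size=(4, 6))
        clr = clr_transform(_counts(counts))
        assert np.allclose(clr.values.sum(axis=1), 0, atol=1e-9)
        # multiplying (counts + pseudocount) by a positive scalar leaves
        # clr unchanged; emulate via direct formula on scaled columns
        scaled = (counts + 1.0) * factor
        logs = np.log(scaled)
        expected = logs - logs.mean(axis=1, keepdims=True)
        assert np.allclose(clr.values, expected, atol=1e-9)


class TestSplsFit:
    def test_shared_column_dominates_first_component(self, rng):
        # construct valid clr-like data (rows sum to 0) that carry one
        # strong shared signal column in both blocks
        shared = rng.standard_normal(30) * 3
        def _block():
            noise = rng.standard_normal((30, 3)) * 0.3
            balance = -(shared + noise.sum(axis=1))  # rows sum to zero
            return np.column_stack([shared, noise, balance])
        x, y = _block(), _block()
        model = spls_fit(_clr_from(x), _clr_from(y), ncomp=1,
                         keep_x=5, keep_y=5)
        # the zero-sum balancing column mixes a little of the noise into
        # the component, so the correlation is near, not exactly, 1
        r = np.corrcoef(model.scores[:, 0], shared - shared.mean())[0, 1]
        assert abs(r) > 0.95

    def test_rank_one_recovery_matches_svd_oracle(self, rng):
        # zero-sum loadings make every row of the rank-1 data sum to zero
        t = rng.standard_normal(40)
        a = np.array([2.0, -1.0, 0.5, -1.5])
        b = np.array([1.5, -2.0, 1.0, -0.5])
        x = np.outer(t, a) + 1e-6 * rng.standard_normal((40, 4))
        y = np.outer(t, b) + 1e-6 * rng.standard_normal((40, 4))
        x -= x.mean(axis=1, keepdims=True)
        y -= y.mean(axis=1, keepdims=True)
        model = spls_fit(_clr_from_raw(x), _clr_from_raw(y), ncomp=1,
                         keep_x=4, keep_y=4)
        # oracle: leading singular vectors of standardised XᵀY
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        ys = (y - y.mean(0)) / y.std(0, ddof=1)
        u_svd, _, vt_svd = np.linalg.svd(xs.T @ ys)
        u, v = model.loadings_x[:, 0], model.loadings_y[:, 0]
        assert abs(u @ u_svd[:, 0]) == pytest.approx(1.0, abs=1e-4)
        assert abs(v @ vt_svd[0]) == pytest.approx(1.0, abs=1e-4)

    def test_keep_one_gives_single_nonzero_loading(self, rng):
        x = rng.standard_normal((25, 6))
        y = rng.standard_normal((25, 5))
        model = spls_fit(_clr_from(x), _clr_from(y), ncomp=2,
                         keep_x=1, keep_y=2)
        for h in range(2):
            assert np.count_nonzero(model.loadings_x[:, h]) == 1
            assert np.count_nonzero(model.loadings_y[:, h]) <= 2

    def test_scores_mutually_orthogonal(self, rng):
        x = rng.standard_normal((30, 8))
        y = rng.standard_normal((30, 6))
        model = spls_fit(_clr_from(x), _clr_from(y), ncomp=3,
                         keep_x=5, keep_y=4)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_mismatched_samples_rejected(self, rng):
        x = _clr_from(rng.standard_normal((10, 3)))
        y = _clr_from(rng.standard_normal((10, 3)))
        y.sample_ids = [f"Z{i}" for i in range(10)]
        with pytest.raises(ValueError, match="samples"):
            spls_fit(x, y, ncomp=1, keep_x=2, keep_y=2)

    def test_constant_column_named_in_error(self, rng):
        # middle column identically zero while rows still sum to zero
        a = rng.standard_normal(10)
        x = np.column_stack([a, np.zeros(10), -a])
        with pytest.raises(ValueError, match="constant column"):
            spls_fit(
                ClrMatrix(x, [f"S{i}" for i in range(10)], list("abc")),
                _clr_from(np.random.default_rng(1).standard_normal((10, 3))),
                ncomp=1, keep_x=2, keep_y=2,
            )

    def test_matches_mixomics_reference(self, tmp_path):
        """Cross-check loadings and scores against R mixOmics spls."""
        spec = synth.make_latent_spec(1, 10, 10, support=3, seed=5)
        x, y, _ = synth.simulate_count_matrices(40, 10, 10, spec, seed=5)
        cx, cy = clr_transform(x), clr_transform(y)
        np.savetxt(tmp_path / "X.tsv", cx.values, delimiter="\t")
        np.savetxt(tmp_path / "Y.tsv", cy.values, delimiter="\t")
        script = textwrap.dedent("""
            suppressMessages(library(mixOmics))
            X <- as.matrix(read.table("X.tsv"))
            Y <- as.matrix(read.table("Y.tsv"))
            m <- spls(X, Y, ncomp=2, keepX=c(3,3), keepY=c(3,3),
                      mode="regression")
            write.table(m$loadings$X, "lx.tsv", sep="\\t",
                        col.names=FALSE, row.names=FALSE)
            write.table(m$variates$X, "vx.tsv", sep="\\t",
                        col.names=FALSE, row.names=FALSE)
        """)
        (tmp_path / "cross.R").write_text(script)
        subprocess.run(
            ["Rscript", "cross.R"], cwd=tmp_path, check=True,
            capture_output=True,
        )
        lx = np.loadtxt(tmp_path / "lx.tsv")
        vx = np.loadtxt(tmp_path / "vx.tsv")
        model = spls_fit(cx, cy, ncomp=2, keep_x=3, keep_y=3)
        for h in range(2):
            u, ur = model.loadings_x[:, h], lx[:, h]
            assert set(np.flatnonzero(u)) == set(np.flatnonzero(ur))
            cos = abs(u @ ur) / np.linalg.norm(u) / np.linalg.norm(ur)
            assert cos > 0.999
            score_r = abs(np.corrcoef(model.scores[:, h], vx[:, h])[0, 1])
            assert score_r > 0.999


def _clr_from_raw(values):
    """Wrap already-centered real data as a ClrMatrix for fitting."""
    return _clr_from(values)


class TestCim:
    def test_single_component_entries_bounded_by_one(self, rng):
        x = rng.standard_normal((20, 5))
        y = rng.standard_normal((20, 4))
        cx, cy = _clr_from(x), _clr_from(y)
        model = spls_fit(cx, cy, ncomp=1, keep_x=5, keep_y=4)
        cim = cim_matrix(cx, cy, model)
        assert (cim.abs() <= 1 + 1e-12).all().all()

    def test_negating_y_block_negates_cim(self, rng):
        # correlation antisymmetry: flipping the sign of the Y features
        # flips the sign of every CIM entry under the same fitted scores
        x = rng.standard_normal((20, 4))
        y = rng.standard_normal((20, 4))
        cx, cy = _clr_from(x), _clr_from(y)
        model = spls_fit(cx, cy, ncomp=1, keep_x=4, keep_y=4)
        cim = cim_matrix(cx, cy, model)
        cy_neg = ClrMatrix(-cy.values, cy.sample_ids, cy.feature_ids)
        cim2 = cim_matrix(cx, cy_neg, model)
        assert np.allclose(cim2.to_numpy(), -cim.to_numpy())

    def test_equals_hand_computed_correlation_product(self, rng):
        x = rng.standard_normal((6, 3))
        y = rng.standard_normal((6, 2))
        cx, cy = _clr_from(x), _clr_from(y)
        model = spls_fit(cx, cy, ncomp=2, keep_x=3, keep_y=2)
        cim = cim_matrix(cx, cy, model).to_numpy()
        expected = np.zeros((3, 2))
        for i in range(3):
            for j in range(2):
                for h in range(2):
                    ri = np.corrcoef(cx.values[:, i], model.scores[:, h])[0, 1]
                    rj = np.corrcoef(cy.values[:, j], model.scores[:, h])[0, 1]
                    expected[i, j] += ri * rj
        assert np.allclose(cim, expected, atol=1e-10)


class TestPermutationPvalues:
    def test_deterministic_given_seed(self, rng):
        c_x = rng.standard_normal((8, 2))
        c_y = rng.standard_normal((6, 2))
        obs = c_x @ c_y.T
        p1 = permutation_pvalues(c_x, c_y, obs, n_iter=200, seed=42)
        p2 = permutation_pvalues(c_x, c_y, obs, n_iter=200, seed=42)
        assert np.array_equal(p1, p2)

    def test_unreachable_observed_value_gives_exact_zero(self, rng):
        # raw count/n_iter definition: no pseudo-observation
        c_x = rng.standard_normal((5, 2))
        c_y = rng.standard_normal((5, 2))
        obs = np.full((5, 5), 1e6)
        p = permutation_pvalues(c_x, c_y, obs, n_iter=100, seed=0)
        assert np.all(p == 0.0)

    def test_smoothed_option_adds_pseudo_observation(self, rng):
        c_x = rng.standard_normal((5, 2))
        c_y = rng.standard_normal((5, 2))
        obs = np.full((5, 5), 1e6)
        p = permutation_pvalues(c_x, c_y, obs, n_iter=99, seed=0, smoothed=True)
        assert np.all(p == 1 / 100)

    def test_zero_iterations_rejected(self, rng):
        c = rng.standard_normal((3, 1))
        with pytest.raises(ValueError):
            permutation_pvalues(c, c, c @ c.T, n_iter=0, seed=0)

    def test_identity_permutation_always_counted(self, rng):
        # p can never be exactly 0 for the actually observed CIM, since the
        # identity permutation reproduces it
        c_x = rng.standard_normal((6, 2))
        c_y = rng.standard_normal((6, 2))
        obs = c_x @ c_y.T
        p = permutation_pvalues(c_x, c_y, obs, n_iter=2000, seed=1)
        assert np.all(p > 0)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.42]))[0] == pytest.approx(0.42)

    def test_textbook_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(200)
        q = bh_adjust(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_ref)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_q_at_least_p_and_rank_monotone(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((4, 5))
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p.ravel())
        assert np.all(np.diff(q.ravel()[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestRecoveryAndCalibration:
    def test_planted_factor_support_recovered(self):
        from mirbact.studies import spls_recovery_study

        result = spls_recovery_study(seed=11, n_reps=3)
        assert result["successes"] == 3

    def test_null_p_values_roughly_uniform_at_threshold(self):
        from mirbact.studies import null_calibration_study

        result = null_calibration_study(seed=7, n_reps=1, n_perm=1000)
        se = np.sqrt(0.05 * 0.95 / result["n_entries"])
        assert abs(result["fraction_p05"] - 0.05) < 3 * se


def test_correlate_end_to_end_shapes(rng):
    spec = synth.make_latent_spec(1, 8, 8, support=2, seed=3)
    x, y, _ = synth.simulate_count_matrices(30, 8, 8, spec, seed=3)
    result = correlate(x, y, ncomp=2, keep_x=4, keep_y=4, n_perm=100, seed=3)
    assert result.values.shape == (8, 8)
    assert ((result.p >= 0) & (result.p <= 1)).all().all()
    assert (result.q.to_numpy() >= result.p.to_numpy() - 1e-12).all()
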