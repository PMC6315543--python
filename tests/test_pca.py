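"""Core feature extraction: standardization, SVD attribution, chi-squared
probe p-values, BH adjustment and selection, checked against independent
oracles (covariance eigendecomposition, hand step-up)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pcafe import pca
from pcafe.containers import ExpressionMatrix, ProbeAnnotation, make_labels


def _mat(values, labels=None):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"P{i}" for i in range(values.shape[0])],
        columns=[f"S{j}" for j in range(values.shape[1])],
    )
    lab = make_labels(df.columns, labels) if labels is not None else None
    return ExpressionMatrix(df, lab)


class TestStandardize:
    def test_single_row_example(self):
        out = pca.standardize_probes(_mat([[1, 2, 3]]))
        row = out.values.to_numpy()[0]
        assert row.mean() == pytest.approx(0, abs=1e-12)
        assert row.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_random_matrix_property(self):
        rng = np.random.default_rng(0)
        out = pca.standardize_probes(_mat(rng.normal(size=(100, 10))))
        Z = out.values.to_numpy()
        assert np.abs(Z.mean(axis=1)).max() < 1e-12
        assert np.abs(Z.std(axis=1, ddof=1) - 1).max() < 1e-12

    def test_constant_row_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = pca.standardize_probes(_mat([[1, 2, 3], [5, 5, 5]]))
        assert list(out.probe_ids) == ["P0"]

    def test_all_constant_is_degenerate(self):
        with pytest.raises(pca.DegenerateInputError):
            pca.standardize_probes(_mat([[5, 5, 5], [2, 2, 2]]))

    def test_single_sample_is_degenerate(self):
        with pytest.raises(pca.DegenerateInputError):
            pca.standardize_probes(_mat([[5.0]]))


class TestDecompose:
    def test_matches_covariance_eigendecomposition(self):
        """Loadings/singular values must agree (up to sign) with the
        eigendecomposition of X'X — an independent route to the same PCs."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            n, m = rng.integers(3, 11, size=2)
            X = rng.normal(size=(n, m))
            dec = pca.decompose(_mat(X), n_components=int(min(n, m)))
            evals, evecs = np.linalg.eigh(X.T @ X)
            order = np.argsort(evals)[::-1]
            sv_oracle = np.sqrt(np.clip(evals[order], 0, None))
            np.testing.assert_allclose(
                dec.singular_values, sv_oracle[: dec.n_components], atol=1e-10
            )
            for k in range(dec.n_components):
                if sv_oracle[k] < 1e-8 or sv_oracle[k] - sv_oracle[min(k + 1, len(sv_oracle) - 1)] < 1e-6:
                    continue  # eigenvector not identifiable
                v = dec.loadings.iloc[:, k].to_numpy()
                w = evecs[:, order[k]]
                assert min(np.abs(v - w).max(), np.abs(v + w).max()) < 1e-8

    def test_rank_one_reconstruction(self):
        a = np.array([1.0, -2.0, 3.0, 0.5])
        b = np.array([2.0, 1.0, -1.0])
        dec = pca.decompose(_mat(np.outer(a, b)), n_components=3)
        assert dec.singular_values[0] == pytest.approx(
            np.linalg.norm(a) * np.linalg.norm(b)
        )
        assert np.all(dec.singular_values[1:] < 1e-12)
        recon = dec.scores.to_numpy() @ dec.loadings.to_numpy().T
        np.testing.assert_allclose(recon, np.outer(a, b), atol=1e-12)

    def test_loading_orthonormality_and_variance_share(self, default_dataset):
        _, matrix, _, _ = default_dataset
        dec = pca.decompose(pca.standardize_probes(matrix), n_components=10)
        V = dec.loadings.to_numpy()
        np.testing.assert_allclose(V.T @ V, np.eye(10), atol=1e-10)
        assert np.all(np.diff(dec.variance_share) <= 1e-15)
        assert dec.variance_share.sum() <= 1 + 1e-12
        full = pca.decompose(pca.standardize_probes(matrix))
        assert full.variance_share.sum() == pytest.approx(1.0)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 5))
        d1 = pca.decompose(_mat(X), 5)
        d2 = pca.decompose(_mat(X), 5)
        assert d1.loadings.equals(d2.loadings)
        for k in range(1, 6):
            col = d1.loading(k).to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca.decompose(_mat(np.eye(4)), n_components=5)


class TestAssociation:
    def test_indicator_loading_is_selected(self):
        loadings = pd.DataFrame(
            {
                1: [0.1, -0.2, 0.05, 0.15, -0.1, 0.0],
                2: [1.0, 1.0, 1.0, -1.0, -1.0, -1.0],
            },
            index=[f"S{j}" for j in range(6)],
        )
        dec = pca.PCADecomposition(
            scores=pd.DataFrame(np.zeros((3, 2)), columns=[1, 2]),
            loadings=loadings,
            singular_values=np.array([2.0, 1.0]),
            variance_share=np.array([0.6, 0.4]),
        )
        labels = make_labels(loadings.index, ["control"] * 3 + ["case"] * 3)
        assoc = pca.score_pc_class_association(dec, labels)
        assert assoc.selected_component == 2
        assert assoc.p_values[2] == pytest.approx(0.0, abs=1e-12)

    def test_small_class_rejected(self, small_matrix):
        dec = pca.decompose(pca.standardize_probes(small_matrix), 3)
        labels = make_labels(small_matrix.sample_ids, ["control"] + ["case"] * 11)
        with pytest.raises(pca.DegenerateInputError):
            pca.score_pc_class_association(dec, labels)

    def test_permutation_null_uniform(self, small_matrix):
        """Permuting labels makes any component's association p uniform."""
        dec = pca.decompose(pca.standardize_probes(small_matrix), 3)
        rng = np.random.default_rng(0)
        base = small_matrix.labels.to_numpy()
        ps = []
        for _ in range(300):
            perm = make_labels(small_matrix.sample_ids, rng.permutation(base))
            ps.append(pca.score_pc_class_association(dec, perm).p_values[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.005


class TestProbePValues:
    def _dec_from_scores(self, u):
        u = np.asarray(u, dtype=float)
        scores = pd.DataFrame({1: u}, index=[f"P{i}" for i in range(len(u))])
        return pca.PCADecomposition(
            scores=scores,
            loadings=pd.DataFrame({1: [1.0]}, index=["S0"]),
            singular_values=np.array([1.0]),
            variance_share=np.array([1.0]),
        )

    def test_zero_score_gives_p_one(self):
        dec = self._dec_from_scores([0.0, 1.0, -1.0, 2.0])
        p = pca.attribute_probe_pvalues(dec, [1])
        assert p.iloc[0] == pytest.approx(1.0)

    def test_analytic_chi2_quantile_df1(self):
        # balanced +-1 column has population sd ~1; entry at the normal
        # 97.5% point must get p ~ 0.05 under the chi-squared(1) null
        n = 20000
        u = np.array([1.0, -1.0] * (n // 2))
        u[0] = 1.959964
        u[1] = -1.959964
        dec = self._dec_from_scores(u)
        p = pca.attribute_probe_pvalues(dec, [1])
        assert p.iloc[0] == pytest.approx(0.05, abs=1e-3)

    def test_analytic_chi2_quantile_df2(self):
        n = 20000
        z = np.sqrt(5.991465 / 2)  # z1^2 + z2^2 at the chi2(2) 95% point
        cols = {}
        for c in (1, 2):
            u = np.array([1.0, -1.0] * (n // 2))
            u[0], u[1] = z, -z
            cols[c] = u
        scores = pd.DataFrame(cols, index=[f"P{i}" for i in range(n)])
        dec = pca.PCADecomposition(
            scores=scores,
            loadings=pd.DataFrame(cols, index=[f"S{i}" for i in range(n)]).iloc[:2],
            singular_values=np.array([1.0, 0.5]),
            variance_share=np.array([0.5, 0.5]),
        )
        p = pca.attribute_probe_pvalues(dec, [1, 2])
        assert p.iloc[0] == pytest.approx(0.05, abs=1e-3)

    def test_monotone_in_abs_z(self):
        rng = np.random.default_rng(4)
        u = rng.normal(size=500)
        dec = self._dec_from_scores(u)
        p = pca.attribute_probe_pvalues(dec, [1]).to_numpy()
        order = np.argsort(np.abs(u))
        assert np.all(np.diff(p[order]) <= 1e-15)

    def test_zero_variance_column_degenerate(self):
        dec = self._dec_from_scores([1.0, 1.0, 1.0])
        with pytest.raises(pca.DegenerateInputError):
            pca.attribute_probe_pvalues(dec, [1])

    def test_invalid_component_rejected(self):
        dec = self._dec_from_scores([0.0, 1.0])
        with pytest.raises(ValueError):
            pca.attribute_probe_pvalues(dec, [2])


def _bh_oracle(ps):
    """Step-up BH, written independently of the implementation."""
    n = len(ps)
    order = sorted(range(n), key=lambda i: ps[i])
    adj = [None] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, ps[i] * n / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            pca.adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert pca.adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(pca.adjust_bh([1.0, 1.0, 1.0]), [1, 1, 1])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10))
    def test_matches_step_up_oracle(self, ps):
        np.testing.assert_allclose(pca.adjust_bh(ps), _bh_oracle(ps), atol=1e-12)

    def test_adjusted_not_below_raw(self):
        rng = np.random.default_rng(5)
        ps = rng.uniform(size=200)
        assert np.all(pca.adjust_bh(ps) >= ps - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pca.adjust_bh([0.5, 1.5])


class TestSelection:
    def test_all_p_one_empty(self):
        sel = pca.select_probes(pd.Series([1.0, 1.0], index=["a", "b"]), alpha=0.01)
        assert sel.selected_probes == []

    def test_alpha_one_selects_everything(self):
        sel = pca.select_probes(pd.Series([0.4, 0.9], index=["a", "b"]), alpha=1.0)
        assert sel.selected_probes == ["a", "b"]

    def test_map_probes_dedup_and_unmapped(self):
        ann = ProbeAnnotation({"P1": "G1", "P2": "G1", "P3": "G2"})
        sel = pca.select_probes(
            pd.Series([1e-9, 1e-9, 1e-9, 1e-9], index=["P1", "P2", "P3", "P9"]),
            alpha=0.05,
        )
        with pytest.warns(UserWarning, match="no gene symbol"):
            symbols = pca.map_probes_to_genes(sel, ann)
        assert symbols == ["G1", "G2"]

    def test_empty_selection_maps_to_empty(self):
        ann = ProbeAnnotation({"P1": "G1"})
        sel = pca.select_probes(pd.Series([1.0], index=["P1"]), alpha=0.01)
        assert pca.map_probes_to_genes(sel, ann) == []
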