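"""PCA eigenstructure, conventions and oracle agreement."""

import numpy as np
import pytest

import stressidx as sx


def power_iteration_eig(M: np.ndarray, n_iter: int = 10_000) -> tuple[np.ndarray, np.ndarray]:
    """Independent eigen-solver: power iteration with deflation."""
    M = M.copy().astype(float)
    p = M.shape[0]
    values, vectors = [], []
    for _ in range(p):
        v = np.ones(p) / np.sqrt(p)
        for _ in range(n_iter):
            w = M @ v
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            v = w / norm
        lam = float(v @ M @ v)
        values.append(lam)
        vectors.append(v)
        M = M - lam * np.outer(v, v)
    return np.array(values), np.array(vectors).T


def test_eigenvalue_trace_identity(indices20):
    pca = sx.run_pca(indices20)
    assert pca.eigenvalues.sum() == pytest.approx(11.0, abs=1e-10)
    assert (np.diff(pca.eigenvalues) <= 1e-12).all()
    assert (pca.eigenvalues >= 0).all()
    # YSI/RSI collinearity guarantees a singular correlation matrix
    assert pca.eigenvalues[-1] == pytest.approx(0.0, abs=1e-10)


def test_orthonormal_eigenvectors_and_sign_rule(indices20):
    pca = sx.run_pca(indices20)
    V = pca.eigenvectors.to_numpy()
    np.testing.assert_allclose(V.T @ V, np.eye(11), atol=1e-10)
    for k in range(V.shape[1]):
        lead = np.argmax(np.abs(V[:, k]))
        assert V[lead, k] > 0


def test_score_variance_equals_eigenvalue(indices20):
    pca = sx.run_pca(indices20)
    variances = pca.scores.var(axis=0, ddof=1).to_numpy()
    np.testing.assert_allclose(variances, pca.eigenvalues, atol=1e-10)


def test_reconstruction_of_standardised_data(indices20):
    pca = sx.run_pca(indices20)
    X = indices20.ranked_values().to_numpy()
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    recon = pca.scores.to_numpy() @ pca.eigenvectors.to_numpy().T
    np.testing.assert_allclose(recon, Z, atol=1e-8)


def test_contributions_sum_to_hundred(indices20):
    pca = sx.run_pca(indices20)
    np.testing.assert_allclose(pca.contributions.sum(axis=0), 100.0, atol=1e-9)


def test_rank_one_fixture_single_component():
    rng = np.random.default_rng(11)
    x = rng.normal(size=30)
    data = np.column_stack([x, 3.0 * x + 1.0])  # two perfectly correlated variables
    pca = sx.pca_from_matrix(data, ["u", "v"])
    np.testing.assert_allclose(pca.eigenvalues, [2.0, 0.0], atol=1e-12)
    assert pca.explained[0] == pytest.approx(1.0, abs=1e-12)
    # all points lie on the PC1 axis
    assert np.abs(pca.scores["PC2"].to_numpy()).max() < 1e-8


def test_affine_rescaling_invariance_in_correlation_mode(indices20):
    pca = sx.run_pca(indices20, mode="correlation")
    X = indices20.ranked_values().to_numpy().copy()
    rng = np.random.default_rng(2)
    X = X * rng.uniform(0.5, 20, X.shape[1]) + rng.uniform(-5, 5, X.shape[1])
    other = sx.pca_from_matrix(X, list(indices20.ranked_values().columns))
    np.testing.assert_allclose(other.eigenvalues, pca.eigenvalues, atol=1e-9)
    # eigenvectors are only identifiable where the spectrum is simple:
    # compare them for eigenvalues separated from their neighbours
    lam = pca.eigenvalues
    gaps = np.minimum(
        np.r_[np.inf, np.abs(np.diff(lam))], np.r_[np.abs(np.diff(lam)), np.inf]
    )
    for k in np.nonzero((gaps > 1e-6) & (lam > 1e-8))[0]:
        dot = abs(
            other.eigenvectors.to_numpy()[:, k] @ pca.eigenvectors.to_numpy()[:, k]
        )
        assert dot == pytest.approx(1.0, abs=1e-7)


def test_agrees_with_power_iteration_oracle():
    rng = np.random.default_rng(4)
    data = rng.normal(size=(40, 4)) @ rng.normal(size=(4, 4))
    pca = sx.pca_from_matrix(data, list("wxyz"))
    values, vectors = power_iteration_eig(pca.matrix.to_numpy())
    np.testing.assert_allclose(pca.eigenvalues, values, atol=1e-6)
    for k in range(4):
        dot = abs(vectors[:, k] @ pca.eigenvectors.to_numpy()[:, k])
        assert dot == pytest.approx(1.0, abs=1e-6)


def test_agrees_with_sklearn_on_covariance_mode():
    from sklearn.decomposition import PCA as SkPCA

    rng = np.random.default_rng(9)
    data = rng.normal(size=(25, 5)) * [1, 2, 3, 4, 5]
    ours = sx.pca_from_matrix(data, [f"v{i}" for i in range(5)], mode="covariance")
    ref = SkPCA().fit(data)
    np.testing.assert_allclose(ours.eigenvalues, ref.explained_variance_, rtol=1e-9)
    for k in range(5):
        dot = abs(ours.eigenvectors.to_numpy()[:, k] @ ref.components_[k])
        assert dot == pytest.approx(1.0, abs=1e-8)


def test_degenerate_inputs_rejected_or_dropped(indices20):
    with pytest.raises(sx.ValidationError):
        sx.pca_from_matrix(np.random.default_rng(0).normal(size=(2, 4)))
    data = np.column_stack(
        [np.ones(10), np.random.default_rng(1).normal(size=(10, 2))]
    )
    with pytest.warns(UserWarning, match="constant variables"):
        pca = sx.pca_from_matrix(data, ["c", "a", "b"])
    assert pca.variables == ("a", "b")
    data = np.random.default_rng(2).normal(size=(10, 3))
    data[4, 1] = np.nan
    with pytest.warns(UserWarning, match="rows with undefined"):
        pca = sx.pca_from_matrix(data, list("abc"))
    assert len(pca.scores) == 9


def test_biplot_data_selection_and_labels(indices20):
    pca = sx.run_pca(indices20)
    spec = sx.biplot_data(pca, (1, 2))
    assert list(spec.points.columns) == ["PC1", "PC2"]
    assert spec.x_label.startswith("PC1 (")
    spec13 = sx.biplot_data(pca, (1, 3))
    assert spec13.y_label.startswith("PC3 (")
    assert spec13.arrow_scale > 0
    with pytest.raises(ValueError):
        sx.biplot_data(pca, (2, 1))
    with pytest.raises(ValueError):
        sx.biplot_data(pca, (1, 99))
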