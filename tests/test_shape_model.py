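import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from vaultshape.shape_model import (
    ControlReference,
    ModelError,
    ResponseDesign,
    fit_pca,
    fit_plsda,
    latent_axis_shapes,
    project_scores,
    reconstruct_shape,
    ucs_si,
    vip_scores,
)


def literal_nipals(x, y, n_components, tol=1e-14, max_iter=100_000):
    """Textbook NIPALS PLS2 with X-deflation only (independent oracle)."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    ws, ts, ps, qs = [], [], [], []
    for _ in range(n_components):
        u = y[:, int(np.argmax(np.sum(y**2, axis=0)))].copy()
        w_old = None
        for _ in range(max_iter):
            w = x.T @ u
            w /= np.linalg.norm(w)
            t = x @ w
            q = y.T @ t / (t @ t)
            u = y @ q / (q @ q)
            if w_old is not None and np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        p = x.T @ t / (t @ t)
        x = x - np.outer(t, p)
        ws.append(w)
        ts.append(t)
        ps.append(p)
        qs.append(q)
    return (np.stack(ws, 1), np.stack(ts, 1), np.stack(ps, 1), np.stack(qs, 1))


class TestPCA:
    def test_matches_eigendecomposition(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10, 12))
        model = fit_pca(x)
        evals, evecs = np.linalg.eigh(np.cov(x.T))
        evals = evals[::-1]
        evecs = evecs[:, ::-1]
        k = model.n_components
        assert np.abs(model.explained_variance - evals[:k]).max() < 1e-8
        for a in range(k):
            v1, v2 = model.loadings[:, a], evecs[:, a]
            assert min(np.abs(v1 - v2).max(), np.abs(v1 + v2).max()) < 1e-8
        assert model.total_variance == pytest.approx(evals.sum())

    def test_single_direction(self):
        rng = np.random.default_rng(1)
        direction = rng.standard_normal(6)
        x = np.outer(rng.standard_normal(8), direction)
        model = fit_pca(x)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_two_shapes_one_component(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 9))
        model = fit_pca(x)
        assert model.n_components == 1
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_invariants(self):
        rng = np.random.default_rng(3)
        model = fit_pca(rng.standard_normal((15, 9)), 5)
        k = model.n_components
        assert np.abs(model.loadings.T @ model.loadings - np.eye(k)).max() < 1e-8
        assert np.abs(model.scores.mean(axis=0)).max() < 1e-8
        assert np.all(np.diff(model.explained_variance) <= 1e-12)
        # sign convention: largest-|entry| of each loading is positive
        for a in range(k):
            col = model.loadings[:, a]
            assert col[np.argmax(np.abs(col))] > 0

    def test_k_out_of_range(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ModelError):
            fit_pca(rng.standard_normal((5, 8)), 7)


class TestPLSDA:
    def test_matches_literal_nipals(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((8, 5))
        y = rng.standard_normal((8, 2))
        model = fit_plsda(x, ResponseDesign("dual", y, ["a", "b"]), 3)
        w_o, t_o, p_o, _ = literal_nipals(x, y, 3)
        for a in range(3):
            sign = np.sign(w_o[:, a] @ model.weights[:, a])
            assert np.abs(model.weights[:, a] - sign * w_o[:, a]).max() < 1e-8
            assert np.abs(model.scores[:, a] - sign * t_o[:, a]).max() < 1e-8
            assert np.abs(model.x_loadings[:, a] - sign * p_o[:, a]).max() < 1e-8

    def test_matches_sklearn(self):
        """Independent library route (Y-deflation does not change the
        weight/score sequence in regression-mode PLS2)."""
        rng = np.random.default_rng(6)
        x = rng.standard_normal((12, 7))
        y = rng.standard_normal((12, 2))
        model = fit_plsda(x, ResponseDesign("dual", y, ["a", "b"]), 2)
        sk = PLSRegression(n_components=2, scale=False, tol=1e-12,
                           max_iter=10_000).fit(x, y)
        for a in range(2):
            sign = np.sign(sk.x_weights_[:, a] @ model.weights[:, a])
            assert np.abs(
                model.weights[:, a] - sign * sk.x_weights_[:, a]
            ).max() < 1e-5

    def test_single_proportional_column(self):
        y = np.arange(6, dtype=float)[:, None]
        x = np.zeros((6, 3))
        x[:, 1] = 2.0 * y[:, 0]
        model = fit_plsda(x, ResponseDesign("binary_like", y, ["y"]), 1)
        assert abs(abs(model.weights[1, 0]) - 1.0) < 1e-12
        assert model.ssy[0] == pytest.approx(np.sum((y - y.mean()) ** 2))

    def test_separated_clusters(self):
        rng = np.random.default_rng(7)
        x = np.vstack([
            rng.standard_normal((10, 4)) + np.array([10, 0, 0, 0]),
            rng.standard_normal((10, 4)) - np.array([10, 0, 0, 0]),
        ])
        labels = np.array([1.0] * 10 + [0.0] * 10)
        model = fit_plsda(x, ResponseDesign.binary(labels), 1)
        lv1 = model.scores[:, 0]
        threshold = lv1.mean()
        pred = (lv1 > threshold) == (lv1[labels == 1].mean() > threshold)
        assert np.all(pred == (labels == 1))

    def test_score_orthogonality(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((20, 10))
        y = rng.standard_normal((20, 2))
        model = fit_plsda(x, ResponseDesign("dual", y, ["a", "b"]), 4)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6
        assert np.all(model.ssy >= 0)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ModelError):
            fit_plsda(
                rng.standard_normal((6, 4)),
                ResponseDesign.binary(np.ones(6)), 1,
            )


class TestVIP:
    def test_equal_weights_all_one(self):
        rng = np.random.default_rng(10)
        n, p = 12, 6
        # build a model with one component and equal weights by feeding X
        # whose covariance with y is flat across coordinates
        y = rng.standard_normal(n)
        x = np.tile(y[:, None], (1, p))
        model = fit_plsda(x, ResponseDesign("reg", y[:, None], ["y"]), 1)
        vip, _ = vip_scores(model)
        assert np.abs(vip - 1.0).max() < 1e-8

    def test_hand_case_sqrt2(self):
        """p=2, one component, w=(1,0) → VIP = (√2, 0)."""
        y = np.arange(8, dtype=float)
        x = np.zeros((8, 2))
        x[:, 0] = y
        model = fit_plsda(x, ResponseDesign("reg", y[:, None], ["y"]), 1)
        vip, _ = vip_scores(model)
        assert vip[0] == pytest.approx(np.sqrt(2), abs=1e-10)
        assert vip[1] == pytest.approx(0.0, abs=1e-10)

    def test_mean_square_identity(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((15, 9))
        y = rng.standard_normal((15, 2))
        for a in (1, 2, 3):
            model = fit_plsda(x, ResponseDesign("dual", y, ["a", "b"]), a)
            vip, per_vertex = vip_scores(model)
            assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-8)
            assert per_vertex.shape == (3,)  # 9 coords → 3 vertices


class TestProjectionReconstruction:
    def test_mean_maps_to_zero(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((10, 6))
        model = fit_pca(x, 3)
        assert np.abs(project_scores(model, model.mean)).max() < 1e-10

    def test_training_scores_reproduced(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((10, 6))
        pca = fit_pca(x, 4)
        assert np.abs(project_scores(pca, x) - pca.scores).max() < 1e-8
        y = rng.standard_normal((10, 2))
        pls = fit_plsda(x, ResponseDesign("dual", y, ["a", "b"]), 3)
        assert np.abs(project_scores(pls, x) - pls.scores).max() < 1e-8

    def test_axis_excursion_score(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((10, 6))
        model = fit_pca(x, 3)
        sd = np.sqrt(model.explained_variance[0])
        shape = model.mean + 2 * sd * model.loadings[:, 0]
        scores = project_scores(model, shape)
        assert scores[0] == pytest.approx(2 * sd)
        assert np.abs(scores[1:]).max() < 1e-10

    def test_full_rank_roundtrip(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal((8, 5))
        model = fit_pca(x)  # full rank
        recon = reconstruct_shape(model, project_scores(model, x))
        assert np.abs(recon - x).max() < 1e-6

    def test_zero_scores_give_mean(self):
        rng = np.random.default_rng(16)
        model = fit_pca(rng.standard_normal((8, 5)), 2)
        assert np.array_equal(reconstruct_shape(model, np.zeros(2)), model.mean)

    def test_excursions_symmetric_about_mean(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal((10, 6))
        y = rng.standard_normal((10, 2))
        model = fit_plsda(x, ResponseDesign("dual", y, ["a", "b"]), 2)
        plus = reconstruct_shape(model, np.array([1.5, -0.5]))
        minus = reconstruct_shape(model, np.array([-1.5, 0.5]))
        assert np.abs((plus + minus) / 2 - model.mean_x).max() < 1e-10

    def test_latent_axis_shapes(self):
        rng = np.random.default_rng(18)
        x = rng.standard_normal((12, 6))
        y = rng.integers(0, 2, 12).astype(float)
        y[:3] = 1.0
        y[3:6] = 0.0
        model = fit_plsda(x, ResponseDesign.binary(y), 2)
        case_scores = model.scores[y == 1]
        shapes = latent_axis_shapes(model, case_scores, n_sd=2.0)
        assert set(shapes) == {"mean", "lv1_plus", "lv1_minus",
                               "lv2_plus", "lv2_minus"}
        mid = (shapes["lv1_plus"] + shapes["lv1_minus"]) / 2
        assert np.abs(mid - shapes["mean"]).max() < 1e-10


class TestUcsSi:
    def test_formula(self):
        ref = ControlReference(mean=np.zeros(2), sd=np.ones(2))
        scores = np.array([[0.0, 0.0], [1.0, 1.0], [-3.0, 4.0]])
        si = ucs_si(scores, ref)
        assert si == pytest.approx([0.0, 2.0, 25.0])

    def test_standardization(self):
        ref = ControlReference(mean=np.array([1.0, -1.0]),
                               sd=np.array([2.0, 0.5]))
        si = ucs_si(np.array([[3.0, 0.0]]), ref)
        assert si[0] == pytest.approx(1.0 + 4.0)

    def test_raw_mode(self):
        si = ucs_si(np.array([[2.0, 3.0]]), None, standardize=False)
        assert si[0] == pytest.approx(13.0)

    def test_missing_reference_rejected(self):
        with pytest.raises(ModelError):
            ucs_si(np.array([[1.0, 1.0]]), None, standardize=True)

    def test_zero_control_sd_rejected(self):
        with pytest.raises(ModelError):
            ControlReference(mean=np.zeros(2), sd=np.array([1.0, 0.0]))
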