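"""Statistical shape models on Procrustes-aligned coordinates.

PCA gives unsupervised modes of shape variation (cPC/bPC for the combined
and balanced cohorts); PLS-DA gives supervised latent variables (cLV/bLV)
maximising covariance between shape and a diagnostic response.  VIP maps
localise the discriminative signal on the surface, and the UCS-SI severity
index is the squared Mahalanobis-style distance of a subject's (bLV1, bLV2)
scores from the control distribution in latent space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import AlignedShapeSet
from .mesh import CorrespondedShapeSet


class ModelError(ValueError):
    """Invalid model inputs or parameters."""


def _as_matrix(data: AlignedShapeSet | np.ndarray) -> np.ndarray:
    if isinstance(data, AlignedShapeSet):
        return data.flattened
    x = np.asarray(data, dtype=float)
    if x.ndim == 3:
        return x.reshape(x.shape[0], -1)
    return x


def _fix_signs(basis: np.ndarray, *coupled: np.ndarray) -> None:
    """In place: make the largest-|entry| of each basis column positive,
    flipping the matching columns of the coupled arrays with it."""
    for a in range(basis.shape[1]):
        col = basis[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            basis[:, a] = -col
            for other in coupled:
                other[:, a] = -other[:, a]


@dataclass
class PCAModel:
    """Centred PCA of an N×3V shape matrix."""

    mean: np.ndarray
    loadings: np.ndarray  # 3V × K, orthonormal columns
    explained_variance: np.ndarray
    scores: np.ndarray  # N × K
    cohort_tag: str = "combined"  # "combined" → cPC_k, "balanced" → bPC_k

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[1])

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.total_variance

    @property
    def total_variance(self) -> float:
        return float(self._total_variance)

    _total_variance: float = 0.0

    def component_names(self) -> list[str]:
        prefix = "cPC" if self.cohort_tag == "combined" else "bPC"
        return [f"{prefix}_{k + 1}" for k in range(self.n_components)]


def fit_pca(
    data: AlignedShapeSet | np.ndarray, n_components: int | None = None,
    cohort_tag: str = "combined",
) -> PCAModel:
    """PCA via SVD of the centred shape matrix.

    Component signs follow a fixed convention (largest-magnitude loading
    entry positive) so results are reproducible across platforms.
    """
    x = _as_matrix(data)
    n, p = x.shape
    if n < 2:
        raise ModelError("PCA needs at least two shapes")
    max_k = min(n - 1, p)
    if n_components is None:
        n_components = max_k
    if not 1 <= n_components <= max_k:
        raise ModelError(f"n_components must lie in [1, {max_k}]")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = n_components
    loadings = vt[:k].T.copy()
    scores = (u[:, :k] * s[:k]).copy()
    _fix_signs(loadings, scores)
    var = s**2 / (n - 1)
    model = PCAModel(
        mean=mean,
        loadings=loadings,
        explained_variance=var[:k],
        scores=scores,
        cohort_tag=cohort_tag,
    )
    model._total_variance = float(var.sum())
    return model


@dataclass
class ResponseDesign:
    """Class-membership response block for PLS-DA.

    ``binary``: one column, pathology ∈ {0, 1}.  ``dual``: two columns,
    pathology ∈ {0, 1} and laterality ∈ {−1, +1} with controls coded 0
    (laterality-neutral).  The dual design is meant for the balanced cohort
    (native + mirrored instances of every subject).
    """

    mode: str
    y: np.ndarray
    column_names: list[str]

    @classmethod
    def binary(cls, pathology: np.ndarray) -> "ResponseDesign":
        pathology = np.asarray(pathology, dtype=float)
        if not set(np.unique(pathology)).issubset({0.0, 1.0}):
            raise ModelError("pathology must be coded 0/1")
        return cls(mode="binary", y=pathology[:, None], column_names=["pathology"])

    @classmethod
    def dual(cls, pathology: np.ndarray, laterality: np.ndarray) -> "ResponseDesign":
        pathology = np.asarray(pathology, dtype=float)
        laterality = np.asarray(laterality, dtype=float)
        if not set(np.unique(pathology)).issubset({0.0, 1.0}):
            raise ModelError("pathology must be coded 0/1")
        if not set(np.unique(laterality)).issubset({-1.0, 0.0, 1.0}):
            raise ModelError("laterality must be coded −1/0/+1")
        y = np.stack([pathology, laterality], axis=1)
        return cls(mode="dual", y=y, column_names=["pathology", "laterality"])

    @classmethod
    def from_shape_set(cls, shape_set: CorrespondedShapeSet,
                       mode: str = "binary") -> "ResponseDesign":
        pathology = np.array([g == "UCS" for g in shape_set.groups], dtype=float)
        if mode == "binary":
            return cls.binary(pathology)
        side = {"right": 1.0, "left": -1.0, "none": 0.0}
        laterality = np.array([side[l] for l in shape_set.lateralities])
        return cls.dual(pathology, laterality)


@dataclass
class PLSDAModel:
    """Two-block NIPALS PLS (PLS2) with X-deflation only.

    ``ssy`` holds the response sum of squares explained per component,
    the quantity the VIP formula weights each component by.
    """

    mean_x: np.ndarray
    mean_y: np.ndarray
    weights: np.ndarray   # W: 3V × A, unit columns
    x_loadings: np.ndarray  # P: 3V × A
    y_loadings: np.ndarray  # Q: q × A
    scores: np.ndarray    # T: N × A, mutually orthogonal columns
    ssy: np.ndarray       # A
    design: ResponseDesign
    cohort_tag: str = "combined"  # "combined" → cLV_a, "balanced" → bLV_a

    @property
    def n_components(self) -> int:
        return int(self.weights.shape[1])

    @property
    def rotation(self) -> np.ndarray:
        """R = W (PᵀW)⁻¹, so that T = (X − mean) R without deflation."""
        return self.weights @ np.linalg.inv(self.x_loadings.T @ self.weights)

    def component_names(self) -> list[str]:
        prefix = "cLV" if self.cohort_tag == "combined" else "bLV"
        return [f"{prefix}_{a + 1}" for a in range(self.n_components)]


def fit_plsda(
    data: AlignedShapeSet | np.ndarray,
    design: ResponseDesign,
    n_components: int = 2,
    cohort_tag: str = "combined",
) -> PLSDAModel:
    """Fit PLS-DA (NIPALS PLS2 with X-deflation only) on column-centred
    X and Y.

    Per component: w is the NIPALS fixed point (dominant left singular
    vector of XᵀY), t = Xw, q = Yᵀt/tᵀt, p = Xᵀt/tᵀt, then X ← X − t pᵀ.
    Y is left undeflated: it does not alter the score sequence in
    regression-mode PLS2 and keeps the SSY accounting direct.
    """
    x = _as_matrix(data)
    y = np.asarray(design.y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, p = x.shape
    if y.shape[0] != n:
        raise ModelError("X and Y row counts differ")
    if n_components < 1:
        raise ModelError("need at least one component")
    for col in range(y.shape[1]):
        if np.ptp(y[:, col]) == 0 and col == 0:
            raise ModelError("response has a single class")
    mean_x = x.mean(axis=0)
    mean_y = y.mean(axis=0)
    xc = x - mean_x
    yc = y - mean_y
    ssy_total = float(np.sum(yc**2))
    if ssy_total == 0:
        raise ModelError("response has zero variance")

    w_list, p_list, q_list, t_list, ssy = [], [], [], [], []
    xd = xc.copy()
    for _ in range(n_components):
        # NIPALS fixed point, computed exactly: w is the dominant left
        # singular vector of XᵀY (the vector the u/w/t/q iteration
        # converges to), so components are deterministic to machine
        # precision regardless of eigengap.
        cov = xd.T @ yc
        if np.linalg.norm(cov) < 1e-300:
            raise ModelError("degenerate component (zero weight vector)")
        u_svd, _, _ = np.linalg.svd(cov, full_matrices=False)
        w = u_svd[:, 0]
        t = xd @ w
        q = yc.T @ t / (t @ t)
        p_vec = xd.T @ t / (t @ t)
        xd = xd - np.outer(t, p_vec)
        w_list.append(w)
        t_list.append(t)
        p_list.append(p_vec)
        q_list.append(q)
        ssy.append(float((t @ t) * (q @ q)))

    weights = np.stack(w_list, axis=1)
    scores = np.stack(t_list, axis=1)
    x_loadings = np.stack(p_list, axis=1)
    y_loadings = np.stack(q_list, axis=1)
    _fix_signs(weights, scores, x_loadings)
    # q must flip with t so that t qᵀ is unchanged: recompute against the
    # sign-fixed scores
    y_loadings = (yc.T @ scores) / np.sum(scores**2, axis=0)
    return PLSDAModel(
        mean_x=mean_x,
        mean_y=mean_y,
        weights=weights,
        x_loadings=x_loadings,
        y_loadings=y_loadings,
        scores=scores,
        ssy=np.asarray(ssy),
        design=design,
        cohort_tag=cohort_tag,
    )


def vip_scores(model: PLSDAModel) -> tuple[np.ndarray, np.ndarray]:
    """Variable importance in projection.

    Per coordinate j:  VIP_j = sqrt( p · Σ_a SSY_a (w_ja / ‖w_a‖)² / Σ_a SSY_a )
    with p the number of coordinates; per-vertex VIP is the RMS of the
    vertex's three coordinate VIPs.  mean(VIP²) = 1 identically.
    """
    ssy = model.ssy
    total = ssy.sum()
    if total <= 0:
        raise ModelError("model explains no response variance")
    w = model.weights
    p = w.shape[0]
    wnorm2 = np.sum(w**2, axis=0)
    contrib = (w**2 / wnorm2) @ ssy
    vip = np.sqrt(p * contrib / total)
    if p % 3 == 0:
        per_vertex = np.sqrt(np.mean(vip.reshape(-1, 3) ** 2, axis=1))
    else:  # non-coordinate predictor blocks (e.g. generic matrices)
        per_vertex = vip.copy()
    return vip, per_vertex


def project_scores(
    model: PCAModel | PLSDAModel, shapes: np.ndarray
) -> np.ndarray:
    """Project shapes (already in the model's aligned frame) onto the
    model's latent axes; projecting the training set reproduces the stored
    scores."""
    x = _as_matrix(shapes)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if isinstance(model, PCAModel):
        if x.shape[1] != model.mean.size:
            raise ModelError("shape dimension does not match the model")
        out = (x - model.mean) @ model.loadings
    else:
        if x.shape[1] != model.mean_x.size:
            raise ModelError("shape dimension does not match the model")
        out = (x - model.mean_x) @ model.rotation
    return out[0] if single else out


def reconstruct_shape(
    model: PCAModel | PLSDAModel, scores: np.ndarray
) -> np.ndarray:
    """Linear reconstruction mean + Σ_a score_a · basis_a.

    PCA uses its orthonormal loadings; PLS uses the X-loading basis P (the
    least-squares reconstruction from its scores).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if isinstance(model, PCAModel):
        basis = model.loadings
        mean = model.mean
    else:
        basis = model.x_loadings
        mean = model.mean_x
    a = scores.shape[1]
    if a > basis.shape[1]:
        raise ModelError("more scores than model components")
    out = mean + scores @ basis[:, :a].T
    return out[0] if out.shape[0] == 1 else out


def latent_axis_shapes(
    model: PCAModel | PLSDAModel,
    case_scores: np.ndarray,
    n_sd: float = 2.0,
    invert_lv2: bool = True,
) -> dict[str, np.ndarray]:
    """Mean ± n_sd·SD reconstructions along the first two latent axes.

    ``case_scores`` are the scores of the case group; the excursions are
    centred on their mean and scaled by their per-axis SD.  With
    ``invert_lv2`` the sign of the axis-2 deviation is inverted so that
    "plus" consistently means anatomically more severe when the second
    axis's score direction opposes the first's.
    """
    case_scores = np.asarray(case_scores, dtype=float)
    centre = case_scores.mean(axis=0)
    sd = case_scores.std(axis=0, ddof=1)
    out: dict[str, np.ndarray] = {"mean": reconstruct_shape(model, centre[:2])}
    for axis in (0, 1):
        flip = -1.0 if (axis == 1 and invert_lv2) else 1.0
        for sign, name in ((+1.0, "plus"), (-1.0, "minus")):
            sc = centre[:2].copy()
            sc[axis] += flip * sign * n_sd * sd[axis]
            out[f"lv{axis + 1}_{name}"] = reconstruct_shape(model, sc)
    return out


@dataclass
class ControlReference:
    """Per-LV control-group mean and SD used to standardize scores."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.sd <= 0):
            raise ModelError("control SDs must be positive")

    @classmethod
    def from_scores(cls, scores: np.ndarray, is_control: np.ndarray,
                    n_components: int = 2) -> "ControlReference":
        scores = np.asarray(scores, dtype=float)[:, :n_components]
        ctl = scores[np.asarray(is_control, dtype=bool)]
        if len(ctl) < 2:
            raise ModelError("need at least two controls for a reference")
        return cls(mean=ctl.mean(axis=0), sd=ctl.std(axis=0, ddof=1))


def ucs_si(
    scores: np.ndarray,
    control_reference: ControlReference | None,
    standardize: bool = True,
) -> np.ndarray:
    """Composite severity index: sum of squared (standardized) scores on
    the first two balanced-cohort latent variables.

    With standardization (default), each LV score is z-scored against the
    control-group mean and SD, so the index measures squared deviation from
    the control shape distribution in latent space; ``standardize=False``
    gives the raw sum of squares for sensitivity analysis.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))[:, :2]
    if standardize:
        if control_reference is None:
            raise ModelError("standardized UCS-SI needs a control reference")
        z = (scores - control_reference.mean[:2]) / control_reference.sd[:2]
    else:
        z = scores
    return np.sum(z**2, axis=1)


def training_auc(scores: np.ndarray, is_case: np.ndarray) -> float:
    """Area under the ROC curve of a 1-D score separating cases from
    controls (orientation-free: returns max(AUC, 1−AUC))."""
    from sklearn.metrics import roc_auc_score

    auc = float(roc_auc_score(np.asarray(is_case, dtype=int), np.asarray(scores)))
    return max(auc, 1.0 - auc)


def save_model(model: PCAModel | PLSDAModel, path: str | Path) -> None:
    """Persist a model as an .npz array container + JSON metadata sidecar."""
    path = Path(path)
    meta = {"cohort_tag": model.cohort_tag,
            "sign_convention": "largest-|loading| entry positive"}
    if isinstance(model, PCAModel):
        meta["kind"] = "pca"
        np.savez(
            path, mean=model.mean, loadings=model.loadings,
            explained_variance=model.explained_variance, scores=model.scores,
            total_variance=np.array(model.total_variance),
        )
    else:
        meta["kind"] = "plsda"
        meta["design_mode"] = model.design.mode
        meta["n_components"] = model.n_components
        np.savez(
            path, mean_x=model.mean_x, mean_y=model.mean_y,
            weights=model.weights, x_loadings=model.x_loadings,
            y_loadings=model.y_loadings, scores=model.scores, ssy=model.ssy,
            y=model.design.y,
        )
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> PCAModel | PLSDAModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.load(path)
    if meta["kind"] == "pca":
        model = PCAModel(
            mean=data["mean"], loadings=data["loadings"],
            explained_variance=data["explained_variance"], scores=data["scores"],
            cohort_tag=meta["cohort_tag"],
        )
        model._total_variance = float(data["total_variance"])
        return model
    y = data["y"]
    if meta["design_mode"] == "binary":
        design = ResponseDesign.binary(y[:, 0])
    else:
        design = ResponseDesign.dual(y[:, 0], y[:, 1])
    return PLSDAModel(
        mean_x=data["mean_x"], mean_y=data["mean_y"], weights=data["weights"],
        x_loadings=data["x_loadings"], y_loadings=data["y_loadings"],
        scores=data["scores"], ssy=data["ssy"], design=design,
        cohort_tag=meta["cohort_tag"],
    )
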