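"""End-to-end study pipeline on a synthetic cohort.

Replicates the analysis chain at desk scale: synthesize corresponded vault
meshes → build the combined right-aligned cohort (left-sided cases
mirrored) and the balanced cohort (native + mirrored instance of every
subject) → generalized Procrustes alignment → PCA (cPC/bPC) and PLS-DA
(cLV/bLV) shape models → VIP surface map → UCS-SI severity index →
classical index battery → simulated expert pairwise judgments →
Davidson–Bradley–Terry ranking → correlation benchmarking → report.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, indices, ranking, shape_model, synthetic
from .mesh import CorrespondedShapeSet, TriangleMesh


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class StudyConfig:
    """Fully serializable description of one synthetic study run."""

    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    gpa_with_scaling: bool = True
    gpa_tol: float = 1e-10
    n_components: int = 2
    ucs_si_standardize: bool = True
    index: indices.IndexConfig = field(default_factory=indices.IndexConfig)
    n_raters: int = 3
    perceptual_noise_sd: float = 0.1
    tie_width: float = 0.05
    ranking_n_ucs: int = 15
    ranking_n_controls: int = 2
    mcmc_steps: int = 1500
    mcmc_burn_in: int = 500
    master_seed: int = 0
    write_meshes: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        data = json.loads(text)
        if "cohort" in data:
            c = dict(data["cohort"])
            if "severity_params" in c:
                c["severity_params"] = tuple(c["severity_params"])
            data["cohort"] = synthetic.CohortConfig(**c)
        if "index" in data:
            data["index"] = indices.IndexConfig(**data["index"])
        return cls(**data)

    def derived_seed(self, offset: int) -> int:
        return int((self.master_seed * 9973 + offset) % (2**31 - 1))


def build_combined_cohort(shape_set: CorrespondedShapeSet) -> CorrespondedShapeSet:
    """Right-aligned cohort: left-sided cases mirrored to the right, one
    instance per subject, so laterality no longer partitions the cases."""
    shapes = shape_set.shapes.copy()
    lateralities = list(shape_set.lateralities)
    mirrored = shape_set.mirrored.copy()
    for i, lat in enumerate(shape_set.lateralities):
        if lat == "left":
            shapes[i] = geometry.mirror_shape(shapes[i], shape_set.pairing)
            lateralities[i] = "right"
            mirrored[i] = True
    return CorrespondedShapeSet(
        shapes=shapes,
        subject_ids=list(shape_set.subject_ids),
        groups=list(shape_set.groups),
        lateralities=lateralities,
        mirrored=mirrored,
        faces=shape_set.faces,
        pairing=shape_set.pairing,
        extra=dict(shape_set.extra),
    )


def build_balanced_cohort(shape_set: CorrespondedShapeSet) -> CorrespondedShapeSet:
    """Balanced cohort: the native AND mirrored instance of every subject,
    so the shape model cannot confound laterality with pathology."""
    n = shape_set.n_shapes
    flip = {"left": "right", "right": "left", "none": "none"}
    mirrored_shapes = np.stack(
        [geometry.mirror_shape(s, shape_set.pairing) for s in shape_set.shapes]
    )
    return CorrespondedShapeSet(
        shapes=np.concatenate([shape_set.shapes, mirrored_shapes]),
        subject_ids=list(shape_set.subject_ids) * 2,
        groups=list(shape_set.groups) * 2,
        lateralities=list(shape_set.lateralities)
        + [flip[l] for l in shape_set.lateralities],
        mirrored=np.concatenate(
            [shape_set.mirrored, ~shape_set.mirrored]
        ),
        faces=shape_set.faces,
        pairing=shape_set.pairing,
        extra=dict(shape_set.extra),
    )


def export_vip_surface(
    mean_shape: np.ndarray,
    faces: np.ndarray,
    per_vertex_vip: np.ndarray,
    path: str | Path,
) -> None:
    """Write the mean shape as ASCII PLY with per-vertex VIP in the
    ``quality`` channel, for colour mapping in external 3D viewers."""
    mesh = TriangleMesh(vertices=np.asarray(mean_shape).reshape(-1, 3), faces=faces)
    mesh.save(path, vertex_scalar=per_vertex_vip)


@dataclass
class StudyReport:
    """All study outputs, with a manifest of written files."""

    config: StudyConfig
    truth: pd.DataFrame
    severity_table: pd.DataFrame
    pca_combined: shape_model.PCAModel
    pca_balanced: shape_model.PCAModel
    pls_combined: shape_model.PLSDAModel
    pls_balanced: shape_model.PLSDAModel
    control_reference: shape_model.ControlReference
    aligned_balanced: geometry.AlignedShapeSet
    balanced_set: CorrespondedShapeSet
    vip_per_vertex: np.ndarray
    judgments: ranking.PairwiseJudgments
    davidson: ranking.DavidsonModel
    ranking_result: ranking.RankingResult
    kendall_w: dict
    benchmark: pd.DataFrame
    score_correlations: pd.DataFrame
    summary: dict
    manifest: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: StudyConfig, out_dir: str | Path | None = None,
              verbose: bool = False) -> StudyReport:
    """Execute the full synthetic study; optionally persist all artifacts.

    Any stage failure raises :class:`StageError` naming the stage; outputs
    of completed stages are already on disk when ``out_dir`` is given.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    timings: dict[str, float] = {}

    def _write_df(df: pd.DataFrame, name: str) -> None:
        if out is None:
            return
        path = out / name
        df.to_csv(path, index=False)
        manifest[name] = _checksum(path)

    def _log(stage: str, t0: float, **params) -> None:
        timings[stage] = time.perf_counter() - t0
        if verbose:
            extras = " ".join(f"{k}={v}" for k, v in params.items())
            print(f"[{stage}] {timings[stage]:.2f}s {extras}")

    stage = "synth"
    try:
        t0 = time.perf_counter()
        template = synthetic.build_symmetric_template(
            config.cohort.template_subdivisions
        )
        cohort_cfg = synthetic.CohortConfig(
            **{**asdict(config.cohort),
               "master_seed": config.cohort.master_seed},
        )
        shape_set, truth = synthetic.synthesize_cohort(cohort_cfg, template)
        _write_df(truth, "ground_truth.csv")
        if out is not None:
            (out / "study_config.json").write_text(config.to_json())
            manifest["study_config.json"] = _checksum(out / "study_config.json")
            if config.write_meshes:
                mesh_dir = out / "meshes"
                mesh_dir.mkdir(exist_ok=True)
                for i in range(shape_set.n_shapes):
                    shape_set.mesh(i).save(
                        mesh_dir / f"{shape_set.subject_ids[i]}.ply"
                    )
        _log(stage, t0, n=shape_set.n_shapes, V=shape_set.n_vertices,
             seed=config.cohort.master_seed)

        stage = "align"
        t0 = time.perf_counter()
        combined = build_combined_cohort(shape_set)
        balanced = build_balanced_cohort(shape_set)
        aligned_combined = geometry.generalized_procrustes(
            combined, with_scaling=config.gpa_with_scaling, tol=config.gpa_tol
        )
        aligned_balanced = geometry.generalized_procrustes(
            balanced, with_scaling=config.gpa_with_scaling, tol=config.gpa_tol
        )
        _log(stage, t0, combined=aligned_combined.n_shapes,
             balanced=aligned_balanced.n_shapes)

        stage = "ssm"
        t0 = time.perf_counter()
        k = config.n_components
        pca_c = shape_model.fit_pca(aligned_combined, k, cohort_tag="combined")
        pca_b = shape_model.fit_pca(aligned_balanced, k, cohort_tag="balanced")
        pls_c = shape_model.fit_plsda(
            aligned_combined,
            shape_model.ResponseDesign.from_shape_set(combined, mode="binary"),
            n_components=k, cohort_tag="combined",
        )
        pls_b = shape_model.fit_plsda(
            aligned_balanced,
            shape_model.ResponseDesign.from_shape_set(balanced, mode="dual"),
            n_components=k, cohort_tag="balanced",
        )
        _, vip_vertex = shape_model.vip_scores(pls_b)
        if out is not None:
            export_vip_surface(
                aligned_balanced.consensus, balanced.faces, vip_vertex,
                out / "vip_surface.ply",
            )
            manifest["vip_surface.ply"] = _checksum(out / "vip_surface.ply")
            for name, model in (
                ("pca_combined", pca_c), ("pca_balanced", pca_b),
                ("pls_combined", pls_c), ("pls_balanced", pls_b),
            ):
                shape_model.save_model(model, out / f"{name}.npz")
                manifest[f"{name}.npz"] = _checksum(out / f"{name}.npz")
        _log(stage, t0, components=k)

        stage = "severity"
        t0 = time.perf_counter()
        is_control_balanced = np.array(
            [g == "control" for g in balanced.groups]
        )
        control_ref = shape_model.ControlReference.from_scores(
            pls_b.scores, is_control_balanced, n_components=2
        )
        n = shape_set.n_shapes  # native instances are the first n rows
        si = shape_model.ucs_si(
            pls_b.scores[:n, :2], control_ref,
            standardize=config.ucs_si_standardize,
        )
        scores_df = pd.DataFrame({"subject_id": shape_set.subject_ids})
        for nm, col in zip(pca_c.component_names(), pca_c.scores.T):
            scores_df[nm] = col
        for nm, col in zip(pls_c.component_names(), pls_c.scores.T):
            scores_df[nm] = col
        for nm, col in zip(pca_b.component_names(), pca_b.scores[:n].T):
            scores_df[nm] = col
        for nm, col in zip(pls_b.component_names(), pls_b.scores[:n].T):
            scores_df[nm] = col
        scores_df["UCS_SI"] = si
        _log(stage, t0)

        stage = "indices"
        t0 = time.perf_counter()
        index_df = indices.compute_all_indices(shape_set, config.index)
        severity_table = index_df.merge(scores_df, on="subject_id")
        _write_df(severity_table, "severity_table.csv")
        if out is not None:
            sidecar = {
                "diagonal_angle": config.index.diagonal_angle,
                "dice_resolution": config.index.dice_resolution,
                "n_contour_samples": config.index.n_contour_samples,
                "plane_height": config.index.plane_height,
                "master_seed": config.master_seed,
            }
            (out / "severity_table.json").write_text(json.dumps(sidecar, indent=2))
            manifest["severity_table.json"] = _checksum(out / "severity_table.json")
        _log(stage, t0, rows=len(severity_table))

        stage = "rank"
        t0 = time.perf_counter()
        rng = np.random.default_rng(config.derived_seed(1))
        ucs_ids = truth.loc[truth.group == "UCS", "subject_id"].to_numpy()
        ctl_ids = truth.loc[truth.group == "control", "subject_id"].to_numpy()
        roster = list(
            rng.choice(ucs_ids, min(config.ranking_n_ucs, len(ucs_ids)),
                       replace=False)
        ) + list(
            rng.choice(ctl_ids, min(config.ranking_n_controls, len(ctl_ids)),
                       replace=False)
        )
        true_sev = truth.set_index("subject_id").loc[roster, "severity"]
        judgments = synthetic.simulate_pairwise_judgments(
            true_sev,
            n_raters=config.n_raters,
            perceptual_noise_sd=config.perceptual_noise_sd,
            tie_width=config.tie_width,
            seed=config.derived_seed(2),
        )
        if out is not None:
            judgments.to_csv(out / "judgments.csv")
            manifest["judgments.csv"] = _checksum(out / "judgments.csv")
        davidson, rank_result = ranking.fit_davidson_bt(
            judgments,
            n_steps=config.mcmc_steps,
            burn_in=config.mcmc_burn_in,
            seed=config.derived_seed(3),
        )
        w = ranking.kendalls_w(ranking.rankings_from_judgments(judgments))
        _write_df(rank_result.to_frame(), "expert_ranking.csv")
        if out is not None:
            (out / "ranking_diagnostics.json").write_text(
                json.dumps({**rank_result.diagnostics, "kendalls_w": w}, indent=2)
            )
            manifest["ranking_diagnostics.json"] = _checksum(
                out / "ranking_diagnostics.json"
            )
        _log(stage, t0, judgments=judgments.n_judgments, W=round(w["W"], 3))

        stage = "benchmark"
        t0 = time.perf_counter()
        numeric = [
            c for c in severity_table.columns
            if pd.api.types.is_numeric_dtype(severity_table[c])
            and c not in ("plane_height",)
        ]
        bench = ranking.benchmark_indices(
            severity_table, rank_result, method="kendall", index_columns=numeric
        )
        fig6_cols = [c for c in ("bLV_1", "bLV_2", "UCS_SI", "CVAI",
                                 "forehead_asymmetry_ratio", "gradient_ratio")
                     if c in severity_table.columns]
        ucs_rows = severity_table["group"] == "UCS"
        score_corr = ranking.pairwise_score_correlations(
            severity_table.loc[ucs_rows], fig6_cols, method="spearman"
        )
        _write_df(bench, "benchmark_correlations.csv")
        if out is not None:
            score_corr.to_csv(out / "score_correlations.csv")
            manifest["score_correlations.csv"] = _checksum(
                out / "score_correlations.csv"
            )
        _log(stage, t0)

        stage = "report"
        t0 = time.perf_counter()
        merged = severity_table.merge(truth, on=["subject_id", "group",
                                                 "laterality"])
        from scipy import stats as _st

        ucs_mask = merged["group"] == "UCS"
        spearman_si = float(
            _st.spearmanr(merged["UCS_SI"], merged["severity"]).statistic
        )
        # bLV1 encodes laterality (mirror-antisymmetric): UCS instances sit
        # at ±score with controls near zero, so its discriminative content
        # is the magnitude of deviation from the control centre.
        z1_abs = np.abs(
            (pls_b.scores[:n, 0] - control_ref.mean[0]) / control_ref.sd[0]
        )
        auc_blv1 = shape_model.training_auc(
            z1_abs, [g == "UCS" for g in shape_set.groups]
        )
        recover = truth.set_index("subject_id").loc[
            rank_result.roster, "severity"
        ]
        spearman_rank = float(
            _st.spearmanr(rank_result.posterior_mean, recover).statistic
        )
        summary = {
            "n_subjects": int(shape_set.n_shapes),
            "n_vertices": int(shape_set.n_vertices),
            "pca_combined_explained": pca_c.explained_variance_ratio.tolist(),
            "pca_balanced_explained": pca_b.explained_variance_ratio.tolist(),
            "pls_balanced_ssy": pls_b.ssy.tolist(),
            "spearman_ucs_si_vs_severity": spearman_si,
            "blv1_training_auc": auc_blv1,
            "kendalls_w": w["W"],
            "kendalls_w_p": w["p"],
            "spearman_ranking_recovery": spearman_rank,
            "vip_max": float(vip_vertex.max()),
            "master_seed": config.master_seed,
        }
        if out is not None:
            (out / "report.json").write_text(
                json.dumps({"summary": summary, "manifest": manifest,
                            "timings": timings}, indent=2)
            )
            lines = ["Synthetic cranial-vault severity study", ""]
            lines += [f"{k}: {v}" for k, v in summary.items()]
            (out / "report.txt").write_text("\n".join(lines) + "\n")
        _log(stage, t0)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        raise StageError(stage, exc) from exc

    return StudyReport(
        config=config,
        truth=truth,
        severity_table=severity_table,
        pca_combined=pca_c,
        pca_balanced=pca_b,
        pls_combined=pls_c,
        pls_balanced=pls_b,
        control_reference=control_ref,
        aligned_balanced=aligned_balanced,
        balanced_set=balanced,
        vip_per_vertex=vip_vertex,
        judgments=judgments,
        davidson=davidson,
        ranking_result=rank_result,
        kendall_w=w,
        benchmark=bench,
        score_correlations=score_corr,
        summary=summary,
        manifest=manifest,
        timings=timings,
    )
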