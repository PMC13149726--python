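"""Synthetic cohort generator: corresponded vault-like meshes with known
severity and laterality ground truth, plus simulated expert judgments.

The template is a bilaterally symmetric half-ellipsoid vault (infant-like
semi-axes, base capped flat) whose vertices carry an exact left/right
symmetry pairing.  A unicoronal-synostosis-like deformity is synthesised as
a smooth unilateral field — ipsilateral fronto-supraorbital flattening with
contralateral-frontal and ipsilateral-parietal compensatory bossing — whose
amplitude scales linearly with a generative severity in [0, 1].  Because
the field is built from Gaussians of Euclidean distance and ellipsoid
normals, swapping laterality commutes exactly with mirroring.

Per-subject "normal variation" is a random combination of a small fixed set
of smooth low-frequency trigonometric basis fields (not i.i.d. vertex
jitter), so meshes stay manifold and the noise is spatially correlated like
real anatomical variation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .mesh import CorrespondedShapeSet, MeshError, SymmetryPairing, TriangleMesh
from .ranking import PairwiseJudgments

# Infant-like vault semi-axes (mm): lateral (x), anteroposterior (y),
# vertical (z).
SEMI_AXES = (70.0, 90.0, 65.0)

# Deformation design: (azimuth deg from anterior, + toward the LEFT;
# polar deg from vertex; amplitude mm at severity 1, negative = inward).
# Laterality "right" places the ipsilateral bumps at negative azimuth (+x).
_BUMPS_RIGHT = (
    (-40.0, 55.0, -10.0),  # ipsilateral frontal/supraorbital flattening
    (+40.0, 55.0, +5.0),   # contralateral frontal compensatory bossing
    (-130.0, 45.0, +5.0),  # ipsilateral parietal compensation
)
_BUMP_SIGMA = 28.0  # Gaussian width of each deformation lobe (mm)
_BASE_PIN = 20.0    # soft window pinning the vault base (mm)


class CohortError(ValueError):
    """Invalid cohort or subject specification."""


@dataclass(frozen=True)
class SubjectSpec:
    """Generative ground truth for one synthetic subject."""

    subject_id: str
    group: str  # "UCS" | "control"
    laterality: str  # "left" | "right" | "none"
    severity: float
    size_scale: float = 1.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("UCS", "control"):
            raise CohortError(f"unknown group {self.group!r}")
        if not 0.0 <= self.severity <= 1.0:
            raise CohortError("severity must lie in [0, 1]")
        if self.size_scale <= 0:
            raise CohortError("size_scale must be positive")
        if self.noise_scale < 0:
            raise CohortError("noise_scale must be non-negative")
        if self.group == "control":
            if self.severity != 0 or self.laterality != "none":
                raise CohortError("controls must have severity 0, laterality none")
        else:
            if self.laterality not in ("left", "right"):
                raise CohortError("UCS subjects need laterality left or right")


@dataclass(frozen=True)
class CohortConfig:
    """Reproducible description of a synthetic cohort.

    Defaults emulate the study conditions: ~2/3 right-sided cases, severity
    spread over most of the generative range, millimetre-scale smooth
    normal variation.
    """

    n_ucs: int = 40
    n_controls: int = 20
    severity_distribution: str = "uniform"
    severity_params: tuple = (0.2, 1.0)
    fraction_right: float = 0.68
    template_subdivisions: int = 8
    noise_scale: float = 1.0
    size_scale_sd: float = 0.03
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ucs < 0 or self.n_controls < 0:
            raise CohortError("subject counts must be non-negative")
        if not 0.0 <= self.fraction_right <= 1.0:
            raise CohortError("fraction_right must lie in [0, 1]")
        if self.severity_distribution not in ("uniform", "beta", "constant"):
            raise CohortError(
                f"unknown severity distribution {self.severity_distribution!r}"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        data = json.loads(text)
        if "severity_params" in data:
            data["severity_params"] = tuple(data["severity_params"])
        return cls(**data)


def build_symmetric_template(subdivisions: int = 8) -> TriangleMesh:
    """Closed, bilaterally symmetric half-ellipsoid vault mesh.

    ``subdivisions`` controls resolution: the dome has ``4·s`` latitude
    rings of ``8·s`` vertices plus apex and base-centre vertices, so the
    vertex count is ``2 + 32·s²`` (s=8 → 2050 vertices).  Every vertex has
    an exact symmetry partner across x = 0.
    """
    if subdivisions < 1:
        raise CohortError("subdivisions must be ≥ 1")
    s = int(subdivisions)
    n = 8 * s  # azimuth samples (even, so both midline meridians exist)
    m = 4 * s  # latitude rings, ring m is the base equator at z = 0
    rx, ry, rz = SEMI_AXES

    theta = np.arange(n) * (2 * np.pi / n)  # 0 = anterior, + toward left
    verts = [np.array([0.0, 0.0, rz])]  # apex
    for k in range(1, m + 1):
        phi = (np.pi / 2) * k / m
        x = -rx * np.sin(phi) * np.sin(theta)
        y = ry * np.sin(phi) * np.cos(theta)
        z = np.full(n, rz * np.cos(phi))
        verts.append(np.stack([x, y, z], axis=1))
    apex = 0
    ring0 = 1

    def vid(k: int, j: int) -> int:
        return ring0 + (k - 1) * n + (j % n)

    base_centre = ring0 + m * n
    vertices = np.vstack([verts[0][None, :], *verts[1:], np.zeros((1, 3))])

    faces: list[tuple[int, int, int]] = []
    for j in range(n):
        faces.append((apex, vid(1, j), vid(1, j + 1)))
    for k in range(1, m):
        for j in range(n):
            a, b = vid(k, j), vid(k, j + 1)
            c, d = vid(k + 1, j), vid(k + 1, j + 1)
            faces.append((a, c, d))
            faces.append((a, d, b))
    for j in range(n):
        faces.append((base_centre, vid(m, j + 1), vid(m, j)))

    partner = np.arange(len(vertices))
    for k in range(1, m + 1):
        for j in range(n):
            partner[vid(k, j)] = vid(k, (n - j) % n)
    pairing = SymmetryPairing(partner=partner)
    return TriangleMesh(
        vertices=vertices, faces=np.asarray(faces, dtype=np.intp), pairing=pairing
    )


def _ellipsoid_point(azimuth_deg: float, polar_deg: float) -> np.ndarray:
    rx, ry, rz = SEMI_AXES
    th = np.deg2rad(azimuth_deg)
    ph = np.deg2rad(polar_deg)
    return np.array(
        [-rx * np.sin(ph) * np.sin(th), ry * np.sin(ph) * np.cos(th),
         rz * np.cos(ph)]
    )


def _outward_normals(vertices: np.ndarray) -> np.ndarray:
    rx, ry, rz = SEMI_AXES
    n = vertices / np.array([rx**2, ry**2, rz**2])
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    return n / norms


def _base_window(z: np.ndarray) -> np.ndarray:
    """Smooth 0→1 factor pinning the base plane (z = 0) in place."""
    return z**2 / (z**2 + _BASE_PIN**2)


def deformation_field(
    vertices: np.ndarray, severity: float, laterality: str
) -> np.ndarray:
    """Smooth unilateral deformity displacement (V×3, mm), linear in
    severity.  Exactly mirror-equivariant in laterality."""
    if severity == 0:
        return np.zeros_like(vertices)
    sign = 1.0 if laterality == "right" else -1.0
    disp = np.zeros_like(vertices)
    normals = _outward_normals(vertices)
    window = _base_window(vertices[:, 2])
    for azim, polar, amp in _BUMPS_RIGHT:
        centre = _ellipsoid_point(sign * azim, polar)
        centre[0] *= 1.0  # azimuth sign flip already mirrors x
        d2 = np.sum((vertices - centre) ** 2, axis=1)
        g = np.exp(-d2 / (2 * _BUMP_SIGMA**2))
        disp += (severity * amp) * (g * window)[:, None] * normals
    return disp


def deformation_support(vertices: np.ndarray, laterality: str = "right",
                        threshold: float = 0.2) -> np.ndarray:
    """Boolean mask of vertices inside the deformity's support (Gaussian
    response above ``threshold`` of its peak for any lobe).  Used to check
    that high-VIP regions coincide with where the generator actually acts."""
    sign = 1.0 if laterality == "right" else -1.0
    window = _base_window(vertices[:, 2])
    mask = np.zeros(len(vertices), dtype=bool)
    for azim, polar, _amp in _BUMPS_RIGHT:
        centre = _ellipsoid_point(sign * azim, polar)
        d2 = np.sum((vertices - centre) ** 2, axis=1)
        mask |= np.exp(-d2 / (2 * _BUMP_SIGMA**2)) * window > threshold
    return mask


# Fixed low-frequency wave vectors for the smooth noise basis (rad/mm).
_NOISE_WAVES = np.array(
    [
        [w / 60.0, 0.0, 0.0] for w in (1.0, 2.0)
    ]
    + [[0.0, w / 60.0, 0.0] for w in (1.0, 2.0)]
    + [[0.0, 0.0, w / 60.0] for w in (1.0, 2.0)]
    + [
        [1 / 70.0, 1 / 80.0, 0.0],
        [1 / 70.0, -1 / 80.0, 0.0],
        [0.0, 1 / 80.0, 1 / 60.0],
        [1 / 70.0, 0.0, -1 / 60.0],
        [1 / 90.0, 1 / 90.0, 1 / 90.0],
        [-1 / 90.0, 1 / 90.0, 1 / 90.0],
    ]
)
_NOISE_PHASES = np.linspace(0.3, 5.9, len(_NOISE_WAVES))


def smooth_noise_field(
    vertices: np.ndarray, noise_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Correlated per-subject shape noise: random coefficients on the fixed
    smooth basis, displacing along outward normals; RMS ≈ noise_scale mm."""
    if noise_scale == 0:
        # keep the rng stream advancing identically regardless of scale
        rng.standard_normal(len(_NOISE_WAVES))
        return np.zeros_like(vertices)
    coeff = rng.standard_normal(len(_NOISE_WAVES))
    phase = vertices @ _NOISE_WAVES.T + _NOISE_PHASES
    basis = np.sin(phase)  # V × n_basis, each roughly unit-power
    f = basis @ coeff / np.sqrt(len(_NOISE_WAVES) / 2.0)
    window = _base_window(vertices[:, 2])
    return noise_scale * (f * window)[:, None] * _outward_normals(vertices)


def synthesize_subject(template: TriangleMesh, spec: SubjectSpec) -> TriangleMesh:
    """Deform the template into one synthetic subject.

    Deterministic in (spec, seed); severity 0 with zero noise and unit size
    returns the template exactly.
    """
    if template.pairing is None:
        raise MeshError("template needs a symmetry pairing")
    rng = np.random.default_rng(spec.seed)
    v = template.vertices
    disp = deformation_field(v, spec.severity, spec.laterality or "right")
    noise = smooth_noise_field(v, spec.noise_scale, rng)
    out = (v + disp + noise) * spec.size_scale
    return template.with_vertices(out)


def _draw_severities(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    p = config.severity_params
    if config.severity_distribution == "uniform":
        return rng.uniform(p[0], p[1], config.n_ucs)
    if config.severity_distribution == "beta":
        return rng.beta(p[0], p[1], config.n_ucs)
    return np.full(config.n_ucs, float(p[0]))


def synthesize_cohort(
    config: CohortConfig, template: TriangleMesh | None = None
) -> tuple[CorrespondedShapeSet, pd.DataFrame]:
    """Generate the full cohort and its ground-truth table.

    Returns the corresponded shape set (one native instance per subject)
    and a DataFrame with columns subject_id, group, laterality, severity,
    size_scale, seed.
    """
    n_total = config.n_ucs + config.n_controls
    if n_total == 0:
        raise CohortError("cohort must contain at least one subject")
    if template is None:
        template = build_symmetric_template(config.template_subdivisions)
    rng = np.random.default_rng(config.master_seed)
    severities = _draw_severities(config, rng)
    n_right = int(round(config.fraction_right * config.n_ucs))
    sides = np.array(["right"] * n_right + ["left"] * (config.n_ucs - n_right))
    rng.shuffle(sides)
    size_scales = 1.0 + config.size_scale_sd * rng.standard_normal(n_total)
    size_scales = np.clip(size_scales, 0.5, 1.5)
    seeds = rng.integers(0, 2**31 - 1, n_total)

    specs: list[SubjectSpec] = []
    for i in range(config.n_ucs):
        specs.append(
            SubjectSpec(
                subject_id=f"ucs{i:03d}",
                group="UCS",
                laterality=str(sides[i]),
                severity=float(severities[i]),
                size_scale=float(size_scales[i]),
                noise_scale=config.noise_scale,
                seed=int(seeds[i]),
            )
        )
    for i in range(config.n_controls):
        j = config.n_ucs + i
        specs.append(
            SubjectSpec(
                subject_id=f"ctl{i:03d}",
                group="control",
                laterality="none",
                severity=0.0,
                size_scale=float(size_scales[j]),
                noise_scale=config.noise_scale,
                seed=int(seeds[j]),
            )
        )

    shapes = np.stack(
        [synthesize_subject(template, spec).vertices for spec in specs]
    )
    shape_set = CorrespondedShapeSet(
        shapes=shapes,
        subject_ids=[s.subject_id for s in specs],
        groups=[s.group for s in specs],
        lateralities=[s.laterality for s in specs],
        mirrored=np.zeros(n_total, dtype=bool),
        faces=template.faces,
        pairing=template.pairing,
        extra={"config": asdict(config)},
    )
    truth = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in specs],
            "group": [s.group for s in specs],
            "laterality": [s.laterality for s in specs],
            "severity": [s.severity for s in specs],
            "size_scale": [s.size_scale for s in specs],
            "seed": [s.seed for s in specs],
        }
    )
    return shape_set, truth


def simulate_pairwise_judgments(
    true_severity: pd.Series | dict[str, float],
    n_raters: int = 3,
    perceptual_noise_sd: float = 0.1,
    tie_width: float = 0.05,
    design: str = "all_pairs",
    n_pairs_per_rater: int | None = None,
    seed: int = 0,
) -> PairwiseJudgments:
    """Simulate expert pairwise severity comparisons.

    Each rater perceives every subject with independent Gaussian error of
    SD ``perceptual_noise_sd`` (severity units) per comparison; a pair is a
    tie when perceived severities differ by less than ``tie_width``.
    ``all_pairs`` presents every pair to every rater; ``random_k`` samples
    ``n_pairs_per_rater`` pairs with replacement per rater.
    """
    if isinstance(true_severity, dict):
        true_severity = pd.Series(true_severity)
    roster = list(true_severity.index.astype(str))
    sev = true_severity.to_numpy(dtype=float)
    if len(roster) < 2:
        raise CohortError("need at least two subjects to compare")
    if n_raters < 1:
        raise CohortError("need at least one rater")
    if tie_width < 0:
        raise CohortError("tie_width must be non-negative")
    if design not in ("all_pairs", "random_k"):
        raise CohortError(f"unknown design {design!r}")
    rng = np.random.default_rng(seed)
    all_pairs = list(itertools.combinations(range(len(roster)), 2))
    rows = []
    for r in range(n_raters):
        if design == "all_pairs":
            pairs = all_pairs
        else:
            if not n_pairs_per_rater:
                raise CohortError("random_k design needs n_pairs_per_rater")
            pick = rng.integers(0, len(all_pairs), n_pairs_per_rater)
            pairs = [all_pairs[k] for k in pick]
        for i, j in pairs:
            si = sev[i] + perceptual_noise_sd * rng.standard_normal()
            sj = sev[j] + perceptual_noise_sd * rng.standard_normal()
            if abs(si - sj) < tie_width:
                outcome = "tie"
            else:
                outcome = "i" if si > sj else "j"
            rows.append(
                {
                    "rater_id": f"rater{r + 1}",
                    "subject_i": roster[i],
                    "subject_j": roster[j],
                    "outcome": outcome,
                }
            )
    table = pd.DataFrame(rows)
    return PairwiseJudgments(table=table, roster=roster)
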