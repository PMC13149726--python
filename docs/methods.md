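# Methods

## Problem and approach

Unicoronal synostosis (UCS) — premature fusion of one coronal suture —
produces a characteristic unilateral cranial deformity: flattening of the
ipsilateral frontal and supraorbital region with compensatory bossing of
the contralateral forehead and ipsilateral parietal region. Classical
severity measures (CVA/CVAI diagonals, contour quantifiers, hemisphere
ratios) reduce this 3-D deformity to a handful of predefined distances.
`vaultshape` instead learns the deformity axis from the shapes themselves:
a statistical shape model over corresponded vault meshes yields latent
axes of UCS-specific variation, and a subject's severity (UCS-SI) is its
squared standardized deviation from the control cluster in that latent
space. An expert-perception reference (pairwise comparisons fed to a
Bayesian Davidson–Bradley–Terry model) provides the validation target
against which all indices are benchmarked.

Everything runs on synthetic cohorts with known generative severity, so
each stage's recovery can be measured exactly.

## Coordinate conventions

One global anatomical frame is used everywhere: midsagittal plane at
x = 0, subject's right = +x, anterior = +y, superior = +z, units mm.
Radial head contours are sampled at uniform angles θ with θ = 0 anterior
and θ increasing toward the subject's left, so θ ∈ (0°, 90°) is the left
anterior quadrant.

## Synthetic cohort generator

The template is a watertight half-ellipsoid vault (semi-axes 70 × 90 ×
65 mm lateral/AP/vertical — infant-like proportions, cephalic index
77.8) capped flat at its base, built on a structured ring lattice so that
every vertex has an exact mirror partner across x = 0 (`subdivisions` s
gives 2 + 32·s² vertices; the default s = 8 → 2050 vertices keeps all
desk-scale analyses fast while the correspondence logic is
resolution-independent).

The UCS-like deformity is a smooth displacement field along the
ellipsoid's outward normals, built from three Gaussian lobes
(width σ = 28 mm) at anatomical proxy points:

| lobe | azimuth, polar | peak amplitude at severity 1 |
|---|---|---|
| ipsilateral frontal/supraorbital flattening | ∓40°, 55° | −10 mm |
| contralateral frontal bossing | ±40°, 55° | +5 mm |
| ipsilateral parietal compensation | ∓130°, 45° | +5 mm |

Amplitudes scale linearly with a generative severity in [0, 1]; a smooth
window (z²/(z² + 20²)) pins the vault base. A 10 mm peak flattening is a
plausible upper end for untreated infant UCS relative to a ~140 mm head
width. Because the field is a function of Euclidean distances and
ellipsoid normals only, swapping laterality commutes *exactly* with
mirroring — the property all mirror-consistency checks rest on.

Per-subject normal variation is not i.i.d. vertex jitter but random
coefficients on 12 fixed low-frequency trigonometric basis fields
(wavelengths ~60–90 mm·2π), displacing along outward normals with RMS ≈
`noise_scale` (default 1.0 mm). This emulates smooth anatomical
variability and keeps meshes manifold.

Default cohort: 40 UCS + 20 controls, 68% right-sided (matching typical
UCS laterality prevalence), severity ~ Uniform(0.2, 1) (diagnosed cases
are not asymptomatic); recovery experiments that stress the low end use
Uniform(0, 1) explicitly. All randomness flows from a single master seed
through per-subject seeds, so cohorts are bit-reproducible.

What the generator does **not** emulate: sutures, skull base, orbits and
face; CT noise and segmentation artefacts; growth; non-rigid registration
error (correspondence is exact by construction). Passing recovery tests
therefore demonstrates the statistical machinery is correct and
well-conditioned, not that clinical-data performance will match.

Simulated raters perceive each subject's severity with independent
Gaussian error (SD `perceptual_noise_sd`, default 0.1 severity units —
raters disagree on neighbouring cases but not on coarse ordering) and
declare ties below a perceptual difference of `tie_width` (default 0.05).

## Alignment and shape models

Generalized Procrustes analysis removes translation, size (unit centroid
size; size removal is the default and can be disabled) and rotation.
Rotations are Kabsch solutions constrained to det +1 — reflections are
forbidden so mirrored instances remain mirrored; mirroring happens only
through the explicit vertex-pairing operator. The consensus is
initialized from the mean of the centred shapes, which fixes the
rotational gauge and makes the result invariant to input ordering;
iteration stops when the consensus RMS change falls below 1e-10.

Two cohort constructions feed the models:

* **combined** (prefix c): left-sided cases mirrored to the right, one
  instance per subject — laterality no longer partitions the cases;
* **balanced** (prefix b): native *and* mirrored instance of every
  subject — the model cannot confound laterality with pathology, and
  every latent axis is either mirror-symmetric or mirror-antisymmetric.

PCA (cPC/bPC) is computed by SVD of the centred N×3V matrix. PLS-DA
(cLV/bLV) is NIPALS PLS2 with X-deflation only; each component's weight
vector is the NIPALS fixed point computed exactly as the dominant left
singular vector of XᵀY, so components are deterministic to machine
precision regardless of eigengap (a literal iterative NIPALS and
scikit-learn's PLSRegression serve as independent oracles in the test
suite). Y is left undeflated — in regression-mode PLS2 this does not
change the weight/score sequence and keeps the per-component response
sum-of-squares SSY_a = (t_aᵀt_a)‖q_a‖² direct, which the VIP formula
needs:

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ),  p = 3V.

mean(VIP²) = 1 identically; per-vertex VIP is the RMS of a vertex's three
coordinate VIPs. All components carry a fixed sign convention (the
largest-magnitude loading entry is positive) for cross-platform
reproducibility.

Responses: binary (pathology 0/1) on the combined cohort; dual
(pathology 0/1, laterality −1/+1) on the balanced cohort. Controls are
coded 0 on the laterality column — they are laterality-neutral, and any
±1 assignment would be arbitrary.

## UCS-SI

With the balanced dual-response model, bLV1 is the mirror-antisymmetric
laterality-encoding axis (controls cluster at zero, cases sit at ±score
by side) and bLV2 is mirror-invariant. Each of the first two LV scores is
standardized against the control group's mean and SD, and

    UCS-SI = z₁² + z₂²,

the squared deviation from the control shape distribution in latent
space. Standardizing before squaring makes the two axes commensurate;
the raw (unstandardized) sum of squares is available behind a flag for
sensitivity analysis. The index is invariant to mirroring by
construction (z₁ flips sign, z₂ is unchanged), which the tests verify to
1e-6 per subject.

Because bLV1 is sign-symmetric in laterality, group separation is
carried by |z₁| rather than the raw score; the discrimination check
(training AUC of cases vs controls, ≥ 0.95 on the default synthetic
conditions) therefore uses the deviation magnitude — the same quantity
UCS-SI squares.

## Classical index battery

* **Measurement plane**: by default the axial section of maximal contour
  area (scanned over the central 5–95% of the vertical extent, logged per
  subject); configurable.
* **CVA/CVAI**: cross-diagonals through the section centroid at ±30°
  (common convention, configurable) off the AP axis;
  CVA = |d1 − d2|, CVAI = 100·|d1 − d2|/max(d1, d2).
* **UCSQ-family measures** (forehead asymmetry ratio, gradient ratio,
  peak positions): computed on the radial contour's anterior quadrants.
  These are a documented local operationalization of the named
  variables, not the canonical published formulas.
* **Hemisphere ratios**: the mesh is clipped at x = 0; capped-half
  volumes are obtained from the open halves via the divergence theorem
  with field (x, 0, 0) (the planar cap at x = 0 carries zero x-flux),
  surface ratios exclude the cut face.
* **Vertex-wise asymmetry**: distance of each vertex to its partner
  after rigidly re-aligning the mirror image using the known
  correspondence (rigid-motion invariant).
* **Contour AUC**: ∫₀^π |r(θ) − r(2π−θ)| dθ, trapezoid rule.
* **Dice symmetry**: mirror → rigid ICP back onto the native mesh →
  voxelize both on one shared grid → 100·2|A∩B|/(|A|+|B|). Default voxel
  pitch 2 mm in the cohort battery (1 mm for single-mesh checks);
  voxelization marks a voxel occupied iff its centre is inside the
  surface, by even–odd counting of triangle crossings along z-columns
  (a tiny irrational grid offset removes ray/edge coincidences).
  Non-watertight meshes are rejected, not repaired.
* **ICP** uses nearest-point-on-surface correspondence (vectorized
  point–triangle closest point, candidates from the nearest vertex's
  incident faces). Nearest-vertex matching is reserved for bare point
  clouds: on structured lattices like the template (azimuth pitch ≈ 5.6°)
  it locks onto the shifted lattice and stalls several degrees from the
  true pose.

## Expert ranking

The Davidson extension of Bradley–Terry models each judgment of subjects
(i, j) with P(i) = π_i/D, P(j) = π_j/D, P(tie) = ν√(π_iπ_j)/D,
D = π_i + π_j + ν√(π_iπ_j). The likelihood is invariant to a common
rescaling of π, so λ = log π carries a sum-to-zero constraint. Priors:
λ_i ~ Normal(0, prior_sd²) (default prior_sd 2 — weakly informative on
the log-odds scale), log ν ~ Normal(0, 1). The posterior is sampled with
a seeded affine-invariant ensemble sampler (64 walkers, 1500 steps, 500
burn-in, thin 2 by default); λ is sampled unconstrained and each draw is
centred — exact because the likelihood is shift-invariant and the prior
exchangeable. Subjects are ranked by posterior-mean λ; controls are part
of the ranked roster.

Inter-rater agreement uses Kendall's W with mid-ranks and tie
correction, p from the χ² approximation (m(n−1)W, n−1 df) and optionally
a seeded permutation test. Index benchmarking uses Kendall's tau-b
(exact p for n ≤ 8 without ties) or Spearman correlation against the
posterior-mean severities.

## Problem sizes and defaults

The default study is 40 UCS + 20 controls on the 2050-vertex template —
large enough that PLS-DA axes and control references are stable, small
enough that the full pipeline (including per-subject Dice at 2 mm and the
MCMC ranking fit) completes in about a minute on one core. The expert
ranking roster is 15 affected + 2 controls with 3 raters over all 136
pairs, the roster size at which perception experiments of this kind are
practical.

## Known limitations

* All performance figures are on the synthetic generator; none transfer
  quantitatively to clinical meshes.
* The UCSQ-family formulas are local operationalizations.
* The shape model is linear; strongly non-linear deformity trajectories
  would need kernelized or geodesic extensions.
* No cross-validated component selection or permutation testing of the
  PLS-DA models; A = 2 components are retained by default.
* Dice and CVAI depend on voxel pitch and plane choice respectively;
  both parameters are logged in the severity-table sidecar.
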