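"""Fit the balanced-cohort shape model and compute the UCS-SI severity
index.

Every subject enters the model twice (native + mirrored), the dual
PLS-DA response encodes pathology (0/1) and laterality (−1/+1, controls
0), and UCS-SI is the squared standardized deviation of a subject's
(bLV1, bLV2) scores from the control cluster.  The printed Spearman
correlation shows how well the index recovers the generative severity.
"""

import numpy as np
from scipy import stats

from vaultshape import (
    CohortConfig,
    ControlReference,
    ResponseDesign,
    build_balanced_cohort,
    fit_plsda,
    generalized_procrustes,
    synthesize_cohort,
    ucs_si,
    vip_scores,
)

config = CohortConfig(n_ucs=20, n_controls=10, template_subdivisions=6,
                      master_seed=1)
shape_set, truth = synthesize_cohort(config)
balanced = build_balanced_cohort(shape_set)
aligned = generalized_procrustes(balanced)

design = ResponseDesign.from_shape_set(balanced, mode="dual")
pls = fit_plsda(aligned, design, n_components=2, cohort_tag="balanced")
print(f"response SS explained per LV: {np.round(pls.ssy, 1)}")

is_control = np.array([g == "control" for g in balanced.groups])
ref = ControlReference.from_scores(pls.scores, is_control)
n = shape_set.n_shapes
si = ucs_si(pls.scores[:n, :2], ref)

rho = stats.spearmanr(si, truth["severity"]).statistic
print(f"Spearman(UCS-SI, generative severity) = {rho:.3f}")
print("(values near 1 mean the latent-space index orders subjects almost "
      "exactly by their true deformity)")

# VIP localises where on the skull the discriminative signal lives
_, vip_vertex = vip_scores(pls)
print(f"per-vertex VIP: max {vip_vertex.max():.2f}, "
      f"90th percentile {np.quantile(vip_vertex, 0.9):.2f} "
      "(high values mark the fronto-parietal deformation zones)")
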