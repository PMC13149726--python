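"""Compute the classical cranial asymmetry battery on one synthetic case.

CVA/CVAI come from contour cross-diagonals, UCSQ-family measures from the
radial head contour, hemisphere ratios from midplane clipping, and the
Dice score from mirror-overlap voxelization.  A severity-0.8 case is
compared against the perfectly symmetric template.
"""

from vaultshape import (
    SubjectSpec,
    build_symmetric_template,
    cva_cvai,
    dice_asymmetry,
    hemisphere_ratios,
    synthesize_subject,
    vertexwise_asymmetry,
)
from vaultshape.geometry import axial_radial_contour
from vaultshape.indices import contour_curve_difference, ucsq_measures

template = build_symmetric_template(8)
case = synthesize_subject(
    template,
    SubjectSpec("case", "UCS", "right", severity=0.8, noise_scale=0.0, seed=7),
)

for name, mesh in (("symmetric template", template), ("severity-0.8 case", case)):
    print(f"\n--- {name} ---")
    res = cva_cvai(mesh, plane_height=30.0)
    print(f"CVA  = {res['CVA']:6.2f} mm   CVAI = {res['CVAI']:5.2f} %")
    curve = axial_radial_contour(mesh, 30.0)
    ucsq = ucsq_measures(curve)
    print(f"forehead asymmetry ratio = {ucsq['forehead_asymmetry_ratio']:.3f}"
          f"   contour AUC = {contour_curve_difference(curve):.2f} mm·rad")
    hemi = hemisphere_ratios(mesh)
    print(f"hemisphere volume ratio (L/R) = {hemi['volume_ratio']:.3f}")
    asym = vertexwise_asymmetry(mesh.vertices, mesh.pairing)
    print(f"vertex-wise asymmetry: mean {asym['mean_asymmetry']:.2f} mm, "
          f"max {asym['max_asymmetry']:.2f} mm")
    print(f"Dice mirror symmetry = {dice_asymmetry(mesh, 2.0):.1f} % "
          "(100 = perfectly symmetric)")
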