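"""LAURA distributed source localization on the three-shell sphere model.

Builds a solution grid and the analytic three-shell lead field for the
110-channel montage, then checks that noiseless single-dipole scalp maps are
localized back to their generating point by the LAURA inverse.
"""

import numpy as np

from erpfield import (
    PERIPHERAL_BELT,
    HeadModel,
    apply_exclusion,
    build_laura_operator,
    build_montage,
    build_solution_grid,
    compute_leadfield,
)

mont = apply_exclusion(build_montage(), PERIPHERAL_BELT)
grid = build_solution_grid(spacing=0.15, brain_radius=0.85)
head = HeadModel()
lead = compute_leadfield(grid, mont, head)
op = build_laura_operator(lead, grid)
print(f"solution grid: {grid.n_points} points, spacing {grid.spacing} head radii")
print(f"lead field: {lead.gain.shape[0]} points x 3 components x "
      f"{lead.gain.shape[2]} channels")
print(f"regularization lambda^2 = {op.lambda2:.2e}")

rng = np.random.default_rng(1)
errs = []
for i in rng.choice(grid.n_points, 20, replace=False):
    scalp = lead.gain[i].T @ rng.standard_normal(3)  # noiseless dipole map
    mag = np.linalg.norm(op.apply(scalp), axis=1)
    j = int(np.argmax(mag))
    errs.append(np.linalg.norm(grid.points[j] - grid.points[i]) / grid.spacing)
print(f"\nsingle-dipole localization error over 20 random sources:")
print(f"  mean {np.mean(errs):.2f} grid spacings, max {np.max(errs):.2f}")
print("The estimated current-density peak lands on or next to the true source")
print("point; distributed inverses blur but should not displace focal sources.")
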