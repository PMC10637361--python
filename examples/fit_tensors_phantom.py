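"""Fit diffusion tensors on a synthetic DWI phantom and inspect FA.

Builds a straight tensor corridor (eigenvalues 1.7/0.3/0.3 x 1e-3 mm^2/s
inside, isotropic outside), simulates single-shell signals (b = 1200,
56 directions, SNR 20), and runs the supersample -> smooth -> fit chain.
"""

import numpy as np

from tfusplan import fa_map, fit_tensors, gaussian_smooth, make_scheme
from tfusplan.phantom import PhantomSpec, make_phantom

scheme = make_scheme()
phantom = make_phantom(PhantomSpec(seed=7), scheme)   # Gaussian noise, SNR 20

smoothed = gaussian_smooth(phantom.dwi, sigma_mm=1.0)
tensors = fit_tensors(smoothed, scheme)
fa = fa_map(tensors)

inside = phantom.centerline_distance(
    phantom.truth.grid().voxel_to_world(np.argwhere(fa.data > 0.3))
)
print(f"fitted voxels:      {int(tensors.mask.sum())}")
print(f"FA on the corridor: {fa.data.max():.3f} (noise-free truth 0.799)")
print(f"high-FA voxels within the 4 mm tube: {np.mean(inside < 4.5):.1%}")

# FA peaks near the analytic value of the bundle tensor; smoothing blends
# the corridor boundary, so suprathreshold FA stays essentially inside the
# true tube.
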