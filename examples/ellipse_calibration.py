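"""Check the calibration of the 75% tolerance ellipse on simulated data.

A tolerance ellipse fitted to bivariate-normal scatter should contain about
the nominal fraction of the points; the finite-sample F radius converges to
the chi-square radius sqrt(chi2_inv(0.75; 2)) ~ 1.665 as n grows.
"""

import numpy as np

from gaitplane import ellipse_radius, fit_ellipse
from gaitplane.ellipse import mahalanobis_sq

rng = np.random.default_rng(0)
for n in (100, 1_000, 10_000):
    pts = rng.standard_normal((n, 2))
    e = fit_ellipse(pts, level=0.75)
    inside = float(np.mean(mahalanobis_sq(e, pts) <= e.r**2))
    print(f"n={n:6d}  radius r={e.r:.4f}  empirical coverage={inside:.3f} "
          f"(nominal 0.75)")

print(f"\nlarge-sample radius limit: {ellipse_radius(0.75, 10**6):.5f} "
      f"(chi-square value {ellipse_radius(0.75, 10, family='chi2'):.5f})")
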