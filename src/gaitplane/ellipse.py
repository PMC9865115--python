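"""Bivariate-normal tolerance (data) ellipses.

A tolerance ellipse at level ``p`` is the set
``{x : (x − m)ᵀ S⁻¹ (x − m) ≤ r²}`` with ``m`` the sample mean, ``S`` the
unbiased sample covariance and radius ``r = sqrt(2 · F⁻¹(p; 2, n−1))`` — the
convention of the standard R data-ellipse routine.  As n → ∞ this converges
to the chi-square radius ``sqrt(χ²⁻¹(p; 2))`` (≈1.66511 at p = 0.75).  A
chi-square radius is selectable for large-sample work.

Semi-axes come from the eigen-decomposition of S: ``a = r·sqrt(λ_max)``,
``b = r·sqrt(λ_min)``; the tilt is the major-axis angle versus +x in
(−π/2, π/2], with tilt = 0 as the deterministic tie-break for circular
scatter.  The default area convention is π·a·b over the semi-axes; the
literal full-axis product (4·π·a·b) is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

_DEGENERATE_RTOL = 1e-12


def ellipse_radius(level: float, n: int, family: str = "f") -> float:
    """Scalar Mahalanobis radius of the tolerance ellipse.

    family='f'    : r = sqrt(2·F⁻¹(level; 2, n−1))  (finite-sample default)
    family='chi2' : r = sqrt(χ²⁻¹(level; 2))         (large-sample limit)
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly inside (0, 1)")
    if family == "f":
        if n < 2:
            raise ValueError("F radius needs n >= 2")
        return float(np.sqrt(2.0 * stats.f.ppf(level, 2, n - 1)))
    if family == "chi2":
        return float(np.sqrt(stats.chi2.ppf(level, 2)))
    raise ValueError(f"unknown radius family {family!r}; expected 'f' or 'chi2'")


@dataclass(frozen=True)
class ToleranceEllipse:
    center: np.ndarray      # sample mean (2,)
    a: float                # semi-major axis length
    b: float                # semi-minor axis length
    tilt: float             # major-axis angle vs +x, radians in (−π/2, π/2]
    level: float
    n: int
    r: float                # scalar radius multiplier
    covariance: np.ndarray  # unbiased 2x2 sample covariance
    degenerate: bool = False

    def area(self, convention: str = "semi") -> float:
        """Ellipse area: 'semi' -> π·a·b (default); 'full_axis' -> 4·π·a·b."""
        if convention == "semi":
            return float(np.pi * self.a * self.b)
        if convention == "full_axis":
            return float(4.0 * np.pi * self.a * self.b)
        raise ValueError(f"unknown area convention {convention!r}")


def fit_ellipse(points: np.ndarray, level: float = 0.75,
                radius_family: str = "f") -> ToleranceEllipse:
    """Fit the tolerance ellipse of a 2D point cloud.

    Requires n >= 3.  Rank-deficient scatter (collinear points) yields a
    flagged degenerate ellipse with b = 0 rather than an exception.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not np.all(np.isfinite(pts)):
        pts = pts[np.all(np.isfinite(pts), axis=1)]
    n = pts.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points to fit an ellipse, got {n}")

    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    r = ellipse_radius(level, n, radius_family)

    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_min, lam_max = float(evals[0]), float(evals[1])
    lam_min = max(lam_min, 0.0)
    lam_max = max(lam_max, 0.0)

    degenerate = lam_min <= _DEGENERATE_RTOL * max(lam_max, 1e-300)
    circular = (lam_max - lam_min) <= 1e-12 * max(lam_max, 1e-300)
    if circular:
        tilt = 0.0  # deterministic tie-break: major axis along +x
    else:
        v = evecs[:, 1]
        tilt = float(np.arctan2(v[1], v[0]))
        if tilt <= -np.pi / 2:
            tilt += np.pi
        elif tilt > np.pi / 2:
            tilt -= np.pi
    a = r * float(np.sqrt(lam_max))
    b = 0.0 if degenerate else r * float(np.sqrt(lam_min))
    return ToleranceEllipse(center=center, a=a, b=b, tilt=tilt, level=level,
                            n=n, r=r, covariance=cov, degenerate=degenerate)


def major_axis_endpoints(e: ToleranceEllipse) -> tuple[np.ndarray, np.ndarray]:
    """The two points ``center ± a·(cos tilt, sin tilt)``.

    For a fully degenerate ellipse (a = 0) both endpoints coincide with the
    center.
    """
    u = np.array([np.cos(e.tilt), np.sin(e.tilt)])
    return e.center - e.a * u, e.center + e.a * u


def contains(e: ToleranceEllipse, p: np.ndarray) -> bool:
    """Boundary-inclusive membership test via the Mahalanobis quadratic form."""
    d = np.asarray(p, dtype=float) - e.center
    if e.degenerate:
        return bool(np.allclose(d, 0.0))
    q = float(d @ np.linalg.solve(e.covariance, d))
    return q <= e.r**2 * (1.0 + 1e-9)


def mahalanobis_sq(e: ToleranceEllipse, points: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis radius of many points (vectorized helper)."""
    d = np.asarray(points, dtype=float) - e.center
    sol = np.linalg.solve(e.covariance, d.T).T
    return np.einsum("ij,ij->i", d, sol)


def y_width(e: ToleranceEllipse) -> float:
    """Full vertical extent of the ellipse: ``2·r·sqrt(S_yy)``."""
    return float(2.0 * e.r * np.sqrt(max(e.covariance[1, 1], 0.0)))


def fit_or_none(points: np.ndarray | None, level: float,
                radius_family: str = "f", what: str = "") -> ToleranceEllipse | None:
    """Fit when possible; warn and return None on too few points."""
    if points is None or np.asarray(points).shape[0] < 3:
        warnings.warn(f"not enough points to fit ellipse{' for ' + what if what else ''}",
                      stacklevel=2)
        return None
    return fit_ellipse(points, level=level, radius_family=radius_family)
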