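"""Least-squares sphere fitting and the scanner accuracy/precision protocol.

The protocol repeatedly subsamples a scanned calibration-sphere cloud,
fits a sphere to each subsample, and summarises the fitted radii as
trueness (mean error vs the nominal radius) and precision (SD).  The
analysis cutoff is derived as |trueness| + precision rounded up to the
next 10 um step — the rule that maps the observed (10.7 um, 27.9 um)
to the 40 um cutoff used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .synthetic import SpherePointCloud

__all__ = [
    "SphereFitResult",
    "AccuracyReport",
    "fit_sphere_least_squares",
    "accuracy_protocol",
    "derive_cutoff",
]

CUTOFF_GRID_MM = 0.010


@dataclass(frozen=True)
class SphereFitResult:
    center: np.ndarray
    radius: float
    rms_residual: float
    n_points: int


@dataclass
class AccuracyReport:
    radii: np.ndarray
    true_radius: float
    n_points: int
    n_iterations: int
    seed: int

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radii))

    @property
    def trueness(self) -> float:
        """Signed mean-radius error vs the true radius (mm)."""
        return self.mean_radius - self.true_radius

    @property
    def precision(self) -> float:
        """SD of the fitted radii (mm)."""
        return float(np.std(self.radii, ddof=1)) if len(self.radii) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "true_radius_mm": self.true_radius,
            "mean_radius_mm": self.mean_radius,
            "trueness_mm": self.trueness,
            "precision_mm": self.precision,
            "n_points": self.n_points,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "radii_mm": np.asarray(self.radii).tolist(),
        }


def fit_sphere_least_squares(
    points: np.ndarray, max_refine: int = 20
) -> SphereFitResult:
    """Fit center and radius to >= 4 non-coplanar points.

    Algebraic linear least squares on |p|^2 = 2 c.p + (r^2 - |c|^2) gives
    the start; up to ``max_refine`` Gauss-Newton steps then minimise the
    geometric objective sum(|p - c| - r)^2.
    """
    p = np.asarray(points, dtype=np.float64)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValidationError("points must be (n, 3)")
    if len(p) < 4:
        raise ValidationError("need at least 4 points to fit a sphere")

    design = np.column_stack([2.0 * p, np.ones(len(p))])
    rhs = np.einsum("ij,ij->i", p, p)
    sol, _, rank, _ = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < 4:
        raise ValidationError("degenerate (coplanar) point configuration")
    center = sol[:3]
    r_sq = sol[3] + center @ center
    if r_sq <= 0.0:
        raise ValidationError("algebraic fit produced non-positive radius")
    radius = math.sqrt(r_sq)

    for _ in range(max_refine):
        diff = p - center
        dist = np.linalg.norm(diff, axis=1)
        if (dist == 0.0).any():
            break  # a point at the center: geometric Jacobian undefined
        resid = dist - radius
        jac = np.empty((len(p), 4))
        jac[:, :3] = -diff / dist[:, None]
        jac[:, 3] = -1.0
        step, *_ = np.linalg.lstsq(jac, -resid, rcond=None)
        center = center + step[:3]
        radius = radius + step[3]
        if np.linalg.norm(step) < 1e-13:
            break

    dist = np.linalg.norm(p - center, axis=1)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return SphereFitResult(center=center, radius=float(radius), rms_residual=rms, n_points=len(p))


def accuracy_protocol(
    cloud: SpherePointCloud,
    n_points: int = 100,
    n_iterations: int = 1000,
    seed: int = 0,
) -> AccuracyReport:
    """Repeated random subsampling + sphere fitting.

    Each iteration draws ``n_points`` without replacement (a fresh,
    independent draw every time) and fits a sphere; the radii list feeds
    trueness/precision.  Deterministic per seed.
    """
    if n_points < 4:
        raise ValidationError("n_points must be >= 4")
    if len(cloud) < n_points:
        raise ValidationError(
            f"cloud has {len(cloud)} points, fewer than n_points={n_points}"
        )
    rng = np.random.default_rng(seed)
    radii = np.empty(n_iterations)
    for i in range(n_iterations):
        pick = rng.choice(len(cloud), size=n_points, replace=False)
        radii[i] = fit_sphere_least_squares(cloud.points[pick]).radius
    return AccuracyReport(
        radii=radii,
        true_radius=cloud.true_radius,
        n_points=n_points,
        n_iterations=n_iterations,
        seed=seed,
    )


def derive_cutoff(report: AccuracyReport) -> float:
    """|trueness| + precision, rounded UP to the next 0.010 mm grid step.

    An exact grid value stays; zero rounds up to the first step (0.010).
    This is an interpretive reconstruction of the published rule that
    turned a 38.6 um combined error into a 40 um cutoff.
    """
    return derive_cutoff_from_values(report.trueness, report.precision)


def derive_cutoff_from_values(trueness: float, precision: float) -> float:
    combined = abs(trueness) + precision
    steps = math.ceil(combined / CUTOFF_GRID_MM - 1e-9)
    return max(steps, 1) * CUTOFF_GRID_MM
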