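"""Direct least-squares ellipse fitting and hysteresis-loop characterization.

A closed trajectory in the plane of two lagged physiological variables
(here rumen temperature on x and dry-matter intake on y) is summarized by
the general conic

    a*x^2 + b*x*y + c*y^2 + d*x + e*y + f = 0.

Coefficients are estimated by ellipse-specific least squares under the
constraint ``4ac - b^2 = 1`` (a direct, non-iterative solution of a
generalized eigenproblem, using the numerically stabilized block partition
of the scatter matrix).  The constraint guarantees an elliptical solution
whenever the data admit one.  Input points are centered and scaled to unit
variance per axis before solving and the coefficients are back-transformed,
because the two axes can differ in scale by an order of magnitude (RT spans
~1 deg C while DMI spans ~4 kg).

From the algebraic fit the module derives the geometry a physiologist
reads off the loop: center, semi-axes, rotation, the four tangency
extrema (predicted maximum/minimum of each variable and where on the other
axis they occur), the traversal direction of the time-ordered points
(clockwise = the x-variable leads), and two goodness-of-fit measures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .exceptions import (
    ContractViolationError,
    DegenerateDataError,
    InsufficientDataError,
    NonEllipticalFitError,
    ValidationError,
)

__all__ = [
    "ConicFit",
    "EllipseGeometry",
    "EllipseR2",
    "fit_conic",
    "conic_to_geometry",
    "ellipse_r2",
    "traversal_direction",
    "describe_ellipse",
    "conic_value",
]


@dataclass(frozen=True)
class ConicFit:
    """Scale-normalized conic coefficients ``(a, b, c, d, e, f)``.

    Coefficients are normalized to unit Euclidean norm with ``a + c > 0``,
    so two fits of the same curve are comparable.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    n_points: int

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e, self.f])

    @property
    def discriminant(self) -> float:
        """``b^2 - 4ac``; negative for ellipses."""
        return self.b * self.b - 4.0 * self.a * self.c

    @property
    def is_ellipse(self) -> bool:
        if self.discriminant >= 0:
            return False
        # real and non-degenerate: the translated constant must have sign
        # opposite to a (equivalently the conic contains real points)
        try:
            x0, y0 = _conic_center(self.coefficients)
        except DegenerateDataError:
            return False
        fc = conic_value(self.coefficients, x0, y0)
        return fc * self.a < 0


def conic_value(coef: Sequence[float], x, y):
    """Evaluate ``a x^2 + b x y + c y^2 + d x + e y + f``."""
    a, b, c, d, e, f = coef
    return a * x * x + b * x * y + c * y * y + d * x + e * y + f


def _normalize_coef(coef: np.ndarray) -> np.ndarray:
    coef = np.asarray(coef, float)
    nrm = np.linalg.norm(coef)
    if nrm == 0:
        raise DegenerateDataError("conic coefficients are all zero")
    coef = coef / nrm
    if coef[0] + coef[2] < 0:
        coef = -coef
    return coef


def _conic_center(coef: np.ndarray) -> tuple[float, float]:
    a, b, c, d, e, _ = coef
    m = np.array([[2 * a, b], [b, 2 * c]])
    det = 4 * a * c - b * b
    if abs(det) < 1e-300:
        raise DegenerateDataError("conic has no finite center (parabolic or degenerate)")
    x0, y0 = np.linalg.solve(m, [-d, -e])
    return float(x0), float(y0)


def _unconstrained_conic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Algebraic least-squares conic via the SVD null vector (diagnostic)."""
    design = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    _, _, vt = np.linalg.svd(design, full_matrices=False)
    return _normalize_coef(vt[-1])


def _fit_halir_flusser(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct ellipse fit under 4ac - b^2 = 1, stabilized block form.

    Works on conditioned (centered/scaled) coordinates.  Returns raw
    coefficients in those coordinates.
    """
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as err:
        raise DegenerateDataError(f"rank-deficient design (collinear points?): {err}") from err
    m = s1 + s2 @ t
    # premultiply by inv(C) for the constraint matrix C = [[0,0,2],[0,-1,0],[2,0,0]]
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m)
    # the valid solution has 4ac - b^2 > 0
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    good = np.where((cond > 0) & np.isfinite(eigval))[0]
    if good.size == 0:
        raise NonEllipticalFitError(
            "no ellipse satisfies the constrained least-squares problem",
            diagnostic=None,
        )
    # among valid vectors pick the one with the (unique) positive eigenvalue
    k = good[np.argmax(eigval[good].real)]
    a1 = np.real(eigvec[:, k])
    a2 = t @ a1
    return np.concatenate([a1, a2])


def fit_conic(points: Sequence, *, condition: bool = True) -> ConicFit:
    """Fit an ellipse-constrained conic to bivariate points.

    Parameters
    ----------
    points : (n, 2) array-like
        Observed ``(x, y)`` pairs; at least 6, not collinear, with nonzero
        variance on each axis.
    condition : bool
        Center and scale each axis to unit variance before solving, then
        back-transform the coefficients (recommended; raw RT/DMI units are
        ill-conditioned).

    Returns
    -------
    ConicFit
        Scale-normalized coefficients with ``is_ellipse`` true.

    Raises
    ------
    InsufficientDataError, DegenerateDataError, NonEllipticalFitError
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"points must be an (n, 2) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        pts = pts[np.all(np.isfinite(pts), axis=1)]
    n = len(pts)
    if n < 6:
        raise InsufficientDataError(f"conic fit needs >= 6 points, got {n}")
    x, y = pts[:, 0], pts[:, 1]
    sx_raw, sy_raw = np.std(x), np.std(y)
    if sx_raw == 0 or sy_raw == 0:
        raise DegenerateDataError("x and y must each have nonzero variance")
    if np.linalg.matrix_rank(np.column_stack([x, y, np.ones_like(x)]), tol=1e-10 * max(sx_raw, sy_raw, 1)) < 3:
        raise DegenerateDataError("points are collinear; no non-degenerate conic exists")

    if condition:
        mx, my = x.mean(), y.mean()
        sx, sy = sx_raw, sy_raw
    else:
        mx = my = 0.0
        sx = sy = 1.0
    u = (x - mx) / sx
    v = (y - my) / sy

    try:
        A, B, C, D, E, F = _fit_halir_flusser(u, v)
    except NonEllipticalFitError:
        raise NonEllipticalFitError(
            "no ellipse satisfies the constrained least-squares problem",
            diagnostic=_unconstrained_conic(x, y),
        ) from None

    # back-transform u = (x - mx)/sx, v = (y - my)/sy into raw coordinates
    a = A / sx**2
    b = B / (sx * sy)
    c = C / sy**2
    d = -2 * A * mx / sx**2 - B * my / (sx * sy) + D / sx
    e = -2 * C * my / sy**2 - B * mx / (sx * sy) + E / sy
    f = (
        A * mx**2 / sx**2
        + B * mx * my / (sx * sy)
        + C * my**2 / sy**2
        - D * mx / sx
        - E * my / sy
        + F
    )
    coef = _normalize_coef(np.array([a, b, c, d, e, f]))
    fit = ConicFit(*coef, n_points=n)
    if not fit.is_ellipse:
        raise NonEllipticalFitError(
            "constrained fit degenerated to a non-elliptical conic",
            diagnostic=_unconstrained_conic(x, y),
        )
    return fit


@dataclass(frozen=True)
class EllipseGeometry:
    """Geometric readout of a fitted ellipse, in data units.

    Tangency points are where the tangent is horizontal (``y_max_point`` /
    ``y_min_point``: the predicted extrema of y and the x at which they
    occur) or vertical (``x_max_point`` / ``x_min_point``).  ``rotation``
    is the major-axis angle in ``(-pi/2, pi/2]``.  ``direction`` is set
    from the time ordering of the fitted points when available.
    """

    center: tuple
    semi_major: float
    semi_minor: float
    rotation: float
    y_max_point: tuple
    y_min_point: tuple
    x_max_point: tuple
    x_min_point: tuple
    direction: Optional[str] = None
    r2: Optional["EllipseR2"] = None

    def point_at(self, theta):
        """Parametric point(s): center + Rot(rotation) @ (A cos, B sin)."""
        t = self.rotation
        ct, st = math.cos(t), math.sin(t)
        ax = self.semi_major * np.cos(theta)
        bx = self.semi_minor * np.sin(theta)
        return np.stack(
            [self.center[0] + ax * ct - bx * st, self.center[1] + ax * st + bx * ct],
            axis=-1,
        )

    def to_dict(self) -> dict:
        out = asdict(self)
        return out


def conic_to_geometry(fit: ConicFit, time_order: Optional[Sequence] = None) -> EllipseGeometry:
    """Derive center, axes, rotation and tangency extrema from a conic fit.

    The center solves the gradient system ``2a x0 + b y0 + d = 0``,
    ``b x0 + 2c y0 + e = 0``; semi-axes and rotation come from the
    eigen-decomposition of ``[[a, b/2], [b/2, c]]`` together with the
    translated constant.  Tangency extrema follow in closed form from the
    parametric representation.  When ``time_order`` (the chronologically
    ordered points) is given, the traversal direction is attached.
    """
    if not fit.is_ellipse:
        raise ContractViolationError("conic_to_geometry requires an elliptical fit")
    coef = fit.coefficients
    a, b, c, d, e, f = coef
    x0, y0 = _conic_center(coef)
    fc = conic_value(coef, x0, y0)
    m = np.array([[a, b / 2.0], [b / 2.0, c]])
    eigval, eigvec = np.linalg.eigh(m)
    # translated conic: lam1 X'^2 + lam2 Y'^2 = -fc; semi-axis_i = sqrt(-fc/lam_i)
    with np.errstate(invalid="raise"):
        axes = np.sqrt(-fc / eigval)
    i_maj = int(np.argmax(axes))
    semi_major = float(axes[i_maj])
    semi_minor = float(axes[1 - i_maj])
    vec = eigvec[:, i_maj]
    rotation = math.atan2(vec[1], vec[0])
    if rotation <= -math.pi / 2:
        rotation += math.pi
    elif rotation > math.pi / 2:
        rotation -= math.pi

    t = rotation
    A, B = semi_major, semi_minor
    ct, st = math.cos(t), math.sin(t)

    def _pt(theta):
        return (
            x0 + A * math.cos(theta) * ct - B * math.sin(theta) * st,
            y0 + A * math.cos(theta) * st + B * math.sin(theta) * ct,
        )

    theta_y = math.atan2(B * ct, A * st)  # maximizes y
    theta_x = math.atan2(-B * st, A * ct)  # maximizes x
    y_max_point = _pt(theta_y)
    y_min_point = _pt(theta_y + math.pi)
    x_max_point = _pt(theta_x)
    x_min_point = _pt(theta_x + math.pi)

    direction = traversal_direction(time_order) if time_order is not None else None
    return EllipseGeometry(
        center=(x0, y0),
        semi_major=semi_major,
        semi_minor=semi_minor,
        rotation=rotation,
        y_max_point=y_max_point,
        y_min_point=y_min_point,
        x_max_point=x_max_point,
        x_min_point=x_min_point,
        direction=direction,
    )


@dataclass(frozen=True)
class EllipseR2:
    """Goodness of fit under two explicit definitions.

    ``response``: responding-variable R^2 -- observed y against the nearer
    ellipse branch at each observed x (1 - SS_res/SS_tot about the mean of
    observed y).  ``sampson``: algebraic R^2 from squared Sampson distances
    normalized by the total bivariate scatter.  A bare "R^2" is never
    reported without its tag.
    """

    response: float
    sampson: float
    n: int
    undefined: bool = False


def _branch_ys(coef: np.ndarray, x: float) -> Optional[tuple[float, float]]:
    """The two y's where the vertical line at x meets the conic (lower, upper)."""
    a, b, c, d, e, f = coef
    qa = c
    qb = b * x + e
    qc = a * x * x + d * x + f
    disc = qb * qb - 4 * qa * qc
    if disc < 0:
        if disc > -1e-12 * max(qb * qb, 1.0):
            disc = 0.0
        else:
            return None
    r = math.sqrt(disc)
    y1 = (-qb - r) / (2 * qa)
    y2 = (-qb + r) / (2 * qa)
    return (min(y1, y2), max(y1, y2))


def ellipse_r2(
    points: Sequence, fit: ConicFit, geometry: Optional[EllipseGeometry] = None
) -> EllipseR2:
    """Goodness of fit of an ellipse to observed points (both definitions).

    For the responding-variable definition, each observed x inside the
    ellipse's x-extent predicts y on the nearer branch (ties go to the
    upper branch); x outside the extent contributes its residual to the
    nearest vertical-tangency point's y.
    """
    if not fit.is_ellipse:
        raise ContractViolationError("ellipse_r2 requires an elliptical fit")
    pts = np.asarray(points, float)
    if len(pts) < 6:
        raise InsufficientDataError(f"ellipse_r2 needs >= 6 points, got {len(pts)}")
    if geometry is None:
        geometry = conic_to_geometry(fit)
    coef = fit.coefficients
    x_obs, y_obs = pts[:, 0], pts[:, 1]
    x_lo, x_hi = geometry.x_min_point[0], geometry.x_max_point[0]

    ss_res = 0.0
    for xi, yi in zip(x_obs, y_obs):
        if xi < x_lo:
            pred = geometry.x_min_point[1]
        elif xi > x_hi:
            pred = geometry.x_max_point[1]
        else:
            branches = _branch_ys(coef, xi)
            if branches is None:  # numerically just outside: snap to nearest tangency
                pred = (
                    geometry.x_min_point[1]
                    if abs(xi - x_lo) < abs(xi - x_hi)
                    else geometry.x_max_point[1]
                )
            else:
                lo, hi = branches
                # nearer branch; tie -> upper branch (deterministic)
                pred = hi if abs(yi - hi) <= abs(yi - lo) else lo
        ss_res += (yi - pred) ** 2
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if ss_tot == 0.0:
        return EllipseR2(response=float("nan"), sampson=float("nan"), n=len(pts), undefined=True)
    response = 1.0 - ss_res / ss_tot

    # algebraic (Sampson) definition
    a, b, c, d, e, _ = coef
    fvals = conic_value(coef, x_obs, y_obs)
    gx = 2 * a * x_obs + b * y_obs + d
    gy = b * x_obs + 2 * c * y_obs + e
    grad2 = gx * gx + gy * gy
    sampson2 = np.where(grad2 > 0, fvals * fvals / grad2, 0.0)
    scatter = float(np.sum((x_obs - x_obs.mean()) ** 2 + (y_obs - y_obs.mean()) ** 2))
    sampson = 1.0 - float(np.sum(sampson2)) / scatter
    return EllipseR2(response=float(response), sampson=sampson, n=len(pts))


def traversal_direction(points: Sequence, rel_tol: float = 1e-9) -> str:
    """Orientation of a time-ordered closed trajectory.

    Sign of the closed shoelace sum over chronological order, in the
    plotting frame (x rightward, y upward): positive signed area is
    counterclockwise, negative is clockwise.  A signed area below
    ``rel_tol`` times the bounding-box area is ``"undetermined"``.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValidationError("traversal_direction needs >= 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    signed2 = float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    bbox = (x.max() - x.min()) * (y.max() - y.min())
    if bbox == 0 or abs(signed2) / 2.0 <= rel_tol * bbox:
        return "undetermined"
    return "counterclockwise" if signed2 > 0 else "clockwise"


def describe_ellipse(points: Sequence) -> EllipseGeometry:
    """Fit + geometry + goodness-of-fit + direction in one call.

    ``points`` must be in chronological order; the traversal direction is
    derived from that ordering.
    """
    fit = fit_conic(points)
    geom = conic_to_geometry(fit, time_order=points)
    r2 = ellipse_r2(points, fit, geom)
    return EllipseGeometry(
        center=geom.center,
        semi_major=geom.semi_major,
        semi_minor=geom.semi_minor,
        rotation=geom.rotation,
        y_max_point=geom.y_max_point,
        y_min_point=geom.y_min_point,
        x_max_point=geom.x_max_point,
        x_min_point=geom.x_min_point,
        direction=geom.direction,
        r2=r2,
    )


def fit_to_json(points: Sequence, *, x_name: str = "x", y_name: str = "y") -> str:
    """Serialize a full ellipse characterization of ``points`` as JSON."""
    fit = fit_conic(points)
    geom = conic_to_geometry(fit, time_order=points)
    r2 = ellipse_r2(points, fit, geom)
    payload = {
        "x_name": x_name,
        "y_name": y_name,
        "coefficients": dict(zip("abcdef", (float(v) for v in fit.coefficients))),
        "discriminant": fit.discriminant,
        "n_points": fit.n_points,
        "center": list(geom.center),
        "semi_major": geom.semi_major,
        "semi_minor": geom.semi_minor,
        "rotation_rad": geom.rotation,
        "y_max_point": list(geom.y_max_point),
        "y_min_point": list(geom.y_min_point),
        "x_max_point": list(geom.x_max_point),
        "x_min_point": list(geom.x_min_point),
        "direction": geom.direction,
        "r2_response": r2.response,
        "r2_sampson": r2.sampson,
    }
    return json.dumps(payload, indent=2, sort_keys=True)
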