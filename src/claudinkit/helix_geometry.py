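"""Helix-axis fitting and vertex-anchored bend angles.

The bend angle of a transmembrane helix is measured as the deviation from
collinearity between axes fitted to the two arms on either side of a
designated vertex residue (the "thenar" position, Pro134 in claudin-3): a
perfectly straight helix scores near 0°. Both arm axes are oriented N→C
before taking the arccos of their dot product, and the vertex belongs to
neither arm so it cannot bias either axis.

Axis estimation: a plain principal-component line fit to Cα positions of a
short helical arm is systematically tilted (up to ~2°) whenever the arm
does not span an integer number of helical turns — the lever arm of the
residual helical wobble couples into the first eigenvector. The fit here
therefore uses PCA only as the initial guess, refines it with a cylinder
fit (axis minimizing the variance of radial distances), and finishes with
a full helix-model least-squares fit (axis, center, radius, phase, twist,
rise). For an ideal helix the recovered axis is exact to machine
precision; under 0.3 Å coordinate noise the bend-angle error stays within
about 2° for ~15-residue arms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import CoverageError, InsufficientPointsError, ValidationError
from .structure_io import StructureModel, select_calpha

_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class HelixAxis:
    """A fitted helix axis: a point, an N→C unit direction, and fit quality."""

    centroid: np.ndarray
    direction: np.ndarray  # unit, oriented from first to last residue
    residue_range: tuple[int, int] | None
    rms_residual: float  # RMS perpendicular distance of points to the line
    n_points: int


@dataclass(frozen=True)
class BendMeasurement:
    chain_id: str
    vertex_residue: int
    proximal_range: tuple[int, int]
    distal_range: tuple[int, int]
    proximal_axis: HelixAxis
    distal_axis: HelixAxis
    angle: float  # degrees in [0, 180]


def _pca_direction(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _cylinder_refine(points: np.ndarray, d0: np.ndarray) -> np.ndarray:
    """Axis direction minimizing the variance of point-to-axis distances."""
    e1, e2 = _perp_basis(d0)
    c0 = points.mean(axis=0)

    def residuals(x):
        t1, t2, c1, c2 = x
        d = d0 + t1 * e1 + t2 * e2
        d = d / np.linalg.norm(d)
        q = points - (c0 + c1 * e1 + c2 * e2)
        perp = q - np.outer(q @ d, d)
        r = np.linalg.norm(perp, axis=1)
        return r - r.mean()

    sol = least_squares(residuals, np.zeros(4), method="lm", max_nfev=500)
    d = d0 + sol.x[0] * e1 + sol.x[1] * e2
    return d / np.linalg.norm(d)


def _helix_model_refine(points: np.ndarray, d0: np.ndarray) -> np.ndarray:
    """Full helix least-squares fit; returns the refined axis direction."""
    n = len(points)
    e1, e2 = _perp_basis(d0)
    c0 = points.mean(axis=0)
    i = np.arange(n) - (n - 1) / 2.0
    q = points - c0
    u, v = q @ e1, q @ e2
    r0 = max(float(np.sqrt(u**2 + v**2).mean()), 0.1)
    z0 = q @ d0
    h0 = float(np.polyfit(i, z0, 1)[0])
    if abs(h0) < 0.1:
        h0 = 0.1
    w0 = np.deg2rad(100.0)

    def residuals(x):
        t1, t2, c1, c2, ph, r, w, h = x
        d = d0 + t1 * e1 + t2 * e2
        d = d / np.linalg.norm(d)
        # azimuthal frame that coincides with (e1, e2) at d = d0, so the
        # initial phase guess is consistent with the model's frame
        f1 = e1 - (e1 @ d) * d
        f1 = f1 / np.linalg.norm(f1)
        f2 = np.cross(d, f1)
        c = c0 + c1 * e1 + c2 * e2
        ang = ph + w * i
        pts = (
            c[None, :]
            + r * np.cos(ang)[:, None] * f1
            + r * np.sin(ang)[:, None] * f2
            + (h * i)[:, None] * d
        )
        return (pts - points).ravel()

    best = None
    # try both twist handednesses: the apparent twist sign depends on the
    # helix chirality, and LM cannot cross between the two basins
    for w_init in (w0, -w0):
        ph0 = float(np.arctan2(v[0], u[0]) - w_init * i[0])
        try:
            sol = least_squares(
                residuals, [0, 0, 0, 0, ph0, r0, w_init, h0], method="lm", max_nfev=2000
            )
        except Exception:  # pragma: no cover - fall back to the cylinder axis
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:  # pragma: no cover
        return d0
    d = d0 + best.x[0] * e1 + best.x[1] * e2
    return d / np.linalg.norm(d)


def fit_axis(
    points: np.ndarray, residue_range: tuple[int, int] | None = None
) -> HelixAxis:
    """Fit the axis of an ordered run of Cα positions.

    The direction is oriented from the first to the last residue. Exactly
    collinear input degenerates gracefully to the line itself (residual 0).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValidationError("points must be an (n, 3) array")
    n = len(points)
    if n < 5:
        raise InsufficientPointsError(f"axis fit needs ≥ 5 points, got {n}")
    d = _pca_direction(points)
    centered = points - points.mean(axis=0)
    perp = centered - np.outer(centered @ d, d)
    pca_residual = float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
    if pca_residual > _COLLINEAR_TOL:
        d = _cylinder_refine(points, d)
        d = _helix_model_refine(points, d)
    if d @ (points[-1] - points[0]) < 0:
        d = -d
    perp = centered - np.outer(centered @ d, d)
    rms = float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
    return HelixAxis(
        centroid=points.mean(axis=0),
        direction=d,
        residue_range=residue_range,
        rms_residual=rms,
        n_points=n,
    )


def _arm_trace(
    model: StructureModel, chain: str, arm_range: tuple[int, int], label: str
):
    trace = select_calpha(model, chain, arm_range)
    width = arm_range[1] - arm_range[0] + 1
    if len(trace) < max(5, int(np.ceil(0.8 * width))):
        raise CoverageError(
            f"{label} arm {arm_range} on chain {chain}: only {len(trace)}/{width} "
            f"residues have a Cα (missing {trace.missing})",
            missing=trace.missing,
        )
    return trace


def bend_angle(
    model: StructureModel,
    chain: str,
    proximal_range: tuple[int, int],
    vertex_residue: int,
    distal_range: tuple[int, int],
) -> BendMeasurement:
    """Vertex-anchored bend angle between two helix arms of one chain.

    ``angle`` is the unsigned deviation from collinearity (degrees) between
    the N→C arm axes; the vertex must lie strictly between the arms and in
    neither of them.
    """
    if proximal_range[0] > proximal_range[1] or distal_range[0] > distal_range[1]:
        raise ValidationError("arm ranges must be nonempty intervals")
    if not proximal_range[1] < vertex_residue < distal_range[0]:
        raise ValidationError(
            f"vertex {vertex_residue} must lie strictly between the proximal arm "
            f"{proximal_range} and the distal arm {distal_range}"
        )
    prox = _arm_trace(model, chain, proximal_range, "proximal")
    dist = _arm_trace(model, chain, distal_range, "distal")
    ax_p = fit_axis(prox.coords, proximal_range)
    ax_d = fit_axis(dist.coords, distal_range)
    cosang = float(np.clip(ax_p.direction @ ax_d.direction, -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    return BendMeasurement(
        chain_id=chain,
        vertex_residue=vertex_residue,
        proximal_range=proximal_range,
        distal_range=distal_range,
        proximal_axis=ax_p,
        distal_axis=ax_d,
        angle=angle,
    )


@dataclass(frozen=True)
class MeanBendResult:
    per_chain: dict[str, BendMeasurement]
    mean_angle: float


def mean_bend(
    model: StructureModel,
    chains: Sequence[str],
    proximal_range: tuple[int, int],
    vertex_residue: int,
    distal_range: tuple[int, int],
) -> MeanBendResult:
    """Arithmetic mean of per-chain bend angles over the measurable chains.

    Raises an aggregate error if every chain fails coverage.
    """
    per_chain: dict[str, BendMeasurement] = {}
    failures: list[str] = []
    for chain in chains:
        try:
            per_chain[chain] = bend_angle(
                model, chain, proximal_range, vertex_residue, distal_range
            )
        except CoverageError as exc:
            failures.append(f"{chain}: {exc}")
    if not per_chain:
        raise CoverageError(
            "no chain measurable: " + "; ".join(failures) if failures else "no chains given"
        )
    mean_angle = float(np.mean([m.angle for m in per_chain.values()]))
    return MeanBendResult(per_chain=per_chain, mean_angle=mean_angle)


def bend_difference(measurement_a, measurement_b) -> float:
    """Signed angle difference a − b in degrees.

    Accepts degrees, :class:`BendMeasurement` or :class:`MeanBendResult`.
    Convention: pass the proline-type (bent) measurement first, so a
    positive value means the first helix is more bent.
    """
    return _as_degrees(measurement_a) - _as_degrees(measurement_b)


def _as_degrees(value) -> float:
    if isinstance(value, BendMeasurement):
        return value.angle
    if isinstance(value, MeanBendResult):
        return value.mean_angle
    return float(value)
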