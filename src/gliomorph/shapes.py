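"""Star-shaped nucleus outlines with analytic ground truth.

Simulated nuclei are radial-Fourier perturbed ellipses: the radius at
polar angle theta is ``r(theta) = s(theta) * (1 + sum_k a_k cos(k*theta +
phi_k))`` for harmonics k = 2..6, where ``s`` is the ellipse radius for
the requested aspect ratio and the total harmonic amplitude equals the
``irregularity`` parameter.  Restricting the total amplitude below 0.5
keeps the radius positive, so every outline is star-shaped and therefore
simple (non-self-intersecting).  Pleomorphic tumour nuclei are emulated
by larger irregularity and aspect-ratio spread.

All ground-truth quantities (area, perimeter, moment-equivalent axes,
roundness) are computed analytically from the polygon itself, so the
rasterized measurements can be validated against an exact twin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import InvalidParameterError

__all__ = [
    "GroundTruthNucleus",
    "generate_nucleus_polygon",
    "shoelace_area",
    "polygon_perimeter",
    "polygon_moment_axes",
]

#: Boundary harmonics used for the shape perturbation (2..6 keeps outlines
#: star-convex; harmonic 1 would merely translate the centroid).
_HARMONICS = np.arange(2, 7)


@dataclass
class GroundTruthNucleus:
    """One simulated nucleus: outline plus exact shape parameters.

    ``boundary`` is an (n, 2) array of (x, y) vertices in microns, open
    (the closing edge from last to first vertex is implicit).  The
    ``true_*`` fields are analytic values computed from the polygon:
    shoelace area, polyline perimeter, moment-equivalent ellipse axes and
    the roundness shape factor 4*pi*A/P^2 * 100.
    """

    sample_id: str
    field_id: int
    label_id: int
    centroid: tuple[float, float]
    boundary: np.ndarray = field(repr=False)
    true_area_um2: float
    true_perimeter_um: float
    true_majx_um: float
    true_minx_um: float
    true_nr: float

    def translated(self, dx: float, dy: float) -> "GroundTruthNucleus":
        """Rigid translation; all shape truths are invariant."""
        b = self.boundary + np.array([dx, dy])
        cx, cy = self.centroid
        return replace(self, boundary=b, centroid=(cx + dx, cy + dy))

    def rotated(self, angle_rad: float) -> "GroundTruthNucleus":
        """Rotation about the centroid; all shape truths are invariant."""
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        rot = np.array([[c, -s], [s, c]])
        ctr = np.asarray(self.centroid)
        b = (self.boundary - ctr) @ rot.T + ctr
        return replace(self, boundary=b)


def shoelace_area(boundary: np.ndarray) -> float:
    """Unsigned shoelace (Gauss) area of a simple polygon."""
    x, y = boundary[:, 0], boundary[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def polygon_perimeter(boundary: np.ndarray) -> float:
    """Closed polyline length of the polygon boundary."""
    d = np.diff(np.vstack([boundary, boundary[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def polygon_moment_axes(boundary: np.ndarray) -> tuple[float, float]:
    """Major/minor axis lengths of the moment-equivalent ellipse.

    Second central area moments of the polygon are evaluated exactly with
    the shoelace-type formulas (Green's theorem); the axes are
    ``4 * sqrt(eigenvalues)`` of the normalized covariance matrix, the
    same definition used for pixel regions, so for an ellipse outline
    they equal the true axis lengths.
    """
    x, y = boundary[:, 0], boundary[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a_signed = 0.5 * cross.sum()
    if a_signed == 0:
        raise InvalidParameterError("degenerate polygon (zero area)")
    cx = ((x + x1) * cross).sum() / (6.0 * a_signed)
    cy = ((y + y1) * cross).sum() / (6.0 * a_signed)
    # raw second moments about the origin
    sxx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    syy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    sxy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    var_x = sxx / a_signed - cx * cx
    var_y = syy / a_signed - cy * cy
    cov = sxy / a_signed - cx * cy
    eigs = np.linalg.eigvalsh(np.array([[var_x, cov], [cov, var_y]]))
    eigs = np.clip(eigs, 0.0, None)
    minor, major = 4.0 * np.sqrt(eigs)
    return float(major), float(minor)


def _ellipse_radius(theta: np.ndarray, aspect_ratio: float) -> np.ndarray:
    # unit-area-free ellipse radius with semi-axes (aspect_ratio, 1)
    a, b = aspect_ratio, 1.0
    return a * b / np.hypot(b * np.cos(theta), a * np.sin(theta))


def generate_nucleus_polygon(
    target_area: float,
    aspect_ratio: float,
    irregularity: float,
    rng: np.random.Generator,
    n_vertices: int = 96,
) -> GroundTruthNucleus:
    """Generate one nucleus outline with exact ground truth.

    Parameters
    ----------
    target_area
        Enclosed (shoelace) area in µm²; matched to <0.1% by rescaling.
    aspect_ratio
        Major/minor axis ratio of the underlying ellipse, >= 1.
    irregularity
        Total amplitude of the boundary harmonics, in [0, 0.5).  0 gives
        a pure ellipse (a circle when ``aspect_ratio`` is 1).
    rng
        Seeded :class:`numpy.random.Generator`; consumed for harmonic
        amplitudes and phases.
    n_vertices
        Polygon resolution (>= 64).

    The returned nucleus is centred on its centroid at the origin with
    its major axis along x; placement code translates/rotates it.
    """
    if target_area <= 0:
        raise InvalidParameterError("target_area must be > 0")
    if aspect_ratio < 1:
        raise InvalidParameterError("aspect_ratio must be >= 1")
    if not 0 <= irregularity < 0.5:
        raise InvalidParameterError("irregularity must lie in [0, 0.5)")
    if n_vertices < 64:
        raise InvalidParameterError("n_vertices must be >= 64")

    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = _ellipse_radius(theta, aspect_ratio)
    if irregularity > 0:
        weights = rng.dirichlet(np.ones(_HARMONICS.size))
        amplitudes = irregularity * weights
        phases = rng.uniform(0.0, 2.0 * np.pi, _HARMONICS.size)
        pert = np.sum(
            amplitudes[:, None] * np.cos(_HARMONICS[:, None] * theta[None, :]
                                         + phases[:, None]),
            axis=0,
        )
        r = r * (1.0 + pert)
    boundary = np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    boundary *= np.sqrt(target_area / shoelace_area(boundary))
    # centre exactly on the area centroid
    x, y = boundary[:, 0], boundary[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a_signed = 0.5 * cross.sum()
    cx = ((x + x1) * cross).sum() / (6.0 * a_signed)
    cy = ((y + y1) * cross).sum() / (6.0 * a_signed)
    boundary -= [cx, cy]

    area = shoelace_area(boundary)
    perim = polygon_perimeter(boundary)
    major, minor = polygon_moment_axes(boundary)
    return GroundTruthNucleus(
        sample_id="",
        field_id=-1,
        label_id=-1,
        centroid=(0.0, 0.0),
        boundary=boundary,
        true_area_um2=float(area),
        true_perimeter_um=float(perim),
        true_majx_um=major,
        true_minx_um=minor,
        true_nr=float(4.0 * np.pi * area / perim**2 * 100.0),
    )
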