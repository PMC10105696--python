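"""Centroid size, ordinary and generalized Procrustes analysis, and sliding.

Configurations are superimposed by translating each to a common centroid,
scaling to unit centroid size, and rotating to minimise the summed squared
distances to an iteratively re-estimated consensus.  Reflections are never
allowed: teeth are chiral, and a right tooth must be mirrored explicitly
before analysis.  When a :class:`~molargm.bending.SlidingSpec` is supplied,
semilandmarks slide against the current consensus by the bending-energy
criterion between alignment passes.

The consensus orientation is fixed deterministically (principal axis along x,
sign by third moments), so the result is invariant to specimen input order and
to similarity transforms pre-applied to any specimen.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bending import BendingEnergyModel, SlidingSpec, slide_semilandmarks
from .errors import DegenerateConfigurationError, ValidationError
from .io import LandmarkConfiguration, MorphometricDataset

logger = logging.getLogger("molargm")


def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared distances of all points to their centroid."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValidationError("centroid size needs at least 2 points")
    if not np.isfinite(pts).all():
        raise ValidationError("non-finite coordinates")
    centred = pts - pts.mean(0)
    cs = float(np.sqrt((centred ** 2).sum()))
    if cs <= 1e-12 * (1.0 + np.abs(pts).max()):
        raise DegenerateConfigurationError("all points coincide: centroid size is zero")
    return cs


def normalize_shape(points: np.ndarray) -> np.ndarray:
    """Centre at the origin and scale to unit centroid size."""
    pts = np.asarray(points, dtype=float)
    return (pts - pts.mean(0)) / centroid_size(pts)


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (2x2, det +1) minimising ||source @ R - target||_F.

    Both inputs are assumed centred.  Reflections are excluded.
    """
    m = source.T @ target
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def opa_align(points: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Ordinary Procrustes alignment of one configuration onto a reference.

    Centre, scale to unit centroid size, rotate (no reflection) onto the
    centred reference.
    """
    ref = np.asarray(reference, dtype=float)
    refc = ref - ref.mean(0)
    shape = normalize_shape(points)
    return shape @ optimal_rotation(shape, refc)


def procrustes_distance(shape_a: np.ndarray, shape_b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Zero iff the configurations are similarity-equivalent (reflections
    excluded); symmetric in its arguments.
    """
    a = normalize_shape(shape_a)
    b = normalize_shape(shape_b)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a @ optimal_rotation(a, b) - b))


def canonical_orientation(shape: np.ndarray) -> np.ndarray:
    """Deterministic rotation fixing the global orientation of a centred shape.

    Principal axis to x, with signs chosen by the third central moments so the
    result is unique for any shape without special symmetry.
    """
    s = np.asarray(shape, dtype=float)
    s = s - s.mean(0)
    _, _, vt = np.linalg.svd(s, full_matrices=False)
    r = vt.T
    if np.linalg.det(r) < 0:
        r = r @ np.diag([1.0, -1.0])
    rot = s @ r
    # resolve the residual 180-degree ambiguity
    mx, my = (rot ** 3).sum(0)
    flip = None
    if abs(mx) > 1e-9:
        flip = mx < 0
    elif abs(my) > 1e-9:
        flip = my < 0
    else:  # fall back to the first point's coordinates
        flip = rot[0, 0] < 0 or (rot[0, 0] == 0 and rot[0, 1] < 0)
    if flip:
        r = r @ np.diag([-1.0, -1.0])
    return r


@dataclass
class AlignedSample:
    """Procrustes-aligned shapes with sizes and consensus from GPA."""

    shapes: np.ndarray                  # (n, K, 2) aligned coordinates
    centroid_sizes: np.ndarray          # (n,) original centroid sizes
    consensus: np.ndarray               # (K, 2) mean shape
    n_iterations: int
    final_change: float
    converged: bool = True
    specimen_ids: list[str] | None = None
    roles: np.ndarray | None = None
    segment_index: np.ndarray | None = None
    slid: bool = False

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1]

    def flattened(self) -> np.ndarray:
        """Shapes as an (n, 2K) matrix, x coordinates first."""
        return np.concatenate([self.shapes[:, :, 0], self.shapes[:, :, 1]], axis=1)

    def tangent_coordinates(self) -> np.ndarray:
        """Orthogonal projection of the flattened shapes onto the tangent space
        at the consensus (standard small-variation treatment)."""
        return tangent_project(self.flattened(), self.consensus)


def tangent_project(flat_coords: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Project flattened shape rows orthogonally onto the tangent space at the
    consensus: the component along the consensus direction beyond the consensus
    itself is removed."""
    flat = np.atleast_2d(np.asarray(flat_coords, dtype=float))
    vec = np.concatenate([consensus[:, 0], consensus[:, 1]])
    norm = np.linalg.norm(vec)
    t = vec / norm
    return flat - np.outer(flat @ t - norm, t)


def _as_point_stack(
    data: MorphometricDataset | Sequence[LandmarkConfiguration] | np.ndarray,
) -> tuple[np.ndarray, list[str] | None, np.ndarray | None, np.ndarray | None]:
    if isinstance(data, MorphometricDataset):
        configs = data.configurations
    elif isinstance(data, np.ndarray):
        arr = np.asarray(data, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise ValidationError(f"expected (n, K, 2) array, got {arr.shape}")
        return arr, None, None, None
    else:
        configs = list(data)
    if len(configs) < 2:
        raise ValidationError("GPA needs at least two configurations")
    ks = {c.k for c in configs}
    if len(ks) != 1:
        raise ValidationError(f"heterogeneous landmark counts: {sorted(ks)}")
    ids = [c.specimen_id for c in configs]
    roles = configs[0].roles
    seg = configs[0].segment_index
    return np.stack([c.points for c in configs]), ids, roles, seg


def gpa(
    data: MorphometricDataset | Sequence[LandmarkConfiguration] | np.ndarray,
    sliding: SlidingSpec | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> AlignedSample:
    """Generalized Procrustes Analysis, optionally with semilandmark sliding.

    Iterates (align every configuration to the consensus, re-estimate the
    consensus) until the RMS consensus displacement falls below ``tol``.  With
    ``sliding``, converged alignment rounds alternate with a joint
    bending-energy slide of all semilandmarks against the current consensus,
    for at most ``sliding.max_outer_iterations`` rounds.
    """
    points, ids, roles, seg = _as_point_stack(data)
    n, k, _ = points.shape

    sizes = np.empty(n)
    shapes = np.empty_like(points)
    for i in range(n):
        try:
            sizes[i] = centroid_size(points[i])
        except DegenerateConfigurationError as exc:
            name = ids[i] if ids else str(i)
            raise DegenerateConfigurationError(f"specimen {name!r}: {exc}") from exc
        shapes[i] = (points[i] - points[i].mean(0)) / sizes[i]

    semi_mask = None
    if sliding is not None:
        if roles is None:
            raise ValidationError("sliding requested but configurations carry no roles")
        semi_mask = roles == "semi"

    def _converge(shapes: np.ndarray, consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, float]:
        change = np.inf
        it = 0
        for it in range(1, max_iter + 1):
            for i in range(n):
                shapes[i] = shapes[i] @ optimal_rotation(shapes[i], consensus)
            new_consensus = normalize_shape(shapes.mean(0))
            change = float(np.sqrt(((new_consensus - consensus) ** 2).mean()))
            consensus = new_consensus
            if change < tol:
                break
        return shapes, consensus, it, change

    consensus = normalize_shape(shapes[0])
    total_iter = 0
    shapes, consensus, it, change = _converge(shapes, consensus)
    total_iter += it

    if sliding is not None:
        for outer in range(sliding.max_outer_iterations):
            model = BendingEnergyModel.from_reference(consensus)
            for i in range(n):
                slid = slide_semilandmarks(shapes[i], model, sliding, semi_mask=semi_mask)
                shapes[i] = normalize_shape(slid)
            prev = consensus
            shapes, consensus, it, change = _converge(shapes, consensus)
            total_iter += it
            slide_change = float(np.sqrt(((consensus - prev) ** 2).mean()))
            if slide_change < sliding.tolerance:
                break

    converged = change < tol
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3g})",
            stacklevel=2,
        )

    # fix global orientation so the result is order- and input-frame-invariant,
    # then re-rotate every shape onto the final consensus so the aligned
    # coordinates are a deterministic function of it (not of the iteration path)
    r = canonical_orientation(consensus)
    consensus = consensus @ r
    shapes = shapes @ r
    for i in range(n):
        shapes[i] = shapes[i] @ optimal_rotation(shapes[i], consensus)
    consensus = shapes.mean(0)

    return AlignedSample(
        shapes=shapes,
        centroid_sizes=sizes,
        consensus=consensus,
        n_iterations=total_iter,
        final_change=change,
        converged=converged,
        specimen_ids=ids,
        roles=roles,
        segment_index=seg,
        slid=sliding is not None,
    )


def resample_equidistant(polyline: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline into ``n`` points equally spaced by arc length.

    Endpoints are preserved exactly; intermediate points lie on the polyline.
    """
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2:
        raise ValidationError("polyline needs at least 2 points")
    if n < 2:
        raise ValidationError("n must be >= 2")
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise DegenerateConfigurationError("zero-length polyline")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n)
    out = np.column_stack(
        [np.interp(targets, cum, poly[:, 0]), np.interp(targets, cum, poly[:, 1])]
    )
    out[0], out[-1] = poly[0], poly[-1]
    return out
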