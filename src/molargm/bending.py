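"""Thin-plate spline bending energy and semilandmark sliding.

The thin-plate spline (TPS) interpolates the deformation of a reference
configuration into a target.  Its bending energy — the integral of squared
second derivatives of the interpolant — is a quadratic form ``d' B d`` in the
displacements ``d``, where the bending-energy matrix ``B`` depends only on the
reference.  ``B`` annihilates affine displacement fields, so the energy
measures purely non-affine (localised) deformation.

Semilandmarks carry no point-wise homology along the outline, so during
superimposition each one is allowed to slide along its local tangent direction
to minimise the bending energy of the TPS relating the specimen to the
reference.  All sliding amplitudes are solved jointly in one linear system
(Gower/Bookstein formulation), not greedily per point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateConfigurationError, ValidationError
from .io import LandmarkConfiguration


def tps_kernel(r2: np.ndarray) -> np.ndarray:
    """2D TPS radial kernel U(r) = r^2 log r^2, with U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bending-energy matrix of the TPS anchored on ``reference`` (K x 2).

    Returns the K x K upper-left block of the inverse of the bordered TPS
    system ``[[K, P], [P', 0]]`` with ``P = [1, x, y]``.  Symmetric, positive
    semi-definite, and zero on affine displacement fields.
    """
    ref = np.asarray(reference, dtype=float)
    k = ref.shape[0]
    if k < 4:
        raise ValidationError("bending energy needs at least 4 reference points")
    diff = ref[:, None, :] - ref[None, :, :]
    r2 = (diff ** 2).sum(-1)
    if (r2 + np.eye(k) <= 0).any():
        raise DegenerateConfigurationError("coincident reference points: TPS kernel singular")
    kmat = tps_kernel(r2)
    p = np.column_stack([np.ones(k), ref])
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = kmat
    lmat[:k, k:] = p
    lmat[k:, :k] = p.T
    try:
        linv = np.linalg.inv(lmat)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConfigurationError(f"singular TPS system: {exc}") from exc
    b = linv[:k, :k]
    return (b + b.T) / 2.0


@dataclass
class BendingEnergyModel:
    """A reference shape together with its bending-energy quadratic form."""

    reference: np.ndarray
    energy_matrix: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        if self.energy_matrix is None:
            self.energy_matrix = bending_energy_matrix(self.reference)

    @classmethod
    def from_reference(cls, reference: np.ndarray) -> "BendingEnergyModel":
        return cls(reference=reference)


def bending_energy(model: BendingEnergyModel, target: np.ndarray) -> float:
    """Bending energy of the TPS deforming the model reference into ``target``."""
    target = np.asarray(target, dtype=float)
    if target.shape != model.reference.shape:
        raise ValidationError(
            f"target shape {target.shape} != reference {model.reference.shape}"
        )
    d = target - model.reference
    b = model.energy_matrix
    return float(d[:, 0] @ b @ d[:, 0] + d[:, 1] @ b @ d[:, 1])


@dataclass
class SlidingSpec:
    """How semilandmarks slide during superimposition.

    ``tangent_mode='chord'`` estimates each semilandmark's tangent as the chord
    through its two outline neighbours (fixed landmarks included); the points
    are then displaced along those straight tangents (pure linearised sliding).
    ``'projected_curve'`` additionally re-projects the slid points onto the
    specimen's own piecewise-linear outline.
    """

    max_outer_iterations: int = 5
    tolerance: float = 1e-6
    tangent_mode: str = "chord"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be > 0")
        if self.tangent_mode not in ("chord", "projected_curve"):
            raise ValidationError(f"unknown tangent_mode {self.tangent_mode!r}")


def outline_tangents(points: np.ndarray, semi_indices: np.ndarray) -> np.ndarray:
    """Unit chord tangents at the given points of a closed outline."""
    k = points.shape[0]
    tangents = np.empty((semi_indices.size, 2))
    for row, j in enumerate(semi_indices):
        chord = points[(j + 1) % k] - points[(j - 1) % k]
        norm = np.hypot(*chord)
        if norm <= 1e-12:
            raise DegenerateConfigurationError(
                f"zero-length tangent at point {j}: coincident neighbours"
            )
        tangents[row] = chord / norm
    return tangents


def _project_to_polyline(point: np.ndarray, poly: np.ndarray) -> np.ndarray:
    seg = poly[1:] - poly[:-1]
    rel = point - poly[:-1]
    denom = (seg ** 2).sum(-1)
    t = np.clip(np.where(denom > 0, (rel * seg).sum(-1) / np.where(denom > 0, denom, 1.0), 0.0), 0, 1)
    candidates = poly[:-1] + t[:, None] * seg
    d2 = ((candidates - point) ** 2).sum(-1)
    return candidates[np.argmin(d2)]


def slide_semilandmarks(
    config: LandmarkConfiguration | np.ndarray,
    reference: BendingEnergyModel | np.ndarray,
    spec: SlidingSpec | None = None,
    semi_mask: np.ndarray | None = None,
) -> LandmarkConfiguration | np.ndarray:
    """Slide semilandmarks along their tangents to minimise bending energy.

    Fixed landmarks never move.  The sliding amplitudes of all semilandmarks
    are the joint minimiser of the bending energy of the displaced
    configuration relative to the reference, so the energy never increases.
    Returns the same type as ``config``.
    """
    spec = spec or SlidingSpec()
    if isinstance(config, LandmarkConfiguration):
        points = config.points
        mask = config.semi_mask
    else:
        points = np.asarray(config, dtype=float)
        if semi_mask is None:
            raise ValidationError("semi_mask required when config is a bare array")
        mask = np.asarray(semi_mask, dtype=bool)
    if not isinstance(reference, BendingEnergyModel):
        reference = BendingEnergyModel.from_reference(reference)
    if not mask.any():
        return config

    semi_idx = np.flatnonzero(mask)
    tangents = outline_tangents(points, semi_idx)
    b = reference.energy_matrix
    d0 = points - reference.reference  # K x 2
    # quadratic form over sliding amplitudes lam (m,):
    #   E(lam) = sum_c (d0_c + Ux_c lam)' B (d0_c + U_c lam)
    ux = np.zeros((points.shape[0], semi_idx.size))
    uy = np.zeros_like(ux)
    ux[semi_idx, np.arange(semi_idx.size)] = tangents[:, 0]
    uy[semi_idx, np.arange(semi_idx.size)] = tangents[:, 1]
    w = ux.T @ b @ ux + uy.T @ b @ uy
    rhs = -(ux.T @ b @ d0[:, 0] + uy.T @ b @ d0[:, 1])
    lam, *_ = np.linalg.lstsq(w, rhs, rcond=None)
    slid = points.copy()
    slid[semi_idx, 0] += lam * tangents[:, 0]
    slid[semi_idx, 1] += lam * tangents[:, 1]
    if spec.tangent_mode == "projected_curve":
        closed = np.vstack([points, points[:1]])
        for j in semi_idx:
            slid[j] = _project_to_polyline(slid[j], closed)
    if isinstance(config, LandmarkConfiguration):
        return config.with_points(slid)
    return slid
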