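"""Synthetic molar-outline datasets with known, recoverable structure.

The generator emulates the statistical structure the analysis pipeline
assumes in real reindeer molars: two subspecies separated by a mean-shape
offset, a dominant wear deformation with centroid size increasing across wear
classes, weak sex effects, population-level size differences, optional
allometry, and isotropic digitising noise — all planted on a bilobed
molar-like closed outline carrying 9 fixed landmarks at curvature extrema and
66 equidistantly resampled sliding semilandmarks.

Planted shape-effect vectors live in the template's tangent space and are
orthogonalised against the affine displacement fields of the template, so no
planted effect can be absorbed by superimposition — parameter-recovery tests
stay honest.  Every specimen receives a random rotation and translation (and
its own centroid size), so the superimposition machinery is genuinely
exercised.  A fixed seed fixes the complete dataset, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (LandmarkConfiguration, MorphometricDataset, default_role_layout)
from .superimposition import centroid_size, resample_equidistant


# ---------------------------------------------------------------------------
# Template outline
# ---------------------------------------------------------------------------

def _outline(theta: np.ndarray, phases: tuple[float, float]) -> np.ndarray:
    """Star-shaped bilobed outline: two lobes with mild higher harmonics.

    Harmonic amplitudes keep r > 0.6 everywhere, so the curve never
    self-intersects.
    """
    r = (1.0
         + 0.28 * np.cos(2 * theta)
         + 0.06 * np.cos(3 * theta + phases[0])
         + 0.03 * np.cos(4 * theta + phases[1]))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _curvature(theta: np.ndarray, pts: np.ndarray) -> np.ndarray:
    dx = np.gradient(pts[:, 0], theta)
    dy = np.gradient(pts[:, 1], theta)
    ddx = np.gradient(dx, theta)
    ddy = np.gradient(dy, theta)
    return np.abs(dx * ddy - dy * ddx) / np.maximum((dx * dx + dy * dy) ** 1.5, 1e-12)


def make_template(
    n_fixed: int = 9, n_semi: int = 66, seed: int | None = 0
) -> LandmarkConfiguration:
    """Build the synthetic landmarking template.

    Fixed landmarks sit at the strongest curvature extrema of the outline
    (mimicking landmarks at curvature extrema of the enamel-dentine junction);
    the semilandmarks are spread across the inter-landmark segments (as equal
    as possible, remainder to the longest segments) and resampled to equal
    arc-length spacing.  Deterministic for a given seed; centred with unit
    centroid size.
    """
    if n_fixed < 3:
        raise ValidationError("need at least 3 fixed landmarks for a closed outline")
    rng = np.random.default_rng(seed)
    phases = tuple(rng.uniform(-0.4, 0.4, size=2))
    dense_n = 4000
    theta = np.linspace(0.0, 2 * np.pi, dense_n, endpoint=False)
    dense = _outline(theta, phases)
    curv = _curvature(theta, dense)

    # local curvature maxima, strongest first, enforcing angular separation
    is_max = (curv > np.roll(curv, 1)) & (curv >= np.roll(curv, -1))
    candidates = np.flatnonzero(is_max)[np.argsort(curv[np.flatnonzero(is_max)])[::-1]]
    min_sep = dense_n // (3 * n_fixed)
    chosen: list[int] = []
    for c in candidates:
        if all(min(abs(c - o), dense_n - abs(c - o)) >= min_sep for o in chosen):
            chosen.append(int(c))
        if len(chosen) == n_fixed:
            break
    while len(chosen) < n_fixed:  # symmetric outlines may have too few extrema
        filler = (chosen[-1] + dense_n // n_fixed) % dense_n if chosen else 0
        if filler not in chosen:
            chosen.append(filler)
    chosen = sorted(chosen)

    seg_arcs = []
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    for s in range(n_fixed):
        i0, i1 = chosen[s], chosen[(s + 1) % n_fixed]
        length = arc[i1] - arc[i0] if i1 > i0 else arc[-1] + np.linalg.norm(
            dense[0] - dense[-1]) - arc[i0] + arc[i1]
        seg_arcs.append(length)
    roles, seg_index = default_role_layout(n_fixed, n_semi, segment_lengths=seg_arcs)
    alloc = [int((seg_index == s).sum()) for s in range(n_fixed)]

    pts: list[np.ndarray] = []
    for s in range(n_fixed):
        i0, i1 = chosen[s], chosen[(s + 1) % n_fixed]
        if i1 > i0:
            segment = dense[i0: i1 + 1]
        else:
            segment = np.vstack([dense[i0:], dense[: i1 + 1]])
        pts.append(dense[i0])
        if alloc[s]:
            resampled = resample_equidistant(segment, alloc[s] + 2)
            pts.extend(resampled[1:-1])
    points = np.asarray(pts)
    points = points - points.mean(0)
    points = points / centroid_size(points)
    return LandmarkConfiguration(
        specimen_id="template", points=points, roles=roles, segment_index=seg_index
    )


# ---------------------------------------------------------------------------
# Effect vectors
# ---------------------------------------------------------------------------

def _affine_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of affine displacement fields, flattened (x..., y...)."""
    k = template.shape[0]
    x, y = template[:, 0], template[:, 1]
    zero = np.zeros(k)
    one = np.ones(k)
    fields = np.column_stack([
        np.concatenate([one, zero]), np.concatenate([zero, one]),
        np.concatenate([x, zero]), np.concatenate([zero, x]),
        np.concatenate([y, zero]), np.concatenate([zero, y]),
    ])
    q, _ = np.linalg.qr(fields)
    return q


def effect_vector(
    rng: np.random.Generator, template: np.ndarray, magnitude: float = 1.0
) -> np.ndarray:
    """Random unit shape-effect vector orthogonal to the template's affine
    displacement fields, scaled to ``magnitude`` (Procrustes units)."""
    k = template.shape[0]
    q = _affine_basis(template)
    v = rng.standard_normal(2 * k)
    v -= q @ (q.T @ v)
    v /= np.linalg.norm(v)
    return magnitude * v


def _unflatten(v: np.ndarray) -> np.ndarray:
    k = v.size // 2
    return np.column_stack([v[:k], v[k:]])


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """One simulated population: taxonomy plus size and shape offsets."""

    subspecies: str
    status: str
    base_size: float              # mean centroid size in mm
    offset_magnitude: float = 0.0  # Procrustes units
    population: str | None = None


@dataclass
class SimulationDesign:
    """Full specification of a synthetic dataset.

    Defaults (see :func:`default_design`) emulate the study conditions: wear
    dominates shape variation, the two subspecies separate but overlap, forest
    reindeer are larger, sex effects are negligible, and centroid size
    increases with wear.
    """

    template: LandmarkConfiguration
    groups: Mapping[str, GroupSpec]
    wear_classes: Sequence[int] = (1, 2, 3)
    wear_magnitude_per_class: float = 0.08   # Procrustes units per wear class
    size_wear_factors: Mapping[int, float] = field(
        default_factory=lambda: {0: 1.0, 1: 1.03, 2: 1.06, 3: 1.09, 4: 1.12}
    )
    sexes: Sequence[str] = ("F", "M")
    sex_size_factor: float = 1.03            # male multiplicative size factor
    sex_shape_magnitude: float = 0.005
    allometry_magnitude: float = 0.0         # shape units per unit log size
    noise_sd: float = 0.005                  # isotropic digitising noise (Procrustes units)
    within_group_sd: float = 0.0             # biological overlap along the group axis
    biological_modes: int = 0                # concentrated within-group shape modes
    biological_sd: float = 0.0               # sd per biological mode
    size_cv: float = 0.04                    # log-normal individual size scatter
    n_per_cell: int = 10                     # per (group, wear class, sex)
    tooth: str = "m1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.wear_magnitude_per_class < 0 or self.sex_shape_magnitude < 0:
            raise ValidationError("effect magnitudes must be nonnegative")
        if self.n_per_cell < 1:
            raise ValidationError("empty cells: n_per_cell must be >= 1")
        factors = [self.size_wear_factors[c] for c in sorted(self.size_wear_factors)]
        if any(b < a for a, b in zip(factors, factors[1:])):
            raise ValidationError("size_wear_factors must be non-decreasing with wear")


def default_design(seed: int = 0, n_per_cell: int = 10) -> SimulationDesign:
    """Study-condition defaults: three populations of the two subspecies.

    Forest reindeer are larger than mountain reindeer, and domestic mountain
    reindeer slightly smaller than wild ones; the subspecies mean-shape offset
    over the within-group scatter gives a planted Mahalanobis separation near
    2, i.e. ~84% expected two-group assignment accuracy; wear dominates shape
    variation, with sex effects negligible.  Within-group biological variation
    is concentrated in a handful of shape modes (as in real outlines), with a
    small isotropic digitising noise floor on top.
    """
    template = make_template(seed=seed)
    d = 0.06  # subspecies mean-shape offset (Procrustes units)
    groups = {
        "fennicus_wild": GroupSpec("fennicus", "wild_forest", base_size=16.5,
                                   offset_magnitude=+d / 2),
        "tarandus_wild": GroupSpec("tarandus", "wild_mountain", base_size=15.4,
                                   offset_magnitude=-d / 2),
        "tarandus_domestic": GroupSpec("tarandus", "domestic", base_size=15.0,
                                       offset_magnitude=-d / 2),
    }
    return SimulationDesign(
        template=template,
        groups=groups,
        noise_sd=0.002,
        within_group_sd=0.029,
        biological_modes=5,
        biological_sd=0.02,
        n_per_cell=n_per_cell,
        seed=seed,
    )


def two_group_design(
    delta: float = 2.0,
    n_per_group: int = 100,
    n_fixed: int = 4,
    n_semi: int = 4,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> SimulationDesign:
    """Minimal two-group design with a planted Mahalanobis separation.

    The group mean offset is ``delta * noise_sd`` along a non-affine unit
    direction, so the true Mahalanobis distance between the groups (isotropic
    noise) is exactly ``delta``.  Single wear class and sex keep every other
    factor silent.
    """
    template = make_template(n_fixed=n_fixed, n_semi=n_semi, seed=seed)
    d = delta * noise_sd
    groups = {
        "fennicus_wild": GroupSpec("fennicus", "wild_forest", base_size=1.0,
                                   offset_magnitude=+d / 2),
        "tarandus_wild": GroupSpec("tarandus", "wild_mountain", base_size=1.0,
                                   offset_magnitude=-d / 2),
    }
    return SimulationDesign(
        template=template,
        groups=groups,
        wear_classes=(2,),
        wear_magnitude_per_class=0.0,
        sexes=("F",),
        sex_shape_magnitude=0.0,
        noise_sd=noise_sd,
        size_cv=0.02,
        n_per_cell=n_per_group,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _planted_directions(design: SimulationDesign) -> dict[str, np.ndarray]:
    """Deterministic unit directions of all planted effects.

    Drawn from the design seed and mutually orthonormalised (after projecting
    out the template's affine fields), so each planted effect contributes an
    independent variance component.
    """
    rng = np.random.default_rng(design.seed)
    t_pts = design.template.points
    k = t_pts.shape[0]
    names = ["wear", "sex", "allometry", "group"] + [
        f"bio{i}" for i in range(design.biological_modes)
    ]
    q_aff = _affine_basis(t_pts)
    basis: list[np.ndarray] = []
    out: dict[str, np.ndarray] = {}
    for name in names:
        v = rng.standard_normal(2 * k)
        v -= q_aff @ (q_aff.T @ v)
        for b in basis:
            v -= (b @ v) * b
        norm = np.linalg.norm(v)
        if norm < 1e-8:
            raise ValidationError(
                "template too small for the requested number of effect directions"
            )
        v /= norm
        basis.append(v)
        out[name] = v
    return out


def _expected_percents(design: SimulationDesign, k: int) -> dict[str, float]:
    """Planted variance fractions implied by the design (balanced cells)."""
    mags = np.array([design.wear_magnitude_per_class * c for c in design.wear_classes])
    var_wear = mags.var()
    offsets = np.array([g.offset_magnitude for g in design.groups.values()])
    var_group = offsets.var() if len(offsets) > 1 else 0.0
    var_sex = (design.sex_shape_magnitude ** 2) / 4 if len(design.sexes) > 1 else 0.0
    var_noise = ((2 * k - 4) * design.noise_sd ** 2 + design.within_group_sd ** 2
                 + design.biological_modes * design.biological_sd ** 2)
    total = var_wear + var_group + var_sex + var_noise
    if total == 0:
        return {"wear": 0.0, "group": 0.0, "sex": 0.0, "residual": 0.0}
    return {
        "wear": 100 * var_wear / total,
        "group": 100 * var_group / total,
        "sex": 100 * var_sex / total,
        "residual": 100 * var_noise / total,
    }


def simulate_dataset(
    design: SimulationDesign,
) -> tuple[MorphometricDataset, dict]:
    """Draw a synthetic dataset and return it with its ground truth.

    Each specimen's shape is template + group offset + wear deformation +
    sex effect (+ allometric shape change) + isotropic noise, then scaled to
    its drawn centroid size and placed at a random rotation and translation.
    The returned truth record carries every planted vector and the variance
    fractions and group separation the design implies.
    """
    rng = np.random.default_rng(design.seed)
    template = design.template
    t_pts = template.points
    k = template.k

    dirs = _planted_directions(design)
    rng.bit_generator.advance(10_000)  # decouple from the direction draws
    wear_dir, sex_dir, allom_dir = dirs["wear"], dirs["sex"], dirs["allometry"]
    group_axis = dirs["group"]
    bio_dirs = [dirs[f"bio{i}"] for i in range(design.biological_modes)]
    group_offsets = {
        name: spec.offset_magnitude * group_axis for name, spec in design.groups.items()
    }

    log_size_ref = float(np.mean([np.log(g.base_size) for g in design.groups.values()]))

    configs: list[LandmarkConfiguration] = []
    rows: list[dict] = []
    for gname in sorted(design.groups):
        spec = design.groups[gname]
        for wear in sorted(design.wear_classes):
            for sex in design.sexes:
                for i in range(design.n_per_cell):
                    size = (spec.base_size
                            * design.size_wear_factors[wear]
                            * (design.sex_size_factor if sex == "M" else 1.0)
                            * float(np.exp(rng.normal(0.0, design.size_cv))))
                    flat = np.concatenate([t_pts[:, 0], t_pts[:, 1]]).copy()
                    flat += group_offsets[gname]
                    flat += design.within_group_sd * rng.normal() * group_axis
                    for bio in bio_dirs:
                        flat += design.biological_sd * rng.normal() * bio
                    flat += design.wear_magnitude_per_class * wear * wear_dir
                    if sex == "M":
                        flat += design.sex_shape_magnitude * sex_dir
                    if design.allometry_magnitude:
                        flat += (design.allometry_magnitude
                                 * (np.log(size) - log_size_ref) * allom_dir)
                    flat += rng.normal(0.0, design.noise_sd, size=2 * k)
                    shape = _unflatten(flat)
                    shape = shape - shape.mean(0)
                    shape = shape / centroid_size(shape) * size
                    angle = rng.uniform(0.0, 2 * np.pi)
                    rot = np.array([[np.cos(angle), -np.sin(angle)],
                                    [np.sin(angle), np.cos(angle)]])
                    shape = shape @ rot.T + rng.uniform(-5.0, 5.0, size=2)
                    sid = f"{gname}_w{wear}_{sex}_{i:03d}"
                    configs.append(
                        LandmarkConfiguration(
                            specimen_id=sid, points=shape,
                            roles=template.roles, segment_index=template.segment_index,
                        )
                    )
                    rows.append(dict(
                        specimen_id=sid, tooth=design.tooth, wear_class=wear,
                        subspecies=spec.subspecies, status=spec.status, sex=sex,
                        population=spec.population or gname, provenance="modern",
                    ))

    metadata = pd.DataFrame(rows).set_index("specimen_id", drop=False)
    dataset = MorphometricDataset(configs, metadata)
    sigma = np.hypot(design.noise_sd, design.within_group_sd)
    offsets = [g.offset_magnitude for g in design.groups.values()]
    truth = dict(
        wear_direction=wear_dir,
        sex_direction=sex_dir,
        allometry_direction=allom_dir,
        group_axis=group_axis,
        group_offsets=group_offsets,
        expected_percent=_expected_percents(design, k),
        mahalanobis_separation=(max(offsets) - min(offsets)) / sigma if sigma else np.inf,
        seed=design.seed,
    )
    return dataset, truth


def simulate_unknowns(
    design: SimulationDesign,
    site_specs: Mapping[str, Mapping[str, int]],
    wear_class: int | None = None,
    seed: int | None = None,
) -> tuple[MorphometricDataset, pd.Series]:
    """Draw archaeological specimens from the same group distributions.

    ``site_specs`` maps site name -> {group label -> count}.  The returned
    metadata carry unknown subspecies/status/sex (as in real archaeological
    material); the true group of each specimen comes back as a Series for
    recovery checks.
    """
    rng = np.random.default_rng(design.seed + 7919 if seed is None else seed)
    template = design.template
    t_pts = template.points
    k = template.k
    # same planted directions as simulate_dataset (derived from design.seed)
    dirs = _planted_directions(design)
    wear_dir = dirs["wear"]
    group_axis = dirs["group"]
    bio_dirs = [dirs[f"bio{i}"] for i in range(design.biological_modes)]

    wear = wear_class if wear_class is not None else sorted(design.wear_classes)[0]
    configs, rows, true_groups = [], [], {}
    for site in sorted(site_specs):
        for gname in sorted(site_specs[site]):
            spec = design.groups[gname]
            for i in range(site_specs[site][gname]):
                size = (spec.base_size * design.size_wear_factors[wear]
                        * float(np.exp(rng.normal(0.0, design.size_cv))))
                flat = np.concatenate([t_pts[:, 0], t_pts[:, 1]]).copy()
                flat += spec.offset_magnitude * group_axis
                flat += design.within_group_sd * rng.normal() * group_axis
                for bio in bio_dirs:
                    flat += design.biological_sd * rng.normal() * bio
                flat += design.wear_magnitude_per_class * wear * wear_dir
                flat += rng.normal(0.0, design.noise_sd, size=2 * k)
                shape = _unflatten(flat)
                shape = shape - shape.mean(0)
                shape = shape / centroid_size(shape) * size
                angle = rng.uniform(0.0, 2 * np.pi)
                rot = np.array([[np.cos(angle), -np.sin(angle)],
                                [np.sin(angle), np.cos(angle)]])
                shape = shape @ rot.T + rng.uniform(-5.0, 5.0, size=2)
                sid = f"{site}_{gname}_{i:03d}"
                configs.append(LandmarkConfiguration(
                    specimen_id=sid, points=shape,
                    roles=template.roles, segment_index=template.segment_index,
                ))
                rows.append(dict(
                    specimen_id=sid, tooth=design.tooth, wear_class=wear,
                    subspecies="unknown", status="unknown", sex="ND",
                    population=site, provenance="archaeological",
                ))
                true_groups[sid] = gname
    metadata = pd.DataFrame(rows).set_index("specimen_id", drop=False)
    return MorphometricDataset(configs, metadata), pd.Series(true_groups, name="true_group")
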