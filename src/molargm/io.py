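"""Reading, writing and validation of landmark data and specimen metadata.

Landmark coordinates travel in TPS files (the flat-file dialect written by
tpsDig: ``LM=`` record headers, coordinate rows, optional ``IMAGE=``, ``ID=``,
``SCALE=`` and ``COMMENT=`` lines).  Specimen metadata travel in a CSV with one
row per tooth.  The two sides are joined into a :class:`MorphometricDataset`,
which every downstream stage consumes.

Coordinates are stored y-up exactly as read; no image-axis flip is applied.
Mirroring of right teeth onto the left template must be explicit, never silent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, TPSParseError, ValidationError

logger = logging.getLogger("molargm")

#: default landmarking protocol: 9 fixed landmarks at curvature extrema of the
#: enamel-dentine junction plus 66 sliding semilandmarks along the outline.
N_FIXED_DEFAULT = 9
N_SEMI_DEFAULT = 66

ROLE_FIXED = "fixed"
ROLE_SEMI = "semi"

TOOTH_LEVELS = ("m1", "m2")
WEAR_LEVELS = (0, 1, 2, 3, 4)
SUBSPECIES_LEVELS = ("tarandus", "fennicus", "unknown")
STATUS_LEVELS = ("wild_mountain", "wild_forest", "domestic", "unknown")
SEX_LEVELS = ("F", "M", "ND")
PROVENANCE_LEVELS = ("modern", "archaeological")

#: wear classes retained for analysis, per tooth.  Unworn (0) and highly worn
#: (4) teeth cannot be landmarked reliably; for m2 the heavily worn class 3 is
#: additionally dropped for want of specimens.
ANALYSIS_WEAR_CLASSES = {"m1": (1, 2, 3), "m2": (1, 2)}

METADATA_COLUMNS = (
    "specimen_id",
    "tooth",
    "wear_class",
    "subspecies",
    "status",
    "sex",
    "population",
    "provenance",
)


def default_role_layout(
    n_fixed: int = N_FIXED_DEFAULT,
    n_semi: int = N_SEMI_DEFAULT,
    allocation: Sequence[int] | None = None,
    segment_lengths: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(roles, segment_index)`` for a closed outline protocol.

    Points are ordered around the outline: fixed landmark 0, the semilandmarks
    of segment 0, fixed landmark 1, and so on.  Segment ``s`` runs from fixed
    landmark ``s`` to fixed landmark ``(s+1) % n_fixed``.

    Parameters
    ----------
    allocation
        Number of semilandmarks per segment (length ``n_fixed``).  If omitted,
        semilandmarks are split as equally as possible, the remainder going to
        the longest segments of ``segment_lengths`` (or simply the first
        segments when no lengths are given).
    """
    if n_fixed < 3:
        raise ValidationError("a closed outline needs at least 3 fixed landmarks")
    if allocation is None:
        base, extra = divmod(n_semi, n_fixed)
        alloc = np.full(n_fixed, base, dtype=int)
        if extra:
            if segment_lengths is not None:
                order = np.argsort(np.asarray(segment_lengths))[::-1]
            else:
                order = np.arange(n_fixed)
            alloc[order[:extra]] += 1
    else:
        alloc = np.asarray(allocation, dtype=int)
        if alloc.size != n_fixed or alloc.sum() != n_semi or (alloc < 0).any():
            raise ValidationError(
                f"allocation must be {n_fixed} nonnegative counts summing to {n_semi}"
            )
    roles, seg = [], []
    for s in range(n_fixed):
        roles.append(ROLE_FIXED)
        seg.append(-1)
        roles.extend([ROLE_SEMI] * alloc[s])
        seg.extend([s] * alloc[s])
    return np.array(roles), np.array(seg, dtype=int)


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2D point set with fixed/semilandmark roles.

    ``points`` are in millimetres once the TPS scale factor has been applied;
    ``unit_known`` is False when no scale factor was available.  ``roles`` and
    ``segment_index`` may be None for freshly read files and are attached with
    :meth:`with_roles` once the protocol layout is known.
    """

    specimen_id: str
    points: np.ndarray
    roles: np.ndarray | None = None
    segment_index: np.ndarray | None = None
    unit_known: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError(
                f"{self.specimen_id}: points must be a K x 2 array, got {self.points.shape}"
            )
        if not np.isfinite(self.points).all():
            raise ValidationError(f"{self.specimen_id}: non-finite coordinate")
        if self.roles is not None:
            self.roles = np.asarray(self.roles)
            if self.roles.shape != (self.k,):
                raise ValidationError(f"{self.specimen_id}: roles length != K")
            bad = set(np.unique(self.roles)) - {ROLE_FIXED, ROLE_SEMI}
            if bad:
                raise ValidationError(f"{self.specimen_id}: unknown roles {bad}")
        if self.segment_index is not None:
            self.segment_index = np.asarray(self.segment_index, dtype=int)
            if self.segment_index.shape != (self.k,):
                raise ValidationError(f"{self.specimen_id}: segment_index length != K")

    @property
    def k(self) -> int:
        return self.points.shape[0]

    @property
    def n_fixed(self) -> int:
        if self.roles is None:
            return self.k
        return int((self.roles == ROLE_FIXED).sum())

    @property
    def n_semi(self) -> int:
        return self.k - self.n_fixed

    @property
    def semi_mask(self) -> np.ndarray:
        if self.roles is None:
            return np.zeros(self.k, dtype=bool)
        return self.roles == ROLE_SEMI

    def with_roles(
        self, roles: np.ndarray, segment_index: np.ndarray | None = None
    ) -> "LandmarkConfiguration":
        return replace(self, roles=roles, segment_index=segment_index)

    def with_points(self, points: np.ndarray) -> "LandmarkConfiguration":
        return replace(self, points=np.asarray(points, dtype=float))


@dataclass
class MorphometricDataset:
    """Landmark configurations joined to their specimen metadata."""

    configurations: list[LandmarkConfiguration]
    metadata: pd.DataFrame = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        return self.configurations[0].k if self.configurations else 0

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coordinates(self) -> np.ndarray:
        """Stacked raw coordinates, shape (n, K, 2)."""
        return np.stack([c.points for c in self.configurations])

    def subset(self, ids: Sequence[str]) -> "MorphometricDataset":
        wanted = list(ids)
        configs = {c.specimen_id: c for c in self.configurations}
        missing = [i for i in wanted if i not in configs]
        if missing:
            raise ValidationError(f"unknown specimen ids: {missing}")
        return MorphometricDataset(
            [configs[i] for i in wanted], self.metadata.loc[wanted].copy()
        )


# ---------------------------------------------------------------------------
# TPS files
# ---------------------------------------------------------------------------

def read_tps(path: str | Path, apply_scale: bool = True) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file (tpsDig dialect).

    Each record starts with ``LM=k`` followed by ``k`` coordinate rows and
    optional ``IMAGE=``, ``ID=``, ``SCALE=`` and ``COMMENT=`` lines.  Keys are
    case-insensitive; CRLF line endings are accepted.  With ``apply_scale``,
    coordinates are multiplied by the record's SCALE factor; records lacking
    one are flagged ``unit_known=False`` with a warning.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    configs: list[LandmarkConfiguration] = []
    seen_ids: set[str] = set()

    i, ordinal = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        key, _, value = line.partition("=")
        if key.strip().upper() != "LM":
            raise TPSParseError(f"{path}:{i + 1}: expected LM= record header, got {line!r}")
        try:
            k = int(value.strip())
        except ValueError as exc:
            raise TPSParseError(f"{path}:{i + 1}: bad LM count {value!r}") from exc
        i += 1
        pts = np.empty((k, 2))
        for j in range(k):
            if i >= len(lines):
                raise TPSParseError(
                    f"{path}: record {ordinal}: LM={k} but file ends after {j} coordinate rows"
                )
            row = lines[i].strip().split()
            if len(row) != 2:
                raise TPSParseError(
                    f"{path}:{i + 1}: record {ordinal}: LM={k} but row {j} is not two "
                    f"coordinates: {lines[i]!r}"
                )
            try:
                pts[j] = [float(row[0]), float(row[1])]
            except ValueError as exc:
                raise TPSParseError(
                    f"{path}:{i + 1}: non-numeric coordinate {lines[i]!r}"
                ) from exc
            i += 1
        image = spec_id = None
        scale = None
        while i < len(lines):
            stripped = lines[i].strip()
            if not stripped:
                i += 1
                continue
            key, sep, value = stripped.partition("=")
            keyu = key.strip().upper()
            if keyu == "LM":
                break
            if not sep:
                raise TPSParseError(f"{path}:{i + 1}: unexpected line {stripped!r}")
            if keyu == "IMAGE":
                image = value.strip()
            elif keyu == "ID":
                spec_id = value.strip()
            elif keyu == "SCALE":
                try:
                    scale = float(value.strip())
                except ValueError as exc:
                    raise TPSParseError(f"{path}:{i + 1}: bad SCALE {value!r}") from exc
            elif keyu == "COMMENT":
                pass
            else:
                logger.debug("ignoring TPS key %s at %s:%d", keyu, path, i + 1)
            i += 1
        unit_known = True
        if apply_scale:
            if scale is not None:
                pts = pts * scale
            else:
                warnings.warn(
                    f"record {ordinal} ({spec_id or image or 'unnamed'}) has no SCALE=; "
                    "coordinates kept in pixel units (unit_known=False)",
                    stacklevel=2,
                )
                unit_known = False
        if spec_id is None:
            spec_id = Path(image).stem if image else str(ordinal)
        if spec_id in seen_ids:
            raise ValidationError(f"{path}: duplicate specimen id {spec_id!r}")
        seen_ids.add(spec_id)
        configs.append(
            LandmarkConfiguration(specimen_id=spec_id, points=pts, unit_known=unit_known)
        )
        ordinal += 1
    return configs


def write_tps(
    configs: Sequence[LandmarkConfiguration], path: str | Path, scale: float | None = 1.0
) -> None:
    """Write configurations as a TPS file that round-trips with :func:`read_tps`.

    Coordinates are written in the units they carry; the default ``SCALE=1``
    line marks them as already in millimetres.  Pass ``scale=None`` to omit
    the SCALE line (pixel-unit files).
    """
    if not configs:
        raise ValidationError("refusing to write an empty TPS file")
    out = []
    for c in configs:
        out.append(f"LM={c.k}")
        for x, y in c.points:
            out.append(f"{x:.12g} {y:.12g}")
        out.append(f"ID={c.specimen_id}")
        if scale is not None:
            out.append(f"SCALE={scale:.12g}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def _validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    df = df.copy()
    df["specimen_id"] = df["specimen_id"].astype(str)
    if df["specimen_id"].duplicated().any():
        dupes = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValidationError(f"duplicate specimen ids in metadata: {dupes}")
    df["wear_class"] = pd.to_numeric(df["wear_class"], errors="raise").astype(int)
    bad_wear = ~df["wear_class"].isin(WEAR_LEVELS)
    if bad_wear.any():
        raise ValidationError(
            f"wear_class outside 0-4 for: {df.loc[bad_wear, 'specimen_id'].tolist()}"
        )
    for col, levels in [
        ("tooth", TOOTH_LEVELS),
        ("subspecies", SUBSPECIES_LEVELS),
        ("status", STATUS_LEVELS),
        ("sex", SEX_LEVELS),
        ("provenance", PROVENANCE_LEVELS),
    ]:
        df[col] = df[col].astype(str)
        bad = ~df[col].isin(levels)
        if bad.any():
            raise ValidationError(
                f"invalid {col} values {sorted(df.loc[bad, col].unique())}; "
                f"allowed: {levels}"
            )
    # unknown tokens are legitimate only for archaeological specimens
    modern = df["provenance"] == "modern"
    for col in ("subspecies", "status"):
        bad = modern & (df[col] == "unknown")
        if bad.any():
            raise ValidationError(
                f"modern specimens with unknown {col}: "
                f"{df.loc[bad, 'specimen_id'].tolist()}"
            )
    # status determines subspecies for known statuses
    implied = {"wild_forest": "fennicus", "domestic": "tarandus", "wild_mountain": "tarandus"}
    for status, sub in implied.items():
        bad = (df["status"] == status) & (df["subspecies"] != sub)
        if bad.any():
            raise ValidationError(
                f"status {status} implies subspecies {sub}, violated by: "
                f"{df.loc[bad, 'specimen_id'].tolist()}"
            )
    return df.set_index("specimen_id", drop=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the specimen metadata CSV (one row per tooth)."""
    df = pd.read_csv(path, comment="#")
    return _validate_metadata(df)


def assemble_dataset(
    configs: Sequence[LandmarkConfiguration], metadata: pd.DataFrame
) -> MorphometricDataset:
    """Join configurations to metadata rows; every configuration must match."""
    if not configs:
        raise ValidationError("no configurations to assemble")
    if "specimen_id" in metadata.columns and metadata.index.name != "specimen_id":
        metadata = metadata.set_index("specimen_id", drop=False)
    ids = [c.specimen_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate specimen ids among configurations")
    missing = [i for i in ids if i not in metadata.index]
    if missing:
        raise ValidationError(f"configurations without metadata: {missing}")
    ks = {c.k for c in configs}
    if len(ks) != 1:
        raise ValidationError(f"heterogeneous landmark counts: {sorted(ks)}")
    unmatched = metadata.index.difference(ids)
    if len(unmatched):
        logger.info("%d metadata rows without configurations: %s",
                    len(unmatched), list(unmatched[:10]))
    return MorphometricDataset(list(configs), metadata.loc[ids].copy())


def filter_analysis_set(dataset: MorphometricDataset, tooth: str) -> MorphometricDataset:
    """Apply the wear-class inclusion rules for one tooth.

    Keeps wear classes 1-3 for m1 and 1-2 for m2: unworn and highly worn teeth
    cannot be landmarked consistently, and too few worn m2 (class 3) exist to
    support group statistics.  Removal counts per class are logged.
    """
    if tooth not in TOOTH_LEVELS:
        raise ValidationError(f"tooth must be one of {TOOTH_LEVELS}, got {tooth!r}")
    keep_classes = ANALYSIS_WEAR_CLASSES[tooth]
    md = dataset.metadata
    mask = (md["tooth"] == tooth) & md["wear_class"].isin(keep_classes)
    dropped = md.loc[(md["tooth"] == tooth) & ~md["wear_class"].isin(keep_classes)]
    for cls, cnt in dropped["wear_class"].value_counts().sort_index().items():
        logger.info("filter_analysis_set(%s): dropped %d specimens of wear class %d",
                    tooth, cnt, cls)
    kept = md.index[mask].tolist()
    if not kept:
        raise EmptySelectionError(
            f"no {tooth} specimens left in wear classes {keep_classes}"
        )
    return dataset.subset(kept)
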