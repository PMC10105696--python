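"""Canonical variate analysis, cross-validated classification and assignment
of archaeological unknowns.

The classification core follows the model/results idiom: :class:`CVA` is built
from retained principal-component scores and group labels; :meth:`CVA.fit`
returns a :class:`CVAResults` carrying the canonical axes, Mahalanobis
distances between group means, a leave-one-out cross-validated confusion
matrix and a text ``summary()``.  Group-membership probabilities use a linear
Gaussian discriminant with pooled within-group covariance and, by default,
equal priors — archaeological base rates are unknown.

Archaeological specimens never influence the consensus or the eigenvectors:
they are Procrustes-aligned onto the modern consensus and projected into the
modern shape space (project-only), then classified.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .bending import BendingEnergyModel, SlidingSpec, slide_semilandmarks
from .errors import ValidationError
from .io import LandmarkConfiguration
from .shape_stats import ShapeSpace
from .superimposition import AlignedSample, normalize_shape, opa_align, tangent_project

logger = logging.getLogger("molargm")

#: cumulative variance retained before a CVA, to keep the cross-validation
#: honest in the face of high-dimensional shape data
RETENTION_THRESHOLD = 0.95


def retain_components(
    space: ShapeSpace, threshold: float = RETENTION_THRESHOLD
) -> tuple[np.ndarray, int]:
    """Scores of the smallest leading component set reaching ``threshold``
    cumulative variance (at least one component)."""
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    cum = np.cumsum(space.variance_proportions)
    n_keep = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    n_keep = max(1, min(n_keep, space.n_components))
    return space.scores[:, :n_keep], n_keep


def _pooled_stats(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[list[str], dict[str, np.ndarray], np.ndarray]:
    groups = sorted(set(labels))
    n, p = scores.shape
    means = {}
    pooled = np.zeros((p, p))
    for g in groups:
        block = scores[labels == g]
        means[g] = block.mean(0)
        pooled += (block - means[g]).T @ (block - means[g])
    pooled /= n - len(groups)
    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > 1e10:
        warnings.warn(
            f"pooled covariance ill-conditioned (cond={cond:.2g}); "
            "shrinking toward its diagonal",
            stacklevel=3,
        )
        pooled = (1 - 1e-8) * pooled + 1e-8 * np.diag(np.diag(pooled))
    return groups, means, pooled


def _log_posteriors(
    x: np.ndarray,
    groups: list[str],
    means: dict[str, np.ndarray],
    pooled: np.ndarray,
    priors: dict[str, float],
) -> np.ndarray:
    """Posterior probabilities (rows of x by groups) of the linear Gaussian
    discriminant with shared covariance."""
    chol = sla.cho_factor(pooled)
    scores = np.empty((x.shape[0], len(groups)))
    for j, g in enumerate(groups):
        diff = x - means[g]
        sol = sla.cho_solve(chol, diff.T).T
        scores[:, j] = -0.5 * (diff * sol).sum(1) + np.log(priors[g])
    scores -= scores.max(1, keepdims=True)
    post = np.exp(scores)
    post /= post.sum(1, keepdims=True)
    return post


def _resolve_priors(priors, groups: list[str], labels: np.ndarray) -> dict[str, float]:
    if priors in (None, "equal"):
        return {g: 1.0 / len(groups) for g in groups}
    if priors == "proportional":
        n = len(labels)
        return {g: (labels == g).sum() / n for g in groups}
    if isinstance(priors, dict):
        total = sum(priors.values())
        return {g: priors[g] / total for g in groups}
    raise ValidationError(f"unsupported priors {priors!r}")


@dataclass
class ClassificationReport:
    """Cross-validated confusion matrix and accuracies, or unknown assignments."""

    confusion: pd.DataFrame | None      # rows = truth, columns = predicted
    per_group_accuracy: dict[str, float] | None
    overall_accuracy: float | None      # percent
    assignments: pd.DataFrame | None = None  # unknowns: assigned + posteriors

    def summary(self) -> str:
        parts = []
        if self.confusion is not None:
            parts.append("Cross-validated confusion (rows = truth):")
            parts.append(self.confusion.to_string())
            accs = ", ".join(f"{g}: {a:.1f}%" for g, a in self.per_group_accuracy.items())
            parts.append(f"Per-group accuracy: {accs}")
            parts.append(f"Overall accuracy: {self.overall_accuracy:.1f}%")
        if self.assignments is not None:
            parts.append(f"Assignments ({len(self.assignments)} unknowns):")
            parts.append(self.assignments.to_string())
        return "\n".join(parts)


class CVA:
    """Canonical variate analysis of retained PC scores grouped by labels.

    Parameters
    ----------
    scores : (n, p) array
        Retained principal-component scores (see :func:`retain_components`).
    groups : sequence of str
        Group label per specimen; at least two groups of two.
    """

    def __init__(self, scores: np.ndarray, groups) -> None:
        scores = np.asarray(scores, dtype=float)
        if scores.ndim == 1:
            scores = scores[:, None]
        labels = pd.Series(groups).astype(str).to_numpy()
        if scores.shape[0] != labels.shape[0]:
            raise ValidationError("scores and groups differ in length")
        names, counts = np.unique(labels, return_counts=True)
        if len(names) < 2:
            raise ValidationError("CVA needs at least 2 groups")
        if (counts < 2).any():
            small = names[counts < 2].tolist()
            raise ValidationError(f"groups with < 2 specimens: {small}")
        if scores.shape[0] <= scores.shape[1]:
            p_new = scores.shape[0] - len(names) - 1
            if p_new < 1:
                raise ValidationError("too few specimens for any component")
            warnings.warn(
                f"n={scores.shape[0]} <= p={scores.shape[1]}; "
                f"reducing to first {p_new} components",
                stacklevel=2,
            )
            scores = scores[:, :p_new]
        self.scores = scores
        self.labels = labels

    def fit(self) -> "CVAResults":
        scores, labels = self.scores, self.labels
        groups, means, pooled = _pooled_stats(scores, labels)
        g = len(groups)
        n, p = scores.shape
        grand = scores.mean(0)
        between = np.zeros((p, p))
        for name in groups:
            nk = (labels == name).sum()
            dev = means[name] - grand
            between += nk * np.outer(dev, dev)
        between /= max(g - 1, 1)
        # canonical axes: generalized symmetric eigenproblem B a = l W a
        evals, evecs = sla.eigh(between, pooled)
        order = np.argsort(evals)[::-1]
        n_axes = min(g - 1, p)
        evals = evals[order][:n_axes]
        axes = evecs[:, order][:, :n_axes]
        # unit within-group variance along each axis; deterministic sign
        for j in range(axes.shape[1]):
            norm = np.sqrt(axes[:, j] @ pooled @ axes[:, j])
            axes[:, j] /= norm
            i = np.argmax(np.abs(axes[:, j]))
            if axes[i, j] < 0:
                axes[:, j] *= -1

        winv = np.linalg.inv(pooled)
        maha = pd.DataFrame(0.0, index=groups, columns=groups)
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                d = means[a] - means[b]
                maha.loc[a, b] = maha.loc[b, a] = float(np.sqrt(d @ winv @ d))

        canon_scores = scores @ axes
        canon_means = pd.DataFrame(
            {g_: means[g_] @ axes for g_ in groups}
        ).T
        canon_means.columns = [f"CV{j + 1}" for j in range(n_axes)]

        return CVAResults(
            model=self,
            groups=groups,
            group_sizes={g_: int((labels == g_).sum()) for g_ in groups},
            means={g_: means[g_] for g_ in groups},
            pooled_covariance=pooled,
            axes=axes,
            eigenvalues=evals,
            canonical_scores=canon_scores,
            canonical_means=canon_means,
            mahalanobis=maha,
        )


@dataclass
class CVAResults:
    """Fitted canonical space: axes, Mahalanobis distances, classification."""

    model: CVA
    groups: list[str]
    group_sizes: dict[str, int]
    means: dict[str, np.ndarray]
    pooled_covariance: np.ndarray
    axes: np.ndarray                # (p, n_axes)
    eigenvalues: np.ndarray
    canonical_scores: np.ndarray    # (n, n_axes)
    canonical_means: pd.DataFrame
    mahalanobis: pd.DataFrame
    _loo: ClassificationReport | None = field(default=None, repr=False)

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    def loo_classification(self, priors="equal") -> ClassificationReport:
        if self._loo is None:
            self._loo = loo_cross_validate(self.model.scores, self.model.labels, priors)
        return self._loo

    def classify(self, unknown_scores: np.ndarray, priors="equal",
                 ids=None) -> ClassificationReport:
        return classify_unknowns(
            self.model.scores, self.model.labels, unknown_scores, priors, ids=ids
        )

    def summary(self) -> str:
        lines = [
            "Canonical Variate Analysis",
            f"  groups: {', '.join(f'{g} (n={self.group_sizes[g]})' for g in self.groups)}",
            f"  retained components: {self.model.scores.shape[1]}; "
            f"canonical axes: {self.n_axes}",
            "",
            "Group means in canonical space:",
            self.canonical_means.to_string(float_format=lambda v: f"{v:.3f}"),
            "",
            "Mahalanobis distances between group means:",
            self.mahalanobis.to_string(float_format=lambda v: f"{v:.3f}"),
            "",
            self.loo_classification().summary(),
        ]
        return "\n".join(lines)


def cva_fit(scores: np.ndarray, groups) -> CVAResults:
    """Functional wrapper: ``CVA(scores, groups).fit()``."""
    return CVA(scores, groups).fit()


def loo_cross_validate(scores: np.ndarray, groups, priors="equal") -> ClassificationReport:
    """Leave-one-out cross-validated linear discriminant classification.

    For every specimen the group means and pooled covariance are recomputed
    from the remaining n-1 specimens before the held-out specimen is assigned
    to the maximum-posterior group.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    labels = pd.Series(groups).astype(str).to_numpy()
    names = sorted(set(labels))
    n = scores.shape[0]
    predicted = np.empty(n, dtype=object)
    kept = np.ones(n, dtype=bool)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        rest_labels = labels[mask]
        if any((rest_labels == g).sum() < 1 for g in names):
            warnings.warn(
                f"leaving out specimen {i} empties a group; specimen skipped",
                stacklevel=2,
            )
            kept[i] = False
            continue
        g_names, means, pooled = _pooled_stats(scores[mask], rest_labels)
        pri = _resolve_priors(priors, g_names, rest_labels)
        post = _log_posteriors(scores[i: i + 1], g_names, means, pooled, pri)
        predicted[i] = g_names[int(np.argmax(post[0]))]

    confusion = pd.DataFrame(0, index=names, columns=names)
    for truth, pred in zip(labels[kept], predicted[kept]):
        confusion.loc[truth, pred] += 1
    per_group = {}
    for g in names:
        total = confusion.loc[g].sum()
        per_group[g] = 100.0 * confusion.loc[g, g] / total if total else np.nan
    correct = np.trace(confusion.to_numpy())
    overall = 100.0 * correct / confusion.to_numpy().sum()
    return ClassificationReport(confusion, per_group, float(overall))


def project_unknowns(
    aligned_reference: AlignedSample,
    space: ShapeSpace,
    unknowns: list[LandmarkConfiguration] | np.ndarray,
    sliding: SlidingSpec | None = None,
) -> np.ndarray:
    """Project unknown configurations into the modern shape space.

    Each unknown is ordinary-Procrustes aligned to the reference consensus
    (translated, scaled to unit centroid size, rotated; optionally slid
    against the consensus), tangent-projected like the training sample, then
    centred on the space's mean shape and projected onto the eigenvectors.
    The reference sample itself is never modified.
    """
    if isinstance(unknowns, np.ndarray):
        arrs = [unknowns[i] for i in range(unknowns.shape[0])]
        masks = [None] * len(arrs)
    else:
        arrs = [u.points for u in unknowns]
        masks = [u.semi_mask for u in unknowns]
    consensus = aligned_reference.consensus
    k = consensus.shape[0]
    out = np.empty((len(arrs), space.n_components))
    mean_flat = np.concatenate([space.mean_shape[:, 0], space.mean_shape[:, 1]])
    be_model = None
    for i, (pts, mask) in enumerate(zip(arrs, masks)):
        if pts.shape[0] != k:
            raise ValidationError(f"unknown {i}: K={pts.shape[0]} != reference K={k}")
        aligned = opa_align(pts, consensus)
        if sliding is not None and mask is not None and mask.any():
            if be_model is None:
                be_model = BendingEnergyModel.from_reference(consensus)
            aligned = slide_semilandmarks(aligned, be_model, sliding, semi_mask=mask)
            aligned = normalize_shape(aligned)
            aligned = opa_align(aligned, consensus)
        flat = np.concatenate([aligned[:, 0], aligned[:, 1]])
        if space.projected:
            flat = tangent_project(flat, consensus)[0]
        out[i] = (flat - mean_flat) @ space.eigenvectors.T
    return out


def classify_unknowns(
    train_scores: np.ndarray,
    train_groups,
    unknown_scores: np.ndarray,
    priors="equal",
    ids=None,
) -> ClassificationReport:
    """Linear predictive discriminant assignment of unknown specimens.

    Fits the pooled-covariance Gaussian discriminant on the training scores
    and reports, per unknown, the posterior probability of each group and the
    maximum-posterior assignment.  Exact posterior ties are broken toward the
    first group in sorted label order and flagged.
    """
    train_scores = np.asarray(train_scores, dtype=float)
    unknown_scores = np.atleast_2d(np.asarray(unknown_scores, dtype=float))
    if train_scores.ndim == 1:
        train_scores = train_scores[:, None]
    labels = pd.Series(train_groups).astype(str).to_numpy()
    if unknown_scores.shape[1] != train_scores.shape[1]:
        raise ValidationError(
            f"unknown scores have {unknown_scores.shape[1]} dims, "
            f"training has {train_scores.shape[1]}"
        )
    groups, means, pooled = _pooled_stats(train_scores, labels)
    pri = _resolve_priors(priors, groups, labels)
    post = _log_posteriors(unknown_scores, groups, means, pooled, pri)
    best = np.argmax(post, axis=1)
    tie = np.isclose(post, post[np.arange(len(best)), best][:, None]).sum(1) > 1
    if ids is None:
        ids = [str(i) for i in range(len(best))]
    table = pd.DataFrame(post, columns=[f"p_{g}" for g in groups], index=ids)
    table.insert(0, "assigned", [groups[b] for b in best])
    table["tie"] = tie
    return ClassificationReport(None, None, None, assignments=table)


def summarize_assignments(
    assignments: pd.DataFrame, by: list[str] | None = None
) -> pd.DataFrame:
    """Count/percent table of assignments, optionally stratified.

    ``assignments`` must carry an ``assigned`` column plus any grouping keys
    (e.g. site, tooth).  Percentages are reported raw and rounded to the
    nearest integer for display.
    """
    if "assigned" not in assignments.columns:
        raise ValidationError("assignments table lacks an 'assigned' column")
    keys = list(by) if by else []
    rows = []
    grouped = assignments.groupby(keys, sort=True) if keys else [((), assignments)]
    for strat, block in grouped:
        if not isinstance(strat, tuple):
            strat = (strat,)
        total = len(block)
        counts = block["assigned"].value_counts().sort_index()
        for group, count in counts.items():
            pct = 100.0 * count / total
            rows.append(
                dict(zip(keys, strat))
                | dict(assigned=group, n=int(count), total=int(total),
                       percent=pct, percent_rounded=int(round(pct)))
            )
    return pd.DataFrame(rows)
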