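"""Ordination, variance decomposition, size tests and allometry.

Shape statistics operate on Procrustes-aligned coordinates, orthogonally
projected into the tangent space at the consensus.  "Shape variance explained"
by a factor is a sequential (Type I) sum-of-squares decomposition over all
shape variables (Goodall-style Procrustes ANOVA); significance comes from
permutation of reduced-model residuals, so no multivariate normality is
assumed.  Size is analysed on log-transformed centroid size with a one-way
ANOVA and pairwise Wilcoxon rank-sum tests under Benjamini-Hochberg false
discovery rate control.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .superimposition import AlignedSample


# ---------------------------------------------------------------------------
# PCA of shape
# ---------------------------------------------------------------------------

@dataclass
class ShapeSpace:
    """Principal-component decomposition of aligned shape coordinates."""

    mean_shape: np.ndarray            # (K, 2)
    eigenvectors: np.ndarray          # (n_components, 2K) rows are loadings
    eigenvalues: np.ndarray           # (n_components,)
    variance_proportions: np.ndarray  # (n_components,) summing to 1
    scores: np.ndarray                # (n, n_components)
    projected: bool = True
    specimen_ids: list[str] | None = None

    @property
    def k(self) -> int:
        return self.mean_shape.shape[0]

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[0]


def _shape_matrix(aligned: AlignedSample, project: bool) -> np.ndarray:
    return aligned.tangent_coordinates() if project else aligned.flattened()


def pca_shapes(aligned: AlignedSample | np.ndarray, project: bool = True) -> ShapeSpace:
    """PCA of aligned shapes (tangent-space coordinates by default).

    Components are ordered by decreasing eigenvalue; the sign of each
    component is fixed so its largest-magnitude loading is positive.  All
    components with non-negligible variance are kept, so the centred data are
    exactly reconstructible from the scores.
    """
    if isinstance(aligned, AlignedSample):
        flat = _shape_matrix(aligned, project)
        ids = aligned.specimen_ids
        k = aligned.k
    else:
        flat = np.asarray(aligned, dtype=float)
        ids = None
        if flat.ndim != 2 or flat.shape[1] % 2:
            raise ValidationError("expected an (n, 2K) matrix of flattened shapes")
        k = flat.shape[1] // 2
    n = flat.shape[0]
    if n < 3:
        raise ValidationError("PCA needs at least 3 specimens")
    mean = flat.mean(0)
    centred = flat - mean
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    total = eigvals.sum()
    keep = eigvals > max(1e-14 * total, 0.0)
    if not keep.any():
        keep[0] = True
    vt = vt[keep]
    eigvals = eigvals[keep]
    # deterministic sign: largest-|loading| entry of each component positive
    for row in vt:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1
    scores = centred @ vt.T
    return ShapeSpace(
        mean_shape=np.column_stack([mean[:k], mean[k:]]),
        eigenvectors=vt,
        eigenvalues=eigvals,
        variance_proportions=eigvals / total,
        scores=scores,
        projected=project,
        specimen_ids=list(ids) if ids is not None else None,
    )


def reconstruct_shape(space: ShapeSpace, component: int, score: float) -> np.ndarray:
    """Deform the mean shape along one principal component.

    Returns ``mean + score * eigenvector`` as a K x 2 configuration; used to
    visualise what a component means morphologically.
    """
    if not 0 <= component < space.n_components:
        raise ValidationError(
            f"component {component} out of range (have {space.n_components})"
        )
    flat = np.concatenate([space.mean_shape[:, 0], space.mean_shape[:, 1]])
    flat = flat + score * space.eigenvectors[component]
    k = space.k
    return np.column_stack([flat[:k], flat[k:]])


# ---------------------------------------------------------------------------
# Procrustes ANOVA / variance decomposition
# ---------------------------------------------------------------------------

@dataclass
class VarianceDecomposition:
    """Sequential SS decomposition of shape variance over one or two factors."""

    terms: pd.DataFrame   # rows: factors (+ interaction) + residual
    n_permutations: int
    seed: int | None
    exhaustive: bool = False

    def summary(self) -> str:
        return self.terms.to_string(float_format=lambda v: f"{v:.4f}")


def _dummy_block(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels.astype(str), drop_first=True, dtype=float).to_numpy()


def _fit_ss(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, int]:
    """Fitted values and design rank for an OLS fit of each column of y."""
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    rank = int((diag > diag.max() * 1e-10).sum()) if diag.size else 0
    fitted = q @ (q.T @ y)
    return fitted, rank


def _sequential_ss(y: np.ndarray, blocks: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Sequential sums of squares for incremental design blocks (after intercept)."""
    n = y.shape[0]
    design = np.ones((n, 1))
    fitted, rank = _fit_ss(y, design)
    ss = []
    dfs = []
    prev_fit, prev_rank = fitted, rank
    for block in blocks:
        design = np.column_stack([design, block])
        fitted, rank = _fit_ss(y, design)
        ss.append(float(((fitted - prev_fit) ** 2).sum()))
        dfs.append(rank - prev_rank)
        prev_fit, prev_rank = fitted, rank
    ss_res = float(((y - prev_fit) ** 2).sum())
    df_res = n - prev_rank
    return np.array(ss), np.array(dfs), ss_res, df_res


def variance_decomposition(
    aligned: AlignedSample | np.ndarray,
    factors: pd.DataFrame | dict,
    n_perm: int = 999,
    seed: int | None = 0,
    project: bool = True,
) -> VarianceDecomposition:
    """Permutation Procrustes ANOVA of shape on one or two factors.

    Main effects enter in the order given; with two factors their interaction
    is added last.  ``percent_variation`` is each term's share of the total
    sum of squares (rows plus residual total 100).  P-values come from
    permutation of reduced-model residuals (Freedman-Lane) with the given
    seed; for a single factor with n! - 1 <= n_perm all permutations are
    enumerated instead, making the p-value exact.
    """
    if isinstance(aligned, AlignedSample):
        y = _shape_matrix(aligned, project)
    else:
        y = np.asarray(aligned, dtype=float)
    factors = pd.DataFrame(factors)
    if not 1 <= factors.shape[1] <= 2:
        raise ValidationError("variance_decomposition takes one or two factors")
    n = y.shape[0]
    if len(factors) != n:
        raise ValidationError("factor rows != number of specimens")
    for name, col in factors.items():
        levels, counts = np.unique(col.astype(str), return_counts=True)
        if len(levels) < 2:
            raise ValidationError(f"factor {name!r} has a single level")
        if (counts < 2).any():
            raise ValidationError(f"factor {name!r} has levels with < 2 specimens")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} gives a coarse permutation p-value", stacklevel=2)

    y = y - y.mean(0)
    names = list(factors.columns)
    blocks = [_dummy_block(factors[name]) for name in names]
    if len(names) == 2:
        a = pd.get_dummies(factors[names[0]].astype(str), drop_first=True, dtype=float)
        b = pd.get_dummies(factors[names[1]].astype(str), drop_first=True, dtype=float)
        inter = np.einsum("ij,ik->ijk", a.to_numpy(), b.to_numpy()).reshape(n, -1)
        blocks.append(inter)
        names = names + [f"{names[0]}:{names[1]}"]

    ss, dfs, ss_res, df_res = _sequential_ss(y, blocks)
    ss_total = float((y ** 2).sum())
    msr = ss_res / df_res if df_res > 0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        fstats = (ss / np.maximum(dfs, 1)) / msr

    rng = np.random.default_rng(seed)
    exhaustive = len(blocks) == 1 and n <= 8 and math.factorial(n) - 1 <= n_perm
    pvals = np.empty(len(blocks))
    for t in range(len(blocks)):
        reduced = np.column_stack([np.ones((n, 1))] + blocks[:t])
        fit_red, _ = _fit_ss(y, reduced)
        resid = y - fit_red
        if exhaustive:
            perms = itertools.permutations(range(n))
            count = 0
            total_perms = 0
            for perm in perms:
                y_star = fit_red + resid[list(perm)]
                y_star = y_star - y_star.mean(0)
                ss_s, dfs_s, ss_res_s, df_res_s = _sequential_ss(y_star, blocks)
                with np.errstate(divide="ignore", invalid="ignore"):
                    f_star = (ss_s[t] / max(dfs_s[t], 1)) / (ss_res_s / df_res_s)
                count += f_star >= fstats[t] - 1e-12
                total_perms += 1
            pvals[t] = count / total_perms
        else:
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                y_star = fit_red + resid[perm]
                y_star = y_star - y_star.mean(0)
                ss_s, dfs_s, ss_res_s, df_res_s = _sequential_ss(y_star, blocks)
                with np.errstate(divide="ignore", invalid="ignore"):
                    f_star = (ss_s[t] / max(dfs_s[t], 1)) / (ss_res_s / df_res_s)
                count += f_star >= fstats[t] - 1e-12
            pvals[t] = (1 + count) / (n_perm + 1)

    rows = []
    for i, name in enumerate(names):
        rows.append(
            dict(term=name, ss=ss[i], df=int(dfs[i]),
                 percent_variation=100 * ss[i] / ss_total,
                 F=fstats[i], p=pvals[i])
        )
    rows.append(
        dict(term="residual", ss=ss_res, df=int(df_res),
             percent_variation=100 * ss_res / ss_total, F=np.nan, p=np.nan)
    )
    table = pd.DataFrame(rows).set_index("term")
    return VarianceDecomposition(table, n_perm, seed, exhaustive)


# ---------------------------------------------------------------------------
# Size tests
# ---------------------------------------------------------------------------

@dataclass
class SizeTestReport:
    """One-way ANOVA on log centroid size plus pairwise Wilcoxon matrix."""

    anova_f: float
    anova_p: float
    groups: list[str]
    group_sizes: dict[str, int]
    pairwise_p: pd.DataFrame
    adjusted_p: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.anova_p < self.alpha


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (false discovery rate control)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small tie-free samples,
    normal approximation with continuity correction (mid-ranks) otherwise."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def size_tests(
    centroid_sizes: np.ndarray,
    groups,
    log_transform: bool = True,
    alpha: float = 0.05,
) -> SizeTestReport:
    """Group comparison of (log) centroid size.

    One-way ANOVA at the 5% threshold plus all pairwise Wilcoxon rank-sum
    tests with Benjamini-Hochberg step-up adjustment over the whole pairwise
    family.  Groups with fewer than 2 members are excluded with a warning.
    """
    sizes = np.asarray(centroid_sizes, dtype=float)
    if (sizes <= 0).any():
        raise ValidationError("centroid sizes must be positive")
    labels = pd.Series(groups).astype(str).to_numpy()
    values = np.log(sizes) if log_transform else sizes

    by_group: dict[str, np.ndarray] = {}
    for g in sorted(set(labels)):
        members = values[labels == g]
        if len(members) < 2:
            warnings.warn(f"group {g!r} has {len(members)} member(s); excluded", stacklevel=2)
            continue
        by_group[g] = members
    if len(by_group) < 2:
        raise ValidationError("size_tests needs at least 2 groups with >= 2 members")

    names = list(by_group)
    f, p = sps.f_oneway(*by_group.values())

    raw = pd.DataFrame(np.nan, index=names, columns=names)
    pairs = list(itertools.combinations(names, 2))
    pvec = [_wilcoxon_rank_sum(by_group[a], by_group[b]) for a, b in pairs]
    adj = benjamini_hochberg(pvec) if pvec else np.array([])
    adj_df = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b), pr, pa in zip(pairs, pvec, adj):
        raw.loc[a, b] = raw.loc[b, a] = pr
        adj_df.loc[a, b] = adj_df.loc[b, a] = pa
    np.fill_diagonal(raw.values, 1.0)
    np.fill_diagonal(adj_df.values, 1.0)

    return SizeTestReport(
        anova_f=float(f), anova_p=float(p), groups=names,
        group_sizes={g: len(v) for g, v in by_group.items()},
        pairwise_p=raw, adjusted_p=adj_df, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Allometry
# ---------------------------------------------------------------------------

@dataclass
class AllometryResult:
    """Multivariate regression of shape on log centroid size."""

    r_squared: float
    p_value: float
    coefficients: np.ndarray   # (2K,) shape change per unit log size
    n_permutations: int
    seed: int | None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def allometry_regression(
    aligned: AlignedSample,
    n_perm: int = 999,
    seed: int | None = 0,
    project: bool = True,
) -> AllometryResult:
    """Test for allometry: shape regressed on log centroid size.

    R^2 is the fraction of total shape variance explained by the regression;
    its permutation p-value shuffles sizes against shapes.
    """
    y = _shape_matrix(aligned, project)
    n = y.shape[0]
    if n < 4:
        raise ValidationError("allometry regression needs at least 4 specimens")
    x = np.log(np.asarray(aligned.centroid_sizes, dtype=float))
    if np.ptp(x) == 0:
        raise ValidationError("centroid sizes are all equal; allometry undefined")
    y = y - y.mean(0)
    xc = x - x.mean()

    def _r2(xc: np.ndarray) -> tuple[float, np.ndarray]:
        coef = (xc @ y) / (xc @ xc)
        fitted = np.outer(xc, coef)
        return float((fitted ** 2).sum() / (y ** 2).sum()), coef

    r2, coef = _r2(xc)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r2_star, _ = _r2(rng.permutation(xc))
        count += r2_star >= r2 - 1e-15
    p = (1 + count) / (n_perm + 1)
    return AllometryResult(r2, float(p), coef, n_perm, seed)
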