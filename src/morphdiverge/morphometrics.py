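"""Shape analysis and morph discrimination.

Generalized Procrustes superimposition, allometric size correction, shape
PCA, UPGMA clustering of combined trait/shape features, two-group Fisher
discriminant analysis with Wilks' lambda and leave-one-out jackknife
validation, and the associated group tests (MANOVA with pairwise post hoc
contrasts, sex t tests, parasite ANCOVA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .types import (
    TRAIT_NAMES,
    DegenerateConfigurationError,
    LandmarkSet,
)

# ---------------------------------------------------------------------------
# Superimposition
# ---------------------------------------------------------------------------


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared landmark distances from the centroid.

    Invariant to translation and rotation; scales linearly with uniform
    scaling. Raises for a fully coincident (degenerate) configuration.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size <= 0.0 or not np.isfinite(size):
        raise DegenerateConfigurationError(
            "all landmarks coincide; centroid size undefined"
        )
    return size


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, reflections disallowed) minimizing |source@R - target|."""
    m = source.T @ target
    u, _s, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


@dataclass
class SuperimposedShapes:
    """Result of generalized Procrustes superimposition."""

    aligned: np.ndarray  # (n, k, 2) Procrustes coordinates
    centroid_sizes: np.ndarray  # (n,) original sizes
    consensus: np.ndarray  # (k, 2), unit centroid size
    iterations: int
    converged: bool
    specimen_ids: list[str] = field(default_factory=list)

    @property
    def flat(self) -> np.ndarray:
        """Aligned coordinates as an (n, 2k) matrix of shape variables."""
        return self.aligned.reshape(self.aligned.shape[0], -1)


def gpa(
    sets: list[LandmarkSet] | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
    use_scale: bool = False,
) -> SuperimposedShapes:
    """Generalized Procrustes analysis of two or more configurations.

    Each configuration is centered, scaled to unit centroid size and
    rotated (SVD rotation, reflections disallowed) onto the running
    consensus; the consensus is re-estimated until it moves less than
    ``tol`` or ``max_iter`` iterations are reached. Original centroid
    sizes are returned alongside. With ``use_scale`` the stored TPS scale
    factor is applied first, so centroid sizes come out in physical units.
    """
    ids: list[str] = []
    if len(sets) and isinstance(sets[0], LandmarkSet):
        ids = [s.specimen_id for s in sets]
        arrays = [s.coords_scaled if use_scale else s.coords for s in sets]
    else:
        arrays = [np.asarray(a, dtype=float) for a in sets]
        ids = [f"specimen_{i + 1}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("GPA needs at least two configurations")
    k = arrays[0].shape[0]
    for sid, a in zip(ids, arrays):
        if a.shape != (k, 2):
            raise ValueError(f"specimen {sid!r}: landmark counts differ")

    sizes = np.empty(len(arrays))
    x = np.empty((len(arrays), k, 2))
    for i, (sid, a) in enumerate(zip(ids, arrays)):
        centered = a - a.mean(axis=0)
        try:
            sizes[i] = centroid_size(a)
        except DegenerateConfigurationError as exc:
            raise DegenerateConfigurationError(
                f"specimen {sid!r}: {exc}"
            ) from exc
        x[i] = centered / sizes[i]

    consensus = x[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(len(x)):
            x[i] = x[i] @ _optimal_rotation(x[i], consensus)
        new_consensus = x.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt(np.sum(new_consensus**2))
        change = float(np.sqrt(np.sum((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    # final rotation onto the converged consensus
    for i in range(len(x)):
        x[i] = x[i] @ _optimal_rotation(x[i], consensus)
    # canonical orientation: consensus principal axes (major axis along x,
    # 180-degree ambiguity anchored by the landmark farthest from the
    # centroid), so the result does not depend on input orientations
    evals, evecs = np.linalg.eigh(consensus.T @ consensus)
    rot = evecs[:, ::-1]
    if np.linalg.det(rot) < 0:
        rot[:, 1] *= -1
    consensus = consensus @ rot
    j = int(np.argmax(np.sum(consensus**2, axis=1)))
    if consensus[j, 0] < 0:
        consensus = -consensus
        rot = -rot
    x = x @ rot
    return SuperimposedShapes(
        aligned=x,
        centroid_sizes=sizes,
        consensus=consensus,
        iterations=iterations,
        converged=converged,
        specimen_ids=ids,
    )


# ---------------------------------------------------------------------------
# Allometric correction and shape PCA
# ---------------------------------------------------------------------------


@dataclass
class AllometryResult:
    residuals: np.ndarray  # (n, 2k) residual shape variables
    slope: np.ndarray  # (2k,) shape change per unit (log-)size
    intercept: np.ndarray  # (2k,)
    size: np.ndarray  # the regressor actually used
    pct_variance_explained: float
    size_transform: str


def allometry_residuals(
    shapes: SuperimposedShapes, size_transform: str = "raw"
) -> AllometryResult:
    """Regress each Procrustes coordinate on centroid size; keep residuals.

    ``size_transform`` is "raw" (regress on centroid size itself) or "log"
    (natural log of centroid size). Reports the percentage of total shape
    variance explained by size.
    """
    if size_transform not in ("raw", "log"):
        raise ValueError("size_transform must be 'raw' or 'log'")
    y = shapes.flat
    n = y.shape[0]
    if n <= 2:
        raise ValueError("allometric regression needs n > 2")
    s = shapes.centroid_sizes.astype(float)
    if size_transform == "log":
        s = np.log(s)
    sc = s - s.mean()
    denom = float(sc @ sc)
    if denom <= 0:
        raise ValueError("zero variance in centroid size; regression undefined")
    yc = y - y.mean(axis=0)
    slope = (sc @ yc) / denom
    fitted = np.outer(sc, slope)
    residuals = yc - fitted
    total = float(np.sum(yc**2))
    explained = float(np.sum(fitted**2))
    pct = 100.0 * explained / total if total > 0 else 0.0
    intercept = y.mean(axis=0) - slope * s.mean()
    return AllometryResult(
        residuals=residuals,
        slope=slope,
        intercept=intercept,
        size=s,
        pct_variance_explained=pct,
        size_transform=size_transform,
    )


@dataclass
class ShapePCA:
    scores: np.ndarray  # (n, m)
    loadings: np.ndarray  # (m, p) rows are components
    variance_explained: np.ndarray  # proportions, non-increasing
    eigenvalues: np.ndarray
    mean: np.ndarray


def shape_pca(x: np.ndarray) -> ShapePCA:
    """PCA of a variables matrix via SVD of the centered data."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n <= 2:
        raise ValueError("PCA needs n > 2")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    if total <= 0:
        raise ValueError("matrix has rank 0; PCA undefined")
    keep = s > s[0] * 1e-12
    scores = (u * s)[:, keep]
    # deterministic sign: largest-magnitude loading positive
    loadings = vt[keep]
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    return ShapePCA(
        scores=scores,
        loadings=loadings,
        variance_explained=eigenvalues[keep] / total,
        eigenvalues=eigenvalues[keep],
        mean=mean,
    )


def feature_matrix(
    traits: pd.DataFrame,
    pca: ShapePCA | None = None,
    n_pcs: int = 2,
    standardize: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Combine the seven linear traits with the first shape PCs.

    Columns are HeadH, UpperL1, HeadL, SnoutL, Upper2, LowerL, JawD
    followed by PC1..PCn. Columns are z-scored by default (traits and PC
    scores live on incommensurate scales; unstandardized mixing would let
    one variable dominate the clustering distance).
    """
    missing = [t for t in TRAIT_NAMES if t not in traits.columns]
    if missing:
        raise KeyError(f"trait table is missing columns: {missing}")
    cols = [traits[t].to_numpy(dtype=float) for t in TRAIT_NAMES]
    names = list(TRAIT_NAMES)
    if n_pcs > 0:
        if pca is None:
            raise ValueError("n_pcs > 0 requires a ShapePCA")
        if n_pcs > pca.scores.shape[1]:
            raise ValueError(
                f"requested {n_pcs} PCs but only {pca.scores.shape[1]} available"
            )
        if pca.scores.shape[0] != len(traits):
            raise ValueError("PCA scores and trait table have different n")
        for i in range(n_pcs):
            cols.append(pca.scores[:, i])
            names.append(f"PC{i + 1}")
    x = np.column_stack(cols)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    return x, names


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix (UPGMA)
    labels: np.ndarray  # two-cluster assignment, values 1/2
    heights: np.ndarray  # merge heights, non-decreasing (ultrametric)


def upgma(x: np.ndarray, metric: str = "euclidean") -> ClusterResult:
    """Average-linkage (UPGMA) clustering; two-cluster cut at the last merge."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("clustering needs n >= 2")
    d = pdist(x, metric=metric)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite pairwise distances")
    z = linkage(d, method="average")
    labels = fcluster(z, t=2, criterion="maxclust")
    return ClusterResult(linkage=z, labels=labels, heights=z[:, 2])


def cluster_agreement(labels: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of specimens on which a 2-cluster split matches the true
    partition, maximized over the label permutation."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    t_codes = pd.factorize(truth)[0]
    l_codes = pd.factorize(labels)[0]
    same = np.mean(l_codes == t_codes)
    return float(max(same, 1.0 - same))


# ---------------------------------------------------------------------------
# Discriminant analysis
# ---------------------------------------------------------------------------


@dataclass
class DiscriminantResult:
    wilks_lambda: float
    axis: np.ndarray  # discriminant direction (unit norm)
    group_names: list
    jackknife_pct: dict  # per-group % correctly classified, leave-one-out
    confusion: np.ndarray  # rows true, cols predicted (jackknifed)
    resubstitution_pct: dict
    ridge_used: bool = False


def _scatter_matrices(x: np.ndarray, labels: np.ndarray):
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(groups)}")
    grand = x.mean(axis=0)
    w = np.zeros((x.shape[1], x.shape[1]))
    b = np.zeros_like(w)
    means = {}
    for g in groups:
        xg = x[labels == g]
        if xg.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        mg = xg.mean(axis=0)
        means[g] = mg
        dev = xg - mg
        w += dev.T @ dev
        diff = (mg - grand)[:, None]
        b += xg.shape[0] * (diff @ diff.T)
    return groups, means, w, b


def _fisher_axis(w: np.ndarray, mean_diff: np.ndarray, ridge: float | None):
    ridge_used = False
    ww = w
    try:
        axis = np.linalg.solve(ww, mean_diff)
        if not np.all(np.isfinite(axis)) or np.linalg.cond(ww) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        if ridge is None:
            raise np.linalg.LinAlgError(
                "pooled within-group covariance is singular; pass ridge=... "
                "to regularize"
            )
        scale = np.trace(w) / w.shape[0]
        if scale <= 0:
            scale = 1.0  # fully degenerate W: fall back to an absolute ridge
        ww = w + ridge * scale * np.eye(w.shape[0])
        axis = np.linalg.solve(ww, mean_diff)
        ridge_used = True
    return axis, ridge_used


def _classify(x, axis, means, groups):
    """Prior-free nearest-centroid rule along the discriminant axis."""
    proj = x @ axis
    c0 = means[groups[0]] @ axis
    c1 = means[groups[1]] @ axis
    mid = 0.5 * (c0 + c1)
    if c0 >= c1:
        return np.where(proj >= mid, groups[0], groups[1])
    return np.where(proj < mid, groups[0], groups[1])


def lda_two_group(
    x: np.ndarray, labels: np.ndarray, ridge: float | None = None
) -> DiscriminantResult:
    """Fisher linear discriminant for two groups.

    Wilks' lambda is det(W)/det(W+B) from the within/between cross-product
    matrices. Classification is by nearest group centroid along the
    discriminant (prior-free); the jackknife refits the full discriminant
    with each specimen left out in turn and reports per-group % correct.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    groups, means, w, b = _scatter_matrices(x, labels)
    sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(w + b)
    if sign_w <= 0 or sign_t <= 0:
        if ridge is None:
            raise np.linalg.LinAlgError(
                "singular scatter matrix; Wilks' lambda undefined without ridge"
            )
        lam = np.nan
    else:
        lam = float(np.exp(logdet_w - logdet_t))
    mean_diff = means[groups[0]] - means[groups[1]]
    axis, ridge_used = _fisher_axis(w, mean_diff, ridge)
    axis = axis / np.linalg.norm(axis)

    resub = _classify(x, axis, means, groups)
    # leave-one-out jackknife: refit the whole discriminant per specimen
    jack_pred = np.empty(len(labels), dtype=object)
    idx = np.arange(len(labels))
    for i in idx:
        keep = idx != i
        g_i, m_i, w_i, _ = _scatter_matrices(x[keep], labels[keep])
        ax_i, _ = _fisher_axis(w_i, m_i[g_i[0]] - m_i[g_i[1]], ridge)
        jack_pred[i] = _classify(x[i : i + 1], ax_i, m_i, g_i)[0]

    confusion = np.zeros((2, 2), dtype=int)
    jackknife_pct = {}
    resub_pct = {}
    for gi, g in enumerate(groups):
        mask = labels == g
        for hj, h in enumerate(groups):
            confusion[gi, hj] = int(np.sum(jack_pred[mask] == h))
        jackknife_pct[g] = 100.0 * np.mean(jack_pred[mask] == g)
        resub_pct[g] = 100.0 * np.mean(resub[mask] == g)
    if np.isfinite(lam):
        # clamp floating-point noise into the statistic's (0, 1] range
        lam = float(np.clip(lam, np.finfo(float).tiny, 1.0))
    return DiscriminantResult(
        wilks_lambda=lam,
        axis=axis,
        group_names=list(groups),
        jackknife_pct=jackknife_pct,
        confusion=confusion,
        resubstitution_pct=resub_pct,
        ridge_used=ridge_used,
    )


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------


def manova_and_posthoc(
    x: np.ndarray, labels: np.ndarray, names: list[str] | None = None
) -> dict:
    """One-way two-group MANOVA plus per-variable univariate tests.

    Overall Wilks' lambda with the exact F transform for two groups
    (F = (1-lambda)/lambda * (n-p-1)/p on (p, n-p-1) df). With two groups
    the Tukey HSD post hoc comparison reduces to the pairwise t contrast,
    which is what the per-variable F test reports (F = t^2). Variables
    with zero variance are flagged undefined rather than crashing.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if names is None:
        names = [f"var{i + 1}" for i in range(x.shape[1])]
    groups, _means, w, b = _scatter_matrices(x, labels)
    n, p = x.shape
    sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(w + b)
    if sign_w <= 0 or sign_t <= 0 or n - p - 1 <= 0:
        lam = np.nan
        f_overall = np.nan
        p_overall = np.nan
    else:
        lam = float(np.exp(logdet_w - logdet_t))
        f_overall = (1.0 - lam) / lam * (n - p - 1) / p
        p_overall = float(stats.f.sf(f_overall, p, n - p - 1))
    per_variable = []
    for j, name in enumerate(names):
        col = x[:, j]
        g0 = col[labels == groups[0]]
        g1 = col[labels == groups[1]]
        if np.var(col) == 0 or (np.var(g0) == 0 and np.var(g1) == 0):
            per_variable.append(
                {"variable": name, "F": np.nan, "p": np.nan, "undefined": True}
            )
            continue
        f_j, p_j = stats.f_oneway(g0, g1)
        per_variable.append(
            {"variable": name, "F": float(f_j), "p": float(p_j), "undefined": False}
        )
    return {
        "groups": [str(g) for g in groups],
        "wilks_lambda": lam,
        "F": f_overall,
        "df": (p, n - p - 1),
        "p": p_overall,
        "per_variable": per_variable,
    }


def ancova_covariate(
    trait: np.ndarray, group: np.ndarray, covariate: np.ndarray
) -> dict:
    """Linear model trait ~ group + covariate (e.g. parasite flag).

    Reports type-II F and p for the group factor and the covariate. If the
    covariate takes a single value it is dropped with a warning flag; a
    zero-variance trait is flagged undefined.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    trait = np.asarray(trait, dtype=float)
    group = np.asarray(group)
    covariate = np.asarray(covariate, dtype=float)
    out = {"covariate_dropped": False, "undefined": False}
    if np.var(trait) == 0:
        out.update(
            undefined=True, F_group=np.nan, p_group=np.nan, F_cov=np.nan, p_cov=np.nan
        )
        return out
    df = pd.DataFrame({"trait": trait, "grp": group, "cov": covariate})
    if df["cov"].nunique() < 2:
        out["covariate_dropped"] = True
        model = smf.ols("trait ~ C(grp)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        out.update(
            F_group=float(anova.loc["C(grp)", "F"]),
            p_group=float(anova.loc["C(grp)", "PR(>F)"]),
            F_cov=np.nan,
            p_cov=np.nan,
        )
        return out
    model = smf.ols("trait ~ C(grp) + cov", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    out.update(
        F_group=float(anova.loc["C(grp)", "F"]),
        p_group=float(anova.loc["C(grp)", "PR(>F)"]),
        F_cov=float(anova.loc["cov", "F"]),
        p_cov=float(anova.loc["cov", "PR(>F)"]),
    )
    return out


def sex_ttests(
    x: np.ndarray, sex: np.ndarray, names: list[str] | None = None
) -> pd.DataFrame:
    """Two-sample t tests of each column between the sexes."""
    x = np.asarray(x, dtype=float)
    sex = np.asarray(sex)
    if names is None:
        names = [f"var{i + 1}" for i in range(x.shape[1])]
    levels = pd.unique(sex)
    if len(levels) != 2:
        raise ValueError("sex t tests need exactly two levels")
    rows = []
    for j, name in enumerate(names):
        t, p = stats.ttest_ind(x[sex == levels[0], j], x[sex == levels[1], j])
        rows.append({"variable": name, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def mean_shape_by_group(
    shapes: SuperimposedShapes, labels: np.ndarray
) -> dict:
    """Per-group landmark means and the between-group displacement field.

    Returns {"means": {group: (k, 2)}, "difference": (k, 2)} where the
    difference is mean(group2) - mean(group1) in Procrustes coordinates —
    the displacement arrows used in shape-reconstruction plots.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != shapes.aligned.shape[0]:
        raise ValueError(
            f"{labels.shape[0]} labels for {shapes.aligned.shape[0]} specimens"
        )
    groups = pd.unique(labels)
    means = {}
    for g in groups:
        mask = labels == g
        if not np.any(mask):
            raise ValueError(f"empty group {g!r}")
        means[g] = shapes.aligned[mask].mean(axis=0)
    out = {"means": means}
    if len(groups) == 2:
        out["difference"] = means[groups[1]] - means[groups[0]]
    return out
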