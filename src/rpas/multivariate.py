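"""The multivariate battery over chunk feature tables.

Pearson screening, hierarchical clustering, the KMO / Bartlett factorability
gates, the iterative EFA/PCA loop, forward-stepwise linear discriminant
analysis with Wilks' lambda entry tests, canonical-space centroid
distances, and the RA-power-to-richness (AtoR) anomaly map.

Generic numerics (linkage, eigendecompositions, distributions) are
delegated to scipy; the KMO/Bartlett statistics, the varimax-rotated
iterative-removal EFA loop, and the stepwise Wilks machinery are
implemented here.  Conventions follow the common social-science defaults:
analyses run on the correlation matrix (standardized variables), rotation
is varimax, stepwise thresholds are F-to-enter 3.84 / F-to-remove 2.71,
and classification uses equal priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "METADATA_COLUMNS",
    "split_feature_table",
    "pearson_matrix",
    "hierarchical_clusters",
    "kmo",
    "bartlett_sphericity",
    "varimax",
    "EFAResult",
    "iterative_efa",
    "LDAResult",
    "stepwise_lda",
    "centroid_distance",
    "ator_pairs",
]

#: Non-feature columns of a feature table (see features.feature_table).
METADATA_COLUMNS = ("chunk_id", "work_id", "author", "N", "w")


def split_feature_table(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series | None]:
    """Split a feature table into (numeric feature columns, author labels)."""
    feats = table.drop(columns=[c for c in METADATA_COLUMNS if c in table.columns])
    labels = table["author"] if "author" in table.columns else None
    return feats, labels


def _as_matrix(table: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(table.columns)
    x = np.asarray(table, dtype=float)
    return x, [f"x{i}" for i in range(x.shape[1])]


# ---------------------------------------------------------------------------
# Correlation screening
# ---------------------------------------------------------------------------


def pearson_matrix(
    table: pd.DataFrame | np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Pairwise Pearson r with two-tailed p-values.

    Returns (r, p, n).  p comes from the exact t reference distribution
    with n-2 df.  Zero-variance columns yield NaN entries and a warning
    naming them (never silent NaN).
    """
    x, names = _as_matrix(table)
    n = x.shape[0]
    if n < 3:
        raise ValueError("pearson_matrix needs at least 3 rows")
    sd = x.std(axis=0, ddof=1)
    dead = [names[j] for j in np.flatnonzero(sd == 0)]
    if dead:
        warnings.warn(
            f"zero-variance columns {dead}: correlations undefined (NaN)",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, np.where(sd == 0, np.nan, 1.0))
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    p[np.isnan(r)] = np.nan
    p[np.abs(r) == 1.0] = 0.0
    return (
        pd.DataFrame(r, index=names, columns=names),
        pd.DataFrame(p, index=names, columns=names),
        n,
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


def hierarchical_clusters(
    table: pd.DataFrame | np.ndarray,
    method: str = "ward",
    metric: str = "squared_euclidean",
    k: int = 3,
) -> pd.Series:
    """Cut an agglomerative dendrogram into exactly ``k`` clusters.

    ``method='ward'`` (minimum-variance; squared-Euclidean geometry only)
    or ``'nearest_neighbor'`` (single linkage) with squared-Euclidean or
    cosine dissimilarity.  Labels are 1..k in first-appearance order;
    scipy's lowest-index merge rule makes the result deterministic for a
    given row order.
    """
    x, _ = _as_matrix(table)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the number of rows ({x.shape[0]})")
    if method == "ward":
        if metric != "squared_euclidean":
            raise ValueError("Ward linkage is only defined for squared_euclidean")
        z = linkage(x, method="ward")
    elif method == "nearest_neighbor":
        scipy_metric = {"squared_euclidean": "sqeuclidean", "cosine": "cosine"}.get(
            metric
        )
        if scipy_metric is None:
            raise ValueError(f"unknown metric {metric!r}")
        z = linkage(pdist(x, metric=scipy_metric), method="single")
    else:
        raise ValueError(f"unknown method {method!r}")
    raw = fcluster(z, t=k, criterion="maxclust")
    # renumber clusters by first appearance so labels are row-order stable
    remap: dict[int, int] = {}
    labels = np.array([remap.setdefault(c, len(remap) + 1) for c in raw])
    index = table.index if isinstance(table, pd.DataFrame) else None
    return pd.Series(labels, index=index, name="cluster")


# ---------------------------------------------------------------------------
# Factorability gates
# ---------------------------------------------------------------------------


def _correlation(x: np.ndarray, names: Sequence[str]) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    dead = [names[j] for j in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(f"zero-variance columns: {dead}")
    return np.corrcoef(x, rowvar=False)


def _check_invertible(r: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(r, tol=1e-10) < r.shape[0]:
        close = [
            (names[i], names[j])
            for i in range(r.shape[0])
            for j in range(i + 1, r.shape[0])
            if abs(r[i, j]) > 1.0 - 1e-8
        ]
        raise ValueError(
            "correlation matrix is singular"
            + (f"; near-duplicate columns: {close}" if close else "")
        )


def kmo(table: pd.DataFrame | np.ndarray) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy (overall).

    Ratio of summed squared correlations to summed squared correlations
    plus summed squared anti-image partial correlations; values above 0.5
    are conventionally adequate for factor analysis.
    """
    x, names = _as_matrix(table)
    r = _correlation(x, names)
    _check_invertible(r, names)
    inv = np.linalg.inv(r)
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = np.sum(r[off] ** 2)
    q2 = np.sum(partial[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett_sphericity(table: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Bartlett's test of sphericity: H0 is an identity correlation matrix.

    chi2 = -(n - 1 - (2p + 5) / 6) * ln|R| with p(p-1)/2 df.
    """
    x, names = _as_matrix(table)
    n, p = x.shape
    r = _correlation(x, names)
    _check_invertible(r, names)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    return float(chi2), float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Iterative EFA / PCA
# ---------------------------------------------------------------------------


def varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal varimax rotation of a loading matrix (Kaiser criterion)."""
    p, k = loadings.shape
    if k < 2:
        return loadings.copy()
    rot = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - lam @ np.diag(np.sum(lam**2, axis=0)) / p)
        )
        rot = u @ vt
        new_var = np.sum(s)
        if new_var - var < tol * max(var, 1.0):
            break
        var = new_var
    return loadings @ rot


@dataclass(frozen=True)
class EFAResult:
    """Outcome of the iterative EFA/PCA loop."""

    retained_factors: int
    loadings: pd.DataFrame  # variable x factor, varimax-rotated
    variance_explained: tuple[float, ...]  # per retained factor, % of total
    total_variance: float  # %
    removed_variables: tuple[str, ...]
    eigenvalues: tuple[float, ...]  # final-iteration spectrum, descending
    kmo: float
    bartlett_chi2: float
    bartlett_p: float


def iterative_efa(
    table: pd.DataFrame | np.ndarray,
    loading_threshold: float = 0.30,
) -> EFAResult:
    """Principal-component EFA with iterative weak-variable removal.

    Each pass extracts components of the correlation matrix, keeps factors
    with eigenvalue > 1 (Kaiser's rule), varimax-rotates, and drops the
    variable whose largest absolute rotated loading is smallest, if that
    loading falls below ``loading_threshold``; the loop repeats until every
    surviving variable loads at or above the threshold.  Variance explained
    is reported on the final variable set.
    """
    if isinstance(table, np.ndarray):
        table = pd.DataFrame(table, columns=[f"x{i}" for i in range(table.shape[1])])
    working = table.copy()
    removed: list[str] = []
    if working.shape[1] < 3:
        raise ValueError("iterative_efa needs at least 3 variables")
    while True:
        x, names = _as_matrix(working)
        overall_kmo = kmo(working)
        if overall_kmo <= 0.5:
            warnings.warn(
                f"KMO {overall_kmo:.3f} <= 0.5: sampling adequacy is poor",
                stacklevel=2,
            )
        chi2, bart_p = bartlett_sphericity(working)
        r = np.corrcoef(x, rowvar=False)
        eigval, eigvec = np.linalg.eigh(r)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        # Kaiser's rule with a tolerance so an exactly-spherical spectrum
        # (all eigenvalues 1 to rounding) retains nothing
        m = int(np.sum(eigval > 1.0 + 1e-9))
        if m == 0:
            warnings.warn(
                "no eigenvalue exceeds 1: nothing to retain under Kaiser's rule",
                stacklevel=2,
            )
            return EFAResult(
                retained_factors=0,
                loadings=pd.DataFrame(index=names),
                variance_explained=(),
                total_variance=0.0,
                removed_variables=tuple(removed),
                eigenvalues=tuple(float(v) for v in eigval),
                kmo=overall_kmo,
                bartlett_chi2=chi2,
                bartlett_p=bart_p,
            )
        load = eigvec[:, :m] * np.sqrt(eigval[:m])
        load = varimax(load)
        # deterministic sign: dominant loading of each factor is positive
        signs = np.sign(load[np.argmax(np.abs(load), axis=0), range(m)])
        signs[signs == 0] = 1.0
        load = load * signs
        max_abs = np.max(np.abs(load), axis=1)
        worst = int(np.argmin(max_abs))
        if max_abs[worst] < loading_threshold:
            removed.append(names[worst])
            working = working.drop(columns=[names[worst]])
            if working.shape[1] < 3:
                raise ValueError(
                    "iterative removal left fewer than 3 variables "
                    f"(removed: {removed})"
                )
            continue
        p = len(names)
        ss_loadings = np.sum(load**2, axis=0)
        per_factor = tuple(float(100.0 * s / p) for s in ss_loadings)
        cols = [f"F{i + 1}" for i in range(m)]
        return EFAResult(
            retained_factors=m,
            loadings=pd.DataFrame(load, index=names, columns=cols),
            variance_explained=per_factor,
            total_variance=float(sum(per_factor)),
            removed_variables=tuple(removed),
            eigenvalues=tuple(float(v) for v in eigval),
            kmo=overall_kmo,
            bartlett_chi2=chi2,
            bartlett_p=bart_p,
        )


# ---------------------------------------------------------------------------
# Stepwise linear discriminant analysis
# ---------------------------------------------------------------------------


def _sscp(x: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group and total SSCP matrices."""
    grand = x.mean(axis=0)
    t = (x - grand).T @ (x - grand)
    w = np.zeros_like(t)
    for g in np.unique(groups):
        xg = x[groups == g]
        cg = xg - xg.mean(axis=0)
        w += cg.T @ cg
    return w, t


def _wilks(x: np.ndarray, groups: np.ndarray, cols: Sequence[int]) -> float:
    if not cols:
        return 1.0
    sub = x[:, list(cols)]
    w, t = _sscp(sub, groups)
    sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(t)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError("singular SSCP matrix")
    return float(np.exp(logdet_w - logdet_t))


@dataclass(frozen=True)
class LDAResult:
    """Stepwise LDA outcome: selection path, canonical space, classification."""

    selected_variables: tuple[str, ...]
    functions: pd.DataFrame  # variable x function canonical coefficients
    eigenvalues: tuple[float, ...]
    wilks: tuple[tuple[float, float], ...]  # per function: (lambda, p)
    centroids: Mapping[str, np.ndarray]  # group -> canonical coordinates
    classification: pd.Series  # row -> predicted group
    entry_f: Mapping[str, float] = field(default_factory=dict)

    @property
    def accuracy(self) -> float | None:
        return None  # computed by callers holding the true labels


def stepwise_lda(
    table: pd.DataFrame | np.ndarray,
    labels: Sequence[str],
    f_enter: float = 3.84,
    f_remove: float = 2.71,
) -> LDAResult:
    """Forward-stepwise LDA with Wilks' lambda partial-F entry/removal.

    At each step the candidate minimizing Wilks' lambda enters if its
    partial F exceeds ``f_enter``; previously entered variables whose
    partial F drops below ``f_remove`` leave again.  Canonical functions
    are extracted on the selected set (coefficients scaled to unit pooled
    within-group variance; at most min(groups - 1, variables) functions),
    each tested by the chi-square approximation to Wilks' lambda.
    Classification is in-sample via Fisher linear classification functions
    with equal priors.  If no variable passes the entry test the result has
    an empty selection and every row is assigned to the alphabetically
    first group.
    """
    x, names = _as_matrix(table)
    groups = np.asarray(labels)
    if x.shape[0] != groups.shape[0]:
        raise ValueError("labels length does not match the number of rows")
    uniq, counts = np.unique(groups, return_counts=True)
    g = len(uniq)
    if g < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 rows each")
    n = x.shape[0]
    index = table.index if isinstance(table, pd.DataFrame) else pd.RangeIndex(n)

    selected: list[int] = []
    entry_f: dict[str, float] = {}
    current_lambda = 1.0
    seen_states: set[frozenset[int]] = set()
    while True:
        state = frozenset(selected)
        if state in seen_states:  # enter/remove cycle: stop at current set
            break
        seen_states.add(state)
        changed = False
        # entry: best candidate by resulting lambda
        best_j, best_lambda = None, None
        for j in range(x.shape[1]):
            if j in selected:
                continue
            try:
                lam = _wilks(x, groups, selected + [j])
            except np.linalg.LinAlgError:
                continue
            if best_lambda is None or lam < best_lambda:
                best_j, best_lambda = j, lam
        if best_j is not None and best_lambda < current_lambda:
            p_in = len(selected)
            f_stat = ((n - g - p_in) / (g - 1)) * (current_lambda / best_lambda - 1.0)
            if f_stat > f_enter:
                selected.append(best_j)
                entry_f[names[best_j]] = float(f_stat)
                current_lambda = best_lambda
                changed = True
        # removal: weakest included variable by partial F
        if len(selected) > 1:
            p_in = len(selected)
            worst_j, worst_f = None, None
            for j in selected:
                rest = [c for c in selected if c != j]
                lam_rest = _wilks(x, groups, rest)
                f_stat = ((n - g - (p_in - 1)) / (g - 1)) * (
                    lam_rest / current_lambda - 1.0
                )
                if worst_f is None or f_stat < worst_f:
                    worst_j, worst_f = j, f_stat
            if worst_f is not None and worst_f < f_remove:
                selected.remove(worst_j)
                current_lambda = _wilks(x, groups, selected)
                changed = True
        if not changed:
            break

    sel_names = tuple(names[j] for j in selected)
    if not selected:
        fallback = str(sorted(uniq)[0])
        return LDAResult(
            selected_variables=(),
            functions=pd.DataFrame(),
            eigenvalues=(),
            wilks=(),
            centroids={},
            classification=pd.Series([fallback] * n, index=index, name="predicted"),
            entry_f={},
        )

    xs = x[:, selected]
    w, t = _sscp(xs, groups)
    b = t - w
    try:
        # generalized symmetric eigenproblem B v = lambda W v
        from scipy.linalg import eigh as geigh

        eigval, eigvec = geigh(b, w)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "within-group covariance is singular; remove collinear variables"
        ) from exc
    order = np.argsort(eigval)[::-1]
    q = min(g - 1, len(selected))
    eigval = np.maximum(eigval[order][:q], 0.0)
    vec = eigvec[:, order][:, :q]
    # scale: unit pooled within-group variance of each discriminant score
    within_cov = w / (n - g)
    scale = np.sqrt(np.einsum("ij,jk,ki->i", vec.T, within_cov, vec))
    vec = vec / scale
    # deterministic sign convention
    signs = np.sign(vec[np.argmax(np.abs(vec), axis=0), range(q)])
    signs[signs == 0] = 1.0
    vec = vec * signs

    # per-function Wilks' lambda significance (chi-square approximation)
    wilks_rows = []
    p_sel = len(selected)
    for m in range(q):
        lam = float(np.prod(1.0 / (1.0 + eigval[m:])))
        chi2 = -(n - 1 - (p_sel + g) / 2.0) * np.log(lam)
        df = (p_sel - m) * (g - 1 - m)
        wilks_rows.append((lam, float(stats.chi2.sf(chi2, df))))

    scores = xs @ vec
    centroids = {
        str(gname): scores[groups == gname].mean(axis=0) for gname in uniq
    }

    # Fisher linear classification functions on the selected variables
    inv_cov = np.linalg.inv(within_cov)
    means = {str(gname): xs[groups == gname].mean(axis=0) for gname in uniq}
    disc = np.column_stack(
        [
            xs @ inv_cov @ means[str(gname)]
            - 0.5 * means[str(gname)] @ inv_cov @ means[str(gname)]
            for gname in uniq
        ]
    )
    predicted = [str(uniq[i]) for i in np.argmax(disc, axis=1)]

    return LDAResult(
        selected_variables=sel_names,
        functions=pd.DataFrame(
            vec, index=sel_names, columns=[f"LD{i + 1}" for i in range(q)]
        ),
        eigenvalues=tuple(float(v) for v in eigval),
        wilks=tuple(wilks_rows),
        centroids=centroids,
        classification=pd.Series(predicted, index=index, name="predicted"),
        entry_f=entry_f,
    )


def centroid_distance(
    result: LDAResult | pd.DataFrame | np.ndarray,
    group_a: str,
    group_b: str,
    dims: int = 3,
    labels: Sequence[str] | None = None,
) -> float:
    """Euclidean distance between two group centroids.

    On an :class:`LDAResult` the centroids live in canonical-function
    space (truncated to the first ``dims`` functions); on a raw coordinate
    table ``labels`` assigns rows to groups and the first ``dims`` columns
    are used.
    """
    if isinstance(result, LDAResult):
        try:
            ca, cb = result.centroids[group_a], result.centroids[group_b]
        except KeyError as exc:
            raise ValueError(f"group {exc.args[0]!r} not present") from exc
        d = min(dims, len(ca))
        return float(np.linalg.norm(ca[:d] - cb[:d]))
    if labels is None:
        raise ValueError("labels are required for a raw coordinate table")
    x, _ = _as_matrix(result)
    groups = np.asarray(labels)
    d = min(dims, x.shape[1])
    out = []
    for gname in (group_a, group_b):
        mask = groups == gname
        if not mask.any():
            raise ValueError(f"group {gname!r} is empty")
        out.append(x[mask, :d].mean(axis=0))
    return float(np.linalg.norm(out[0] - out[1]))


# ---------------------------------------------------------------------------
# AtoR anomaly map
# ---------------------------------------------------------------------------


def ator_pairs(
    table: pd.DataFrame,
    r_percentile: float = 90.0,
    a_percentile: float = 10.0,
) -> pd.DataFrame:
    """Per-chunk (A, R) pairs with a high-richness / low-RA outlier flag.

    A chunk is flagged when its richness is at or above the corpus
    ``r_percentile`` AND its aggregate RA power at or below the
    ``a_percentile`` — the signature of unusually rich but referentially
    flat (abstract, low-concreteness) writing.
    """
    missing = {"R"} - set(table.columns)
    if "A" not in table.columns:
        a_cols = [c for c in table.columns if c.startswith("A_")]
        if not a_cols:
            missing.add("A")
    if missing:
        raise ValueError(f"feature table lacks columns: {sorted(missing)}")
    a = table["A"] if "A" in table.columns else table[a_cols].sum(axis=1)
    r = table["R"]
    r_cut = np.percentile(r, r_percentile)
    a_cut = np.percentile(a, a_percentile)
    out = pd.DataFrame({"A": a, "R": r})
    for col in ("chunk_id", "work_id", "author"):
        if col in table.columns:
            out.insert(0, col, table[col])
    out["outlier"] = (r >= r_cut) & (a <= a_cut)
    return out
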