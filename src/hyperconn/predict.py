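"""Group statistics and the iterated cross-validated outcome-prediction model.

The predictive procedure repeats, over many random k-fold splits of the
cohort: (1) PCA of the training subjects' regional features, keeping 10
components; (2) a two-class Fisher discriminant between the study groups in
component space; (3) back-projection of the discriminant axis to regions and
selection of the 16 regions carrying the most energy (squared coefficient)
on it; (4) an ordinary-least-squares linear model of the behavior score on
those regions; (5) prediction of the held-out fold.  After all iterations
the pooled out-of-bag predictions are compared to the truth by Pearson
correlation, and each region's selection frequency is reported.

Every training-fold statistic (PCA mean/loadings, discriminant axis, region
selection, regression coefficients) is computed from training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "FeatureMatrix",
    "CVConfig",
    "PredictionResult",
    "kfold_split",
    "pca_reduce",
    "discriminant_axis",
    "select_regions",
    "fit_linear_model",
    "run_cv_prediction",
    "mann_whitney_u",
    "auroc",
    "pearson_r",
]


@dataclass
class FeatureMatrix:
    """Subjects x regions feature table with scores and group labels."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    weeks: np.ndarray
    region_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.groups = np.asarray(self.groups)
        self.weeks = np.asarray(self.weeks)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.groups) == len(self.weeks) == n):
            raise ValueError("row counts of X, y, groups, weeks must agree")
        if self.X.shape[1] != len(self.region_names):
            raise ValueError("region_names length must match feature columns")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("features and scores must be finite (no missing values)")

    @classmethod
    def from_records(cls, records) -> "FeatureMatrix":
        """Build from a list of cohort SubjectRecords."""
        X = np.stack([r.regional_features for r in records])
        names = records[0].connectome.node_names
        return cls(
            X=X,
            y=np.array([r.behavior_score for r in records]),
            groups=np.array([r.group for r in records]),
            weeks=np.array([r.week for r in records]),
            region_names=list(names),
        )


@dataclass
class CVConfig:
    """Cross-validation scheme of the iterated prediction model.

    ``scheme="weekly"`` filters to one week (``week`` must be given) and
    defaults to 4 folds; ``scheme="integral"`` pools all weeks and defaults
    to 3 folds.
    """

    scheme: str = "integral"
    week: int | None = None
    k_folds: int | None = None
    n_iterations: int = 1000
    n_components: int = 10
    n_selected_regions: int = 16
    bootstrap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("weekly", "integral"):
            raise ValueError("scheme must be 'weekly' or 'integral'")
        if self.k_folds is None:
            self.k_folds = 4 if self.scheme == "weekly" else 3
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")


@dataclass
class PredictionResult:
    """Pooled out-of-bag predictions and region-selection frequencies.

    ``selection_frequency`` counts per fold-model (the primary report);
    ``selection_frequency_per_iteration`` counts an iteration once if any of
    its fold models selected the region.
    """

    oob_iteration: np.ndarray
    oob_subject: np.ndarray
    oob_true: np.ndarray
    oob_pred: np.ndarray
    pooled_r: float
    per_iteration_r: np.ndarray
    selection_frequency: np.ndarray
    selection_frequency_per_iteration: np.ndarray
    region_names: list[str]
    n_iterations_used: int
    n_folds_skipped: int = 0


# ---------------------------------------------------------------------------
# building blocks


def kfold_split(n: int, k: int, rng: np.random.Generator | int):
    """Random permutation split into k near-equal folds.

    Returns a list of (train_idx, test_idx); fold sizes differ by at most 1,
    folds are pairwise disjoint and cover all indices.
    """
    if k > n:
        raise ValueError(f"cannot split {n} subjects into {k} folds")
    if k < 2:
        raise ValueError("k must be at least 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i, test in enumerate(folds):
        train = np.concatenate([f for j, f in enumerate(folds) if j != i])
        out.append((np.sort(train), np.sort(test)))
    return out


def pca_reduce(X_train: np.ndarray, n_components: int):
    """PCA of the training rows via SVD of the centered matrix.

    Returns ``(scores, loadings, mean_vector)`` with orthonormal loading
    columns ordered by decreasing variance.  Rank-deficient input keeps only
    the components with nonzero variance (truncation shows in the returned
    column count).
    """
    X = np.asarray(X_train, dtype=float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, cols)={min(n - 1, p)}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(n, p) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank == 0:
        raise ValueError("PCA input has no variance (constant rows)")
    keep = min(n_components, rank)
    loadings = vt[:keep].T
    scores = u[:, :keep] * s[:keep]
    return scores, loadings, mean


def discriminant_axis(
    scores: np.ndarray, group_labels: np.ndarray, ridge: float = 1e-8
) -> np.ndarray:
    """Two-class Fisher discriminant axis in component space.

    ``a`` solves ``(S_W + ridge*scale*I) a = mu1 - mu0`` with S_W the pooled
    within-class scatter (the ridge regularizes singular scatter).  The axis
    is unit-normalized with its sign fixed so the second class's mean
    projects positive.
    """
    labels = np.asarray(group_labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("discriminant analysis needs exactly two groups in training data")
    x0 = scores[labels == classes[0]]
    x1 = scores[labels == classes[1]]
    d = scores.shape[1]
    sw = np.zeros((d, d))
    for xg in (x0, x1):
        c = xg - xg.mean(axis=0)
        sw += c.T @ c
    scale = np.trace(sw) / d if np.trace(sw) > 0 else 1.0
    diff = x1.mean(axis=0) - x0.mean(axis=0)
    a = np.linalg.solve(sw + ridge * scale * np.eye(d), diff)
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("degenerate discriminant axis (identical group means)")
    a = a / norm
    if diff @ a < 0:
        a = -a
    return a


def select_regions(region_axis: np.ndarray, n_selected: int) -> np.ndarray:
    """Indices of the regions with most energy (squared coefficient) on the
    discriminant axis; ties broken by lower region index."""
    axis = np.asarray(region_axis, dtype=float)
    if n_selected > axis.size:
        raise ValueError("cannot select more regions than the axis length")
    energy = axis**2
    order = np.lexsort((np.arange(axis.size), -energy))
    return np.sort(order[:n_selected])


def fit_linear_model(X_train: np.ndarray, y_train: np.ndarray):
    """Ordinary least squares with intercept; minimum-norm solution when the
    system is underdetermined.  Constant columns are dropped (coefficient 0).

    Returns ``(coefficients, intercept, dropped_columns)``.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    ptp = X.max(axis=0) - X.min(axis=0) if X.size else np.zeros(X.shape[1])
    keep = ptp > 0
    design = np.column_stack([np.ones(len(y)), X[:, keep]])
    sol, *_ = np.linalg.lstsq(design, y, rcond=None)
    coef = np.zeros(X.shape[1])
    coef[keep] = sol[1:]
    return coef, float(sol[0]), np.flatnonzero(~keep)


def pearson_r(a, b) -> float:
    """Product-moment correlation; rejects constant or too-short input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("pearson_r needs two equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("pearson_r is undefined for constant input")
    am = a - a.mean()
    bm = b - b.mean()
    return float(am @ bm / np.sqrt((am @ am) * (bm @ bm)))


# ---------------------------------------------------------------------------
# iterated CV engine


def run_cv_prediction(data: FeatureMatrix, cfg: CVConfig) -> PredictionResult:
    """The iterated cross-validated prediction model (see module docstring).

    Deterministic given ``cfg.seed``.  Iterations redraw the folds each time
    (``cfg.bootstrap=True`` instead resamples subjects with replacement and
    predicts the out-of-bag subjects).  Folds whose training rows contain a
    single group are skipped and counted in ``n_folds_skipped``.
    """
    if cfg.scheme == "weekly":
        if cfg.week is None:
            raise ValueError("weekly scheme requires cfg.week")
        sel = np.flatnonzero(data.weeks == cfg.week)
    else:
        sel = np.arange(len(data.y))
    X = data.X[sel]
    y = data.y[sel]
    groups = data.groups[sel]
    n, p = X.shape
    if n < cfg.k_folds:
        raise ValueError(f"{n} subjects cannot be split into {cfg.k_folds} folds")

    rng = np.random.default_rng(cfg.seed)
    it_col: list[int] = []
    subj_col: list[int] = []
    true_col: list[float] = []
    pred_col: list[float] = []
    sel_counts_fold = np.zeros(p)
    sel_counts_iter = np.zeros(p)
    per_iter_r = np.full(cfg.n_iterations, np.nan)
    n_models = 0
    n_skipped = 0

    for it in range(cfg.n_iterations):
        if cfg.bootstrap:
            train_all = np.sort(rng.integers(0, n, n))
            test_all = np.setdiff1d(np.arange(n), train_all)
            splits = [(train_all, test_all)] if len(test_all) else []
        else:
            splits = kfold_split(n, cfg.k_folds, rng)
        iter_true: list[float] = []
        iter_pred: list[float] = []
        iter_regions = np.zeros(p, dtype=bool)
        for train, test in splits:
            if len(np.unique(groups[train])) < 2:
                n_skipped += 1
                continue
            n_comp = min(cfg.n_components, len(train) - 1)
            scores, loadings, _ = pca_reduce(X[train], n_comp)
            a = discriminant_axis(scores, groups[train])
            region_axis = loadings @ a
            regions = select_regions(region_axis, min(cfg.n_selected_regions, p))
            coef, intercept, _ = fit_linear_model(X[train][:, regions], y[train])
            y_hat = X[test][:, regions] @ coef + intercept
            it_col.extend([it] * len(test))
            subj_col.extend(sel[test].tolist())
            true_col.extend(y[test].tolist())
            pred_col.extend(y_hat.tolist())
            iter_true.extend(y[test].tolist())
            iter_pred.extend(y_hat.tolist())
            sel_counts_fold[regions] += 1
            iter_regions[regions] = True
            n_models += 1
        sel_counts_iter += iter_regions
        if len(iter_true) >= 3 and np.ptp(iter_true) > 0 and np.ptp(iter_pred) > 0:
            per_iter_r[it] = pearson_r(iter_true, iter_pred)

    oob_true = np.array(true_col)
    oob_pred = np.array(pred_col)
    pooled = pearson_r(oob_true, oob_pred) if len(oob_true) >= 3 else np.nan
    freq_fold = sel_counts_fold / n_models if n_models else sel_counts_fold
    freq_iter = sel_counts_iter / cfg.n_iterations
    return PredictionResult(
        oob_iteration=np.array(it_col),
        oob_subject=np.array(subj_col),
        oob_true=oob_true,
        oob_pred=oob_pred,
        pooled_r=float(pooled),
        per_iteration_r=per_iter_r,
        selection_frequency=freq_fold,
        selection_frequency_per_iteration=freq_iter,
        region_names=list(data.region_names),
        n_iterations_used=cfg.n_iterations,
        n_folds_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# group-discrimination statistics


def _norm_sf(z: float) -> float:
    return 0.5 * (1.0 - erf(z / sqrt(2.0)))


def _u_null_distribution(nx: int, ny: int) -> np.ndarray:
    """Exact null pmf of U by enumerating all rank assignments (no ties)."""
    n = nx + ny
    counts = np.zeros(nx * ny + 1)
    base = nx * (nx + 1) // 2
    for ranks in combinations(range(1, n + 1), nx):
        counts[sum(ranks) - base] += 1
    return counts / comb(n, nx)


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U statistic (for x) with midrank ties.

    The p-value is exact (enumeration of the rank-assignment null) when
    n_x + n_y <= 12 and there are no ties; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    has_ties = len(np.unique(pooled)) < nx + ny

    if nx + ny <= 12 and not has_ties:
        pmf = _u_null_distribution(nx, ny)
        u_int = int(round(u_x))
        cdf = float(pmf[: u_int + 1].sum())
        sf = float(pmf[u_int:].sum())
        if alternative == "two-sided":
            p = 2.0 * min(cdf, sf)
        elif alternative == "greater":
            p = sf
        else:
            p = cdf
        return u_x, float(min(1.0, p))

    mu = nx * ny / 2.0
    n = nx + ny
    _, t = np.unique(pooled, return_counts=True)
    tie_term = np.sum(t**3 - t) / (n * (n - 1)) if n > 1 else 0.0
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_x, 1.0
    sd = sqrt(var)
    if alternative == "two-sided":
        z = (abs(u_x - mu) - 0.5) / sd
        p = 2.0 * _norm_sf(max(z, 0.0))
    elif alternative == "greater":
        p = _norm_sf((u_x - mu - 0.5) / sd)
    else:
        p = _norm_sf((mu - u_x - 0.5) / sd)
    return u_x, float(min(1.0, p))


def auroc(scores, binary_labels) -> float:
    """Probability that a random positive outranks a random negative
    (pair counting; ties count 1/2).  The positive class is the
    lexicographically larger label."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(binary_labels)
    classes = np.unique(lab)
    if len(classes) != 2:
        raise ValueError("auroc needs both classes present")
    pos = s[lab == classes[1]]
    neg = s[lab == classes[0]]
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))
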