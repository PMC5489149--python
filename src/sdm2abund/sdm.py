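"""Stage 1 — multi-algorithm habitat-suitability ensemble.

For a species' presence cells on a working grid, each repetition draws fresh
pseudo-absences from unoccupied land cells, makes a stratified 75/25
train/test split, fits seven suitability algorithms (Bioclim, Domain,
Mahalanobis distance, binomial GLM with subset selection, random forest,
support vector machine, and a MaxEnt-style penalized logistic model on
expanded features), evaluates each by AUC on the test set after correcting
for spatial sorting bias, keeps the best algorithm, converts its map to a
presence threshold maximising sensitivity + specificity, and min-max
standardizes map and threshold to [0, 1]. The ensemble output is the
per-cell mean standardized suitability and mean threshold over (by default)
100 repetitions, with the per-cell relative standard error of the mean
tracked as a stability diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import cKDTree
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .grids import (
    DegenerateScaleError,
    GridSpec,
    RasterLayer,
    minmax_standardize,
)

__all__ = [
    "ALGORITHM_PRIORITY",
    "EnsembleConfig",
    "FeatureTable",
    "RepetitionResult",
    "EnsembleSuitability",
    "build_feature_table",
    "sample_pseudo_absences",
    "split_train_test",
    "score_bioclim",
    "score_domain",
    "score_mahalanobis",
    "fit_score_glm",
    "fit_score_ml",
    "auc",
    "ssb_adjust",
    "max_sss_threshold",
    "run_ensemble",
    "InsufficientAbsencesError",
    "SplitError",
    "EnsembleError",
    "AlgorithmSkipped",
]

# Fixed tie-break priority when several algorithms attain the maximal AUC.
ALGORITHM_PRIORITY = (
    "maxent_like",
    "random_forest",
    "svm",
    "glm",
    "mahalanobis",
    "domain",
    "bioclim",
)


class InsufficientAbsencesError(ValueError):
    """Fewer unoccupied land cells than requested pseudo-absences."""


class SplitError(ValueError):
    """Too few presences or absences to form a train/test split."""


class EnsembleError(RuntimeError):
    """All repetitions were degenerate."""


class AlgorithmSkipped(RuntimeError):
    """An algorithm could not be fitted for this repetition."""


@dataclass
class EnsembleConfig:
    """Knobs for :func:`run_ensemble`.

    Defaults mirror the working protocol: 100 repetitions, 500
    pseudo-absences at a 10 km working grid (use 5000 at 1 km), 25% of the
    presence/absence set held out for testing.
    """

    n_reps: int = 100
    n_pseudo_absences: int = 500
    test_fraction: float = 0.25
    seed: int = 0
    algorithms: tuple[str, ...] = ALGORITHM_PRIORITY
    external_scorers: dict = field(default_factory=dict)
    rse_floor: float = 1e-6  # cells with smaller mean are excluded from RSE


@dataclass
class FeatureTable:
    """Environmental features for every land cell, in land-cell order.

    ``cont`` holds the continuous layers as an (n_land, p) matrix; ``cat``
    the single categorical land-class code per cell (or None); ``rows`` /
    ``cols`` map land-cell index back to the grid; ``x`` / ``y`` are cell
    centroids in metres.
    """

    cont: np.ndarray
    cat: np.ndarray | None
    cont_names: list[str]
    rows: np.ndarray
    cols: np.ndarray
    x: np.ndarray
    y: np.ndarray
    grid: GridSpec

    @property
    def n_cells(self) -> int:
        return self.cont.shape[0]

    def onehot(self) -> tuple[np.ndarray, list[str]]:
        """Continuous columns plus dummy-coded land class (first level
        dropped as reference)."""
        if self.cat is None:
            return self.cont, list(self.cont_names)
        levels = np.unique(self.cat)
        dummies = (self.cat[:, None] == levels[None, 1:]).astype(float)
        X = np.column_stack([self.cont, dummies])
        names = list(self.cont_names) + [f"class_{lv}" for lv in levels[1:]]
        return X, names


def build_feature_table(
    env_layers: list[RasterLayer], land_mask: np.ndarray
) -> FeatureTable:
    """Assemble per-land-cell features from an environmental raster stack.

    Continuous and binary layers become columns of ``cont``; at most one
    categorical layer is allowed and becomes the land-class code.
    """
    grid = env_layers[0].grid
    land_mask = np.asarray(land_mask, dtype=bool)
    rows, cols = np.nonzero(land_mask)
    cont_cols, names = [], []
    cat = None
    for layer in env_layers:
        if layer.grid != grid:
            raise ValueError("environmental layers must share one grid")
        vals = layer.values[rows, cols]
        if layer.kind == "categorical":
            if cat is not None:
                raise ValueError("at most one categorical layer is supported")
            cat = np.asarray(vals).astype(int)
        else:
            cont_cols.append(np.asarray(vals, dtype=float))
            names.append(layer.name or f"var{len(names)}")
    ee, nn = grid.cell_centroids()
    return FeatureTable(
        cont=np.column_stack(cont_cols) if cont_cols else np.empty((len(rows), 0)),
        cat=cat,
        cont_names=names,
        rows=rows,
        cols=cols,
        x=ee[rows, cols],
        y=nn[rows, cols],
        grid=grid,
    )


# ---------------------------------------------------------------------------
# sampling & splitting
# ---------------------------------------------------------------------------

def sample_pseudo_absences(
    presence: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` distinct unoccupied land cells uniformly without
    replacement.

    ``presence`` is a boolean vector over land cells. Draws that would land
    on occupied cells never enter the absence set (those cells are already
    presences), so sampling is directly from the unoccupied pool.
    """
    pool = np.nonzero(~np.asarray(presence, dtype=bool))[0]
    if pool.size < n:
        raise InsufficientAbsencesError(
            f"only {pool.size} unoccupied land cells available, need {n}"
        )
    return rng.choice(pool, size=n, replace=False)


def split_train_test(
    n_presence: int,
    n_absence: int,
    test_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split; returns boolean test masks for the presence
    and absence sets. Each class contributes ``floor(f*n)`` (at least 1) test
    points, preserving the class ratio within rounding."""
    if n_presence < 2 or n_absence < 2:
        raise SplitError("need at least 2 presences and 2 absences to split")
    masks = []
    for n in (n_presence, n_absence):
        n_test = max(1, int(np.floor(test_fraction * n)))
        if n_test >= n:
            n_test = n - 1
        m = np.zeros(n, dtype=bool)
        m[rng.choice(n, size=n_test, replace=False)] = True
        masks.append(m)
    return masks[0], masks[1]


# ---------------------------------------------------------------------------
# profile (presence-only) scorers
# ---------------------------------------------------------------------------

def score_bioclim(train_cont: np.ndarray, query_cont: np.ndarray) -> np.ndarray:
    """Bioclim envelope score.

    Per variable, a query value's percentile within the training presences is
    ``p = (#strictly below + 0.5 * #equal) / n``; the variable score is
    ``2*min(p, 1-p)`` and the overall score the minimum over variables.
    Zero-variance variables are skipped.
    """
    train = np.asarray(train_cont, dtype=float)
    query = np.atleast_2d(np.asarray(query_cont, dtype=float))
    keep = train.std(axis=0) > 0
    if not keep.any():
        raise AlgorithmSkipped("all training variables are constant")
    if not keep.all():
        warnings.warn("bioclim: zero-variance variable(s) skipped", stacklevel=2)
    train = train[:, keep]
    query = query[:, keep]
    n = train.shape[0]
    ts = np.sort(train, axis=0)
    scores = np.empty(query.shape, dtype=float)
    for j in range(train.shape[1]):
        below = np.searchsorted(ts[:, j], query[:, j], side="left")
        below_eq = np.searchsorted(ts[:, j], query[:, j], side="right")
        p = (below + 0.5 * (below_eq - below)) / n
        scores[:, j] = 2.0 * np.minimum(p, 1.0 - p)
    return np.clip(scores.min(axis=1), 0.0, 1.0)


def score_domain(
    train_cont: np.ndarray,
    query_cont: np.ndarray,
    train_cat: np.ndarray | None = None,
    query_cat: np.ndarray | None = None,
    ranges: np.ndarray | None = None,
    chunk: int = 512,
) -> np.ndarray:
    """Domain similarity: 1 minus the Gower distance to the nearest training
    presence, clipped to [0, 1].

    Gower distance averages, over variables, ``|Δ|/range`` for continuous
    variables (range taken over training presences) and a 0/1 mismatch for
    the categorical land class. A zero-range variable contributes 0 when the
    query equals the constant and 1 otherwise.
    """
    train = np.asarray(train_cont, dtype=float)
    query = np.atleast_2d(np.asarray(query_cont, dtype=float))
    if ranges is None:
        ranges = train.max(axis=0) - train.min(axis=0)
    ranges = np.asarray(ranges, dtype=float)
    n_var = train.shape[1] + (0 if train_cat is None else 1)
    safe = np.where(ranges > 0, ranges, 1.0)
    best = np.empty(query.shape[0], dtype=float)
    for start in range(0, query.shape[0], chunk):
        q = query[start : start + chunk]
        diff = np.abs(q[:, None, :] - train[None, :, :]) / safe
        # zero-range variables: distance 0 iff exactly equal, else 1
        zr = ranges <= 0
        if zr.any():
            diff[..., zr] = (np.abs(q[:, None, zr] - train[None, :, zr]) > 0).astype(float)
        total = diff.sum(axis=2)
        if train_cat is not None:
            qc = np.asarray(query_cat)[start : start + chunk]
            total = total + (qc[:, None] != np.asarray(train_cat)[None, :]).astype(float)
        best[start : start + chunk] = total.min(axis=1) / n_var
    return np.clip(1.0 - best, 0.0, 1.0)


def score_mahalanobis(
    train_cont: np.ndarray, query_cont: np.ndarray, ridge: float = 1e-8
) -> np.ndarray:
    """Squared Mahalanobis distance to the training-presence mean, mapped to
    the bounded score ``1 / (1 + D²)`` (same ordering, range (0, 1])."""
    train = np.asarray(train_cont, dtype=float)
    query = np.atleast_2d(np.asarray(query_cont, dtype=float))
    if train.shape[0] <= train.shape[1]:
        raise AlgorithmSkipped("need more training presences than variables")
    mu = train.mean(axis=0)
    cov = np.cov(train, rowvar=False)
    cov = np.atleast_2d(cov)
    scale = np.trace(cov) / cov.shape[0]
    for eps in (ridge, 1e-4):
        try:
            chol = np.linalg.cholesky(cov + eps * scale * np.eye(cov.shape[0]))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise AlgorithmSkipped("singular training covariance")
    z = np.linalg.solve(chol, (query - mu).T)
    d2 = np.sum(z**2, axis=0)
    return 1.0 / (1.0 + d2)


# ---------------------------------------------------------------------------
# regression / machine-learning scorers
# ---------------------------------------------------------------------------

def _aicc_from_llf(llf: float, k: int, n: int) -> float:
    denom = max(n - k - 1, 1)
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / denom


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Fit a plain binomial GLM; returns (params, llf) or None when the fit
    is unusable (separation, singular design)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception:
            return None
    if not np.all(np.isfinite(res.params)) or not np.isfinite(res.llf):
        return None
    if np.max(np.abs(res.params)) > 1e3:  # effectively separated
        return None
    return np.asarray(res.params), float(res.llf)


def fit_score_glm(
    train_X: np.ndarray,
    train_y: np.ndarray,
    feature_names: list[str] | None = None,
):
    """Binomial GLM with deterministic greedy forward-backward subset
    selection by the small-sample-corrected information criterion (AICc).

    Returns ``(scorer, selected_names)`` where ``scorer`` maps a query
    feature matrix (same columns as ``train_X``) to predicted presence
    probabilities. With an empty candidate list or no improving candidate the
    model is intercept-only. Perfect separation falls back to an L2-penalized
    fit on the selected columns.
    """
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if len(np.unique(y)) < 2:
        raise AlgorithmSkipped("single-class training data")

    def candidate_aicc(cols: tuple[int, ...]) -> float:
        design = np.column_stack([np.ones(n)] + [X[:, j] for j in cols])
        fit = _fit_logit(y, design)
        if fit is None:
            return np.inf
        return _aicc_from_llf(fit[1], design.shape[1], n)

    current: tuple[int, ...] = ()
    current_aicc = candidate_aicc(current)
    improved = True
    while improved:
        improved = False
        # forward
        for j in range(p):
            if j in current:
                continue
            trial = tuple(sorted(current + (j,)))
            a = candidate_aicc(trial)
            if a < current_aicc - 1e-9:
                current, current_aicc, improved = trial, a, True
        # backward
        for j in list(current):
            trial = tuple(k for k in current if k != j)
            a = candidate_aicc(trial)
            if a < current_aicc - 1e-9:
                current, current_aicc, improved = trial, a, True

    cols = current
    design = np.column_stack([np.ones(n)] + [X[:, j] for j in cols])
    fit = _fit_logit(y, design)
    if fit is not None:
        params = fit[0]

        def scorer(Q: np.ndarray) -> np.ndarray:
            Q = np.asarray(Q, dtype=float)
            D = np.column_stack([np.ones(Q.shape[0])] + [Q[:, j] for j in cols])
            eta = D @ params
            return 1.0 / (1.0 + np.exp(-eta))

    else:  # separated even on the selected subset: penalized fallback
        lr = LogisticRegression(C=1.0, max_iter=2000)
        sub = X[:, cols] if cols else np.zeros((n, 1))
        lr.fit(sub, y)

        def scorer(Q: np.ndarray) -> np.ndarray:
            Q = np.asarray(Q, dtype=float)
            sub_q = Q[:, cols] if cols else np.zeros((Q.shape[0], 1))
            return lr.predict_proba(sub_q)[:, 1]

    selected = [feature_names[j] for j in cols]
    return scorer, selected


def _expand_maxent_features(cont: np.ndarray, mu, sd) -> np.ndarray:
    z = (cont - mu) / sd
    parts = [z, z**2]
    p = z.shape[1]
    prods = [z[:, i] * z[:, j] for i in range(p) for j in range(i + 1, p)]
    if prods:
        parts.append(np.column_stack(prods))
    return np.column_stack(parts)


def fit_score_ml(
    algorithm: str,
    train_cont: np.ndarray,
    train_y: np.ndarray,
    train_cat_onehot: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
):
    """Fit one of the machine-learning scorers and return a callable mapping
    ``(query_cont, query_cat_onehot)`` to scores monotone in the fitted
    class probability / decision value.

    ``maxent_like`` is an L2-penalized binomial model on expanded continuous
    features (linear + quadratic + pairwise products) plus land-class
    dummies, with the pseudo-absences as background.
    """
    y = np.asarray(train_y, dtype=int)
    if len(np.unique(y)) < 2:
        raise AlgorithmSkipped("single-class training data")
    cont = np.asarray(train_cont, dtype=float)
    mu = cont.mean(axis=0)
    sd = np.where(cont.std(axis=0) > 0, cont.std(axis=0), 1.0)

    def assemble(c, oh, expand):
        z = _expand_maxent_features(c, mu, sd) if expand else (c - mu) / sd
        if oh is not None:
            z = np.column_stack([z, oh])
        return z

    seed_int = int(rng.integers(0, 2**31 - 1)) if rng is not None else 0
    if algorithm == "random_forest":
        model = RandomForestClassifier(
            n_estimators=100, random_state=seed_int, n_jobs=1
        )
        X = assemble(cont, train_cat_onehot, expand=False)
        model.fit(X, y)

        def scorer(qc, qoh=None):
            return model.predict_proba(assemble(np.asarray(qc, float), qoh, False))[:, 1]

    elif algorithm == "svm":
        # probability scale (Platt) so maps are comparable across algorithms,
        # matching the kernlab prob.model workflow
        model = SVC(kernel="rbf", C=1.0, gamma="scale", probability=True,
                    random_state=seed_int)
        X = assemble(cont, train_cat_onehot, expand=False)
        model.fit(X, y)

        def scorer(qc, qoh=None):
            return model.predict_proba(assemble(np.asarray(qc, float), qoh, False))[:, 1]

    elif algorithm == "maxent_like":
        model = LogisticRegression(C=1.0, max_iter=3000)
        X = assemble(cont, train_cat_onehot, expand=True)
        model.fit(X, y)

        def scorer(qc, qoh=None):
            return model.predict_proba(assemble(np.asarray(qc, float), qoh, True))[:, 1]

    else:
        raise ValueError(f"unknown ML algorithm {algorithm!r}")
    return scorer


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def auc(presence_scores: np.ndarray, absence_scores: np.ndarray) -> float:
    """Rank-statistic AUC: (#concordant pairs + 0.5·#ties) / (n_p · n_a)."""
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score groups must be non-empty")
    order = np.sort(a)
    below = np.searchsorted(order, p, side="left")
    below_eq = np.searchsorted(order, p, side="right")
    wins = below + 0.5 * (below_eq - below)
    return float(wins.sum() / (p.size * a.size))


def ssb_adjust(
    train_presence_xy: np.ndarray,
    test_presence_xy: np.ndarray,
    test_absence_xy: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Spatial-sorting-bias correction of the test absences.

    SSB is the ratio of mean nearest-neighbour distances to the training
    presences: (test presences) / (test absences). A ratio below 1 means the
    test absences sit systematically farther from the training data than the
    test presences, which inflates AUC. In that case each test presence is
    greedily matched (in random order, without replacement) to the unused
    test absence whose distance-to-nearest-training-presence is closest to
    its own, and only the matched absences are kept.

    Returns ``(indices of retained test absences, ssb)``.
    """
    tree = cKDTree(np.asarray(train_presence_xy, dtype=float))
    dp, _ = tree.query(np.asarray(test_presence_xy, dtype=float))
    da, _ = tree.query(np.asarray(test_absence_xy, dtype=float))
    ssb = float(dp.mean() / da.mean()) if da.mean() > 0 else 1.0
    n_a = da.shape[0]
    if ssb >= 1.0:
        return np.arange(n_a), ssb
    if n_a <= dp.shape[0]:
        warnings.warn(
            "ssb_adjust: fewer test absences than presences; using all absences",
            stacklevel=2,
        )
        return np.arange(n_a), ssb
    order = rng.permutation(dp.shape[0])
    available = np.ones(n_a, dtype=bool)
    chosen = []
    for i in order:
        idx = np.nonzero(available)[0]
        j = idx[np.argmin(np.abs(da[idx] - dp[i]))]
        chosen.append(j)
        available[j] = False
    return np.sort(np.asarray(chosen)), ssb


def max_sss_threshold(
    presence_scores: np.ndarray, absence_scores: np.ndarray
) -> float:
    """Threshold maximising sensitivity + specificity.

    Candidates are the midpoints between consecutive sorted unique pooled
    scores plus the pooled extremes. Sensitivity counts presences with score
    >= t, specificity absences with score < t; the lowest maximising
    candidate is returned (the objective is piecewise constant, so this
    candidate set is exhaustive).
    """
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    pooled = np.unique(np.concatenate([p, a]))
    if pooled.size == 1:
        return float(pooled[0])
    mids = 0.5 * (pooled[:-1] + pooled[1:])
    candidates = np.unique(np.concatenate([pooled[[0, -1]], mids]))
    sens = (p[None, :] >= candidates[:, None]).mean(axis=1)
    spec = (a[None, :] < candidates[:, None]).mean(axis=1)
    total = sens + spec
    best = np.nonzero(total >= total.max() - 1e-12)[0][0]
    return float(candidates[best])


# ---------------------------------------------------------------------------
# the ensemble
# ---------------------------------------------------------------------------

@dataclass
class RepetitionResult:
    best_algorithm: str
    algorithm_aucs: dict[str, float]
    auc_adjusted: float
    threshold: float
    ssb: float
    skipped: list[str]


@dataclass
class EnsembleSuitability:
    """Mean standardized suitability map, mean threshold and stability
    diagnostics from repeated best-model fits."""

    mean_suitability: RasterLayer
    mean_threshold: float
    n_reps: int
    max_rse: float  # max over cells of (sd/sqrt(n))/mean; NaN when n_reps < 2
    rep_table: pd.DataFrame
    win_counts: dict[str, int]
    rse_map: RasterLayer | None = None  # per-cell RSE of the mean (diagnostic)

    def presence_mask(self) -> np.ndarray:
        """Boolean grid of predicted presence: mean suitability at or above
        the mean threshold (NaN cells are absent)."""
        vals = self.mean_suitability.values
        with np.errstate(invalid="ignore"):
            return np.where(np.isfinite(vals), vals >= self.mean_threshold, False)


def _fit_all_algorithms(
    features: FeatureTable,
    X_onehot: np.ndarray,
    onehot_names: list[str],
    train_idx: np.ndarray,
    train_y: np.ndarray,
    algorithms,
    external,
    rng: np.random.Generator,
):
    """Fit every requested algorithm; returns {name: scorer(cell_idx)->scores}
    plus names skipped. Scorers take land-cell index arrays."""
    cont = features.cont
    cat = features.cat
    pres_idx = train_idx[train_y == 1]
    n_cont_cols = cont.shape[1]

    scorers = {}
    skipped = []
    for name in algorithms:
        try:
            if name in external:
                scorers[name] = external[name](features, train_idx, train_y, rng)
            elif name == "bioclim":
                if pres_idx.size < 2:
                    raise AlgorithmSkipped("need >=2 training presences")
                tr = cont[pres_idx]

                def sc(idx, tr=tr):
                    return score_bioclim(tr, cont[idx])

                scorers[name] = sc
            elif name == "domain":
                if pres_idx.size < 1:
                    raise AlgorithmSkipped("no training presences")
                tr = cont[pres_idx]
                trc = cat[pres_idx] if cat is not None else None
                ranges = tr.max(axis=0) - tr.min(axis=0)

                def sc(idx, tr=tr, trc=trc, ranges=ranges):
                    qc = cat[idx] if cat is not None else None
                    return score_domain(tr, cont[idx], trc, qc, ranges)

                scorers[name] = sc
            elif name == "mahalanobis":
                tr = cont[pres_idx]

                def sc(idx, tr=tr):
                    return score_mahalanobis(tr, cont[idx])

                scorers[name] = sc
            elif name == "glm":
                scorer, _sel = fit_score_glm(
                    X_onehot[train_idx], train_y, onehot_names
                )

                def sc(idx, scorer=scorer):
                    return scorer(X_onehot[idx])

                scorers[name] = sc
            elif name in ("random_forest", "svm", "maxent_like"):
                oh = X_onehot[:, n_cont_cols:] if X_onehot.shape[1] > n_cont_cols else None
                scorer = fit_score_ml(
                    name,
                    cont[train_idx],
                    train_y,
                    oh[train_idx] if oh is not None else None,
                    rng,
                )

                def sc(idx, scorer=scorer, oh=oh):
                    return scorer(cont[idx], oh[idx] if oh is not None else None)

                scorers[name] = sc
            else:
                raise ValueError(f"unknown algorithm {name!r}")
        except AlgorithmSkipped:
            skipped.append(name)
    return scorers, skipped


def run_ensemble(
    occurrence: RasterLayer,
    env_layers: list[RasterLayer],
    land_mask: np.ndarray,
    config: EnsembleConfig | None = None,
) -> EnsembleSuitability:
    """Run the full repetition ensemble for one species on one working grid.

    All randomness descends from ``config.seed`` through per-repetition
    substreams, so increasing ``n_reps`` extends rather than perturbs a run.
    Repetitions whose best map is constant (degenerate standardization) are
    discarded and logged in the repetition table.
    """
    config = config or EnsembleConfig()
    features = build_feature_table(env_layers, land_mask)
    X_onehot, onehot_names = features.onehot()
    occ = occurrence.values[features.rows, features.cols]
    presence = np.asarray(occ) > 0
    pres_cells = np.nonzero(presence)[0]
    if pres_cells.size < 2:
        raise SplitError("species has too few presence cells")

    streams = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    n_land = features.n_cells
    sum_map = np.zeros(n_land)
    sumsq_map = np.zeros(n_land)
    thresholds = []
    reps: list[dict] = []
    win_counts: dict[str, int] = {}
    n_used = 0

    for rep_i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        abs_cells = sample_pseudo_absences(presence, config.n_pseudo_absences, rng)
        test_p, test_a = split_train_test(
            pres_cells.size, abs_cells.size, config.test_fraction, rng
        )
        train_idx = np.concatenate([pres_cells[~test_p], abs_cells[~test_a]])
        train_y = np.concatenate(
            [np.ones((~test_p).sum()), np.zeros((~test_a).sum())]
        )
        test_pres_idx = pres_cells[test_p]
        test_abs_idx = abs_cells[test_a]

        scorers, skipped = _fit_all_algorithms(
            features, X_onehot, onehot_names,
            train_idx, train_y, config.algorithms, config.external_scorers, rng,
        )
        if not scorers:
            reps.append({"best_algorithm": "none", "degenerate": True})
            continue

        train_pres_xy = np.column_stack(
            [features.x[pres_cells[~test_p]], features.y[pres_cells[~test_p]]]
        )
        keep_abs, ssb = ssb_adjust(
            train_pres_xy,
            np.column_stack([features.x[test_pres_idx], features.y[test_pres_idx]]),
            np.column_stack([features.x[test_abs_idx], features.y[test_abs_idx]]),
            rng,
        )

        aucs_raw: dict[str, float] = {}
        aucs_adj: dict[str, float] = {}
        test_scores: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, sc in scorers.items():
            try:
                sp = np.asarray(sc(test_pres_idx), dtype=float)
                sa = np.asarray(sc(test_abs_idx), dtype=float)
            except AlgorithmSkipped:
                skipped.append(name)
                continue
            test_scores[name] = (sp, sa)
            aucs_raw[name] = auc(sp, sa)
            aucs_adj[name] = auc(sp, sa[keep_abs])
        if not aucs_adj:
            reps.append({"best_algorithm": "none", "degenerate": True})
            continue

        best = max(
            aucs_adj,
            key=lambda k: (aucs_adj[k], -ALGORITHM_PRIORITY.index(k)
                           if k in ALGORITHM_PRIORITY else 0),
        )
        full = np.asarray(scorers[best](np.arange(n_land)), dtype=float)
        thr = max_sss_threshold(*test_scores[best])
        try:
            scaled, (thr_s,) = minmax_standardize(full, [thr])
        except DegenerateScaleError:
            reps.append({"best_algorithm": best, "degenerate": True})
            continue
        thr_s = float(np.clip(thr_s, 0.0, 1.0))

        sum_map += scaled
        sumsq_map += scaled**2
        thresholds.append(thr_s)
        n_used += 1
        win_counts[best] = win_counts.get(best, 0) + 1
        reps.append(
            {
                "best_algorithm": best,
                "auc_raw": aucs_raw[best],
                "auc_adjusted": aucs_adj[best],
                "threshold": thr_s,
                "ssb": ssb,
                "skipped": ",".join(skipped),
                "degenerate": False,
            }
        )

    if n_used == 0:
        raise EnsembleError("all repetitions were degenerate")

    mean = sum_map / n_used
    rse = np.full(n_land, np.nan)
    if n_used >= 2:
        var = np.maximum(sumsq_map / n_used - mean**2, 0.0) * n_used / (n_used - 1)
        sem = np.sqrt(var / n_used)
        with np.errstate(divide="ignore", invalid="ignore"):
            rse = np.where(mean > config.rse_floor, sem / mean, np.nan)
        max_rse = float(np.nanmax(rse)) if np.isfinite(rse).any() else float("nan")
    else:
        max_rse = float("nan")

    grid = features.grid
    map_vals = np.full(grid.shape, np.nan)
    map_vals[features.rows, features.cols] = mean
    rse_vals = np.full(grid.shape, np.nan)
    rse_vals[features.rows, features.cols] = rse
    return EnsembleSuitability(
        mean_suitability=RasterLayer(
            grid, map_vals, kind="continuous", nodata=np.nan, name="mean_suitability"
        ),
        mean_threshold=float(np.mean(thresholds)),
        n_reps=n_used,
        max_rse=max_rse,
        rep_table=pd.DataFrame(reps),
        win_counts=win_counts,
        rse_map=RasterLayer(grid, rse_vals, nodata=np.nan, name="rse_of_mean"),
    )
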