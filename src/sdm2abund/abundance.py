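"""Stage 2b — density~suitability regression cascade and abundance totals.

For each response bound (minimum / maximum density) the cascade is:

1. **Normality gate.** Shapiro–Wilk at α = 0.1 on the raw densities. If
   rejected, the optimal Box-Cox power λ ∈ [−2, 2] is found by profile
   likelihood (with a shift of half the smallest positive value when zeros
   are present) and the transformed data retested; a second rejection sends
   the analysis down the GLM branch on the raw response.
2. **Model selection.** On the (possibly transformed) normal branch,
   generalized-least-squares fits with correlation structure ∈ {none,
   gaussian, exponential, spherical} on cell-centroid distances and a
   suitability polynomial of degree 1 or 2 are compared by AICc (the
   small-sample-corrected criterion). On the GLM branch, families
   {gaussian, gamma, poisson} (poisson on the rounded response) are compared
   by AIC.
3. **Prediction.** The selected model predicts density for every cell
   predicted present; the inverse transform is applied, negatives clamp to
   zero, and density × land area (km²) gives per-cell abundance. Cells below
   the suitability threshold carry exactly zero. Totals are the sum over
   cells; the minimum and maximum bounds are fitted as two independent
   cascades.

When the training table is large, random 2000-row subsets are fitted 10
times and the mean prediction taken, with the relative standard error of the
mean total reported as a stability diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import pdist, squareform

from .grids import LandAreaRaster, RasterLayer
from .sdm import EnsembleSuitability

__all__ = [
    "GateError",
    "SelectionError",
    "MissingWeightError",
    "ModelSelectionRecord",
    "AbundanceResult",
    "normality_gate",
    "boxcox_lambda",
    "apply_boxcox",
    "inverse_boxcox",
    "select_density_model",
    "predict_abundance",
    "subsample_fit",
    "biomass",
]

SHAPIRO_ALPHA = 0.1
CORRELATION_STRUCTURES = ("none", "gaussian", "exponential", "spherical")
GLM_FAMILIES = ("gaussian", "gamma", "poisson")


class GateError(ValueError):
    """Normality gate received constant or insufficient data."""


class SelectionError(RuntimeError):
    """Every candidate model failed to fit."""


class MissingWeightError(KeyError):
    """A species with predicted abundance lacks a standard weight."""


# ---------------------------------------------------------------------------
# Box-Cox machinery
# ---------------------------------------------------------------------------

def boxcox_lambda(values: np.ndarray, shift: float = 0.0) -> float:
    """Profile-likelihood-optimal Box-Cox power on λ ∈ [−2, 2].

    ``values + shift`` must be strictly positive.
    """
    y = np.asarray(values, dtype=float) + shift
    if np.any(y <= 0):
        raise ValueError("values must be positive after shift")
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, y),
        bounds=(-2.0, 2.0),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(res.x)


def apply_boxcox(values: np.ndarray, lam: float, shift: float = 0.0) -> np.ndarray:
    y = np.asarray(values, dtype=float) + shift
    if abs(lam) < 1e-12:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def inverse_boxcox(z: np.ndarray, lam: float, shift: float = 0.0) -> np.ndarray:
    """Invert the power transform; bases that would be negative under a
    fractional power are clamped to zero (callers count these)."""
    z = np.asarray(z, dtype=float)
    if abs(lam) < 1e-12:
        return np.exp(z) - shift
    base = lam * z + 1.0
    with np.errstate(invalid="ignore"):
        y = np.where(base > 0, np.power(np.maximum(base, 0.0), 1.0 / lam), 0.0)
    return y - shift


def normality_gate(values: np.ndarray) -> tuple[str, float | None, float]:
    """Shapiro–Wilk gate deciding the regression branch.

    Returns ``(branch, lambda, shift)`` with branch in
    ``{"normal", "transform", "glm"}``; ``lambda`` is the Box-Cox power when
    branch is ``"transform"`` (None otherwise) and ``shift`` the offset
    applied before the power transform (half the smallest positive value
    when zeros are present).
    """
    y = np.asarray(values, dtype=float)
    if y.size < 3 or np.ptp(y) == 0:
        raise GateError("need at least 3 distinct finite values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.shapiro(y)
    if p >= SHAPIRO_ALPHA:
        return "normal", None, 0.0
    shift = 0.0
    if np.any(y <= 0):
        positive = y[y > 0]
        if positive.size == 0:
            raise GateError("all values are zero; nothing to transform")
        shift = 0.5 * float(positive.min()) - float(min(y.min(), 0.0))
    lam = boxcox_lambda(y, shift)
    z = apply_boxcox(y, lam, shift)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p2 = stats.shapiro(z)
    if p2 >= SHAPIRO_ALPHA:
        return "transform", lam, shift
    return "glm", None, 0.0


# ---------------------------------------------------------------------------
# GLS with spatial correlation structures
# ---------------------------------------------------------------------------

def _correlation_matrix(d: np.ndarray, structure: str, rng_param: float) -> np.ndarray:
    h = d / rng_param
    if structure == "gaussian":
        return np.exp(-(h**2))
    if structure == "exponential":
        return np.exp(-h)
    if structure == "spherical":
        r = np.where(h < 1.0, 1.0 - 1.5 * h + 0.5 * h**3, 0.0)
        return r
    raise ValueError(structure)


def _gls_profile(y, X, R) -> tuple[np.ndarray, float, float]:
    """Profile out β and σ² for fixed correlation matrix R; returns
    (beta, sigma2, loglik)."""
    n = y.shape[0]
    c, low = cho_factor(R + 1e-10 * np.eye(n))
    Ri_X = cho_solve((c, low), X)
    Ri_y = cho_solve((c, low), y)
    XtRiX = X.T @ Ri_X
    beta = np.linalg.solve(XtRiX, X.T @ Ri_y)
    resid = y - X @ beta
    quad = float(resid @ cho_solve((c, low), resid))
    sigma2 = quad / n
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return beta, sigma2, ll


def _design(suit: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(suit), suit]
    if degree == 2:
        cols.append(suit**2)
    return np.column_stack(cols)


def _aicc(ll: float, k: int, n: int) -> float:
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / max(n - k - 1, 1)


@dataclass
class ModelSelectionRecord:
    """Provenance of one bound's fitted density model."""

    response_bound: str                 # "min" | "max"
    branch: str                         # "normal" | "transform" | "glm"
    transform_lambda: float | None
    transform_shift: float
    family: str                         # gaussian / gamma / poisson (glm branch)
    correlation: str                    # none / gaussian / exponential / spherical
    correlation_range: float | None
    degree: int
    coefficients: np.ndarray
    criterion: str                      # "AICc" | "AIC"
    candidates: pd.DataFrame            # every candidate with its criterion value
    glm_result: object = None           # fitted statsmodels result on glm branch

    def predict_density(self, suitability: np.ndarray) -> np.ndarray:
        """Predict raw-scale density (before clamping) for suitability
        scores, applying the inverse transform when one was used."""
        X = _design(np.asarray(suitability, dtype=float), self.degree)
        if self.branch == "glm":
            return np.asarray(self.glm_result.predict(X))
        z = X @ self.coefficients
        if self.branch == "transform":
            return inverse_boxcox(z, self.transform_lambda, self.transform_shift)
        return z


def select_density_model(
    pairs: pd.DataFrame,
    bound: str,
    min_rows: int = 10,
    n_range_grid: int = 12,
) -> ModelSelectionRecord:
    """Fit and compare the candidate density models for one response bound.

    Normal/transform branch: GLS with correlation in
    {none, gaussian, exponential, spherical} on centroid distances (range
    parameter profiled by maximum likelihood over a grid of candidate
    ranges) × suitability polynomial degree {1, 2}, compared by AICc.
    GLM branch: families {gaussian, gamma, poisson} × degree {1, 2}
    compared by AIC (poisson on the rounded response, logged in the record).
    """
    col = f"{bound}_density"
    if col not in pairs.columns:
        raise KeyError(f"pairs table lacks column {col!r}")
    df = pairs.dropna(subset=[col, "suitability"]).reset_index(drop=True)
    if len(df) < min_rows:
        raise SelectionError(f"only {len(df)} usable rows; need >= {min_rows}")
    y_raw = df[col].to_numpy(dtype=float)
    suit = df["suitability"].to_numpy(dtype=float)
    xy = df[["x", "y"]].to_numpy(dtype=float)

    branch, lam, shift = normality_gate(y_raw)

    candidates: list[dict] = []
    if branch in ("normal", "transform"):
        y = apply_boxcox(y_raw, lam, shift) if branch == "transform" else y_raw
        d = squareform(pdist(xy))
        pos = d[np.triu_indices_from(d, k=1)]
        pos = pos[pos > 0]
        if pos.size == 0:
            raise SelectionError("all training cells share one location")
        r_grid = np.geomspace(np.quantile(pos, 0.05), pos.max() * 2.0, n_range_grid)
        n = y.shape[0]
        best = None
        for degree in (1, 2):
            X = _design(suit, degree)
            p = X.shape[1]
            # independent errors
            beta, s2, ll = _gls_profile(y, X, np.eye(n))
            a = _aicc(ll, p + 1, n)
            candidates.append(
                dict(correlation="none", degree=degree, range=None, aicc=a)
            )
            if best is None or a < best["aicc"]:
                best = dict(
                    correlation="none", degree=degree, range=None, aicc=a, beta=beta
                )
            for structure in CORRELATION_STRUCTURES[1:]:
                best_r = None
                for r in r_grid:
                    R = _correlation_matrix(d, structure, r)
                    try:
                        beta, s2, ll = _gls_profile(y, X, R)
                    except np.linalg.LinAlgError:
                        continue
                    if best_r is None or ll > best_r[2]:
                        best_r = (beta, r, ll)
                if best_r is None:
                    continue  # candidate dropped (all ranges ill-conditioned)
                beta, r, ll = best_r
                a = _aicc(ll, p + 2, n)  # + sigma2 + range
                candidates.append(
                    dict(correlation=structure, degree=degree, range=float(r), aicc=a)
                )
                if a < best["aicc"]:
                    best = dict(
                        correlation=structure,
                        degree=degree,
                        range=float(r),
                        aicc=a,
                        beta=beta,
                    )
        if best is None:
            raise SelectionError("no GLS candidate converged")
        return ModelSelectionRecord(
            response_bound=bound,
            branch=branch,
            transform_lambda=lam,
            transform_shift=shift,
            family="gaussian",
            correlation=best["correlation"],
            correlation_range=best["range"],
            degree=best["degree"],
            coefficients=np.asarray(best["beta"]),
            criterion="AICc",
            candidates=pd.DataFrame(candidates),
        )

    # GLM branch: family comparison on the raw response by plain AIC
    best = None
    for degree in (1, 2):
        X = _design(suit, degree)
        for family_name in GLM_FAMILIES:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if family_name == "gaussian":
                        res = sm.GLM(y_raw, X, family=sm.families.Gaussian()).fit()
                    elif family_name == "gamma":
                        if np.any(y_raw <= 0):
                            continue  # gamma undefined at zero; candidate dropped
                        res = sm.GLM(
                            y_raw, X, family=sm.families.Gamma(sm.families.links.Log())
                        ).fit()
                    else:  # poisson on rounded response
                        res = sm.GLM(
                            np.round(y_raw), X, family=sm.families.Poisson()
                        ).fit()
            except Exception:
                continue
            aic = float(res.aic)
            candidates.append(dict(family=family_name, degree=degree, aic=aic))
            if best is None or aic < best[0]:
                best = (aic, family_name, degree, res)
    if best is None:
        raise SelectionError("no GLM family converged")
    _, family_name, degree, res = best
    return ModelSelectionRecord(
        response_bound=bound,
        branch="glm",
        transform_lambda=None,
        transform_shift=0.0,
        family=family_name,
        correlation="none",
        correlation_range=None,
        degree=degree,
        coefficients=np.asarray(res.params),
        criterion="AIC",
        candidates=pd.DataFrame(candidates),
        glm_result=res,
    )


# ---------------------------------------------------------------------------
# prediction and integration
# ---------------------------------------------------------------------------

@dataclass
class AbundanceResult:
    """Per-cell and total abundance bounds with model provenance."""

    per_cell_min: RasterLayer
    per_cell_max: RasterLayer
    total_min: float
    total_max: float
    model_min: ModelSelectionRecord | None
    model_max: ModelSelectionRecord | None
    n_clamped: int = 0
    subsample_rse: dict = field(default_factory=dict)


def _predict_bound(
    record: ModelSelectionRecord,
    ensemble: EnsembleSuitability,
    land: LandAreaRaster,
) -> tuple[np.ndarray, float, int]:
    grid = land.grid
    present = ensemble.presence_mask() & land.land_mask()
    rows, cols = np.nonzero(present)
    dens = record.predict_density(ensemble.mean_suitability.values[rows, cols])
    n_clamped = int(np.sum(dens < 0))
    dens = np.clip(dens, 0.0, None)
    per_cell = np.zeros(grid.shape)
    per_cell[rows, cols] = dens * land.area_km2[rows, cols]
    return per_cell, float(per_cell.sum()), n_clamped


def predict_abundance(
    model_min: ModelSelectionRecord | None,
    model_max: ModelSelectionRecord | None,
    ensemble: EnsembleSuitability,
    land: LandAreaRaster,
) -> AbundanceResult:
    """Predict density for every presence cell, convert to abundance via
    per-cell land area, and sum. Absence cells carry exactly zero. Negative
    back-transformed densities clamp to zero; the run warns when more than
    1% of presence cells are affected."""
    if ensemble.mean_suitability.grid != land.grid:
        raise ValueError("suitability and land-area grids differ")
    grid = land.grid
    zeros = np.zeros(grid.shape)
    out = {}
    clamped = 0
    n_present = max(int((ensemble.presence_mask() & land.land_mask()).sum()), 1)
    for tag, record in (("min", model_min), ("max", model_max)):
        if record is None:
            out[tag] = (zeros.copy(), 0.0)
            continue
        per_cell, total, n_c = _predict_bound(record, ensemble, land)
        clamped += n_c
        out[tag] = (per_cell, total)
    if clamped > 0.01 * n_present:
        warnings.warn(
            f"{clamped} predicted densities clamped to zero "
            f"({100*clamped/n_present:.1f}% of presence cells)"
        )
    return AbundanceResult(
        per_cell_min=RasterLayer(grid, out["min"][0], name="abundance_min"),
        per_cell_max=RasterLayer(grid, out["max"][0], name="abundance_max"),
        total_min=out["min"][1],
        total_max=out["max"][1],
        model_min=model_min,
        model_max=model_max,
        n_clamped=clamped,
    )


def subsample_fit(
    pairs: pd.DataFrame,
    ensemble: EnsembleSuitability,
    land: LandAreaRaster,
    k: int = 2000,
    reps: int = 10,
    seed: int = 0,
    bounds: tuple[str, ...] = ("min", "max"),
) -> AbundanceResult:
    """Fit the cascade on ``reps`` random ``k``-row subsets and average.

    With ``len(pairs) <= k`` this is a single plain fit. Otherwise each
    repetition draws a fresh subset without replacement, runs the full
    selection + prediction, and the per-cell maps and totals are averaged;
    the relative standard error of the mean total is reported per bound.
    """
    if len(pairs) <= k:
        records = {
            b: select_density_model(pairs, b) if b in bounds else None
            for b in ("min", "max")
        }
        return predict_abundance(records["min"], records["max"], ensemble, land)

    rng = np.random.default_rng(seed)
    grid = land.grid
    acc = {b: np.zeros(grid.shape) for b in ("min", "max")}
    totals = {b: [] for b in bounds}
    last_records: dict[str, ModelSelectionRecord | None] = {"min": None, "max": None}
    clamped = 0
    for _ in range(reps):
        idx = rng.choice(len(pairs), size=k, replace=False)
        sub = pairs.iloc[idx].reset_index(drop=True)
        for b in bounds:
            record = select_density_model(sub, b)
            per_cell, total, n_c = _predict_bound(record, ensemble, land)
            acc[b] += per_cell
            totals[b].append(total)
            last_records[b] = record
            clamped += n_c
    rse = {}
    for b in bounds:
        t = np.asarray(totals[b])
        mean_t = t.mean()
        rse[b] = float((t.std(ddof=1) / np.sqrt(reps)) / mean_t) if mean_t > 0 else np.nan
    result = AbundanceResult(
        per_cell_min=RasterLayer(grid, acc["min"] / reps, name="abundance_min"),
        per_cell_max=RasterLayer(grid, acc["max"] / reps, name="abundance_max"),
        total_min=float(np.mean(totals["min"])) if "min" in bounds else 0.0,
        total_max=float(np.mean(totals["max"])) if "max" in bounds else 0.0,
        model_min=last_records["min"],
        model_max=last_records["max"],
        n_clamped=clamped,
        subsample_rse=rse,
    )
    return result


def biomass(
    results: dict[str, AbundanceResult], standard_weights_kg: dict[str, float]
) -> dict:
    """Cell-wise and national biomass: Σ over species of abundance × standard
    weight (kg). Raises :class:`MissingWeightError` listing any species with
    abundance but no weight."""
    missing = [s for s in results if s not in standard_weights_kg]
    if missing:
        raise MissingWeightError(f"no standard weight for: {sorted(missing)}")
    per_cell = {"min": None, "max": None}
    for species, res in results.items():
        w = standard_weights_kg[species]
        for tag, layer in (("min", res.per_cell_min), ("max", res.per_cell_max)):
            contrib = layer.values * w
            per_cell[tag] = contrib if per_cell[tag] is None else per_cell[tag] + contrib
    return {
        "per_cell_min_kg": per_cell["min"],
        "per_cell_max_kg": per_cell["max"],
        "national_min_kg": float(per_cell["min"].sum()) if per_cell["min"] is not None else 0.0,
        "national_max_kg": float(per_cell["max"].sum()) if per_cell["max"] is not None else 0.0,
    }
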