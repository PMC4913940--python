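"""OLS and spatially filtered (SEVM) regression with AICc model selection.

The analysis grid for each response (Z_NODF or Z_M): a full OLS model with
all predictors, all-subsets enumeration ranked by AICc (species richness is
never dropped), Akaike weights, per-variable importance (sum of weights of
models containing the variable), conditional model averaging over the 95%
confidence set, and a global Moran's test on residuals.  When the OLS
residuals are spatially autocorrelated, Moran-eigenvector spatial filtering
(SEVM) appends selected eigenvectors of the doubly centered spatial weights
matrix as fixed covariates and repeats the whole grid.

The residual Moran's test uses the Cliff-Ord moment formulas under the
normal-theory null: with M = I - X(X'X)^-1 X' and A = M W_sym M,

    E[I]   = (n/S0) tr(A) / (n-k)
    E[I^2] = (n/S0)^2 [tr(A)^2 + 2 tr(A^2)] / ((n-k)(n-k+2))

and a two-sided normal p-value; a 999-permutation p-value is available as a
cross-check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ecoweb.geo_velocity import EARTH_RADIUS_KM

#: Predictors of the standard analysis, in table order. ``n_species`` is a
#: fixed term: importance 1 by construction.
DEFAULT_PREDICTORS = (
    "n_species",
    "elevation",
    "T_mean",
    "T_seasonality",
    "P_ann",
    "P_seasonality",
    "human_impact",
    "log_T_velocity",
    "log_P_velocity",
)
FIXED_TERMS = ("n_species",)


@dataclass
class DesignTable:
    """Standardizable response + predictors + site coordinates."""

    response: pd.Series
    predictors: pd.DataFrame
    coords: np.ndarray  # (n, 2) latitude, longitude

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.response)
        if len(self.predictors) != n or self.coords.shape != (n, 2):
            raise ValueError("response, predictors and coordinates must align")
        if self.response.isna().any() or self.predictors.isna().any().any():
            raise ValueError("design table contains missing values")
        if n < self.predictors.shape[1] + 10:
            raise ValueError("need at least 10 more rows than predictors")

    @property
    def n(self) -> int:
        return len(self.response)


def standardize_design(table: DesignTable) -> DesignTable:
    """Center response and predictors to mean 0, scale to unit SD (ddof=0)."""
    for name, col in itertools.chain(
        [(table.response.name or "response", table.response)],
        ((c, table.predictors[c]) for c in table.predictors.columns),
    ):
        if float(np.std(col)) == 0.0:
            raise ValueError(f"zero-variance column: {name}")
    y = (table.response - table.response.mean()) / table.response.std(ddof=0)
    x = (table.predictors - table.predictors.mean()) / table.predictors.std(ddof=0)
    return DesignTable(y, x, table.coords)


# ---------------------------------------------------------------------------
# spatial weights
# ---------------------------------------------------------------------------


@dataclass
class SpatialWeights:
    """n x n spatial connectivity matrix, zero diagonal."""

    matrix: np.ndarray
    style: str = "row-standardized"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, m = self.matrix.shape
        if n != m:
            raise ValueError("weights matrix must be square")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("weights diagonal must be zero")
        if np.any(self.matrix < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())


def great_circle_km(coords: np.ndarray) -> np.ndarray:
    """Pairwise haversine distances (km) between (lat, lon) rows."""
    lat = np.radians(coords[:, 0])[:, None]
    lon = np.radians(coords[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    h = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def knn_weights(coords: np.ndarray, k: int = 6, style: str = "row-standardized") -> SpatialWeights:
    """k-nearest-neighbor weights by great-circle distance."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k < 1 or k >= n:
        raise ValueError("need 1 <= k < n sites")
    d = great_circle_km(coords)
    np.fill_diagonal(d, np.inf)
    w = np.zeros((n, n))
    for i in range(n):
        w[i, np.argsort(d[i])[:k]] = 1.0
    if style == "row-standardized":
        w = w / w.sum(axis=1, keepdims=True)
    elif style != "binary":
        raise ValueError(f"unknown weights style {style!r}")
    return SpatialWeights(w, style)


# ---------------------------------------------------------------------------
# OLS with AICc
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """One least-squares fit: standardized coefficients, AICc, residual diagnostics."""

    terms: tuple
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r2: float
    llf: float
    aicc: float
    residuals: np.ndarray
    design_matrix: np.ndarray  # including intercept and any spatial filter
    spatial_filter: tuple = ()
    moran: "MoranTestResult | None" = None


@dataclass
class MoranTestResult:
    I: float
    expectation: float
    variance: float
    z: float
    p: float


def fit_ols(
    design: DesignTable,
    terms: tuple | list,
    filter_vectors: np.ndarray | None = None,
    filter_indices: tuple = (),
) -> FitResult:
    """OLS with intercept; optional spatial-filter eigenvectors as extra columns.

    AICc counts k = number of mean parameters + 1 (error variance):
    AICc = AIC + 2k(k+1)/(n-k-1), with the Gaussian profile log-likelihood.
    """
    terms = tuple(terms)
    y = design.response.to_numpy(dtype=float)
    n = y.size
    cols = [np.ones(n)]
    names = ["intercept"]
    for t in terms:
        cols.append(design.predictors[t].to_numpy(dtype=float))
        names.append(t)
    if filter_vectors is not None and filter_vectors.size:
        for j, idx in enumerate(filter_indices):
            cols.append(filter_vectors[:, j])
            names.append(f"MEM{idx}")
    X = np.column_stack(cols)
    p = X.shape[1]
    if n <= p:
        raise ValueError("more parameters than observations")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError(f"rank-deficient design (rank {rank} < {p})")
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df if df > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    bse = np.sqrt(np.diag(xtx_inv) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / bse
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    llf = -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)
    k = p + 1  # mean parameters + error variance
    aic = -2.0 * llf + 2.0 * k
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else math.inf
    idx = pd.Index(names)
    return FitResult(
        terms=terms,
        params=pd.Series(beta, index=idx),
        bse=pd.Series(bse, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        r2=r2,
        llf=llf,
        aicc=aicc,
        residuals=resid,
        design_matrix=X,
        spatial_filter=tuple(filter_indices),
    )


# ---------------------------------------------------------------------------
# residual Moran's test
# ---------------------------------------------------------------------------


def morans_test_residuals(
    fit: FitResult, weights: SpatialWeights, permutations: int = 0, seed: int = 0
) -> MoranTestResult:
    """Global Moran's test on regression residuals (normal approximation).

    With ``permutations`` > 0 the p-value is instead taken from that many
    random permutations of the residuals (two-sided, rank-based).
    """
    e = fit.residuals
    n = e.size
    ete = float(e @ e)
    if ete == 0.0:
        raise ValueError("residuals are identically zero; Moran's I undefined")
    W = weights.matrix
    s0 = weights.s0
    I = (n / s0) * float(e @ W @ e) / ete
    X = fit.design_matrix
    k = X.shape[1]
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    M = np.eye(n) - H
    Ws = (W + W.T) / 2.0
    A = M @ Ws @ M
    trA = float(np.trace(A))
    trA2 = float(np.trace(A @ A))
    e_i = (n / s0) * trA / (n - k)
    e_i2 = (n / s0) ** 2 * (trA**2 + 2.0 * trA2) / ((n - k) * (n - k + 2))
    var = e_i2 - e_i**2
    if var <= 0:
        raise ValueError("nonpositive Moran variance; degenerate weights or design")
    z = (I - e_i) / math.sqrt(var)
    if permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            ep = rng.permutation(e)
            Ip = (n / s0) * float(ep @ W @ ep) / ete
            if abs(Ip - e_i) >= abs(I - e_i) - 1e-15:
                count += 1
        p = (count + 1) / (permutations + 1)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return MoranTestResult(I, e_i, var, z, p)


# ---------------------------------------------------------------------------
# model selection / averaging
# ---------------------------------------------------------------------------


@dataclass
class ModelSet:
    """All-subsets fits with Akaike weights, ranked best first."""

    models: list
    weights: np.ndarray
    candidate_terms: tuple
    fixed_terms: tuple

    @property
    def best(self) -> FitResult:
        return self.models[0]


def select_best_aicc(
    design: DesignTable,
    candidate_terms,
    fixed_terms=FIXED_TERMS,
    filter_vectors: np.ndarray | None = None,
    filter_indices: tuple = (),
) -> ModelSet:
    """Fit every subset of candidate terms (fixed terms always included).

    Ranked by AICc; Akaike weights w_i = exp(-d_i/2)/sum_j exp(-d_j/2) with
    d_i the AICc difference to the best model.
    """
    candidate_terms = tuple(t for t in candidate_terms if t not in fixed_terms)
    if len(candidate_terms) > 20:
        raise ValueError("more than 20 candidate terms; exhaustive enumeration refused")
    fixed_terms = tuple(fixed_terms)
    fits = []
    for r in range(len(candidate_terms) + 1):
        for subset in itertools.combinations(candidate_terms, r):
            fits.append(
                fit_ols(design, fixed_terms + subset, filter_vectors, filter_indices)
            )
    aiccs = np.array([f.aicc for f in fits])
    order = np.argsort(aiccs, kind="stable")
    fits = [fits[i] for i in order]
    delta = aiccs[order] - aiccs[order][0]
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    return ModelSet(fits, w, candidate_terms, fixed_terms)


def variable_importance(models: ModelSet) -> pd.Series:
    """Per-predictor sum of Akaike weights over models containing it."""
    all_terms = models.fixed_terms + models.candidate_terms
    imp = {t: 0.0 for t in all_terms}
    for fit, w in zip(models.models, models.weights):
        for t in fit.terms:
            imp[t] += float(w)
    return pd.Series(imp)


def model_average(models: ModelSet, conf: float = 0.95, method: str = "conditional") -> pd.DataFrame:
    """Average coefficients over the top ``conf`` confidence set of models.

    Conditional (subset) averaging: a coefficient is averaged over retained
    models that contain it, with weights renormalized within that subset;
    ``method="full"`` instead averages over all retained models treating the
    coefficient as 0 where absent.  Standard errors use the weighted
    unconditional-variance formula; p-values from a normal approximation.
    """
    cum = np.cumsum(models.weights)
    n_keep = int(np.searchsorted(cum, conf) + 1)
    n_keep = min(n_keep, len(models.models))
    kept = models.models[:n_keep]
    kw = models.weights[:n_keep]
    rows = {}
    for term in ("intercept",) + models.fixed_terms + models.candidate_terms:
        betas, ses, ws = [], [], []
        for fit, w in zip(kept, kw):
            if term in fit.params.index:
                betas.append(fit.params[term])
                ses.append(fit.bse[term])
                ws.append(w)
            elif method == "full":
                betas.append(0.0)
                ses.append(0.0)
                ws.append(w)
        if not ws:
            continue
        ws_arr = np.array(ws) / np.sum(ws)
        beta_bar = float(np.dot(ws_arr, betas))
        se_bar = float(
            np.dot(ws_arr, np.sqrt(np.array(ses) ** 2 + (np.array(betas) - beta_bar) ** 2))
        )
        if se_bar > 0:
            p = 2.0 * stats.norm.sf(abs(beta_bar / se_bar))
        else:
            p = float("nan")
        rows[term] = {"estimate": beta_bar, "se": se_bar, "p": p}
    out = pd.DataFrame(rows).T
    out.attrs["n_models"] = n_keep
    return out


# ---------------------------------------------------------------------------
# Moran eigenvector filtering (SEVM)
# ---------------------------------------------------------------------------


def mem_eigenvectors(weights: SpatialWeights, positive_only: bool = True):
    """Moran-eigenvector basis of the doubly centered symmetric weights.

    Eigenvectors of H W_sym H with H = I - 11'/n, sorted by descending
    eigenvalue (descending Moran coefficient); each is mean-zero with unit
    norm.  By default only vectors with positive eigenvalue (positive
    spatial autocorrelation patterns) are returned as filter candidates.
    """
    n = weights.n
    if n < 3:
        raise ValueError("need at least 3 sites for eigenvector filtering")
    Ws = (weights.matrix + weights.matrix.T) / 2.0
    H = np.eye(n) - np.ones((n, n)) / n
    C = H @ Ws @ H
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    if positive_only:
        keep = eigval > 1e-10 * max(1.0, abs(eigval[0]))
        eigval = eigval[keep]
        eigvec = eigvec[:, keep]
    return eigval, eigvec


def sevm_select_filter(
    design: DesignTable,
    terms,
    weights: SpatialWeights,
    alpha: float = 0.05,
    max_vectors: int | None = None,
) -> tuple:
    """Greedy forward selection of Moran eigenvectors for the full model.

    At each step the candidate that most reduces the absolute standardized
    residual Moran statistic of the full model is appended; selection stops
    when the residual Moran p-value exceeds ``alpha`` or no candidate
    improves.  An empty filter is a valid outcome.
    """
    terms = tuple(terms)
    _, vecs = mem_eigenvectors(weights)
    if max_vectors is None:
        max_vectors = max(0, min(vecs.shape[1], design.n - len(terms) - 12))
    selected: list[int] = []

    def moran_abs_z(indices: list[int]) -> tuple[float, float]:
        fv = vecs[:, indices] if indices else None
        fit = fit_ols(design, terms, fv, tuple(indices))
        res = morans_test_residuals(fit, weights)
        return abs(res.z), res.p

    current_z, current_p = moran_abs_z(selected)
    while current_p <= alpha and len(selected) < max_vectors:
        best_idx = None
        best_z, best_p = current_z, current_p
        for cand in range(vecs.shape[1]):
            if cand in selected:
                continue
            z, p = moran_abs_z(selected + [cand])
            if z < best_z - 1e-12:
                best_idx, best_z, best_p = cand, z, p
        if best_idx is None:
            break
        selected.append(best_idx)
        current_z, current_p = best_z, best_p
    return tuple(selected)


# ---------------------------------------------------------------------------
# full analysis grid
# ---------------------------------------------------------------------------


@dataclass
class RegressionSuite:
    """OLS and SEVM grids for one response: full/best/averaged + importances."""

    ols_full: FitResult
    ols_models: ModelSet
    ols_averaged: pd.DataFrame
    ols_importance: pd.Series
    sevm_filter: tuple
    sevm_full: FitResult
    sevm_models: ModelSet
    sevm_averaged: pd.DataFrame
    sevm_importance: pd.Series
    filter_vectors: np.ndarray

    def to_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """The variable x {full, best, averaged, importance} grid for OLS and SEVM.

        Cells hold "estimate (p)" strings as in the published layout, plus
        Moran's I rows for the full and best models and R-squared rows.
        """

        def cell(fit: FitResult, term: str) -> str:
            if term not in fit.params.index:
                return ""
            return f"{fit.params[term]:.3f} ({_fmt_p(fit.pvalues[term])})"

        def avg_cell(avg: pd.DataFrame, term: str) -> str:
            if term not in avg.index:
                return ""
            return f"{avg.loc[term, 'estimate']:.3f} ({_fmt_p(avg.loc[term, 'p'])})"

        terms = self.ols_models.fixed_terms + self.ols_models.candidate_terms
        rows = {}
        for t in terms:
            rows[t] = {
                "OLS_full": cell(self.ols_full, t),
                "OLS_best": cell(self.ols_models.best, t),
                "OLS_averaged": avg_cell(self.ols_averaged, t),
                "OLS_importance": f"{self.ols_importance[t]:.2f}",
                "SEVM_full": cell(self.sevm_full, t),
                "SEVM_best": cell(self.sevm_models.best, t),
                "SEVM_averaged": avg_cell(self.sevm_averaged, t),
                "SEVM_importance": f"{self.sevm_importance[t]:.2f}",
            }
        rows["Moran_I"] = {
            "OLS_full": _fmt_moran(self.ols_full.moran),
            "OLS_best": _fmt_moran(self.ols_models.best.moran),
            "SEVM_full": _fmt_moran(self.sevm_full.moran),
            "SEVM_best": _fmt_moran(self.sevm_models.best.moran),
            "OLS_averaged": "",
            "OLS_importance": "",
            "SEVM_averaged": "",
            "SEVM_importance": "",
        }
        rows["R2"] = {
            "OLS_full": f"{self.ols_full.r2:.2f}",
            "OLS_best": f"{self.ols_models.best.r2:.2f}",
            "SEVM_full": f"{self.sevm_full.r2:.2f}",
            "SEVM_best": f"{self.sevm_models.best.r2:.2f}",
            "OLS_averaged": "",
            "OLS_importance": "",
            "SEVM_averaged": "",
            "SEVM_importance": "",
        }
        return pd.DataFrame(rows).T[
            [
                "OLS_full",
                "OLS_best",
                "OLS_averaged",
                "OLS_importance",
                "SEVM_full",
                "SEVM_best",
                "SEVM_averaged",
                "SEVM_importance",
            ]
        ]


def _fmt_p(p: float) -> str:
    return "<0.01" if p < 0.01 else f"{p:.2f}"


def _fmt_moran(res: MoranTestResult | None) -> str:
    if res is None:
        return ""
    return f"{res.I:.2f} ({_fmt_p(res.p)})"


def run_regression_suite(
    design: DesignTable,
    weights: SpatialWeights,
    candidate_terms=None,
    fixed_terms=FIXED_TERMS,
    alpha: float = 0.05,
    conf: float = 0.95,
    average_method: str = "conditional",
    standardize: bool = True,
) -> RegressionSuite:
    """The complete per-response analysis: OLS grid, then SEVM grid.

    The spatial filter is selected once on the full model and held fixed
    through the SEVM subset enumeration and averaging.
    """
    if standardize:
        design = standardize_design(design)
    if candidate_terms is None:
        candidate_terms = tuple(design.predictors.columns)
    all_terms = tuple(fixed_terms) + tuple(t for t in candidate_terms if t not in fixed_terms)

    ols_full = fit_ols(design, all_terms)
    ols_full.moran = morans_test_residuals(ols_full, weights)
    ols_models = select_best_aicc(design, candidate_terms, fixed_terms)
    ols_models.best.moran = morans_test_residuals(ols_models.best, weights)
    ols_avg = model_average(ols_models, conf, average_method)
    ols_imp = variable_importance(ols_models)

    filt = sevm_select_filter(design, all_terms, weights, alpha=alpha)
    _, vecs = mem_eigenvectors(weights)
    fv = vecs[:, list(filt)] if filt else None
    sevm_full = fit_ols(design, all_terms, fv, filt)
    sevm_full.moran = morans_test_residuals(sevm_full, weights)
    sevm_models = select_best_aicc(design, candidate_terms, fixed_terms, fv, filt)
    sevm_models.best.moran = morans_test_residuals(sevm_models.best, weights)
    sevm_avg = model_average(sevm_models, conf, average_method)
    sevm_imp = variable_importance(sevm_models)

    return RegressionSuite(
        ols_full,
        ols_models,
        ols_avg,
        ols_imp,
        filt,
        sevm_full,
        sevm_models,
        sevm_avg,
        sevm_imp,
        vecs[:, list(filt)] if filt else np.empty((design.n, 0)),
    )
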