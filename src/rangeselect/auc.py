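"""AUC goodness-of-fit, estimator ranking, and the statistical comparison.

The area-under-the-curve statistic asks how well the cells an estimator
scores as intensely used coincide with the cells that actually contain
relocations.  On the shared reference grid, the response is binary presence
per cell (a cell with ten fixes counts once) and the predictor is the
estimator's cell score; AUC is the tie-corrected rank-sum (Mann-Whitney)
statistic, identical to the trapezoidal ROC area.  1.0 means every occupied
cell outranks every empty cell; 0.5 means no discrimination.

The comparison procedure mirrors a standard estimator-evaluation design:
Kruskal-Wallis across technology x estimator groups, Bonferroni-adjusted
pairwise Welch t-tests, and random-intercept (animal) linear mixed models on
logit-AUC compared by AICc over a fixed 12-model candidate set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from scipy.optimize import minimize_scalar

from . import geometric, kernels, movement
from .core_io import (
    CellScoreField,
    ReferenceGrid,
    Trajectory,
    build_reference_grid,
    points_to_cells,
)

__all__ = [
    "AUCRecord",
    "ModelRow",
    "EstimatorConfig",
    "ESTIMATOR_TAGS",
    "compute_auc",
    "run_estimator",
    "auc_table",
    "records_to_dataframe",
    "kruskal_wallis",
    "pairwise_t_bonferroni",
    "logit",
    "logit_clamped",
    "aicc",
    "model_selection",
    "fit_lmm_random_intercept",
    "run_comparison",
]

#: The eight estimators of the comparison suite.
ESTIMATOR_TAGS = ("locoh", "slca", "char", "lkde", "pkde", "mkde", "bbmm", "dbbmm")

#: Reference level for the estimator covariate in the mixed models.
ESTIMATOR_REFERENCE = "slca"

N_LOCATIONS_BINS = ("<100", "101-500", "501-1000", ">1000")


def n_locations_class(n: int) -> str:
    """Printed sample-size bins; [1, 100] falls in the first class."""
    if n <= 100:
        return N_LOCATIONS_BINS[0]
    if n <= 500:
        return N_LOCATIONS_BINS[1]
    if n <= 1000:
        return N_LOCATIONS_BINS[2]
    return N_LOCATIONS_BINS[3]


@dataclass
class AUCRecord:
    """One (animal, estimator, technology) result row with covariates."""

    animal_id: str
    estimator: str
    technology: str
    auc: float | None
    n_locations: int
    n_locations_class: str
    fix_success: float
    schedule_class: str
    study_area: str
    n_cells: int
    status: str = "ok"

    def __post_init__(self):
        if self.auc is not None and not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc must be in [0, 1]")
        if not (0.0 <= self.fix_success <= 1.0):
            raise ValueError("fix_success must be in [0, 1]")


@dataclass
class ModelRow:
    """One candidate model in the AICc table."""

    terms: str
    K: int
    aicc: float
    delta: float = 0.0
    weight: float = 0.0
    candidate: bool = True


# ---------------------------------------------------------------------------
# AUC statistic
# ---------------------------------------------------------------------------


def compute_auc(score_field: CellScoreField, traj: Trajectory) -> float:
    """Tie-corrected rank-sum AUC of a score field against the relocations.

    AUC = (pairs where the presence cell outranks the absence cell
    + 0.5 x tied pairs) / (n1 * n0), computed via midranks.
    """
    grid = score_field.grid
    rows, cols, inside = points_to_cells(grid, traj.x, traj.y)
    presence = np.zeros(grid.shape, dtype=bool)
    presence[rows[inside], cols[inside]] = True
    presence = presence.ravel()
    n1 = int(presence.sum())
    n0 = presence.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError(
            "AUC undefined: need at least one presence and one absence cell"
        )
    ranks = scipy.stats.rankdata(score_field.score.ravel())
    r1 = ranks[presence].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# Running the estimator suite
# ---------------------------------------------------------------------------


@dataclass
class EstimatorConfig:
    """Shared parameters for the estimator suite."""

    grain: float = 100.0
    buffer: float | None = None  # None -> 3 grains per side
    locoh_k: int | None = None  # None -> round(sqrt(n))
    default_err_sd: float = 0.0
    n_integration_steps: int = 10
    window_size: int = 31
    margin: int = 11
    hmin: float = 34.0
    tau: float = 300.0
    tmax: float = 43200.0
    lmin: float = 5.0
    diffusion: float | None = None  # None -> method-of-moments estimate
    isopleth_levels: tuple = (50.0, 95.0, 100.0)


def run_estimator(
    tag: str, traj: Trajectory, grid: ReferenceGrid, config: EstimatorConfig
) -> CellScoreField:
    """Run one named estimator on a trajectory over the shared grid."""
    pts = traj.points
    if tag == "locoh":
        _, fld = geometric.locoh_k(pts, k=config.locoh_k, grid=grid)
        return fld
    if tag == "slca":
        _, fld = geometric.slca(pts, grid=grid)
        return fld
    if tag == "char":
        _, fld = geometric.char_hull(pts, grid=grid)
        return fld
    if tag == "lkde":
        return kernels.kde_ud(pts, kernels.href_bandwidth(pts), grid, "lkde")
    if tag == "pkde":
        return kernels.kde_ud(pts, kernels.plugin_bandwidth(pts), grid, "pkde")
    if tag == "lscv":
        res = kernels.lscv_bandwidth(pts)
        if res.failed:
            raise RuntimeError(res.reason)
        return kernels.kde_ud(pts, res.bandwidth, grid, "lscv")
    if tag == "mkde":
        params = movement.BRBParams(
            hmin=config.hmin,
            D=config.diffusion,
            Tmax=config.tmax,
            Lmin=config.lmin,
            tau=config.tau,
        )
        return movement.mkde_brb_ud(traj, params, grid)
    if tag == "bbmm":
        params = movement.BBMMParams(
            default_err_sd=config.default_err_sd,
            n_integration_steps=config.n_integration_steps,
        )
        return movement.bbmm_ud(traj, params, grid)
    if tag == "dbbmm":
        params = movement.DBBMMParams(
            window_size=config.window_size,
            margin=config.margin,
            default_err_sd=config.default_err_sd,
        )
        variances = movement.dbbmm_variances(traj, params)
        return movement.dbbmm_ud(
            traj, variances, config.default_err_sd, grid, config.n_integration_steps
        )
    raise ValueError(f"unknown estimator tag {tag!r}")


def auc_table(
    trajs,
    estimators=ESTIMATOR_TAGS,
    config: EstimatorConfig | None = None,
    meta: dict | None = None,
) -> list[AUCRecord]:
    """One AUCRecord per (animal, estimator, technology).

    Estimators that cannot run on a trajectory (e.g. MKDE on a sparse VHF
    track) are recorded as missing (``auc=None`` with the failure reason in
    ``status``), never as zero.  *meta* optionally maps animal_id to a dict
    with ``fix_success`` and ``study_area``.
    """
    config = config or EstimatorConfig()
    meta = meta or {}
    records = []
    for traj in trajs:
        grid = build_reference_grid(traj, config.grain, config.buffer)
        info = meta.get(traj.animal_id, {})
        common = dict(
            animal_id=traj.animal_id,
            technology=traj.technology,
            n_locations=traj.n,
            n_locations_class=n_locations_class(traj.n),
            fix_success=float(info.get("fix_success", 1.0)),
            schedule_class=traj.schedule_class,
            study_area=str(info.get("study_area", "unknown")),
            n_cells=grid.n_cells,
        )
        for tag in estimators:
            try:
                fld = run_estimator(tag, traj, grid, config)
                auc = compute_auc(fld, traj)
                records.append(AUCRecord(estimator=tag, auc=auc, **common))
            except (ValueError, RuntimeError) as exc:
                records.append(
                    AUCRecord(estimator=tag, auc=None, status=str(exc), **common)
                )
    return records


def records_to_dataframe(records) -> pd.DataFrame:
    """AUCRecords as a DataFrame in the declared column order."""
    cols = [
        "animal_id",
        "estimator",
        "technology",
        "auc",
        "n_locations",
        "n_locations_class",
        "fix_success",
        "schedule_class",
        "study_area",
        "n_cells",
        "status",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Kruskal-Wallis H (tie-corrected), degrees of freedom, chi2 p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        # all values identical across groups: no rank variation
        return 0.0, df, 1.0
    H, p = scipy.stats.kruskal(*groups)
    return float(H), df, float(p)


def pairwise_t_bonferroni(groups) -> np.ndarray:
    """Bonferroni-adjusted Welch pairwise t-test p-values (k x k matrix)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least two values")
    m = k * (k - 1) // 2
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
                p = 1.0 if a.mean() == b.mean() else 0.0
            else:
                p = float(scipy.stats.ttest_ind(a, b, equal_var=False).pvalue)
            adj = min(1.0, p * m)
            out[i, j] = out[j, i] = adj
    return out


# ---------------------------------------------------------------------------
# Transforms and information criteria
# ---------------------------------------------------------------------------


def logit(x: float) -> float:
    """ln(x / (1-x)) for a proportion strictly inside (0, 1)."""
    if not (0.0 < x < 1.0):
        raise ValueError(f"logit undefined at {x}; clamp first")
    return math.log(x / (1.0 - x))


def logit_clamped(x: float, n_cells: int) -> float:
    """logit with boundary values clamped to 1/(2 n_cells) from the edge.

    Hull estimators on tiny grids can produce AUC exactly 1; clamping keeps
    the response finite without discarding records.
    """
    eps = 1.0 / (2.0 * n_cells)
    if x >= 1.0:
        warnings.warn(
            f"AUC {x} clamped to {1.0 - eps} before logit", UserWarning, stacklevel=2
        )
        x = 1.0 - eps
    elif x <= 0.0:
        warnings.warn(
            f"AUC {x} clamped to {eps} before logit", UserWarning, stacklevel=2
        )
        x = eps
    return logit(x)


def aicc(loglik: float, K: int, n: int) -> float:
    """Small-sample corrected AIC: -2 loglik + 2K + 2K(K+1)/(n-K-1)."""
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={K + 1}")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def model_selection(rows) -> list[ModelRow]:
    """Delta-AICc and Akaike weights for a candidate set, sorted by AICc.

    *rows* are (terms, K, AICc) triples or ModelRow instances.  A model is a
    candidate when its delta < 4.0.
    """
    parsed = []
    for r in rows:
        if isinstance(r, ModelRow):
            parsed.append((r.terms, r.K, r.aicc))
        else:
            terms, K, a = r
            parsed.append((str(terms), int(K), float(a)))
    if not parsed:
        raise ValueError("need at least one model")
    aiccs = np.array([p[2] for p in parsed])
    deltas = aiccs - aiccs.min()
    w = np.exp(-deltas / 2.0)
    w = w / w.sum()
    out = [
        ModelRow(
            terms=p[0],
            K=p[1],
            aicc=p[2],
            delta=float(d),
            weight=float(wi),
            candidate=bool(d < 4.0),
        )
        for p, d, wi in zip(parsed, deltas, w)
    ]
    out.sort(key=lambda r: r.aicc)
    return out


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model (profiled likelihood)
# ---------------------------------------------------------------------------

COVARIATE_COLUMNS = {
    "estimator": "estimator",
    "fix_success": "fix_success",
    "schedule": "schedule_class",
    "n_locations": "n_locations_class",
    "study_area": "study_area",
}


@dataclass
class LmmFit:
    """Fitted random-intercept model."""

    params: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    re_sd: float
    resid_sd: float
    loglik: float  # ML log-likelihood (used for AICc)
    loglik_reml: float
    K: int  # fixed effects + 2 variance parameters
    n: int
    terms: tuple


def _design_matrix(df: pd.DataFrame, fixed_terms) -> pd.DataFrame:
    """Treatment-coded design matrix with an intercept.

    The estimator covariate uses SLCA as its reference level; other
    categorical covariates use their first sorted level.
    """
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    for term in fixed_terms:
        col = COVARIATE_COLUMNS.get(term, term)
        if col not in df.columns:
            raise ValueError(f"unknown covariate {term!r}")
        series = df[col]
        categorical = {"estimator", "schedule", "n_locations", "study_area"}
        if term not in categorical and pd.api.types.is_numeric_dtype(series):
            X[term] = series.astype(float).to_numpy()
            continue
        levels = sorted(series.astype(str).unique())
        ref = ESTIMATOR_REFERENCE if term == "estimator" else levels[0]
        if ref in levels:
            levels = [ref] + [lv for lv in levels if lv != ref]
        for lv in levels[1:]:
            X[f"{term}[{lv}]"] = (series.astype(str) == lv).astype(float).to_numpy()
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    _, R, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < arr.shape[1]:
        aliased = [X.columns[piv[i]] for i in range(rank, arr.shape[1])]
        raise ValueError(f"singular design; aliased terms: {aliased}")


def _profiled_crit(lam, y, X, group_idx, group_sizes, reml):
    """Negative profiled (RE)ML log-likelihood at variance ratio lam."""
    n, p = X.shape
    A = np.zeros((p, p))
    c = np.zeros(p)
    yvy = 0.0
    logdet_v = 0.0
    for idx, m in zip(group_idx, group_sizes):
        Xg = X[idx]
        yg = y[idx]
        shrink = lam / (1.0 + lam * m)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        A += Xg.T @ Xg - shrink * np.outer(sx, sx)
        c += Xg.T @ yg - shrink * sx * sy
        yvy += yg @ yg - shrink * sy * sy
        logdet_v += math.log1p(lam * m)
    beta = np.linalg.solve(A, c)
    rss = yvy - c @ beta
    rss = max(rss, 1e-300)
    if reml:
        dof = n - p
        sign, logdet_a = np.linalg.slogdet(A)
        sigma2 = rss / dof
        ll = -0.5 * (logdet_v + logdet_a + dof * (math.log(2 * math.pi * sigma2) + 1.0))
    else:
        sigma2 = rss / n
        ll = -0.5 * (logdet_v + n * (math.log(2 * math.pi * sigma2) + 1.0))
    return -ll, beta, sigma2, A


def fit_lmm_random_intercept(
    records, fixed_terms, response: str = "logit_auc", group: str = "animal_id"
) -> LmmFit:
    """REML random-intercept fit by profiling the variance ratio.

    The model is ``y = X beta + a_g + e`` with one random intercept per
    animal; the REML criterion is profiled over the ratio
    ``lambda = var(a)/var(e)`` and maximized by bounded 1-D search (with the
    OLS boundary ``lambda = 0`` evaluated explicitly, so a zero random
    variance reduces exactly to ordinary least squares).  Coefficient
    estimates, SEs and Wald 95% CIs come from the REML fit; the returned
    ``loglik`` is the ML log-likelihood at its own profiled optimum, the
    quantity AICc model selection needs.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = records_to_dataframe(records)
    if response == "logit_auc" and "logit_auc" not in df.columns:
        df = df.dropna(subset=["auc"])
        df["logit_auc"] = [
            logit_clamped(a, nc) for a, nc in zip(df["auc"], df["n_cells"])
        ]
    if df[group].nunique() < 2:
        raise ValueError("need at least two grouping levels (animals)")
    X = _design_matrix(df, fixed_terms)
    _check_full_rank(X)
    y = df[response].to_numpy(dtype=float)
    Xa = X.to_numpy()
    n, p = Xa.shape
    codes, _ = pd.factorize(df[group])
    group_idx = [np.flatnonzero(codes == k) for k in range(codes.max() + 1)]
    group_sizes = [idx.size for idx in group_idx]

    def optimum(reml):
        def f(u):
            return _profiled_crit(math.exp(u), y, Xa, group_idx, group_sizes, reml)[0]

        res = minimize_scalar(
            f, bounds=(-25.0, 25.0), method="bounded", options={"xatol": 1e-10}
        )
        nll0 = _profiled_crit(0.0, y, Xa, group_idx, group_sizes, reml)[0]
        if nll0 <= res.fun:
            return 0.0, -nll0
        return math.exp(res.x), -res.fun

    lam_reml, ll_reml = optimum(reml=True)
    lam_ml, ll_ml = optimum(reml=False)
    _, beta, sigma2, A = _profiled_crit(
        lam_reml, y, Xa, group_idx, group_sizes, reml=True
    )
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    params = pd.Series(beta, index=X.columns)
    se_s = pd.Series(se, index=X.columns)
    return LmmFit(
        params=params,
        se=se_s,
        ci_low=params - 1.96 * se_s,
        ci_high=params + 1.96 * se_s,
        re_sd=math.sqrt(lam_reml * sigma2),
        resid_sd=math.sqrt(sigma2),
        loglik=ll_ml,
        loglik_reml=ll_reml,
        K=p + 2,
        n=n,
        terms=tuple(fixed_terms),
    )


# ---------------------------------------------------------------------------
# The full comparison
# ---------------------------------------------------------------------------

#: The a priori 12-model candidate set (term lists; every model also carries
#: the animal random intercept).
MODEL_SET = (
    ("estimator",),
    ("estimator", "fix_success", "schedule", "n_locations", "study_area"),
    (),
    ("schedule",),
    ("fix_success",),
    ("n_locations",),
    ("fix_success", "schedule"),
    ("schedule", "n_locations"),
    ("study_area",),
    ("fix_success", "schedule", "n_locations"),
    ("n_locations", "study_area"),
    ("n_locations", "schedule", "study_area"),
)

TERM_LABELS = {
    "estimator": "Estimator",
    "fix_success": "Percent fix success",
    "schedule": "GPS schedule",
    "n_locations": "Number of locations",
    "study_area": "Study Area",
}


def _terms_label(terms) -> str:
    if not terms:
        return "Intercept + (1|animal)"
    return " + ".join(TERM_LABELS[t] for t in terms) + " + (1|animal)"


@dataclass
class ComparisonReport:
    model_rows: list
    fits: dict
    best_fit: LmmFit
    kruskal: tuple
    pairwise: pd.DataFrame
    means: pd.DataFrame
    dropped_terms: list = field(default_factory=list)


def run_comparison(records) -> ComparisonReport:
    """Fit the 12-model candidate set and the nonparametric group comparison.

    Mixed models are fit to logit-AUC of GPS records only; the
    Kruskal-Wallis/pairwise summary and the mean +/- SE table use all
    technology x estimator groups with at least one valid AUC.  Covariates
    with a single observed level are dropped from the model set with a
    warning.
    """
    df = records_to_dataframe(records).dropna(subset=["auc"]).copy()
    if df.empty:
        raise ValueError("no valid AUC records")
    df["logit_auc"] = [
        logit_clamped(a, nc) for a, nc in zip(df["auc"], df["n_cells"])
    ]
    gps = df[df["technology"] == "GPS"].copy()

    dropped = []
    usable = []
    for term, col in COVARIATE_COLUMNS.items():
        if term == "fix_success":
            n_levels = gps[col].nunique()
        else:
            n_levels = gps[col].astype(str).nunique()
        if n_levels < 2:
            dropped.append(term)
            warnings.warn(
                f"covariate {term!r} has a single level; dropped from models",
                UserWarning,
                stacklevel=2,
            )
        else:
            usable.append(term)

    fits = {}
    rows = []
    for terms in MODEL_SET:
        kept = tuple(t for t in terms if t in usable)
        label = _terms_label(kept)
        if label in fits:
            continue  # dropping a covariate can collapse two models into one
        fit = fit_lmm_random_intercept(gps, kept)
        fits[label] = fit
        rows.append((label, fit.K, aicc(fit.loglik, fit.K, fit.n)))
    model_rows = model_selection(rows)
    best_fit = fits[model_rows[0].terms]

    # technology x estimator groups
    grouped = df.groupby(["technology", "estimator"])["auc"]
    keys = [k for k, g in grouped if len(g) > 0]
    groups = [grouped.get_group(k).to_numpy() for k in keys]
    kw = kruskal_wallis(groups)
    pw = pd.DataFrame(
        pairwise_t_bonferroni(groups),
        index=[f"{t}:{e}" for t, e in keys],
        columns=[f"{t}:{e}" for t, e in keys],
    )
    means = (
        df.groupby(["technology", "estimator"])["auc"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    means["se"] = means["sd"] / np.sqrt(means["n"])
    return ComparisonReport(
        model_rows=model_rows,
        fits=fits,
        best_fit=best_fit,
        kruskal=kw,
        pairwise=pw,
        means=means,
        dropped_terms=dropped,
    )
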