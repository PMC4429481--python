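"""Third-generation estimators: BBMM, dBBMM and the biased-random-bridge MKDE.

These estimators use the time stamps of the relocations, the per-fix
location error, and an animal-specific motion parameter, so — unlike the
hull and location-based kernel estimators — consecutive fixes condition the
probability mass between them.

The Brownian bridge movement model (BBMM) links successive fixes with
conditional Brownian bridges.  Its single motion parameter, the Brownian
motion variance sigma2_m (m^2/s), is estimated by a leave-one-out
likelihood: odd-indexed fixes define the bridges and each even-indexed fix
is scored against the bivariate normal predictive density centered on the
linear interpolation with per-axis variance

    T * a * (1 - a) * sigma2_m
        + (1 - a)^2 * delta_1^2 + a^2 * delta_2^2 + delta_mid^2

where a is the fix's relative time in its bracketing interval of length T,
delta_1/delta_2 are the location-error SDs of the bracketing fixes, and
delta_mid is the scored fix's own error SD.  Including delta_mid is the
full predictive variance of an *observed* middle fix; omitting it (as some
implementations do) inflates the variance estimate by delta_mid^2 /
(T a (1-a)), which is far from negligible at GPS error scales.

The dynamic BBMM (dBBMM) replaces the single global variance with a per-fix
variance obtained by sliding a window along the path and, within each
window, choosing by BIC between a single-variance model and two-variance
models split at each admissible breakpoint, so behaviourally distinct path
segments get their own diffusion level.

The movement-based kernel density estimator (MKDE) interpolates each
usable segment in time and places a normal kernel at every interpolated
point with bridge-shaped smoothing h^2(p) = hmin^2 + 2 p (1-p) D T.
Segments longer than Tmax are unusable; a track with no usable segment at
all (the typical VHF case, with days between fixes) cannot be estimated and
raises :class:`MkdeNotEstimableError`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .core_io import ReferenceGrid, Trajectory, UtilizationDistribution, normalize_to_ud
from .core_io import CellScoreField
from .kernels import accumulate_isotropic_gaussians

logger = logging.getLogger("rangeselect")

__all__ = [
    "BBMMParams",
    "DBBMMParams",
    "BRBParams",
    "MkdeNotEstimableError",
    "bbmm_fit_variance",
    "bbmm_ud",
    "dbbmm_variances",
    "dbbmm_ud",
    "mkde_brb_ud",
    "estimate_diffusion",
]


class MkdeNotEstimableError(RuntimeError):
    """MKDE cannot be computed (no segment shorter than Tmax)."""


@dataclass
class BBMMParams:
    sigma2_m: float | None = None  # Brownian motion variance, m^2/s
    default_err_sd: float = 0.0  # used where a fix lacks err_sd, m
    n_integration_steps: int = 10  # interior quadrature points per segment

    def __post_init__(self):
        if self.sigma2_m is not None and self.sigma2_m < 0:
            raise ValueError("sigma2_m must be >= 0")
        if self.default_err_sd < 0:
            raise ValueError("default_err_sd must be >= 0")
        if self.n_integration_steps < 5:
            raise ValueError("n_integration_steps must be >= 5")


@dataclass
class DBBMMParams:
    window_size: int = 31  # odd number of fixes
    margin: int = 11  # fixes kept clear of window edges
    default_err_sd: float = 0.0

    def __post_init__(self):
        if self.margin < 3:
            raise ValueError("margin must be >= 3")
        if self.window_size < 2 * self.margin + 3:
            raise ValueError("window_size must be >= 2*margin + 3")
        if self.window_size % 2 == 0:
            raise ValueError("window_size must be odd")
        if self.default_err_sd < 0:
            raise ValueError("default_err_sd must be >= 0")


@dataclass
class BRBParams:
    hmin: float = 34.0  # minimum smoothing, m (GPS-error scale)
    D: float | None = None  # diffusion, m^2/s; None -> method-of-moments fit
    Tmax: float = 43200.0  # longest usable segment, s (12 h)
    Lmin: float = 5.0  # below this length a segment is stationary, m
    tau: float = 300.0  # interpolation step, s

    def __post_init__(self):
        if self.hmin <= 0:
            raise ValueError("hmin must be > 0")
        if self.D is not None and self.D < 0:
            raise ValueError("D must be >= 0")
        if self.Tmax <= 0 or self.tau <= 0:
            raise ValueError("Tmax and tau must be > 0")
        if self.Lmin < 0:
            raise ValueError("Lmin must be >= 0")


# ---------------------------------------------------------------------------
# BBMM variance likelihood
# ---------------------------------------------------------------------------


def _bridge_terms(t, x, y, err):
    """Leave-one-out bridge terms for a (sub-)track.

    Alternate fixes are bridge endpoints (positions 0, 2, 4, ...); the
    interior fixes between them (1, 3, ...) are scored.  Returns arrays
    (a, b, d2) so that the per-axis predictive variance of each scored fix
    is s = a*sigma2 + b and d2 is its squared deviation from the
    interpolated mean.  A trailing unpaired fix contributes nothing.
    """
    n = len(t)
    evens = [e for e in range(1, n - 1, 2)]
    a = np.empty(len(evens))
    b = np.empty(len(evens))
    d2 = np.empty(len(evens))
    for i, e in enumerate(evens):
        lo, hi = e - 1, e + 1
        T = t[hi] - t[lo]
        al = (t[e] - t[lo]) / T
        a[i] = T * al * (1.0 - al)
        b[i] = (
            (1.0 - al) ** 2 * err[lo] ** 2 + al**2 * err[hi] ** 2 + err[e] ** 2
        )
        mx = (1.0 - al) * x[lo] + al * x[hi]
        my = (1.0 - al) * y[lo] + al * y[hi]
        d2[i] = (x[e] - mx) ** 2 + (y[e] - my) ** 2
    return a, b, d2


def _neg_loglik(sigma2, a, b, d2):
    s = a * sigma2 + b
    return float(np.sum(np.log(2.0 * math.pi * s) + d2 / (2.0 * s)))


def _fit_sigma2(a, b, d2):
    """Maximize the bridge likelihood over sigma2 (bounded 1-D search)."""
    if a.size == 0:
        raise ValueError("no scored fixes; need at least 3 fixes")
    upper = 20.0 * float(np.max(d2 / (2.0 * a))) + 1e-6
    if np.all(d2 <= 0) and np.all(b <= 0):
        warnings.warn(
            "all scored fixes lie exactly on the interpolation lines with "
            "zero location error; sigma2_m estimated at the boundary 0",
            UserWarning,
            stacklevel=3,
        )
        return 0.0
    res = minimize_scalar(
        lambda u: _neg_loglik(math.exp(u), a, b, d2),
        bounds=(math.log(1e-12 * upper), math.log(upper)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    sigma2 = math.exp(res.x)
    # the boundary sigma2 = 0 is admissible when every fix has location error
    if np.all(b > 0) and _neg_loglik(0.0, a, b, d2) <= res.fun:
        return 0.0
    return sigma2


def bbmm_fit_variance(traj: Trajectory, default_err_sd: float = 0.0) -> float:
    """MLE of the Brownian motion variance sigma2_m (m^2/s)."""
    if traj.n < 3:
        raise ValueError("BBMM variance fit needs at least 3 fixes")
    err = traj.error_sd_or(default_err_sd)
    a, b, d2 = _bridge_terms(traj.t, traj.x, traj.y, err)
    return _fit_sigma2(a, b, d2)


# ---------------------------------------------------------------------------
# Bridge rasterization
# ---------------------------------------------------------------------------


def _bridge_kernels(t, x, y, err, sigma2_per_seg, n_steps):
    """Kernel centers/SDs/weights for all bridge segments of a track.

    Each segment contributes *n_steps* interior midpoint-rule kernels; the
    segment weight is its duration, split evenly across its kernels.
    """
    nseg = len(t) - 1
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    centers = []
    sds = []
    weights = []
    for i in range(nseg):
        T = t[i + 1] - t[i]
        if T <= 0:
            warnings.warn("zero-duration segment skipped", UserWarning, stacklevel=3)
            continue
        s2 = (
            T * alphas * (1.0 - alphas) * sigma2_per_seg[i]
            + (1.0 - alphas) ** 2 * err[i] ** 2
            + alphas**2 * err[i + 1] ** 2
        )
        cx = (1.0 - alphas) * x[i] + alphas * x[i + 1]
        cy = (1.0 - alphas) * y[i] + alphas * y[i + 1]
        centers.append(np.column_stack([cx, cy]))
        sds.append(np.sqrt(np.maximum(s2, 1e-12)))
        weights.append(np.full(n_steps, T / n_steps))
    if not centers:
        raise ValueError("no usable segments")
    return np.vstack(centers), np.concatenate(sds), np.concatenate(weights)


def bbmm_ud(
    traj: Trajectory, params: BBMMParams, grid: ReferenceGrid
) -> UtilizationDistribution:
    """Brownian bridge UD: duration-weighted average of bridge densities."""
    sigma2 = params.sigma2_m
    if sigma2 is None:
        sigma2 = bbmm_fit_variance(traj, params.default_err_sd)
    err = traj.error_sd_or(params.default_err_sd)
    centers, sds, weights = _bridge_kernels(
        traj.t, traj.x, traj.y, err, np.full(traj.n - 1, sigma2), params.n_integration_steps
    )
    mass = accumulate_isotropic_gaussians(grid, centers, sds, weights)
    field = CellScoreField(
        grid=grid,
        score=mass,
        estimator_tag="bbmm",
        params={"sigma2_m": sigma2, "n_integration_steps": params.n_integration_steps},
    )
    return normalize_to_ud(field)


# ---------------------------------------------------------------------------
# dBBMM
# ---------------------------------------------------------------------------


def dbbmm_variances(traj: Trajectory, params: DBBMMParams) -> np.ndarray:
    """Per-fix Brownian motion variances from the sliding-window BIC model.

    Within each window the single-variance model competes against
    two-variance models split at each interior breakpoint at least *margin*
    fixes from the window edges (BIC = -2 loglik + k ln(m), m = scored
    fixes).  Breakpoints are restricted to bridge endpoints (even offsets
    within the window) so that every candidate model scores exactly the same
    leave-one-out fixes — otherwise a split changes the pairing parity,
    silently drops a scored fix and wins the BIC comparison spuriously.
    Each non-margin fix receives the average of the selected-model variances
    over all windows covering it; margin fixes inherit the nearest interior
    value.
    """
    n = traj.n
    w = params.window_size
    mg = params.margin
    if n < w:
        raise ValueError(
            f"track has {n} fixes but the window needs {w}; "
            "use BBMM for short tracks"
        )
    err = traj.error_sd_or(params.default_err_sd)
    t, x, y = traj.t, traj.x, traj.y

    def fit_slice(lo, hi):
        """(loglik, sigma2, n_scored) for the sub-track [lo, hi)."""
        a, b, d2 = _bridge_terms(t[lo:hi], x[lo:hi], y[lo:hi], err[lo:hi])
        if a.size == 0:
            return 0.0, None, 0
        s2 = _fit_sigma2(a, b, d2)
        return -_neg_loglik(max(s2, 1e-300), a, b, d2), s2, a.size

    acc = np.zeros(n)
    cnt = np.zeros(n)
    for s in range(0, n - w + 1):
        ll1, s2_single, m1 = fit_slice(s, s + w)
        best = (-2.0 * ll1 + 1.0 * math.log(max(m1, 1)), None, s2_single, None)
        for brk in range(mg + mg % 2, w - mg, 2):
            ll_l, s2_l, m_l = fit_slice(s, s + brk + 1)
            ll_r, s2_r, m_r = fit_slice(s + brk, s + w)
            m = m_l + m_r
            if m == 0 or s2_l is None or s2_r is None:
                continue
            # two variances plus the estimated breakpoint location
            bic = -2.0 * (ll_l + ll_r) + 3.0 * math.log(m)
            if bic < best[0]:
                best = (bic, brk, s2_l, s2_r)
        _, brk, s2_a, s2_b = best
        win_var = np.full(w, s2_a)
        if brk is not None:
            win_var[brk + 1 :] = s2_b  # breakpoint fix stays with the left phase
        interior = slice(s + mg, s + w - mg)
        acc[interior] += win_var[mg : w - mg]
        cnt[interior] += 1.0
    have = cnt > 0
    out = np.empty(n)
    out[have] = acc[have] / cnt[have]
    # margins inherit the nearest interior value
    idx = np.flatnonzero(have)
    first, last = idx[0], idx[-1]
    out[:first] = out[first]
    out[last + 1 :] = out[last]
    return out


def dbbmm_ud(
    traj: Trajectory,
    variances: np.ndarray,
    default_err_sd: float,
    grid: ReferenceGrid,
    n_integration_steps: int = 10,
) -> UtilizationDistribution:
    """dBBMM UD: like BBMM but each segment uses its endpoints' mean variance."""
    variances = np.asarray(variances, dtype=float)
    if variances.size != traj.n:
        raise ValueError("need one variance per fix")
    err = traj.error_sd_or(default_err_sd)
    seg_var = 0.5 * (variances[:-1] + variances[1:])
    centers, sds, weights = _bridge_kernels(
        traj.t, traj.x, traj.y, err, seg_var, n_integration_steps
    )
    mass = accumulate_isotropic_gaussians(grid, centers, sds, weights)
    field = CellScoreField(
        grid=grid,
        score=mass,
        estimator_tag="dbbmm",
        params={"n_integration_steps": n_integration_steps},
    )
    return normalize_to_ud(field)


# ---------------------------------------------------------------------------
# Biased-random-bridge MKDE
# ---------------------------------------------------------------------------


def estimate_diffusion(traj: Trajectory) -> float:
    """Method-of-moments diffusion: mean over segments of d^2 / (4 T)."""
    if traj.n < 2:
        raise ValueError("diffusion estimate needs at least 2 fixes")
    dt = np.diff(traj.t)
    d2 = np.diff(traj.x) ** 2 + np.diff(traj.y) ** 2
    return float(np.mean(d2 / (4.0 * dt)))


def brb_smoothing_sq(p, hmin: float, D: float, T: float):
    """Bridge-shaped smoothing: h^2(p) = hmin^2 + 2 p (1-p) D T.

    Pinned to hmin at the fixes (p = 0, 1) and widest mid-bridge.  The
    scale factor 2 is this package's committed form of the bridge variance
    inflation; it is isolated here so it can be revised in one place.
    """
    return hmin**2 + 2.0 * p * (1.0 - p) * D * T


def mkde_brb_ud(
    traj: Trajectory, params: BRBParams, grid: ReferenceGrid
) -> UtilizationDistribution:
    """Biased-random-bridge movement-based KDE.

    Segments longer than Tmax are skipped; segments shorter than Lmin are
    treated as stationary (kernels of SD hmin at both endpoints); all others
    are interpolated roughly every tau seconds, each interpolated point
    carrying a normal kernel of SD h(p) weighted by its time share.
    """
    D = params.D
    if D is None:
        D = estimate_diffusion(traj)
    t, x, y = traj.t, traj.x, traj.y
    centers = []
    sds = []
    weights = []
    n_skipped = 0
    for i in range(traj.n - 1):
        T = t[i + 1] - t[i]
        if T > params.Tmax:
            n_skipped += 1
            continue
        L = math.hypot(x[i + 1] - x[i], y[i + 1] - y[i])
        if L < params.Lmin:
            centers.append([[x[i], y[i]], [x[i + 1], y[i + 1]]])
            sds.append([params.hmin, params.hmin])
            weights.append([T / 2.0, T / 2.0])
            continue
        m = max(1, int(round(T / params.tau)))
        p = (np.arange(m) + 0.5) / m
        h = np.sqrt(brb_smoothing_sq(p, params.hmin, D, T))
        cx = (1.0 - p) * x[i] + p * x[i + 1]
        cy = (1.0 - p) * y[i] + p * y[i + 1]
        centers.append(np.column_stack([cx, cy]))
        sds.append(h)
        weights.append(np.full(m, T / m))
    if n_skipped:
        logger.info(
            "MKDE: skipped %d of %d segments longer than Tmax=%.0f s",
            n_skipped,
            traj.n - 1,
            params.Tmax,
        )
    if not centers:
        raise MkdeNotEstimableError(
            f"no segment of track {traj.animal_id!r} is shorter than "
            f"Tmax={params.Tmax:.0f} s; MKDE is not estimable on such sparse "
            "(e.g. VHF) sampling"
        )
    centers = np.vstack([np.asarray(c, dtype=float) for c in centers])
    sds = np.concatenate([np.asarray(s, dtype=float) for s in sds])
    weights = np.concatenate([np.asarray(w, dtype=float) for w in weights])
    mass = accumulate_isotropic_gaussians(grid, centers, sds, weights)
    field = CellScoreField(
        grid=grid,
        score=mass,
        estimator_tag="mkde",
        params={
            "hmin": params.hmin,
            "D": D,
            "Tmax": params.Tmax,
            "Lmin": params.Lmin,
            "tau": params.tau,
        },
    )
    return normalize_to_ud(field)
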