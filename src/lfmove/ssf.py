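"""Step-selection-function construction and fitting.

Each realized movement step is matched with random available steps sharing
its start (gamma-distributed lengths, uniform turn angles), forming a
stratum of one used and ``n_random`` available alternatives with binary
feature covariates.  Coefficients are estimated by maximizing the exact
stratum-conditional (conditional logistic) likelihood; an equivalent
Poisson route with weakly-penalized per-stratum intercepts is provided as
an independent cross-check, and individual-level Gaussian random slopes are
supported through a Laplace approximation.  Relative selection strength is
the exponentiated coefficient.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .errors import DegenerateFitError, NonIdentifiableError, ValidationError
from .geometry import Landscape, count_crossings_segments, points_in_polygon_mask
from .trajectory import Trajectory, derive_steps

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_COVARIATES",
    "GammaFit",
    "SsfFit",
    "annotate_choice_sets",
    "fit_conditional_logistic",
    "fit_gamma",
    "fit_poisson_reformulation",
    "generate_choice_sets",
    "log_rss",
    "rss",
    "rss_interval",
    "summary_table",
]

DEFAULT_COVARIATES = ("road_cross", "trail_cross", "end_in_powerline", "end_in_buffer")

CHOICE_COLUMNS = [
    "stratum_id", "animal_id", "sex", "year", "used",
    "start_x", "start_y", "end_x", "end_y",
]

# |beta| beyond this during Newton iterations is treated as separation.
SEPARATION_CAP = 12.0


@dataclass
class GammaFit:
    """Maximum-likelihood gamma distribution of positive step lengths."""

    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        return rng.gamma(self.shape, self.scale, size)


@dataclass
class SsfFit:
    """Fitted step-selection coefficients with Wald 95% intervals."""

    covariates: tuple
    beta: dict
    se: dict
    ci_lower: dict
    ci_upper: dict
    re_variance: dict | None = None
    sex: str | None = None
    n_strata: int = 0
    loglik: float = float("nan")
    converged: bool = True
    method: str = "conditional_logistic"
    vcov: np.ndarray | None = field(default=None, repr=False)


def fit_gamma(lengths) -> GammaFit:
    """ML gamma fit (location fixed at zero) of positive step lengths."""
    x = np.asarray(lengths, dtype=float)
    if x.size < 5:
        raise ValidationError("need at least 5 step lengths to fit a gamma")
    if np.any(x <= 0):
        raise ValidationError("step lengths must be strictly positive")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant step lengths; gamma fit is degenerate")
    shape, _, scale = scipy.stats.gamma.fit(x, floc=0)
    return GammaFit(shape=float(shape), scale=float(scale))


def generate_choice_sets(
    traj: Trajectory, fit: GammaFit, n_random: int = 10, seed: int = 0
) -> pd.DataFrame:
    """One stratum per realized movement step plus ``n_random`` alternatives.

    The first movement step of a trajectory has no turn angle and is not a
    stratum.  Random steps share the realized step's start; their lengths are
    drawn from ``fit`` and their bearings from the previous movement heading
    plus a uniform turn on (-pi, pi].  Output is byte-identical for a fixed
    seed.
    """
    steps = derive_steps(traj, movement_only=True)
    if len(steps) < 2:
        warnings.warn(
            f"trajectory {traj.animal_id}/{traj.year} too short for choice sets", stacklevel=2
        )
        return pd.DataFrame(columns=CHOICE_COLUMNS)
    key = zlib.crc32(f"{traj.animal_id}|{traj.year}".encode())
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), key]))

    strata = steps.iloc[1:].reset_index(drop=True)
    prev_heading = steps["heading"].to_numpy()[:-1]
    n_strata = len(strata)
    lengths = fit.sample(rng, (n_strata, n_random))
    turns = rng.uniform(-np.pi, np.pi, (n_strata, n_random))
    bearings = prev_heading[:, None] + turns
    sx = strata["start_x"].to_numpy()[:, None]
    sy = strata["start_y"].to_numpy()[:, None]
    ex = sx + lengths * np.cos(bearings)
    ey = sy + lengths * np.sin(bearings)

    per = n_random + 1
    stratum_ids = np.repeat(
        [f"{traj.animal_id}-{traj.year}-{i:04d}" for i in range(n_strata)], per
    )
    used = np.tile(np.r_[1, np.zeros(n_random, dtype=int)], n_strata)
    end_x = np.column_stack([strata["end_x"].to_numpy()[:, None], ex]).ravel()
    end_y = np.column_stack([strata["end_y"].to_numpy()[:, None], ey]).ravel()
    return pd.DataFrame(
        {
            "stratum_id": stratum_ids,
            "animal_id": traj.animal_id,
            "sex": traj.sex,
            "year": traj.year,
            "used": used,
            "start_x": np.repeat(sx.ravel(), per),
            "start_y": np.repeat(sy.ravel(), per),
            "end_x": end_x,
            "end_y": end_y,
        }
    )


def annotate_choice_sets(sets: pd.DataFrame, landscape: Landscape) -> pd.DataFrame:
    """Attach the four binary feature covariates to every step.

    Crossing covariates flag a transversal intersection of the straight
    start-to-end segment with any road/trail line; occupancy covariates flag
    the end point lying inside (or on the boundary of) the polygon layer.
    """
    out = sets.copy()
    if len(out) == 0:
        for c in DEFAULT_COVARIATES:
            out[c] = pd.Series(dtype=int)
        return out
    segs = np.stack(
        [
            out[["start_x", "start_y"]].to_numpy(dtype=float),
            out[["end_x", "end_y"]].to_numpy(dtype=float),
        ],
        axis=1,
    )  # (n, 2, 2) treated as length-2 paths
    ends = out[["end_x", "end_y"]].to_numpy(dtype=float)
    out["road_cross"] = (count_crossings_segments(segs, landscape.road_segments) > 0).astype(int)
    out["trail_cross"] = (count_crossings_segments(segs, landscape.trail_segments) > 0).astype(int)
    out["end_in_powerline"] = points_in_polygon_mask(ends, landscape.powerline_union).astype(int)
    out["end_in_buffer"] = points_in_polygon_mask(ends, landscape.road_buffer).astype(int)
    return out


def identifiable_covariates(sets: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> tuple:
    """Subset of covariates with within-stratum variation in at least one stratum."""
    keep = []
    for name in covariates:
        spread = sets.groupby("stratum_id")[name].agg(lambda s: s.max() - s.min())
        if (spread > 0).any():
            keep.append(name)
    return tuple(keep)


# ---------------------------------------------------------------------------
# conditional logistic likelihood machinery


def _prepare(sets: pd.DataFrame, covariates, stratum_col="stratum_id"):
    df = sets.sort_values(stratum_col, kind="stable").reset_index(drop=True)
    codes, _ = pd.factorize(df[stratum_col], sort=False)
    offsets = np.flatnonzero(np.r_[1, np.diff(codes)])
    X = df[list(covariates)].to_numpy(dtype=float)
    y = df["used"].to_numpy(dtype=int)
    used_per = np.add.reduceat(y, offsets)
    if np.any(used_per != 1):
        raise ValidationError("every stratum must contain exactly one used step")
    for k, name in enumerate(covariates):
        hi = np.maximum.reduceat(X[:, k], offsets)
        lo = np.minimum.reduceat(X[:, k], offsets)
        if np.all(hi - lo == 0):
            raise NonIdentifiableError(
                f"covariate {name!r} is constant within every stratum"
            )
    return df, X, y, codes, offsets


def _cond_parts(X, y, codes, offsets, beta):
    """Conditional-logistic log-likelihood, gradient, and information matrix."""
    eta = X @ beta
    m = np.maximum.reduceat(eta, offsets)
    z = np.exp(eta - m[codes])
    denom = np.add.reduceat(z, offsets)
    p = z / denom[codes]
    ll = float(eta[y == 1].sum() - (m + np.log(denom)).sum())
    grad = (y - p) @ X
    pX = p[:, None] * X
    M = np.add.reduceat(pX, offsets, axis=0)
    info = X.T @ pX - M.T @ M
    return ll, grad, info


def _newton(X, y, codes, offsets, beta0=None, ridge=1e-10, penalty=None, max_iter=100):
    p = X.shape[1]
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll, grad, info = _cond_parts(X, y, codes, offsets, beta)
    capped = False
    for _ in range(max_iter):
        if penalty is not None:
            grad = grad - beta / penalty
            info = info + np.diag(np.full(p, 1.0 / penalty))
        step = np.linalg.solve(info + ridge * np.eye(p), grad)
        new = beta + step
        for _ in range(30):  # step halving
            nll, ngrad, ninfo = _cond_parts(X, y, codes, offsets, new)
            if penalty is not None:
                nll = nll - float(new @ new) / (2 * penalty)
                ll_cur = ll - float(beta @ beta) / (2 * penalty)
            else:
                ll_cur = ll
            if nll >= ll_cur - 1e-12:
                break
            step = step / 2
            new = beta + step
        if np.any(np.abs(new) > SEPARATION_CAP):
            warnings.warn(
                "possible separation in conditional logistic fit; estimate capped",
                stacklevel=3,
            )
            new = np.clip(new, -SEPARATION_CAP, SEPARATION_CAP)
            capped = True
        done = np.max(np.abs(new - beta)) < 1e-10
        beta, ll, grad, info = new, nll, ngrad, ninfo
        if done or capped:
            break
    return beta, ll, grad, info, capped


def _laplace_loglik(theta, animal_data, p, u_cache):
    beta = theta[:p]
    sig2 = np.exp(theta[p:])
    total = 0.0
    for aid, (X, y, codes, offsets) in animal_data.items():
        u = u_cache.get(aid, np.zeros(p)).copy()
        # inner Newton for the conditional mode of the random slopes
        for _ in range(50):
            ll, grad, info = _cond_parts(X, y, codes, offsets, beta + u)
            g = grad - u / sig2
            H = info + np.diag(1.0 / sig2)
            step = np.linalg.solve(H, g)
            u_new = u + np.clip(step, -5, 5)
            if np.max(np.abs(u_new - u)) < 1e-9:
                u = u_new
                break
            u = u_new
        u_cache[aid] = u
        ll, _, info = _cond_parts(X, y, codes, offsets, beta + u)
        G = info + np.diag(1.0 / sig2)
        sign, logdet = np.linalg.slogdet(G)
        if sign <= 0:
            return 1e10
        total += ll - 0.5 * float(u @ (u / sig2)) - 0.5 * logdet - 0.5 * float(np.sum(np.log(sig2)))
    return -total


def _numeric_hessian(fun, x, h=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * h * h)
    return H


def fit_conditional_logistic(
    sets: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    random_effects: bool = False,
    sex: str | None = None,
) -> SsfFit:
    """Fit the SSF by maximizing the stratum-conditional likelihood.

    With ``random_effects`` the likelihood is integrated over independent
    Gaussian random slopes per covariate at the animal level (Laplace
    approximation); the stratum intercepts of the equivalent Poisson
    formulation are conditioned out exactly, which corresponds to the
    large-variance limit used in that reformulation.
    """
    covariates = tuple(covariates)
    df, X, y, codes, offsets = _prepare(sets, covariates)
    p = len(covariates)
    z = scipy.stats.norm.ppf(0.975)

    if not random_effects:
        beta, ll, grad, info, capped = _newton(X, y, codes, offsets)
        vcov = np.linalg.inv(info + 1e-10 * np.eye(p))
        se = np.sqrt(np.diag(vcov))
        return SsfFit(
            covariates=covariates,
            beta=dict(zip(covariates, beta)),
            se=dict(zip(covariates, se)),
            ci_lower=dict(zip(covariates, beta - z * se)),
            ci_upper=dict(zip(covariates, beta + z * se)),
            sex=sex,
            n_strata=len(offsets),
            loglik=ll,
            converged=not capped,
            vcov=vcov,
        )

    animal_data = {}
    for aid, g in df.groupby("animal_id", sort=True):
        sub = g.reset_index(drop=True)
        acodes, _ = pd.factorize(sub["stratum_id"], sort=False)
        aoffs = np.flatnonzero(np.r_[1, np.diff(acodes)])
        animal_data[aid] = (
            sub[list(covariates)].to_numpy(dtype=float),
            sub["used"].to_numpy(dtype=int),
            acodes,
            aoffs,
        )
    beta0, *_ = _newton(X, y, codes, offsets)
    u_cache: dict = {}
    theta0 = np.r_[beta0, np.full(p, np.log(0.1))]
    bounds = [(None, None)] * p + [(np.log(1e-4), np.log(20.0))] * p
    res = scipy.optimize.minimize(
        _laplace_loglik,
        theta0,
        args=(animal_data, p, u_cache),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 300, "ftol": 1e-11},
    )
    theta = res.x
    H = _numeric_hessian(lambda t: _laplace_loglik(t, animal_data, p, dict(u_cache)), theta)
    try:
        vcov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov_full = np.linalg.pinv(H)
    beta = theta[:p]
    se = np.sqrt(np.clip(np.diag(vcov_full)[:p], 0, None))
    return SsfFit(
        covariates=covariates,
        beta=dict(zip(covariates, beta)),
        se=dict(zip(covariates, se)),
        ci_lower=dict(zip(covariates, beta - z * se)),
        ci_upper=dict(zip(covariates, beta + z * se)),
        re_variance=dict(zip(covariates, np.exp(theta[p:]))),
        sex=sex,
        n_strata=len(offsets),
        loglik=-res.fun,
        converged=bool(res.success),
        method="laplace_mixed_conditional_logistic",
        vcov=vcov_full[:p, :p],
    )


def fit_poisson_reformulation(
    sets: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    stratum_variance: float = 1e6,
    sex: str | None = None,
) -> SsfFit:
    """Poisson reformulation of the conditional logistic model.

    Each stratum receives its own intercept with a Gaussian penalty of fixed
    large variance (default 1e6), and the used/available indicator is treated
    as a Poisson response.  The intercepts are profiled out by per-stratum
    Newton steps; the fixed effects then maximize the penalized Poisson
    likelihood.  This is an independent computational route whose estimates
    agree with :func:`fit_conditional_logistic` as the variance grows.
    """
    covariates = tuple(covariates)
    df, X, y, codes, offsets = _prepare(sets, covariates)
    p = len(covariates)
    v = float(stratum_variance)

    def profile_alpha(beta):
        eta = X @ beta
        T = np.add.reduceat(np.exp(eta), offsets)
        alpha = -np.log(T)
        for _ in range(50):
            e = np.exp(alpha) * T
            f = 1.0 - e - alpha / v
            fp = -e - 1.0 / v
            step = f / fp
            alpha = alpha - step
            if np.max(np.abs(step)) < 1e-12:
                break
        return alpha, eta

    def nll_grad(beta):
        alpha, eta = profile_alpha(beta)
        lin = alpha[codes] + eta
        mu = np.exp(lin)
        ll = float((y * lin - mu).sum() - (alpha @ alpha) / (2 * v))
        grad = (y - mu) @ X  # envelope: d alpha / d beta terms vanish at the profile optimum
        return -ll, -grad

    res = scipy.optimize.minimize(nll_grad, np.zeros(p), jac=True, method="BFGS",
                                  options={"gtol": 1e-10, "maxiter": 500})
    beta = res.x
    alpha, eta = profile_alpha(beta)
    mu = np.exp(alpha[codes] + eta)
    muX = mu[:, None] * X
    H_bb = X.T @ muX
    H_ab = np.add.reduceat(muX, offsets, axis=0)  # (S, p)
    H_aa = np.add.reduceat(mu, offsets) + 1.0 / v
    info = H_bb - H_ab.T @ (H_ab / H_aa[:, None])
    vcov = np.linalg.inv(info)
    se = np.sqrt(np.diag(vcov))
    z = scipy.stats.norm.ppf(0.975)
    return SsfFit(
        covariates=covariates,
        beta=dict(zip(covariates, beta)),
        se=dict(zip(covariates, se)),
        ci_lower=dict(zip(covariates, beta - z * se)),
        ci_upper=dict(zip(covariates, beta + z * se)),
        sex=sex,
        n_strata=len(offsets),
        loglik=-res.fun,
        converged=bool(res.success),
        method="poisson_reformulation",
        vcov=vcov,
    )


def rss(beta: float) -> float:
    """Relative selection strength: exp(beta)."""
    return float(np.exp(beta))


def log_rss(beta: float) -> float:
    """Log relative selection strength (the coefficient itself)."""
    return float(beta)


def rss_interval(lower: float, upper: float) -> tuple:
    """Exponentiate interval endpoints onto the RSS scale."""
    return float(np.exp(lower)), float(np.exp(upper))


def summary_table(fit: SsfFit) -> pd.DataFrame:
    """Coefficient table: beta, 95% CI, RSS, and RSS CI per covariate."""
    rows = []
    for c in fit.covariates:
        lo, hi = fit.ci_lower[c], fit.ci_upper[c]
        rows.append(
            {
                "sex": fit.sex,
                "feature": c,
                "beta": fit.beta[c],
                "beta_lo": lo,
                "beta_hi": hi,
                "rss": rss(fit.beta[c]),
                "rss_lo": rss(lo),
                "rss_hi": rss(hi),
            }
        )
    return pd.DataFrame(rows)
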