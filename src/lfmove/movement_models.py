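"""Hurdle and context-dependent movement models, plus reporting transforms.

The hurdle model separates the probability of moving at all (binomial, sex
effect) from the positive step length given movement (gamma with log link,
sex effect); both parts carry an animal-level Gaussian random intercept
fitted by a Laplace approximation, and the likelihood factorizes so the two
submodels are fitted independently.  The context model is a binomial
mixed-effects logistic regression of move/remain on the habitat occupied at
the previous relocation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats

from .errors import DegenerateFitError, NonIdentifiableError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "ContextFit",
    "HurdleFit",
    "fit_context_movement",
    "fit_hurdle",
    "odds_percent_change",
    "shift_probability",
]

_Z95 = 1.959963984540054


def odds_percent_change(beta: float) -> float:
    """Percent change in odds implied by a log-odds coefficient.

    Returns ``(exp(beta) - 1) * 100``; negative values read as "X% lower".
    """
    if not np.isfinite(beta):
        raise ValidationError("beta must be finite")
    return float(np.expm1(beta) * 100.0)


def shift_probability(p_base: float, beta: float) -> float:
    """Shift a baseline probability by ``beta`` on the log-odds scale."""
    if not (0.0 < p_base < 1.0):
        raise ValidationError("p_base must lie strictly between 0 and 1")
    if not np.isfinite(beta):
        raise ValidationError("beta must be finite")
    return float(scipy.special.expit(scipy.special.logit(p_base) + beta))


# ---------------------------------------------------------------------------
# Laplace-approximate GLMM with a single random intercept per group


def _binom_parts(eta, y):
    mu = scipy.special.expit(eta)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return ll, y - mu, mu * (1 - mu)


def _gamma_parts(eta, y, shape):
    # gamma log-link: mu = exp(eta); density Gamma(shape, scale=mu/shape)
    r = y * np.exp(-eta)
    ll = float(
        np.sum(
            shape * np.log(shape)
            - scipy.special.gammaln(shape)
            + (shape - 1) * np.log(y)
            - shape * eta
            - shape * r
        )
    )
    return ll, shape * (r - 1.0), shape * r


def _glmm_loglik(X, y, gidx, n_groups, beta, sig2, family, shape=None, b_cache=None):
    """Laplace log-likelihood; also returns the conditional modes."""
    b = np.zeros(n_groups) if b_cache is None else b_cache.copy()
    fixed = X @ beta
    for _ in range(100):
        eta = fixed + b[gidx]
        if family == "binomial":
            _, resid, w = _binom_parts(eta, y)
        else:
            _, resid, w = _gamma_parts(eta, y, shape)
        g = np.bincount(gidx, weights=resid, minlength=n_groups) - b / sig2
        info = np.bincount(gidx, weights=w, minlength=n_groups) + 1.0 / sig2
        step = np.clip(g / info, -5, 5)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = fixed + b[gidx]
    if family == "binomial":
        ll_rows, _, w = _binom_parts(eta, y)
    else:
        ll_rows, _, w = _gamma_parts(eta, y, shape)
    G = np.bincount(gidx, weights=w, minlength=n_groups) + 1.0 / sig2
    ll = ll_rows - 0.5 * float(b @ b) / sig2 - 0.5 * float(np.sum(np.log(sig2 * G)))
    return ll, b


def _glm_loglik(X, y, beta, family, shape=None):
    eta = X @ beta
    if family == "binomial":
        ll, _, _ = _binom_parts(eta, y)
    else:
        ll, _, _ = _gamma_parts(eta, y, shape)
    return ll


def _start_beta(X, y, family):
    beta = np.zeros(X.shape[1])
    m = float(np.mean(y))
    if family == "binomial":
        m = min(max(m, 1e-3), 1 - 1e-3)
        beta[0] = scipy.special.logit(m)
    else:
        beta[0] = np.log(max(m, 1e-6))
    return beta


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


def laplace_glmm(X, y, groups, family: str) -> dict:
    """Fit a GLM with one Gaussian random intercept per group (Laplace).

    ``family`` is ``"binomial"`` (logit link) or ``"gamma"`` (log link, shape
    estimated).  With fewer than two groups the random effect is dropped with
    a warning.  Returns a dict with ``beta``, ``se``, ``vcov``, ``sigma2``,
    ``loglik``, and for the gamma family ``shape``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    codes, uniq = pd.factorize(pd.Series(groups), sort=True)
    n_groups = len(uniq)
    p = X.shape[1]
    is_gamma = family == "gamma"
    beta0 = _start_beta(X, y, family)
    use_re = n_groups >= 2
    if not use_re:
        warnings.warn("fewer than two groups; random intercept dropped", stacklevel=2)

    if is_gamma:
        m, v = float(np.mean(y)), float(np.var(y))
        shape0 = np.log(max(m * m / v, 0.1)) if v > 0 else 0.0
        theta0 = np.r_[beta0, shape0] if not use_re else np.r_[beta0, np.log(0.25), shape0]
    else:
        theta0 = beta0 if not use_re else np.r_[beta0, np.log(0.25)]

    cache = {"b": None}

    def nll(theta):
        beta = theta[:p]
        shape = np.exp(theta[-1]) if is_gamma else None
        if not use_re:
            return -_glm_loglik(X, y, beta, family, shape)
        sig2 = float(np.exp(theta[p]))
        ll, b = _glmm_loglik(X, y, codes, n_groups, beta, sig2, family, shape, cache["b"])
        cache["b"] = b
        return -ll

    res = scipy.optimize.minimize(nll, theta0, method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-12})
    theta = res.x
    b_final = None if cache["b"] is None else cache["b"].copy()

    def nll_frozen(t):
        saved = cache["b"]
        out = nll(t)
        cache["b"] = saved
        return out

    H = _numeric_hessian(nll_frozen, theta)
    try:
        vcov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov_full = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(vcov_full)[:p], 0, None))
    out = {
        "beta": theta[:p],
        "se": se,
        "vcov": vcov_full[:p, :p],
        "sigma2": float(np.exp(theta[p])) if use_re else 0.0,
        "loglik": -res.fun,
        "converged": bool(res.success),
        "n_groups": n_groups,
        "ranef": b_final,
    }
    if is_gamma:
        out["shape"] = float(np.exp(theta[-1]))
    return out


# ---------------------------------------------------------------------------
# hurdle model


@dataclass
class HurdleFit:
    """Sex-specific gamma hurdle model for movement probability and step length."""

    binomial: dict | None
    gamma: dict
    mean_step: dict  # sex -> (estimate, lower, upper)
    loglik: float

    @property
    def loglik_binomial(self):
        return self.binomial["loglik"] if self.binomial else 0.0

    @property
    def loglik_gamma(self):
        return self.gamma["loglik"]


def _design_sex(sex_series):
    sex = np.asarray(sex_series)
    male = (sex == "M").astype(float)
    return np.column_stack([np.ones(len(male)), male])


def fit_hurdle(records: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> HurdleFit:
    """Fit the two-part movement model on relocation-level records.

    ``records`` needs columns ``moved`` (0/1), ``length`` (meters, used where
    moved), ``sex`` ('M'/'F'), and ``animal_id``.  Both submodels carry an
    animal random intercept.  Sex-specific mean step lengths are predicted at
    zero random effect, with 95% intervals from a parametric bootstrap of the
    fixed effects.
    """
    for col in ("moved", "length", "sex", "animal_id"):
        if col not in records.columns:
            raise ValidationError(f"records missing column {col!r}")
    if set(records["sex"].unique()) != {"M", "F"}:
        raise ValidationError("both sexes must be present")
    moved = records["moved"].to_numpy(dtype=int)

    binom = None
    if moved.min() == moved.max():
        warnings.warn("all records share one moved value; binomial hurdle part degenerate", stacklevel=2)
    else:
        binom = laplace_glmm(
            _design_sex(records["sex"]), moved, records["animal_id"], "binomial"
        )

    movers = records[records["moved"] == 1]
    for sex in ("M", "F"):
        if (movers["sex"] == sex).sum() == 0:
            raise DegenerateFitError(f"no movements recorded for sex {sex!r}")
    lengths = movers["length"].to_numpy(dtype=float)
    if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
        raise ValidationError("movement step lengths must be positive and finite")
    gam = laplace_glmm(_design_sex(movers["sex"]), lengths, movers["animal_id"], "gamma")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(gam["beta"], gam["vcov"], size=n_boot)
    mean_step = {}
    for sex, xrow in (("F", np.array([1.0, 0.0])), ("M", np.array([1.0, 1.0]))):
        est = float(np.exp(gam["beta"] @ xrow))
        boot = np.exp(draws @ xrow)
        mean_step[sex] = (est, float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))

    total = (binom["loglik"] if binom else 0.0) + gam["loglik"]
    return HurdleFit(binomial=binom, gamma=gam, mean_step=mean_step, loglik=total)


# ---------------------------------------------------------------------------
# context-dependent movement


@dataclass
class ContextFit:
    """Movement probability as a function of prior-location habitat occupancy."""

    intercept: float
    beta: float
    se: float
    ci_lower: float
    ci_upper: float
    re_variance: float
    p_in: tuple  # (estimate, lower, upper)
    p_out: tuple
    loglik: float

    @property
    def odds_change_percent(self) -> float:
        return odds_percent_change(self.beta)


def fit_context_movement(records: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> ContextFit:
    """Logistic regression of move/remain on prior-location habitat occupancy.

    ``records`` needs columns ``moved`` (0/1), ``in_habitat_prior`` (0/1),
    and ``animal_id``; individuals are pooled across sexes with an animal
    random intercept.
    """
    for col in ("moved", "in_habitat_prior", "animal_id"):
        if col not in records.columns:
            raise ValidationError(f"records missing column {col!r}")
    h = records["in_habitat_prior"].to_numpy(dtype=float)
    if h.min() == h.max():
        raise NonIdentifiableError("habitat indicator is constant; effect not identifiable")
    X = np.column_stack([np.ones(len(h)), h])
    fit = laplace_glmm(X, records["moved"].to_numpy(dtype=int), records["animal_id"], "binomial")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit["beta"], fit["vcov"], size=n_boot)

    def prob(xrow):
        est = float(scipy.special.expit(fit["beta"] @ xrow))
        boot = scipy.special.expit(draws @ xrow)
        return (est, float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))

    beta = float(fit["beta"][1])
    se = float(fit["se"][1])
    return ContextFit(
        intercept=float(fit["beta"][0]),
        beta=beta,
        se=se,
        ci_lower=beta - _Z95 * se,
        ci_upper=beta + _Z95 * se,
        re_variance=fit["sigma2"],
        p_in=prob(np.array([1.0, 1.0])),
        p_out=prob(np.array([1.0, 0.0])),
        loglik=fit["loglik"],
    )


def hurdle_records(trajs) -> pd.DataFrame:
    """Relocation-level move/length records for :func:`fit_hurdle`.

    One row per relocation after the first of each trajectory: whether the
    animal moved, and the step length when it did.
    """
    rows = []
    for traj in trajs:
        pts = traj.points()
        moved = traj.relocations["moved"].to_numpy(dtype=bool)
        d = np.hypot(*(pts[1:] - pts[:-1]).T)
        for i in range(1, len(pts)):
            rows.append(
                {
                    "animal_id": traj.animal_id,
                    "sex": traj.sex,
                    "moved": int(moved[i]),
                    "length": d[i - 1] if moved[i] else np.nan,
                }
            )
    return pd.DataFrame(rows)


def context_records(trajs, habitat_polygon) -> pd.DataFrame:
    """Move/remain records keyed to prior-location habitat occupancy.

    For each relocation after the first, the predictor is whether the
    *previous* relocation lay inside ``habitat_polygon``.
    """
    from .geometry import points_in_polygon_mask

    rows = []
    for traj in trajs:
        pts = traj.points()
        inside = points_in_polygon_mask(pts, habitat_polygon)
        moved = traj.relocations["moved"].to_numpy(dtype=bool)
        for i in range(1, len(pts)):
            rows.append(
                {
                    "animal_id": traj.animal_id,
                    "moved": int(moved[i]),
                    "in_habitat_prior": int(inside[i - 1]),
                }
            )
    return pd.DataFrame(rows)


def context_summary(fit: ContextFit, label: str = "habitat") -> pd.DataFrame:
    """One-row summary mirroring the reported quantities."""
    return pd.DataFrame(
        [
            {
                "habitat": label,
                "beta": fit.beta,
                "se": fit.se,
                "ci_lower": fit.ci_lower,
                "ci_upper": fit.ci_upper,
                "odds_change_percent": fit.odds_change_percent,
                "p_in": fit.p_in[0],
                "p_in_lo": fit.p_in[1],
                "p_in_hi": fit.p_in[2],
                "p_out": fit.p_out[0],
                "p_out_lo": fit.p_out[1],
                "p_out_hi": fit.p_out[2],
            }
        ]
    )


def hurdle_summary(fit: HurdleFit) -> pd.DataFrame:
    """Term-level summary for both hurdle submodels."""
    rows = []
    for part, d in (("binomial", fit.binomial), ("gamma", fit.gamma)):
        if d is None:
            continue
        for name, est, se in zip(("intercept", "sex_male"), d["beta"], d["se"]):
            rows.append(
                {
                    "part": part,
                    "term": name,
                    "estimate": est,
                    "se": se,
                    "ci_lower": est - _Z95 * se,
                    "ci_upper": est + _Z95 * se,
                }
            )
        rows.append(
            {
                "part": part,
                "term": "random_intercept_variance",
                "estimate": d["sigma2"],
                "se": np.nan,
                "ci_lower": np.nan,
                "ci_upper": np.nan,
            }
        )
    for sex, (est, lo, hi) in fit.mean_step.items():
        rows.append(
            {
                "part": "prediction",
                "term": f"mean_step_{sex}",
                "estimate": est,
                "se": np.nan,
                "ci_lower": lo,
                "ci_upper": hi,
            }
        )
    return pd.DataFrame(rows)
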