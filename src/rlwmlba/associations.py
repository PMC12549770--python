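"""Bayesian association analyses.

Linear regression with N(0,1) coefficient priors sampled by Gibbs-within-MH,
Savage-Dickey Bayes factors against the point null at zero with the
conventional evidence bands, a trial-level mixed logistic model of accuracy
with task factors and subject intercepts (Laplace approximation), and an
item-level cumulative-logit ordinal regression with subject intercepts
(adaptive Metropolis-within-Gibbs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, log_expit
from scipy.stats import gaussian_kde, norm

PRIOR_SD = 1.0  # N(0, 1) coefficient prior used throughout
RHAT_THRESHOLD = 1.02


class ConvergenceWarning(UserWarning):
    pass


class SeparationError(RuntimeError):
    """Degenerate accuracy pattern: a predictor separates the outcome."""


def standardize(x) -> np.ndarray:
    """Z-score with the population-SD convention (divide by n)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0.0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one scalar quantity.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half.
    """
    n_chains, n_draws = chains.shape
    half = n_draws // 2
    splits = chains[:, : 2 * half].reshape(n_chains * 2, half)
    m, n = splits.shape
    means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


@dataclass
class RegressionResult:
    """Posterior summary per coefficient, with draws and diagnostics."""

    names: list
    draws: np.ndarray  # (n_total_draws, n_coef)
    mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    bf01: np.ndarray
    rhat: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.names,
                "mean": self.mean,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "bf01": self.bf01,
                "band": [interpret_bf(b).label for b in self.bf01],
                "rhat": self.rhat,
            }
        )

    def coefficient(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "mean": float(self.mean[i]),
            "ci": (float(self.ci_lower[i]), float(self.ci_upper[i])),
            "bf01": float(self.bf01[i]),
            "draws": self.draws[:, i],
        }


def _summarize(names, chains, diagnostics, prior_sd=PRIOR_SD) -> RegressionResult:
    """chains: (n_chains, n_draws, n_coef)."""
    n_coef = chains.shape[2]
    draws = chains.reshape(-1, n_coef)
    rhat = np.array([split_rhat(chains[:, :, j]) for j in range(n_coef)])
    if np.any(rhat > RHAT_THRESHOLD):
        bad = [names[j] for j in np.flatnonzero(rhat > RHAT_THRESHOLD)]
        diagnostics = {**diagnostics, "converged": False, "nonconverged": bad}
        warnings.warn(
            f"split R-hat above {RHAT_THRESHOLD} for {bad}", ConvergenceWarning
        )
    else:
        diagnostics = {**diagnostics, "converged": True}
    return RegressionResult(
        names=list(names),
        draws=draws,
        mean=draws.mean(axis=0),
        ci_lower=np.percentile(draws, 2.5, axis=0),
        ci_upper=np.percentile(draws, 97.5, axis=0),
        bf01=np.array(
            [savage_dickey_bf01(draws[:, j], prior_sd=prior_sd) for j in range(n_coef)]
        ),
        rhat=rhat,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Savage-Dickey Bayes factors and evidence bands
# ---------------------------------------------------------------------------


def savage_dickey_bf01(draws: np.ndarray, prior_sd: float = PRIOR_SD) -> float:
    """BF01 = posterior density at 0 (Gaussian KDE) / prior density at 0."""
    draws = np.asarray(draws, dtype=float)
    if len(draws) < 1000:
        warnings.warn("fewer than 1000 draws; Savage-Dickey estimate is noisy")
    if 0.0 < draws.min() or 0.0 > draws.max():
        warnings.warn(
            "0 lies outside the posterior draw range; density estimate unreliable"
        )
    post_at_zero = float(gaussian_kde(draws)(0.0)[0])
    prior_at_zero = float(norm.pdf(0.0, 0.0, prior_sd))
    # keep the ratio strictly positive even when the KDE underflows
    return max(post_at_zero / prior_at_zero, 1e-300)


@dataclass(frozen=True)
class EvidenceBand:
    bf01: float
    label: str


_BANDS = ["anecdotal", "moderate", "strong", "very strong", "extreme"]
_EDGES = [1.0, 3.0, 10.0, 30.0, 100.0]


def interpret_bf(bf01: float) -> EvidenceBand:
    """Evidence band for a BF01 value.

    Bands are symmetric around 1 (null side: 1-3 anecdotal, 3-10 moderate,
    10-30 strong, 30-100 very strong, >100 extreme; alternative side the
    reciprocals). Intervals are closed on the boundary further from 1, so
    BF01 = 0.3 is "moderate" and BF01 = 3 is "moderate".
    """
    if not bf01 > 0:
        raise ValueError("BF01 must be positive")
    if bf01 >= 1.0:
        side = "null"
        x = bf01
    else:
        side = "alternative"
        x = 1.0 / bf01
    idx = 0
    for i, edge in enumerate(_EDGES[1:], start=1):
        if x >= edge:
            idx = i
    return EvidenceBand(bf01=float(bf01), label=f"{_BANDS[idx]} ({side})")


# ---------------------------------------------------------------------------
# Bayesian linear regression (Gibbs for beta, MH for sigma)
# ---------------------------------------------------------------------------


def bayes_linear_regression(
    y,
    X: pd.DataFrame | np.ndarray,
    *,
    seed: int = 0,
    n_chains: int = 4,
    n_draws: int = 5000,
    warmup: int = 1000,
    sigma: Optional[float] = None,
    names: Optional[Sequence[str]] = None,
) -> RegressionResult:
    """Linear model with N(0,1) coefficient priors.

    The response is centered internally; coefficients are drawn from their
    conjugate conditional given the residual SD, and the residual SD (weak
    half-normal prior) is updated by random-walk MH on the log scale. Pass
    ``sigma`` to fix the residual SD (the fully conjugate case).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if names is None else list(names)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])] if names is None else list(names)
    y = np.asarray(y, dtype=float)
    y_c = y - y.mean()
    n, p = X.shape
    xtx = X.T @ X
    xty = X.T @ y_c
    sigma_prior_scale = 5.0 * max(y_c.std(), 1e-12)

    rng = np.random.default_rng(seed)
    chains = np.empty((n_chains, n_draws, p))
    accepts = []
    for c in range(n_chains):
        sig = y_c.std() if sigma is None else float(sigma)
        log_sig = np.log(max(sig, 1e-12))
        step = 0.2
        n_acc = 0
        beta = np.zeros(p)
        for it in range(warmup + n_draws):
            # beta | sigma: conjugate ridge-form normal
            prec = xtx / sig**2 + np.eye(p) / PRIOR_SD**2
            cov = np.linalg.inv(prec)
            mean = cov @ xty / sig**2
            beta = rng.multivariate_normal(mean, cov, method="cholesky")
            if sigma is None:
                # sigma | beta: random-walk MH on log sigma with half-normal prior
                resid = y_c - X @ beta
                prop = log_sig + step * rng.standard_normal()

                def _logp(ls):
                    s2 = np.exp(2 * ls)
                    return (
                        -0.5 * (resid**2).sum() / s2
                        - n * ls
                        - 0.5 * np.exp(2 * ls) / sigma_prior_scale**2
                        + ls  # log-scale Jacobian
                    )

                if np.log(rng.random()) < _logp(prop) - _logp(log_sig):
                    log_sig = prop
                    n_acc += 1
                sig = np.exp(log_sig)
                if it < warmup and (it + 1) % 100 == 0:
                    rate = n_acc / (it + 1)
                    step *= np.exp(0.5 * (rate - 0.44))
            if it >= warmup:
                chains[c, it - warmup] = beta
        accepts.append(n_acc / (warmup + n_draws))
    return _summarize(names, chains, {"accept_rate_sigma": accepts})


# ---------------------------------------------------------------------------
# Trial-level mixed logistic regression (Laplace approximation)
# ---------------------------------------------------------------------------

DEFAULT_TASK_FACTORS = ["delay", "set_size", "reward_history", "block"]


def _logistic_map(y, X, subj_idx, n_subj, max_coef=12.0):
    """MAP of (beta, u, log sigma_u) for the Bernoulli-logit mixed model."""
    n, p = X.shape

    def unpack(theta):
        return theta[:p], theta[p : p + n_subj], theta[p + n_subj]

    def negloglik(theta):
        beta, u, log_su = unpack(theta)
        su = np.exp(log_su)
        eta = X @ beta + u[subj_idx]
        # Bernoulli-logit log-likelihood via log_expit for stability
        ll = np.where(y == 1, log_expit(eta), log_expit(-eta)).sum()
        lp = (
            -0.5 * (beta**2).sum() / PRIOR_SD**2
            - 0.5 * (u**2).sum() / su**2
            - n_subj * log_su
            - 0.5 * su**2  # half-normal(0, 1) prior on sigma_u
            + log_su  # Jacobian of the log parametrization
        )
        return -(ll + lp)

    def grad(theta):
        beta, u, log_su = unpack(theta)
        su = np.exp(log_su)
        eta = X @ beta + u[subj_idx]
        resid = y - expit(eta)
        g_beta = X.T @ resid - beta / PRIOR_SD**2
        g_u = np.bincount(subj_idx, weights=resid, minlength=n_subj) - u / su**2
        g_ls = (u**2).sum() / su**2 - n_subj - su**2 + 1.0
        return -np.concatenate([g_beta, g_u, [g_ls]])

    theta0 = np.zeros(p + n_subj + 1)
    res = optimize.minimize(
        negloglik, theta0, jac=grad, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-12},
    )
    beta, u, log_su = unpack(res.x)
    if np.any(np.abs(beta) > max_coef):
        raise SeparationError(
            "a coefficient diverged during fitting; the accuracy pattern is "
            "degenerate (quasi-separation)"
        )
    return beta, u, log_su, res


def _logistic_laplace_cov(beta, u, log_su, X, subj_idx, n_subj):
    """Analytic Gaussian-approximation covariance of (beta, u) at the mode."""
    p = X.shape[1]
    su = np.exp(log_su)
    eta = X @ beta + u[subj_idx]
    w = expit(eta) * (1.0 - expit(eta))
    H = np.zeros((p + n_subj, p + n_subj))
    H[:p, :p] = (X * w[:, None]).T @ X + np.eye(p) / PRIOR_SD**2
    wu = np.bincount(subj_idx, weights=w, minlength=n_subj)
    H[p:, p:] = np.diag(wu + 1.0 / su**2)
    xw = X * w[:, None]
    for j in range(n_subj):
        mask = subj_idx == j
        H[:p, p + j] = xw[mask].sum(axis=0)
        H[p + j, :p] = H[:p, p + j]
    return np.linalg.inv(H)


def trial_logistic_model(
    trials: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    *,
    predictors: Optional[Sequence[str]] = None,
    covariate_columns: Sequence[str] = (),
    seed: int = 0,
    n_draws: int = 5000,
    n_chains: int = 4,
) -> RegressionResult:
    """Mixed logistic regression of trial accuracy on standardized task factors.

    Subject-level random intercepts share a Normal(0, sigma_u) prior
    (half-normal hyperprior); the posterior of the fixed effects is
    approximated by the Laplace method at the joint mode and draws are taken
    from the resulting Gaussian. Coefficients are reported on the log-odds
    scale in ``draws`` and as odds ratios in the ``or_*`` diagnostics.

    First presentations (undefined delay) and non-responses are dropped.
    """
    predictors = list(predictors) if predictors is not None else list(DEFAULT_TASK_FACTORS)
    df = trials[trials["action"].notna() & trials["delay"].notna()].copy()
    if covariates is not None and len(covariate_columns):
        df = df.merge(covariates[["subject_id", *covariate_columns]], on="subject_id")
        predictors = predictors + list(covariate_columns)
    y = df["reward"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise SeparationError("accuracy is constant; logistic model is degenerate")
    X = np.column_stack([standardize(df[c]) for c in predictors])
    X = np.column_stack([np.ones(len(df)), X])
    names = ["intercept", *predictors]
    subjects, subj_idx = np.unique(df["subject_id"].to_numpy(), return_inverse=True)

    beta, u, log_su, res = _logistic_map(y, X, subj_idx, len(subjects))
    cov = _logistic_laplace_cov(beta, u, log_su, X, subj_idx, len(subjects))
    cov_beta = cov[: X.shape[1], : X.shape[1]]

    rng = np.random.default_rng(seed)
    chains = rng.multivariate_normal(
        beta, cov_beta, size=(n_chains, n_draws), method="cholesky"
    )
    result = _summarize(
        names, chains,
        {
            "optimizer_message": str(res.message),
            "sigma_u": float(np.exp(log_su)),
            "n_obs": int(len(df)),
        },
    )
    result.diagnostics["odds_ratio"] = dict(zip(names, np.exp(result.mean)))
    result.diagnostics["or_ci"] = {
        n_: (float(np.exp(lo)), float(np.exp(hi)))
        for n_, lo, hi in zip(names, result.ci_lower, result.ci_upper)
    }
    return result


# ---------------------------------------------------------------------------
# Cumulative-logit ordinal regression (MH within Gibbs)
# ---------------------------------------------------------------------------


def cumulative_logit_probs(eta: np.ndarray, cutpoints: np.ndarray) -> np.ndarray:
    """P(y = k | eta) for each of the K levels implied by K-1 ordered cutpoints."""
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    cum = expit(cutpoints[None, :] - eta[:, None])  # (n, K-1)
    cum = np.hstack([cum, np.ones((len(eta), 1))])
    probs = np.diff(np.hstack([np.zeros((len(eta), 1)), cum]), axis=1)
    return probs


def _ordinal_loglik_terms(y, eta, cutpoints):
    """Per-observation log-likelihood of the cumulative-logit model."""
    k = len(cutpoints) + 1
    hi = np.where(y == k - 1, np.inf, cutpoints[np.minimum(y, k - 2)] - eta)
    lo = np.where(y == 0, -np.inf, cutpoints[np.maximum(y - 1, 0)] - eta)
    p = expit(hi) - expit(lo)
    return np.log(np.maximum(p, 1e-300))


def bayes_ordinal_regression(
    y,
    X: pd.DataFrame | np.ndarray,
    subject_ids,
    *,
    seed: int = 0,
    n_chains: int = 4,
    n_draws: int = 5000,
    warmup: int = 1000,
    thin: int = 1,
    names: Optional[Sequence[str]] = None,
    collapse_missing_levels: bool = False,
) -> RegressionResult:
    """Cumulative-logit model with subject intercepts, sampled by adaptive MH.

    ``y`` holds ordinal responses coded 0..K-1 (every level must be observed
    somewhere unless ``collapse_missing_levels``); ``X`` the standardized
    predictors; ``subject_ids`` maps observations to subjects. Coefficient
    draws carry N(0,1) priors and feed :func:`savage_dickey_bf01`.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if names is None else list(names)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])] if names is None else list(names)
    y = np.asarray(y, dtype=np.int64)
    levels = np.unique(y)
    k = int(y.max()) + 1
    if len(levels) < k or levels[0] != 0:
        if not collapse_missing_levels:
            raise ValueError(
                f"unobserved response levels {sorted(set(range(k)) - set(levels))}; "
                "cutpoints are unidentifiable (set collapse_missing_levels=True)"
            )
        remap = {lv: i for i, lv in enumerate(levels)}
        y = np.array([remap[v] for v in y])
        k = len(levels)
    if k < 2:
        raise ValueError("need at least two observed response levels")
    subjects, subj_idx = np.unique(np.asarray(subject_ids), return_inverse=True)
    n_subj = len(subjects)
    n, p = X.shape

    # empirical-quantile initialization for the cutpoints
    cum_freq = np.cumsum(np.bincount(y, minlength=k)[:-1]) / n
    cut0 = np.log(cum_freq / (1.0 - cum_freq))

    rng = np.random.default_rng(seed)
    chains = np.empty((n_chains, n_draws, p))
    accept = {"beta": [], "cut": [], "u": [], "sigma_u": []}
    for c in range(n_chains):
        beta = np.zeros(p)
        cuts = cut0.copy()
        u = np.zeros(n_subj)
        log_su = np.log(0.5)
        steps = {"beta": 0.05, "cut": 0.05, "u": 0.3, "sigma_u": 0.3}
        acc = {kk: 0 for kk in steps}
        tries = {kk: 0 for kk in steps}

        eta = X @ beta + u[subj_idx]
        ll_terms = _ordinal_loglik_terms(y, eta, cuts)
        ll = ll_terms.sum()
        for it in range(warmup + n_draws):
            # beta block
            prop = beta + steps["beta"] * rng.standard_normal(p)
            eta_p = X @ prop + u[subj_idx]
            ll_p = _ordinal_loglik_terms(y, eta_p, cuts).sum()
            lr = ll_p - ll - 0.5 * ((prop**2).sum() - (beta**2).sum()) / PRIOR_SD**2
            tries["beta"] += 1
            if np.log(rng.random()) < lr:
                beta, eta, ll = prop, eta_p, ll_p
                acc["beta"] += 1

            # cutpoint block (random-walk on first cutpoint + log increments)
            raw = np.concatenate([[cuts[0]], np.log(np.diff(cuts))]) if k > 2 else cuts[:1].copy()
            raw_p = raw + steps["cut"] * rng.standard_normal(len(raw))
            cuts_p = (
                np.concatenate([[raw_p[0]], raw_p[0] + np.cumsum(np.exp(raw_p[1:]))])
                if k > 2
                else raw_p.copy()
            )
            ll_p = _ordinal_loglik_terms(y, eta, cuts_p).sum()
            # weak N(0, 5) prior on cutpoints, plus the log-increment Jacobian
            lpr = -0.5 * ((cuts_p**2).sum() - (cuts**2).sum()) / 25.0
            jac = raw_p[1:].sum() - raw[1:].sum() if k > 2 else 0.0
            tries["cut"] += 1
            if np.log(rng.random()) < ll_p - ll + lpr + jac:
                cuts, ll = cuts_p, ll_p
                acc["cut"] += 1

            # subject intercepts: independent elementwise MH, vectorized
            su = np.exp(log_su)
            u_prop = u + steps["u"] * rng.standard_normal(n_subj)
            eta_p = X @ beta + u_prop[subj_idx]
            terms_p = _ordinal_loglik_terms(y, eta_p, cuts)
            terms_c = _ordinal_loglik_terms(y, eta, cuts)
            per_subj_p = np.bincount(subj_idx, weights=terms_p, minlength=n_subj)
            per_subj_c = np.bincount(subj_idx, weights=terms_c, minlength=n_subj)
            lr_u = per_subj_p - per_subj_c - 0.5 * (u_prop**2 - u**2) / su**2
            accept_mask = np.log(rng.random(n_subj)) < lr_u
            u = np.where(accept_mask, u_prop, u)
            eta = X @ beta + u[subj_idx]
            ll = _ordinal_loglik_terms(y, eta, cuts).sum()
            tries["u"] += 1
            acc["u"] += accept_mask.mean()

            # sigma_u: MH on the log scale with half-normal(0,1) prior
            prop_ls = log_su + steps["sigma_u"] * rng.standard_normal()

            def _lp_su(ls):
                s = np.exp(ls)
                return (
                    -0.5 * (u**2).sum() / s**2 - n_subj * ls - 0.5 * s**2 + ls
                )

            tries["sigma_u"] += 1
            if np.log(rng.random()) < _lp_su(prop_ls) - _lp_su(log_su):
                log_su = prop_ls
                acc["sigma_u"] += 1

            if it < warmup and (it + 1) % 50 == 0:
                for kk in steps:
                    rate = acc[kk] / tries[kk]
                    target = 0.44 if kk in ("u", "sigma_u") else 0.23
                    steps[kk] *= np.exp(0.5 * (rate - target))
            if it >= warmup:
                chains[c, it - warmup] = beta
        for kk in steps:
            accept[kk].append(acc[kk] / tries[kk])

    return _summarize(names, chains, {"accept_rates": accept, "n_levels": k})
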