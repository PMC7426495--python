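"""Single-trait genomic prediction: closed-form GBLUP and Bayesian RKHS.

Stage 2 of the pipeline regresses family BLUPs on the genomic
relationship matrix K:

    y = 1 beta + alpha + eps,  alpha ~ N(0, K sigma2_u),  eps ~ N(0, I sigma2_e)

:class:`GBLUP` fits this by REML (a one-dimensional profile likelihood in
the variance ratio, after rotating into the eigenbasis of K) and returns
best linear unbiased predictions of the breeding values alpha for *all*
individuals in K, observed or not, via the conditional expectation of the
joint multivariate normal.

:class:`RKHSRegression` is the Bayesian counterpart: a reproducing-kernel
Hilbert-space regression with K as the (linear) kernel, sampled by Gibbs.
With a linear kernel RKHS and GBLUP are the same model, so the two
fitters agree up to Monte-Carlo error; the sampler exists because the
multi-trait extension (:mod:`mtgp.multitrait`) is Bayesian and the pair
share machinery and priors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from mtgp.grm import GRM

logger = logging.getLogger(__name__)

__all__ = ["GBLUP", "RKHSRegression", "STResults", "scaled_inv_chi2_prior"]


def _as_grm(K) -> GRM:
    return K if isinstance(K, GRM) else GRM(np.asarray(K, dtype=float))


def _observed_vector(y, K: GRM) -> np.ndarray:
    """Align a response to the GRM sample order; NaN marks unobserved."""
    if isinstance(y, pd.Series):
        full = np.full(K.n, np.nan)
        idx = K.index_of(y.index)
        full[idx] = y.to_numpy(dtype=float)
        return full
    y = np.asarray(y, dtype=float)
    if y.shape[0] != K.n:
        raise ValueError("response length does not match kernel dimension")
    return y


@dataclass
class STResults:
    """Single-trait fit: GEBVs for every individual plus variance estimates."""

    gebv: pd.Series  # breeding values, all individuals in K
    beta: float
    sigma2_u: float
    sigma2_e: float
    method: str
    gebv_sd: "pd.Series | None" = None
    n_iter: int = 0
    burn_in: int = 0
    ess: dict = field(default_factory=dict)
    loglik: float = np.nan

    @property
    def h2(self) -> float:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_e)

    def predict(self, ids) -> pd.Series:
        return self.gebv.loc[list(ids)]

    def summary(self) -> str:
        lines = [
            f"Single-trait genomic prediction ({self.method})",
            f"  n individuals: {len(self.gebv)}   observed: "
            f"{int((~np.isnan(self._y_obs)).sum()) if hasattr(self, '_y_obs') else 'n/a'}",
            f"  beta = {self.beta:.4f}",
            f"  sigma2_u = {self.sigma2_u:.4f}   sigma2_e = {self.sigma2_e:.4f}"
            f"   h2 = {self.h2:.3f}",
        ]
        if self.n_iter:
            lines.append(f"  chain: {self.n_iter} iterations, {self.burn_in} burn-in")
        return "\n".join(lines)


class GBLUP:
    """Closed-form GBLUP with REML variance components.

    Parameters
    ----------
    y : Series or ndarray
        Response (family BLUPs); a Series is aligned to the GRM by id, an
        array must match the GRM order.  NaN = unobserved (predicted only).
    K : GRM or ndarray
        Relationship kernel over all individuals.
    """

    def __init__(self, y, K) -> None:
        self.K = _as_grm(K)
        self.K, self._bend = self.K.bend()
        self.y = _observed_vector(y, self.K)
        self.obs = ~np.isnan(self.y)
        if self.obs.sum() < 3:
            raise ValueError("need at least 3 observed individuals")

    def fit(self, varcomp: "tuple[float, float] | None" = None) -> STResults:
        """Fit by REML (or at supplied ``varcomp = (sigma2_u, sigma2_e)``)."""
        obs = self.obs
        yo = self.y[obs]
        n = int(obs.sum())
        Koo = self.K.values[np.ix_(obs, obs)]
        d, U = np.linalg.eigh(Koo)
        d = np.clip(d, 0.0, None)
        yt = U.T @ yo
        xt = U.T @ np.ones(n)

        def neg_restricted_ll(log_gamma: float) -> float:
            g = np.exp(log_gamma)
            v = g * d + 1.0  # V / sigma2_e
            xvx = np.sum(xt**2 / v)
            beta = np.sum(xt * yt / v) / xvx
            r = yt - xt * beta
            rss = np.sum(r**2 / v)
            s2e = rss / (n - 1)
            return 0.5 * (
                np.sum(np.log(v)) + (n - 1) * np.log(s2e) + np.log(xvx) + (n - 1)
            )

        if varcomp is None:
            opt = minimize_scalar(
                neg_restricted_ll, bounds=(-10.0, 10.0), method="bounded",
                options={"xatol": 1e-10},
            )
            gamma = float(np.exp(opt.x))
            v = gamma * d + 1.0
            xvx = np.sum(xt**2 / v)
            beta = float(np.sum(xt * yt / v) / xvx)
            s2e = float(np.sum((yt - xt * beta) ** 2 / v) / (n - 1))
            s2u = gamma * s2e
            ll = -opt.fun
        else:
            s2u, s2e = map(float, varcomp)
            gamma = s2u / s2e
            v = gamma * d + 1.0
            xvx = np.sum(xt**2 / v)
            beta = float(np.sum(xt * yt / v) / xvx)
            ll = np.nan

        # alpha_hat = s2u * K[:, obs] @ Voo^{-1} (y - beta); Voo = s2e (gamma Koo + I)
        w = U @ ((yt - xt * beta) / v)  # (gamma Koo + I)^{-1} (y - 1 beta)
        alpha = gamma * (self.K.values[:, obs] @ w)
        gebv = pd.Series(alpha, index=pd.Index(self.K.sample_ids, name="family"))
        res = STResults(
            gebv=gebv, beta=beta, sigma2_u=s2u, sigma2_e=s2e, method="gblup-reml",
            loglik=ll,
        )
        res._y_obs = self.y
        return res


def scaled_inv_chi2_prior(df: float, mode: float) -> tuple[float, float]:
    """(df, scale) of a scaled-inverse-chi² with the requested prior mode."""
    return df, mode * (df + 2.0) / df


class RKHSRegression:
    """Bayesian RKHS regression with a linear kernel, fitted by Gibbs.

    The kernel eigendecomposition K = U D U' is computed once; the model
    is then y = 1 beta + U delta + eps with independent delta_j ~
    N(0, sigma2_u d_j), so every full conditional is univariate and one
    Gibbs sweep costs O(n).  Flat prior on beta; scaled-inverse-chi²
    priors (default df 5, mode 0.5 var(y)) on both variances.  Unobserved
    responses are imputed by data augmentation; the residual-variance
    update uses observed cells only, so imputation cannot bias it.
    """

    def __init__(self, y, K) -> None:
        self.K = _as_grm(K)
        self.K, self._bend = self.K.bend()
        self.y = _observed_vector(y, self.K)
        self.obs = ~np.isnan(self.y)
        if self.obs.sum() < 3:
            raise ValueError("need at least 3 observed individuals")
        d, U = np.linalg.eigh(self.K.values)
        keep = d > 1e-10 * d.max()
        self._d = d[keep]
        self._U = U[:, keep]

    def fit(
        self,
        n_iter: int = 3000,
        burn_in: int = 1500,
        seed: int = 0,
        priors: "dict | None" = None,
    ) -> STResults:
        if n_iter <= burn_in:
            raise ValueError("n_iter must exceed burn_in")
        rng = np.random.default_rng(seed)
        obs = self.obs
        yo = self.y[obs]
        n = self.K.n
        n_obs = int(obs.sum())
        d, U = self._d, self._U
        r = d.size
        vy = float(np.var(yo))
        if vy == 0.0:  # degenerate constant response: keep conditionals proper
            vy = 1e-12

        priors = priors or {}
        df_u, S_u = priors.get("u", scaled_inv_chi2_prior(5.0, 0.5 * vy))
        df_e, S_e = priors.get("e", scaled_inv_chi2_prior(5.0, 0.5 * vy))

        beta = float(np.mean(yo))
        s2u, s2e = 0.5 * vy, 0.5 * vy
        delta = np.zeros(r)
        alpha = np.zeros(n)
        yc = self.y.copy()
        yc[~obs] = beta

        keep_n = n_iter - burn_in
        sum_alpha = np.zeros(n)
        sum_alpha2 = np.zeros(n)
        chain = {"beta": np.empty(keep_n), "s2u": np.empty(keep_n), "s2e": np.empty(keep_n)}

        for it in range(n_iter):
            yc[~obs] = beta + alpha[~obs] + rng.standard_normal((~obs).sum()) * np.sqrt(s2e)
            beta = float(np.mean(yc - alpha)) + rng.standard_normal() * np.sqrt(s2e / n)
            rt = self._U.T @ (yc - beta)
            prec = 1.0 / s2e + 1.0 / (s2u * d)
            mean = (rt / s2e) / prec
            delta = mean + rng.standard_normal(r) / np.sqrt(prec)
            alpha = self._U @ delta
            if not np.all(np.isfinite(alpha)):
                raise FloatingPointError(f"chain diverged at iteration {it} (seed {seed})")
            s2u = (np.sum(delta**2 / d) + df_u * S_u) / rng.chisquare(df_u + r)
            e_obs = yo - beta - alpha[obs]
            s2e = (np.sum(e_obs**2) + df_e * S_e) / rng.chisquare(df_e + n_obs)
            if it >= burn_in:
                j = it - burn_in
                sum_alpha += alpha
                sum_alpha2 += alpha**2
                chain["beta"][j] = beta
                chain["s2u"][j] = s2u
                chain["s2e"][j] = s2e

        mean_alpha = sum_alpha / keep_n
        sd_alpha = np.sqrt(np.maximum(sum_alpha2 / keep_n - mean_alpha**2, 0.0))
        idx = pd.Index(self.K.sample_ids, name="family")
        res = STResults(
            gebv=pd.Series(mean_alpha, index=idx),
            beta=float(np.mean(chain["beta"])),
            sigma2_u=float(np.mean(chain["s2u"])),
            sigma2_e=float(np.mean(chain["s2e"])),
            method="rkhs-gibbs",
            gebv_sd=pd.Series(sd_alpha, index=idx),
            n_iter=n_iter,
            burn_in=burn_in,
            ess={k: _ess(v) for k, v in chain.items()},
        )
        res._y_obs = self.y
        res.chain = chain
        return res


def _ess(x: np.ndarray) -> float:
    """Effective sample size by the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    m = x.size
    x = x - x.mean()
    var = float(x @ x) / m
    if var == 0:
        return float(m)
    rho_sum = 0.0
    for lag in range(1, m // 2):
        rho = float(x[:-lag] @ x[lag:]) / (m * var)
        if rho <= 0:
            break
        rho_sum += rho
    return m / (1.0 + 2.0 * rho_sum)
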