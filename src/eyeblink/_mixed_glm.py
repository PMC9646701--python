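"""Maximum-likelihood mixed-effects GLMs (binomial and beta families).

Implements the marginal likelihood of a GLM with per-cluster Gaussian random
effects via the Laplace approximation,

    l(beta, theta) = sum_i log  int  prod_j f(y_ij | eta_ij) N(b; 0, D) db,
    eta_ij = x_ij' beta + z_ij' b_i,

maximized over the fixed effects, the random-effect variance and (for the
beta family) the precision. Two random structures are supported: a scalar
random intercept per cluster (vectorized inner Newton across clusters) and
per-level random effects for a categorical time variable with one shared
variance (diagonal covariance). The Laplace approximation is the same
default used by lme4's glmer (nAGQ = 1).

Families:
  * binomial — Bernoulli with logit link, for trial-level 0/1 outcomes.
  * beta     — mean-precision beta regression with logit link for the mean,
               for proportion outcomes strictly inside (0, 1).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special

_ETA_CLIP = 30.0


def _sigmoid(eta):
    return special.expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


class Binomial:
    """Binomial log-likelihood (successes y out of n trials, logit link);
    n = 1 gives the Bernoulli trial-level model. Derivatives are w.r.t. the
    linear predictor."""

    n_extra = 0

    def __init__(self, n=None):
        self.n = 1.0 if n is None else np.asarray(n, dtype=float)

    def loglik(self, y, eta, extra):
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        return y * eta - self.n * np.logaddexp(0.0, eta)

    def d1(self, y, eta, extra):
        return y - self.n * _sigmoid(eta)

    def d2(self, y, eta, extra):
        p = _sigmoid(eta)
        return -self.n * p * (1.0 - p)


class Beta:
    """Beta log-likelihood (mean mu = sigmoid(eta), precision phi = exp(extra))."""

    n_extra = 1

    @staticmethod
    def loglik(y, eta, extra):
        phi = np.exp(extra[0])
        mu = _sigmoid(eta)
        a, b = mu * phi, (1.0 - mu) * phi
        return (special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
                + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))

    @staticmethod
    def d1(y, eta, extra):
        phi = np.exp(extra[0])
        mu = _sigmoid(eta)
        g = np.log(y / (1.0 - y)) - special.digamma(mu * phi) + special.digamma((1.0 - mu) * phi)
        return phi * mu * (1.0 - mu) * g

    @staticmethod
    def d2(y, eta, extra):
        phi = np.exp(extra[0])
        mu = _sigmoid(eta)
        mp = mu * (1.0 - mu)
        g = np.log(y / (1.0 - y)) - special.digamma(mu * phi) + special.digamma((1.0 - mu) * phi)
        dg = -phi * mp * (special.polygamma(1, mu * phi) + special.polygamma(1, (1.0 - mu) * phi))
        return phi * (mp * (1.0 - 2.0 * mu) * g + mp * dg)


FAMILIES = {"binomial": Binomial, "beta": Beta}


class MixedGLM:
    """Laplace-ML mixed GLM.

    Parameters
    ----------
    y : outcome vector.
    X : fixed-effects design matrix (n, p).
    cluster : integer cluster codes (0..q-1) per observation.
    family : "binomial" or "beta".
    Z_levels : None for a random intercept; otherwise integer level codes
        per observation (e.g. day level) for per-level random effects with a
        single shared variance.
    """

    def __init__(self, y, X, cluster, family="binomial", Z_levels=None,
                 n_trials=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.cluster = np.asarray(cluster, dtype=int)
        self.n_clusters = int(self.cluster.max()) + 1
        self.family = Binomial(n_trials) if family == "binomial" else Beta()
        self.family_name = family
        self.Z_levels = None if Z_levels is None else np.asarray(Z_levels, dtype=int)
        self.n_levels = 0 if Z_levels is None else int(self.Z_levels.max()) + 1
        self.p = self.X.shape[1]
        self._bhat = None  # warm start for the inner mode search

    # ----- inner problem: per-cluster posterior modes -----------------------

    def _laplace_intercept(self, beta, sigma2, extra):
        """Vectorized Laplace over clusters for scalar random intercepts."""
        xb = self.X @ beta
        c = self.cluster
        b = (self._bhat if self._bhat is not None and self._bhat.shape == (self.n_clusters,)
             else np.zeros(self.n_clusters))
        b = b.copy()
        for _ in range(50):
            eta = xb + b[c]
            g = np.bincount(c, self.family.d1(self.y, eta, extra),
                            minlength=self.n_clusters) - b / sigma2
            h = np.bincount(c, self.family.d2(self.y, eta, extra),
                            minlength=self.n_clusters) - 1.0 / sigma2
            h = np.minimum(h, -1e-8)
            # clipped Newton keeps the mode search stable where the
            # per-observation loglik is locally non-concave (beta family)
            step = np.clip(g / h, -3.0, 3.0)
            b = np.clip(b - step, -30.0, 30.0)
            if np.max(np.abs(step)) < 1e-10:
                break
        self._bhat = b
        eta = xb + b[c]
        ll_obs = np.sum(self.family.loglik(self.y, eta, extra))
        h = np.minimum(np.bincount(c, self.family.d2(self.y, eta, extra),
                                   minlength=self.n_clusters) - 1.0 / sigma2,
                       -1e-8)
        ll = (ll_obs - np.sum(b**2) / (2.0 * sigma2)
              - 0.5 * self.n_clusters * np.log(sigma2)
              - 0.5 * np.sum(np.log(-h)))
        return ll

    def _laplace_levels(self, beta, sigma2_int, sigma2_slope, extra):
        """Per-cluster Laplace for a random intercept plus day-level random
        effects with a shared slope variance: b = (b0, b_1..b_q),
        eta = xb + b0 + b_{level}. Nests the intercept-only structure
        (sigma2_slope -> 0)."""
        xb = self.X @ beta
        q = self.n_levels
        dim = q + 1
        if self._bhat is None or self._bhat.shape != (self.n_clusters, dim):
            self._bhat = np.zeros((self.n_clusters, dim))
        pen = np.concatenate([[1.0 / sigma2_int],
                              np.full(q, 1.0 / sigma2_slope)])
        ll = 0.0
        for i in range(self.n_clusters):
            m = self.cluster == i
            yi, xbi, lv = self.y[m], xb[m], self.Z_levels[m]
            b = self._bhat[i].copy()
            fam = self.family
            H = np.empty((dim, dim))
            for _ in range(50):
                eta = xbi + b[0] + b[1 + lv]
                d1 = fam.d1(yi, eta, extra)
                d2 = fam.d2(yi, eta, extra)
                g = np.concatenate([[d1.sum()],
                                    np.bincount(lv, d1, minlength=q)]) - pen * b
                lvl2 = np.bincount(lv, d2, minlength=q)
                H[:] = 0.0
                H[0, 0] = d2.sum()
                H[0, 1:] = H[1:, 0] = lvl2
                H[1:, 1:] = np.diag(lvl2)
                Hp = H - np.diag(pen)
                step = np.linalg.solve(Hp, g)
                nrm = np.max(np.abs(step))
                if nrm > 3.0:
                    step *= 3.0 / nrm
                b = np.clip(b - step, -30.0, 30.0)
                if nrm < 1e-10:
                    break
            self._bhat[i] = b
            eta = xbi + b[0] + b[1 + lv]
            d2 = fam.d2(yi, eta, extra)
            lvl2 = np.bincount(lv, d2, minlength=q)
            H[:] = 0.0
            H[0, 0] = d2.sum()
            H[0, 1:] = H[1:, 0] = lvl2
            H[1:, 1:] = np.diag(lvl2)
            Hp = H - np.diag(pen)
            sign, logdet = np.linalg.slogdet(-Hp)
            ll += (np.sum(fam.loglik(yi, eta, extra))
                   - 0.5 * np.sum(pen * b**2)
                   - 0.5 * (np.log(sigma2_int) + q * np.log(sigma2_slope))
                   - 0.5 * logdet)
        return ll

    @property
    def n_var_params(self):
        return 1 if self.Z_levels is None else 2

    def loglik(self, params):
        beta = params[: self.p]
        sigma2 = np.exp(2.0 * params[self.p])
        extra = params[self.p + self.n_var_params:]
        if self.Z_levels is None:
            return self._laplace_intercept(beta, sigma2, extra)
        sigma2_slope = np.exp(2.0 * params[self.p + 1])
        return self._laplace_levels(beta, sigma2, sigma2_slope, extra)

    def _start(self):
        if self.family_name == "binomial":
            ybar = np.clip(np.mean(self.y / self.family.n), 1e-3, 1 - 1e-3)
            beta0 = np.zeros(self.p)
            beta0[0] = np.log(ybar / (1 - ybar))
            extra0 = []
        else:
            z = np.log(self.y / (1.0 - self.y))
            beta0, *_ = np.linalg.lstsq(self.X, z, rcond=None)
            extra0 = [np.log(5.0)]
        return np.concatenate(
            [beta0, [np.log(0.3)] * self.n_var_params, extra0])

    def fit(self, maxiter=400):
        x0 = self._start()
        self._bhat = None
        # bounds keep the variance and precision parameters off infinities
        # for degenerate data (e.g. an outcome with no residual variation)
        bounds = ([(None, None)] * self.p + [(-8.0, 3.0)] * self.n_var_params
                  + [(-3.0, 12.0)] * self.family.n_extra)
        res = optimize.minimize(
            lambda p: -self.loglik(p), x0, method="L-BFGS-B", bounds=bounds,
            options=dict(maxiter=maxiter, maxfun=20 * maxiter))
        self.params_ = res.x
        self.loglik_ = -res.fun
        self.converged_ = bool(res.success)
        self.beta_ = res.x[: self.p]
        self.sigma_ = float(np.exp(res.x[self.p]))
        return self

    def beta_cov(self):
        """Covariance of the fixed effects: inverse observed information at
        the optimum, with the variance (and precision) parameters held at
        their estimates — the same conditioning glmer's vcov uses."""
        theta = self.params_.copy()
        p = self.p

        def f(beta):
            th = theta.copy()
            th[:p] = beta
            return -self.loglik(th)

        b0 = theta[:p]
        h = 1e-4 * np.maximum(1.0, np.abs(b0))
        H = np.empty((p, p))
        for i in range(p):
            for j in range(i, p):
                ei = np.zeros(p); ei[i] = h[i]
                ej = np.zeros(p); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(b0 + ei + ej) - f(b0 + ei - ej)
                    - f(b0 - ei + ej) + f(b0 - ei - ej)
                ) / (4.0 * h[i] * h[j])
        # symmetric pseudo-inverse guards against near-singular information
        return np.linalg.pinv(H)

    @property
    def df_model(self):
        return self.p + self.n_var_params + self.family.n_extra
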