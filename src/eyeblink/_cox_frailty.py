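"""Cox proportional-hazards regression with a log-normal per-cluster frailty.

The model is h_ij(t) = h0(t) exp(x_ij' beta + b_i), b_i ~ N(0, theta),
fitted by maximizing the penalized Breslow partial likelihood over
(beta, b) jointly, with the frailty variance theta chosen by maximizing the
Laplace-approximate integrated partial likelihood — the approach of the
coxme package. Right censoring is supported through an event indicator.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


class CoxFrailty:
    """Cox PH with shared per-cluster normal random effect on the log hazard.

    Parameters
    ----------
    duration, event : survival times and event indicators (0 = censored).
    X : covariate matrix (n, p).
    cluster : integer cluster codes (0..q-1).
    """

    def __init__(self, duration, event, X, cluster):
        self.duration = np.asarray(duration, dtype=float)
        self.event = np.asarray(event, dtype=bool)
        self.X = np.asarray(X, dtype=float)
        self.cluster = np.asarray(cluster, dtype=int)
        if self.event.sum() == 0:
            raise ValueError("no events: every observation is censored")
        self.n, self.p = self.X.shape
        self.q = int(self.cluster.max()) + 1
        # combined design: fixed covariates + cluster dummies for the frailty
        Z = np.zeros((self.n, self.q))
        Z[np.arange(self.n), self.cluster] = 1.0
        self.U = np.hstack([self.X, Z])
        order = np.argsort(-self.duration, kind="stable")  # descending time
        self._ord = order

    def _ppl_parts(self, coefs):
        """Breslow partial loglik, gradient and Hessian w.r.t. all coefs."""
        U, d = self.U[self._ord], self.duration[self._ord]
        ev = self.event[self._ord]
        eta = U @ coefs
        w = np.exp(eta - eta.max())
        dtot = self.p + self.q
        ll = 0.0
        grad = np.zeros(dtot)
        hess = np.zeros((dtot, dtot))
        S0, S1 = 0.0, np.zeros(dtot)
        S2 = np.zeros((dtot, dtot))
        i = 0
        n = len(d)
        log_shift = eta.max()
        while i < n:
            j = i
            while j < n and d[j] == d[i]:
                # grow risk set with all subjects whose time >= current time
                S0 += w[j]
                S1 += w[j] * U[j]
                S2 += w[j] * np.outer(U[j], U[j])
                j += 1
            for k in range(i, j):
                if ev[k]:
                    ll += eta[k] - (np.log(S0) + log_shift)
                    mu = S1 / S0
                    grad += U[k] - mu
                    hess -= S2 / S0 - np.outer(mu, mu)
            i = j
        return ll, grad, hess

    def _fit_coefs(self, theta, start=None):
        """Inner Newton: maximize penalized ppl over (beta, b) at fixed theta."""
        coefs = np.zeros(self.p + self.q) if start is None else start.copy()
        pen_diag = np.zeros(self.p + self.q)
        pen_diag[self.p:] = 1.0 / theta
        ll = -np.inf
        for _ in range(50):
            ll_new, grad, hess = self._ppl_parts(coefs)
            pll = ll_new - 0.5 * np.sum(coefs[self.p:] ** 2) / theta
            grad = grad - pen_diag * coefs
            H = hess - np.diag(pen_diag)
            # small ridge for numerical safety
            step = np.linalg.solve(H - 1e-10 * np.eye(len(H)), grad)
            coefs = coefs - step
            if np.max(np.abs(step)) < 1e-9:
                break
            ll = pll
        ll_final, grad, hess = self._ppl_parts(coefs)
        H = hess - np.diag(pen_diag)
        return coefs, ll_final, H

    def _integrated(self, theta, start=None):
        """Laplace-approximate integrated partial loglik at theta."""
        coefs, ll, H = self._fit_coefs(theta, start)
        b = coefs[self.p:]
        Hbb = H[self.p:, self.p:]
        pll = ll - 0.5 * np.sum(b**2) / theta
        sign, logdet = np.linalg.slogdet(-Hbb * theta)
        ilik = pll - 0.5 * logdet
        return ilik, coefs, H

    def fit(self, theta_bounds=(1e-4, 25.0)):
        state = {"start": None}

        def neg(log_theta):
            ilik, coefs, _ = self._integrated(np.exp(log_theta), state["start"])
            state["start"] = coefs
            return -ilik

        res = optimize.minimize_scalar(
            neg, bounds=np.log(theta_bounds), method="bounded",
            options=dict(xatol=1e-3))
        self.theta_ = float(np.exp(res.x))
        self.ilik_, coefs, H = self._integrated(self.theta_, state["start"])
        self.coefs_ = coefs
        self.beta_ = coefs[: self.p]
        self.frailty_ = coefs[self.p:]
        # covariance of beta from the full penalized information, beta block
        cov = np.linalg.pinv(-H)
        self.beta_cov_ = cov[: self.p, : self.p]
        self.converged_ = True
        return self

    def loglik_null_frailty(self):
        """Unpenalized Breslow partial loglik of the no-frailty model (b=0),
        maximized over beta only — for reporting/reference."""
        coefs, ll, _ = self._fit_coefs(1e-10)
        return ll
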