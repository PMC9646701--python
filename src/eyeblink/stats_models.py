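"""The multilevel statistical battery for repeated-measures behavior.

One model per outcome type, all with training day (categorical), genotype
and their interaction as fixed effects and per-mouse random effects:

  * trial-level CR presence     -> mixed binomial logistic (Wald chi-square)
  * NEC amplitudes, latencies   -> linear mixed models, ML (LR tests)
  * proportions in (0, 1)       -> mixed beta regression (LR tests)
  * censored latencies to fall  -> Cox PH with log-normal frailty (Wald)

Two random structures are considered: random intercepts per mouse, and
day-level random effects per mouse with a shared variance ("random slopes
per time point"); a likelihood-ratio test picks the better-fitting one.
Post-hoc per-day genotype contrasts are Holm-adjusted within the phase.
Also here: the two-sample t-test sample-size calculation used to plan such
experiments.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._cox_frailty import CoxFrailty
from ._mixed_glm import MixedGLM

ALPHA = 0.05


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome column, family, and the fixed/random structure."""

    outcome: str
    family: str  # binomial | gaussian | beta | cox
    time_var: str = "day"
    group_var: str = "genotype"
    interaction: bool = True
    random: str = "auto"  # auto | intercept | slopes
    transform: str = "none"  # none | log
    mouse_var: str = "mouse"

    def __post_init__(self):
        if self.family not in ("binomial", "gaussian", "beta", "cox"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.transform == "log" and self.family != "gaussian":
            raise ValueError("log transform applies to gaussian outcomes only")
        if self.random not in ("auto", "intercept", "slopes"):
            raise ValueError("random must be auto, intercept or slopes")


@dataclass
class FitResult:
    """One fitted model: omnibus tests, coefficients, Holm-adjusted post-hocs."""

    spec: ModelSpec
    loglik: float
    chosen_random_structure: str
    terms: pd.DataFrame       # term, kind (LR/Wald), statistic, df, df_resid, p
    coef: pd.DataFrame        # name, estimate, se
    posthoc: pd.DataFrame     # level, estimate, ci_low, ci_high, raw_p, adj_p, ...
    converged: bool = True
    warnings: list[str] = field(default_factory=list)
    structure_logliks: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# elementary operations


def lr_test(loglik0: float, loglik1: float, df0: int, df1: int,
            tol: float = 1e-5):
    """Likelihood-ratio test of nested models (model 1 nests model 0).

    Small negative statistics (within `tol`, relative to the loglik scale)
    are clamped to zero: independently-optimized nested fits can disagree at
    that level on flat likelihoods without either fit being wrong.
    """
    if df1 <= df0:
        raise ValueError("models not nested: df1 must exceed df0")
    stat = 2.0 * (loglik1 - loglik0)
    if stat < -tol * max(1.0, abs(loglik1)):
        raise ValueError(
            f"larger model has lower log-likelihood ({loglik1:.6g} < {loglik0:.6g})")
    stat = max(stat, 0.0)
    df = df1 - df0
    return stat, df, float(sps.chi2.sf(stat, df))


def holm_adjust(p_values):
    """Holm step-down adjustment: sort ascending, multiply by (m - rank + 1),
    enforce monotonicity, cap at 1, restore input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def power_sample_size(delta: float, sd: float, power: float = 0.80,
                      alpha: float = 0.05, two_sided: bool = True,
                      max_n: int = 100000) -> int:
    """Smallest equal group size n for a two-sample t-test to reach `power`
    at raw difference `delta` and common SD `sd` (noncentral-t iteration)."""
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be > 0")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    if power <= alpha:
        raise ValueError("requested power must exceed alpha")
    d = delta / sd
    for n in range(2, max_n + 1):
        if t_test_power(d, n, alpha, two_sided) >= power:
            return n
    raise ValueError("no attainable n below max_n")


def t_test_power(effect_size: float, n_per_group: int, alpha: float = 0.05,
                 two_sided: bool = True) -> float:
    """Power of the two-sample t-test at standardized effect size d."""
    df = 2 * n_per_group - 2
    nc = effect_size * np.sqrt(n_per_group / 2.0)
    if two_sided:
        crit = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc))
    crit = sps.t.ppf(1.0 - alpha, df)
    return float(sps.nct.sf(crit, df, nc))


# ---------------------------------------------------------------------------
# design construction


class _Design:
    """Treatment-coded day x genotype design with named columns."""

    def __init__(self, df: pd.DataFrame, spec: ModelSpec):
        self.t_levels = sorted(df[spec.time_var].unique())
        g = sorted(df[spec.group_var].unique())
        if "WT" in g:  # wild type is the reference genotype when present
            g = ["WT"] + [x for x in g if x != "WT"]
        self.g_levels = g
        if len(g) > 2:
            raise ValueError("exactly two genotype groups are supported")
        self.spec = spec
        n = len(df)
        cols, names = [np.ones(n)], ["const"]
        tv = df[spec.time_var].to_numpy()
        for lvl in self.t_levels[1:]:
            cols.append((tv == lvl).astype(float))
            names.append(f"{spec.time_var}[{lvl}]")
        self.has_group = len(g) == 2
        if self.has_group:
            gv = (df[spec.group_var].to_numpy() == g[1]).astype(float)
            cols.append(gv)
            names.append(f"{spec.group_var}[{g[1]}]")
            if spec.interaction:
                for lvl in self.t_levels[1:]:
                    cols.append(((tv == lvl).astype(float)) * gv)
                    names.append(f"{spec.time_var}[{lvl}]:{spec.group_var}[{g[1]}]")
        self.X = np.column_stack(cols)
        self.names = names
        self.mouse_codes, self.mice = pd.factorize(df[spec.mouse_var], sort=True)
        self.time_codes = np.searchsorted(self.t_levels, tv)

    def term_columns(self, term: str) -> list[int]:
        s = self.spec
        if term == s.time_var:
            want = lambda n: n.startswith(f"{s.time_var}[") and ":" not in n
        elif term == s.group_var:
            want = lambda n: n.startswith(f"{s.group_var}[") and ":" not in n
        elif term == "interaction":
            want = lambda n: ":" in n
        else:
            raise ValueError(f"unknown term {term!r}")
        return [i for i, n in enumerate(self.names) if want(n)]

    def drop(self, term: str) -> np.ndarray:
        keep = [i for i in range(len(self.names))
                if i not in self.term_columns(term)]
        return self.X[:, keep]

    def contrast_at(self, t_level) -> np.ndarray:
        """Genotype contrast (group level 2 minus reference) at one day."""
        c = np.zeros(len(self.names))
        s = self.spec
        c[self.names.index(f"{s.group_var}[{self.g_levels[1]}]")] = 1.0
        inter = f"{s.time_var}[{t_level}]:{s.group_var}[{self.g_levels[1]}]"
        if inter in self.names:
            c[self.names.index(inter)] = 1.0
        return c

    @property
    def terms(self) -> list[str]:
        out = [self.spec.time_var] if len(self.t_levels) > 1 else []
        if self.has_group:
            out.append(self.spec.group_var)
            if self.spec.interaction and len(self.t_levels) > 1:
                out.append("interaction")
        return out


def _posthoc_table(design: _Design, beta, cov, *, df_t=None, link="identity",
                   alpha=ALPHA) -> pd.DataFrame:
    """Per-day genotype contrasts with CIs, raw and Holm-adjusted p."""
    rows = []
    for lvl in design.t_levels:
        c = design.contrast_at(lvl)
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        if df_t is None:
            z = est / se if se > 0 else np.inf
            p = 2.0 * sps.norm.sf(abs(z))
            crit = sps.norm.ppf(1 - alpha / 2)
        else:
            z = est / se if se > 0 else np.inf
            p = 2.0 * sps.t.sf(abs(z), df_t)
            crit = sps.t.ppf(1 - alpha / 2, df_t)
        lo, hi = est - crit * se, est + crit * se
        row = dict(level=lvl, estimate=est, se=se, ci_low=lo, ci_high=hi,
                   raw_p=min(max(p, np.finfo(float).tiny), 1.0),
                   unstable=bool(se > 5.0) if link == "log" else False)
        if link == "log":
            row.update(ratio=np.exp(est), ratio_ci_low=np.exp(lo),
                       ratio_ci_high=np.exp(hi))
        rows.append(row)
    out = pd.DataFrame(rows)
    out["adj_p"] = holm_adjust(out["raw_p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# family fits


def _choose_structure(fit_intercept, fit_slopes, random: str):
    """Apply the LR-based random-structure selection rule.

    `fit_intercept`/`fit_slopes` are callables returning (model, loglik,
    df_model). Returns (model, structure_name, logliks, warnings)."""
    warns = []
    if random == "intercept":
        m, ll, _ = fit_intercept()
        return m, "intercepts_per_mouse", {"intercept": ll}, warns
    if random == "slopes":
        m, ll, _ = fit_slopes()
        return m, "slopes_per_day_per_mouse", {"slopes": ll}, warns
    mi, lli, dfi = fit_intercept()
    try:
        ms, lls, dfs = fit_slopes()
    except Exception as exc:  # non-convergence: fall back with a warning
        warns.append(f"slopes model failed ({exc}); using intercepts")
        return mi, "intercepts_per_mouse", {"intercept": lli}, warns
    logliks = {"intercept": lli, "slopes": lls}
    if lls < lli - 1e-6:
        warns.append("slopes model did not improve the likelihood; "
                     "using intercepts")
        return mi, "intercepts_per_mouse", logliks, warns
    _, _, p = lr_test(lli, lls, dfi, dfs)
    if p < ALPHA:
        return ms, "slopes_per_day_per_mouse", logliks, warns
    return mi, "intercepts_per_mouse", logliks, warns


def _wald_terms(design: _Design, beta, cov, nobs) -> pd.DataFrame:
    rows = []
    for term in design.terms:
        idx = design.term_columns(term)
        bt = beta[idx]
        Vt = cov[np.ix_(idx, idx)]
        stat = float(bt @ np.linalg.solve(Vt, bt))
        df = len(idx)
        rows.append(dict(term=term, kind="Wald", statistic=stat, df=df,
                         df_resid=nobs - len(beta),
                         p=float(sps.chi2.sf(stat, df))))
    return pd.DataFrame(rows)


def fit_trialwise_logistic(df: pd.DataFrame, spec: ModelSpec | None = None,
                           *, aggregate: str = "trial") -> FitResult:
    """Mixed binomial logistic regression for CR presence (or any 0/1 trial
    outcome): day, genotype, day x genotype fixed effects, per-mouse random
    effects, Wald chi-square omnibus tests and per-day genotype odds ratios.

    `aggregate="session"` fits the equivalent binomial-counts model on
    per-mouse-per-day successes/trials (identical likelihood up to a
    constant).
    """
    spec = spec or ModelSpec(outcome="is_cr", family="binomial")
    if aggregate not in ("trial", "session"):
        raise ValueError("aggregate must be 'trial' or 'session'")
    work = df.copy()
    y = work[spec.outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError("degenerate fit: outcome has no variation")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binomial outcome must be 0/1")
    if aggregate == "session":
        keys = [spec.mouse_var, spec.group_var, spec.time_var]
        agg = (work.groupby(keys, as_index=False)[spec.outcome]
               .agg(successes="sum", n="count"))
        work = agg
        y = work["successes"].astype(float)
        n_trials = work["n"].to_numpy(float)
    else:
        n_trials = None

    design = _Design(work, spec)

    def fit_with(z_levels):
        m = MixedGLM(y.to_numpy(), design.X, design.mouse_codes,
                     "binomial", Z_levels=z_levels, n_trials=n_trials).fit()
        if not m.converged_:
            raise RuntimeError("optimizer did not converge")
        return m, m.loglik_, m.df_model

    model, structure, logliks, warns = _choose_structure(
        lambda: fit_with(None), lambda: fit_with(design.time_codes), spec.random)

    cov = model.beta_cov()
    terms = _wald_terms(design, model.beta_, cov, len(work))
    posthoc = _posthoc_table(design, model.beta_, cov, link="log")
    coef = pd.DataFrame(dict(name=design.names, estimate=model.beta_,
                             se=np.sqrt(np.diag(cov))))
    return FitResult(spec=spec, loglik=model.loglik_,
                     chosen_random_structure=structure, terms=terms,
                     coef=coef, posthoc=posthoc, converged=model.converged_,
                     warnings=warns, structure_logliks=logliks,
                     extra={"sigma": model.sigma_})


def fit_beta_mixed(df: pd.DataFrame, spec: ModelSpec | None = None,
                   terms: tuple[str, ...] | None = None) -> FitResult:
    """Mixed beta regression (logit link) for proportion outcomes strictly in
    (0, 1), with LR omnibus tests per term. `terms` restricts which omnibus
    tests are computed (each costs one reduced-model refit)."""
    spec = spec or ModelSpec(outcome="prop_correct", family="beta")
    y = df[spec.outcome].astype(float).to_numpy()
    if np.any((y <= 0.0) | (y >= 1.0)):
        raise ValueError(
            "beta outcomes must lie strictly in (0, 1); apply the boundary "
            "compression y' = (y*(n-1) + 0.5)/n (see compress_proportions) "
            "after removing structural ones/zeros")
    design = _Design(df, spec)

    def fit_on(X, z_levels):
        m = MixedGLM(y, X, design.mouse_codes, "beta", Z_levels=z_levels).fit()
        if not m.converged_:
            raise RuntimeError("optimizer did not converge")
        return m, m.loglik_, m.df_model

    z_full = {"intercepts_per_mouse": None,
              "slopes_per_day_per_mouse": design.time_codes}
    model, structure, logliks, warns = _choose_structure(
        lambda: fit_on(design.X, None),
        lambda: fit_on(design.X, design.time_codes), spec.random)
    zl = z_full[structure]

    rows = []
    for term in design.terms:
        if terms is not None and term not in terms:
            continue
        Xr = design.drop(term)
        mr, llr, _ = fit_on(Xr, zl)
        stat, dfree, p = lr_test(llr, model.loglik_,
                                 Xr.shape[1], design.X.shape[1])
        rows.append(dict(term=term, kind="LR", statistic=stat, df=dfree,
                         df_resid=len(df) - design.X.shape[1], p=p))
    cov = model.beta_cov()
    posthoc = _posthoc_table(design, model.beta_, cov, link="log")
    coef = pd.DataFrame(dict(name=design.names, estimate=model.beta_,
                             se=np.sqrt(np.diag(cov))))
    return FitResult(spec=spec, loglik=model.loglik_,
                     chosen_random_structure=structure,
                     terms=pd.DataFrame(rows), coef=coef, posthoc=posthoc,
                     converged=model.converged_, warnings=warns,
                     structure_logliks=logliks,
                     extra={"sigma": model.sigma_,
                            "phi": float(np.exp(model.params_[-1]))})


def compress_proportions(y, n: int | None = None):
    """Smithson-Verkuilen boundary compression y' = (y*(n-1) + 0.5)/n."""
    y = np.asarray(y, dtype=float)
    n = len(y) if n is None else n
    return (y * (n - 1) + 0.5) / n


def fit_lmm(df: pd.DataFrame, spec: ModelSpec,
            terms: tuple[str, ...] | None = None) -> FitResult:
    """Linear mixed model (ML via statsmodels MixedLM) with LR omnibus tests
    and per-day genotype mean differences (t-based CIs, Holm-adjusted).
    `terms` restricts which omnibus tests are computed."""
    from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

    work = df.copy()
    y = work[spec.outcome].astype(float).to_numpy()
    if spec.transform == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires positive outcomes")
        y = np.log(y)
    design = _Design(work, spec)
    groups = design.mouse_codes

    day_dummies = np.zeros((len(work), len(design.t_levels)))
    day_dummies[np.arange(len(work)), design.time_codes] = 1.0

    def fit_on(X, slopes):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            if slopes:
                vcs = VCSpec(
                    names=["day"],
                    colnames=[[[f"d{l}" for l in design.t_levels]]
                              * len(design.mice)],
                    mats=[[day_dummies[groups == g]
                           for g in range(len(design.mice))]])
                md = MixedLM(y, X, groups, exog_re=np.ones((len(work), 1)),
                             exog_vc=vcs)
            else:
                md = MixedLM(y, X, groups, exog_re=np.ones((len(work), 1)))
            fit = None
            for method in ("lbfgs", "powell", "nm"):
                try:
                    fit = md.fit(reml=False, method=method, maxiter=1000)
                    break
                except np.linalg.LinAlgError:
                    continue  # singular Hessian (variance on the boundary)
            if fit is None:
                raise RuntimeError("LMM optimization failed for all methods")
        k_var = 2 if slopes else 1
        return fit, float(fit.llf), X.shape[1] + k_var + 1

    def fit_full_intercept():
        f, ll, k = fit_on(design.X, False)
        return f, ll, k

    def fit_full_slopes():
        f, ll, k = fit_on(design.X, True)
        if not f.converged:
            raise RuntimeError("slopes LMM did not converge")
        return f, ll, k

    model, structure, logliks, warns = _choose_structure(
        fit_full_intercept, fit_full_slopes, spec.random)
    slopes = structure == "slopes_per_day_per_mouse"

    rows = []
    for term in design.terms:
        if terms is not None and term not in terms:
            continue
        Xr = design.drop(term)
        mr, llr, _ = fit_on(Xr, slopes)
        stat, dfree, p = lr_test(llr, float(model.llf),
                                 Xr.shape[1], design.X.shape[1])
        rows.append(dict(term=term, kind="LR", statistic=stat, df=dfree,
                         df_resid=len(work) - design.X.shape[1], p=p))

    k_fe = design.X.shape[1]
    beta = np.asarray(model.fe_params)
    cov = np.asarray(model.cov_params())[:k_fe, :k_fe]
    df_t = max(len(design.mice) - len(design.g_levels), 1)
    posthoc = (_posthoc_table(design, beta, cov, df_t=df_t)
               if design.has_group else pd.DataFrame())
    coef = pd.DataFrame(dict(name=design.names, estimate=beta,
                             se=np.sqrt(np.diag(cov))))
    return FitResult(spec=spec, loglik=float(model.llf),
                     chosen_random_structure=structure,
                     terms=pd.DataFrame(rows), coef=coef, posthoc=posthoc,
                     converged=bool(model.converged), warnings=warns,
                     structure_logliks=logliks,
                     extra={"df_t": df_t, "model": model})


def fit_cox_frailty(df: pd.DataFrame, spec: ModelSpec | None = None,
                    *, duration_col: str = "latency_s",
                    event_col: str = "censored") -> FitResult:
    """Multilevel Cox proportional hazards for censored latencies: day,
    genotype and interaction fixed effects, per-mouse log-normal frailty,
    Wald chi-square omnibus tests, per-day hazard ratios Holm-adjusted.
    `event_col` holds the *censoring* flag (True = no event)."""
    spec = spec or ModelSpec(outcome=duration_col, family="cox")
    design = _Design(df, spec)
    X = design.X[:, 1:]  # Cox has no intercept (absorbed in the baseline)
    names = design.names[1:]
    event = ~df[event_col].astype(bool).to_numpy()
    model = CoxFrailty(df[duration_col].to_numpy(float), event, X,
                       design.mouse_codes).fit()
    beta = model.beta_
    cov = model.beta_cov_

    offset = 1  # column indices shift because the constant was removed
    rows = []
    for term in design.terms:
        idx = [i - offset for i in design.term_columns(term)]
        bt = beta[idx]
        Vt = cov[np.ix_(idx, idx)]
        stat = float(bt @ np.linalg.solve(Vt, bt))
        rows.append(dict(term=term, kind="Wald", statistic=stat, df=len(idx),
                         df_resid=len(df) - len(beta),
                         p=float(sps.chi2.sf(stat, len(idx)))))

    full_beta = np.concatenate([[0.0], beta])
    full_cov = np.zeros((len(design.names), len(design.names)))
    full_cov[1:, 1:] = cov
    posthoc = _posthoc_table(design, full_beta, full_cov, link="log")
    coef = pd.DataFrame(dict(name=names, estimate=beta,
                             se=np.sqrt(np.diag(cov))))
    return FitResult(spec=spec, loglik=float(model.ilik_),
                     chosen_random_structure="frailty_per_mouse",
                     terms=pd.DataFrame(rows), coef=coef, posthoc=posthoc,
                     converged=model.converged_,
                     extra={"theta": model.theta_, "n_events": int(event.sum())})


def select_random_structure(df: pd.DataFrame, spec: ModelSpec) -> str:
    """Fit both candidate random structures for `spec` and return the name
    of the LR-selected one (the fit_* functions apply the same rule when
    spec.random == "auto")."""
    fitter = {"binomial": fit_trialwise_logistic, "gaussian": fit_lmm,
              "beta": fit_beta_mixed}.get(spec.family)
    if fitter is None:
        return "frailty_per_mouse"  # the Cox model has one structure
    res = fitter(df, spec)
    return res.chosen_random_structure
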