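"""Motor-battery analyses: ladder two-part step analysis, rotarod censored
latencies, balance-beam and grip-strength log-scale models.

The ladder's correct-step proportion has a two-part distribution: a point
mass of trials with only correct steps ("clean sweeps") and a continuous
mixture of correct steps and missteps. The two parts are analyzed
separately — a mixed logistic model on the clean-sweep indicator over all
trials, and a mixed beta regression on the proportions of the mixed trials.
Rotarod latencies are right-censored at 300 s and go to the Cox frailty
model (the 80 RPM sub-experiment is excluded). Beam crossing times and grip
forces are positively skewed and modeled on the log scale, with estimates
back-translated to the raw scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats_models import (
    ALPHA,
    FitResult,
    ModelSpec,
    compress_proportions,
    fit_beta_mixed,
    fit_cox_frailty,
    fit_lmm,
    fit_trialwise_logistic,
    holm_adjust,
)

CLEAN_SWEEP_TOL = 1e-9
ROTAROD_CAP_S = 300.0


def ladder_prepare(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split ladder trials into the dichotomous clean-sweep table (all
    trials) and the mixed-trial table (proportions < 1 only).

    A clean sweep is a trial whose correct-step proportion equals 1 (after
    upstream backstep exclusion), within a 1e-9 tolerance.
    """
    prop = table["prop_correct"].astype(float)
    if ((prop < 0) | (prop > 1)).any():
        raise ValueError("prop_correct must lie in [0, 1]")
    clean = table.copy()
    clean["is_clean_sweep"] = (prop >= 1.0 - CLEAN_SWEEP_TOL).astype(int)
    mixed = clean[clean["is_clean_sweep"] == 0].drop(columns="is_clean_sweep")
    return clean, mixed.copy()


def ladder_analyze(table: pd.DataFrame, *, random: str = "auto"
                   ) -> tuple[FitResult, FitResult]:
    """Two-part ladder analysis: mixed logistic on clean sweeps over all
    trials, mixed beta regression on the mixed-trial proportions (after
    Smithson-Verkuilen boundary compression, since mixed trials can still
    contain proportion 0)."""
    clean, mixed = ladder_prepare(table)
    if len(mixed) == 0:
        raise ValueError("no mixed trials: every trial is a clean sweep, "
                         "the beta stage has no input")
    logit_res = fit_trialwise_logistic(
        clean, ModelSpec(outcome="is_clean_sweep", family="binomial",
                         random=random))
    mixed = mixed.copy()
    mixed["prop_correct"] = compress_proportions(
        mixed["prop_correct"].to_numpy())
    beta_res = fit_beta_mixed(
        mixed, ModelSpec(outcome="prop_correct", family="beta", random=random))
    return logit_res, beta_res


def rotarod_prepare(table: pd.DataFrame, cap_s: float = ROTAROD_CAP_S
                    ) -> pd.DataFrame:
    """Keep the 40 RPM condition only and flag latencies at the cap as
    right-censored."""
    out = table[table["rpm_condition"] == 40].copy()
    out["latency_s"] = out["latency_s"].astype(float).clip(upper=cap_s)
    out["censored"] = out["latency_s"] >= cap_s
    return out


def rotarod_analyze(table: pd.DataFrame) -> FitResult:
    """Cox PH with per-mouse frailty on the prepared 40 RPM latencies."""
    return fit_cox_frailty(rotarod_prepare(table))


def beam_analyze(table: pd.DataFrame) -> FitResult:
    """Log-time LMM for beam crossing: beam width, genotype and their
    interaction as fixed effects, random intercepts per mouse, per-width
    genotype post-hocs (Holm)."""
    if (table["time_s"] <= 0).any():
        raise ValueError("crossing times must be positive")
    spec = ModelSpec(outcome="time_s", family="gaussian", time_var="width_mm",
                     transform="log", random="intercept")
    return fit_lmm(table, spec)


def grip_analyze(table: pd.DataFrame) -> FitResult:
    """Log-force LMM for grip strength: genotype fixed effect, random
    intercepts per mouse; group means back-translated to newton with CIs and
    the genotype difference reported on the raw scale (delta method)."""
    if (table["force_n"] <= 0).any():
        raise ValueError("forces must be positive")
    if table["force_n"].nunique() == 1:
        # degenerate input: no variance to model, means are exact
        c = float(table["force_n"].iloc[0])
        back = pd.DataFrame(
            dict(genotype=sorted(table["genotype"].unique()),
                 mean_n=c, ci_low=c, ci_high=c))
        res = FitResult(
            spec=ModelSpec(outcome="force_n", family="gaussian"),
            loglik=np.nan, chosen_random_structure="intercepts_per_mouse",
            terms=pd.DataFrame(), coef=pd.DataFrame(), posthoc=pd.DataFrame(),
            extra={"back_translated": back,
                   "difference": dict(estimate=0.0, ci_low=0.0, ci_high=0.0,
                                      t=0.0, df=np.nan, p=1.0)})
        return res
    work = table.copy()
    work["_one"] = 1
    spec = ModelSpec(outcome="force_n", family="gaussian", time_var="_one",
                     transform="log", random="intercept")
    res = fit_lmm(work, spec)

    names = list(res.coef["name"])
    beta = res.coef["estimate"].to_numpy()
    cov = np.zeros((len(beta), len(beta)))
    se = res.coef["se"].to_numpy()
    model = res.extra["model"]
    k_fe = len(beta)
    cov = np.asarray(model.cov_params())[:k_fe, :k_fe]
    df_t = res.extra["df_t"]
    crit = sps.t.ppf(1 - ALPHA / 2, df_t)

    g_idx = next((i for i, n in enumerate(names) if n.startswith("genotype[")),
                 None)
    rows = {}
    # log-scale group means: reference = const, other = const + genotype
    c_ref = np.zeros(len(beta)); c_ref[0] = 1.0
    groups = {"WT": c_ref}
    other = None
    if g_idx is not None:
        c_other = c_ref.copy(); c_other[g_idx] = 1.0
        other = names[g_idx].split("[")[1].rstrip("]")
        groups[other] = c_other
    for gname, c in groups.items():
        m = float(c @ beta)
        s = float(np.sqrt(c @ cov @ c))
        rows[gname] = dict(mean_n=np.exp(m), ci_low=np.exp(m - crit * s),
                           ci_high=np.exp(m + crit * s))
    back = pd.DataFrame(rows).T.rename_axis("genotype").reset_index()

    diff = None
    if g_idx is not None:
        mu_ref = float(c_ref @ beta)
        mu_oth = float(groups[other] @ beta)
        # delta method on f(beta) = exp(mu_oth) - exp(mu_ref)
        grad = np.exp(mu_oth) * groups[other] - np.exp(mu_ref) * c_ref
        sd = float(np.sqrt(grad @ cov @ grad))
        est = np.exp(mu_oth) - np.exp(mu_ref)
        tstat = float(beta[g_idx] / se[g_idx])
        diff = dict(estimate=est, ci_low=est - crit * sd, ci_high=est + crit * sd,
                    t=tstat, df=df_t, p=float(2 * sps.t.sf(abs(tstat), df_t)))
    res.extra["back_translated"] = back
    res.extra["difference"] = diff
    return res
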