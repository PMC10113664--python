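"""Retrospective-cohort statistics.

Sample-size calculation for two proportions, the 2009 CKD-EPI creatinine
equation with KDIGO staging, propensity-score estimation with inverse
probability of treatment weighting (IPTW) and greedy 1:1 matching,
standardized-mean-difference balance diagnostics, summary-statistic t and
chi-square tests, and 2x2 risk/odds-ratio effect estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "SampleSizeSpec",
    "sample_size_two_proportions",
    "egfr_ckd_epi",
    "kdigo_stage",
    "PropensityModel",
    "propensity_scores",
    "iptw_weights",
    "nn_match",
    "standardized_mean_difference",
    "balance_table",
    "ttest_from_summary",
    "chisq_test",
    "effect_estimates",
    "weighted_logistic_or",
]

UMOL_PER_MGDL = 88.4  # creatinine unit conversion


@dataclass
class SampleSizeSpec:
    """Two-proportion sample-size inputs.  If z quantiles are not given
    they are derived from alpha/beta and sidedness via the exact normal
    inverse CDF; the rounded textbook values (e.g. 1.65/1.28) may be
    passed explicitly to match a published calculation."""

    p0: float
    p1: float
    alpha: float = 0.05
    beta: float = 0.1
    sided: str = "one"
    z_alpha: float | None = None
    z_beta: float | None = None

    def quantiles(self) -> tuple[float, float]:
        za = self.z_alpha
        if za is None:
            a = self.alpha / 2 if self.sided == "two" else self.alpha
            za = float(stats.norm.isf(a))
        zb = self.z_beta if self.z_beta is not None else float(stats.norm.isf(self.beta))
        return za, zb


def sample_size_two_proportions(spec: SampleSizeSpec) -> int:
    """Per-group n for comparing two proportions:

    n = (Za * sqrt(2 p(1-p)) + Zb * sqrt(p1(1-p1) + p0(1-p0)))^2 / (p1-p0)^2

    with p the average of p0 and p1; returns the ceiling.
    """
    p0, p1 = spec.p0, spec.p1
    if not (0 < p0 < 1 and 0 < p1 < 1):
        raise ValueError("proportions must lie in (0, 1)")
    if p0 == p1:
        raise ValueError("p0 == p1: the formula divides by zero")
    za, zb = spec.quantiles()
    pbar = (p0 + p1) / 2
    num = za * np.sqrt(2 * pbar * (1 - pbar)) + zb * np.sqrt(
        p1 * (1 - p1) + p0 * (1 - p0)
    )
    return int(np.ceil(num**2 / (p1 - p0) ** 2))


def egfr_ckd_epi(scr_umol_l, age, sex, black: bool = False):
    """2009 CKD-EPI creatinine eGFR (ml/min/1.73 m^2).

    Creatinine is taken in umol/L (converted internally at 88.4);
    ``sex`` is 'male'/'female' (or an array of them).
    """
    scr = np.asarray(scr_umol_l, dtype=float)
    age = np.asarray(age, dtype=float)
    if (scr <= 0).any() or (age <= 0).any():
        raise ValueError("creatinine and age must be positive")
    female = np.asarray(pd.Series(np.atleast_1d(sex)).str.lower() == "female")
    scr_mgdl = scr / UMOL_PER_MGDL
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = scr_mgdl / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993**age
        * np.where(female, 1.018, 1.0)
        * (1.159 if black else 1.0)
    )
    return float(np.ravel(egfr)[0]) if np.isscalar(scr_umol_l) else egfr


def kdigo_stage(egfr):
    """KDIGO CKD stage from eGFR: >=90 G1, 60-89 G2, 30-59 G3, 15-29 G4,
    <15 G5 (lower bounds inclusive)."""
    e = np.asarray(egfr, dtype=float)
    if (e < 0).any():
        raise ValueError("eGFR must be non-negative")
    stage = np.select([e >= 90, e >= 60, e >= 30, e >= 15], [1, 2, 3, 4], default=5)
    return int(stage) if np.isscalar(egfr) else stage


class PropensityModel:
    """Logistic propensity model of treatment on baseline covariates.

    ``fit`` runs iteratively reweighted least squares (statsmodels GLM
    Newton) to a tight gradient tolerance and returns the statsmodels
    results object; ``scores`` gives per-patient treatment probabilities.
    """

    def __init__(self, frame: pd.DataFrame, covariates: Sequence[str],
                 treated_col: str = "treated"):
        self.frame = frame
        self.covariates = list(covariates)
        self.treated_col = treated_col
        self.results_ = None

    def fit(self):
        import statsmodels.api as sm

        x = sm.add_constant(self.frame[self.covariates].astype(float))
        y = self.frame[self.treated_col].astype(int)
        if y.nunique() < 2:
            raise ValueError("need both treated and control patients")
        model = sm.GLM(y, x, family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            try:
                self.results_ = model.fit(maxiter=200, tol=1e-10)
            except Exception as err:  # separation, non-convergence

                raise ValueError(f"propensity fit failed: {err}") from None
        p = np.asarray(self.results_.fittedvalues)
        if ((p <= 1e-12) | (p >= 1 - 1e-12)).any():
            raise ValueError("propensity fit produced degenerate probabilities "
                             "(perfect separation?)")
        return self.results_

    def scores(self) -> np.ndarray:
        if self.results_ is None:
            self.fit()
        return np.asarray(self.results_.fittedvalues)


def propensity_scores(frame: pd.DataFrame, covariates: Sequence[str],
                      treated_col: str = "treated") -> np.ndarray:
    return PropensityModel(frame, covariates, treated_col).scores()


def iptw_weights(
    scores: np.ndarray,
    treated: np.ndarray,
    stabilized: bool = True,
    truncate_pct: float | None = 99.0,
) -> np.ndarray:
    """Inverse-probability-of-treatment weights: 1/p for treated, 1/(1-p)
    for controls; stabilized weights multiply by the marginal arm
    prevalence.  Weights above the ``truncate_pct`` percentile are capped
    (logged) to limit extreme-weight variance."""
    p = np.asarray(scores, float)
    t = np.asarray(treated, bool)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    w = np.where(t, 1 / p, 1 / (1 - p))
    if stabilized:
        prev = t.mean()
        w = w * np.where(t, prev, 1 - prev)
    if truncate_pct is not None:
        cap = np.percentile(w, truncate_pct)
        n_cap = int((w > cap).sum())
        if n_cap:
            log.info("truncating %d weights at the %.0fth percentile (%.3f)",
                     n_cap, truncate_pct, cap)
        w = np.minimum(w, cap)
    return w


def nn_match(
    scores: np.ndarray,
    treated: np.ndarray,
    caliper: float | None = None,
) -> list[tuple[int, int]]:
    """Greedy 1:1 nearest-neighbour matching on the logit of the
    propensity score, without replacement.

    Default caliper is 0.2 sd of the logit scores.  Treated units are
    processed in score order; unmatched units are dropped.  Returns
    (treated_index, control_index) pairs into the input arrays.
    """
    p = np.asarray(scores, float)
    t = np.asarray(treated, bool)
    logit = np.log(p / (1 - p))
    if caliper is None:
        caliper = 0.2 * logit.std(ddof=0)
    t_idx = np.where(t)[0]
    c_idx = np.where(~t)[0]
    if len(t_idx) == 0 or len(c_idx) == 0:
        raise ValueError("both arms must be non-empty")
    available = dict.fromkeys(c_idx)  # insertion-ordered set
    pairs = []
    for i in sorted(t_idx, key=lambda i: logit[i]):
        cands = list(available)
        if not cands:
            break
        dists = np.abs(logit[cands] - logit[i])
        j = int(np.argmin(dists))
        if dists[j] <= caliper:
            pairs.append((int(i), int(cands[j])))
            del available[cands[j]]
    if not pairs:
        warnings.warn("no pairs found within the caliper")
    return pairs


def standardized_mean_difference(
    x_treated, x_control, w_treated=None, w_control=None, binary: bool | None = None
) -> float:
    """Absolute standardized mean difference between arms.

    |m_t - m_c| / sqrt((s_t^2 + s_c^2) / 2); binary covariates use the
    proportion variance p(1-p).  Optional weights give the IPTW-weighted
    version (weighted means and variances).
    """
    xt = np.asarray(x_treated, float)
    xc = np.asarray(x_control, float)
    if len(xt) < 2 or len(xc) < 2:
        raise ValueError("need >=2 values per arm")
    wt = np.ones_like(xt) if w_treated is None else np.asarray(w_treated, float)
    wc = np.ones_like(xc) if w_control is None else np.asarray(w_control, float)
    if binary is None:
        binary = set(np.unique(np.concatenate([xt, xc]))) <= {0.0, 1.0}

    def wmean(x, w):
        return np.average(x, weights=w)

    def wvar(x, w):
        m = wmean(x, w)
        return np.average((x - m) ** 2, weights=w)

    mt, mc = wmean(xt, wt), wmean(xc, wc)
    if binary:
        vt, vc = mt * (1 - mt), mc * (1 - mc)
    else:
        vt, vc = wvar(xt, wt), wvar(xc, wc)
    pooled = (vt + vc) / 2
    if pooled == 0:
        if np.isclose(mt, mc):
            return 0.0
        raise ValueError("zero pooled variance with unequal means")
    return float(abs(mt - mc) / np.sqrt(pooled))


def balance_table(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    treated_col: str = "treated",
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Before/after-weighting SMD and p-value per covariate (the shape of
    a propensity-balance table)."""
    t = frame[treated_col].astype(bool).to_numpy()
    w = np.ones(len(frame)) if weights is None else np.asarray(weights, float)
    rows = []
    for cov in covariates:
        x = frame[cov].astype(float).to_numpy()
        xt, xc = x[t], x[~t]
        binary = set(np.unique(x)) <= {0.0, 1.0}
        if binary:
            tab = np.array(
                [[xt.sum(), len(xt) - xt.sum()], [xc.sum(), len(xc) - xc.sum()]]
            )
            _, _, p_before = chisq_test(tab, yates=True)
        else:
            p_before = float(stats.ttest_ind(xt, xc, equal_var=True).pvalue)
        rows.append(
            {
                "covariate": cov,
                "p_before": p_before,
                "smd_before": standardized_mean_difference(xt, xc, binary=binary),
                "smd_after": standardized_mean_difference(
                    xt, xc, w[t], w[~t], binary=binary
                ),
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def ttest_from_summary(m1, s1, n1, m2, s2, n2) -> tuple[float, float, float]:
    """Pooled-variance two-sample t-test from summary statistics;
    returns (t, df, two-sided p)."""
    if min(n1, n2) < 2 or min(s1, s2) <= 0:
        raise ValueError("need n >= 2 and positive sds in both groups")
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(res.statistic), float(n1 + n2 - 2), float(res.pvalue)


def chisq_test(table, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c count table.

    Yates continuity correction (|O-E| reduced by 0.5, clamped at 0)
    applies only to 2x2 tables; df = (r-1)(c-1).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    rowsum = obs.sum(axis=1)
    colsum = obs.sum(axis=0)
    if (rowsum == 0).any() or (colsum == 0).any():
        raise ValueError("zero margin in the table")
    expected = np.outer(rowsum, colsum) / obs.sum()
    dev = np.abs(obs - expected)
    if yates and obs.shape == (2, 2):
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def effect_estimates(table) -> dict:
    """Risk ratio and odds ratio with 95% log-normal CIs from a 2x2
    table [[a, b], [c, d]] (rows = exposed/unexposed, cols =
    event/no-event).  A zero cell triggers the Haldane-Anscombe 0.5
    correction (flagged)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    corrected = bool((obs == 0).any())
    a, b, c, d = (obs + 0.5).ravel() if corrected else obs.ravel()
    rr = (a / (a + b)) / (c / (c + d))
    or_ = (a * d) / (b * c)
    se_rr = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    se_or = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.isf(0.025)
    return {
        "rr": float(rr),
        "rr_ci": (float(np.exp(np.log(rr) - z * se_rr)),
                  float(np.exp(np.log(rr) + z * se_rr))),
        "or": float(or_),
        "or_ci": (float(np.exp(np.log(or_) - z * se_or)),
                  float(np.exp(np.log(or_) + z * se_or))),
        "haldane_corrected": corrected,
    }


def weighted_logistic_or(
    outcome: np.ndarray, treated: np.ndarray, weights: np.ndarray
) -> dict:
    """IPTW-weighted logistic regression of the outcome on treatment.

    Robust (HC0 sandwich) standard errors treat the weights as fixed,
    the standard marginal-structural-model variance.  Returns the odds
    ratio with its 95% CI.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, int)
    x = sm.add_constant(np.asarray(treated, float))
    res = sm.GLM(y, x, family=sm.families.Binomial(), freq_weights=np.asarray(weights)
                 ).fit(cov_type="HC0")
    beta = res.params[1]
    se = res.bse[1]
    z = stats.norm.isf(0.025)
    return {
        "or": float(np.exp(beta)),
        "or_ci": (float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
        "log_or_se": float(se),
    }
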