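"""Statistical toolkit: rank correlation, rank-sum test, ROC, logistic
regression, Kaplan-Meier / log-rank / Cox hazard ratios.

Small-sample paths are exact (full enumeration) and switch to standard
approximations beyond fixed cutoffs: Spearman p-values are enumerated for
n <= 9, Wilcoxon rank-sum for combined n <= 12.  ROC confidence intervals
use DeLong's method; Cox models handle ties with Efron's approximation
(the lifelines default).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

SPEARMAN_EXACT_N = 9
RANKSUM_EXACT_N = 12


class StatsError(ValueError):
    pass


class SeparationError(StatsError):
    """Perfectly separated logistic regression; retry with firth=True."""


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "p": self.p_value, "n": self.n, "method": self.method}


def spearman_rho(x, y) -> TestResult:
    """Midrank Spearman correlation; exact permutation p for n <= 9."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatsError("length mismatch")
    n = len(x)
    if n < 3:
        raise StatsError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("all-tied input: correlation undefined")
    rho = float(sps.spearmanr(x, y).statistic)
    if n <= SPEARMAN_EXACT_N:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rx = (rx - rx.mean()) / rx.std()
        ry = (ry - ry.mean()) / ry.std()
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (rx[perms] * ry).mean(axis=1) / 1.0
        # rho of each permutation: correlation of standardized midranks
        obs = (rx * ry).mean()
        p = float(np.mean(np.abs(rhos) >= abs(obs) - 1e-12))
        method = "exact permutation"
    else:
        p = float(sps.spearmanr(x, y).pvalue)  # t approximation
        method = "t approximation"
    return TestResult(statistic=rho, p_value=p, n=n, method=method)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def rank_sum_test(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact (full enumeration of group assignments, midranks, so ties are
    handled) when n_a + n_b <= 12; otherwise the normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise StatsError("empty group")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    ranks = sps.rankdata(np.concatenate([a, b]))
    w = float(ranks[:n_a].sum())
    if n <= RANKSUM_EXACT_N:
        sums = np.array([
            ranks[list(idx)].sum() for idx in itertools.combinations(range(n), n_a)
        ])
        lo = float(np.mean(sums <= w + 1e-9))
        hi = float(np.mean(sums >= w - 1e-9))
        p = min(1.0, 2.0 * min(lo, hi))
        method = "exact enumeration"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "normal approximation"
    return TestResult(statistic=w, p_value=p, n=n, method=method)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "ci95_lo": self.ci95[0], "ci95_hi": self.ci95[1],
            "optimal_cutoff": self.optimal_cutoff,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "n": self.n_pos + self.n_neg,
        }


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float) -> tuple[float, float]:
    # structural components: V10 per positive, V01 per negative
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > q) + 0.5 * (pos == q)) for q in neg])
    var = 0.0
    if len(pos) > 1:
        var += v10.var(ddof=1) / len(pos)
    if len(neg) > 1:
        var += v01.var(ddof=1) / len(neg)
    half = 1.959963984540054 * np.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc_analysis(scores, labels) -> ROCResult:
    """AUC (midrank Mann-Whitney), Youden-optimal cutoff, DeLong 95% CI.

    A sample is called positive when its score is strictly above the cutoff,
    matching the dichotomization rule used downstream; the reported cutoff
    maximizes Youden's J = sensitivity + specificity - 1 (smallest such
    cutoff on ties).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise StatsError("length mismatch")
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise StatsError("both classes must be present")
    ranks = sps.rankdata(scores)
    auc = float((ranks[labels].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))

    candidates = np.unique(scores)
    # evaluating at each observed value; "positive" means score > cutoff
    best_j, best = -np.inf, None
    for c in candidates:
        sens = float(np.mean(pos > c))
        spec = float(np.mean(neg <= c))
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best = j, (c, sens, spec)
    cutoff, sens, spec = best
    return ROCResult(
        auc=auc,
        ci95=_delong_ci(pos, neg, auc),
        optimal_cutoff=float(cutoff),
        sensitivity=sens,
        specificity=spec,
        n_pos=len(pos),
        n_neg=len(neg),
    )


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def _firth_logit(y: np.ndarray, x: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Firth bias-reduced logistic regression (Jeffreys-prior penalty)."""
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        xw = x * w[:, None]
        info = x.T @ xw
        cov = np.linalg.inv(info)
        hat = np.einsum("ij,jk,ik->i", xw, cov, x)  # leverages of the weighted fit
        score = x.T @ (y - mu + hat * (0.5 - mu))
        step = cov @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    info = x.T @ (x * (mu * (1 - mu))[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


def logistic_fit(y, X, firth: bool = False) -> pd.DataFrame:
    """Maximum-likelihood logistic regression with Wald p-values.

    Raises :class:`SeparationError` on (quasi-)perfect separation unless
    ``firth=True``, which switches to Firth's penalized likelihood.
    """
    y = np.asarray(y).astype(float)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        xmat = X.to_numpy(dtype=float)
    else:
        xmat = np.atleast_2d(np.asarray(X, dtype=float))
        if xmat.shape[0] == len(y) and xmat.shape[0] != xmat.shape[1]:
            pass
        elif xmat.shape[1] == len(y):
            xmat = xmat.T
        names = [f"x{i}" for i in range(xmat.shape[1])]
    if xmat.ndim == 1:
        xmat = xmat[:, None]
    if len(y) <= xmat.shape[1] + 1:
        raise StatsError("need more observations than coefficients")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise StatsError("y must be binary 0/1")
    design = np.column_stack([np.ones(len(y)), xmat])
    names = ["intercept"] + names

    if firth:
        beta, se = _firth_logit(y, design)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            except Exception as exc:  # statsmodels raises on hard separation
                raise SeparationError(
                    f"logistic fit failed ({exc}); data may be separated — try firth=True"
                ) from exc
        mu = fit.predict(design)
        if np.max(np.abs(fit.params)) > 50 or np.all(np.abs(mu - y) < 1e-6):
            raise SeparationError(
                "perfect separation detected; coefficients diverge — try firth=True"
            )
        beta, se = np.asarray(fit.params), np.asarray(fit.bse)

    z = beta / se
    p = 2 * sps.norm.sf(np.abs(z))
    return pd.DataFrame({"coef": beta, "se": se, "z": z, "p": p}, index=names)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    km: dict[str, pd.DataFrame]  # per group: time, survival, n_at_risk
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float
    hr_ci95: tuple[float, float]
    hr_p: float
    hr_defined: bool
    groups: tuple[str, str]

    def to_dict(self) -> dict:
        return {
            "logrank_chi2": self.logrank_chi2, "logrank_p": self.logrank_p,
            "hazard_ratio": self.hazard_ratio,
            "hr_ci95_lo": self.hr_ci95[0], "hr_ci95_hi": self.hr_ci95[1],
            "hr_p": self.hr_p, "hr_defined": self.hr_defined,
        }


def survival_analysis(time, event, group) -> SurvivalFit:
    """Kaplan-Meier curves, two-group log-rank test and Cox hazard ratio.

    The hazard ratio is for the *second* group level (sorted order) relative
    to the first, from a Cox fit on the group indicator with Efron tie
    handling.  If either group has zero events the HR is flagged undefined.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    group = np.asarray(group)
    if np.any(time <= 0):
        raise StatsError("survival times must be positive")
    levels = sorted(pd.unique(group).tolist())
    if len(levels) != 2:
        raise StatsError(f"group must have exactly 2 levels, got {levels}")
    g0, g1 = levels
    m0, m1 = group == g0, group == g1

    km = {}
    for name, m in ((g0, m0), (g1, m1)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(name))
        tbl = kmf.event_table
        km[str(name)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "n_at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )

    lr = logrank_test(time[m0], time[m1], event[m0], event[m1])

    hr_defined = event[m0].sum() > 0 and event[m1].sum() > 0
    if hr_defined:
        df = pd.DataFrame({"t": time, "e": event, "g": m1.astype(int)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter().fit(df, duration_col="t", event_col="e", formula="g")
        coef = float(cph.params_["g"])
        se = float(cph.standard_errors_["g"])
        hr = float(np.exp(coef))
        ci = (
            float(np.exp(np.clip(coef - 1.96 * se, -700, 700))),
            float(np.exp(np.clip(coef + 1.96 * se, -700, 700))),
        )
        hr_p = float(cph.summary.loc["g", "p"])
    else:
        hr, ci, hr_p = float("nan"), (float("nan"), float("nan")), float("nan")

    return SurvivalFit(
        km=km,
        logrank_chi2=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hazard_ratio=hr,
        hr_ci95=ci,
        hr_p=hr_p,
        hr_defined=hr_defined,
        groups=(str(g0), str(g1)),
    )
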