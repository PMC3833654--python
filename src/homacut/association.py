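"""Quintile odds-ratio analysis and insulin-resistance prevalence tables.

The exposure is HOMA-IR, binned into quintiles of its cohort
distribution; the outcomes are metabolic syndrome and its five
components. Odds ratios per quintile (lowest quintile referent) come
from a maximum-likelihood logistic model with optional adjustment for
age, sex and pubertal (Tanner) stage, with Wald 95% intervals. A
closed-form 2x2 odds ratio with a Woolf interval is kept alongside as
the independent oracle for the unadjusted fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

from .errors import DegenerateDataError, InputError
from .metrics import quantile

__all__ = [
    "QuintileAssignment",
    "assign_quintiles",
    "crude_or",
    "fit_logistic_or",
    "chi_square",
    "PrevalenceTable",
    "prevalence_of_ir",
]

Z_95 = 1.959963984540054  # standard-normal 97.5% point


@dataclass
class QuintileAssignment:
    """Quintile index (1-5) per subject plus the four interior bounds."""

    quintile: pd.Series
    bounds: np.ndarray

    def sizes(self) -> pd.Series:
        return self.quintile.value_counts().sort_index()


def assign_quintiles(values, bounds=None) -> QuintileAssignment:
    """Bin values into quintiles of their own distribution.

    Interior bounds are the 20/40/60/80th percentiles (shared quantile
    convention); a subject falls in quintile ``k`` per the half-open
    intervals ``(-inf, b1], (b1, b2], ..., (b4, inf)``. Externally
    supplied fixed bounds (e.g. published quintile values) can be passed
    via ``bounds``.

    Raises
    ------
    DegenerateDataError
        If the bounds are not strictly increasing (massive ties collapse
        quintiles; flagged, never silently mis-binned).
    """
    v = pd.Series(values, dtype=float)
    if bounds is None:
        if len(v) < 5:
            raise InputError(f"need at least 5 values for quintiles, got {len(v)}")
        bounds = np.asarray(quantile(v, [0.2, 0.4, 0.6, 0.8]), dtype=float)
    else:
        bounds = np.asarray(bounds, dtype=float)
        if bounds.shape != (4,):
            raise InputError("quintile bounds must be four values")
    if not np.all(np.diff(bounds) > 0):
        raise DegenerateDataError(
            f"quintile bounds are not strictly increasing: {bounds.tolist()} "
            "(ties collapse quintiles)"
        )
    idx = np.searchsorted(bounds, v.to_numpy(), side="left") + 1
    return QuintileAssignment(
        quintile=pd.Series(idx, index=v.index, name="quintile"), bounds=bounds
    )


def crude_or(a: float, b: float, c: float, d: float) -> dict:
    """Closed-form 2x2 odds ratio with a Woolf 95% interval.

    Table layout: exposed cases ``a``, exposed non-cases ``b``, unexposed
    cases ``c``, unexposed non-cases ``d``; OR = ad/bc. A zero cell adds
    0.5 to all four cells (Haldane-Anscombe), flagged in the result.
    """
    cells = np.asarray([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise InputError("2x2 cell counts must be >= 0")
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    return {
        "or": float(or_),
        "ci_low": float(np.exp(np.log(or_) - Z_95 * se)),
        "ci_high": float(np.exp(np.log(or_) + Z_95 * se)),
        "corrected": corrected,
    }


def fit_logistic_or(
    outcome,
    quintile,
    covariates: pd.DataFrame | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> pd.DataFrame:
    """Quintile odds ratios from a maximum-likelihood logistic fit.

    The model is ``logit P(outcome) = b0 + sum_k b_k 1[quintile = k] +
    covariates`` with quintile 1 the referent. Fitting is Newton's
    method to parameter tolerance ``tol``; odds ratios are exponentiated
    coefficients with Wald 95% intervals and Wald p-values. Adjusted
    analyses pass ``covariates`` with columns such as ``age`` (years),
    ``sex`` (0/1 indicator) and ``tanner`` (ordinal 1-5 treated as
    numeric; use indicator columns for factor coding).

    Returns a DataFrame indexed ``q2..q5`` with columns ``or, ci_low,
    ci_high, p, flagged``; the referent row ``q1`` carries OR 1 by
    definition and is omitted. Non-convergence or perfect separation
    yields flagged rows with infinite intervals rather than a crash.
    """
    y = np.asarray(outcome, dtype=float)
    q = np.asarray(quintile, dtype=int)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise InputError("outcome must be binary")
    if y.min() == y.max():
        raise InputError("outcome has a single class")
    levels = [2, 3, 4, 5]
    X = pd.DataFrame({f"q{k}": (q == k).astype(float) for k in levels})
    if covariates is not None:
        cov = covariates.reset_index(drop=True).astype(float)
        X = pd.concat([X, cov], axis=1)
    X = sm.add_constant(X, prepend=True)

    flagged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            res = sm.Logit(y, X).fit(
                method="newton", tol=tol, maxiter=maxiter, disp=0, warn_convergence=True
            )
        if not res.mle_retvals.get("converged", False):
            flagged = True
    except (PerfectSeparationError, ConvergenceWarning, np.linalg.LinAlgError):
        rows = {
            f"q{k}": {
                "or": np.inf,
                "ci_low": 0.0,
                "ci_high": np.inf,
                "p": np.nan,
                "flagged": True,
            }
            for k in levels
        }
        return pd.DataFrame(rows).T

    params = res.params
    bse = res.bse
    pvals = res.pvalues
    rows = {}
    for k in levels:
        name = f"q{k}"
        beta, se = params[name], bse[name]
        rows[name] = {
            "or": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - Z_95 * se)),
            "ci_high": float(np.exp(beta + Z_95 * se)),
            "p": float(pvals[name]),
            "flagged": flagged,
        }
    return pd.DataFrame(rows).T


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction; expected counts from the margins;
    ``df = (r - 1)(c - 1)``. A zero row or column margin is an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise InputError("chi-square table must be at least 2x2")
    if np.any(obs < 0):
        raise InputError("counts must be >= 0")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise InputError("chi-square table has a zero margin")
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass
class PrevalenceTable:
    """Prevalence of insulin resistance (%) by group and HOMA-IR cut-off.

    ``prevalence`` has one row per group (MS, each component, each weight
    category) and one column per labelled cut-off; cells are percentages,
    NaN for an empty group. ``group_n`` gives group sizes.
    ``weight_status_chi2`` compares IR prevalence across the
    normal/overweight/obese rows per cut-off (statistic, df, p).
    """

    prevalence: pd.DataFrame
    group_n: pd.Series
    weight_status_chi2: pd.DataFrame


def prevalence_of_ir(
    cohort: pd.DataFrame,
    profiles: pd.DataFrame,
    weight: pd.DataFrame,
    cutoffs: dict,
    inclusive: bool = False,
) -> PrevalenceTable:
    """Prevalence of insulin resistance under each labelled HOMA-IR cut-off.

    A subject is insulin resistant when HOMA-IR is strictly above the
    cut-off (``>=`` when ``inclusive``). Groups are metabolic syndrome,
    each of its five components, and the three weight-status categories.
    """
    if not cutoffs:
        raise InputError("at least one labelled cutoff is required")
    if "homa_ir" not in cohort.columns:
        from .metrics import compute_homa_ir

        cohort = cohort.copy()
        cohort["homa_ir"] = compute_homa_ir(cohort["insulin"], cohort["glucose"])

    groups = {
        "ms": profiles["ms"],
        "central_obesity": profiles["central_obesity"],
        "high_bp": profiles["high_bp"],
        "high_tg": profiles["high_tg"],
        "low_hdl": profiles["low_hdl"],
        "ifg": profiles["ifg"],
        "normal": weight["category"] == "normal",
        "overweight": weight["category"] == "overweight",
        "obese": weight["category"] == "obese",
    }
    homa = cohort["homa_ir"].to_numpy(dtype=float)
    prev = pd.DataFrame(index=list(groups), columns=list(cutoffs), dtype=float)
    n_by_group = pd.Series({g: int(np.asarray(m, bool).sum()) for g, m in groups.items()})
    for label, cut in cutoffs.items():
        ir = homa >= cut if inclusive else homa > cut
        for g, mask in groups.items():
            m = np.asarray(mask, dtype=bool)
            prev.loc[g, label] = 100.0 * ir[m].mean() if m.any() else np.nan

    chi_rows = {}
    for label, cut in cutoffs.items():
        ir = homa >= cut if inclusive else homa > cut
        tab = []
        for g in ("normal", "overweight", "obese"):
            m = np.asarray(groups[g], dtype=bool)
            tab.append([int(ir[m].sum()), int((~ir[m]).sum())])
        try:
            stat, dof, p = chi_square(tab)
        except InputError:
            stat, dof, p = np.nan, 0, np.nan
        chi_rows[label] = {"chi_sq": stat, "df": dof, "p": p}
    return PrevalenceTable(
        prevalence=prev, group_n=n_by_group, weight_status_chi2=pd.DataFrame(chi_rows).T
    )
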