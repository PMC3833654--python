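"""Per-subject indices and the shared quantile engine.

This module holds the three primitives everything else builds on:

* :func:`compute_homa_ir` — the homeostasis-model insulin-resistance index,
  fasting insulin (mU/L) x fasting glucose (mmol/L) / 22.5;
* :func:`quantile` — the single quantile convention used for every
  percentile-based threshold in the package (linear interpolation at rank
  ``1 + (n - 1) * p`` on the order statistics);
* :func:`classify_weight_status` — BMI-for-age-and-sex banding into
  normal / overweight / obese against an injected growth reference.

The growth reference is deliberately pluggable: population growth charts
(e.g. national LMS tables) are external data, so :class:`GrowthReference`
accepts an empirical sample per age/sex stratum, a three-curve percentile
table (p05/p85/p95), or LMS triplets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "COHORT_COLUMNS",
    "compute_homa_ir",
    "quantile",
    "GrowthReference",
    "WeightStatus",
    "classify_weight_status",
]

#: Canonical column order of a cohort table (one row per subject).
COHORT_COLUMNS = [
    "id",
    "sex",
    "age",
    "tanner",
    "height_cm",
    "weight_kg",
    "bmi",
    "wc_cm",
    "fat_pct",
    "sbp",
    "dbp",
    "tc",
    "tg",
    "hdl",
    "ldl",
    "glucose",
    "insulin",
]


def compute_homa_ir(insulin, glucose):
    """Homeostasis-model assessment of insulin resistance.

    Parameters
    ----------
    insulin : float or array-like
        Fasting insulin in mU/L. Must be >= 0.
    glucose : float or array-like
        Fasting plasma glucose in mmol/L. Must be > 0.

    Returns
    -------
    float or ndarray
        ``insulin * glucose / 22.5`` (unitless index).
    """
    ins = np.asarray(insulin, dtype=float)
    glu = np.asarray(glucose, dtype=float)
    if np.any(ins < 0) or np.any(np.isnan(ins)):
        raise InputError("fasting insulin must be >= 0 and non-missing")
    if np.any(glu <= 0) or np.any(np.isnan(glu)):
        raise InputError("fasting glucose must be > 0 and non-missing")
    out = ins * glu / 22.5
    if out.ndim == 0:
        return float(out)
    return out


def quantile(values, p):
    """Quantile by linear interpolation at rank ``1 + (n - 1) * p``.

    This is the package-wide convention for every percentile threshold
    (waist p90, blood-pressure p95, HOMA-IR p95, quintile bounds). It is
    the classic order-statistics interpolation (numpy's ``"linear"``
    method): with sorted values ``x_(1) <= ... <= x_(n)`` the result is
    the value at fractional rank ``h = 1 + (n - 1) p``.

    Parameters
    ----------
    values : array-like
        Non-empty collection of reals.
    p : float or array-like of float
        Probability level(s) in [0, 1].

    Returns
    -------
    float or ndarray
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InputError("quantile of an empty collection is undefined")
    if np.any(np.isnan(arr)):
        raise InputError("quantile input contains missing values")
    pv = np.asarray(p, dtype=float)
    if np.any((pv < 0) | (pv > 1)):
        raise InputError(f"quantile level must be in [0, 1], got {p!r}")
    out = np.quantile(arr, pv, method="linear")
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class WeightStatus:
    """BMI-for-age-and-sex weight category of one subject.

    ``category`` is one of ``"underweight"``, ``"normal"``, ``"overweight"``,
    ``"obese"``; bands are closed on the left boundary: percentile in
    [5, 85] is normal, (85, 95] overweight, > 95 obese, < 5 underweight.
    Underweight subjects are flagged so they can be excluded from the
    normal-metabolic reference population.

    ``bmi_percentile`` is the age-sex-standardised BMI percentile when the
    reference can supply one exactly (empirical or LMS reference); it is
    NaN for a three-curve band table outside the [5, 95] range, where only
    the category is defined.
    """

    category: Literal["underweight", "normal", "overweight", "obese"]
    bmi_percentile: float


class GrowthReference:
    """Age- and sex-specific BMI percentile curves.

    Three constructions are supported:

    * :meth:`from_samples` — an empirical reference: for each (sex, age
      band) a sample of BMI values; any percentile is computed with the
      shared :func:`quantile` engine and a BMI is converted back to a
      percentile by inverting the same interpolation.
    * :meth:`from_percentile_table` — a table with columns
      ``age, sex, p05, p85, p95``; only the three band boundaries are
      known, so categories are exact but the reported percentile is
      interpolated between the known curves (NaN outside [p05, p95]).
    * :meth:`from_lms_table` — a table with columns ``age, sex, L, M, S``;
      the percentile is ``100 * Phi(((bmi / M)**L - 1) / (L * S))``.

    Ages are binned to integer years (floor) for lookup; the reference must
    cover every (sex, floor(age)) it is queried with.
    """

    def __init__(self, kind: str, table: dict):
        self._kind = kind
        self._table = table

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_samples(cls, bmi, age, sex) -> "GrowthReference":
        """Build an empirical reference from per-subject BMI/age/sex arrays."""
        bmi = np.asarray(bmi, dtype=float)
        age = np.asarray(age, dtype=float)
        sex = np.asarray(sex)
        if not (len(bmi) == len(age) == len(sex)):
            raise InputError("bmi, age and sex must have equal length")
        table: dict = {}
        for key in {(s, int(np.floor(a))) for s, a in zip(sex, age)}:
            mask = (sex == key[0]) & (np.floor(age).astype(int) == key[1])
            table[key] = np.sort(bmi[mask])
        return cls("samples", table)

    @classmethod
    def from_percentile_table(cls, df: pd.DataFrame) -> "GrowthReference":
        required = {"age", "sex", "p05", "p85", "p95"}
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"percentile table missing columns: {sorted(missing)}")
        table = {
            (row.sex, int(row.age)): (row.p05, row.p85, row.p95)
            for row in df.itertuples()
        }
        return cls("bands", table)

    @classmethod
    def from_lms_table(cls, df: pd.DataFrame) -> "GrowthReference":
        required = {"age", "sex", "L", "M", "S"}
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"LMS table missing columns: {sorted(missing)}")
        table = {
            (row.sex, int(row.age)): (row.L, row.M, row.S) for row in df.itertuples()
        }
        return cls("lms", table)

    @classmethod
    def from_csv(cls, path) -> "GrowthReference":
        """Load a reference CSV; band (p05/p85/p95) and LMS layouts are auto-detected."""
        df = pd.read_csv(path)
        if {"p05", "p85", "p95"} <= set(df.columns):
            return cls.from_percentile_table(df)
        if {"L", "M", "S"} <= set(df.columns):
            return cls.from_lms_table(df)
        raise InputError(
            "growth reference CSV must carry p05/p85/p95 or L/M/S columns"
        )

    # -- queries ----------------------------------------------------------

    def _entry(self, age: float, sex: str):
        key = (sex, int(np.floor(age)))
        if key not in self._table:
            raise InputError(f"growth reference does not cover (sex={sex}, age={key[1]})")
        return self._table[key]

    def percentile(self, bmi: float, age: float, sex: str) -> float:
        """Age-sex-standardised BMI percentile (NaN when only bands are known)."""
        entry = self._entry(age, sex)
        if self._kind == "samples":
            vals = entry
            n = len(vals)
            if n == 1:
                return 50.0 if bmi == vals[0] else (0.0 if bmi < vals[0] else 100.0)
            # invert the rank-interpolation convention: p = (h - 1) / (n - 1)
            pct = np.interp(bmi, vals, np.linspace(0.0, 100.0, n))
            return float(pct)
        if self._kind == "lms":
            L, M, S = entry
            if L == 0:
                z = np.log(bmi / M) / S
            else:
                z = ((bmi / M) ** L - 1.0) / (L * S)
            return float(100.0 * stats.norm.cdf(z))
        p05, p85, p95 = entry
        if bmi < p05 or bmi > p95:
            return float("nan")
        return float(np.interp(bmi, [p05, p85, p95], [5.0, 85.0, 95.0]))

    def band_values(self, age: float, sex: str) -> tuple[float, float, float]:
        """The (p05, p85, p95) BMI values for this age/sex stratum."""
        entry = self._entry(age, sex)
        if self._kind == "samples":
            return tuple(quantile(entry, [0.05, 0.85, 0.95]))  # type: ignore[return-value]
        if self._kind == "lms":
            L, M, S = entry
            out = []
            for p in (0.05, 0.85, 0.95):
                z = stats.norm.ppf(p)
                if L == 0:
                    out.append(M * np.exp(S * z))
                else:
                    out.append(M * (1.0 + L * S * z) ** (1.0 / L))
            return tuple(float(v) for v in out)  # type: ignore[return-value]
        return self._table[(sex, int(np.floor(age)))]


def classify_weight_status(
    bmi: float, age: float, sex: str, growth_reference: GrowthReference
) -> WeightStatus:
    """Classify BMI into weight-status bands against a growth reference.

    Band boundaries are closed on the left: percentile in [5, 85] is
    normal, exactly 85 is still normal; (85, 95] is overweight, exactly 95
    is still overweight; strictly above 95 is obese. BMI below the 5th
    percentile is flagged ``underweight`` (such subjects are excluded when
    selecting the normal-metabolic reference population, never silently
    labelled normal).
    """
    if bmi <= 0:
        raise InputError(f"bmi must be > 0, got {bmi}")
    p05, p85, p95 = growth_reference.band_values(age, sex)
    pct = growth_reference.percentile(bmi, age, sex)
    if bmi < p05:
        category = "underweight"
    elif bmi <= p85:
        category = "normal"
    elif bmi <= p95:
        category = "overweight"
    else:
        category = "obese"
    return WeightStatus(category=category, bmi_percentile=pct)


def classify_weight_status_frame(
    df: pd.DataFrame, growth_reference: GrowthReference
) -> pd.DataFrame:
    """Vectorised :func:`classify_weight_status` over a cohort table.

    Returns a DataFrame indexed like ``df`` with columns ``category`` and
    ``bmi_percentile``.
    """
    cats = []
    pcts = []
    for row in df.itertuples():
        ws = classify_weight_status(row.bmi, row.age, row.sex, growth_reference)
        cats.append(ws.category)
        pcts.append(ws.bmi_percentile)
    return pd.DataFrame({"category": cats, "bmi_percentile": pcts}, index=df.index)
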