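"""HOMA-IR cut-off derivation: reference percentiles and ROC optima.

Two families of cut-off are produced:

* the 95th percentile of HOMA-IR in a normal-metabolic reference
  population, tabulated overall and by sex, age band, and Tanner band
  (:func:`derive_reference_p95_table`);
* the ROC-optimal operating point against metabolic-syndrome status,
  selected either by the maximum Youden index ``J = sens + spec - 1`` or
  by the minimum squared distance to the perfect-classification corner
  ``(1 - sens)^2 + (1 - spec)^2`` (:func:`build_roc`,
  :func:`optimal_cutoff`).

The positive-call convention is strictly-greater (``score > cutoff``),
matching the clinical reading of "HOMA-IR > 3.0"; an inclusive rule is
available behind ``inclusive=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import EmptyStratumError, InputError
from .metrics import quantile

__all__ = [
    "ROCCurve",
    "CutoffResult",
    "build_roc",
    "optimal_cutoff",
    "operating_characteristics",
    "derive_reference_p95_table",
    "REFERENCE_STRATA",
]


@dataclass
class ROCCurve:
    """Empirical ROC curve of a score against a binary label.

    ``cutoffs`` is ascending; the first entry is a sentinel below the
    minimum score (every subject called positive: sens 1, spec 0) and the
    last is the maximum score (nobody called positive under the
    strictly-greater rule: sens 0, spec 1). ``auc`` is the trapezoidal
    area over (1 - specificity, sensitivity), which for this candidate
    set equals the tie-corrected pairwise concordance probability.
    """

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int
    auc: float
    inclusive: bool = False
    _scores: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _labels: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def operating_points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


@dataclass(frozen=True)
class CutoffResult:
    """A selected cut-off with its operating characteristics.

    ``youden = sensitivity + specificity - 1``;
    ``distance_sq = (1 - sensitivity)^2 + (1 - specificity)^2``.
    """

    cutoff: float
    sensitivity: float
    specificity: float
    youden: float
    distance_sq: float
    method: Literal["youden", "distance", "percentile"]


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J statistic, ``sensitivity + specificity - 1``."""
    return sensitivity + specificity - 1.0


def distance_to_corner_sq(sensitivity: float, specificity: float) -> float:
    """Squared ROC-plane distance to the (0, 1) corner."""
    return (1.0 - sensitivity) ** 2 + (1.0 - specificity) ** 2


def build_roc(scores, labels, inclusive: bool = False) -> ROCCurve:
    """Build the empirical ROC curve of ``scores`` against boolean ``labels``.

    Candidate cut-offs are the distinct observed scores plus one sentinel
    below the minimum. A subject is called positive when its score is
    strictly greater than the cut-off (``>=`` when ``inclusive``).

    Raises
    ------
    InputError
        If only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise InputError("scores and labels must be equal-length 1-d arrays")
    if np.any(np.isnan(s)):
        raise InputError("scores contain missing values")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("ROC requires both classes present")

    distinct = np.unique(s)
    sentinel = distinct[0] - 1.0
    cutoffs = np.concatenate([[sentinel], distinct])

    pos_sorted = np.sort(s[y])
    neg_sorted = np.sort(s[~y])
    side = "left" if inclusive else "right"
    # positives called: score > c  (or >= c when inclusive)
    tp = n_pos - np.searchsorted(pos_sorted, cutoffs, side=side)
    fp = n_neg - np.searchsorted(neg_sorted, cutoffs, side=side)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg

    fpr = 1.0 - spec
    # cutoffs ascending => fpr non-increasing; integrate over increasing fpr
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    return ROCCurve(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        n_pos=n_pos,
        n_neg=n_neg,
        auc=auc,
        inclusive=inclusive,
        _scores=s,
        _labels=y,
    )


def optimal_cutoff(roc: ROCCurve, method: Literal["youden", "distance"]) -> CutoffResult:
    """Select the ROC-optimal operating point.

    ``method="youden"`` maximises ``sens + spec - 1``; ``method="distance"``
    minimises ``(1 - sens)^2 + (1 - spec)^2``. Ties on the primary
    criterion are broken by the other criterion, then by the smaller
    cut-off, so the result is deterministic.
    """
    if method not in ("youden", "distance"):
        raise InputError(f"unknown cut-off method {method!r}")
    j = roc.sensitivity + roc.specificity - 1.0
    d2 = (1.0 - roc.sensitivity) ** 2 + (1.0 - roc.specificity) ** 2
    if method == "youden":
        keys = np.lexsort((roc.cutoffs, d2, -j))
    else:
        keys = np.lexsort((roc.cutoffs, -j, d2))
    i = int(keys[0])
    return CutoffResult(
        cutoff=float(roc.cutoffs[i]),
        sensitivity=float(roc.sensitivity[i]),
        specificity=float(roc.specificity[i]),
        youden=float(j[i]),
        distance_sq=float(d2[i]),
        method=method,
    )


def operating_characteristics(roc: ROCCurve, cutoff: float) -> tuple[float, float]:
    """Sensitivity and specificity at an arbitrary (possibly off-grid) cut-off.

    Recomputed from the stored scores with the same positive-call rule
    the curve was built with, so a cut-off equal to an observed candidate
    reproduces that operating point exactly.
    """
    s, y = roc._scores, roc._labels
    if s is None:
        raise InputError("ROC curve does not carry its scores")
    called = s >= cutoff if roc.inclusive else s > cutoff
    sens = float(called[y].mean())
    spec = float((~called[~y]).mean())
    return sens, spec


#: Stratum labels of the reference p95 table, with their row predicates.
REFERENCE_STRATA = [
    ("total", lambda d: pd.Series(True, index=d.index)),
    ("male", lambda d: d["sex"] == "M"),
    ("female", lambda d: d["sex"] == "F"),
    ("age_6_9", lambda d: (d["age"] >= 6) & (d["age"] < 10)),
    ("age_ge10", lambda d: d["age"] >= 10),
    ("age_10_15", lambda d: (d["age"] >= 10) & (d["age"] < 16)),
    ("age_ge16", lambda d: d["age"] >= 16),
    ("tanner_I", lambda d: d["tanner"] == 1),
    ("tanner_ge_II", lambda d: d["tanner"] >= 2),
    ("tanner_II_IV", lambda d: (d["tanner"] >= 2) & (d["tanner"] <= 4)),
    ("tanner_V", lambda d: d["tanner"] == 5),
]


def derive_reference_p95_table(reference: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum n / mean / SD / p95 of HOMA-IR in the reference population.

    Strata overlap by design (``age_ge10`` contains both ``age_10_15`` and
    ``age_ge16``; ``tanner_ge_II`` contains ``tanner_II_IV`` and
    ``tanner_V``), so row n's need not sum to the total. An empty stratum
    is kept with ``n = 0`` and NaN statistics rather than dropped, so the
    table layout is stable. ``reference`` must carry a ``homa_ir`` column
    (or ``insulin``/``glucose`` from which it is computed).
    """
    if len(reference) == 0:
        raise EmptyStratumError("reference population is empty")
    ref = reference
    if "homa_ir" not in ref.columns:
        from .metrics import compute_homa_ir

        ref = ref.copy()
        ref["homa_ir"] = compute_homa_ir(ref["insulin"], ref["glucose"])

    rows = []
    for label, pred in REFERENCE_STRATA:
        vals = ref.loc[pred(ref), "homa_ir"].to_numpy(dtype=float)
        if vals.size == 0:
            rows.append({"stratum": label, "n": 0, "mean": np.nan, "sd": np.nan, "p95": np.nan})
            continue
        rows.append(
            {
                "stratum": label,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "p95": quantile(vals, 0.95),
            }
        )
    return pd.DataFrame(rows).set_index("stratum")
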