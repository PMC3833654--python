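"""Modified ATP III metabolic-syndrome classification for children.

Five components, three-or-more rule:

1. central obesity — waist circumference >= the 90th percentile for age
   and sex (cohort-derived);
2. elevated blood pressure — systolic and/or diastolic BP >= the 95th
   percentile for age, sex and height (cohort-derived, height handled by
   within-stratum bands);
3. hypertriglyceridemia — TG >= 1.24 mmol/L (fixed cut, the 90th
   percentile of the original reference population);
4. low HDL cholesterol — HDL-C <= 1.03 mmol/L (fixed cut, ~5th
   percentile of the original reference population);
5. impaired fasting glucose — fasting glucose >= 5.6 mmol/L (fixed cut).

All fixed cuts are inclusive exactly as printed (>= / <=). The percentile
thresholds use the shared quantile engine, so a cohort applied to its own
thresholds exceeds its waist p90 in ~10% of each stratum by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptyStratumError, InputError
from .metrics import quantile

__all__ = [
    "TG_CUT_MMOL_L",
    "HDL_CUT_MMOL_L",
    "GLUCOSE_CUT_MMOL_L",
    "ComponentThresholds",
    "derive_component_thresholds",
    "classify_components",
    "select_reference_population",
]

TG_CUT_MMOL_L = 1.24
HDL_CUT_MMOL_L = 1.03
GLUCOSE_CUT_MMOL_L = 5.6

COMPONENT_FLAGS = ["central_obesity", "high_bp", "high_tg", "low_hdl", "ifg"]


def _age_group(age, width: float, origin: float):
    """Integer age-band index for one or many ages."""
    return np.floor((np.asarray(age, dtype=float) - origin) / width).astype(int)


@dataclass
class ComponentThresholds:
    """Stratified and fixed component thresholds for MS classification.

    ``wc_p90`` maps (sex, age_group) -> waist p90 in cm. ``sbp_p95`` and
    ``dbp_p95`` map (sex, age_group, height_band) -> BP p95 in mmHg, with
    ``height_band_edges`` holding the interior height-band boundaries per
    (sex, age_group). Fixed cuts are carried verbatim so that a serialized
    thresholds object is self-contained.
    """

    wc_p90: dict
    sbp_p95: dict
    dbp_p95: dict
    height_band_edges: dict
    age_group_width: float
    age_origin: float
    n_height_bands: int
    tg_cut: float = TG_CUT_MMOL_L
    hdl_cut: float = HDL_CUT_MMOL_L
    glucose_cut: float = GLUCOSE_CUT_MMOL_L

    # -- stratum lookup ---------------------------------------------------

    def age_group_of(self, age: float) -> int:
        return int(_age_group(age, self.age_group_width, self.age_origin))

    def height_band_of(self, sex: str, age_group: int, height: float) -> int:
        edges = self.height_band_edges[(sex, age_group)]
        return int(np.searchsorted(edges, height, side="right"))

    # -- (de)serialization ------------------------------------------------

    def to_json(self) -> str:
        def enc(d: Mapping) -> dict:
            return {"|".join(str(k) for k in key): v for key, v in d.items()}

        payload = {
            "age_group_width": self.age_group_width,
            "age_origin": self.age_origin,
            "n_height_bands": self.n_height_bands,
            "tg_cut": self.tg_cut,
            "hdl_cut": self.hdl_cut,
            "glucose_cut": self.glucose_cut,
            "wc_p90": enc(self.wc_p90),
            "sbp_p95": enc(self.sbp_p95),
            "dbp_p95": enc(self.dbp_p95),
            "height_band_edges": {
                "|".join(str(k) for k in key): list(v)
                for key, v in self.height_band_edges.items()
            },
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ComponentThresholds":
        raw = json.loads(text)

        def dec2(d: Mapping) -> dict:
            out = {}
            for key, v in d.items():
                sex, grp = key.split("|")
                out[(sex, int(grp))] = v
            return out

        def dec3(d: Mapping) -> dict:
            out = {}
            for key, v in d.items():
                sex, grp, band = key.split("|")
                out[(sex, int(grp), int(band))] = v
            return out

        return cls(
            wc_p90=dec2(raw["wc_p90"]),
            sbp_p95=dec3(raw["sbp_p95"]),
            dbp_p95=dec3(raw["dbp_p95"]),
            height_band_edges={
                k: np.asarray(v, dtype=float)
                for k, v in dec2(raw["height_band_edges"]).items()
            },
            age_group_width=raw["age_group_width"],
            age_origin=raw["age_origin"],
            n_height_bands=raw["n_height_bands"],
            tg_cut=raw["tg_cut"],
            hdl_cut=raw["hdl_cut"],
            glucose_cut=raw["glucose_cut"],
        )


def derive_component_thresholds(
    cohort: pd.DataFrame,
    age_group_width: float = 1.0,
    n_height_bands: int = 3,
    min_stratum_size: int = 20,
) -> ComponentThresholds:
    """Derive the stratified percentile thresholds from a cohort.

    Waist p90 is computed within (sex, age-band) strata; SBP/DBP p95
    within (sex, age-band, height-band) strata, height bands being
    equal-probability quantile bands of height within the (sex, age-band)
    stratum (``n_height_bands=1`` disables height adjustment). The fixed
    TG / HDL / glucose cuts are attached verbatim.

    Parameters
    ----------
    cohort : DataFrame
        One row per subject with at least sex, age, height_cm, wc_cm,
        sbp, dbp.
    age_group_width : float
        Width of age bands in years (default one-year bands).
    n_height_bands : int
        Number of height bands within each age/sex stratum (default
        tertiles).
    min_stratum_size : int
        Minimum (sex, age-band) stratum size; an undersized stratum is an
        error naming the stratum.
    """
    if age_group_width <= 0:
        raise InputError("age_group_width must be > 0")
    if n_height_bands < 1:
        raise InputError("n_height_bands must be >= 1")
    origin = float(np.floor(cohort["age"].min()))
    groups = _age_group(cohort["age"], age_group_width, origin)

    wc_p90: dict = {}
    sbp_p95: dict = {}
    dbp_p95: dict = {}
    edges_map: dict = {}
    for (sex, grp), sub in cohort.groupby([cohort["sex"], groups]):
        if len(sub) < min_stratum_size:
            raise EmptyStratumError(
                f"stratum (sex={sex}, age_group={grp}) has n={len(sub)} "
                f"< required {min_stratum_size}"
            )
        wc_p90[(sex, grp)] = quantile(sub["wc_cm"], 0.90)
        if n_height_bands > 1:
            ps = np.arange(1, n_height_bands) / n_height_bands
            edges = np.atleast_1d(quantile(sub["height_cm"], ps))
        else:
            edges = np.asarray([], dtype=float)
        edges_map[(sex, grp)] = edges
        bands = np.searchsorted(edges, sub["height_cm"].to_numpy(), side="right")
        for band in range(n_height_bands):
            bsub = sub[bands == band]
            if len(bsub) == 0:
                raise EmptyStratumError(
                    f"height band {band} empty in stratum (sex={sex}, age_group={grp})"
                )
            sbp_p95[(sex, grp, band)] = quantile(bsub["sbp"], 0.95)
            dbp_p95[(sex, grp, band)] = quantile(bsub["dbp"], 0.95)

    return ComponentThresholds(
        wc_p90=wc_p90,
        sbp_p95=sbp_p95,
        dbp_p95=dbp_p95,
        height_band_edges=edges_map,
        age_group_width=age_group_width,
        age_origin=origin,
        n_height_bands=n_height_bands,
    )


def classify_components(
    cohort: pd.DataFrame, thresholds: ComponentThresholds
) -> pd.DataFrame:
    """Per-subject component flags, count, and MS status.

    Returns a DataFrame aligned to ``cohort`` with boolean columns
    ``central_obesity, high_bp, high_tg, low_hdl, ifg``, integer
    ``count``, and boolean ``ms`` (count >= 3). Flag semantics: waist >=
    stratum p90; SBP >= its stratum p95 OR DBP >= its stratum p95; TG >=
    tg_cut; HDL <= hdl_cut; glucose >= glucose_cut — all inclusive.
    """
    needed = ["sex", "age", "height_cm", "wc_cm", "sbp", "dbp", "tg", "hdl", "glucose"]
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise InputError(f"cohort missing columns: {missing_cols}")
    na_fields = [c for c in needed if cohort[c].isna().any()]
    if na_fields:
        raise InputError(f"missing measurements in fields: {na_fields}")

    wc_cut = np.empty(len(cohort))
    sbp_cut = np.empty(len(cohort))
    dbp_cut = np.empty(len(cohort))
    for i, row in enumerate(cohort.itertuples()):
        grp = thresholds.age_group_of(row.age)
        key = (row.sex, grp)
        if key not in thresholds.wc_p90:
            sid = getattr(row, "id", row.Index)
            raise InputError(
                f"subject {sid!r}: stratum (sex={row.sex}, age_group={grp}) "
                "not covered by thresholds"
            )
        wc_cut[i] = thresholds.wc_p90[key]
        band = thresholds.height_band_of(row.sex, grp, row.height_cm)
        band = min(band, thresholds.n_height_bands - 1)
        sbp_cut[i] = thresholds.sbp_p95[(row.sex, grp, band)]
        dbp_cut[i] = thresholds.dbp_p95[(row.sex, grp, band)]

    out = pd.DataFrame(index=cohort.index)
    out["central_obesity"] = cohort["wc_cm"].to_numpy() >= wc_cut
    out["high_bp"] = (cohort["sbp"].to_numpy() >= sbp_cut) | (
        cohort["dbp"].to_numpy() >= dbp_cut
    )
    out["high_tg"] = cohort["tg"] >= thresholds.tg_cut
    out["low_hdl"] = cohort["hdl"] <= thresholds.hdl_cut
    out["ifg"] = cohort["glucose"] >= thresholds.glucose_cut
    out["count"] = out[COMPONENT_FLAGS].sum(axis=1).astype(int)
    out["ms"] = out["count"] >= 3
    return out


def select_reference_population(
    cohort: pd.DataFrame, profiles: pd.DataFrame, weight: pd.DataFrame
) -> pd.DataFrame:
    """Normal-metabolic reference subset: normal weight AND zero components.

    ``profiles`` and ``weight`` must be index-aligned to ``cohort``. Order
    is preserved. An empty subset is an error because reference
    percentiles would be undefined.
    """
    if not (cohort.index.equals(profiles.index) and cohort.index.equals(weight.index)):
        raise InputError("profiles/weight must be index-aligned to the cohort")
    mask = (weight["category"] == "normal") & (profiles["count"] == 0)
    subset = cohort.loc[mask]
    if len(subset) == 0:
        raise EmptyStratumError(
            "reference population is empty (no normal-weight, zero-component subjects)"
        )
    return subset
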