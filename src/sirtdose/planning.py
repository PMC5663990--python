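"""Prescribed-activity planning.

All partition doses are linear in the administered activity A0, so the
threshold-constrained prescription has a closed form: A0 is the largest
activity for which the mean normal-liver dose and the lung dose stay at or
below their limits, i.e. the minimum of the two single-constraint
inversions.  The tumor-dose threshold is a report-only check (a plan is
still returned when it is missed).  The empirical body-surface-area (BSA)
prescription is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosimetry import (
    DOSE_FACTOR,
    mean_normal_liver_dose,
    mean_tumor_dose,
    pm_doses,
    tm_doses,
)
from .errors import InfeasiblePlanError, InvalidInputError
from .uptake import (
    ROLE_NL,
    ROLE_TUMOR,
    PartitionTable,
    lung_shunt_fraction,
    tn_ratio,
)

__all__ = [
    "Thresholds",
    "PatientBody",
    "PlanResult",
    "plan_activity",
    "bsa_activity",
    "compare_models",
]


@dataclass(frozen=True)
class Thresholds:
    """Dose limits defining the planning constraint set (Gy).

    ``d_tumor_min`` is a target to report against, not a constraint.  An
    optional ``d_tumor_max`` cap on the mean tumor dose can be supplied as a
    third constraint (off by default).
    """

    d_lung_max: float
    d_normal_liver_max: float
    d_tumor_min: float
    name: str = "custom"
    d_tumor_max: float | None = None

    def __post_init__(self):
        if min(self.d_lung_max, self.d_normal_liver_max, self.d_tumor_min) <= 0:
            raise InvalidInputError("all thresholds must be > 0")

    @classmethod
    def t1(cls) -> "Thresholds":
        """Package-insert limits: lung 25 Gy, normal liver 70 Gy, tumor > 100 Gy."""
        return cls(25.0, 70.0, 100.0, name="T1")

    @classmethod
    def t2(cls) -> "Thresholds":
        """Conservative limits: lung 25 Gy, normal liver 40 Gy, tumor > 100 Gy."""
        return cls(25.0, 40.0, 100.0, name="T2")

    @classmethod
    def from_tag(cls, tag: str) -> "Thresholds":
        tag = tag.strip().lower()
        if tag == "t1":
            return cls.t1()
        if tag == "t2":
            return cls.t2()
        raise InvalidInputError(f"unknown thresholds tag {tag!r} (use t1 or t2)")


@dataclass(frozen=True)
class PatientBody:
    """Scalar patient data for the BSA prescription (Eqs. in m, kg, mL)."""

    height_m: float
    weight_kg: float
    tumor_volume_mL: float = 0.0
    total_volume_mL: float = 1.0  # liver + tumor volume

    def __post_init__(self):
        if self.height_m <= 0 or self.weight_kg <= 0:
            raise InvalidInputError("height and weight must be > 0")
        if self.total_volume_mL <= 0:
            raise InvalidInputError("total liver volume must be > 0")
        if not (0.0 <= self.tumor_volume_mL <= self.total_volume_mL):
            raise InvalidInputError("tumor volume must lie in [0, total volume]")

    @property
    def bsa_m2(self) -> float:
        """DuBois body surface area 0.20247 * h^0.725 * w^0.425 (m^2)."""
        return 0.20247 * self.height_m**0.725 * self.weight_kg**0.425


@dataclass
class PlanResult:
    """Outcome of one activity prescription."""

    model: str  # "PM" | "TM" | "BSA"
    a0_GBq: float
    limiting_constraint: str  # "normal_liver" | "lung" | "tumor_cap" | "bsa_formula"
    thresholds: Thresholds | None = None
    doses: dict = field(default_factory=dict)  # summary doses in Gy
    table: PartitionTable | None = None  # TM: full per-partition table
    tumor_dose_ok: dict = field(default_factory=dict)  # per-tumor target flags

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "A0_GBq": self.a0_GBq,
            "limiting_constraint": self.limiting_constraint,
            "thresholds": None
            if self.thresholds is None
            else {
                "name": self.thresholds.name,
                "D_L_max_Gy": self.thresholds.d_lung_max,
                "D_NL_max_Gy": self.thresholds.d_normal_liver_max,
                "D_T_min_Gy": self.thresholds.d_tumor_min,
            },
            "doses_Gy": self.doses,
            "tumor_dose_target_met": self.tumor_dose_ok,
        }


def bsa_activity(body: PatientBody) -> float:
    """Empirical BSA prescription: A [GBq] = BSA - 0.2 + V_T / V_total."""
    return body.bsa_m2 - 0.2 + body.tumor_volume_mL / body.total_volume_mL


def _aggregates(table: PartitionTable):
    lung = table.lung
    if lung is None:
        raise InvalidInputError("planning needs a lung row (even with zero counts)")
    m_lung = float(lung["mass_kg"])
    nl = table.rows(ROLE_NL)
    tum = table.rows(ROLE_TUMOR)
    if nl.empty or float(nl["mass_kg"].sum()) <= 0:
        raise InvalidInputError("no normal-liver partition with positive mass")
    return m_lung, nl, tum


def plan_activity(
    model: str,
    table: PartitionTable,
    thresholds: Thresholds,
    mass_weighted_mean: bool = True,
) -> PlanResult:
    """Threshold-constrained activity for the PM or TM.

    The returned A0 puts the binding constraint exactly at its limit and
    keeps the other constraint satisfied; the per-partition doses are
    recomputed at that A0.
    """
    model = model.upper()
    if model not in ("PM", "TM"):
        raise InvalidInputError("model must be 'PM' or 'TM'")
    L = lung_shunt_fraction(table)
    if L >= 1.0:
        raise InfeasiblePlanError("all activity shunts to the lung (L = 1)")
    m_lung, nl, tum = _aggregates(table)

    a0_lung = (
        np.inf
        if L == 0
        else thresholds.d_lung_max * m_lung / (DOSE_FACTOR * L)
    )

    if model == "PM":
        m_nl = float(nl["mass_kg"].sum())
        m_t = float(tum["mass_kg"].sum())
        tn = tn_ratio(table) if not tum.empty else 0.0
        a0_nl = (
            thresholds.d_normal_liver_max
            * (m_nl + tn * m_t)
            / (DOSE_FACTOR * (1.0 - L))
        )
        candidates = {"normal_liver": a0_nl, "lung": a0_lung}
        if thresholds.d_tumor_max is not None and tn > 0:
            d_t_per_a0 = tn * DOSE_FACTOR * (1.0 - L) / (m_nl + tn * m_t)
            candidates["tumor_cap"] = thresholds.d_tumor_max / d_t_per_a0
        limiting = min(candidates, key=candidates.get)
        a0 = candidates[limiting]
        d_l, d_nl, d_t = pm_doses(a0, L, tn, m_lung, m_nl, m_t)
        doses = {"lung": d_l, "normal_liver": d_nl, "tumor": d_t if not tum.empty else None}
        flags = {
            str(r["partition"]): bool(d_t > thresholds.d_tumor_min)
            for _, r in tum.iterrows()
        }
        return PlanResult(
            model="PM",
            a0_GBq=float(a0),
            limiting_constraint=limiting,
            thresholds=thresholds,
            doses=doses,
            tumor_dose_ok=flags,
        )

    # TM: invert the mean normal-liver dose over the territory partitions
    if float(table.liver_side()["counts"].sum()) <= 0:
        raise InvalidInputError("zero liver-side counts; TM undefined")
    probe = tm_doses(1.0, L, table)  # doses per unit A0 (linearity)
    d_nl_per_a0 = mean_normal_liver_dose(probe, mass_weighted=mass_weighted_mean)
    if d_nl_per_a0 <= 0:
        raise InfeasiblePlanError("normal liver receives no activity; cannot bind")
    candidates = {
        "normal_liver": thresholds.d_normal_liver_max / d_nl_per_a0,
        "lung": a0_lung,
    }
    if thresholds.d_tumor_max is not None and not tum.empty:
        d_t_per_a0 = mean_tumor_dose(probe)
        if d_t_per_a0 > 0:
            candidates["tumor_cap"] = thresholds.d_tumor_max / d_t_per_a0
    limiting = min(candidates, key=candidates.get)
    a0 = float(candidates[limiting])
    final = tm_doses(a0, L, table)
    lung_dose = float(final.lung["dose_Gy"]) if final.lung is not None else None
    doses = {
        "lung": lung_dose,
        "normal_liver": mean_normal_liver_dose(final, mass_weighted=mass_weighted_mean),
        "tumor": mean_tumor_dose(final) if not tum.empty else None,
    }
    flags = {
        str(r["partition"]): bool(float(r["dose_Gy"]) > thresholds.d_tumor_min)
        for _, r in final.rows(ROLE_TUMOR).iterrows()
    }
    return PlanResult(
        model="TM",
        a0_GBq=a0,
        limiting_constraint=limiting,
        thresholds=thresholds,
        doses=doses,
        table=final,
        tumor_dose_ok=flags,
    )


def compare_models(
    pm_table: PartitionTable,
    tm_table: PartitionTable,
    thresholds: Thresholds,
    body: PatientBody | None = None,
) -> pd.DataFrame:
    """Side-by-side PM / TM / BSA prescription report.

    ``pm_table`` is typically built with a 0-mm margin (classical model) and
    ``tm_table`` with the 11-mm exclusion.  The BSA column reports only an
    activity (the method predicts no doses).
    """
    pm = plan_activity("PM", pm_table, thresholds)
    tm = plan_activity("TM", tm_table, thresholds)
    cols: dict[str, dict] = {}
    if body is not None:
        cols["BSA"] = {"A0_GBq": bsa_activity(body)}
    for plan in (pm, tm):
        cols[plan.model] = {
            "A0_GBq": plan.a0_GBq,
            "D_L_Gy": plan.doses.get("lung"),
            "D_NL_Gy": plan.doses.get("normal_liver"),
            "D_T_Gy": plan.doses.get("tumor"),
            "limiting": plan.limiting_constraint,
            "tumor_target_met": all(plan.tumor_dose_ok.values())
            if plan.tumor_dose_ok
            else None,
        }
    index = ["A0_GBq", "D_L_Gy", "D_NL_Gy", "D_T_Gy", "limiting", "tumor_target_met"]
    return pd.DataFrame({k: pd.Series(v) for k, v in cols.items()}).reindex(index)
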