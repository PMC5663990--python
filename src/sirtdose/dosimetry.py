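"""Closed-form Y-90 absorbed-dose computation.

The MIRD-style mean absorbed dose for a partition holding activity A (GBq)
in mass m (kg) is D = k * A / m, where the dose factor

    k = <E> * T_half / ln 2 = 49.38 Gy kg / GBq

follows from the mean energy per nuclear transition <E> = 0.9267 MeV and the
Y-90 half-life of 64.04 h (local energy deposition, complete decay).

Two models are provided on top of this constant:

* the classical partition model (PM) with lung / normal liver / tumor
  compartments, parameterized by the lung shunt fraction L and the
  tumor-to-normal uptake ratio T/N; and
* the territorial model (TM), which generalizes the PM to an arbitrary set
  of liver-side partitions (one per arterial territory and per tumor) via
  the fractional uptake f_i = A_i / sum_j A_j, giving
  D_i = k * A0 * (1 - L) * f_i / m_i.

For a two-partition set {normal liver, tumor} the TM reduces algebraically
to the PM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .uptake import (
    ROLE_LUNG,
    ROLE_MARGIN,
    ROLE_NL,
    ROLE_TUMOR,
    PartitionTable,
    lung_shunt_fraction,
)

__all__ = [
    "MEAN_ENERGY_MEV",
    "HALF_LIFE_H",
    "DOSE_FACTOR",
    "MARGIN_DOSE_SENTINEL",
    "dose_factor",
    "dose_simple",
    "pm_doses",
    "fractional_uptake",
    "tm_doses",
    "mean_normal_liver_dose",
    "mean_tumor_dose",
    "render_dose_map",
]

MEAN_ENERGY_MEV = 0.9267
HALF_LIFE_H = 64.04

_J_PER_MEV = 1.602176634e-13
_DECAYS_PER_S_PER_GBQ = 1.0e9


def dose_factor(
    mean_energy_MeV: float = MEAN_ENERGY_MEV, half_life_h: float = HALF_LIFE_H
) -> float:
    """Dose factor <E> * T_half / ln 2 in Gy kg / GBq (49.38 for Y-90)."""
    energy_J = mean_energy_MeV * _J_PER_MEV
    half_life_s = half_life_h * 3600.0
    return energy_J * _DECAYS_PER_S_PER_GBQ * half_life_s / np.log(2.0)


DOSE_FACTOR = dose_factor()

# rendered in dose maps for the margin-excluded shell (distinct from the 0 Gy
# background; the shell's counts enter no reported dose)
MARGIN_DOSE_SENTINEL = -1.0


def dose_simple(activity_GBq: float, mass_kg: float) -> float:
    """Mean absorbed dose D = k * A / m for one partition."""
    if mass_kg <= 0:
        raise InvalidInputError("mass must be > 0")
    if activity_GBq < 0:
        raise InvalidInputError("activity must be >= 0")
    return DOSE_FACTOR * activity_GBq / mass_kg


def pm_doses(
    a0_GBq: float,
    lung_shunt: float,
    tn: float,
    m_lung_kg: float,
    m_nl_kg: float,
    m_tumor_kg: float,
) -> tuple[float, float, float]:
    """Classical partition-model doses (D_lung, D_normal_liver, D_tumor).

    D_L  = k A0 L / m_L
    D_NL = k A0 (1-L) / (m_NL + T/N * m_T)
    D_T  = T/N * D_NL
    """
    if not (0.0 <= lung_shunt <= 1.0):
        raise InvalidInputError("lung shunt must lie in [0, 1]")
    if tn < 0:
        raise InvalidInputError("T/N must be >= 0")
    if min(m_lung_kg, m_nl_kg) <= 0 or (m_tumor_kg < 0):
        raise InvalidInputError("masses must be positive")
    d_lung = DOSE_FACTOR * a0_GBq * lung_shunt / m_lung_kg
    d_nl = DOSE_FACTOR * a0_GBq * (1.0 - lung_shunt) / (m_nl_kg + tn * m_tumor_kg)
    d_tumor = tn * d_nl
    return d_lung, d_nl, d_tumor


def fractional_uptake(activities, i: int | None = None):
    """Fractional uptake f_i = A_i / sum_j A_j over a partition set.

    With ``i`` given returns the scalar f_i; otherwise the full vector.
    Partitions with zero activity get f = 0 (the well-defined limit of
    1 / (1 + A_rest / A_i)).
    """
    a = np.asarray(activities, dtype=float)
    if (a < 0).any():
        raise InvalidInputError("activities must be >= 0")
    total = a.sum()
    if total <= 0:
        raise InvalidInputError("total activity must be > 0")
    f = np.where(a > 0, a / total, 0.0)
    return float(f[i]) if i is not None else f


def tm_doses(a0_GBq: float, lung_shunt: float, table: PartitionTable) -> PartitionTable:
    """Territorial-model doses for every partition row.

    Liver-side partitions (territories, tumors, margin) receive
    D_i = k * A0 * (1 - L) * f_i / m_i with f_i from their count shares;
    the lung receives D_L = k * A0 * L / m_L.  Returns a new table with
    ``activity_GBq``, ``f``, and ``dose_Gy`` filled.
    """
    if not (0.0 <= lung_shunt < 1.0):
        raise InvalidInputError("lung shunt must lie in [0, 1)")
    out = table.copy()
    df = out.df
    liver = df["role"].isin((ROLE_NL, ROLE_TUMOR, ROLE_MARGIN))
    c = df.loc[liver, "counts"].to_numpy(dtype=float)
    if c.sum() <= 0:
        raise InvalidInputError("liver-side counts are zero")
    if ((c > 0) & (df.loc[liver, "mass_kg"].to_numpy(dtype=float) <= 0)).any():
        raise InvalidInputError("a liver-side partition has counts but no mass")
    f = fractional_uptake(c)
    act = a0_GBq * (1.0 - lung_shunt) * f
    m = df.loc[liver, "mass_kg"].to_numpy(dtype=float)
    dose = np.zeros_like(act)
    nz = act > 0
    dose[nz] = DOSE_FACTOR * act[nz] / m[nz]
    df.loc[liver, "f"] = f
    df.loc[liver, "activity_GBq"] = act
    df.loc[liver, "dose_Gy"] = dose

    lung_rows = df["role"] == ROLE_LUNG
    if lung_rows.any():
        m_l = float(df.loc[lung_rows, "mass_kg"].iloc[0])
        if m_l <= 0:
            raise InvalidInputError("lung mass must be > 0")
        df.loc[lung_rows, "activity_GBq"] = a0_GBq * lung_shunt
        df.loc[lung_rows, "f"] = np.nan
        df.loc[lung_rows, "dose_Gy"] = DOSE_FACTOR * a0_GBq * lung_shunt / m_l
    return out


def mean_normal_liver_dose(table: PartitionTable, mass_weighted: bool = True) -> float:
    """Mean dose over the normal-liver territory rows.

    Mass-weighted by default (equivalent to the pooled normal-liver dose);
    the margin partition never contributes.
    """
    nl = table.rows(ROLE_NL)
    if nl.empty:
        raise InvalidInputError("no normal-liver territory rows")
    d = nl["dose_Gy"].to_numpy(dtype=float)
    if np.isnan(d).any():
        raise InvalidInputError("doses not yet computed")
    if mass_weighted:
        w = nl["mass_kg"].to_numpy(dtype=float)
        return float(np.average(d, weights=w))
    return float(d.mean())


def mean_tumor_dose(table: PartitionTable, mass_weighted: bool = True) -> float:
    tum = table.rows(ROLE_TUMOR)
    if tum.empty:
        raise InvalidInputError("no tumor rows")
    d = tum["dose_Gy"].to_numpy(dtype=float)
    if mass_weighted:
        return float(np.average(d, weights=tum["mass_kg"].to_numpy(dtype=float)))
    return float(d.mean())


def render_dose_map(
    table: PartitionTable, margin_sentinel: float = MARGIN_DOSE_SENTINEL
) -> np.ndarray:
    """Piecewise-constant dose volume from a table with computed doses.

    Every voxel of a partition region takes the partition's dose; the
    excluded-margin shell is rendered with ``margin_sentinel`` so it stays
    visually distinct from the 0 Gy background.
    """
    if table.region_labels is None:
        raise InvalidInputError("table carries no region label volume")
    df = table.df
    if df["dose_Gy"].isna().all():
        raise InvalidInputError("doses not yet computed")
    lut = np.zeros(int(df["region_id"].max()) + 1, dtype=float)
    for _, row in df.iterrows():
        val = row["dose_Gy"]
        if row["role"] == ROLE_MARGIN:
            val = margin_sentinel
        lut[int(row["region_id"])] = 0.0 if pd.isna(val) else float(val)
    return lut[table.region_labels]
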