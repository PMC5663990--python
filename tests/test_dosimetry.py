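"""Dose factor, PM/TM formulas, fractional uptake, dose maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sirtdose as sd
from sirtdose.dosimetry import (
    DOSE_FACTOR,
    MARGIN_DOSE_SENTINEL,
    dose_factor,
    dose_simple,
    fractional_uptake,
    mean_normal_liver_dose,
    pm_doses,
    render_dose_map,
    tm_doses,
)
from sirtdose.errors import InvalidInputError
from sirtdose.uptake import PartitionTable


def test_dose_factor_matches_y90_constant():
    """<E>=0.9267 MeV with T_half=64.04 h gives 49.38 Gy kg/GBq."""
    assert round(dose_factor(), 2) == 49.38
    assert DOSE_FACTOR == dose_factor()


@pytest.mark.parametrize(
    "a, m, expected",
    [
        (1.0, 1.0, DOSE_FACTOR),  # unit activity in unit mass
        (0.0, 1.0, 0.0),
        (2.0, DOSE_FACTOR, 2.0),
    ],
)
def test_dose_simple(a, m, expected):
    assert dose_simple(a, m) == pytest.approx(expected, rel=1e-12)


def test_dose_simple_rejects_nonpositive_mass():
    with pytest.raises(InvalidInputError):
        dose_simple(1.0, 0.0)


def test_pm_doses_hand_computed():
    """Independent arithmetic evaluation of the three PM dose formulas."""
    a0, L, tn, m_l, m_nl, m_t = 1.0, 0.1, 4.0, 1.0, 1.5, 0.25
    k = dose_factor()
    d_l, d_nl, d_t = pm_doses(a0, L, tn, m_l, m_nl, m_t)
    assert d_l == pytest.approx(k * 1.0 * 0.1 / 1.0, rel=1e-12)
    assert d_nl == pytest.approx(k * 1.0 * 0.9 / (1.5 + 4.0 * 0.25), rel=1e-12)
    assert d_t == pytest.approx(4.0 * d_nl, rel=1e-12)


def test_pm_tumor_dose_is_tn_times_nl():
    d_l, d_nl, d_t = pm_doses(2.5, 0.07, 3.3, 0.8, 1.2, 0.4)
    assert d_t / d_nl == pytest.approx(3.3, rel=1e-12)


def test_pm_doses_with_unit_tn_pool_masses():
    _, d_nl, d_t = pm_doses(1.0, 0.0, 1.0, 1.0, 1.5, 0.5)
    assert d_nl == pytest.approx(DOSE_FACTOR / 2.0, rel=1e-12)
    assert d_t == pytest.approx(d_nl)


def test_fractional_uptake_basic():
    assert fractional_uptake([5.0], 0) == 1.0
    assert fractional_uptake([2.0, 2.0], 0) == 0.5
    assert fractional_uptake([0.0, 3.0], 0) == 0.0  # zero-activity limit


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=1, max_size=12).filter(
        lambda a: sum(a) > 0
    )
)
def test_fractional_uptake_normalizes(activities):
    f = fractional_uptake(activities)
    assert np.all(f >= 0) and np.all(f <= 1)
    assert np.sum(f) == pytest.approx(1.0, rel=1e-9)


def _two_partition_table(rng):
    c_nl, c_t = rng.uniform(1e3, 1e6, size=2)
    m_nl, m_t = rng.uniform(0.2, 2.5), rng.uniform(0.01, 0.8)
    m_l = rng.uniform(0.5, 1.5)
    c_l = rng.uniform(0, 0.3) * (c_nl + c_t)
    return PartitionTable.from_rows(
        [
            {"partition": "lung", "role": "lung", "counts": c_l, "mass_kg": m_l},
            {
                "partition": "territory_01",
                "role": "normal_liver_territory",
                "counts": c_nl,
                "mass_kg": m_nl,
            },
            {"partition": "tumor_01", "role": "tumor", "counts": c_t, "mass_kg": m_t},
        ]
    )


def test_tm_reduces_to_pm_for_two_partitions(rng):
    """With one NL and one tumor partition the generalized model must
    reproduce the classical formulas exactly (algebraic identity)."""
    for _ in range(200):
        table = _two_partition_table(rng)
        L = sd.lung_shunt_fraction(table)
        tn = sd.tn_ratio(table)
        a0 = rng.uniform(0.5, 6.0)
        d_l, d_nl, d_t = pm_doses(
            a0,
            L,
            tn,
            float(table.lung["mass_kg"]),
            float(table.rows("normal_liver_territory")["mass_kg"].sum()),
            float(table.rows("tumor")["mass_kg"].sum()),
        )
        dosed = tm_doses(a0, L, table)
        got_nl = float(dosed.rows("normal_liver_territory")["dose_Gy"].iloc[0])
        got_t = float(dosed.rows("tumor")["dose_Gy"].iloc[0])
        got_l = float(dosed.lung["dose_Gy"])
        assert got_nl == pytest.approx(d_nl, rel=1e-10)
        assert got_t == pytest.approx(d_t, rel=1e-10)
        assert got_l == pytest.approx(d_l, rel=1e-10)


def test_tm_energy_conservation(rng):
    """Sum of dose*mass over liver-side partitions equals k*A0*(1-L)."""
    table = _two_partition_table(rng)
    L = sd.lung_shunt_fraction(table)
    dosed = tm_doses(3.0, L, table)
    liver = dosed.liver_side()
    lhs = float((liver["dose_Gy"] * liver["mass_kg"]).sum())
    assert lhs == pytest.approx(DOSE_FACTOR * 3.0 * (1 - L), rel=1e-12)


def test_tm_doses_linear_in_a0(rng):
    table = _two_partition_table(rng)
    L = sd.lung_shunt_fraction(table)
    d1 = tm_doses(1.0, L, table).df["dose_Gy"].to_numpy(float)
    d2 = tm_doses(2.0, L, table).df["dose_Gy"].to_numpy(float)
    np.testing.assert_allclose(d2, 2 * d1, rtol=1e-12)


def test_lung_dose_increases_liver_doses_decrease_with_shunt(rng):
    table = _two_partition_table(rng)
    lo = tm_doses(1.0, 0.05, table)
    hi = tm_doses(1.0, 0.30, table)
    assert float(hi.lung["dose_Gy"]) > float(lo.lung["dose_Gy"])
    assert (
        hi.liver_side()["dose_Gy"].to_numpy(float)
        < lo.liver_side()["dose_Gy"].to_numpy(float)
    ).all()


def test_zero_count_partition_gets_zero_dose():
    table = PartitionTable.from_rows(
        [
            {"partition": "lung", "role": "lung", "counts": 0.0, "mass_kg": 1.0},
            {
                "partition": "territory_01",
                "role": "normal_liver_territory",
                "counts": 100.0,
                "mass_kg": 1.0,
            },
            {
                "partition": "territory_02",
                "role": "normal_liver_territory",
                "counts": 0.0,
                "mass_kg": 0.5,
            },
        ]
    )
    dosed = tm_doses(1.0, 0.0, table)
    nl = dosed.rows("normal_liver_territory")
    assert float(nl[nl["partition"] == "territory_02"]["dose_Gy"].iloc[0]) == 0.0


def test_mean_normal_liver_dose_weighting():
    table = PartitionTable.from_rows(
        [
            {
                "partition": "territory_01",
                "role": "normal_liver_territory",
                "counts": 10.0,
                "mass_kg": 1.0,
                "dose_Gy": 20.0,
            },
            {
                "partition": "territory_02",
                "role": "normal_liver_territory",
                "counts": 10.0,
                "mass_kg": 1.0,
                "dose_Gy": 60.0,
            },
        ]
    )
    assert mean_normal_liver_dose(table) == pytest.approx(40.0)
    assert mean_normal_liver_dose(table, mass_weighted=False) == pytest.approx(40.0)


def test_mass_weighted_mean_equals_pooled_dose(rng):
    """The mass-weighted mean over NL territories equals the single pooled
    normal-liver dose k*A0*(1-L)*f_NL,tot/m_NL,tot."""
    rows = [{"partition": "lung", "role": "lung", "counts": 50.0, "mass_kg": 1.0}]
    for i in range(4):
        rows.append(
            {
                "partition": f"territory_{i + 1:02d}",
                "role": "normal_liver_territory",
                "counts": rng.uniform(10, 1000),
                "mass_kg": rng.uniform(0.1, 0.8),
            }
        )
    table = PartitionTable.from_rows(rows)
    L = sd.lung_shunt_fraction(table)
    dosed = tm_doses(2.0, L, table)
    nl = dosed.rows("normal_liver_territory")
    f_tot = float(nl["f"].sum())
    m_tot = float(nl["mass_kg"].sum())
    pooled = DOSE_FACTOR * 2.0 * (1 - L) * f_tot / m_tot
    assert mean_normal_liver_dose(dosed) == pytest.approx(pooled, rel=1e-12)


def test_render_dose_map_round_trip(default_bundle, noiseless_counts):
    """Voxel dose map is piecewise constant and reproduces the table."""
    from conftest import table_from

    table = table_from(default_bundle, noiseless_counts, margin_mm=11.0)
    L = sd.lung_shunt_fraction(table)
    dosed = tm_doses(2.0, L, table)
    dmap = render_dose_map(dosed)
    assert dmap[dosed.region_labels == 0].max() == 0.0
    for _, row in dosed.df.iterrows():
        region = dosed.region_labels == row["region_id"]
        vals = np.unique(dmap[region])
        assert len(vals) == 1
        expected = (
            MARGIN_DOSE_SENTINEL
            if row["role"] == "excluded_margin"
            else float(row["dose_Gy"])
        )
        assert vals[0] == pytest.approx(expected)
    # margin sentinel distinct from background
    margin = dosed.rows("excluded_margin")
    assert not margin.empty
    assert MARGIN_DOSE_SENTINEL != 0.0
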