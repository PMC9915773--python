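"""Composites, Pearson matrices, Fisher transform, and the Meng z-test."""

import math

import numpy as np
import pandas as pd
import pytest

from patchforage.corrstats import (
    VARIABLES,
    comparison_table,
    composite_scores,
    fisher_z,
    meng_z_test,
    pearson_matrix,
)


def _measures_frame(n_subjects=6, delays=(0.0, 6.0, 12.0, 18.0, 24.0), constant=3.0):
    rows = []
    for i in range(n_subjects):
        for d in delays:
            rows.append(
                {
                    "subject_id": f"S{i}",
                    "sex": "M" if i % 2 == 0 else "F",
                    "cod_s": d,
                    "water_rate": constant,
                    "n_patch_changes": constant,
                    "time_in_patch": constant,
                    "rejection_volume": 100.0,
                    "pct_time_deviation": math.nan if d == 0 else constant,
                    "pct_volume_deviation": constant,
                }
            )
    return pd.DataFrame(rows)


def _fits_frame(n_subjects=6):
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n_subjects)],
            "sex": ["M" if i % 2 == 0 else "F" for i in range(n_subjects)],
            "b": 0.8,
            "k": np.linspace(0.05, 0.5, n_subjects),
            "auc": np.linspace(0.8, 0.3, n_subjects),
            "sse": 0.0,
            "converged": True,
        }
    )


def test_composite_sums_across_delays():
    comp = composite_scores(_measures_frame(), _fits_frame())
    assert len(comp) == 6
    row = comp.set_index("subject_id").loc["S0"]
    assert row["n_patch_changes"] == pytest.approx(15.0)  # 5 delays x 3.0
    assert row["volume_deviation"] == pytest.approx(15.0)
    # time deviation is undefined at COD 0, so it sums the four positive delays
    assert row["time_deviation"] == pytest.approx(12.0)
    assert row["k"] == pytest.approx(0.05)


def test_composite_drops_subject_with_missing_delay(caplog):
    m = _measures_frame()
    m.loc[(m.subject_id == "S1") & (m.cod_s == 12.0), "water_rate"] = math.nan
    with caplog.at_level("WARNING"):
        comp = composite_scores(m, _fits_frame())
    assert "S1" not in set(comp.subject_id)
    assert len(comp) == 5
    assert any("S1" in rec.message for rec in caplog.records)


def test_pearson_matrix_identities(rng):
    n = 40
    x = rng.standard_normal(n)
    table = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "sex": "M",
            "b": 0.8,
            "k": x,
            "auc": -x,
            "volume_deviation": rng.standard_normal(n),
            "time_deviation": rng.standard_normal(n),
            "time_in_patch": rng.standard_normal(n),
            "n_patch_changes": rng.standard_normal(n),
            "water_rate": rng.standard_normal(n),
        }
    )
    r, p = pearson_matrix(table, by_sex=True)["M"]
    assert np.allclose(np.diag(r.to_numpy(dtype=float)), 1.0)
    assert r.loc["k", "AUC"] == pytest.approx(-1.0)
    assert np.allclose(r.to_numpy(dtype=float), r.to_numpy(dtype=float).T)


def test_pearson_matrix_agrees_with_two_pass_covariance(rng):
    """Textbook oracle: r_ij = cov(x_i, x_j) / (s_i s_j) with explicit
    two-pass mean/deviation sums."""
    n = 60
    data = {col: rng.standard_normal(n) for col in VARIABLES}
    table = pd.DataFrame(data)
    table["subject_id"] = [f"S{i}" for i in range(n)]
    table["sex"] = "F"
    table["b"] = 0.8
    r, _ = pearson_matrix(table, by_sex=True)["F"]
    for ci, li in VARIABLES.items():
        for cj, lj in VARIABLES.items():
            x, y = data[ci], data[cj]
            dx, dy = x - x.mean(), y - y.mean()
            oracle = (dx @ dy) / math.sqrt((dx @ dx) * (dy @ dy))
            assert r.loc[li, lj] == pytest.approx(oracle, abs=1e-12)


def test_pearson_matrix_zero_variance_is_missing(rng):
    n = 20
    table = pd.DataFrame({col: rng.standard_normal(n) for col in VARIABLES})
    table["subject_id"] = [f"S{i}" for i in range(n)]
    table["sex"] = "M"
    table["water_rate"] = 5.0
    r, _ = pearson_matrix(table, by_sex=True)["M"]
    assert math.isnan(r.loc["WR", "k"])


def test_fisher_z_values_and_symmetry():
    assert fisher_z(0.0) == 0.0
    assert fisher_z(0.76) == pytest.approx(0.9962, abs=1e-4)
    for r in (0.1, 0.5, 0.9):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r))
    with pytest.raises(ValueError):
        fisher_z(1.0)


def test_meng_equal_correlations_give_zero():
    z, p = meng_z_test(0.5, 0.5, 0.3, 100)
    assert z == 0.0
    assert p == pytest.approx(1.0)


def test_meng_antisymmetry():
    z1, p1 = meng_z_test(0.6, 0.3, 0.2, 100)
    z2, p2 = meng_z_test(0.3, 0.6, 0.2, 100)
    assert z1 == pytest.approx(-z2)
    assert p1 == pytest.approx(p2)


def test_meng_domain_errors():
    with pytest.raises(ValueError):
        meng_z_test(0.5, 0.3, 1.0, 100)
    with pytest.raises(ValueError):
        meng_z_test(0.5, 0.3, 0.2, 3)


def test_meng_z_matches_monte_carlo_oracle(rng):
    """Independent oracle: the z for (0.6, 0.3, 0.2, N=100) should match the
    population Fisher-z difference scaled by the *simulated* sampling SD of
    that difference, and both routes must agree on rejecting at alpha=0.05."""
    z, p = meng_z_test(0.6, 0.3, 0.2, 100)
    R = np.array([[1, 0.6, 0.3], [0.6, 1, 0.2], [0.3, 0.2, 1]])
    L = np.linalg.cholesky(R)
    X = rng.standard_normal((10_000, 100, 3)) @ L.T
    Xc = X - X.mean(axis=1, keepdims=True)
    Xn = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)
    r01 = np.einsum("rn,rn->r", Xn[:, :, 0], Xn[:, :, 1])
    r02 = np.einsum("rn,rn->r", Xn[:, :, 0], Xn[:, :, 2])
    sd = (np.arctanh(r01) - np.arctanh(r02)).std()
    z_mc = (fisher_z(0.6) - fisher_z(0.3)) / sd
    assert z == pytest.approx(z_mc, rel=0.10)
    assert (abs(z) > 1.96) == (abs(z_mc) > 1.96)
    assert p < 0.05


def test_comparison_table_layout_and_antisymmetry(rng):
    n = 50
    table = pd.DataFrame({col: rng.standard_normal(n) for col in VARIABLES})
    table["subject_id"] = [f"S{i}" for i in range(n)]
    table["sex"] = np.where(np.arange(n) % 2 == 0, "M", "F")
    table["b"] = 0.8
    comp = comparison_table(table)
    # k/AUC x VD/TD x TIP/PC/WR contrasts for each sex
    assert comp.groupby("sex").size().eq(12).all()
    assert set(comp.common_variable) == {"TIP", "PC", "WR"}
    assert set(comp.variable_1) == {"k", "AUC"}
    assert set(comp.variable_2) == {"VD", "TD"}


def test_comparison_power_grows_with_sample_size(rng):
    """When time deviation is built from patch changes plus noise, the
    patch-changes correlation contrast sharpens as N grows."""

    def make_table(n, rng):
        pc = rng.standard_normal(n)
        table = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "sex": "M",
                "b": 0.8,
                "k": rng.standard_normal(n),
                "auc": rng.standard_normal(n),
                "volume_deviation": rng.standard_normal(n),
                "time_deviation": pc + 0.5 * rng.standard_normal(n),
                "time_in_patch": rng.standard_normal(n),
                "n_patch_changes": pc,
                "water_rate": rng.standard_normal(n),
            }
        )
        return table

    def pc_td_z(n):
        comp = comparison_table(make_table(n, rng))
        row = comp[
            (comp.common_variable == "PC")
            & (comp.variable_1 == "k")
            & (comp.variable_2 == "TD")
        ].iloc[0]
        return abs(row.z)

    assert pc_td_z(800) > pc_td_z(80)
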