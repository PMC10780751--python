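"""Joint ANOVA and the multiplicative interaction decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metstab as ms
from metstab.ammi import AnovaTable

from conftest import make_dataset

# printed ANOVA of the 34-genotype x 8-environment x 3-replicate rice trial
# that this toolchain reproduces structurally (SS in (g m^-2)^2)
PRINTED_SS = {"ENV": 32_277_639.0, "GEN": 6_685_134.0, "GEN:ENV": 6_311_279.0}
PRINTED_MS_GEN = 202_579.8
PRINTED_MS_RES = 487.1697
PRINTED_SS_PC1 = 5_612_970.0
PRINTED_SS_PC2 = 499_545.4


def printed_anova_table() -> AnovaTable:
    """AnovaTable carrying the published sums of squares (df for 34x8x3)."""
    df = pd.DataFrame(
        {
            "Df": [7, 16, 33, 231, 528],
            "SS": [PRINTED_SS["ENV"], 13_281.69, PRINTED_SS["GEN"],
                   PRINTED_SS["GEN:ENV"], 257_225.6],
        },
        index=["ENV", "REP(ENV)", "GEN", "GEN:ENV", "Residuals"],
    )
    df["MS"] = df["SS"] / df["Df"]
    df["F"] = np.nan
    df["p"] = np.nan
    return AnovaTable(df)


def test_anova_df_column_at_design_scale(paper_scale_sim):
    data, _ = paper_scale_sim
    t = ms.joint_anova(data)
    assert list(t.table["Df"]) == [7, 16, 33, 231, 528]


def test_anova_ss_additivity(small_sim):
    data, _ = small_sim
    t = ms.joint_anova(data)
    y = data.table["yield"].to_numpy()
    total = ((y - y.mean()) ** 2).sum()
    assert t.table["SS"].sum() == pytest.approx(total, rel=1e-9)


def test_anova_constant_data_all_zero():
    d = make_dataset(np.full((4, 3), 9.0), r=2)
    t = ms.joint_anova(d)
    assert t.table["SS"].to_numpy() == pytest.approx(0.0, abs=1e-18)


def test_anova_requires_replicates():
    d = make_dataset(np.arange(12, dtype=float).reshape(4, 3), r=1)
    with pytest.raises(ValueError, match="r >= 2"):
        ms.joint_anova(d)


def test_anova_zero_noise_matches_generator(noiseless_sim):
    data, gt = noiseless_sim
    t = ms.joint_anova(data)
    f_e, f_g, f_gei = gt.config.ss_fractions
    pct = ms.ss_proportions(t)
    assert pct[0] == pytest.approx(100 * f_e, abs=1e-9)
    assert pct[1] == pytest.approx(100 * f_g, abs=1e-9)
    assert pct[2] == pytest.approx(100 * f_gei, abs=1e-9)
    assert t.table.loc["Residuals", "SS"] == pytest.approx(0.0, abs=1e-3)


def test_ss_proportions_reproduce_printed_shares():
    pct = ms.ss_proportions(printed_anova_table())
    assert tuple(round(p, 2) for p in pct) == (71.29, 14.77, 13.94)


def test_ss_proportions_edge_cases():
    t = printed_anova_table()
    eq = t.table.copy()
    eq.loc[["ENV", "GEN", "GEN:ENV"], "SS"] = 5.0
    assert ms.ss_proportions(AnovaTable(eq)) == pytest.approx((100 / 3,) * 3)
    eq.loc["GEN:ENV", "SS"] = 0.0
    assert ms.ss_proportions(AnovaTable(eq))[2] == 0.0
    eq.loc[["ENV", "GEN"], "SS"] = 0.0
    with pytest.raises(ZeroDivisionError):
        ms.ss_proportions(AnovaTable(eq))


def test_f_gen_from_printed_mean_squares():
    assert round(PRINTED_MS_GEN / PRINTED_MS_RES, 2) == 415.83


def test_pc_shares_from_printed_interaction_ss():
    assert round(100 * PRINTED_SS_PC1 / PRINTED_SS["GEN:ENV"], 1) == 88.9
    cum2 = 100 * (PRINTED_SS_PC1 + PRINTED_SS_PC2) / PRINTED_SS["GEN:ENV"]
    assert round(cum2, 1) == 96.9


def test_double_center_examples(hand_matrix):
    additive = ms.GEMatrix(pd.DataFrame([[1.0, 2.0], [3.0, 4.0]],
                                        index=["a", "b"], columns=["x", "y"]))
    assert np.allclose(ms.double_center(additive), 0.0)
    cross = ms.GEMatrix(pd.DataFrame([[1.0, 2.0], [4.0, 3.0]],
                                     index=["a", "b"], columns=["x", "y"]))
    np.testing.assert_allclose(ms.double_center(cross),
                               [[-0.5, 0.5], [0.5, -0.5]])
    np.testing.assert_allclose(ms.double_center(hand_matrix),
                               [[-5, 0, 5], [0, 0, 0], [5, 0, -5]])


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10_000), st.integers(3, 7), st.integers(2, 6))
def test_double_center_margins_vanish(seed, g, e):
    rng = np.random.default_rng(seed)
    m = ms.GEMatrix(pd.DataFrame(rng.normal(50, 10, (g, e))))
    dc = ms.double_center(m)
    assert np.allclose(dc.sum(axis=0), 0.0, atol=1e-9)
    assert np.allclose(dc.sum(axis=1), 0.0, atol=1e-9)


def test_gollob_df_values():
    assert ms.gollob_df(34, 8, 1) == 39
    assert ms.gollob_df(34, 8, 7) == 27
    assert ms.gollob_df(3, 3, 1) == 3
    with pytest.raises(ValueError):
        ms.gollob_df(34, 8, 8)
    with pytest.raises(ValueError):
        ms.gollob_df(34, 8, 0)


def test_gollob_df_sums_to_interaction_df():
    for g, e in [(34, 8), (10, 4), (5, 9)]:
        total = sum(ms.gollob_df(g, e, k) for k in range(1, min(g - 1, e - 1) + 1))
        assert total == (g - 1) * (e - 1)


def test_fit_ammi_hand_matrix(hand_matrix):
    model = ms.fit_ammi(hand_matrix)
    assert model.lambdas[0] == pytest.approx(10.0)
    assert model.prop[0] == pytest.approx(100.0)
    assert model.prop[1] == pytest.approx(0.0, abs=1e-9)
    # documented sign rule: E1 loading (tied largest |.|) made positive
    np.testing.assert_allclose(model.gen_scores["IPCA1"],
                               [-2.2360679, 0.0, 2.2360679], atol=1e-6)


def test_fit_ammi_axis_ss_conservation(small_sim):
    data, _ = small_sim
    t = ms.joint_anova(data)
    model = ms.fit_ammi(data, anova=t)
    assert model.axis_ss.sum() == pytest.approx(
        t.table.loc["GEN:ENV", "SS"], rel=1e-6)
    assert model.axis_df.sum() == (data.g - 1) * (data.e - 1)
    assert model.accum_prop[-1] == pytest.approx(100.0)
    assert np.all(np.diff(model.accum_prop) >= -1e-12)


def test_fit_ammi_recovers_generator_lambdas(noiseless_sim):
    data, gt = noiseless_sim
    model = ms.fit_ammi(data)
    np.testing.assert_allclose(model.lambdas[:4], gt.lambdas, rtol=1e-6)
    assert np.max(np.abs(model.lambdas[4:])) < 1e-6
    # axis subspaces recovered up to sign
    for k in range(4):
        dot = abs(float(model.env_scores.to_numpy()[:, k]
                        / model.lambdas[k] ** 0.5 @ gt.delta[:, k]))
        assert dot == pytest.approx(1.0, abs=1e-6)


def test_fit_ammi_reconstructs_means(small_sim):
    data, _ = small_sim
    m = ms.cell_means(data)
    model = ms.fit_ammi(data)
    # alpha = 0.5 scaling: scores multiply back to lambda * gamma * delta
    interaction = model.gen_scores.to_numpy() @ model.env_scores.to_numpy().T
    recon = (m.grand_mean
             + (m.gen_means.to_numpy() - m.grand_mean)[:, None]
             + (m.env_means.to_numpy() - m.grand_mean)[None, :]
             + interaction)
    np.testing.assert_allclose(recon, m.values.to_numpy(), atol=1e-9)


def test_axis_ss_matches_power_iteration_oracle():
    rng = np.random.default_rng(42)
    for _ in range(5):
        g, e = rng.integers(3, 6), rng.integers(3, 6)
        m = ms.GEMatrix(pd.DataFrame(rng.normal(0, 5, (g, e))))
        dc = ms.double_center(m).to_numpy()
        model = ms.fit_ammi(m)
        # brute-force rank-1 maximization by power iteration with deflation
        resid = dc.copy()
        for k in range(min(g, e) - 1):
            v = rng.normal(size=resid.shape[1])
            for _ in range(2000):
                u = resid @ v
                u /= np.linalg.norm(u) or 1.0
                v = resid.T @ u
                s = np.linalg.norm(v)
                v /= s or 1.0
            assert s**2 == pytest.approx(model.lambdas[k] ** 2, abs=1e-8 * (1 + s**2))
            resid = resid - s * np.outer(u, v)


def test_scores_sign_invariant_construction():
    # same interaction entered with both axis sign conventions -> same model
    rng = np.random.default_rng(0)
    base = rng.normal(100, 10, (6, 4))
    m1 = ms.GEMatrix(pd.DataFrame(base))
    model1 = ms.fit_ammi(m1)
    # negating an SVD axis pair leaves the matrix unchanged, so the fitted
    # scores must be identical no matter how the backend chose signs
    model2 = ms.fit_ammi(ms.GEMatrix(pd.DataFrame(base.copy())))
    pd.testing.assert_frame_equal(model1.gen_scores, model2.gen_scores)
    # the sign rule puts the dominant environment loading positive
    for k in range(model1.p):
        col = model1.env_scores.to_numpy()[:, k]
        assert col[np.argmax(np.abs(col))] >= 0


def test_ammi1_ammi2_coordinates(hand_matrix):
    model = ms.fit_ammi(hand_matrix)
    c1 = ms.ammi1_coords(model, hand_matrix)
    assert len(c1.points) == hand_matrix.g + hand_matrix.e
    gen = c1.points[c1.points.role == "genotype"].set_index("label")
    np.testing.assert_allclose(gen["x"], [20, 25, 30])
    np.testing.assert_allclose(gen["y"], [-2.2360679, 0, 2.2360679], atol=1e-6)
    # zero-interaction genotype sits on the x-axis
    assert gen.loc["G2", "y"] == pytest.approx(0.0, abs=1e-12)
    c2 = ms.ammi2_coords(model)
    assert len(c2.points) == hand_matrix.g + hand_matrix.e
    assert set(c2.points.role) == {"genotype", "environment"}


def test_ammi2_needs_two_axes():
    m = ms.GEMatrix(pd.DataFrame([[1.0, 2.0], [2.0, 1.0], [3.0, 3.0]],
                                 columns=["E1", "E2"], index=["a", "b", "c"]))
    model = ms.fit_ammi(m)
    with pytest.raises(ValueError, match="two interaction axes"):
        ms.ammi2_coords(model)


def test_significant_axes_at_design_scale(paper_scale_sim):
    data, gt = paper_scale_sim
    model = ms.fit_ammi(data)
    sig = model.significant_axes(0.05)
    # generator puts ~89% on axis 1; with printed-scale noise the first
    # axes dominate and at least axis 1 must be significant
    assert 0 in sig
    assert model.prop[0] > 80
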