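"""AMMI: additive main effects and multiplicative interaction.

The model for a balanced MET is

    Y_ge = mu + alpha_g + beta_e + sum_n lambda_n gamma_gn delta_en + rho_ge

where the additive part (grand mean, genotype and environment main
effects) comes from a joint ANOVA of the plot-level RCBD data and the
interaction is decomposed by an SVD of the double-centered cell-means
matrix.  Each interaction principal component axis (IPCA) *n* carries a
singular value ``lambda_n`` and genotype/environment eigenvectors
``gamma_gn`` / ``delta_en``; its sum of squares on the plot scale is
``r * lambda_n**2`` and it is tested approximately against the pooled
residual with Gollob degrees of freedom ``g + e - 1 - 2n``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .data import GEMatrix, METDataset, cell_means

__all__ = [
    "AnovaTable",
    "AMMIModel",
    "BiplotCoords",
    "joint_anova",
    "ss_proportions",
    "double_center",
    "fit_ammi",
    "gollob_df",
    "ammi1_coords",
    "ammi2_coords",
]

_ANOVA_ROWS = ["ENV", "REP(ENV)", "GEN", "GEN:ENV", "Residuals"]


@dataclasses.dataclass(frozen=True)
class AnovaTable:
    """Joint ANOVA of the balanced RCBD MET (plot scale).

    ``table`` has rows ENV, REP(ENV), GEN, GEN:ENV, Residuals and
    columns Df, SS, MS, F, p.  F(ENV) is tested against the REP(ENV)
    mean square; GEN and GEN:ENV against the pooled residual.
    """

    table: pd.DataFrame

    def __getitem__(self, row: str) -> pd.Series:
        return self.table.loc[row]

    @property
    def ms_residual(self) -> float:
        return float(self.table.loc["Residuals", "MS"])


@dataclasses.dataclass(frozen=True)
class AMMIModel:
    """SVD decomposition of the double-centered means matrix.

    Scores are the eigenvectors scaled by ``lambda**alpha`` (genotypes)
    and ``lambda**(1-alpha)`` (environments); ``alpha=0.5`` gives the
    symmetric scaling used for AMMI biplots.  ``axis_ss`` is on the
    plot scale (``r * lambda**2``) so the axes sum to the ANOVA's
    GEN:ENV sum of squares.
    """

    lambdas: np.ndarray          # singular values, descending
    gen_scores: pd.DataFrame     # g x p, columns IPCA1..IPCAp
    env_scores: pd.DataFrame     # e x p
    axis_table: pd.DataFrame     # per-axis Df, SS, MS, F, p, Proportion, Accumulated
    r: int                       # replicates behind each cell mean
    scaling: float               # the alpha exponent used for scores

    @property
    def p(self) -> int:
        return len(self.lambdas)

    @property
    def axis_ss(self) -> np.ndarray:
        return self.axis_table["SS"].to_numpy()

    @property
    def axis_df(self) -> np.ndarray:
        return self.axis_table["Df"].to_numpy()

    @property
    def prop(self) -> np.ndarray:
        return self.axis_table["Proportion"].to_numpy()

    @property
    def accum_prop(self) -> np.ndarray:
        return self.axis_table["Accumulated"].to_numpy()

    def significant_axes(self, alpha: float = 0.05) -> list[int]:
        """0-based indices of axes whose Gollob F-test is below ``alpha``."""
        p = self.axis_table["p"]
        return [i for i in range(self.p) if np.isfinite(p.iloc[i]) and p.iloc[i] <= alpha]


@dataclasses.dataclass(frozen=True)
class BiplotCoords:
    """2-D coordinates for genotype and environment points of a biplot."""

    points: pd.DataFrame  # columns: label, role, x, y
    x_label: str
    y_label: str


def joint_anova(data: METDataset) -> AnovaTable:
    """Joint ANOVA of genotypes, environments, blocks and interaction.

    Requires ``r >= 2`` so the pooled residual exists.  With a
    zero-variance residual the F statistics are +inf with p = 0.
    """
    g, e, r = data.g, data.e, data.r
    if r < 2:
        raise ValueError("joint_anova needs r >= 2 replicates for a residual term")
    df = data.table
    y = df["yield"].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    env_means = df.groupby("env", observed=True)["yield"].mean()
    gen_means = df.groupby("gen", observed=True)["yield"].mean()
    cellm = df.groupby(["env", "gen"], observed=True)["yield"].mean()
    blockm = df.groupby(["env", "rep"], observed=True)["yield"].mean()

    ss_env = g * r * float(((env_means - grand) ** 2).sum())
    ss_gen = e * r * float(((gen_means - grand) ** 2).sum())
    inter = cellm - env_means.reindex(
        cellm.index.get_level_values("env")
    ).to_numpy() - gen_means.reindex(cellm.index.get_level_values("gen")).to_numpy() + grand
    ss_gei = r * float((inter**2).sum())
    ss_rep = g * float(
        ((blockm - env_means.reindex(blockm.index.get_level_values("env")).to_numpy()) ** 2).sum()
    )
    ss_res = ss_total - ss_env - ss_gen - ss_gei - ss_rep

    dfs = np.array([e - 1, e * (r - 1), g - 1, (g - 1) * (e - 1), e * (g - 1) * (r - 1)])
    sss = np.array([ss_env, ss_rep, ss_gen, ss_gei, max(ss_res, 0.0)])
    mss = sss / dfs
    ms_rep, ms_res = mss[1], mss[4]

    def _f(ms, denom):
        if denom > 0:
            return ms / denom
        return np.inf if ms > 0 else np.nan

    fvals = np.array([_f(mss[0], ms_rep), _f(ms_rep, ms_res), _f(mss[2], ms_res),
                      _f(mss[3], ms_res), np.nan])
    denom_df = np.array([dfs[1], dfs[4], dfs[4], dfs[4], np.nan])
    pvals = np.full(5, np.nan)
    for i in range(4):
        if np.isfinite(fvals[i]):
            pvals[i] = stats.f.sf(fvals[i], dfs[i], denom_df[i])
        elif np.isposinf(fvals[i]):
            pvals[i] = 0.0
    table = pd.DataFrame(
        {"Df": dfs, "SS": sss, "MS": mss, "F": fvals, "p": pvals}, index=_ANOVA_ROWS
    )
    return AnovaTable(table)


def ss_proportions(t: AnovaTable) -> tuple[float, float, float]:
    """Percent shares of ENV, GEN and GEN:ENV over their three-way SS total.

    Replicate-block and residual SS are excluded from the denominator;
    this is the decomposition behind statements like "the environment
    accounted for 71.29% of the total sum of squared deviations".
    """
    ss = t.table["SS"]
    total = ss["ENV"] + ss["GEN"] + ss["GEN:ENV"]
    if total == 0:
        raise ZeroDivisionError("all of ENV, GEN and GEN:ENV sums of squares are zero")
    return tuple(100.0 * ss[k] / total for k in ("ENV", "GEN", "GEN:ENV"))


def double_center(m: GEMatrix) -> pd.DataFrame:
    """Interaction residuals: value - row mean - column mean + grand mean."""
    v = m.values
    return v.sub(m.gen_means, axis=0).sub(m.env_means, axis=1) + m.grand_mean


def gollob_df(g: int, e: int, k: int) -> int:
    """Gollob degrees of freedom ``g + e - 1 - 2k`` for the k-th IPCA."""
    p = min(g - 1, e - 1)
    if not 1 <= k <= p:
        raise ValueError(f"axis k={k} out of range 1..{p} for g={g}, e={e}")
    return g + e - 1 - 2 * k


def fit_ammi(
    data: METDataset | GEMatrix,
    score_scaling: float = 0.5,
    anova: AnovaTable | None = None,
) -> AMMIModel:
    """Fit the multiplicative interaction model by SVD.

    Accepts plot-level data (F-tests against the pooled residual) or a
    bare means matrix ("means-only mode", r = 1, no F-tests — used for
    hand-sized worked examples).  Axis signs are fixed by making the
    largest-magnitude environment loading of each axis positive, so
    scores are reproducible across SVD implementations.
    """
    if isinstance(data, GEMatrix):
        m, r = data, 1
        ms_res, df_res = np.nan, 0
    else:
        m, r = cell_means(data), data.r
        if anova is None and r >= 2:
            anova = joint_anova(data)
        if anova is not None:
            ms_res = anova.ms_residual
            df_res = int(anova["Residuals"]["Df"])
        else:
            ms_res, df_res = np.nan, 0

    g, e = m.g, m.e
    p = min(g - 1, e - 1)
    dc = double_center(m).to_numpy()
    u, s, vt = np.linalg.svd(dc, full_matrices=False)
    u, s, vt = u[:, :p], s[:p], vt[:p, :]
    # sign rule: largest-|.| environment loading positive per axis
    for k in range(p):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0

    ss_gei = float((s**2).sum()) * r
    axis_ss = r * s**2
    axis_dfs = np.array([gollob_df(g, e, k) for k in range(1, p + 1)])
    axis_ms = axis_ss / axis_dfs
    if np.isfinite(ms_res) and ms_res > 0:
        axis_f = axis_ms / ms_res
        axis_p = stats.f.sf(axis_f, axis_dfs, df_res)
    else:
        axis_f = np.full(p, np.nan)
        axis_p = np.full(p, np.nan)
    if ss_gei > 0:
        prop = 100.0 * axis_ss / ss_gei
    else:
        prop = np.zeros(p)
    axis_names = [f"IPCA{k}" for k in range(1, p + 1)]
    axis_table = pd.DataFrame(
        {
            "Df": axis_dfs,
            "SS": axis_ss,
            "MS": axis_ms,
            "F": axis_f,
            "p": axis_p,
            "Proportion": prop,
            "Accumulated": np.cumsum(prop),
        },
        index=axis_names,
    )
    a = float(score_scaling)
    gen_scores = pd.DataFrame(u * s**a, index=m.values.index, columns=axis_names)
    env_scores = pd.DataFrame(vt.T * s ** (1 - a), index=m.values.columns, columns=axis_names)
    return AMMIModel(
        lambdas=s,
        gen_scores=gen_scores,
        env_scores=env_scores,
        axis_table=axis_table,
        r=r,
        scaling=a,
    )


def _coords(model: AMMIModel, m: GEMatrix | None, mode: str) -> BiplotCoords:
    rows = []
    if mode == "ammi1":
        if m is None:
            raise ValueError("ammi1 coordinates need the means matrix")
        for lab in model.gen_scores.index:
            rows.append((lab, "genotype", float(m.gen_means[lab]),
                         float(model.gen_scores.loc[lab, "IPCA1"])))
        for lab in model.env_scores.index:
            rows.append((lab, "environment", float(m.env_means[lab]),
                         float(model.env_scores.loc[lab, "IPCA1"])))
        xl, yl = "Mean yield", f"IPCA1 ({model.prop[0]:.1f}%)"
    else:
        if model.p < 2:
            raise ValueError("ammi2 biplot needs at least two interaction axes")
        for df_, role in ((model.gen_scores, "genotype"), (model.env_scores, "environment")):
            for lab in df_.index:
                rows.append((lab, role, float(df_.loc[lab, "IPCA1"]),
                             float(df_.loc[lab, "IPCA2"])))
        xl = f"IPCA1 ({model.prop[0]:.1f}%)"
        yl = f"IPCA2 ({model.prop[1]:.1f}%)"
    pts = pd.DataFrame(rows, columns=["label", "role", "x", "y"])
    return BiplotCoords(pts, xl, yl)


def ammi1_coords(model: AMMIModel, m: GEMatrix) -> BiplotCoords:
    """AMMI1 biplot: mean yield on x, IPCA1 score on y, for both roles."""
    return _coords(model, m, "ammi1")


def ammi2_coords(model: AMMIModel) -> BiplotCoords:
    """AMMI2 biplot: IPCA1 vs IPCA2 scores for genotypes and environments."""
    return _coords(model, None, "ammi2")
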