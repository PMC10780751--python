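"""Yield-stability statistics for balanced MET means tables.

Parametric panel
----------------
* Wricke's ecovalence ``W_i`` — a genotype's summed squared
  interaction residuals.
* Shukla's stability variance ``sigma2_i`` — the unbiased variance
  estimate, linear in ``W_i``.
* Eberhart & Russell joint regression — slope ``b_i`` of genotype
  response on the environmental index and deviation mean square
  ``S2d_i`` (reported as the ``Sij`` column).
* Annicchiarico reliability ``Wi`` — mean percent-of-environment-mean
  minus a one-sided normal quantile times its sd, over all,
  favorable-only and unfavorable-only environments.
* Lin & Binns superiority ``Pi`` — mean squared distance to the best
  genotype per environment, same three environment subsets.
* Environmental variance ``S2x_i``, coefficient of variation ``CV_i``,
  geometric adaptability index ``GAI``.
* Tai's (alpha_i, lambda_i) — partition of the interaction regression;
  alpha near 0 and lambda near 1 indicate average stability.
* Plaisted-Peterson theta_i and Plaisted theta'_i variance components,
  both linear in ``W_i``.

Nonparametric panel
-------------------
Huehn's S1/S2/S3/S6 and Thennarasu's N1, computed from within-
environment genotype ranks (average ranks on ties); S3 and S6 use
ranks of genotype-effect-corrected values.

WAAS
----
The weighted average of absolute IPCA scores, with weights equal to
the share of interaction sum of squares each retained axis explains;
small WAAS = stable.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .ammi import AMMIModel, AnovaTable, double_center
from .data import EnvClassification, GEMatrix, classify_environments

__all__ = [
    "StabilityTable",
    "QuadrantLabels",
    "waas",
    "env_waas",
    "gy_waas_quadrants",
    "parametric_stability",
    "nonparametric_stability",
    "rank_table",
    "stability_table",
    "RANK_DIRECTIONS",
]

#: one-sided 75% normal quantile used in the Annicchiarico index
ANNICCHIARICO_Z = float(stats.norm.ppf(0.75))


@dataclasses.dataclass(frozen=True)
class StabilityTable:
    """Per-genotype stability values plus the parallel rank table.

    ``values`` holds one column per statistic; ``ranks`` the matching
    ``*_R`` columns (rank 1 = most stable, except mean yield and other
    larger-is-better columns where rank 1 = best).
    """

    values: pd.DataFrame
    ranks: pd.DataFrame

    def combined(self) -> pd.DataFrame:
        return pd.concat([self.values, self.ranks], axis=1)


@dataclasses.dataclass(frozen=True)
class QuadrantLabels:
    """Quadrants of the mean-yield x WAAS plane.

    I: low yield, high WAAS (unstable); II: high yield, high WAAS;
    III: low yield, low WAAS; IV: high yield, low WAAS (the broadly
    adapted group).  Points exactly on a dividing line fall on the
    lower-yield / higher-WAAS side.
    """

    genotypes: pd.Series
    environments: pd.Series


def _select_axes(model: AMMIModel, n_axes: str | int, alpha: float) -> list[int]:
    if n_axes == "significant":
        axes = model.significant_axes(alpha)
        # means-only fits have no F-test; fall back to every axis
        if not axes and not np.isfinite(model.axis_table["p"]).any():
            axes = list(range(model.p))
    elif n_axes == "all":
        axes = list(range(model.p))
    else:
        k = int(n_axes)
        if not 1 <= k <= model.p:
            raise ValueError(f"n_axes={k} out of range 1..{model.p}")
        axes = list(range(k))
    if not axes:
        raise ValueError("no interaction axes retained for WAAS")
    return axes


def _waas_of(scores: pd.DataFrame, model: AMMIModel, axes: list[int]) -> pd.Series:
    w = model.prop[axes]
    if w.sum() == 0:  # no interaction at all: WAAS identically zero
        w = np.ones(len(axes))
    vals = scores.iloc[:, axes].abs().to_numpy() @ w / w.sum()
    return pd.Series(vals, index=scores.index, name="WAAS")


def waas(model: AMMIModel, n_axes: str | int = "significant", alpha: float = 0.05) -> pd.Series:
    """Weighted average of absolute IPCA scores per genotype.

    ``n_axes`` may be ``"significant"`` (axes passing the Gollob
    F-test at ``alpha``; falls back to all axes when no F-test is
    available, e.g. means-only fits), ``"all"``, or an explicit count.
    Weights are each axis's percent of interaction SS.
    """
    return _waas_of(model.gen_scores, model, _select_axes(model, n_axes, alpha))


def env_waas(model: AMMIModel, n_axes: str | int = "significant", alpha: float = 0.05) -> pd.Series:
    """Same weighting applied to the absolute environment scores."""
    return _waas_of(model.env_scores, model, _select_axes(model, n_axes, alpha))


def gy_waas_quadrants(
    gen_means: pd.Series,
    gen_waas: pd.Series,
    env_means: pd.Series | None = None,
    env_waas_values: pd.Series | None = None,
) -> QuadrantLabels:
    """Assign genotypes (and optionally environments) to GYxWAAS quadrants."""
    grand = float(gen_means.mean())
    waas_mean = float(gen_waas.mean())

    def _label(means, ws, xcut, ycut):
        out = []
        for m_, w_ in zip(means, ws):
            high_y = m_ > xcut
            high_w = w_ >= ycut  # boundary -> higher-WAAS side
            out.append("II" if (high_y and high_w) else
                       "IV" if high_y else
                       "I" if high_w else "III")
        return out

    gq = pd.Series(_label(gen_means, gen_waas, grand, waas_mean),
                   index=gen_means.index, name="quadrant")
    if env_means is not None and env_waas_values is not None:
        eq = pd.Series(
            _label(env_means, env_waas_values, grand, float(env_waas_values.mean())),
            index=env_means.index, name="quadrant")
    else:
        eq = pd.Series(dtype=object, name="quadrant")
    return QuadrantLabels(gq, eq)


def _ecovalence(dc: np.ndarray) -> np.ndarray:
    return (dc**2).sum(axis=1)


def parametric_stability(
    m: GEMatrix,
    cls: EnvClassification | None = None,
    ms_error: float | None = None,
    r: int = 1,
) -> pd.DataFrame:
    """Parametric stability statistics from the means matrix.

    ``ms_error`` (plot-level pooled residual MS) and ``r`` enable the
    Tai statistics; without them the Tai columns are NA.
    """
    g, e = m.g, m.e
    if g < 3:
        raise ValueError("parametric stability needs at least 3 genotypes")
    if cls is None:
        cls = classify_environments(m)
    v = m.values.to_numpy(dtype=float)
    gen_means = m.gen_means.to_numpy()
    env_means = m.env_means.to_numpy()
    grand = m.grand_mean
    dc = double_center(m).to_numpy()

    W = _ecovalence(dc)
    ss_gei_means = float(W.sum())
    shukla = g * W / ((g - 2) * (e - 1)) - ss_gei_means / ((g - 1) * (g - 2) * (e - 1))

    # joint regression on the environmental index
    idx = env_means - grand
    ss_idx = float((idx**2).sum())
    if ss_idx > 0:
        b = (v - gen_means[:, None]) @ idx / ss_idx
        resid = v - gen_means[:, None] - np.outer(b, idx)
        if e > 2:
            s2d = (resid**2).sum(axis=1) / (e - 2)
        else:
            s2d = np.full(g, np.nan)
    else:
        b = np.full(g, np.nan)
        resid = np.full_like(v, np.nan)
        s2d = np.full(g, np.nan)

    # Annicchiarico reliability and Lin & Binns superiority
    pct = 100.0 * v / env_means[None, :]
    env_max = v.max(axis=0)
    env_labels = np.asarray(m.environments, dtype=object)
    subsets = {
        "a": np.ones(e, dtype=bool),
        "f": np.isin(env_labels, np.asarray(cls.favorable, dtype=object)),
        "u": np.isin(env_labels, np.asarray(cls.unfavorable, dtype=object)),
    }
    wi, pi = {}, {}
    for key, mask in subsets.items():
        n = int(mask.sum())
        if n == 0:
            warnings.warn(
                f"environment subset {key!r} is empty; Wi_{key}/Pi_{key} set to NA",
                stacklevel=2,
            )
            wi[key] = np.full(g, np.nan)
            pi[key] = np.full(g, np.nan)
            continue
        sub = pct[:, mask]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1) if n > 1 else np.zeros(g)
        wi[key] = mean - ANNICCHIARICO_Z * sd
        pi[key] = ((v[:, mask] - env_max[mask]) ** 2).sum(axis=1) / (2 * n)

    s2x = v.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * np.sqrt(s2x) / gen_means
    if (v <= 0).any():
        raise ValueError("GAI requires strictly positive yields")
    gai = np.exp(np.log(v).mean(axis=1))

    # Tai's partition of the interaction regression
    if ms_error is not None and r >= 2 and e > 2 and ss_idx > 0:
        tai_alpha = dc @ idx / ss_idx
        tai_dev = dc - np.outer(tai_alpha, idx)
        s2_mean = ms_error / r  # error variance of a cell mean
        tai_lambda = (tai_dev**2).sum(axis=1) / ((e - 2) * s2_mean)
    else:
        tai_alpha = np.full(g, np.nan)
        tai_lambda = np.full(g, np.nan)

    # Plaisted-Peterson theta (pairwise mean) and Plaisted theta' (drop-one)
    theta = (ss_gei_means + g * W) / (4 * (g - 1) * (e - 1))
    theta_prime = (ss_gei_means - g * W / (g - 1)) / ((g - 2) * (e - 1))

    return pd.DataFrame(
        {
            "GY": gen_means,
            "Ecoval": W,
            "Shukla": shukla,
            "bi": b,
            "Sij": s2d,
            "Wi_g": wi["a"],
            "Wi_f": wi["f"],
            "Wi_u": wi["u"],
            "Pi_a": pi["a"],
            "Pi_f": pi["f"],
            "Pi_u": pi["u"],
            "S2x": s2x,
            "CV": cv,
            "Gai": gai,
            "Tai_alpha": tai_alpha,
            "Tai_lambda": tai_lambda,
            "Theta": theta,
            "ThetaPrime": theta_prime,
        },
        index=m.values.index,
    )


def _env_ranks(v: np.ndarray) -> np.ndarray:
    """Within-environment ranks (1 = lowest), average ranks on ties."""
    return np.column_stack([stats.rankdata(v[:, j], method="average") for j in range(v.shape[1])])


def nonparametric_stability(m: GEMatrix) -> pd.DataFrame:
    """Huehn S1/S2/S3/S6 and Thennarasu N1 rank-based statistics.

    S1, S2 and N1 use ranks of the raw cell means; S3 and S6 use ranks
    of the genotype-effect-corrected values ``x_ie - xbar_i + xbar``,
    per Huehn's original definitions.
    """
    g, e = m.g, m.e
    v = m.values.to_numpy(dtype=float)
    ranks = _env_ranks(v)
    corrected = v - v.mean(axis=1, keepdims=True) + v.mean()
    cranks = _env_ranks(corrected)

    # S1: mean absolute pairwise rank difference over environment pairs
    n_pairs = e * (e - 1) / 2
    s1 = np.zeros(g)
    for j in range(e):
        for k in range(j + 1, e):
            s1 += np.abs(ranks[:, j] - ranks[:, k])
    s1 /= n_pairs
    rbar = ranks.mean(axis=1)
    s2 = ((ranks - rbar[:, None]) ** 2).sum(axis=1) / (e - 1)
    crbar = cranks.mean(axis=1)
    s3 = ((cranks - crbar[:, None]) ** 2).sum(axis=1) / crbar
    s6 = np.abs(cranks - crbar[:, None]).sum(axis=1) / crbar
    med = np.median(ranks, axis=1)
    n1 = np.abs(ranks - med[:, None]).mean(axis=1)

    return pd.DataFrame(
        {"S1": s1, "S2": s2, "S3": s3, "S6": s6, "N1": n1}, index=m.values.index
    )


#: how each column is turned into ranks: "asc" (small = rank 1),
#: "desc" (large = rank 1), "abs1" (|x - 1| ascending), "abs" (|x| ascending)
RANK_DIRECTIONS = {
    "GY": "desc",
    "WAAS": "asc",
    "Ecoval": "asc",
    "Shukla": "asc",
    "bi": "abs1",
    "Sij": "asc",
    "Wi_g": "desc",
    "Wi_f": "desc",
    "Wi_u": "desc",
    "Pi_a": "asc",
    "Pi_f": "asc",
    "Pi_u": "asc",
    "S2x": "asc",
    "CV": "asc",
    "Gai": "desc",
    "Tai_alpha": "abs",
    "Tai_lambda": "asc",
    "Theta": "asc",
    "ThetaPrime": "desc",
    "S1": "asc",
    "S2": "asc",
    "S3": "asc",
    "S6": "asc",
    "N1": "asc",
}


def rank_table(values: pd.DataFrame, directions: dict | None = None) -> pd.DataFrame:
    """Rank every statistic column (average ranks on ties) into ``*_R``.

    Stability statistics rank ascending (small = stable); mean yield,
    GAI and the Annicchiarico/Plaisted' reliability-type columns rank
    descending; the joint-regression slope ranks by ``|b_i - 1|``.
    All-NA columns are dropped with a warning.
    """
    directions = {**RANK_DIRECTIONS, **(directions or {})}
    out = {}
    for col in values.columns:
        x = values[col].to_numpy(dtype=float)
        if np.isnan(x).all():
            warnings.warn(f"column {col!r} is all NA; no rank column emitted", stacklevel=2)
            continue
        mode = directions.get(col, "asc")
        if mode == "desc":
            key = -x
        elif mode == "abs1":
            key = np.abs(x - 1.0)
        elif mode == "abs":
            key = np.abs(x)
        else:
            key = x
        out[f"{col}_R"] = stats.rankdata(key, method="average", nan_policy="omit")
    return pd.DataFrame(out, index=values.index)


def stability_table(
    m: GEMatrix,
    model: AMMIModel | None = None,
    anova: AnovaTable | None = None,
    cls: EnvClassification | None = None,
    n_axes: str | int = "significant",
) -> StabilityTable:
    """Assemble the full stability panel (values + ranks) for a MET."""
    ms_error = anova.ms_residual if anova is not None else None
    r = model.r if model is not None else 1
    values = parametric_stability(m, cls, ms_error=ms_error, r=r)
    if model is not None:
        values.insert(1, "WAAS", waas(model, n_axes))
    values = pd.concat([values, nonparametric_stability(m)], axis=1)
    return StabilityTable(values, rank_table(values))
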