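"""Spearman correlation of yield with the secondary traits.

Rank correlations are computed pairwise on the plot-level records,
either pooled over all environments or separately per environment.
p-values use the t-distribution approximation with n - 2 degrees of
freedom and are starred at the conventional 0.05 / 0.01 / 0.001
levels, without multiplicity adjustment.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .data import METDataset

__all__ = ["CorrMatrix", "spearman_matrix", "star"]


@dataclasses.dataclass(frozen=True)
class CorrMatrix:
    """Trait x trait Spearman rho with matching p-values and stars."""

    rho: pd.DataFrame
    p: pd.DataFrame

    @property
    def stars(self) -> pd.DataFrame:
        return self.p.map(star)

    def formatted(self) -> pd.DataFrame:
        """rho rounded to 3 decimals with significance stars appended."""
        return self.rho.round(3).astype(str) + self.stars


def star(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "***" if p <= 0.001 else "**" if p <= 0.01 else "*" if p <= 0.05 else ""


def _pair_spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 4 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        return np.nan, np.nan
    res = stats.spearmanr(x[ok], y[ok])
    return float(res.statistic), float(res.pvalue)


def spearman_matrix(
    data: METDataset,
    traits: list[str] | None = None,
    scope: str = "pooled",
) -> CorrMatrix | dict[object, CorrMatrix]:
    """Spearman correlation matrix among yield and traits.

    ``scope="pooled"`` concatenates all environments (plot level);
    ``scope="per-env"`` returns a mapping environment -> CorrMatrix.
    Constant variables yield NA correlations.
    """
    if traits is None:
        traits = data.traits  # includes "yield" first
    else:
        traits = ["yield"] + [t for t in traits if t != "yield"]
    missing = [t for t in traits if t not in data.table.columns]
    if missing:
        raise KeyError(f"unknown trait(s) {missing}")

    if scope == "per-env":
        return {
            env: _matrix(sub, traits)
            for env, sub in data.table.groupby("env", sort=False, observed=True)
        }
    if scope != "pooled":
        raise ValueError(f"unknown scope {scope!r}")
    return _matrix(data.table, traits)


def _matrix(df: pd.DataFrame, traits: list[str]) -> CorrMatrix:
    k = len(traits)
    rho = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r_, p_ = _pair_spearman(
                df[traits[i]].to_numpy(dtype=float), df[traits[j]].to_numpy(dtype=float)
            )
            rho[i, j] = rho[j, i] = r_
            p[i, j] = p[j, i] = p_
    idx = pd.Index(traits)
    return CorrMatrix(pd.DataFrame(rho, idx, idx), pd.DataFrame(p, idx, idx))
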