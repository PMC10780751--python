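"""Synthetic balanced MET generator with a controlled variance partition.

Plot values follow the additive-plus-multiplicative model

    Y = mu + alpha_g + beta_e + sum_k lambda_k gamma_gk delta_ek
        + b_(rep within env) + eps

Main effects are drawn from normal distributions, centered, and then
*exactly* rescaled so the environment / genotype / interaction shares
of the pattern (noise-free) three-way sum of squares hit the
configured fractions; the interaction is built from ``gei_rank``
orthonormal axis pairs whose squared singular values follow the
configured per-axis weights.  Defaults reproduce the statistical
structure of a 34-genotype x 8-environment x 3-replicate paddy-rice
trial in which the environment dominates (~71% of the three-way SS)
and the first interaction axis carries ~89% of the interaction.

Block effects are centered within each environment, so the cell-means
matrix — and hence every downstream decomposition — is unaffected by
them; they only feed the REP(ENV) ANOVA stratum.

Secondary traits are attached by a rank-based Gaussian copula with a
configurable Spearman correlation to yield.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .ammi import joint_anova, ss_proportions
from .data import METDataset

__all__ = [
    "SimConfig",
    "TraitSpec",
    "GroundTruth",
    "DEFAULT_TRAITS",
    "simulate_met",
    "simulate_traits",
    "realized_ss_fractions",
]


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic MET.

    ``ss_fractions`` are the (environment, genotype, interaction)
    shares of the pattern three-way sum of squares and must sum to 1;
    ``effect_sd`` sets the absolute scale (RMS of the combined pattern
    per plot, g m^-2).  ``gei_axis_weights`` are the per-axis shares
    of the interaction SS.
    """

    g: int = 34
    e: int = 8
    r: int = 3
    ss_fractions: tuple[float, float, float] = (0.7129, 0.1477, 0.1394)
    gei_rank: int = 4
    gei_axis_weights: tuple[float, ...] = (0.889, 0.079, 0.022, 0.010)
    effect_sd: float = 235.0
    block_sd: float = 3.4
    noise_sd: float = 22.0
    grand_mean: float = 700.0
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.ss_fractions, dtype=float)
        if f.min() < 0 or f.max() > 1 or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("ss_fractions must lie in [0,1] and sum to 1")
        w = np.asarray(self.gei_axis_weights, dtype=float)
        if len(w) != self.gei_rank:
            raise ValueError("gei_axis_weights must have gei_rank entries")
        if self.gei_rank > min(self.g - 1, self.e - 1):
            raise ValueError(
                f"gei_rank={self.gei_rank} infeasible for g={self.g}, e={self.e}"
            )
        if f[2] > 0:
            if self.gei_rank < 1:
                raise ValueError("positive GEI fraction needs gei_rank >= 1")
            if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("gei_axis_weights must be nonnegative and sum to 1")
        if min(self.block_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.g < 3 or self.e < 2 or self.r < 1:
            raise ValueError("need g >= 3, e >= 2, r >= 1")


@dataclasses.dataclass(frozen=True)
class TraitSpec:
    """Target Spearman correlation with yield, plus location and scale."""

    rho: float
    mean: float = 0.0
    scale: float = 1.0
    extra_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho={self.rho} outside [-1, 1]")
        if abs(self.rho) == 1.0 and self.extra_noise_sd > 0:
            raise ValueError("|rho| = 1 is incompatible with positive extra noise")


#: trait targets mirroring the study's pooled rank correlations with yield:
#: panicle length, panicles per plant, thousand-grain weight, sterility %
DEFAULT_TRAITS = {
    "PL": TraitSpec(0.825, mean=22.0, scale=1.5),
    "NPP": TraitSpec(0.904, mean=18.0, scale=3.0),
    "TG": TraitSpec(0.491, mean=24.0, scale=2.0),
    "ST": TraitSpec(-0.6, mean=12.0, scale=4.0),
}


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Every effect the generator drew, for oracle-style testing."""

    mu: float
    alpha: pd.Series           # genotype main effects, sum 0
    beta: pd.Series            # environment main effects, sum 0
    lambdas: np.ndarray        # interaction singular values, descending
    gamma: np.ndarray          # g x k orthonormal genotype axes
    delta: np.ndarray          # e x k orthonormal environment axes
    block: pd.DataFrame        # (env, rep) block effects, centered within env
    cell_means: pd.DataFrame   # noise-free g x e pattern
    config: SimConfig


def _centered_orthonormal(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k orthonormal n-vectors orthogonal to the ones vector."""
    basis = np.ones((n, 1)) / math.sqrt(n)
    x = rng.standard_normal((n, k))
    x -= basis @ (basis.T @ x)       # project out the mean direction
    q, rmat = np.linalg.qr(x)
    q *= np.sign(np.diag(rmat))      # deterministic QR sign
    return q


def _scaled_effects(rng: np.random.Generator, n: int, target_ss: float) -> np.ndarray:
    """Centered normal draw rescaled to an exact sum of squares."""
    x = rng.standard_normal(n)
    x -= x.mean()
    ss = float((x**2).sum())
    if target_ss == 0:
        return np.zeros(n)
    return x * math.sqrt(target_ss / ss)


def simulate_met(cfg: SimConfig) -> tuple[METDataset, GroundTruth]:
    """Generate one balanced RCBD MET plus its ground truth.

    Yields are physical quantities, so a draw whose tails push any
    plot below zero is rejected and redrawn from the next deterministic
    substream; the exact SS rescaling is applied within each attempt,
    so accepted datasets still hit the configured fractions exactly.
    """
    ss_parent = np.random.SeedSequence(cfg.seed)
    for _attempt in range(100):
        table, truth = _simulate_once(cfg, ss_parent.spawn(5))
        if table["yield"].min() >= 0:
            return METDataset(table), truth
    raise RuntimeError(
        "could not draw a non-negative MET in 100 attempts; "
        "raise grand_mean or lower effect_sd"
    )


def _simulate_once(cfg: SimConfig, seeds) -> tuple[pd.DataFrame, GroundTruth]:
    g, e, r = cfg.g, cfg.e, cfg.r
    rngs = [np.random.default_rng(s) for s in seeds]
    r_alpha, r_beta, r_gei, r_block, r_noise = rngs

    total_ss = g * e * r * cfg.effect_sd**2  # plot-level pattern SS
    f_e, f_g, f_gei = cfg.ss_fractions
    beta = _scaled_effects(r_beta, e, f_e * total_ss / (g * r))
    alpha = _scaled_effects(r_alpha, g, f_g * total_ss / (e * r))

    k = cfg.gei_rank
    if f_gei > 0:
        gamma = _centered_orthonormal(r_gei, g, k)
        delta = _centered_orthonormal(r_gei, e, k)
        ss_gei_means = f_gei * total_ss / r
        lambdas = np.sqrt(np.asarray(cfg.gei_axis_weights) * ss_gei_means)
        order = np.argsort(-lambdas)
        lambdas = lambdas[order]
        gamma, delta = gamma[:, order], delta[:, order]
        gei = gamma @ np.diag(lambdas) @ delta.T
    else:
        gamma = np.zeros((g, 0))
        delta = np.zeros((e, 0))
        lambdas = np.zeros(0)
        gei = np.zeros((g, e))

    gens = [f"G{i+1}" for i in range(g)]
    envs = [f"E{j+1}" for j in range(e)]
    reps = [f"R{t+1}" for t in range(r)]
    pattern = cfg.grand_mean + alpha[:, None] + beta[None, :] + gei
    cellm = pd.DataFrame(pattern, index=gens, columns=envs)

    block = r_block.standard_normal((e, r)) * cfg.block_sd
    block -= block.mean(axis=1, keepdims=True)  # centered within env
    noise = r_noise.standard_normal((g, e, r)) * cfg.noise_sd

    rows = []
    for j, env in enumerate(envs):
        for i, gen in enumerate(gens):
            for t, rep in enumerate(reps):
                rows.append(
                    (env, gen, rep, pattern[i, j] + block[j, t] + noise[i, j, t])
                )
    table = pd.DataFrame(rows, columns=["env", "gen", "rep", "yield"])
    truth = GroundTruth(
        mu=cfg.grand_mean,
        alpha=pd.Series(alpha, index=gens, name="alpha"),
        beta=pd.Series(beta, index=envs, name="beta"),
        lambdas=lambdas,
        gamma=gamma,
        delta=delta,
        block=pd.DataFrame(block, index=envs, columns=reps),
        cell_means=cellm,
        config=cfg,
    )
    return table, truth


def simulate_traits(
    data: METDataset,
    traits: dict[str, TraitSpec] | None = None,
    seed: int = 0,
) -> METDataset:
    """Attach copula-correlated secondary traits to the plot table.

    For a target Spearman rho the latent bivariate-normal correlation
    is ``a = 2 sin(pi * rho / 6)``; the trait is an affine transform
    of ``a * z_yield + sqrt(1 - a^2) * noise`` where ``z_yield`` are
    normal scores of the yield ranks, so the target is recovered up to
    Monte-Carlo error (exactly, for |rho| = 1).
    """
    from scipy import stats

    if traits is None:
        traits = DEFAULT_TRAITS
    df = data.table.copy()
    n = len(df)
    ranks = stats.rankdata(df["yield"].to_numpy(), method="average")
    z = stats.norm.ppf((ranks - 0.5) / n)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    for name, spec in traits.items():
        a = 2.0 * math.sin(math.pi * spec.rho / 6.0)
        latent = a * z
        if abs(a) < 1.0:
            latent = latent + math.sqrt(1.0 - a * a) * rng.standard_normal(n)
        if spec.extra_noise_sd > 0:
            latent = latent + spec.extra_noise_sd * rng.standard_normal(n)
        df[name] = spec.mean + spec.scale * latent
    return METDataset(df)


def realized_ss_fractions(data: METDataset) -> tuple[float, float, float]:
    """(f_E, f_G, f_GEI) realized shares of the three-way SS, in [0, 1]."""
    pct = ss_proportions(joint_anova(data))
    return tuple(p / 100.0 for p in pct)
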