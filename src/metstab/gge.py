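"""GGE biplot analysis: environment-centered SVD and its geometry.

The GGE model removes only the environment main effect from the
genotype x environment means table, so the first two singular axes
carry genotype main effect *plus* genotype-by-environment interaction.
Three classic views are computed from the rank-2 scores:

* which-won-where — the convex-hull polygon whose vertex genotypes win
  the environments falling in their sector;
* mean vs stability — projections on the average-environment axis
  (AEA) and its perpendicular (AOE);
* ranking against the "ideal" genotype (on the AEA, at the maximum
  mean projection).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .data import GEMatrix

__all__ = [
    "GGEModel",
    "WWWResult",
    "AEAProjection",
    "DegenerateGeometryError",
    "fit_gge",
    "which_won_where",
    "mean_vs_stability",
    "rank_genotypes",
]


class DegenerateGeometryError(ValueError):
    """Genotype points are collinear/coincident; no polygon exists."""


@dataclasses.dataclass(frozen=True)
class GGEModel:
    """Environment-centered (optionally env-scaled) SVD of the means table.

    The singular values are partitioned between the two point sets
    according to ``svp``: ``genotype`` puts them on the genotype
    coordinates (distances between genotypes are meaningful),
    ``environment`` the reverse, ``symmetric`` splits them as
    ``sqrt(lambda)`` each.  Inner products genotype . environment are
    identical under all three.
    """

    centered: pd.DataFrame
    u: np.ndarray
    s: np.ndarray
    vt: np.ndarray
    svp: str
    pct_explained: np.ndarray
    gen_coords: pd.DataFrame  # g x 2, columns PC1, PC2
    env_coords: pd.DataFrame  # e x 2


@dataclasses.dataclass(frozen=True)
class WWWResult:
    """Which-won-where decomposition of the rank-2 GGE biplot."""

    hull_vertices: list          # genotype labels, counterclockwise
    sector_of_env: dict          # env label -> sector index
    winner_of_sector: dict       # sector index -> genotype label


@dataclasses.dataclass(frozen=True)
class AEAProjection:
    """Mean-performance and stability projections on the AEA."""

    aea_direction: np.ndarray
    table: pd.DataFrame  # per genotype: mean_proj, stab_dist, dist_ideal, rank
    ideal_point: np.ndarray


def fit_gge(m: GEMatrix, scaling: str = "none", svp: str = "symmetric") -> GGEModel:
    """Center columns by environment means (optionally scale by env sd), SVD.

    Parameters
    ----------
    scaling
        ``"none"`` (centering only, the common GGE form) or ``"sd"``
        to divide each centered column by its standard deviation.
    svp
        Singular-value partitioning: ``genotype``, ``environment`` or
        ``symmetric``.
    """
    if svp not in ("genotype", "environment", "symmetric"):
        raise ValueError(f"unknown svp {svp!r}")
    centered = m.values.sub(m.env_means, axis=1)
    if scaling == "sd":
        sd = m.values.std(axis=0, ddof=1)
        zero = sd.index[sd == 0]
        if len(zero):
            raise ValueError(f"environment {zero[0]!r} has zero variance; cannot sd-scale")
        centered = centered.div(sd, axis=1)
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")

    u, s, vt = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    # sign rule as in the AMMI fit: dominant environment loading positive
    for k in range(len(s)):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    tot = float((s**2).sum())
    pct = 100.0 * s**2 / tot if tot > 0 else np.zeros_like(s)

    if svp == "genotype":
        gcoef, ecoef = s[:2], np.ones(2)
    elif svp == "environment":
        gcoef, ecoef = np.ones(2), s[:2]
    else:
        gcoef = ecoef = np.sqrt(s[:2])
    cols = ["PC1", "PC2"]
    gen_coords = pd.DataFrame(u[:, :2] * gcoef, index=m.values.index, columns=cols)
    env_coords = pd.DataFrame(vt[:2].T * ecoef, index=m.values.columns, columns=cols)
    return GGEModel(centered, u, s, vt, svp, pct, gen_coords, env_coords)


def _hull_vertices_ccw(pts: np.ndarray) -> list[int]:
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(
            "genotype points are collinear or coincident; no which-won-where polygon"
        ) from exc
    verts = list(hull.vertices)  # counterclockwise for 2-D
    # deterministic start: rotate so the lowest input index comes first
    k = int(np.argmin(verts))
    return verts[k:] + verts[:k]


def which_won_where(model: GGEModel) -> WWWResult:
    """Convex hull of genotype points; each environment's winner.

    Sectors are the angular regions bounded by rays from the origin
    perpendicular to the hull edges; equivalently, environment *j*
    belongs to the sector of the hull vertex that maximizes the inner
    product with its coordinate vector — that vertex genotype has the
    highest rank-2 modeled value in environment *j*.  Boundary ties go
    to the lower-indexed sector.
    """
    gpts = model.gen_coords.to_numpy()
    glabels = list(model.gen_coords.index)
    vidx = _hull_vertices_ccw(gpts)
    hull_labels = [glabels[i] for i in vidx]

    winner_of_sector = {k: hull_labels[k] for k in range(len(vidx))}
    sector_of_env = {}
    V = gpts[vidx]  # sectors in hull order
    for env, row in model.env_coords.iterrows():
        dots = V @ row.to_numpy()
        # exact ties (env on a sector boundary) -> lowest sector index
        sector_of_env[env] = int(np.flatnonzero(dots == dots.max())[0])
    return WWWResult(hull_labels, sector_of_env, winner_of_sector)


def mean_vs_stability(model: GGEModel) -> AEAProjection:
    """Project genotypes on the average-environment axis.

    The AEA points from the origin through the mean of the environment
    points; a genotype's coordinate along it estimates mean
    performance, the signed perpendicular component (along the AOE)
    its instability.  Genotypes are ranked by Euclidean distance to
    the ideal point (on the AEA at the maximum mean projection).
    """
    e_mean = model.env_coords.to_numpy().mean(axis=0)
    norm = float(np.linalg.norm(e_mean))
    if norm == 0:
        raise ValueError("mean environment coordinate is at the origin; AEA undefined")
    aea = e_mean / norm
    perp = np.array([-aea[1], aea[0]])
    G = model.gen_coords.to_numpy()
    mean_proj = G @ aea
    stab = G @ perp
    ideal = aea * mean_proj.max()
    dist = np.linalg.norm(G - ideal, axis=1)
    order = np.argsort(dist, kind="stable")
    rank = np.empty(len(dist), dtype=int)
    rank[order] = np.arange(1, len(dist) + 1)
    table = pd.DataFrame(
        {"mean_proj": mean_proj, "stab_dist": stab, "dist_ideal": dist, "rank": rank},
        index=model.gen_coords.index,
    )
    return AEAProjection(aea, table, ideal)


def rank_genotypes(model: GGEModel) -> pd.Series:
    """Ideal-genotype ranking (1 = closest to ideal)."""
    return mean_vs_stability(model).table["rank"]
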