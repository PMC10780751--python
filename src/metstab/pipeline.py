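"""End-to-end MET analysis pipeline with a reproducible report bundle.

``run_pipeline`` executes the whole chain — ANOVA, AMMI decomposition,
biplot coordinates, GGE which-won-where and mean-vs-stability, WAAS
and the stability-index panel, rank clustering, trait correlations —
and writes every result as a plain-text table plus a JSON manifest
carrying the configuration hash, so identical configurations yield
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ammi, cluster, correlation, gge, stability
from .data import (
    METDataset,
    cell_means,
    classify_environments,
    read_met_table,
    write_ge_matrix,
)
from .simulate import DEFAULT_TRAITS, SimConfig, simulate_met, simulate_traits

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on.

    Exactly one of ``input_path`` (a plot-level CSV) or ``sim`` (a
    :class:`~metstab.simulate.SimConfig`) must be given.
    """

    out_dir: str | Path
    input_path: str | Path | None = None
    schema: dict | None = None
    sim: SimConfig | None = None
    simulate_trait_panel: bool = True
    traits: list[str] | None = None          # secondary traits to correlate
    score_scaling: float = 0.5               # AMMI biplot exponent
    sig_alpha: float = 0.05                  # IPCA significance level
    waas_axes: str | int = "significant"
    gge_scaling: str = "none"
    www_svp: str = "symmetric"
    rank_svp: str = "genotype"
    cluster_k: int = 8
    ward_on_squared: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("give exactly one of input_path or sim")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        if d["input_path"] is not None:
            d["input_path"] = str(d["input_path"])
        return d


def _log(stage: str, t0: float) -> None:
    print(f"metstab: {stage} done in {time.perf_counter() - t0:.2f}s", file=sys.stderr)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; return the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, sep="\t", float_format="%.10g", **kw)
        artifacts[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    t0 = time.perf_counter()
    if cfg.sim is not None:
        data, _truth = simulate_met(cfg.sim)
        if cfg.simulate_trait_panel:
            data = simulate_traits(data, DEFAULT_TRAITS, seed=cfg.seed)
        data.table.to_csv(out / "dataset.csv", index=False)
        artifacts["dataset.csv"] = hashlib.sha256((out / "dataset.csv").read_bytes()).hexdigest()
    else:
        data = read_met_table(cfg.input_path, cfg.schema)
    _log("load/simulate", t0)

    t0 = time.perf_counter()
    m = cell_means(data)
    cls = classify_environments(m)
    write_ge_matrix(m, out / "ge_matrix.tsv")
    artifacts["ge_matrix.tsv"] = hashlib.sha256((out / "ge_matrix.tsv").read_bytes()).hexdigest()

    anova = ammi.joint_anova(data) if data.r >= 2 else None
    if anova is not None:
        save(anova.table, "anova.tsv", index_label="Source")
    model = ammi.fit_ammi(data, score_scaling=cfg.score_scaling, anova=anova)
    save(model.axis_table, "ammi_axes.tsv", index_label="Axis")
    save(ammi.ammi1_coords(model, m).points, "ammi1_coords.tsv", index=False)
    if model.p >= 2:
        save(ammi.ammi2_coords(model).points, "ammi2_coords.tsv", index=False)
    _log("anova+ammi", t0)

    t0 = time.perf_counter()
    www_model = gge.fit_gge(m, scaling=cfg.gge_scaling, svp=cfg.www_svp)
    www = gge.which_won_where(www_model)
    coords = pd.concat(
        [
            www_model.gen_coords.assign(role="genotype"),
            www_model.env_coords.assign(role="environment"),
        ]
    )
    save(coords, "gge_coords.tsv", index_label="label")
    www_json = {
        "hull_vertices": [str(x) for x in www.hull_vertices],
        "sector_of_env": {str(k): v for k, v in www.sector_of_env.items()},
        "winner_of_sector": {str(k): str(v) for k, v in www.winner_of_sector.items()},
    }
    (out / "www.json").write_text(json.dumps(www_json, indent=1, sort_keys=True) + "\n")
    artifacts["www.json"] = hashlib.sha256((out / "www.json").read_bytes()).hexdigest()

    rank_model = gge.fit_gge(m, scaling=cfg.gge_scaling, svp=cfg.rank_svp)
    proj = gge.mean_vs_stability(rank_model)
    save(proj.table, "gge_ranking.tsv", index_label="GEN")
    _log("gge", t0)

    t0 = time.perf_counter()
    tab = stability.stability_table(
        m, model=model, anova=anova, cls=cls, n_axes=cfg.waas_axes
    )
    save(tab.combined(), "stability.tsv", index_label="GEN")
    quads = stability.gy_waas_quadrants(
        m.gen_means,
        tab.values["WAAS"],
        m.env_means,
        stability.env_waas(model, cfg.waas_axes),
    )
    save(
        pd.concat(
            [
                quads.genotypes.to_frame().assign(role="genotype"),
                quads.environments.to_frame().assign(role="environment"),
            ]
        ),
        "quadrants.tsv",
        index_label="label",
    )
    _log("stability", t0)

    t0 = time.perf_counter()
    dist = cluster.rank_distance(tab.ranks)
    if not cfg.ward_on_squared:
        dist = np.sqrt(dist)
    dendro = cluster.ward_cluster(dist)
    k = min(cfg.cluster_k, data.g)
    labels = cluster.cut_clusters(dendro, k)
    save(labels.to_frame(), "clusters.tsv", index_label="GEN")
    merges = pd.DataFrame(dendro.merges, columns=["node_a", "node_b", "height", "size"])
    save(merges, "cluster_merges.tsv", index=False)
    (out / "dendrogram.nwk").write_text(cluster.to_newick(dendro) + "\n")
    artifacts["dendrogram.nwk"] = hashlib.sha256((out / "dendrogram.nwk").read_bytes()).hexdigest()
    _log("cluster", t0)

    t0 = time.perf_counter()
    trait_cols = cfg.traits if cfg.traits is not None else [
        t for t in data.traits if t != "yield"
    ]
    if trait_cols:
        corr = correlation.spearman_matrix(data, trait_cols, scope="pooled")
        save(corr.rho, "correlation_rho.tsv", index_label="trait")
        save(corr.p, "correlation_p.tsv", index_label="trait")
        (out / "correlation_starred.txt").write_text(corr.formatted().to_string() + "\n")
        artifacts["correlation_starred.txt"] = hashlib.sha256(
            (out / "correlation_starred.txt").read_bytes()
        ).hexdigest()
    _log("correlation", t0)

    cfg_dict = cfg.to_dict()
    manifest = {
        "package": "metstab",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "g": data.g,
        "e": data.e,
        "r": data.r,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
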