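"""Balanced multi-environment trial (MET) data containers and readers.

A MET evaluates *g* genotypes in *e* environments (location x year
combinations) in a randomized complete block design (RCBD) with *r*
replicates per environment.  Everything downstream (the additive-main-
effects ANOVA, the multiplicative interaction decomposition, the GGE
biplot geometry and the stability-index panel) consumes either the
plot-level long table held by :class:`METDataset` or the genotype x
environment cell-means matrix held by :class:`GEMatrix`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "METDataset",
    "GEMatrix",
    "EnvClassification",
    "SchemaError",
    "BalanceError",
    "read_met_table",
    "write_met_table",
    "cell_means",
    "classify_environments",
    "write_ge_matrix",
    "CANONICAL_COLUMNS",
]

#: canonical column names of the long-format plot table
CANONICAL_COLUMNS = {
    "env": "ENV",
    "gen": "GEN",
    "rep": "REP",
    "yield": "YLD",
}

#: canonical names for the optional secondary traits
CANONICAL_TRAITS = ("PL", "NPP", "TG", "ST")


class SchemaError(ValueError):
    """A required column is missing or a value cannot be parsed."""


class BalanceError(ValueError):
    """The replicate structure is not a complete balanced RCBD."""


@dataclasses.dataclass(frozen=True)
class METDataset:
    """Plot-level records of a balanced MET.

    Parameters
    ----------
    table
        Long-format DataFrame with columns ``env``, ``gen``, ``rep``,
        ``yield`` and one column per secondary trait.  Every
        (environment, genotype) cell must contain exactly ``r``
        replicates and yields must be finite and non-negative.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        for col in ("env", "gen", "rep", "yield"):
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        y = pd.to_numeric(df["yield"], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(y.to_numpy(dtype=float)))
        if bad.size:
            raise SchemaError(f"non-numeric or non-finite yield at row {bad[0]}")
        if (y < 0).any():
            raise SchemaError("negative yield values are not allowed")

        counts = df.groupby(["env", "gen"], sort=False, observed=True).size()
        r = int(counts.iloc[0])
        off = counts[counts != r]
        if len(off):
            env, gen = off.index[0]
            raise BalanceError(
                f"cell (env={env!r}, gen={gen!r}) has {int(off.iloc[0])} "
                f"replicates, expected {r}"
            )
        g = df["gen"].nunique()
        e = df["env"].nunique()
        if len(counts) != g * e:
            # some (env, gen) combination absent entirely
            full = pd.MultiIndex.from_product(
                [df["env"].unique(), df["gen"].unique()], names=["env", "gen"]
            )
            missing = full.difference(counts.index)
            env, gen = missing[0]
            raise BalanceError(f"cell (env={env!r}, gen={gen!r}) is missing entirely")
        dup = df.duplicated(subset=["env", "gen", "rep"])
        if dup.any():
            row = df[dup].iloc[0]
            raise BalanceError(
                f"duplicate plot (env={row['env']!r}, gen={row['gen']!r}, "
                f"rep={row['rep']!r})"
            )
        if g < 3:
            raise SchemaError(f"need at least 3 genotypes, got {g}")
        if e < 2:
            raise SchemaError(f"need at least 2 environments, got {e}")

    @property
    def g(self) -> int:
        return self.table["gen"].nunique()

    @property
    def e(self) -> int:
        return self.table["env"].nunique()

    @property
    def r(self) -> int:
        return len(self.table) // (self.g * self.e)

    @property
    def genotypes(self) -> list:
        return list(pd.unique(self.table["gen"]))

    @property
    def environments(self) -> list:
        return list(pd.unique(self.table["env"]))

    @property
    def traits(self) -> list[str]:
        skip = {"env", "gen", "rep"}
        return [c for c in self.table.columns if c not in skip]

    def __len__(self) -> int:
        return len(self.table)


@dataclasses.dataclass(frozen=True)
class GEMatrix:
    """Genotype x environment cell-means matrix with marginal means.

    ``values`` is a DataFrame indexed by genotype with one column per
    environment.  The marginal means are derived properties, so the
    invariant (row/column/grand means consistent with the body of the
    matrix) holds by construction.
    """

    values: pd.DataFrame

    @property
    def gen_means(self) -> pd.Series:
        return self.values.mean(axis=1)

    @property
    def env_means(self) -> pd.Series:
        return self.values.mean(axis=0)

    @property
    def grand_mean(self) -> float:
        return float(self.values.to_numpy().mean())

    @property
    def g(self) -> int:
        return self.values.shape[0]

    @property
    def e(self) -> int:
        return self.values.shape[1]

    @property
    def genotypes(self) -> list:
        return list(self.values.index)

    @property
    def environments(self) -> list:
        return list(self.values.columns)


@dataclasses.dataclass(frozen=True)
class EnvClassification:
    """Per-environment favorability label.

    An environment is *favorable* when its mean yield exceeds the grand
    mean, otherwise *unfavorable* (exact ties go to unfavorable, for
    determinism).  The split drives the favorable/unfavorable variants
    of the Annicchiarico reliability index and the Lin & Binns
    superiority index.
    """

    labels: pd.Series  # env -> "favorable" | "unfavorable"

    @property
    def favorable(self) -> list:
        return list(self.labels.index[self.labels == "favorable"])

    @property
    def unfavorable(self) -> list:
        return list(self.labels.index[self.labels == "unfavorable"])


def read_met_table(path, schema: dict | None = None, impute: bool = False) -> METDataset:
    """Read a plot-level MET CSV into a validated :class:`METDataset`.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Mapping from internal names (``env``, ``gen``, ``rep``,
        ``yield``) to the column names used in the file; defaults to
        the canonical ``ENV,GEN,REP,YLD`` convention.  Columns not
        named in the schema are carried along as secondary traits.
        May also be a path to a JSON/YAML file holding the mapping.
    impute
        By default an incomplete table is rejected (the interaction
        decomposition requires a complete two-way table).  With
        ``impute=True`` a missing plot is filled with the mean of the
        remaining replicates of its cell, and a wholly missing cell
        with the additive expectation ``mu + alpha_g + beta_e``; every
        imputation is reported on stderr.
    """
    if isinstance(schema, (str, Path)):
        schema = _load_schema_file(schema)
    colmap = dict(CANONICAL_COLUMNS)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, float_precision="round_trip")
    rename = {}
    for internal, external in colmap.items():
        if external not in df.columns:
            raise SchemaError(
                f"column {external!r} (for {internal!r}) not found in {path}"
            )
        rename[external] = internal
    df = df.rename(columns=rename)
    for col in df.columns:
        if col not in ("env", "gen", "rep"):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                bad = pd.to_numeric(df[col], errors="coerce")
                row = int(np.flatnonzero(bad.isna() & df[col].notna())[0])
                raise SchemaError(
                    f"non-numeric value in column {col!r} at data row {row}"
                ) from exc
    if impute:
        df = _impute_balanced(df)
    return METDataset(df)


def _impute_balanced(df: pd.DataFrame) -> pd.DataFrame:
    """Fill missing plots/cells so the table becomes a balanced RCBD."""
    import sys

    envs = list(pd.unique(df["env"]))
    gens = list(pd.unique(df["gen"]))
    counts = df.groupby(["env", "gen"], sort=False, observed=True).size()
    r = int(counts.max())
    reps = list(pd.unique(df["rep"]))[:r]
    grand = df["yield"].mean()
    a = df.groupby("gen", observed=True)["yield"].mean() - grand
    b = df.groupby("env", observed=True)["yield"].mean() - grand
    value_cols = [c for c in df.columns if c not in ("env", "gen", "rep")]
    rows = []
    for env in envs:
        for gen in gens:
            sub = df[(df["env"] == env) & (df["gen"] == gen)]
            need = r - len(sub)
            if need == 0:
                continue
            if len(sub):
                fill = {c: sub[c].mean() for c in value_cols}
                how = "cell mean of remaining reps"
            else:
                fill = {c: np.nan for c in value_cols}
                fill["yield"] = grand + a.get(gen, 0.0) + b.get(env, 0.0)
                how = "additive expectation mu+alpha+beta"
            have = set(sub["rep"])
            for rep in [x for x in reps if x not in have][:need]:
                print(
                    f"metstab: imputing plot (env={env!r}, gen={gen!r}, "
                    f"rep={rep!r}) with {how}",
                    file=sys.stderr,
                )
                rows.append({"env": env, "gen": gen, "rep": rep, **fill})
    if rows:
        df = pd.concat([df, pd.DataFrame(rows)], ignore_index=True)
    return df


def write_met_table(data: METDataset, path, schema: dict | None = None) -> None:
    """Write a :class:`METDataset` back to the canonical CSV dialect."""
    colmap = dict(CANONICAL_COLUMNS)
    if schema:
        colmap.update(schema)
    out = data.table.rename(columns={k: v for k, v in colmap.items()})
    out.to_csv(path, index=False)


def _load_schema_file(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def cell_means(data: METDataset, trait: str = "yield") -> GEMatrix:
    """Average replicates into the genotype x environment means matrix."""
    if trait not in data.table.columns:
        raise KeyError(f"unknown trait {trait!r}; have {data.traits}")
    wide = (
        data.table.pivot_table(
            index="gen", columns="env", values=trait, aggfunc="mean", sort=False
        )
        .reindex(index=data.genotypes, columns=data.environments)
    )
    return GEMatrix(wide)


def classify_environments(m: GEMatrix) -> EnvClassification:
    """Label each environment favorable/unfavorable against the grand mean."""
    grand = m.grand_mean
    labels = pd.Series(
        np.where(m.env_means.to_numpy() > grand, "favorable", "unfavorable"),
        index=m.values.columns,
        name="favorability",
    )
    return EnvClassification(labels)


def write_ge_matrix(m: GEMatrix, path) -> None:
    """Write the means matrix as TSV with marginal means appended."""
    out = m.values.copy()
    out["GEN_MEAN"] = m.gen_means
    bottom = m.env_means.copy()
    bottom["GEN_MEAN"] = m.grand_mean
    out.loc["ENV_MEAN"] = bottom
    out.to_csv(path, sep="\t", index_label="GEN")
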