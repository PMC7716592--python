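"""Readers, writers, run configuration and the reproducibility manifest.

Everything on disk is plain delimited text or JSON: the mortality counts are
long-format CSV (``area_id, age_lower, deaths, population``), adjacency is
an edge list or GAL-style file, posterior draws go to one CSV per chain with
a JSON metadata sidecar, and indicator tables round-trip losslessly with
infinite life expectancies carried by an explicit flag column rather than a
numeric sentinel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .indicators import AgeAtDeathRule
from .mcmc import McmcConfig, PosteriorDraws
from .model import MortalityTable, PriorConfig

__all__ = [
    "RunConfig",
    "read_counts",
    "write_counts",
    "write_edges",
    "write_indicators",
    "read_indicators",
    "save_draws",
    "load_draws",
    "write_manifest",
]

COUNT_COLUMNS = ["area_id", "age_lower", "deaths", "population"]


@dataclass
class RunConfig:
    """Run configuration: paths, age grid, period length and model settings."""

    counts: str | None = None
    edges: str | None = None
    reference_population: str | None = None
    out_dir: str = "."
    age_lowers: Sequence[float] = ()
    T: float = 1.0
    priors: PriorConfig = field(default_factory=PriorConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    age_rule: AgeAtDeathRule = field(default_factory=AgeAtDeathRule)
    indicators: Sequence[str] = ("sPoD", "sASR", "sLE")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "priors" in kwargs:
            kwargs["priors"] = PriorConfig(**kwargs["priors"])
        if "mcmc" in kwargs:
            kwargs["mcmc"] = McmcConfig(**kwargs["mcmc"])
        if "age_rule" in kwargs:
            kwargs["age_rule"] = AgeAtDeathRule(**kwargs["age_rule"])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["age_lowers"] = list(map(float, self.age_lowers))
        out["indicators"] = list(self.indicators)
        return out


def read_counts(
    path: str | Path, age_lowers: Sequence[float], T: float = 1.0
) -> MortalityTable:
    """Read a long-format counts file into dense (S, A) arrays.

    Area order follows first appearance in the file; the age grid must match
    ``age_lowers`` exactly.  Missing or duplicated (area, age) cells are
    errors, never imputed.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"counts file lacks columns {missing_cols}")
    lowers = [float(x) for x in age_lowers]
    df["age_lower"] = df["age_lower"].astype(float)
    file_ages = sorted(df["age_lower"].unique())
    if file_ages != sorted(lowers):
        raise ValueError(
            f"age grid mismatch: config {sorted(lowers)} vs file {file_ages}"
        )
    area_ids = list(dict.fromkeys(df["area_id"]))
    dup = df.duplicated(subset=["area_id", "age_lower"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicated cell for area {row['area_id']!r}, age_lower {row['age_lower']}"
        )
    S, A = len(area_ids), len(lowers)
    pivot = df.set_index(["area_id", "age_lower"])
    Y = np.zeros((S, A))
    N = np.zeros((S, A))
    for i, aid in enumerate(area_ids):
        for j, lo in enumerate(lowers):
            try:
                row = pivot.loc[(aid, lo)]
            except KeyError:
                raise ValueError(f"missing cell for area {aid!r}, age_lower {lo:g}") from None
            Y[i, j] = row["deaths"]
            N[i, j] = row["population"]
    return MortalityTable(area_ids=tuple(area_ids), age_lowers=tuple(lowers), Y=Y, N=N, T=T)


def write_counts(table: MortalityTable, path: str | Path) -> None:
    rows = [
        {
            "area_id": aid,
            "age_lower": lo,
            "deaths": int(table.Y[i, j]),
            "population": int(table.N[i, j]),
        }
        for i, aid in enumerate(table.area_ids)
        for j, lo in enumerate(table.age_lowers)
    ]
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, index=False)


def write_edges(graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("from,to\n")
        for a, b in graph.edges():
            fh.write(f"{a},{b}\n")


def write_indicators(table: pd.DataFrame, path: str | Path) -> None:
    """Write an indicator table; infinite values travel as the flag column."""
    out = table.copy()
    out["flag_infinite"] = out["flag_infinite"].astype(bool)
    out.to_csv(path, index=False, float_format="%.12g")


def read_indicators(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "flag_infinite" in df.columns:
        df["flag_infinite"] = df["flag_infinite"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# posterior draw persistence


def save_draws(draws: PosteriorDraws, out_dir: str | Path) -> None:
    """Persist draws as one CSV per chain plus a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names, columns = _draw_columns(draws)
    for c in range(draws.n_chains):
        mat = np.column_stack([arr[c].reshape(draws.n_draws, -1) for arr in columns])
        pd.DataFrame(mat, columns=names).to_csv(out / f"chain_{c}.csv", index=False)
    meta = {
        "area_ids": list(draws.area_ids),
        "age_lowers": list(draws.age_lowers),
        "priors": dataclasses.asdict(draws.priors),
        "config": dataclasses.asdict(draws.config),
        "runtime_seconds": draws.runtime_seconds,
        "n_gamma": draws.gamma.shape[2],
        "version": _pkg_version,
    }
    (out / "draws_meta.json").write_text(json.dumps(meta, indent=2))


def _draw_columns(draws: PosteriorDraws):
    names: list[str] = []
    arrays: list[np.ndarray] = []
    A = len(draws.age_lowers)
    names += [f"mu[{lo:g}]" for lo in draws.age_lowers]
    arrays.append(draws.mu)
    names.append("rho")
    arrays.append(draws.rho[:, :, np.newaxis])
    names.append("sigma")
    arrays.append(draws.sigma[:, :, np.newaxis])
    if draws.gamma.shape[2] == 1:
        names.append("gamma")
    else:
        names += [f"gamma[{lo:g}]" for lo in draws.age_lowers]
    arrays.append(draws.gamma)
    names += [
        f"pstar[{aid}:{lo:g}]" for aid in draws.area_ids for lo in draws.age_lowers
    ]
    arrays.append(draws.pstar.reshape(draws.n_chains, draws.n_draws, -1))
    return names, arrays


def load_draws(out_dir: str | Path) -> PosteriorDraws:
    out = Path(out_dir)
    meta = json.loads((out / "draws_meta.json").read_text())
    config = McmcConfig(**meta["config"])
    priors = PriorConfig(**meta["priors"])
    area_ids = tuple(meta["area_ids"])
    age_lowers = tuple(meta["age_lowers"])
    S, A, G = len(area_ids), len(age_lowers), meta["n_gamma"]
    mats = [
        pd.read_csv(out / f"chain_{c}.csv").to_numpy() for c in range(config.n_chains)
    ]
    stacked = np.stack(mats)  # (C, D, cols)
    D = stacked.shape[1]
    i = 0
    mu = stacked[:, :, i : i + A]
    i += A
    rho = stacked[:, :, i]
    i += 1
    sigma = stacked[:, :, i]
    i += 1
    gamma = stacked[:, :, i : i + G]
    i += G
    pstar = stacked[:, :, i : i + S * A].reshape(len(mats), D, S, A)
    return PosteriorDraws(
        mu=mu,
        rho=rho,
        sigma=sigma,
        gamma=gamma,
        pstar=pstar,
        area_ids=area_ids,
        age_lowers=age_lowers,
        priors=priors,
        config=config,
        runtime_seconds=float(meta.get("runtime_seconds", float("nan"))),
    )


def write_manifest(
    out_dir: str | Path,
    inputs: dict[str, str | Path | None],
    config: dict[str, Any],
    seed: int | None = None,
) -> Path:
    """Write a machine-readable manifest sufficient to re-run bit-identically."""
    hashes = {}
    for name, p in inputs.items():
        if p is None:
            continue
        data = Path(p).read_bytes()
        hashes[name] = {"path": str(p), "sha256": hashlib.sha256(data).hexdigest()}
    manifest = {
        "package": "podsmooth",
        "version": _pkg_version,
        "seed": seed,
        "inputs": hashes,
        "config": config,
    }
    path = Path(out_dir) / "manifest.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
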