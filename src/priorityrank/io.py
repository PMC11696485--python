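"""Readers, writers, run configuration and test-fixture generation.

Tab-separated text is the canonical format (gzip handled transparently by
pandas).  Floats are written with 6 significant digits and a stable column
order, so rewriting the same table is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .density import EffectsTable

__all__ = [
    "InputError",
    "RunConfig",
    "read_effects_table",
    "write_results",
    "read_summary_stats",
    "read_ld_table",
    "make_fixture",
]

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Malformed or missing input data."""


@dataclass
class RunConfig:
    """Serializable run parameters; defaults trace to the method's reference
    settings (histogram of 120 bins, degree-8 basis, Monte-Carlo sizes of
    1e5 resample draws / 2e5 pairs / 500 partners per variable)."""

    input_path: str = ""
    output_path: str = ""
    master_seed: int = 0
    n_bins: int = 120
    degree: int = 8
    m: int = 100_000
    n_pairs: int = 200_000
    k_pairs: int = 500
    fdr_threshold: float = 0.01
    pfdr_threshold: float = 0.001
    r2_clump: float = 0.01
    r2_partner: float = 0.1
    window: int = 1_000_000
    family: str = "normal"
    threads: int = 1

    def __post_init__(self):
        for name in ("n_bins", "degree", "m", "n_pairs", "k_pairs", "threads", "window"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        for name in ("fdr_threshold", "pfdr_threshold", "r2_clump", "r2_partner"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must lie in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _read_table(path, sep="\t"):
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise InputError(f"empty input file: {path}")
    return df


def _require(df, columns, path):
    for col in columns:
        if col not in df.columns:
            raise InputError(f"missing mandatory column {col!r} in {path}")


def read_effects_table(path, sep="\t") -> EffectsTable:
    """Read a delimited effects table with columns id, beta, se (optional p).

    Rows with missing or nonpositive se are dropped with a logged warning
    naming the variable."""
    df = _read_table(path, sep)
    _require(df, ("id", "beta", "se"), path)
    return EffectsTable.from_frame(df)


def write_results(df: pd.DataFrame, path) -> None:
    """Write a results table as TSV with floats at 6 significant digits."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)


def read_summary_stats(path, sep="\t") -> pd.DataFrame:
    """Read GWAS summary statistics (chrom, pos, id, beta, se, p, ...)."""
    df = _read_table(path, sep)
    _require(df, ("chrom", "pos", "id", "beta", "se", "p"), path)
    bad = ~(df["p"] > 0) | (df["p"] > 1)
    if bad.any():
        raise InputError(f"{int(bad.sum())} rows with p outside (0, 1] in {path}")
    return df


def read_ld_table(path, sep="\t") -> pd.DataFrame:
    """Read a PLINK-style LD table; columns SNP_A/SNP_B/R2 or id_a/id_b/r2."""
    df = _read_table(path, sep)
    rename = {"SNP_A": "id_a", "SNP_B": "id_b", "R2": "r2"}
    df = df.rename(columns=rename)
    _require(df, ("id_a", "id_b", "r2"), path)
    return df


# ---------------------------------------------------------------------------
# fixtures


def make_fixture(kind: str, seed: int, size: int, outdir) -> list:
    """Write small deterministic fixture files for tests.

    kind="effects": one TSV drawn from a random simulated architecture.
    kind="summary_stats": summary stats with planted LD-clustered signals.
    kind="ld": the matching symmetric LD pair table (within 1 Mb).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import simulate
    from .io import write_results as _write

    rng = np.random.default_rng(seed)
    written = []
    if kind == "effects":
        arch = simulate.draw_architecture(seed)
        data = simulate.draw_dataset(arch, n=size, seed=seed + 1)
        df = data.to_frame()[["id", "beta", "se"]]
        path = outdir / f"effects_{seed}_{size}.tsv"
        _write(df, path)
        written.append(path)
    elif kind in ("summary_stats", "ld"):
        stats_path = outdir / f"sumstats_{seed}_{size}.tsv"
        ld_path = outdir / f"ld_{seed}_{size}.tsv"
        stats_df, ld_df = _planted_clusters(rng, size)
        _write(stats_df, stats_path)
        _write(ld_df, ld_path)
        written += [stats_path, ld_path]
    else:
        raise InputError(f"unknown fixture kind {kind!r}")
    return written


def _planted_clusters(rng, size, n_clusters=2, cluster_span=50_000):
    """Summary stats with n_clusters planted significant LD clusters plus
    background null variants; returns (stats_df, ld_pairs_df)."""
    rows = []
    pairs = []
    vid = 0
    for k in range(n_clusters):
        base = 1_000_000 + k * 3_000_000
        m = 5
        ids = [f"c{k}_{j}" for j in range(m)]
        for j in range(m):
            p = 10 ** (-12 + 2 * j + rng.uniform(0, 0.5))
            rows.append(("1", base + j * (cluster_span // m), ids[j],
                         0.2 + 0.02 * j, 0.03, p, 0.001))
        for a in range(m):
            for b in range(a + 1, m):
                pairs.append((ids[a], ids[b], 0.5))
    n_bg = max(size - len(rows), 0)
    for j in range(n_bg):
        rows.append(("2", 1_000_000 + j * 10_000, f"bg{vid}",
                     float(rng.normal(0, 0.02)), 0.03,
                     float(rng.uniform(0.05, 1.0)), 0.9))
        vid += 1
    stats_df = pd.DataFrame(rows, columns=["chrom", "pos", "id", "beta", "se", "p", "fdr_tail"])
    ld_df = pd.DataFrame(pairs, columns=["id_a", "id_b", "r2"])
    return stats_df, ld_df
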