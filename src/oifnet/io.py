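"""File I/O: time-series tables, network exports, run configuration.

Tables are comma- or tab-separated text with a mandatory header of unique
variable names; an optional leading time column is recognized by header
name ("time", "t", "date", "index", case-insensitive). Missing values are
rejected with row/column diagnostics rather than imputed -- every
estimator downstream assumes complete series.

Networks are written as labeled CSV matrices, directed weighted edge
lists (zeros implicit; the node set is carried in a comment line so the
round trip is exact), or GraphML via networkx.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .exceptions import OifError
from .networks import InteractionMatrix
from .timeseries import TimeSeriesSet

__all__ = [
    "RunConfig",
    "read_timeseries_table",
    "write_timeseries_table",
    "write_network",
    "read_edge_list",
]

_TIME_NAMES = {"time", "t", "date", "index"}


def read_timeseries_table(path, dialect: str | None = None) -> TimeSeriesSet:
    """Read a CSV/TSV abundance table into a :class:`TimeSeriesSet`.

    ``dialect`` is ``"csv"``, ``"tsv"`` or None (auto-detect from the
    header line). At least two variable columns are required for pairwise
    inference.
    """
    path = Path(path)
    if not path.exists():
        raise OifError(f"no such file: {path}")
    if dialect is None:
        header = path.open().readline()
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    else:
        sep = {"csv": ",", "tsv": "\t"}.get(dialect)
        if sep is None:
            raise ValueError("dialect must be 'csv' or 'tsv'")
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as err:  # parse errors carry pandas' location info
        raise OifError(f"cannot parse {path}: {err}") from err
    raw_names = [str(c) for c in df.columns]
    if len(set(raw_names)) != len(raw_names) or any(
        c.endswith(".1") and c[:-2] in raw_names for c in raw_names
    ):
        raise OifError(f"duplicate column names in {path}")
    if raw_names and raw_names[0].strip().lower() in _TIME_NAMES:
        df = df.drop(columns=raw_names[0])
    if df.shape[1] < 2:
        raise OifError("need at least 2 variable columns for pairwise inference")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise OifError(
                f"non-numeric cell at row {row + 2}, column {col!r}: {df[col][row]!r}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise OifError(f"missing value at row {row + 2}, column {col!r}")
        df[col] = numeric
    return TimeSeriesSet.from_frame(df)


def write_timeseries_table(ts: TimeSeriesSet, path, dialect: str = "csv", time_index: bool = True) -> None:
    """Write a time-series table; inverse of :func:`read_timeseries_table`."""
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError("dialect must be 'csv' or 'tsv'")
    df = ts.to_frame()
    if time_index:
        df.insert(0, "time", np.arange(ts.length))
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_network(m: InteractionMatrix, path, format: str = "matrix") -> None:
    """Write an interaction matrix as ``matrix`` CSV, ``edgelist`` or ``graphml``."""
    path = Path(path)
    if format == "matrix":
        pd.DataFrame(m.values, index=m.species_names, columns=m.species_names).to_csv(path)
    elif format == "edgelist":
        delays = m.delay_used if isinstance(m.delay_used, np.ndarray) else None
        with path.open("w") as fh:
            fh.write(f"# nodes: {','.join(m.species_names)}\n")
            fh.write(f"# method: {m.method} normalized: {m.normalized}\n")
            fh.write("source,target,weight,delay\n")
            for i, si in enumerate(m.species_names):
                for j, sj in enumerate(m.species_names):
                    if i == j or m.values[i, j] == 0.0:
                        continue
                    u = delays[i, j] if delays is not None else (
                        m.delay_used if m.delay_used is not None else ""
                    )
                    fh.write(f"{si},{sj},{float(m.values[i, j])!r},{u}\n")
    elif format == "graphml":
        G = nx.DiGraph()
        G.add_nodes_from(m.species_names)
        for i, si in enumerate(m.species_names):
            for j, sj in enumerate(m.species_names):
                if i != j and m.values[i, j] != 0.0:
                    G.add_edge(si, sj, weight=float(m.values[i, j]))
        nx.write_graphml(G, path)
    else:
        raise ValueError("format must be matrix | edgelist | graphml")


def read_edge_list(path, method: str = "te") -> InteractionMatrix:
    """Reconstruct a matrix from an edge list written by :func:`write_network`.

    Absent edges are zeros; the node set comes from the ``# nodes:``
    comment line, so isolated species survive the round trip.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# nodes:"):
        raise OifError(f"{path} is not an oifnet edge list (missing '# nodes:' line)")
    names = lines[0].split(":", 1)[1].strip().split(",")
    normalized = False
    if len(lines) > 1 and lines[1].startswith("# method:"):
        parts = lines[1].split()
        method = parts[2]
        normalized = parts[-1] == "True"
    body = [ln for ln in lines if not ln.startswith("#")]
    vals = np.zeros((len(names), len(names)))
    delays = np.zeros((len(names), len(names)), dtype=int)
    any_delay = False
    for ln in body[1:]:  # skip header row
        if not ln.strip():
            continue
        src, tgt, w, *rest = ln.split(",")
        i, j = names.index(src), names.index(tgt)
        vals[i, j] = float(w)
        if rest and rest[0] != "":
            delays[i, j] = int(rest[0])
            any_delay = True
    return InteractionMatrix(
        vals, method, names, normalized=normalized,
        delay_used=delays if any_delay else None,
    )


@dataclass
class RunConfig:
    """Everything a run needs, serializable to one YAML file.

    A run re-executed from its archived config reproduces outputs bitwise
    for deterministic methods (and for stochastic ones via the seed).
    """

    command: str = "infer"
    input: str | None = None
    method: str = "te"
    # estimator
    r: float = 0.25
    k: int = 1
    l: int = 1
    u: int = 1
    log_base: float = 2.0
    estimator_kind: str = "histogram"
    te_correction: str = "shuffle"
    mi_correction: str = "mm"
    n_surrogates: int = 10
    # embedding
    E: int | None = None
    tau: int = 1
    theiler: int = 0
    # networks / diversity
    g: int = 30
    window_mode: str = "expanding"
    step: int = 1
    delay_policy: str = "fixed"
    theta_grid: list[float] = field(
        default_factory=lambda: [round(0.05 * i, 2) for i in range(21)]
    )
    criterion: str = "corr"
    # run
    seed: int = 0
    outdir: str = "oifnet_out"
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise OifError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def estimator_config(self):
        from .estimators import EstimatorConfig

        return EstimatorConfig(
            r=self.r, k=self.k, l=self.l, u=self.u, log_base=self.log_base,
            estimator_kind=self.estimator_kind, te_correction=self.te_correction,
            mi_correction=self.mi_correction, n_surrogates=self.n_surrogates,
            surrogate_seed=self.seed,
        )

    def embedding_config(self):
        from .ccm import EmbeddingConfig

        return EmbeddingConfig(E=self.E or 2, tau=self.tau, theiler=self.theiler)
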