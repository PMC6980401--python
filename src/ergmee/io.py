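"""Readers and writers: Pajek arc lists, plain edge lists, attribute
tables, the key=value configuration format, and output tables.

Node ids are 1-based in Pajek files and 0-based in memory.  Self-loops in
input files are dropped with a warning; duplicate arcs are deduplicated.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .graph import AttributeSet, DirectedGraph
from .effects import EffectSpec, ModelSpec

logger = logging.getLogger("ergmee")

__all__ = [
    "read_pajek", "write_pajek", "read_edge_list", "write_edge_list",
    "read_attributes", "parse_effect_list", "EstimationConfig", "read_config",
    "write_estimates_table",
]


def _add_clean(g: DirectedGraph, i: int, j: int, dropped: list) -> None:
    if i == j:
        dropped.append(("self-loop", i, j))
        return
    if g.has_arc(i, j):
        dropped.append(("duplicate", i, j))
        return
    g.add_arc(i, j)


def read_pajek(path) -> DirectedGraph:
    """Read a Pajek network file (``*Vertices`` then ``*Arcs``/``*Edges``).

    Ids are shifted to 0-based; ``*Edges`` pairs are expanded to both
    directions.
    """
    path = Path(path)
    n_nodes = None
    g: Optional[DirectedGraph] = None
    mode = None
    dropped: list = []
    with path.open() as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                parts = line.split()
                if len(parts) < 2 or not parts[1].isdigit():
                    raise ValueError(f"{path}:{ln}: malformed *Vertices header")
                n_nodes = int(parts[1])
                g = DirectedGraph(n_nodes)
                mode = "vertices"
                continue
            if low.startswith("*arcs") or low.startswith("*edges"):
                if g is None:
                    raise ValueError(f"{path}: missing *Vertices header")
                mode = "arcs" if low.startswith("*arcs") else "edges"
                continue
            if low.startswith("*"):
                mode = "skip"
                continue
            if mode == "vertices" or mode == "skip" or mode is None:
                if mode is None:
                    raise ValueError(f"{path}: missing *Vertices header")
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected an id pair")
            i, j = int(parts[0]), int(parts[1])
            if not (1 <= i <= n_nodes and 1 <= j <= n_nodes):
                raise ValueError(f"{path}:{ln}: id out of range 1..{n_nodes}")
            if mode == "arcs":
                _add_clean(g, i - 1, j - 1, dropped)
            else:
                _add_clean(g, i - 1, j - 1, dropped)
                if i != j:
                    _add_clean(g, j - 1, i - 1, dropped)
    if g is None:
        raise ValueError(f"{path}: missing *Vertices header")
    for kind, i, j in dropped:
        logger.warning("%s: dropped %s arc (%d, %d)", path, kind, i + 1, j + 1)
    return g


def write_pajek(path, g: DirectedGraph) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"*Vertices {g.n_nodes}\n*Arcs\n")
        for (i, j) in sorted(g.arc_list):
            fh.write(f"{i + 1} {j + 1}\n")


def read_edge_list(path, delimiter: Optional[str] = None) -> DirectedGraph:
    """Two-column integer edge list; ``#`` comment lines skipped; arbitrary
    integer ids remapped to dense 0-based ids (sorted order)."""
    pairs: list[tuple[int, int]] = []
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two columns")
            try:
                pairs.append((int(parts[0]), int(parts[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer token") from exc
    ids = sorted({x for p in pairs for x in p})
    remap = {x: k for k, x in enumerate(ids)}
    g = DirectedGraph(max(len(ids), 1))
    dropped: list = []
    for (i, j) in pairs:
        _add_clean(g, remap[i], remap[j], dropped)
    for kind, i, j in dropped:
        logger.warning("%s: dropped %s arc (%d, %d)", path, kind, i, j)
    return g


def write_edge_list(path, g: DirectedGraph, delimiter: str = " ") -> None:
    with Path(path).open("w") as fh:
        for (i, j) in sorted(g.arc_list):
            fh.write(f"{i}{delimiter}{j}\n")


def read_attributes(path, kind: str, n_nodes: int,
                    attrs: Optional[AttributeSet] = None) -> AttributeSet:
    """Whitespace-delimited attribute table with a header, one row per
    node in id order; ``NA`` marks missing values."""
    if kind not in ("binary", "categorical", "continuous"):
        raise ValueError(f"unknown attribute kind {kind!r}")
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    if len(df) != n_nodes:
        raise ValueError(
            f"{path}: {len(df)} rows but the network has {n_nodes} nodes")
    if attrs is None:
        attrs = AttributeSet.empty(n_nodes)
    for col in df.columns:
        v = df[col].to_numpy(dtype=np.float64)
        if kind == "binary":
            attrs.add_binary(col, v)
        elif kind == "continuous":
            attrs.add_continuous(col, v)
        else:
            iv = np.where(np.isnan(v), -1, v).astype(np.int64)
            if not np.array_equal(iv[iv >= 0],
                                  v[~np.isnan(v)].astype(np.int64)):
                raise ValueError(f"{path}: non-integer categorical code")
            attrs.add_categorical(col, iv)
    return attrs


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_EFFECT_RE = re.compile(r"^([A-Za-z0-9_-]+)(?:\(([^)]*)\))?$")


def parse_effect_list(text: str) -> ModelSpec:
    """Parse e.g. ``Arc, Reciprocity, AinS(lambda=2), Sender(attr=gender)``."""
    effects = []
    for item in re.split(r",(?![^(]*\))", text):
        item = item.strip()
        if not item:
            continue
        m = _EFFECT_RE.match(item)
        if not m:
            raise ValueError(f"malformed effect spec {item!r}")
        name, argtext = m.group(1), m.group(2)
        lam = None
        attr = None
        if argtext:
            for arg in argtext.split(";"):
                if not arg.strip():
                    continue
                k, _, val = arg.partition("=")
                k, val = k.strip(), val.strip()
                if k == "lambda":
                    lam = float(val)
                elif k == "attr":
                    attr = val
                else:
                    raise ValueError(f"unknown effect argument {k!r} in {item!r}")
        effects.append(EffectSpec(name, lam=lam, attr=attr))
    return ModelSpec(effects)


@dataclass
class EstimationConfig:
    """Resolved contents of a key=value configuration file."""

    network: str
    model: ModelSpec
    attrs_binary: Optional[str] = None
    attrs_categorical: Optional[str] = None
    attrs_continuous: Optional[str] = None
    network_format: str = "pajek"        # "pajek" | "edgelist"
    sampler: str = "basic"
    ee_steps: int = 1000
    steps_per_update: int = 1000
    cd_steps: int = 500
    cd_updates: int = 100
    learning_rate: float = 0.01
    cd_learning_rate: float = 0.1
    theta_min: float = 0.01
    ifd_adapt_rate: float = 0.01
    n_runs: int = 8
    seed: int = 0
    extra: dict = field(default_factory=dict)


_INT_KEYS = {"ee_steps", "steps_per_update", "cd_steps", "cd_updates",
             "n_runs", "seed"}
_FLOAT_KEYS = {"learning_rate", "cd_learning_rate", "theta_min",
               "ifd_adapt_rate"}
_STR_KEYS = {"network", "network_format", "sampler", "attrs_binary",
             "attrs_categorical", "attrs_continuous"}


def read_config(path) -> EstimationConfig:
    """Read a flat ``key = value`` configuration file (# comments)."""
    values: dict = {}
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key = value")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key == "effects":
                values["model"] = parse_effect_list(val)
            elif key in _INT_KEYS:
                values[key] = int(val)
            elif key in _FLOAT_KEYS:
                values[key] = float(val)
            elif key in _STR_KEYS:
                values[key] = val
            else:
                values.setdefault("extra", {})[key] = val
    if "network" not in values:
        raise ValueError(f"{path}: missing 'network' entry")
    if "model" not in values:
        raise ValueError(f"{path}: missing 'effects' entry")
    return EstimationConfig(**values)


def write_estimates_table(path, labels, theta_hat, se,
                          z: float = 1.96) -> None:
    """Estimates table: Effect, Estimate, Std. error, significance star."""
    with Path(path).open("w") as fh:
        fh.write("Effect\tEstimate\tStd.error\t\n")
        for label, th, s in zip(labels, theta_hat, se):
            star = "*" if np.isfinite(s) and abs(th) > z * s else ""
            fh.write(f"{label}\t{th:.4f}\t{s:.4f}\t{star}\n")
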