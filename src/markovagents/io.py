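"""Serialization: kernels (CSV/JSON), graphs (edge-list TSV), permutations
(bracket strings), agents (JSON bundles), and a small TOML config loader.

All user-facing formats use 1-based state labels.  JSON kernel round trips
are bit-exact; CSV round trips are exact to the printed precision (17
significant digits, i.e. float-exact in practice).
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import ConsciousAgent, make_agent
from .decorated import DecoratedPermutation, validate
from .kernels import Kernel, validate_kernel

__all__ = [
    "read_kernel",
    "write_kernel",
    "parse_sigma",
    "format_sigma",
    "read_edge_list",
    "write_edge_list",
    "read_agent",
    "write_agent",
    "load_config",
]


class ParseError(ValueError):
    pass


def _coerce_label(v):
    """Labels serialize as strings; bring pure integers back as ints."""
    if isinstance(v, str):
        try:
            return int(v)
        except ValueError:
            return v
    return v


def read_kernel(path, format: str | None = None, tol_row: float = 1e-9) -> Kernel:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}:{exc.lineno}: invalid JSON: {exc.msg}") from exc
        for key in ("rows", "cols", "matrix"):
            if key not in data:
                raise ParseError(f"{path}: missing key {key!r}")
        rows = tuple(_coerce_label(v) for v in data["rows"])
        cols = tuple(_coerce_label(v) for v in data["cols"])
        return validate_kernel(np.asarray(data["matrix"], dtype=float), rows, cols,
                               tol_row=tol_row)
    if fmt == "csv":
        try:
            frame = pd.read_csv(path, index_col=0)
        except Exception as exc:
            raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
        rows = tuple(_coerce_label(v) for v in frame.index)
        cols = tuple(_coerce_label(v) for v in frame.columns)
        return validate_kernel(frame.to_numpy(dtype=float), rows, cols, tol_row=tol_row)
    raise ValueError(f"unknown kernel format {fmt!r}")


def write_kernel(k: Kernel, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        path.write_text(kernel_to_json(k))
    elif fmt == "csv":
        frame = pd.DataFrame(
            k.matrix.astype(float), index=list(k.row_labels), columns=list(k.col_labels)
        )
        frame.to_csv(path, float_format="%.17g")
    else:
        raise ValueError(f"unknown kernel format {fmt!r}")


def kernel_to_json(k: Kernel) -> str:
    return json.dumps(
        {
            "rows": list(k.row_labels),
            "cols": list(k.col_labels),
            "matrix": [[float(v) for v in row] for row in k.matrix],
        }
    )


def parse_sigma(text: str) -> DecoratedPermutation:
    """Parse a bracket string like "[8,11,4,12,10,15,9,14,16]" (1-based)."""
    s = text.strip()
    if not (s.startswith("[") and s.endswith("]")):
        raise ParseError(f"expected a bracketed permutation, got {text!r}")
    body = s[1:-1].strip()
    if not body:
        raise ParseError("empty permutation")
    images = []
    for tok in body.split(","):
        tok = tok.strip()
        if not tok.lstrip("-").isdigit():
            raise ParseError(f"bad token {tok!r} in {text!r}")
        images.append(int(tok))
    return validate(images)


def format_sigma(sigma: DecoratedPermutation) -> str:
    return str(sigma)


def read_edge_list(path):
    """Directed graph from TSV, one "src<TAB>dst" per line; 1-based labels.
    Isolated nodes may be given as a single-field line."""
    import networkx as nx

    g = nx.DiGraph()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            g.add_node(_coerce_label(parts[0]))
        elif len(parts) == 2:
            g.add_edge(_coerce_label(parts[0]), _coerce_label(parts[1]))
        else:
            raise ParseError(f"{path}:{lineno}: expected 'src<TAB>dst', got {line!r}")
    return g


def write_edge_list(g, path) -> None:
    lines = []
    for u, v in g.edges():
        lines.append(f"{u}\t{v}")
    for node in g.nodes():
        if g.degree(node) == 0:
            lines.append(f"{node}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_agent(agent: ConsciousAgent, path) -> None:
    data = {
        "X": list(agent.X),
        "G": list(agent.G),
        "W": list(agent.W),
        "P": json.loads(kernel_to_json(agent.P)),
        "D": json.loads(kernel_to_json(agent.D)),
        "A": json.loads(kernel_to_json(agent.A)),
    }
    Path(path).write_text(json.dumps(data))


def read_agent(path) -> ConsciousAgent:
    data = json.loads(Path(path).read_text())
    kernels = {}
    for name in ("P", "D", "A"):
        kd = data[name]
        kernels[name] = validate_kernel(
            np.asarray(kd["matrix"], dtype=float),
            tuple(_coerce_label(v) for v in kd["rows"]),
            tuple(_coerce_label(v) for v in kd["cols"]),
        )
    return make_agent(P=kernels["P"], D=kernels["D"], A=kernels["A"])


def load_config(path) -> dict:
    """TOML config with optional keys tol_row, tol_zero, tol_idempotent,
    entropy_base; CLI flags override these."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    allowed = {"tol_row", "tol_zero", "tol_idempotent", "entropy_base"}
    unknown = set(data) - allowed
    if unknown:
        raise ParseError(f"unknown config keys: {sorted(unknown)}")
    return data
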