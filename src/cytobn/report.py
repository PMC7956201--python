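"""Artifact writers: DOT network rendering, TSV tables, run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
import sys

import numpy as np
import pandas as pd

from .bn import BayesianNetwork

__all__ = ["export_dot", "write_manifest"]

HIGHLIGHT_COLOR = "red"          # response / contrast nodes
STRONG_COLOR = "gray25"
WEAK_COLOR = "gray75"


def _sig3(x: float) -> str:
    if x == 0:
        return "0"
    return f"{x:.3g}"


def _quote(name: str) -> str:
    return '"' + str(name).replace('"', r'\"') + '"'


def export_dot(net: BayesianNetwork, highlight=(), strong_nodes=(),
               weak_nodes=()) -> str:
    """Render a network as Graphviz DOT.

    Edge labels are strengths to 3 significant digits; ``highlight`` nodes
    (response/contrast) are filled red, strong/weak neighborhood members
    dark/light grey.
    """
    lines = ["digraph BN {", "  node [shape=ellipse, style=filled, fillcolor=white];"]
    for v in net.nodes:
        attrs = []
        if v in highlight:
            attrs.append(f'fillcolor={HIGHLIGHT_COLOR}, fontcolor=white')
        elif v in strong_nodes:
            attrs.append(f'fillcolor={STRONG_COLOR}, fontcolor=white')
        elif v in weak_nodes:
            attrs.append(f'fillcolor={WEAK_COLOR}')
        lines.append(f"  {_quote(v)}" + (f" [{', '.join(attrs)}]" if attrs else "") + ";")
    for (u, v) in sorted(net.edges()):
        s = net.edge_strengths.get((u, v))
        label = f' [label="{_sig3(s)}"]' if s is not None else ""
        lines.append(f"  {_quote(u)} -> {_quote(v)}{label};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_manifest(path, config: dict, seed: int, inputs=()) -> None:
    """Record everything needed to reproduce a run: config echo, seed,
    versions, and input-file digests."""
    digests = {}
    for p in inputs:
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        digests[str(p)] = h.hexdigest()
    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "platform": platform.platform(),
        },
        "input_digests": digests,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
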