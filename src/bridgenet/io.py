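"""Delimited-text and GraphML round-trips for data, covariates and networks."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .mgm import Network
from .variables import (
    CovariateTable,
    MixedDataMatrix,
    SpecificationError,
    VariableSpec,
)

__all__ = [
    "write_data", "read_data", "write_covariates", "read_covariates",
    "write_edge_list", "read_edge_list", "write_graphml", "read_graphml",
]

_SEP = "\t"


def write_data(data: MixedDataMatrix, path: str | Path) -> None:
    """Data as TSV plus a sidecar ``<path>.vars.json`` with the specs."""
    path = Path(path)
    frame = data.to_frame()
    frame.insert(0, "subject_id", data.subject_ids)
    frame.to_csv(path, sep=_SEP, index=False)
    meta = [
        {"name": s.name, "kind": s.kind, "n_levels": s.n_levels,
         "group": s.group, "index": s.index}
        for s in data.specs
    ]
    Path(str(path) + ".vars.json").write_text(json.dumps(meta, indent=1))


def read_data(path: str | Path) -> MixedDataMatrix:
    path = Path(path)
    meta_path = Path(str(path) + ".vars.json")
    if not meta_path.exists():
        raise SpecificationError(f"missing variable sidecar {meta_path}")
    specs = [VariableSpec(**d) for d in json.loads(meta_path.read_text())]
    frame = pd.read_csv(path, sep=_SEP)
    ids = frame.pop("subject_id").to_numpy()
    data = MixedDataMatrix.from_frame(frame, specs)
    data.subject_ids = ids
    return data


def write_covariates(table: CovariateTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep=_SEP, index=False)


def read_covariates(path: str | Path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path, sep=_SEP))


def write_edge_list(net: Network, path: str | Path) -> None:
    """Tab-delimited node_i / node_j / weight / sign."""
    rows = [f"node_i{_SEP}node_j{_SEP}weight{_SEP}sign"]
    for (a, b), (w, sign) in sorted(net.edges.items()):
        rows.append(f"{a}{_SEP}{b}{_SEP}{w:.10g}{_SEP}{sign}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_edge_list(path: str | Path, nodes: list[VariableSpec]) -> Network:
    net = Network(nodes=list(nodes))
    frame = pd.read_csv(path, sep=_SEP)
    for _, row in frame.iterrows():
        net.add_edge(row["node_i"], row["node_j"], float(row["weight"]), row["sign"])
    return net


def write_graphml(net: Network, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), str(path))


def read_graphml(path: str | Path) -> Network:
    g = nx.read_graphml(str(path))
    specs = [
        VariableSpec(name=n, kind=d["kind"], n_levels=int(d.get("n_levels", 0)),
                     group=d.get("group", "ungrouped"), index=int(d.get("index", k)))
        for k, (n, d) in enumerate(sorted(g.nodes(data=True),
                                          key=lambda nd: int(nd[1].get("index", 0))))
    ]
    net = Network(nodes=specs)
    for a, b, d in g.edges(data=True):
        net.add_edge(a, b, float(d["weight"]), d.get("sign", "undetermined"))
    return net
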