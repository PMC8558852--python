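"""Cohort-difference networks, component census, and lncRNA-mRNA pair extraction.

The difference network keeps the edges present in the case cohort's network
but absent from the comparison cohort's (edge identity is the unordered gene
pair; sign and weight metadata are ignored when differencing).  Its connected
components are censused by size class, its lncRNA-mRNA edges are tabulated
with both genes' fold changes, and antisense partners are flagged from
genomic coordinates (opposite-strand overlap of >= 1 bp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "network_difference",
    "component_census",
    "ComponentCensus",
    "lncrna_mrna_pairs",
    "distinct_mrna_counts",
    "antisense_pairs",
    "export_network",
    "read_network",
]


def _edge_set(g: nx.Graph) -> set[frozenset]:
    return {frozenset((u, v)) for u, v in g.edges}


def network_difference(a: nx.Graph, b: nx.Graph, mode: str = "difference") -> nx.Graph:
    """Edge-set difference (default), intersection, or symmetric difference.

    Nodes of the result are the endpoints of surviving edges; node and edge
    attributes are taken from ``a`` where available, else from ``b``.
    """
    eb = _edge_set(b)
    ea = _edge_set(a)
    if mode == "difference":
        keep = ea - eb
    elif mode == "intersection":
        keep = ea & eb
    elif mode == "symmetric":
        keep = ea ^ eb
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = nx.Graph(**a.graph)
    for pair in keep:
        u, v = tuple(pair)
        src = a if a.has_edge(u, v) else b
        out.add_edge(u, v, **src.get_edge_data(u, v, default={}))
    for n in out.nodes:
        src = a if n in a.nodes else b
        out.nodes[n].update(src.nodes.get(n, {}))
    return out


@dataclass
class ComponentCensus:
    """Connected-component counts by size class plus biotype tallies."""

    n_nodes: int = 0
    n_lncrna: int = 0
    n_mrna: int = 0
    pairs: int = 0
    trios: int = 0
    quartets: int = 0
    quintets: int = 0
    large: list[int] = field(default_factory=list)
    large_min: int = 6

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["large"] = list(self.large)
        return d


def component_census(
    net: nx.Graph, annotation: pd.DataFrame, large_min: int = 6
) -> ComponentCensus:
    """Census the network's connected components by size class."""
    missing = [n for n in net.nodes if n not in annotation.index]
    if missing:
        raise ValueError(f"nodes without annotation: {missing[:10]}")
    census = ComponentCensus(large_min=large_min)
    biotype = annotation["biotype"]
    census.n_nodes = net.number_of_nodes()
    census.n_lncrna = sum(1 for n in net.nodes if biotype[n] == "lncRNA")
    census.n_mrna = census.n_nodes - census.n_lncrna
    sizes = sorted((len(c) for c in nx.connected_components(net)), reverse=True)
    for s in sizes:
        if s == 2:
            census.pairs += 1
        elif s == 3:
            census.trios += 1
        elif s == 4:
            census.quartets += 1
        elif s == 5:
            census.quintets += 1
        if s >= large_min:
            census.large.append(s)
    return census


def lncrna_mrna_pairs(
    net: nx.Graph, annotation: pd.DataFrame, de: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One row per edge joining a lncRNA and an mRNA.

    Fold changes are taken from ``de`` (a table with a log2fc column) when
    given, else from a ``log2fc`` column of the annotation, else NaN.
    """
    def lfc(g: str) -> float:
        if de is not None and g in de.index:
            return float(de.loc[g, "log2fc"])
        if "log2fc" in annotation.columns and g in annotation.index:
            return float(annotation.loc[g, "log2fc"])
        return np.nan

    biotype = annotation["biotype"]
    rows = []
    for u, v in net.edges:
        bu, bv = biotype.get(u), biotype.get(v)
        if {bu, bv} != {"lncRNA", "mRNA"}:
            continue
        lnc, mr = (u, v) if bu == "lncRNA" else (v, u)
        rows.append(
            {
                "lncrna_id": lnc,
                "mrna_id": mr,
                "lncrna_log2fc": lfc(lnc),
                "mrna_log2fc": lfc(mr),
                "antisense": pd.NA,
            }
        )
    cols = ["lncrna_id", "mrna_id", "lncrna_log2fc", "mrna_log2fc", "antisense"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["lncrna_id", "mrna_id"], ignore_index=True
    )


def distinct_mrna_counts(pairs: pd.DataFrame) -> tuple[int, int]:
    """(distinct mRNAs coexpressed with >= 1 lncRNA, those with positive log2fc)."""
    if pairs.empty:
        return 0, 0
    per_mrna = pairs.groupby("mrna_id")["mrna_log2fc"].first()
    return int(per_mrna.size), int((per_mrna > 0).sum())


def antisense_pairs(pairs: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``antisense`` flag: opposite-strand genomic overlap >= 1 bp.

    Genes missing coordinates get a missing flag with a warning rather than
    an error.
    """
    coord_cols = {"chrom", "start", "end", "strand"}
    out = pairs.copy()
    flags = []
    warned = False
    for _, row in out.iterrows():
        ok = all(
            g in annotation.index
            and coord_cols <= set(annotation.columns)
            and pd.notna(annotation.loc[g, "start"])
            for g in (row["lncrna_id"], row["mrna_id"])
        )
        if not ok:
            if not warned:
                warnings.warn("missing coordinates; antisense flag left unknown")
                warned = True
            flags.append(pd.NA)
            continue
        a = annotation.loc[row["lncrna_id"]]
        b = annotation.loc[row["mrna_id"]]
        overlap = (
            a["chrom"] == b["chrom"]
            and int(a["start"]) <= int(b["end"])
            and int(b["start"]) <= int(a["end"])
        )
        flags.append(bool(overlap and a["strand"] != b["strand"]))
    out["antisense"] = pd.array(flags, dtype="boolean")
    return out


# ---------------------------------------------------------------------------
# export


def export_network(net: nx.Graph, path: str | Path, fmt: str | None = None) -> Path:
    """Write a network as SIF (``gene_a  coexp  gene_b``) or GraphML."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "sif":
        lines = [f"{u}\tcoexp\t{v}" for u, v in sorted(map(sorted, net.edges))]
        isolated = sorted(n for n in net.nodes if net.degree(n) == 0)
        lines += isolated
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        g = net.copy()
        for _, d in g.nodes(data=True):
            for k, v in list(d.items()):
                if v is None:
                    del d[k]
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    return path


def read_network(path: str | Path, fmt: str | None = None) -> nx.Graph:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "sif":
        g = nx.Graph()
        for line in path.read_text().splitlines():
            parts = line.split("\t")
            if len(parts) == 1 and parts[0]:
                g.add_node(parts[0])
            elif len(parts) == 3:
                g.add_edge(parts[0], parts[2])
            elif line.strip():
                raise ValueError(f"malformed SIF line: {line!r}")
        return g
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown network format {fmt!r}")
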