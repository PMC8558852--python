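"""Hard-threshold Pearson coexpression networks with data-driven threshold choice.

A similarity matrix of pairwise Pearson correlations is thresholded at
|r| >= tau to give a binary adjacency ("coexpressed or not"); the threshold
is scanned over a grid and chosen where the observed mean clustering
coefficient Co most exceeds the Erdős–Rényi expectation Cr for an equally
dense random graph, subject to the thresholded graph looking scale-free
(R^2 of the log-log degree-frequency fit).  Correlation signs are kept as
edge metadata but play no role in adjacency.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "pearson_similarity",
    "clustering_coefficient",
    "random_expectation_cr",
    "scale_free_fit",
    "threshold_scan",
    "select_threshold",
    "build_network",
    "ThresholdChoice",
    "DEFAULT_TAU_GRID",
]

DEFAULT_TAU_GRID = np.round(np.arange(0.50, 1.00, 0.01), 2)


def pearson_similarity(logcpm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of genes (rows) across samples (columns).

    Genes with zero variance are assigned r = 0 against every other gene
    (with a warning) and r = 1 on the diagonal.
    """
    if logcpm.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    x = logcpm.to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s); correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[np.isnan(r)] = 0.0
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=logcpm.index, columns=logcpm.index)


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.diagonal(a).any():
        raise ValueError("adjacency must have no self-loops")
    return a.astype(bool)


def clustering_coefficient(adj) -> float:
    """Mean local (Watts–Strogatz) clustering coefficient over non-isolated nodes.

    C_i = 2 e_i / (k_i (k_i - 1)) with C_i = 0 when k_i < 2; an edgeless
    graph returns 0.
    """
    a = _check_adjacency(adj).astype(np.int64)
    k = a.sum(axis=1)
    non_iso = k >= 1
    if not non_iso.any():
        return 0.0
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)  # 2 * triangles through i ... actually 2*e_i*?
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return float(c[non_iso].mean())


def random_expectation_cr(n_nodes: int, n_edges: int) -> float:
    """Expected clustering of an Erdős–Rényi graph: the edge density."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError("more edges than the complete graph allows")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def scale_free_fit(degrees) -> tuple[float, float]:
    """Least-squares power-law fit to a degree sequence.

    Positive degrees are logarithmically binned; log10 of the per-bin
    frequency density is regressed on log10 of the bin's geometric-mean
    degree.  Returns (slope, R^2).  The fit abstains (R^2 = 0 with a
    warning) when it cannot be informative: fewer than 5 occupied bins
    leaves a two-parameter line close to saturated, and fewer than 30
    positive-degree nodes is too small a sample to assess a degree
    distribution's tail at all.
    """
    k = np.asarray(degrees, dtype=float)
    k = k[k > 0]
    if k.size == 0:
        raise ValueError("all degrees are zero")
    if k.size < 30:
        warnings.warn("fewer than 30 non-isolated nodes; scale-free fit uninformative")
        return 0.0, 0.0
    kmin, kmax = k.min(), k.max()
    if kmax == kmin:
        warnings.warn("degenerate degree sequence; scale-free fit undefined")
        return 0.0, 0.0
    n_bins = int(min(12, max(3, np.unique(k).size)))
    edges = np.logspace(np.log10(kmin), np.log10(kmax * (1 + 1e-9)), n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    use = counts > 0
    if use.sum() < 5:
        warnings.warn("fewer than 5 occupied degree bins; scale-free fit uninformative")
        return 0.0, 0.0
    lx = np.log10(centers[use])
    ly = np.log10(counts[use] / widths[use])
    slope, intercept = np.polyfit(lx, ly, 1)
    fitted = slope * lx + intercept
    ss_res = np.sum((ly - fitted) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(r2)


def threshold_scan(sim: pd.DataFrame, tau_grid=None) -> pd.DataFrame:
    """Evaluate every candidate threshold on the similarity matrix.

    For each tau the off-diagonal adjacency is |r| >= tau; the scan records
    edge count, observed clustering Co, random expectation Cr, their
    difference, the scale-free fit R^2 and the non-isolated node count.
    """
    grid = DEFAULT_TAU_GRID if tau_grid is None else np.asarray(tau_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty tau grid")
    if np.any((grid <= 0) | (grid >= 1)) or np.any(np.diff(grid) <= 0):
        raise ValueError("tau grid must be ascending within (0, 1)")
    absr = np.abs(sim.to_numpy(dtype=float))
    np.fill_diagonal(absr, 0.0)
    n = absr.shape[0]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tau in grid:
            adj = absr >= tau
            k = adj.sum(axis=1)
            n_edges = int(k.sum() // 2)
            co = clustering_coefficient(adj) if n_edges else 0.0
            cr = random_expectation_cr(n, n_edges) if n >= 2 else 0.0
            if n_edges and (k > 0).sum() >= 2:
                _, r2 = scale_free_fit(k)
            else:
                r2 = 0.0
            rows.append(
                {
                    "tau": float(tau),
                    "n_edges": n_edges,
                    "co": co,
                    "cr": cr,
                    "delta": co - cr,
                    "sf_r2": r2,
                    "n_nonisolated": int((k > 0).sum()),
                }
            )
    return pd.DataFrame(rows)


class ThresholdChoice(NamedTuple):
    tau: float
    scale_free_ok: bool


def select_threshold(
    scan: pd.DataFrame,
    min_sf_r2: float = 0.8,
    rule: str = "plateau",
    plateau_tol: float = 0.05,
) -> ThresholdChoice:
    """Pick the threshold where Co - Cr reaches its plateau.

    Rows with sf_r2 >= min_sf_r2 and at least one edge are eligible.  The
    default ``plateau`` rule returns the smallest eligible tau whose Co - Cr
    is within ``plateau_tol`` (relative) of the eligible maximum: as tau
    approaches the largest attained |r| the graph collapses to a few tight
    cliques whose Co - Cr tends to 1 regardless of structure, so the exact
    argmax is degenerate at the sparse end while the plateau onset is
    stable.  ``rule="max"`` gives the exact argmax (ties to the smallest
    tau).  If no row passes the scale-free gate the same rule is applied to
    all edged rows, with ``scale_free_ok=False`` and a warning.
    """
    if scan.empty:
        raise ValueError("empty threshold scan")
    if rule not in ("plateau", "max"):
        raise ValueError(f"unknown rule {rule!r}")
    edged = scan[scan["n_edges"] > 0]
    if edged.empty:
        raise ValueError("all rows edgeless; no threshold admits any edge")
    eligible = edged[edged["sf_r2"] >= min_sf_r2]
    ok = not eligible.empty
    if not ok:
        warnings.warn("no threshold met the scale-free gate; using best Co-Cr overall")
        eligible = edged
    best = eligible["delta"].max()
    if rule == "plateau" and best > 0:
        near = eligible["delta"] >= best * (1 - plateau_tol)
    else:
        near = np.isclose(eligible["delta"], best)
    tau = float(eligible.loc[near, "tau"].min())
    return ThresholdChoice(tau=tau, scale_free_ok=ok)


def build_network(
    sim: pd.DataFrame, tau: float, annotation: pd.DataFrame
) -> nx.Graph:
    """Binary coexpression network at threshold tau.

    Edge iff |r| >= tau between distinct genes; nodes are the non-isolated
    endpoints, labelled with their biotype; edges carry the correlation and
    its sign.  The chosen tau is stored as a graph attribute.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    missing = [g for g in sim.index if g not in annotation.index]
    if missing:
        raise ValueError(f"genes without biotype annotation: {missing[:10]}")
    r = sim.to_numpy(dtype=float)
    genes = list(sim.index)
    g = nx.Graph(tau=float(tau))
    iu, ju = np.where(np.triu(np.abs(r) >= tau, k=1))
    for i, j in zip(iu, ju):
        g.add_edge(genes[i], genes[j], r=float(r[i, j]), sign=int(np.sign(r[i, j])))
    nx.set_node_attributes(
        g, {n: annotation.loc[n, "biotype"] for n in g.nodes}, "biotype"
    )
    return g
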