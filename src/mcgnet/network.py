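"""Multicellular (TC+TAM) co-expression networks.

Nodes are (gene, compartment) pairs; the observation unit is the paired
animal, so intra- and intercellular correlations are both computed over
the same ``n = number of animals`` aligned columns.  An edge requires
|PCC| > 0.95 and p < 0.05 (both strict).  The sensitive network uses the
Endpoint animals only; each perturbation network adds exactly one
Rebound animal to the Endpoint reference set.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnalysisConfig, CompartmentExperiment, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class CellGeneNode:
    gene: str
    compartment: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.gene}({self.compartment})"


@dataclass(frozen=True)
class NetworkEdge:
    node_a: CellGeneNode
    node_b: CellGeneNode
    pcc: float
    p: float

    @property
    def kind(self) -> str:
        return (
            "intracellular"
            if self.node_a.compartment == self.node_b.compartment
            else "intercellular"
        )


@dataclass
class GeneNetwork:
    """A thresholded correlation network plus its underlying data.

    ``values`` keeps the aligned node x animal matrix the correlations
    were computed from (rows indexed by (gene, compartment)), so that
    downstream differential analysis can recompute correlations from raw
    sample vectors rather than from the binarized edge set.
    """

    label: str
    sample_ids: list[str]  # pairing IDs (animals)
    node_universe: list[CellGeneNode]
    edges: list[NetworkEdge]
    values: pd.DataFrame

    @property
    def nodes(self) -> list[CellGeneNode]:
        """Edge-incident nodes only (isolated nodes are not counted)."""
        seen: dict[CellGeneNode, None] = {}
        for e in self.edges:
            seen.setdefault(e.node_a, None)
            seen.setdefault(e.node_b, None)
        return list(seen)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> set[tuple[CellGeneNode, CellGeneNode]]:
        return {_canonical(e.node_a, e.node_b) for e in self.edges}

    def vector(self, node: CellGeneNode) -> np.ndarray:
        return self.values.loc[(node.gene, node.compartment)].to_numpy(dtype=float)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, pcc=e.pcc, p=e.p, edge_kind=e.kind)
        return g


def _canonical(a: CellGeneNode, b: CellGeneNode) -> tuple[CellGeneNode, CellGeneNode]:
    return (a, b) if a <= b else (b, a)


def pearson_edge(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p from the exact t distribution.

    p is computed from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom; |r| = 1 maps to p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n or n < 3:
        raise ValidationError("pearson_edge needs equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in correlation input")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ValidationError("undefined correlation: zero variance")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-12:  # exact collinearity up to float rounding
        return math.copysign(1.0, r), 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def _aligned_values(
    exp: CompartmentExperiment,
    node_genes: dict[str, list[str]],
    pair_ids: list[str],
) -> pd.DataFrame:
    """Node x animal matrix, rows indexed by (gene, compartment)."""
    rows = []
    index = []
    for comp in ("TC", "TAM"):
        cols = [exp.column_for(pid, comp) for pid in pair_ids]
        for gene in node_genes.get(comp, []):
            if gene not in exp.expression.index:
                raise ValidationError(f"gene {gene!r} absent from expression matrix")
            rows.append(exp.expression.loc[gene, cols].to_numpy(dtype=float))
            index.append((gene, comp))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["gene", "compartment"]),
        columns=pair_ids,
    )


def build_network(
    exp: CompartmentExperiment,
    node_genes: dict[str, list[str]],
    pair_ids: list[str],
    cfg: AnalysisConfig | None = None,
    label: str = "network",
) -> GeneNetwork:
    """Thresholded all-pairs correlation network over the given animals.

    Pairs with zero variance in either vector are skipped (logged).
    """
    cfg = cfg or AnalysisConfig()
    if len(pair_ids) < 3:
        raise ValidationError("need >= 3 paired samples to build a network")
    values = _aligned_values(exp, node_genes, pair_ids)
    if values.isna().any().any():
        n_bad = int(values.isna().any(axis=1).sum())
        log.info("%s: dropping %d nodes with NaN values", label, n_bad)
        values = values.dropna()
    universe = [CellGeneNode(g, c) for g, c in values.index]

    mat = values.to_numpy(dtype=float)
    n = mat.shape[1]
    sd = mat.std(axis=1)
    nonconst = sd > 0
    n_skipped = int((~nonconst).sum())
    if n_skipped:
        log.info("%s: %d constant nodes skipped in correlation", label, n_skipped)
    edges: list[NetworkEdge] = []
    idx = np.flatnonzero(nonconst)
    if len(idx) >= 2:
        sub = mat[idx]
        r = np.corrcoef(sub)
        np.clip(r, -1.0, 1.0, out=r)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.abs(r) == 1.0] = 0.0
        for ii, jj in itertools.combinations(range(len(idx)), 2):
            rij = float(r[ii, jj])
            pij = float(p[ii, jj])
            if abs(rij) > cfg.edge_abs_pcc_threshold and pij < cfg.edge_p_threshold:
                a, b = _canonical(universe[idx[ii]], universe[idx[jj]])
                edges.append(NetworkEdge(a, b, rij, pij))
    edges.sort(key=lambda e: (e.node_a, e.node_b))
    return GeneNetwork(
        label=label, sample_ids=list(pair_ids), node_universe=universe,
        edges=edges, values=values,
    )


def build_sensitive_and_perturbation_networks(
    exp: CompartmentExperiment,
    node_genes: dict[str, list[str]],
    cfg: AnalysisConfig | None = None,
) -> tuple[GeneNetwork, list[GeneNetwork]]:
    """Endpoint-only sensitive network and one perturbation network per
    Rebound animal (Endpoint animals plus that single animal)."""
    cfg = cfg or AnalysisConfig()
    ep_ids = exp.pair_ids(group="Ep")
    reb_ids = exp.pair_ids(group="Reb")
    if not ep_ids:
        raise ValidationError("Endpoint group is empty")
    if not reb_ids:
        raise ValidationError("Rebound group is empty")
    sensitive = build_network(exp, node_genes, ep_ids, cfg, label="sensitive")
    perturbations = [
        build_network(exp, node_genes, ep_ids + [rid], cfg, label=f"perturbation_{rid}")
        for rid in reb_ids
    ]
    return sensitive, perturbations


def topology_metrics(net: GeneNetwork) -> dict[str, float]:
    """Topology summary of the edge-incident subgraph.

    diameter: longest shortest path within the largest connected
    component (0 for an edgeless network); centralization: Freeman degree
    centralization sum(d_max - d_i) / ((n-1)(n-2)); avg_neighbors: mean
    degree 2E/N over non-isolated nodes.
    """
    g = net.to_networkx()
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n == 0 or m == 0:
        return {"n_nodes": n, "n_edges": m, "diameter": 0.0,
                "centralization": 0.0, "avg_neighbors": 0.0}
    largest = max(nx.connected_components(g), key=len)
    diameter = float(nx.diameter(g.subgraph(largest)))
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    if n >= 3:
        centralization = float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))
    else:
        centralization = 0.0
    return {
        "n_nodes": n,
        "n_edges": m,
        "diameter": diameter,
        "centralization": centralization,
        "avg_neighbors": float(2.0 * m / n),
    }
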