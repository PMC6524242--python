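"""Differential-network construction from single-sample perturbations.

For every candidate gene pair, the perturbed correlations (Endpoint
animals plus one Rebound animal) are recomputed from the underlying
sample vectors and compared with the sensitive (Endpoint-only)
correlation.  A pair is a robust differential edge when |dPCC| exceeds
the threshold, with a consistent sign, in at least ``min_perturbations``
of the perturbation networks; robust edges are classed gained
(representative dPCC > 0) or lost (< 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import AnalysisConfig, ValidationError
from .network import CellGeneNode, GeneNetwork, _canonical

log = logging.getLogger(__name__)


@dataclass
class DifferentialEdge:
    node_a: CellGeneNode
    node_b: CellGeneNode
    pcc_sensitive: float
    pcc_perturbed: list[float]
    n_exceed: int
    representative_delta: float
    edge_class: str  # gained | lost | invariant

    @property
    def delta_pcc(self) -> list[float]:
        return [p - self.pcc_sensitive for p in self.pcc_perturbed]

    def is_robust(self, min_perturbations: int) -> bool:
        return self.n_exceed >= min_perturbations


@dataclass
class DifferentialNetwork:
    edges: list[DifferentialEdge]
    invariant_pairs: list[DifferentialEdge] = field(default_factory=list)

    @property
    def nodes(self) -> list[CellGeneNode]:
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

    def fraction_gained(self) -> float:
        if not self.edges:
            return float("nan")
        return sum(e.edge_class == "gained" for e in self.edges) / len(self.edges)


def _pair_correlation(net: GeneNetwork, a: CellGeneNode, b: CellGeneNode) -> float:
    x = net.vector(a)
    y = net.vector(b)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def delta_pcc_table(
    sensitive: GeneNetwork,
    perturbations: list[GeneNetwork],
    cfg: AnalysisConfig | None = None,
    pair_universe: str = "edge-union",
) -> list[DifferentialEdge]:
    """dPCC records for every pair in the chosen universe.

    ``edge-union`` (default): pairs forming a supra-threshold edge in the
    sensitive network or in at least one perturbation network;
    ``all-pairs``: every unordered node pair.  Correlations are always
    recomputed from the stored sample vectors, never read off the
    thresholded edge sets.
    """
    cfg = cfg or AnalysisConfig()
    sens_nodes = set(map(tuple, sensitive.values.index))
    for pert in perturbations:
        if set(map(tuple, pert.values.index)) != sens_nodes:
            raise ValidationError(
                f"node universe of {pert.label!r} differs from the sensitive network"
            )

    if pair_universe == "edge-union":
        pairs: set[tuple[CellGeneNode, CellGeneNode]] = set(sensitive.edge_pairs())
        for pert in perturbations:
            pairs |= pert.edge_pairs()
    elif pair_universe == "all-pairs":
        nodes = [CellGeneNode(g, c) for g, c in sensitive.values.index]
        pairs = {
            _canonical(nodes[i], nodes[j])
            for i in range(len(nodes))
            for j in range(i + 1, len(nodes))
        }
    else:
        raise ValidationError(f"unknown pair_universe {pair_universe!r}")

    thr = cfg.delta_pcc_threshold
    records: list[DifferentialEdge] = []
    for a, b in sorted(pairs):
        r_s = _pair_correlation(sensitive, a, b)
        r_p = [_pair_correlation(pert, a, b) for pert in perturbations]
        if not np.isfinite(r_s) or not all(np.isfinite(r) for r in r_p):
            log.info("skipping pair (%s, %s): undefined correlation", a, b)
            continue
        deltas = np.array(r_p) - r_s
        exceeding = deltas[np.abs(deltas) > thr]
        n_pos = int(np.sum(exceeding > 0))
        n_neg = int(np.sum(exceeding < 0))
        # count the dominant direction: an evenly mixed pair never reaches
        # min_perturbations (> half the perturbations), and the count is
        # non-increasing in the threshold, keeping robustness monotone
        if n_pos >= n_neg and n_pos > 0:
            n_exceed = n_pos
            representative = float(exceeding[exceeding > 0].mean())
        elif n_neg > 0:
            n_exceed = n_neg
            representative = float(exceeding[exceeding < 0].mean())
        else:
            n_exceed = 0
            representative = 0.0
        if n_exceed > 0:
            edge_class = "gained" if representative > 0 else "lost"
        else:
            edge_class = "invariant"
        records.append(
            DifferentialEdge(
                node_a=a, node_b=b, pcc_sensitive=r_s, pcc_perturbed=list(map(float, r_p)),
                n_exceed=n_exceed, representative_delta=representative,
                edge_class=edge_class,
            )
        )
    return records


def build_differential_network(
    delta_table: list[DifferentialEdge], cfg: AnalysisConfig | None = None
) -> DifferentialNetwork:
    """Keep robust edges only; side-table the invariant sensitive-network pairs."""
    cfg = cfg or AnalysisConfig()
    robust = [e for e in delta_table if e.is_robust(cfg.min_perturbations)]
    invariant = [
        e for e in delta_table
        if not e.is_robust(cfg.min_perturbations)
        and max((abs(d) for d in e.delta_pcc), default=0.0) <= cfg.delta_pcc_threshold
    ]
    return DifferentialNetwork(edges=robust, invariant_pairs=invariant)


def candidate_gene_list(
    dnet: DifferentialNetwork, symbol_map: dict[str, str] | None = None
) -> list[str]:
    """Unique human gene symbols of edge-incident nodes.

    ``symbol_map`` is an optional ortholog map (source symbol -> human
    symbol, case-insensitive on the source side); None means identity
    after uppercasing.  Unmapped symbols are dropped and logged.
    """
    if symbol_map is not None:
        symbol_map = {k.upper(): v.upper() for k, v in symbol_map.items()}
    out: dict[str, None] = {}
    dropped = []
    for node in dnet.nodes:
        sym = node.gene.upper()
        if symbol_map is not None:
            if sym not in symbol_map:
                dropped.append(sym)
                continue
            sym = symbol_map[sym]
        out.setdefault(sym, None)
    if dropped:
        log.info("dropped %d unmapped symbols: %s", len(set(dropped)), sorted(set(dropped)))
    return list(out)
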