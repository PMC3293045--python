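"""Bipartite miRNA-gene and TF-miRNA regulatory networks and feedback loops.

The miRNA-gene network has one node per miRNA/gene and one directed
``mirna_targets_gene`` edge per retained target pair; hubs are nodes whose
degree reaches a threshold (default 10, the published core-node criterion).
TF-miRNA edges come from scanning pre-miRNA upstream sequences for IUPAC
consensus binding sites with a mismatch budget, on both strands; when paired
expression is available each TF->miRNA edge is weighted by the Pearson
correlation of the two series ("regulatory ability"). A feedback loop is a
(TF, miRNA) pair where the TF binds the miRNA's promoter and the miRNA in turn
targets the TF's own transcript - predicted self-repression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (DataError, ExpressionMatrix, IUPAC_CODES, MotifSet,
                      PromoterSet, TargetPairSet, reverse_complement)
from .integration import CoordinatePair

NODE_TYPES = ("TF", "miRNA", "gene")
EDGE_TYPES = ("tf_binds_mirna", "mirna_targets_gene")
HUB_DEGREE = 10


@dataclass
class RegulatoryNetwork:
    """Typed directed graph over TF, miRNA and gene nodes."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_edge(self, source: str, target: str, edge_type: str,
                 weight: float | None = None) -> None:
        if edge_type not in EDGE_TYPES:
            raise DataError(f"unknown edge type {edge_type!r}")
        s_type, t_type = (("TF", "miRNA") if edge_type == "tf_binds_mirna"
                          else ("miRNA", "gene"))
        if edge_type == "mirna_targets_gene" and source == target:
            raise DataError(f"self-loop not allowed: {source} targets itself as a miRNA")
        for node, ntype in ((source, s_type), (target, t_type)):
            existing = self.graph.nodes[node]["node_type"] if node in self.graph else None
            if existing is not None and existing != ntype:
                # a gene that is also a TF keeps the TF label
                if {existing, ntype} == {"TF", "gene"}:
                    ntype = "TF"
                else:
                    raise DataError(f"node {node!r} used as both {existing} and {ntype}")
            self.graph.add_node(node, node_type=ntype)
        self.graph.add_edge(source, target, edge_type=edge_type, weight=weight)

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def nodes_of_type(self, node_type: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["node_type"] == node_type]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self, edge_type: str | None = None) -> set[tuple[str, str]]:
        return {(u, v) for u, v, d in self.graph.edges(data=True)
                if edge_type is None or d["edge_type"] == edge_type}


@dataclass(frozen=True)
class MotifHit:
    tf_name: str
    mirna_id: str
    position: int  # 0-based offset on the + strand of the promoter
    strand: str    # '+' or '-'
    matched: str   # promoter substring at [position, position+len(motif))


@dataclass(frozen=True)
class FeedbackLoop:
    tf_name: str
    mirna_id: str

    @property
    def target_gene(self) -> str:
        return self.tf_name


def build_bipartite_network(pairs) -> RegulatoryNetwork:
    """miRNA-gene network from a TargetPairSet or a list of CoordinatePairs."""
    net = RegulatoryNetwork()
    if isinstance(pairs, TargetPairSet):
        items = sorted(pairs.pairs)
    else:
        items = sorted({(c.mirna_id, c.gene_id) for c in pairs})
    for m, g in items:
        net.add_edge(m, g, "mirna_targets_gene")
    return net


def hub_nodes(network: RegulatoryNetwork, min_degree: int = HUB_DEGREE,
              strict_gt: bool = False) -> list[tuple[str, int]]:
    """Nodes at or above the degree threshold, by degree descending then name."""
    passes = (lambda d: d > min_degree) if strict_gt else (lambda d: d >= min_degree)
    out = [(n, d) for n, d in network.graph.degree() if passes(d)]
    return sorted(out, key=lambda nd: (-nd[1], nd[0]))


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def _mismatches(window: str, motif: str) -> int:
    n = 0
    for w, m in zip(window, motif):
        if w not in IUPAC_CODES[m]:
            n += 1
    return n


def scan_promoters(promoters: PromoterSet, motifs: MotifSet, max_mismatch: int = 0,
                   both_strands: bool = True) -> list[MotifHit]:
    """All windows matching each consensus within the mismatch budget.

    Minus-strand hits are windows whose reverse complement matches the motif;
    their position is still the window's 0-based offset on the plus strand.
    Output order is (mirna, tf, position, strand): deterministic.
    """
    hits: list[MotifHit] = []
    for mid in sorted(promoters.sequences):
        seq = promoters.sequences[mid].upper()
        for tf in sorted(motifs.motifs):
            motif = motifs.motifs[tf].upper()
            bad = [c for c in motif if c not in IUPAC_CODES]
            if bad:
                raise DataError(f"motif {tf!r} has invalid IUPAC code(s): {bad}")
            L = len(motif)
            rc_motif = _iupac_revcomp(motif)
            for pos in range(len(seq) - L + 1):
                window = seq[pos:pos + L]
                if _mismatches(window, motif) <= max_mismatch:
                    hits.append(MotifHit(tf, mid, pos, "+", window))
                if both_strands and _mismatches(window, rc_motif) <= max_mismatch:
                    hits.append(MotifHit(tf, mid, pos, "-", window))
    hits.sort(key=lambda h: (h.mirna_id, h.tf_name, h.position, h.strand))
    return hits


_IUPAC_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
                     "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
                     "D": "H", "H": "D", "N": "N"}


def _iupac_revcomp(motif: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(motif))


# ---------------------------------------------------------------------------
# TF-miRNA network and loops
# ---------------------------------------------------------------------------

def build_tf_mirna_network(hits: list[MotifHit],
                           tf_expr: ExpressionMatrix | None = None,
                           mirna_expr: ExpressionMatrix | None = None) -> RegulatoryNetwork:
    """TF->miRNA binding network; edges weighted by expression Pearson r when given."""
    pairs = sorted({(h.tf_name, h.mirna_id) for h in hits})
    weight_fn = None
    if tf_expr is not None and mirna_expr is not None:
        shared = [s for s in tf_expr.sample_ids if s in set(mirna_expr.sample_ids)]
        if len(shared) < 3:
            raise DataError(f"need >=3 shared samples to weight edges, have {len(shared)}")

        def weight_fn(tf, m):
            if tf not in tf_expr.data.index or m not in mirna_expr.data.index:
                return None
            x = tf_expr.data.loc[tf, shared].to_numpy(dtype=float)
            y = mirna_expr.data.loc[m, shared].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                # correlation undefined for a constant series, except the
                # degenerate identical-constant case (perfect co-movement)
                return 1.0 if np.allclose(x, y) else None
            return float(stats.pearsonr(x, y).statistic)

    net = RegulatoryNetwork()
    for tf, m in pairs:
        net.add_edge(tf, m, "tf_binds_mirna",
                     weight=None if weight_fn is None else weight_fn(tf, m))
    return net


def core_tfs(network: RegulatoryNetwork, min_degree: int = HUB_DEGREE,
             strict_gt: bool = False) -> list[tuple[str, int]]:
    """TFs at or above the degree threshold, ranked by degree descending."""
    tfs = set(network.nodes_of_type("TF"))
    return [(n, d) for n, d in hub_nodes(network, min_degree, strict_gt) if n in tfs]


def find_feedback_loops(tf_net: RegulatoryNetwork,
                        target_pairs: TargetPairSet) -> list[FeedbackLoop]:
    """All (TF, miRNA) pairs with TF->miRNA binding and miRNA->TF targeting."""
    binding = tf_net.edge_set("tf_binds_mirna")
    targeting = set(target_pairs.pairs)
    loops = [FeedbackLoop(tf, m) for tf, m in binding if (m, tf) in targeting]
    return sorted(loops, key=lambda l: (l.tf_name, l.mirna_id))


def loops_to_frame(loops: list[FeedbackLoop]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.tf_name, l.mirna_id, l.target_gene) for l in loops],
        columns=["tf", "mirna", "target_gene"],
    )
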