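"""Gene regulatory network construction and motif census.

Nodes are the significant motifs; a directed edge regulator -> target exists
when (i) the target gene's 1 kb promoter carries at least one predicted
binding site of the regulator motif and (ii) the absolute Pearson
correlation between the regulator's activity trajectory and the target
gene's log2 expression profile exceeds a threshold (default 0.8, strict).
Edges are inductive for positive and inhibitory for negative correlation,
weighted by the correlation itself.  The census enumerates feed-forward
loops (a->b, b->c, a->c) and dense overlapping regulons (maximal regulator
groups sharing enough common targets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .activity import ActivityModel
from .counts import ExpressionMatrix
from .errors import InputError
from .motifscan import SiteCountMatrix

logger = logging.getLogger("germnet.grn")

SIGN_LABEL = {1: "inductive", -1: "inhibitory"}


@dataclass
class Network:
    """Directed signed weighted TF network over selected motifs."""

    graph: nx.DiGraph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def edge_table(self) -> pd.DataFrame:
        rows = [(u, v, d["sign"], d["weight"], d["sites"])
                for u, v, d in sorted(self.graph.edges(data=True))]
        return pd.DataFrame(rows, columns=["regulator", "target", "sign",
                                           "weight", "sites"])

    def in_degree(self) -> dict[str, int]:
        return dict(self.graph.in_degree())

    def out_degree(self) -> dict[str, int]:
        return dict(self.graph.out_degree())


def infer_edges(model: ActivityModel, expr: ExpressionMatrix,
                sites: SiteCountMatrix,
                tf_gene_map: dict[str, list[str]],
                threshold: float = 0.8,
                allow_self: bool = False) -> Network:
    """Build the network from activities, expression, and site counts.

    The site condition uses presence (>= 1 site), regardless of whether the
    matrix was binarized.  Correlations run over the activity model's
    samples.  A dimer target node qualifies through any constituent gene
    carrying a site; the strongest-correlated qualifying constituent defines
    the edge.  Nodes whose target gene(s) lack expression data are excluded
    from the target role with a log notice.
    """
    g = nx.DiGraph()
    samples = [s for s in model.samples if s in expr.samples]
    if len(samples) < 3:
        raise InputError("edge inference needs >= 3 shared samples")
    log2 = expr.log2_expr[samples]
    pvals = model.pvalues if model.pvalues is not None else pd.Series(dtype=float)
    for node in model.motif_ids:
        genes = tf_gene_map.get(node, [])
        g.add_node(node, p_value=float(pvals.get(node, np.nan)),
                   tf_genes=";".join(genes))
    A = model.A[samples]
    A_std = A.sub(A.mean(axis=1), axis=0)
    a_norm = np.sqrt((A_std.values ** 2).sum(axis=1))
    for target in model.motif_ids:
        target_genes = [gene for gene in tf_gene_map.get(target, [])
                        if gene in log2.index and gene in sites.N.index]
        if not target_genes:
            logger.info("node %s has no mappable target gene; target role "
                        "skipped", target)
            continue
        for regulator in model.motif_ids:
            if regulator == target and not allow_self:
                continue
            ri = model.motif_ids.index(regulator)
            if a_norm[ri] == 0:
                continue
            best = None
            for gene in target_genes:
                n_sites = int(sites.N.loc[gene, regulator])
                if n_sites < 1:
                    continue
                e = log2.loc[gene].values.astype(float)
                e_std = e - e.mean()
                denom = a_norm[ri] * np.sqrt((e_std ** 2).sum())
                if denom == 0:
                    continue
                r = float(A_std.values[ri] @ e_std / denom)
                if best is None or abs(r) > abs(best[0]):
                    best = (r, gene, n_sites)
            # strict inequality; the epsilon keeps a correlation exactly at
            # the threshold out regardless of floating-point round-off
            if best is not None and abs(best[0]) > threshold + 1e-9:
                r, gene, n_sites = best
                sign = 1 if r > 0 else -1
                g.add_edge(regulator, target, sign=SIGN_LABEL[sign],
                           weight=r, sites=n_sites, target_gene=gene)
    net = Network(g)
    logger.info("network: %d nodes, %d edges", len(net.nodes), len(net.edges))
    return net


# ---------------------------------------------------------------------------
# motif census


def count_ffl(net: Network) -> list[tuple[str, str, str]]:
    """All feed-forward loops: ordered distinct triples with a->b, b->c, a->c.

    Edge signs (for coherence classification) are available on the network's
    edge attributes.
    """
    g = net.graph
    loops = []
    for a, b in g.edges:
        for c in g.successors(b):
            if c != a and c != b and g.has_edge(a, c):
                loops.append((a, b, c))
    return sorted(loops)


def ffl_signs(net: Network, loop: tuple[str, str, str]) -> tuple[str, str, str]:
    a, b, c = loop
    g = net.graph
    return (g[a][b]["sign"], g[b][c]["sign"], g[a][c]["sign"])


def find_dors(net: Network, min_regulators: int = 2,
              min_shared_targets: int = 3) -> list[tuple[frozenset, frozenset]]:
    """Dense overlapping regulons: maximal regulator groups with shared targets.

    A DOR is a set of >= ``min_regulators`` regulators whose target sets
    share >= ``min_shared_targets`` common targets; only maximal groups (no
    strict superset still satisfies the criterion) are reported, largest
    regulator set first.
    """
    g = net.graph
    targets = {n: frozenset(g.successors(n)) for n in g.nodes
               if g.out_degree(n) > 0}
    regs = sorted(targets)
    found: set[tuple[frozenset, frozenset]] = set()

    def extend(group: list[str], shared: frozenset, candidates: list[str]):
        extendable = False
        for i, r in enumerate(candidates):
            new_shared = shared & targets[r]
            if len(new_shared) >= min_shared_targets:
                extendable = True
                extend(group + [r], new_shared, candidates[i + 1:])
        if not extendable and len(group) >= min_regulators:
            # maximal w.r.t. the candidate tail; global maximality check below
            found.add((frozenset(group), shared))

    for i, r in enumerate(regs):
        extend([r], targets[r], regs[i + 1:])

    # drop groups contained in a larger group that still meets the criterion
    maximal = []
    for grp, shared in found:
        if not any(grp < other and len(oshared) >= min_shared_targets
                   for other, oshared in found if other != grp):
            maximal.append((grp, shared))
    maximal.sort(key=lambda t: (-len(t[0]), -len(t[1]),
                                sorted(t[0]), sorted(t[1])))
    return maximal


def compare_networks(net_a: Network, net_b: Network) -> dict:
    """Shared/unique nodes and edges plus per-node roles (by motif id)."""
    nodes_a, nodes_b = set(net_a.nodes), set(net_b.nodes)
    edges_a, edges_b = set(net_a.edges), set(net_b.edges)

    def roles(net: Network) -> dict[str, str]:
        out = {}
        for n in net.nodes:
            tags = []
            if net.graph.out_degree(n) > 0:
                tags.append("input")
            if net.graph.in_degree(n) > 0:
                tags.append("target")
            out[n] = "+".join(tags) if tags else "isolated"
        return out

    return {
        "shared_nodes": sorted(nodes_a & nodes_b),
        "unique_nodes_a": sorted(nodes_a - nodes_b),
        "unique_nodes_b": sorted(nodes_b - nodes_a),
        "shared_edges": sorted(edges_a & edges_b),
        "unique_edges_a": sorted(edges_a - edges_b),
        "unique_edges_b": sorted(edges_b - edges_a),
        "n_shared_nodes": len(nodes_a & nodes_b),
        "n_nodes_a": len(nodes_a),
        "n_nodes_b": len(nodes_b),
        "roles_a": roles(net_a),
        "roles_b": roles(net_b),
    }


# ---------------------------------------------------------------------------
# export


def export_network(net: Network, path, fmt: str = "sif") -> None:
    """Write the network as SIF or GraphML with deterministic ordering."""
    if fmt == "sif":
        lines = [f"{u}\t{d['sign']}\t{v}"
                 for u, v, d in sorted(net.graph.edges(data=True))]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        ordered = nx.DiGraph()
        for n in sorted(net.graph.nodes):
            ordered.add_node(n, **{k: v for k, v in net.graph.nodes[n].items()
                                   if v == v})  # drop NaN attrs
        for u, v in sorted(net.graph.edges):
            ordered.add_edge(u, v, **net.graph.edges[u, v])
        nx.write_graphml(ordered, path)
    else:
        raise InputError(f"unknown export format {fmt!r} "
                         "(supported: sif, graphml)")


def read_graphml(path) -> Network:
    return Network(nx.read_graphml(path))
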