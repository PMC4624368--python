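"""Similarity-network construction, conductance, and nucleus selection.

The network is a simple undirected graph: nodes are sequences, and an edge
joins two sequences when their best pairwise hit passes three filters at
once — e-value below ``max_evalue``, coverage-rescaled identity at or above
``min_adjusted_identity``, and the alignment spanning at least
``min_mutual_coverage`` of *both* sequences.  The mutual-coverage condition
is what keeps a shared domain or fragment from stitching unrelated families
together.

A *nucleus* gene family is a connected component in which at least two
domains of life each form a cohesive, rarely-crossed group.  Cohesion is
measured per domain by conductance: the number of within-component edges
leaving the domain divided by the number of edges internal to it.  Low
conductance for both prokaryotic domains picks out ancient families that are
widely distributed yet rarely transferred between Archaea and Bacteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .config import PipelineConfig
from .similarity import SimilarityHit, adjusted_identity, best_hit_per_pair, mutual_coverage


@dataclass
class FamilyNucleus:
    """One connected component with its per-domain conductance map."""

    component_id: int
    member_ids: list[str]
    conductance: dict[str, float]
    passes: bool

    @property
    def size(self) -> int:
        return len(self.member_ids)


def build_network(
    hits: Iterable[SimilarityHit],
    lengths: Mapping[str, int],
    origins: Mapping[str, str],
    config: PipelineConfig | None = None,
    include_singletons: Iterable[str] = (),
) -> nx.Graph:
    """Build the filtered similarity network.

    An unordered pair is evaluated on the better of its two directional hits
    (higher bitscore, then lower e-value); coverage of both sequences is
    computed from that single hit.  Nodes appear only if they carry a
    qualifying edge, unless listed in ``include_singletons``.
    """
    cfg = config or PipelineConfig()
    # reduce to best directional hit, then best per unordered pair
    directional = best_hit_per_pair(hits)
    pair_best: dict[tuple[str, str], SimilarityHit] = {}
    for (q, s), hit in directional.items():
        key = (q, s) if q < s else (s, q)
        cur = pair_best.get(key)
        if cur is None or (hit.bitscore, -hit.evalue) > (cur.bitscore, -cur.evalue):
            pair_best[key] = hit

    net = nx.Graph()
    for key in sorted(pair_best):
        hit = pair_best[key]
        for sid in key:
            if sid not in lengths:
                raise KeyError(f"hit references unknown id {sid!r} (no length)")
            if sid not in origins:
                raise KeyError(f"hit references unknown id {sid!r} (no origin)")
        len_q, len_s = lengths[hit.query_id], lengths[hit.subject_id]
        if hit.evalue >= cfg.max_evalue:
            continue
        adj = adjusted_identity(hit, len_q, len_s)
        if adj < cfg.min_adjusted_identity:
            continue
        cov_q, cov_s = mutual_coverage(hit, len_q, len_s)
        if cov_q < cfg.min_mutual_coverage or cov_s < cfg.min_mutual_coverage:
            continue
        net.add_edge(
            hit.query_id,
            hit.subject_id,
            adjusted_identity=adj,
            cov_q=cov_q,
            cov_s=cov_s,
            evalue=hit.evalue,
            bitscore=hit.bitscore,
        )
    for sid in include_singletons:
        net.add_node(sid)
    for node in net.nodes:
        net.nodes[node]["origin"] = origins[node]
    return net


def connected_components(net: nx.Graph) -> dict[str, int]:
    """Node -> component id, components numbered by smallest member id."""
    comps = sorted(nx.connected_components(net), key=lambda c: min(c))
    return {node: cid for cid, comp in enumerate(comps) for node in comp}


def domain_conductance(net: nx.Graph, component_nodes: Iterable[str], domain: str) -> float:
    """External-over-internal edge ratio for one domain within one component.

    external = edges (inside the component) with exactly one endpoint in the
    domain; internal = edges with both endpoints in the domain.  A domain
    with no external edges has conductance 0; a domain with external edges
    but no internal ones is maximally unstructured and gets +inf.
    """
    nodes = set(component_nodes)
    in_domain = {n for n in nodes if net.nodes[n].get("origin") == domain}
    external = internal = 0
    for u, v in net.subgraph(nodes).edges:
        u_in, v_in = u in in_domain, v in in_domain
        if u_in and v_in:
            internal += 1
        elif u_in or v_in:
            external += 1
    if external == 0:
        return 0.0
    if internal == 0:
        return math.inf
    return external / internal


def _domain_internal_edges(net: nx.Graph, nodes: set[str], domain: str) -> int:
    sub = net.subgraph(nodes)
    return sum(
        1 for u, v in sub.edges
        if net.nodes[u].get("origin") == domain and net.nodes[v].get("origin") == domain
    )


def select_nuclei(net: nx.Graph, config: PipelineConfig | None = None) -> list[FamilyNucleus]:
    """Score every component; a nucleus needs >= 2 configured domains that
    each form a structured group: conductance strictly below the threshold
    *and* at least one internal edge (a domain that is absent, or present
    only as scattered nodes, has no conserved group to speak of)."""
    cfg = config or PipelineConfig()
    comp_map = connected_components(net)
    by_comp: dict[int, list[str]] = {}
    for node, cid in comp_map.items():
        by_comp.setdefault(cid, []).append(node)
    out: list[FamilyNucleus] = []
    for cid in sorted(by_comp):
        members = sorted(by_comp[cid])
        cond = {
            d: domain_conductance(net, members, d) for d in cfg.conductance_domains
        }
        n_low = sum(
            1
            for d, v in cond.items()
            if v < cfg.conductance_threshold
            and _domain_internal_edges(net, set(members), d) > 0
        )
        out.append(FamilyNucleus(cid, members, cond, passes=n_low >= 2))
    return out


# ---------------------------------------------------------------------------
# Exports


def export_graphml(net: nx.Graph, path: str | Path,
                   annotations: Mapping[str, Mapping[str, object]] | None = None) -> None:
    """Write GraphML with node annotations (class label, CPR identity, ...).

    ``annotations`` maps node id -> {attribute: value}; infinities are not
    representable in GraphML floats and are written as the string "inf".
    """
    g = net.copy()
    comp_map = connected_components(g)
    for node in g.nodes:
        g.nodes[node]["component_id"] = comp_map[node]
        if annotations and node in annotations:
            for k, v in annotations[node].items():
                if isinstance(v, float) and math.isinf(v):
                    v = "inf"
                if v is not None:
                    g.nodes[node][k] = v
    nx.write_graphml(g, str(path))


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    lines = ["u\tv\tadjusted_identity\tevalue"]
    for u, v in sorted(map(lambda e: tuple(sorted(e)), net.edges)):
        d = net.edges[u, v]
        lines.append(
            f"{u}\t{v}\t{d.get('adjusted_identity', ''):.4f}\t{d.get('evalue', ''):.3g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_nuclei_report(nuclei: list[FamilyNucleus], path: str | Path,
                        domains: tuple[str, ...] = ("Archaea", "Bacteria")) -> None:
    header = ["component", "size"] + [f"conductance_{d}" for d in domains] + ["passes"]
    lines = ["\t".join(header)]
    for nuc in nuclei:
        row = [str(nuc.component_id), str(nuc.size)]
        row += [
            "inf" if math.isinf(nuc.conductance.get(d, math.inf))
            else f"{nuc.conductance.get(d, math.inf):.6f}"
            for d in domains
        ]
        row.append(str(nuc.passes))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
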