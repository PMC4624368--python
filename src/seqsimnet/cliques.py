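"""Maximal cliques of highly divergent environmental sequences.

Once every environmental sequence carries a CPR identity, the subgraph
induced on the highly divergent ones (CPR identity below the cutoff, 60 % by
default) is searched for maximal cliques — fully connected groups in which
every pair of members passed the stringent identity/coverage edge filter.
A clique of mutually similar sequences that are all far from anything
published is the network signature of an unexplored, internally diversified
lineage, and each one is characterised by the average residue identity of
its alignment, the number of unambiguously aligned (conserved-block)
columns, and the average pairwise dN/dS of its coding sequences.

Clique enumeration is Bron–Kerbosch with pivoting, written here because the
enumeration order (canonical, sorted) is part of the contract; tests
cross-check it against an independent enumerator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .config import PipelineConfig
from .expansion import CPRRecord


class GraphTooLargeError(RuntimeError):
    pass


def divergent_subgraph(
    net: nx.Graph,
    cpr_records: Sequence[CPRRecord],
    config: PipelineConfig | None = None,
) -> nx.Graph:
    """Subgraph induced on environmental nodes with CPR identity below the
    divergence cutoff.  No-CPR nodes are excluded by default
    (``include_no_cpr_in_divergent`` flips that)."""
    cfg = config or PipelineConfig()
    keep = set()
    for rec in cpr_records:
        if rec.env_id not in net:
            continue
        if rec.has_cpr:
            if rec.cpr_identity < cfg.cpr_divergence_cutoff:
                keep.add(rec.env_id)
        elif cfg.include_no_cpr_in_divergent:
            keep.add(rec.env_id)
    return net.subgraph(keep).copy()


def maximal_cliques(
    graph: nx.Graph,
    min_size: int = 3,
    max_nodes: int = 10_000,
) -> list[tuple[str, ...]]:
    """All maximal cliques of at least ``min_size`` nodes.

    Bron–Kerbosch with pivoting (the pivot is the candidate with most
    neighbours in the candidate set, ties by node order).  Members of each
    clique are sorted and the clique list is sorted lexicographically, so the
    output is canonical.  Overlapping maximal cliques are all reported.
    """
    n = graph.number_of_nodes()
    if n > max_nodes:
        raise GraphTooLargeError(
            f"clique enumeration aborted: {n} nodes exceeds the guard ({max_nodes}); "
            "raise max_nodes explicitly if this is intended"
        )
    order = {node: k for k, node in enumerate(sorted(graph.nodes, key=str))}
    adj = {node: {v for v in graph[node] if v != node} for node in graph.nodes}
    out: list[tuple[str, ...]] = []

    def expand(r: list, p: set, x: set) -> None:
        if not p and not x:
            if len(r) >= min_size:
                out.append(tuple(sorted(r, key=str)))
            return
        pivot = max(p | x, key=lambda u: (len(adj[u] & p), -order[u]))
        for v in sorted(p - adj[pivot], key=lambda u: order[u]):
            expand(r + [v], p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand([], set(adj), set())
    return sorted(out)


def largest_clique_per_component(
    graph: nx.Graph, min_size: int = 3, max_nodes: int = 10_000
) -> list[tuple[str, ...]]:
    """One clique per connected component: the largest, ties broken by
    lexicographic member order."""
    out = []
    for comp in nx.connected_components(graph):
        cliques = maximal_cliques(graph.subgraph(comp), min_size, max_nodes)
        if cliques:
            # cliques are already in lexicographic order, so max-by-size
            # returns the lexicographically smallest of the largest
            out.append(max(cliques, key=len))
    return sorted(out)


def is_maximal_clique(graph: nx.Graph, members: Sequence[str]) -> bool:
    """Independent maximality check by neighbourhood intersection."""
    members = list(members)
    for i, u in enumerate(members):
        for v in members[i + 1:]:
            if not graph.has_edge(u, v):
                return False
    common = set(graph.nodes) - set(members)
    for u in members:
        common &= set(graph[u])
    return not common


# ---------------------------------------------------------------------------
# Alignment-level characterisation


def _check_alignment(rows: Sequence[str]) -> int:
    if len(rows) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    ncols = len(rows[0])
    if any(len(r) != ncols for r in rows):
        raise ValueError("ragged alignment: rows differ in length")
    return ncols


def pairwise_alignment_identity(a: str, b: str) -> float | None:
    """Percent identity over columns where both rows are non-gap; None if no
    such column exists."""
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        return None
    ident = sum(1 for x, y in pairs if x == y)
    return 100.0 * ident / len(pairs)


def clique_average_identity(alignment: Mapping[str, str] | Sequence[str]) -> float | None:
    """Mean pairwise percent identity over all unordered pairs of rows.

    Pairs with zero mutually non-gap columns are excluded; returns None if
    every pair is excluded.
    """
    rows = list(alignment.values()) if isinstance(alignment, Mapping) else list(alignment)
    _check_alignment(rows)
    idents = []
    for i, a in enumerate(rows):
        for b in rows[i + 1:]:
            ident = pairwise_alignment_identity(a, b)
            if ident is not None:
                idents.append(ident)
    if not idents:
        return None
    return sum(idents) / len(idents)


def conserved_block_count(
    alignment: Mapping[str, str] | Sequence[str],
    conserved_fraction: float = 0.5,
    max_gap_fraction: float = 0.0,
    min_block_len: int = 10,
) -> int:
    """Columns retained by a simplified conserved-block (trimming) filter.

    A column is *conserved* when its gap fraction is at most
    ``max_gap_fraction`` and its majority residue is shared by strictly more
    than ``conserved_fraction`` of the sequences (the classic "half plus
    one" rule at the 0.5 default).  Only contiguous runs of at least
    ``min_block_len`` conserved columns are retained; the result is the
    total number of retained columns.  This is a deliberately small,
    deterministic stand-in for full trimming heuristics: downstream logic
    only consumes the retained-column count.
    """
    rows = list(alignment.values()) if isinstance(alignment, Mapping) else list(alignment)
    ncols = _check_alignment(rows)
    nseq = len(rows)
    conserved = []
    for c in range(ncols):
        col = [r[c] for r in rows]
        gaps = col.count("-")
        if gaps / nseq > max_gap_fraction:
            conserved.append(False)
            continue
        residues = [x for x in col if x != "-"]
        top = max(residues.count(x) for x in set(residues))
        conserved.append(top > conserved_fraction * nseq)
    retained = 0
    run = 0
    for flag in conserved + [False]:
        if flag:
            run += 1
        else:
            if run >= min_block_len:
                retained += run
            run = 0
    return retained


@dataclass
class CliqueReport:
    """Summary of one divergent environmental clique."""

    clique_id: int
    member_ids: tuple[str, ...]
    family_component_id: int | None
    avg_identity: float | None
    avg_omega: float | None
    n_omega_pairs: int
    retained_block_columns: int
    alignable: bool

    @property
    def size(self) -> int:
        return len(self.member_ids)


def write_clique_reports(reports: Iterable[CliqueReport], path: str | Path) -> None:
    lines = [
        "clique_id\tsize\tmembers\tfamily_component\tavg_identity\t"
        "avg_omega\tn_omega_pairs\tretained_columns\talignable"
    ]
    for r in reports:
        lines.append("\t".join([
            str(r.clique_id),
            str(r.size),
            ",".join(r.member_ids),
            "" if r.family_component_id is None else str(r.family_component_id),
            "" if r.avg_identity is None else f"{r.avg_identity:.4f}",
            "" if r.avg_omega is None else f"{r.avg_omega:.4f}",
            str(r.n_omega_pairs),
            str(r.retained_block_columns),
            str(r.alignable),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_aligned_fasta(source: str | Path) -> dict[str, str]:
    """Aligned FASTA -> {id: row}; rows must be equal length."""
    from Bio import SeqIO

    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(source), "fasta")}
    if rows:
        _check_alignment(list(rows.values()) + [next(iter(rows.values()))])
    return rows
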