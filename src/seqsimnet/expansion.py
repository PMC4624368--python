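"""Environmental recruitment, topological classes, and CPR identity.

Starting from the nucleus families, environmental homologs are gathered in
successive recruitment rounds: round 1 searches the environmental database
with the nucleus sequences as seeds, round 2 re-searches it with the round-1
recruits as seeds.  Recruitment filters on e-value only; the stringent
identity/coverage filter is applied later, when the exploratory network is
rebuilt over the union.  This looseness is deliberate — it is what lets
round-1 recruits act as bridges that pull in homologs too divergent to hit
the nuclei directly.

In the rebuilt exploratory network, environmental sequences are labeled by
graph distance to the nucleus set: *class 1* at distance 1 (directly
connected to a nucleus sequence), *class 2* at distance 2 (connected to a
class-1 sequence but to no nucleus sequence), *distal* beyond.  Each
environmental sequence is also scored against the published set for its
closest published relative (CPR): the maximum coverage-rescaled identity
over all qualifying hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .config import PipelineConfig
from .records import SequenceRecord
from .similarity import Engine, SimilarityHit, adjusted_identity, best_hit_per_pair


@dataclass(frozen=True)
class CPRRecord:
    """Closest published relative of one environmental sequence.

    ``cpr_identity`` is None when no qualifying hit exists ("no CPR found"),
    never 0.
    """

    env_id: str
    best_published_id: str | None
    cpr_identity: float | None
    stratum: str = ""

    @property
    def has_cpr(self) -> bool:
        return self.cpr_identity is not None


@dataclass
class ExpandedSet:
    """Nucleus sequences plus recruited environmental sequences."""

    sequences: list[SequenceRecord]
    recruited_round: dict[str, int]            # env id -> first round recruited
    recruit_hits: list[SimilarityHit] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]


def _qualifying_hits(
    seeds: Sequence[SequenceRecord],
    env_db: Sequence[SequenceRecord],
    engine: Engine | Iterable[SimilarityHit],
    max_evalue: float,
) -> list[SimilarityHit]:
    """Seed-vs-env hits below the e-value cutoff, seeds as queries."""
    if callable(engine):
        out = []
        for seed in seeds:
            for env in env_db:
                if seed.id == env.id:
                    continue
                hit = engine(seed, env)
                if hit is not None and hit.evalue < max_evalue:
                    out.append(hit)
        return out
    seed_ids = {s.id for s in seeds}
    env_ids = {e.id for e in env_db}
    out = []
    for (q, s), hit in best_hit_per_pair(engine).items():
        if q in seed_ids and s in env_ids and hit.evalue < max_evalue:
            out.append(hit)
    return out


def recruit_round(
    seeds: Sequence[SequenceRecord],
    env_db: Sequence[SequenceRecord],
    engine: Engine | Iterable[SimilarityHit],
    config: PipelineConfig | None = None,
) -> tuple[set[str], list[SimilarityHit]]:
    """One recruitment round: env ids with a qualifying hit from any seed.

    Per seed at most ``recruit_hit_cap`` subjects are kept (ranked by
    bitscore, then e-value, then subject id).  No identity or coverage
    filter is applied here.
    """
    cfg = config or PipelineConfig()
    if not env_db:
        return set(), []
    hits = _qualifying_hits(seeds, env_db, engine, cfg.max_evalue)
    per_seed: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        per_seed.setdefault(h.query_id, []).append(h)
    recruited: set[str] = set()
    kept: list[SimilarityHit] = []
    for qid in sorted(per_seed):
        ranked = sorted(per_seed[qid], key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
        for h in ranked[: cfg.recruit_hit_cap]:
            recruited.add(h.subject_id)
            kept.append(h)
    return recruited, kept


def expand_families(
    nuclei_seqs: Sequence[SequenceRecord],
    env_db: Sequence[SequenceRecord],
    engine: Engine | Iterable[SimilarityHit],
    config: PipelineConfig | None = None,
) -> ExpandedSet:
    """Run ``recruitment_rounds`` rounds and return the expanded sequence set.

    Round r's seeds are round r-1's newly recruited sequences; already
    recruited ids are never recruited again, so the set grows monotonically
    with the number of rounds.
    """
    cfg = config or PipelineConfig()
    env_by_id = {e.id: e for e in env_db}
    recruited_round: dict[str, int] = {}
    all_hits: list[SimilarityHit] = []
    seeds: Sequence[SequenceRecord] = list(nuclei_seqs)
    for rnd in range(1, cfg.recruitment_rounds + 1):
        new_ids, hits = recruit_round(seeds, env_db, engine, cfg)
        all_hits.extend(hits)
        fresh = sorted(i for i in new_ids if i not in recruited_round)
        for i in fresh:
            recruited_round[i] = rnd
        if not fresh:
            break
        seeds = [env_by_id[i] for i in fresh]
    sequences = list(nuclei_seqs) + [env_by_id[i] for i in sorted(recruited_round)]
    return ExpandedSet(sequences, recruited_round, all_hits)


# ---------------------------------------------------------------------------
# Topological classes


def classify_nodes(net: nx.Graph, nucleus_ids: Iterable[str]) -> dict[str, str]:
    """Label every node by breadth-first distance from the nucleus set.

    nucleus -> "nucleus"; distance 1 -> "class1"; distance 2 -> "class2";
    anything farther (or disconnected from all nuclei) -> "distal".
    """
    nuclei = {n for n in nucleus_ids if n in net}
    dist = nx.multi_source_dijkstra_path_length(net, nuclei, weight=None) if nuclei else {}
    labels: dict[str, str] = {}
    for node in net.nodes:
        if node in nuclei:
            labels[node] = "nucleus"
        else:
            d = dist.get(node)
            labels[node] = "class1" if d == 1 else "class2" if d == 2 else "distal"
    return labels


def class_distances(net: nx.Graph, nucleus_ids: Iterable[str]) -> dict[str, float]:
    """Graph distance of each node to the nearest nucleus (inf if unreachable)."""
    nuclei = {n for n in nucleus_ids if n in net}
    dist = nx.multi_source_dijkstra_path_length(net, nuclei, weight=None) if nuclei else {}
    return {node: float(dist.get(node, float("inf"))) for node in net.nodes}


# ---------------------------------------------------------------------------
# Closest published relative


def cpr_identity(
    env_seqs: Sequence[SequenceRecord],
    published_db: Sequence[SequenceRecord],
    engine: Engine | Iterable[SimilarityHit],
    config: PipelineConfig | None = None,
) -> list[CPRRecord]:
    """Score each environmental sequence against the published set.

    The CPR identity is the maximum coverage-rescaled identity over all hits
    with e-value below the cutoff; ties break by higher bitscore, then
    lexicographic published id.  A sequence with no qualifying hit gets an
    explicit no-CPR record.
    """
    cfg = config or PipelineConfig()
    lengths = {s.id: s.length for s in list(env_seqs) + list(published_db)}
    if callable(engine):
        hits: list[SimilarityHit] = []
        for env in env_seqs:
            for pub in published_db:
                h = engine(env, pub)
                if h is not None:
                    hits.append(h)
    else:
        hits = list(engine)
    env_ids = {s.id for s in env_seqs}
    pub_ids = {s.id for s in published_db}
    best: dict[str, tuple[float, float, str]] = {}  # env -> (adj, bitscore, pub)
    for h in hits:
        if h.evalue >= cfg.max_evalue:
            continue
        if h.query_id in env_ids and h.subject_id in pub_ids:
            env_id, pub_id = h.query_id, h.subject_id
        elif h.subject_id in env_ids and h.query_id in pub_ids:
            env_id, pub_id = h.subject_id, h.query_id
        else:
            continue
        adj = adjusted_identity(h, lengths[h.query_id], lengths[h.subject_id])
        cand = (adj, h.bitscore, pub_id)
        cur = best.get(env_id)
        # higher identity, then higher bitscore, then smaller id
        if cur is None or (cand[0], cand[1], _neg_lex(cand[2])) > (cur[0], cur[1], _neg_lex(cur[2])):
            best[env_id] = cand
    strata = {s.id: s.sample_id for s in env_seqs}
    out = []
    for env in env_seqs:
        if env.id in best:
            adj, _, pub_id = best[env.id]
            out.append(CPRRecord(env.id, pub_id, adj, strata[env.id]))
        else:
            out.append(CPRRecord(env.id, None, None, strata[env.id]))
    return out


class _neg_lex(str):
    """Reverses lexicographic comparison so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Reports


def divergence_summary(
    cpr_records: Sequence[CPRRecord],
    bins: Sequence[float],
    strata: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-stratum histogram of CPR identity.

    ``bins`` are edges over (0, 100]; intervals are left-closed except the
    last, which is closed on both sides.  Rows are strata (by default the
    record's own stratum field); columns are bins plus a ``no_cpr`` count
    column.  Bin proportions sum to 1 per stratum over scored records;
    no-CPR records are counted separately, not as zeros.
    """
    edges = list(bins)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bins must be strictly increasing edges")
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    labels[-1] = labels[-1][:-1] + "]"
    rows: dict[str, dict[str, float]] = {}
    counts: dict[str, list[int]] = {}
    no_cpr: dict[str, int] = {}
    for rec in cpr_records:
        stratum = strata.get(rec.env_id, rec.stratum) if strata else rec.stratum
        counts.setdefault(stratum, [0] * len(labels))
        no_cpr.setdefault(stratum, 0)
        if not rec.has_cpr:
            no_cpr[stratum] += 1
            continue
        x = rec.cpr_identity
        for k, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            last = k == len(labels) - 1
            if lo <= x < hi or (last and x == hi):
                counts[stratum][k] += 1
                break
    for stratum in sorted(counts):
        total = sum(counts[stratum])
        rows[stratum] = {
            lab: (c / total if total else 0.0) for lab, c in zip(labels, counts[stratum])
        }
        rows[stratum]["n_scored"] = total
        rows[stratum]["no_cpr"] = no_cpr[stratum]
    return pd.DataFrame.from_dict(rows, orient="index")


def write_cpr_table(records: Sequence[CPRRecord], path: str | Path) -> None:
    lines = ["env_id\tbest_published_id\tcpr_identity\tstratum"]
    for r in records:
        ident = "" if r.cpr_identity is None else f"{r.cpr_identity:.4f}"
        lines.append(f"{r.env_id}\t{r.best_published_id or ''}\t{ident}\t{r.stratum}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_class_table(labels: Mapping[str, str], distances: Mapping[str, float],
                      path: str | Path) -> None:
    lines = ["id\tclass\tdistance"]
    for node in sorted(labels):
        d = distances.get(node, float("inf"))
        lines.append(f"{node}\t{labels[node]}\t{'inf' if d == float('inf') else int(d)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_recruits_manifest(expanded: ExpandedSet, path: str | Path) -> None:
    lines = ["env_id\tround\tseed_id\tevalue"]
    best_seed: dict[str, SimilarityHit] = {}
    for h in expanded.recruit_hits:
        cur = best_seed.get(h.subject_id)
        if cur is None or h.evalue < cur.evalue:
            best_seed[h.subject_id] = h
    for env_id in sorted(expanded.recruited_round):
        rnd = expanded.recruited_round[env_id]
        h = best_seed.get(env_id)
        seed = h.query_id if h else ""
        ev = f"{h.evalue:.3g}" if h else ""
        lines.append(f"{env_id}\t{rnd}\t{seed}\t{ev}")
    Path(path).write_text("\n".join(lines) + "\n")
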