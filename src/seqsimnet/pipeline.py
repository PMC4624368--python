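"""End-to-end orchestration of the similarity-network protocol.

The stages, in order:

1. build the reference network over published (non-environmental)
   sequences and select nucleus families by per-domain conductance;
2. recruit environmental homologs in successive rounds (e-value only);
3. rebuild the exploratory network over the expanded set under the full
   e-value / identity / mutual-coverage edge filter;
4. label environmental nodes class 1 / class 2 / distal by distance to the
   nucleus set, and score each against the published set for its closest
   published relative (CPR);
5. extract maximal cliques of highly divergent environmental sequences and
   characterise each by average identity, conserved-block content, and
   average pairwise dN/dS;
6. write TSV/GraphML reports plus a run manifest.

All ordering is deterministic, so a rerun with the same inputs and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from . import __version__
from .cliques import (
    CliqueReport,
    clique_average_identity,
    conserved_block_count,
    divergent_subgraph,
    largest_clique_per_component,
    maximal_cliques,
    write_clique_reports,
)
from .codon import backthread_codon_alignment, clique_dnds
from .config import PipelineConfig
from .expansion import (
    CPRRecord,
    ExpandedSet,
    class_distances,
    classify_nodes,
    cpr_identity,
    divergence_summary,
    expand_families,
    write_class_table,
    write_cpr_table,
    write_recruits_manifest,
)
from .network import (
    FamilyNucleus,
    build_network,
    connected_components,
    export_graphml,
    select_nuclei,
    write_edge_list,
    write_nuclei_report,
)
from .records import SequenceSet
from .similarity import LocalAligner, all_vs_all
from .stats import ks_test, proportion_report


def trivial_alignment(seqs: Mapping[str, str]) -> dict[str, str] | None:
    """Gap-free alignment of equal-length sequences; None if lengths differ.

    This is the fixture aligner for planted datasets, where clique members
    share a length by construction.  Real datasets should supply externally
    produced alignments instead.
    """
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        return None
    return dict(seqs)


@dataclass
class RunManifest:
    version: str
    config: dict
    input_digests: dict[str, str]
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


@dataclass
class PipelineResult:
    """In-memory results of a full run (the TSVs' source of truth)."""

    config: PipelineConfig
    reference_net: nx.Graph
    nuclei: list[FamilyNucleus]
    expanded: ExpandedSet
    exploratory_net: nx.Graph
    class_labels: dict[str, str]
    cpr_records: list[CPRRecord]
    cliques: list[tuple[str, ...]]
    clique_reports: list[CliqueReport]
    summary: dict
    manifest: RunManifest | None = None

    @property
    def passing_nuclei(self) -> list[FamilyNucleus]:
        return [n for n in self.nuclei if n.passes]


def _digest(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()[:16]


def run_nucleus_stage(
    sequences: SequenceSet,
    config: PipelineConfig | None = None,
    engine=None,
) -> tuple[nx.Graph, list[FamilyNucleus]]:
    """Reference network over published sequences plus conductance scoring.

    This is the first pipeline stage on its own, for callers that only need
    nucleus selection (it skips recruitment and everything downstream).
    """
    cfg = config or PipelineConfig()
    if engine is None:
        engine = LocalAligner(min_score=cfg.min_align_score)
    published = [s for s in sequences if not s.is_environmental]
    ref_hits = all_vs_all(published, engine, cfg.all_vs_all_hit_cap)
    net = build_network(
        ref_hits, sequences.lengths(), sequences.origins(), cfg,
        include_singletons=[s.id for s in published],
    )
    return net, select_nuclei(net, cfg)


def run_pipeline(
    sequences: SequenceSet,
    config: PipelineConfig | None = None,
    cds: Mapping[str, str] | None = None,
    outdir: str | Path | None = None,
    hits: Sequence | None = None,
    largest_clique_only: bool = False,
) -> PipelineResult:
    """Run the whole protocol on an in-memory dataset.

    ``hits``, when given, is a pre-parsed hit table used as the similarity
    engine for every stage; otherwise the built-in local aligner is used.
    ``outdir`` enables report writing; without it the run is in-memory only.
    """
    cfg = config or PipelineConfig()
    engine = list(hits) if hits is not None else LocalAligner(min_score=cfg.min_align_score)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    published = [s for s in sequences if not s.is_environmental]
    env_db = [s for s in sequences if s.is_environmental]
    lengths = sequences.lengths()
    origins = sequences.origins()

    # stage 1: reference network + nucleus selection
    reference_net, nuclei = run_nucleus_stage(sequences, cfg, engine)
    nucleus_ids = sorted(
        i for nuc in nuclei if nuc.passes for i in nuc.member_ids
    )
    nucleus_seqs = [sequences[i] for i in nucleus_ids]
    timings["select_nuclei"] = time.perf_counter() - t0

    # stage 2: recruitment
    t = time.perf_counter()
    expanded = expand_families(nucleus_seqs, env_db, engine, cfg)
    timings["expand"] = time.perf_counter() - t

    # stage 3: exploratory network over the expanded set
    t = time.perf_counter()
    expanded_seqs = expanded.sequences
    exp_hits = all_vs_all(expanded_seqs, engine, cfg.all_vs_all_hit_cap)
    exploratory_net = build_network(
        exp_hits, lengths, origins, cfg, include_singletons=[s.id for s in expanded_seqs]
    )
    timings["exploratory_net"] = time.perf_counter() - t

    # stage 4: classes + CPR
    t = time.perf_counter()
    labels = classify_nodes(exploratory_net, nucleus_ids)
    recruited_env = [sequences[i] for i in sorted(expanded.recruited_round)]
    cpr_records = cpr_identity(recruited_env, published, engine, cfg)
    timings["classify_cpr"] = time.perf_counter() - t

    # stage 5: divergent cliques
    t = time.perf_counter()
    sub = divergent_subgraph(exploratory_net, cpr_records, cfg)
    if largest_clique_only:
        cliques = largest_clique_per_component(sub, cfg.min_clique_size)
    else:
        cliques = maximal_cliques(sub, cfg.min_clique_size)
    comp_map = connected_components(exploratory_net)
    clique_reports = []
    for k, members in enumerate(cliques):
        report = characterize_clique(
            k, members, {i: sequences[i].residues for i in members},
            cds or {}, cfg, family_component=comp_map.get(members[0]),
        )
        clique_reports.append(report)
    timings["cliques"] = time.perf_counter() - t

    summary = summarize(cfg, nuclei, expanded, labels, cpr_records, clique_reports)
    result = PipelineResult(
        cfg, reference_net, nuclei, expanded, exploratory_net, labels,
        cpr_records, cliques, clique_reports, summary,
    )

    if outdir is not None:
        t = time.perf_counter()
        manifest = write_reports(result, sequences, Path(outdir))
        manifest.stage_seconds = {**timings, "reports": time.perf_counter() - t}
        result.manifest = manifest
    return result


def characterize_clique(
    clique_id: int,
    members: Sequence[str],
    member_residues: Mapping[str, str],
    cds: Mapping[str, str],
    cfg: PipelineConfig,
    family_component: int | None = None,
) -> CliqueReport:
    """Average identity, conserved-block columns, and average ω for a clique."""
    alignment = trivial_alignment({i: member_residues[i] for i in members})
    avg_identity = None
    retained = 0
    avg_omega = None
    n_pairs = 0
    if alignment is not None:
        avg_identity = clique_average_identity(alignment)
        retained = conserved_block_count(
            alignment, cfg.conserved_fraction, cfg.max_gap_fraction, cfg.min_block_len
        )
        if all(i in cds for i in members):
            codon_aln = backthread_codon_alignment(alignment, cds)
            avg_omega, pair_results, _ = clique_dnds(codon_aln)
            n_pairs = sum(1 for _, _, r in pair_results if r.omega is not None)
    return CliqueReport(
        clique_id=clique_id,
        member_ids=tuple(members),
        family_component_id=family_component,
        avg_identity=avg_identity,
        avg_omega=avg_omega,
        n_omega_pairs=n_pairs,
        retained_block_columns=retained,
        alignable=retained > cfg.min_block_len,
    )


def summarize(
    cfg: PipelineConfig,
    nuclei: list[FamilyNucleus],
    expanded: ExpandedSet,
    labels: Mapping[str, str],
    cpr_records: Sequence[CPRRecord],
    clique_reports: Sequence[CliqueReport],
) -> dict:
    """The run's headline numbers, including the class-1 vs class-2 CPR
    comparison (one-sided KS) and the stratum-by-divergence proportion test."""
    scored = [r for r in cpr_records if r.has_cpr]
    divergent = [r for r in scored if r.cpr_identity < cfg.cpr_divergence_cutoff]
    c1 = [r.cpr_identity for r in scored if labels.get(r.env_id) == "class1"]
    c2 = [r.cpr_identity for r in scored if labels.get(r.env_id) == "class2"]
    out = {
        "n_components": len(nuclei),
        "n_nucleus_families": sum(1 for n in nuclei if n.passes),
        "n_recruited": len(expanded.recruited_round),
        "n_class1": sum(1 for v in labels.values() if v == "class1"),
        "n_class2": sum(1 for v in labels.values() if v == "class2"),
        "n_distal": sum(1 for v in labels.values() if v == "distal"),
        "n_env_scored": len(scored),
        "n_env_no_cpr": len(cpr_records) - len(scored),
        "prop_divergent": len(divergent) / len(scored) if scored else None,
        "n_cliques": len(clique_reports),
        "n_alignable_cliques": sum(1 for r in clique_reports if r.alignable),
    }
    if c1 and c2:
        d, p = ks_test(c2, c1, "a_below_b")
        out["ks_class2_below_class1_D"] = d
        out["ks_class2_below_class1_p"] = p
    gut = [r for r in scored if r.stratum == "gut"]
    nongut = [r for r in scored if r.stratum != "gut"]
    if gut and nongut:
        table = [
            [sum(1 for r in nongut if r.cpr_identity < cfg.cpr_divergence_cutoff),
             sum(1 for r in nongut if r.cpr_identity >= cfg.cpr_divergence_cutoff)],
            [sum(1 for r in gut if r.cpr_identity < cfg.cpr_divergence_cutoff),
             sum(1 for r in gut if r.cpr_identity >= cfg.cpr_divergence_cutoff)],
        ]
        out["divergence_by_stratum"] = proportion_report(table)
    omegas = [r.avg_omega for r in clique_reports if r.avg_omega is not None]
    if omegas:
        omegas = sorted(omegas)
        mid = len(omegas) // 2
        out["median_clique_omega"] = (
            omegas[mid] if len(omegas) % 2 else (omegas[mid - 1] + omegas[mid]) / 2
        )
    idents = [r.avg_identity for r in clique_reports if r.avg_identity is not None]
    if idents:
        out["mean_clique_identity"] = sum(idents) / len(idents)
    return out


def write_reports(result: PipelineResult, sequences: SequenceSet, outdir: Path) -> RunManifest:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    outputs: dict[str, str] = {}

    def record(name: str, path: Path):
        outputs[name] = str(path)

    p = outdir / "nuclei.tsv"
    write_nuclei_report(result.nuclei, p, cfg.conductance_domains)
    record("nuclei", p)

    p = outdir / "recruits.tsv"
    write_recruits_manifest(result.expanded, p)
    record("recruits", p)

    p = outdir / "edges.tsv"
    write_edge_list(result.exploratory_net, p)
    record("edges", p)

    distances = class_distances(result.exploratory_net, [
        i for n in result.passing_nuclei for i in n.member_ids
    ])
    p = outdir / "classes.tsv"
    write_class_table(result.class_labels, distances, p)
    record("classes", p)

    p = outdir / "cpr.tsv"
    write_cpr_table(result.cpr_records, p)
    record("cpr", p)

    p = outdir / "cpr_histogram.tsv"
    divergence_summary(
        result.cpr_records, [0, 60, 95, 100]
    ).to_csv(p, sep="\t", float_format="%.6f")
    record("cpr_histogram", p)

    p = outdir / "cliques.tsv"
    write_clique_reports(result.clique_reports, p)
    record("cliques", p)

    annotations = {
        r.env_id: {"cpr_identity": r.cpr_identity} for r in result.cpr_records if r.has_cpr
    }
    for node, lab in result.class_labels.items():
        annotations.setdefault(node, {})["class"] = lab
    p = outdir / "exploratory.graphml"
    export_graphml(result.exploratory_net, p, annotations)
    record("graphml", p)

    p = outdir / "summary.json"
    Path(p).write_text(json.dumps(result.summary, indent=2, sort_keys=True) + "\n")
    record("summary", p)

    digest_src = "".join(
        f"{s.id}:{s.residues}:{s.origin}:{s.sample_id};" for s in sorted(sequences, key=lambda r: r.id)
    )
    manifest = RunManifest(
        version=__version__,
        config=cfg.to_dict(),
        input_digests={"sequences": _digest(digest_src.encode())},
        outputs=outputs,
    )
    manifest.to_json(outdir / "manifest.json")
    outputs["manifest"] = str(outdir / "manifest.json")
    return manifest
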