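"""Synthetic datasets with planted network structure.

The generator emits protein (and coding) sequences whose pairwise identity
structure is controlled, so every stage of the pipeline can be tested
against a known truth table:

* two prokaryotic domain clades per family, mutually recognisable
  (about 60 % identity across domains over their shared core, about 75 %
  within a domain);
* for families planted to *pass* the conductance filter, bacterial members
  carry a domain-specific C-terminal extension.  Cross-domain alignments
  then cover only the shared core and fail the 80 % mutual-coverage rule,
  except through a single short-extension "bridge" member — reproducing the
  low-conductance topology of an ancient, rarely transferred family.
  Families planted to *fail* lack the extensions, so every cross-domain
  pair connects and conductance is high;
* environmental clades at controlled divergence: class-1-like clades within
  edge range of the nuclei, class-2-like clades within edge range of a
  class-1 clade but out of range of any nucleus, each with a planted
  closest-published-relative (CPR) identity band and a sample stratum;
* fragments — truncated copies of nucleus members — whose hits violate the
  coverage rule, so they acquire no edges to any full-length sequence;
* coding sequences, either back-threaded consistently with the proteins
  (synonymous noise added) or evolved de novo under a specified dN/dS.

Divergence is modelled as site-wise substitution with a uniform replacement
alphabet: identity bands, not biochemical realism, are the contract here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .codon import GENETIC_CODE, STOP_CODONS
from .records import PROTEIN_ALPHABET, SequenceRecord, SequenceSet


class SimConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class EnvCladeSpec:
    """One planted environmental clade.

    ``anc_identity`` is the percent identity of the clade ancestor to its
    attachment point (the archaeal ancestor for class-1 clades, the parent
    class-1 clade's ancestor for class-2 clades); ``member_identity`` is the
    identity of each member to the clade ancestor.
    """

    name: str
    size: int = 4
    attach: str = "class1"              # "class1" | "class2"
    parent: str | None = None           # class-2 clades name their class-1 parent
    anc_identity: float = 50.0
    member_identity: float = 92.5
    sample: str = "aquatic"
    omega: float | None = None          # intended dN/dS for de-novo codon evolution
    #: identity of an extra Published-origin relative emitted for this clade,
    #: emulating a distant database relative; None = the nuclei are the only
    #: published relatives this clade has.
    published_relative_identity: float | None = None


@dataclass(frozen=True)
class FamilySpec:
    name: str
    n_archaea: int = 7
    n_bacteria: int = 7
    planted_pass: bool = True
    env_clades: tuple[EnvCladeSpec, ...] = ()
    n_fragments: int = 0


def default_env_clades() -> tuple[EnvCladeSpec, ...]:
    """The default planted environmental structure for a passing family:
    a divergent class-1 clade (CPR ~40 %), a conserved gut-like class-1
    clade (CPR ~90 %), and a divergent class-2 clade hanging off the first.
    """
    return (
        EnvCladeSpec("c1div", size=4, attach="class1", anc_identity=50.0,
                     member_identity=92.5, sample="aquatic"),
        EnvCladeSpec("c1gut", size=3, attach="class1", anc_identity=97.0,
                     member_identity=97.0, sample="gut"),
        EnvCladeSpec("c2div", size=4, attach="class2", parent="c1div",
                     anc_identity=45.0, member_identity=92.5, sample="aquatic",
                     published_relative_identity=40.0),
    )


@dataclass
class SimConfig:
    """Generator configuration; the defaults are the study conditions every
    planted-truth test runs under."""

    protein_length: int = 200
    n_pass_families: int = 1
    n_fail_families: int = 1
    #: identity of each domain member to its domain ancestor; two members are
    #: then pairwise ~ (x/100)^2, i.e. 87 -> ~75 % within-domain identity.
    intra_member_identity: float = 87.0
    #: identity of the bacterial core ancestor to the archaeal ancestor;
    #: cross-domain member pairs land near (80 * .87 * .87) ~ 60 %.
    inter_core_identity: float = 80.0
    #: bacterial C-terminal extension, as a fraction of the core length.
    extension_fraction: float = 0.35
    #: the bridge member's shorter extension fraction.
    bridge_extension_fraction: float = 0.125
    fragment_length_fraction: float = 0.4
    families: tuple[FamilySpec, ...] | None = None
    #: per-codon probability of a random synonymous codon swap when threading
    #: CDS behind evolved proteins.
    synonymous_noise: float = 0.2
    rng_seed: int = 0
    min_adjusted_identity: float = 30.0   # edge threshold the bands must respect

    def __post_init__(self) -> None:
        if self.protein_length < 20:
            raise SimConfigError("protein_length must be >= 20")
        if self.families is None:
            fams = []
            for k in range(self.n_pass_families):
                fams.append(FamilySpec(f"fam{k}", planted_pass=True,
                                       env_clades=default_env_clades(), n_fragments=2))
            for k in range(self.n_fail_families):
                fams.append(FamilySpec(f"xfam{k}", planted_pass=False))
            self.families = tuple(fams)
        self._validate_bands()

    def _validate_bands(self) -> None:
        depth = self.intra_member_identity / 100
        for fam in self.families:
            c1 = {c.name: c for c in fam.env_clades if c.attach == "class1"}
            for clade in fam.env_clades:
                if clade.attach == "class2":
                    if clade.parent not in c1:
                        raise SimConfigError(
                            f"{fam.name}/{clade.name}: class-2 clade needs a "
                            f"class-1 parent, got {clade.parent!r}"
                        )
                    par = c1[clade.parent]
                    # expected identity of a class-2 member to a nucleus member
                    to_nucleus = (par.anc_identity / 100) * (clade.anc_identity / 100) \
                        * (clade.member_identity / 100) * depth * 100
                    if to_nucleus >= self.min_adjusted_identity - 3:
                        raise SimConfigError(
                            f"{fam.name}/{clade.name}: planted class-2 band "
                            f"(~{to_nucleus:.0f}% to nuclei) overlaps the edge "
                            f"threshold {self.min_adjusted_identity}%"
                        )

    def expected_cpr(self, fam: FamilySpec, clade: EnvCladeSpec) -> float:
        """Expected CPR identity (percent) of a clade member, by composition
        of the planted substitution fractions.  When the clade carries its
        own published relative, that relative is the closest published
        sequence; otherwise the path runs through the nucleus members."""
        if clade.published_relative_identity is not None:
            return (clade.published_relative_identity / 100) \
                * (clade.member_identity / 100) * 100
        depth = self.intra_member_identity / 100
        path = (clade.anc_identity / 100) * (clade.member_identity / 100)
        if clade.attach == "class2":
            par = next(c for c in fam.env_clades if c.name == clade.parent)
            path *= par.anc_identity / 100
        return path * depth * 100


@dataclass(frozen=True)
class TruthRow:
    seq_id: str
    family: str
    clade: str
    origin: str
    sample: str
    intended_class: str        # nucleus | class1 | class2 | fragment
    family_passes: bool
    cpr_low: float | None = None
    cpr_high: float | None = None
    intended_omega: float | None = None


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    def by_id(self) -> dict[str, TruthRow]:
        return {r.seq_id: r for r in self.rows}

    def ids_with_class(self, label: str) -> list[str]:
        return [r.seq_id for r in self.rows if r.intended_class == label]

    def to_tsv(self, path: str | Path) -> None:
        cols = ["seq_id", "family", "clade", "origin", "sample", "intended_class",
                "family_passes", "cpr_low", "cpr_high", "intended_omega"]
        lines = ["\t".join(cols)]
        for r in self.rows:
            vals = [r.seq_id, r.family, r.clade, r.origin, r.sample,
                    r.intended_class, str(r.family_passes)]
            for x in (r.cpr_low, r.cpr_high, r.intended_omega):
                vals.append("" if x is None else format(x, ".17g"))
            lines.append("\t".join(vals))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        lines = Path(path).read_text().splitlines()
        rows = []
        for line in lines[1:]:
            p = line.split("\t")
            opt = [None if x == "" else float(x) for x in p[7:10]]
            rows.append(TruthRow(p[0], p[1], p[2], p[3], p[4], p[5],
                                 p[6] == "True", *opt))
        return cls(rows)


# ---------------------------------------------------------------------------
# Protein-level evolution


def evolve_protein(ancestor: str, target_identity: float, rng: np.random.Generator,
                   alphabet: str = PROTEIN_ALPHABET) -> str:
    """Descendant at (very nearly) the target percent identity.

    Substitutes a uniformly chosen distinct set of positions, each to a
    uniformly drawn different residue, sized so the realized identity equals
    the target up to rounding (always within the ±3-point band the rest of
    the generator assumes).
    """
    if not ancestor:
        raise GenerationError("ancestor must be non-empty")
    if not 0 < target_identity <= 100:
        raise GenerationError("target_identity must be in (0, 100]")
    n = len(ancestor)
    n_sub = int(round((1 - target_identity / 100) * n))
    if n_sub == 0:
        return ancestor
    positions = rng.choice(n, size=n_sub, replace=False)
    seq = list(ancestor)
    for pos in positions:
        choices = [a for a in alphabet if a != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
    return "".join(seq)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(PROTEIN_ALPHABET[i] for i in rng.integers(len(PROTEIN_ALPHABET), size=length))


def hamming_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length ungapped sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


# ---------------------------------------------------------------------------
# Codon-level evolution


def random_cds_for_protein(protein: str, rng: np.random.Generator) -> str:
    """Random coding sequence translating to the protein (no stop codon)."""
    by_aa: dict[str, list[str]] = {}
    for codon, aa in GENETIC_CODE.items():
        by_aa.setdefault(aa, []).append(codon)
    out = []
    for aa in protein:
        codons = sorted(by_aa[aa])
        out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def evolve_cds(cds: str, omega: float, n_events: int, rng: np.random.Generator) -> str:
    """Evolve a CDS by point-mutation proposals with selection on ω.

    Each event proposes a uniform nucleotide change at a uniform position;
    proposals creating a stop codon are rejected, synonymous proposals are
    accepted, nonsynonymous ones accepted with probability ``omega``.
    """
    if omega <= 0:
        raise SimConfigError("omega must be positive")
    seq = list(cds)
    L = len(seq)
    for _ in range(n_events):
        pos = int(rng.integers(L))
        alts = [c for c in "ACGT" if c != seq[pos]]
        alt = alts[rng.integers(3)]
        start = pos - pos % 3
        old_codon = "".join(seq[start:start + 3])
        new_codon = old_codon[:pos - start] + alt + old_codon[pos - start + 1:]
        if new_codon in STOP_CODONS:
            continue
        if GENETIC_CODE[new_codon] != GENETIC_CODE[old_codon] and rng.random() >= omega:
            continue
        seq[pos] = alt
    return "".join(seq)


def simulate_codons(
    ancestor_protein: str,
    n_members: int,
    omega: float,
    branch_scale: float,
    rng: np.random.Generator,
    member_ids: Sequence[str] | None = None,
) -> dict[str, str]:
    """De-novo codon clade under a specified ω.

    Each member descends independently from a random ancestor CDS along a
    branch of ``branch_scale`` proposal events per nucleotide site.  The
    proteins of the clade are, by construction, the translations of the
    returned coding sequences.
    """
    anc = random_cds_for_protein(ancestor_protein, rng)
    n_events = int(round(branch_scale * len(anc)))
    ids = list(member_ids) if member_ids else [f"m{k}" for k in range(n_members)]
    return {i: evolve_cds(anc, omega, n_events, rng) for i in ids[:n_members]}


def synonymous_point_mutations(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Pure synonymous divergence: each codon, with probability ``rate``,
    moves to a random *single-nucleotide* synonymous neighbour.

    Restricting to one synonymous point step per codon guarantees that every
    codon difference to the input decomposes into synonymous substitutions
    only — the pair then has exactly dN = 0 under path counting, which a
    multi-step synonymous shuffle (through e.g. the two serine codon
    islands) would not guarantee.
    """
    out = []
    for k in range(0, len(cds), 3):
        codon = cds[k:k + 3]
        neighbours = [
            codon[:p] + alt + codon[p + 1:]
            for p in range(3)
            for alt in "ACGT"
            if alt != codon[p]
            and codon[:p] + alt + codon[p + 1:] not in STOP_CODONS
            and GENETIC_CODE.get(codon[:p] + alt + codon[p + 1:]) == GENETIC_CODE.get(codon)
        ]
        if neighbours and rng.random() < rate:
            codon = neighbours[rng.integers(len(neighbours))]
        out.append(codon)
    return "".join(out)


def _syn_alternatives(codon: str) -> list[str]:
    aa = GENETIC_CODE[codon]
    return sorted(c for c, a in GENETIC_CODE.items() if a == aa and c != codon)


def thread_cds_behind_protein(
    ancestor_cds: str,
    member_protein: str,
    ancestor_protein: str,
    synonymous_noise: float,
    rng: np.random.Generator,
) -> str:
    """A member CDS consistent with an already-evolved member protein.

    Positions where the member protein changed get a random codon of the new
    residue; unchanged positions keep the ancestral codon or, with
    probability ``synonymous_noise``, swap to a random synonymous codon —
    this is what gives family coding sequences a nonzero dS.
    """
    by_aa: dict[str, list[str]] = {}
    for codon, aa in GENETIC_CODE.items():
        by_aa.setdefault(aa, []).append(codon)
    out = []
    for i, aa in enumerate(member_protein):
        anc_codon = ancestor_cds[3 * i:3 * i + 3]
        if aa != ancestor_protein[i]:
            codons = sorted(by_aa[aa])
            out.append(codons[rng.integers(len(codons))])
        else:
            alts = _syn_alternatives(anc_codon)
            if alts and rng.random() < synonymous_noise:
                out.append(alts[rng.integers(len(alts))])
            else:
                out.append(anc_codon)
    return "".join(out)


# ---------------------------------------------------------------------------
# Whole-dataset simulation


@dataclass
class SimulatedDataset:
    proteins: SequenceSet
    cds: dict[str, str]
    truth: TruthTable
    config: SimConfig


def simulate_family(
    spec: FamilySpec, cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[SequenceRecord], dict[str, str], list[TruthRow]]:
    """Generate one family's sequences, coding sequences, and truth rows."""
    L = cfg.protein_length
    depth = cfg.intra_member_identity
    records: list[SequenceRecord] = []
    cds: dict[str, str] = {}
    rows: list[TruthRow] = []

    arch_anc = random_protein(L, rng)
    bact_core_anc = evolve_protein(arch_anc, cfg.inter_core_identity, rng)
    ext_len = int(round(cfg.extension_fraction * L))
    bridge_len = int(round(cfg.bridge_extension_fraction * L))
    ext_anc = random_protein(ext_len, rng) if spec.planted_pass else ""

    def add(seq_id, residues, origin, sample, clade, klass, cpr=None, omega=None):
        records.append(SequenceRecord(seq_id, residues, alphabet="protein",
                                      origin=origin, sample_id=sample))
        rows.append(TruthRow(seq_id, spec.name, clade, origin, sample, klass,
                             spec.planted_pass,
                             None if cpr is None else cpr[0],
                             None if cpr is None else cpr[1],
                             omega))

    arch_members: list[str] = []
    for k in range(spec.n_archaea):
        seq = evolve_protein(arch_anc, depth, rng)
        arch_members.append(seq)
        add(f"{spec.name}_A{k}", seq, "Archaea", "", "archaea", "nucleus")
    for k in range(spec.n_bacteria):
        core = evolve_protein(bact_core_anc, depth, rng)
        if spec.planted_pass:
            # member 0 is the bridge: short extension keeps cross-domain
            # coverage above the 80 % rule for this one member only
            ext_src = ext_anc[:bridge_len] if k == 0 else ext_anc
            ext = evolve_protein(ext_src, depth, rng) if ext_src else ""
            seq = core + ext
        else:
            seq = core
        add(f"{spec.name}_B{k}", seq, "Bacteria", "", "bacteria", "nucleus")

    clade_ancestors: dict[str, str] = {}
    for clade in spec.env_clades:
        if clade.attach == "class1":
            anc = evolve_protein(arch_anc, clade.anc_identity, rng)
        else:
            anc = evolve_protein(clade_ancestors[clade.parent], clade.anc_identity, rng)
        clade_ancestors[clade.name] = anc
        if clade.published_relative_identity is not None:
            rel = evolve_protein(anc, clade.published_relative_identity, rng)
            add(f"{spec.name}_{clade.name}_rel", rel, "Published", "",
                f"{clade.name}_rel", "published")
        anc_cds = random_cds_for_protein(anc, rng)
        exp = cfg.expected_cpr(spec, clade)
        band = (max(exp - 10.0, 0.0), min(exp + 10.0, 100.0))
        for k in range(clade.size):
            seq = evolve_protein(anc, clade.member_identity, rng)
            seq_id = f"{spec.name}_{clade.name}_{k}"
            add(seq_id, seq, "Environment", clade.sample, clade.name,
                clade.attach, cpr=band, omega=clade.omega)
            cds[seq_id] = thread_cds_behind_protein(
                anc_cds, seq, anc, cfg.synonymous_noise, rng)

    frag_len = int(round(cfg.fragment_length_fraction * L))
    for k in range(spec.n_fragments):
        src = arch_members[k % len(arch_members)]
        add(f"{spec.name}_frag{k}", src[:frag_len], "Environment", "aquatic",
            "fragment", "fragment")
    return records, cds, rows


def simulate_dataset(cfg: SimConfig | None = None) -> SimulatedDataset:
    """Generate the full dataset the default study conditions describe.

    Deterministic for a fixed ``rng_seed``: the same seed yields
    byte-identical FASTA, CDS, and truth outputs.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    proteins = SequenceSet()
    cds: dict[str, str] = {}
    truth = TruthTable()
    for spec in cfg.families:
        records, fam_cds, rows = simulate_family(spec, cfg, rng)
        for rec in records:
            proteins.add(rec)
        cds.update(fam_cds)
        truth.rows.extend(rows)
    return SimulatedDataset(proteins, cds, truth, cfg)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write protein FASTA, CDS FASTA, metadata TSV, and truth TSV."""
    from .records import write_fasta, write_metadata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": outdir / "proteins.fasta",
        "cds": outdir / "cds.fasta",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(list(ds.proteins), paths["proteins"])
    cds_records = [
        SequenceRecord(i, s, alphabet="dna", origin=ds.proteins[i].origin,
                       sample_id=ds.proteins[i].sample_id)
        for i, s in sorted(ds.cds.items())
    ]
    write_fasta(cds_records, paths["cds"])
    write_metadata(list(ds.proteins), paths["metadata"])
    ds.truth.to_tsv(paths["truth"])
    return paths
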