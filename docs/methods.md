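# Methods

This note documents the models and procedures `seqsimnet` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Similarity engine

Pairwise similarity comes either from BLAST-style tabular files (12-column
`outfmt 6`, or 14-column with `qlen slen` appended) or from the built-in
local aligner: Smith–Waterman with affine gaps via Biopython's
`PairwiseAligner` (BLOSUM62; gap open 11, extend 1, i.e. a gap of length k
costs 11 + k).  Percent identity is identical columns over aligned columns
*including* gap columns — the BLAST denominator — so gappy alignments are
not flattered.

Two derived quantities drive everything downstream:

* **coverage-rescaled identity** = pident × min(aln_len / min(len_q,
  len_s), 1).  The cap at 1 guards against gap-inflated alignment lengths
  and malformed coordinates.
* **mutual coverage** = the aligned span as a fraction of each sequence.

When several HSPs exist for an ordered pair, only the best (highest
bitscore, then lowest e-value) is kept; an unordered pair is judged on the
better of its two directional hits, with coverage of both sequences taken
from that single alignment.

The built-in aligner's e-value is a Karlin–Altschul-style surrogate,
E = K·m·N·exp(−λS) with λ = 0.267, K = 0.041 (the conventional gapped
BLOSUM62 constants) and an effective search space N = 1e15 residues.  N is
an operating-point choice, not a physical database size: it places the
significance threshold at E < 1e-5 near raw score 180 (~70 bits) for a
200-residue query, which is what a genuinely large database search demands
of a hit.  With a smaller N, chance local matches between unrelated
~200-residue sequences (raw scores straggling up to ~150 in the synthetic
datasets) would count as significant and recruitment would lose its
specificity.  The surrogate is rank-consistent with the raw score and
comparable across a run; it is not a calibrated BLAST e-value, and analyses
that need real e-values should supply hit tables.

## Network construction and nucleus selection

The similarity network is a simple undirected graph; an edge requires all
three filters at once: e-value < `max_evalue` (1e-5), coverage-rescaled
identity ≥ `min_adjusted_identity` (30 %, inclusive), and mutual coverage
≥ `min_mutual_coverage` (0.80) of *both* sequences.  The identity bound is
inclusive (≥ 30) and the mutual-coverage condition is enforced for every
network, including the initial reference network: it is the condition that
prevents a shared domain or fragment from fusing unrelated families.

For a domain D within a connected component, conductance is the ratio of
external edges (one endpoint in D, both endpoints in the component) to
internal edges (both endpoints in D).  Zero external edges gives 0; a
positive numerator over zero internal edges gives +∞.  Sequences from
other origins (Eukaryote, MGE, Environment) count as "outside D" in the
numerator.  A component is selected as a **nucleus family** when at least
two configured domains each have conductance strictly below
`conductance_threshold` (0.4) *and* at least one internal edge — a domain
with no internal edge has no cohesive group to be conserved, so an absent
or scattered domain can never contribute to the pass.  Edge
classification is confined to within-component edges (between connected
components there are, by definition, none).

All orderings are deterministic: components are numbered by smallest
member id, hits are ranked by bitscore, then e-value, then subject id, and
every output table is sorted, so identical inputs and seed give
byte-identical outputs.

## Recruitment and topological classes

Recruitment filters on e-value only, with a per-seed hit cap
(`recruit_hit_cap`, 500); the identity/coverage filter is deliberately
deferred to network reconstruction.  This looseness is what produces the
bridge phenomenon: round-1 recruits connect the nuclei to round-2 recruits
that no nucleus hits directly.  Recruitment operates on predicted
protein/ORF sequences throughout; recovering frameshifted nucleotide
matches is out of scope.  Recruitment is monotone in the number of rounds
(an id, once recruited, keeps the round number of its first recruitment).

In the rebuilt exploratory network (per-query cap `all_vs_all_hit_cap`,
5000), nodes are labeled by breadth-first distance from the nucleus set:
distance 1 = class 1, distance 2 = class 2, anything farther or
disconnected = distal (retained and reported, not discarded).  Nucleus
adjacency wins: a node adjacent to both a nucleus and a class-1 node is
class 1.

The **closest published relative** (CPR) of an environmental sequence is
the published sequence with the highest coverage-rescaled identity among
hits with e-value < 1e-5 (ties: higher bitscore, then lexicographically
smaller id); "published" means all non-environmental sequences, nuclei
included.  A sequence with no qualifying hit is recorded explicitly as
having no CPR — never as identity 0 — and is excluded from histograms but
counted in a separate row.  Note that a class-1 sequence can still be
highly divergent (CPR below 60 %): edge thresholds bound the identity to
*one* nucleus neighbour from below by 30 %, not by the divergence cutoff.

## Divergent cliques

The divergent subgraph is induced on environmental nodes with CPR identity
strictly below `cpr_divergence_cutoff` (60 %); no-CPR nodes are excluded
by default (configurable).  Maximal cliques come from Bron–Kerbosch with
pivoting (pivot = candidate with most neighbours in the candidate set),
with canonical output ordering and a node-count guard (default 10,000)
against pathological inputs.  All maximal cliques of size ≥
`min_clique_size` are reported; the default minimum is 3, because a pair
of similar sequences is not evidence of a diversified group (configurable
to 2).  A `--largest-per-component` mode keeps one clique per connected
component of the divergent subgraph (the largest; ties go to the
lexicographically smallest member tuple) for users who want
non-overlapping groups.

Cliques are characterised on a multiple alignment of their members.  Real
datasets should supply externally produced alignments (aligned FASTA); for
planted data the members share a length by construction and a trivial
gap-free alignment is used.  Average identity is the mean over unordered
pairs of identical columns / mutually non-gap columns × 100; a pair with
no mutually non-gap column is excluded (undefined overall if every pair
is).

The **conserved-block filter** is a deliberately small, three-parameter
stand-in for full alignment-trimming heuristics, since only the
retained-column count feeds downstream decisions: a column is conserved
when its gap fraction is ≤ `max_gap_fraction` (0) and its majority residue
is shared by strictly more than `conserved_fraction` (0.5) of the
sequences; contiguous runs of ≥ `min_block_len` (10) conserved columns are
retained, and a clique is "alignable" when more than 10 columns survive.
The count is monotone non-increasing in the conserved-fraction parameter.

## dN/dS (ω) estimation

Pairwise ω uses Nei–Gojobori (1986) counting.  Sites: each codon position
contributes 1/3 of a site per possible point mutation, synonymous or
nonsynonymous by the universal code; mutations that would create a stop
codon are excluded from the site opportunity entirely (so S + N < 3 for
stop-adjacent codons), and site counts are averaged over the two
sequences.  Differences: codons differing at k positions are decomposed
over all k! orderings of the substitutions; paths passing through a stop
codon are dropped, the rest are weighted equally (no transition/
transversion weighting); a codon pair whose every path crosses a stop is
excluded from the comparison (with its site mass) and counted.  Columns
with gaps, ambiguity codes, or stop codons in either sequence are likewise
skipped.  Proportions pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4; ω = dN/dS is undefined when
dS = 0 or either correction saturates.  The estimator is exactly symmetric
in its arguments.  Results carry a `method` tag ("NG86") so a
Yang–Nielsen-style estimator with ts/tv and codon-frequency corrections
could be added later; NG86 is sufficient for the purpose the ratio serves
here — establishing purifying selection — and recovers simulated ω within
±0.1 at 500 codons over 100 replicate pairs (verified for ω 0.2 and 1.0 in
the acceptance suite).

A clique's average ω is the mean of its defined pairwise ω values; pairs
with undefined ω (identical pairs, saturated dS — common between clades
whose coding sequences share no recent ancestor) are excluded from the
mean and reported as a count.  Codon alignments are obtained by
back-threading the protein alignment with the unaligned coding sequences:
each residue column expands to its codon, each gap to `---`; a trailing
stop codon is stripped, and each CDS must translate exactly to its protein
(validation names the first offending residue).

## Synthetic data: what is planted and what is not

The generator's defaults are the study conditions the tests and the
acceptance script run under.  Proteins are 200 residues; divergence is
site-wise substitution with a uniform replacement alphabet over a 20-letter
protein alphabet.  `evolve_protein` substitutes an exact number of
distinct positions, so a descendant's identity to its ancestor equals the
target up to rounding; identities between two descendants compose
multiplicatively (87 % to the ancestor ⇒ ~75 % pairwise).

Each dataset holds one family planted to **pass** the conductance filter
and one planted to **fail**:

* *Pass family* — 7 archaeal and 7 bacterial members; the bacterial
  ancestor's conserved core sits at 80 % of the archaeal ancestor (so
  cross-domain member pairs land near 60 % identity — clearly homologous,
  clearly divergent), but bacterial members carry a C-terminal extension
  (35 % of the core length) that pushes cross-domain mutual coverage below
  the 80 % rule.  One bridge member has a short extension (12.5 %), so
  exactly the bridge's cross-domain edges survive: conductance 1/3 for
  both domains, and the component stays connected.  This reproduces, by a
  concrete mechanism (domain-specific architecture breaking mutual
  coverage), the low-conductance topology of an ancient rarely transferred
  family.
* *Fail family* — identical construction without extensions: every
  cross-domain pair connects and conductance is ~2.3 for both domains.

Environmental structure attached to the pass family: a divergent class-1
clade (ancestor at 50 % of the archaeal ancestor, members at 92.5 %,
planted CPR ≈ 40 %), a conserved "gut" class-1 clade (97 %/97 %, CPR ≈
83 %), and a divergent class-2 clade hanging off the first (45 % of the
class-1 ancestor ⇒ ~18 % to any nucleus, safely outside both edge range
and e-value significance, while staying at ~38 % to the class-1 clade).
The class-2 clade also gets a *published relative* at 40 % of its ancestor
— emulating the breadth of a real reference database — which is what gives
class-2 sequences a defined CPR (≈ 37 %) below the class-1 clade's, so the
class-1 vs class-2 divergence contrast (one-sided KS) is planted in the
expected direction.  Two fragments (40 % of a nucleus member's length) are
emitted as environmental sequences; they are recruited (near-identity
hits) but acquire no edges to full-length sequences, demonstrating the
coverage rule.  The generator refuses configurations whose class-2 band
would overlap the edge threshold toward the nuclei.

Coding sequences exist in two flavours.  For family clades, CDS are
threaded behind the already-evolved proteins: ancestral codons are kept
where the residue is unchanged (with probability 0.2 of a random
synonymous swap — this is what gives within-clade pairs a realized ω well
below 1) and replaced by a random codon of the new residue otherwise;
ω here is emergent, not controlled.  For controlled-ω experiments,
`simulate_codons`/`evolve_cds` evolve codons de novo: uniform
point-mutation proposals, stop proposals rejected, synonymous proposals
accepted, nonsynonymous accepted with probability ω (branch length 0.05
proposals per site by default) — exactly the mutation model NG86 assumes,
which is what makes the recovery test a calibration of the estimator
rather than of the generator.  A separate single-step synonymous mutator
exists for the dN = 0 contract: it moves codons only to single-nucleotide
synonymous neighbours, because multi-step synonymous shuffles (e.g. across
the two serine codon islands) produce codon pairs whose minimal paths
cross nonsynonymous intermediates and would legitimately yield dN > 0.

What the generator does **not** emulate: empirical substitution matrices
and residue composition (uniform replacement is the contract — identity
bands, not biochemistry), indels within homologous cores, rate
heterogeneity across sites, codon usage bias, sequencing error,
recombination, and chimerism.  Passing tests therefore demonstrate that
the pipeline recovers planted *identity/topology structure* under its own
stated filters, not that those filters are optimal for any particular real
dataset.

## Problem sizes and reproducibility

The test and acceptance workloads are sized for a single CPU: ~42-sequence
datasets, 100 seeded replicates for nucleus recovery (conductance
pass/fail), 10 full pipeline replicates for class labels, CPR fractions
and clique statistics, 200 random ≤12-node graphs against each brute-force
oracle (conductance and clique enumeration), and 100 replicate pairs × 500
codons per simulated ω.  Every random draw descends from a single seed;
`scripts/acceptance.py --seed N --out f.json` derives all replicate seeds
from N and writes each measured quantity with the problem size it came
from.  Two runs with the same inputs and seed produce byte-identical
tables.

## Known limitations

* The built-in aligner is O(n·m) per pair and all-vs-all is O(k²) pairs;
  it is a desk-scale engine.  Large datasets should supply precomputed hit
  tables.
* The e-value surrogate is rank-consistent, not calibrated; analyses that
  hinge on absolute e-values need real search output.
* The conserved-block filter is a simplification, not a re-implementation
  of full trimming heuristics; only its retained-column count is used.
* NG86 omits ts/tv bias and codon-frequency corrections; clique averages
  exclude undefined pairs, which biases averages toward the less diverged
  pairs when saturation is widespread (the excluded count is reported
  alongside).
* Multiple alignment of real (unequal-length) cliques is an external
  step; the built-in gap-free alignment only serves equal-length planted
  data.
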