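"""Pairwise dN/dS on codon alignments, Nei–Gojobori (1986) style.

The ratio ω = dN/dS compares the rate of nonsynonymous (amino-acid
changing) to synonymous (silent) substitution; ω well below 1 is the
signature of purifying selection and is what distinguishes a real,
functioning gene family from pseudogenes or sequencing artefacts.

The estimator counts synonymous (S) and nonsynonymous (N) *sites* by the
fractional method — each codon position contributes 1/3 of a site per
possible point mutation, classified by whether the mutation is silent —
and synonymous/nonsynonymous *differences* (Sd, Nd) by averaging over all
minimal mutational paths between the two observed codons.  Mutations that
would create a stop codon are excluded both from the site opportunity and
from the difference paths.  Proportions pS = Sd/S and pN = Nd/N are
corrected for multiple hits with the Jukes–Cantor transform
d = -(3/4)·ln(1 - (4/3)p), which is undefined at p >= 3/4 (saturation).

Codon alignments are not built here: a protein alignment is *back-threaded*
with the unaligned coding sequences, each residue column expanding to its
codon and each gap to ``---``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

_STANDARD = unambiguous_dna_by_id[1]

#: codon -> amino acid for the universal code; stop codons absent.
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

_NUCS = "ACGT"


class CodonValidationError(ValueError):
    pass


def translate_codon(codon: str, code: Mapping[str, str] | None = None) -> str | None:
    """Amino acid for a codon, '*' for stop, None if ambiguous/gapped."""
    code = code or GENETIC_CODE
    if codon in STOP_CODONS:
        return "*"
    return code.get(codon)


def codon_sites(codon: str, code: Mapping[str, str] | None = None) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one codon.

    Each of the nine possible point mutations carries 1/3 site; mutations to
    stop codons are excluded from the opportunity altogether, so S + N can be
    below 3 for stop-adjacent codons.
    """
    code = code or GENETIC_CODE
    aa = translate_codon(codon, code)
    if aa is None or aa == "*":
        raise CodonValidationError(f"cannot count sites for codon {codon!r}")
    s = n = 0.0
    for pos in range(3):
        for alt in _NUCS:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            if code[mutant] == aa:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def codon_path_differences(
    a: str, b: str, code: Mapping[str, str] | None = None
) -> tuple[float, float] | None:
    """(synonymous, nonsynonymous) differences between two codons.

    Averages over all minimal substitution paths that never pass through a
    stop codon, each path weighted equally.  Returns None when every minimal
    path passes through a stop (the codon pair is then not comparable).
    """
    code = code or GENETIC_CODE
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in permutations(diff_pos):
        cur = a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if code[cur] == code[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return None
    k = len(totals)
    return sum(t[0] for t in totals) / k, sum(t[1] for t in totals) / k


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass
class NG86Result:
    """Pairwise dN/dS estimate; ``method`` tags the counting scheme."""

    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0
    pS: float | None = None
    pN: float | None = None
    dS: float | None = None
    dN: float | None = None
    omega: float | None = None
    n_codons: int = 0            # comparable codon columns
    n_excluded: int = 0          # gapped/ambiguous/stop/stop-path columns
    flags: list[str] = field(default_factory=list)
    method: str = "NG86"


def _is_clean_codon(codon: str, code: Mapping[str, str]) -> bool:
    return all(c in _NUCS for c in codon) and codon not in STOP_CODONS and codon in code


def ng86_pair(
    codons_a: str,
    codons_b: str,
    code: Mapping[str, str] | None = None,
) -> NG86Result:
    """NG86 estimate for a pair of equal-length codon strings.

    Columns with gaps, ambiguity codes, or stop codons in either sequence
    are skipped, as are columns whose every minimal path crosses a stop.
    The result is symmetric in the two sequences (site counts are averaged
    over both).
    """
    if len(codons_a) != len(codons_b):
        raise CodonValidationError("codon strings differ in length")
    if len(codons_a) % 3:
        raise CodonValidationError("codon string length is not a multiple of 3")
    code = code or GENETIC_CODE
    res = NG86Result()
    for k in range(0, len(codons_a), 3):
        ca, cb = codons_a[k:k + 3], codons_b[k:k + 3]
        if not (_is_clean_codon(ca, code) and _is_clean_codon(cb, code)):
            res.n_excluded += 1
            continue
        diffs = codon_path_differences(ca, cb, code)
        if diffs is None:
            res.n_excluded += 1
            continue
        sa, na = codon_sites(ca, code)
        sb, nb = codon_sites(cb, code)
        res.S += (sa + sb) / 2
        res.N += (na + nb) / 2
        res.Sd += diffs[0]
        res.Nd += diffs[1]
        res.n_codons += 1
    if res.n_codons == 0 or res.S == 0 or res.N == 0:
        res.flags.append("no_comparable_codons")
        return res
    res.pS = res.Sd / res.S
    res.pN = res.Nd / res.N
    res.dS = _jc_correct(res.pS)
    res.dN = _jc_correct(res.pN)
    if res.dS is None:
        res.flags.append("dS_saturated")
    if res.dN is None:
        res.flags.append("dN_saturated")
    if res.dS is not None and res.dN is not None:
        if res.dS > 0:
            res.omega = res.dN / res.dS
        else:
            res.flags.append("omega_undefined_dS_zero")
    return res


# ---------------------------------------------------------------------------
# Back-threading protein alignments to codon alignments


def backthread_codon_alignment(
    protein_alignment: Mapping[str, str],
    cds_by_id: Mapping[str, str],
    code: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Thread coding sequences through a protein alignment.

    Each aligned residue becomes its source codon; each gap becomes ``---``.
    A trailing stop codon on a CDS is stripped before threading.  Every CDS
    must be exactly three times its ungapped protein length and translate to
    the protein under the (standard) code.
    """
    code = code or GENETIC_CODE
    out: dict[str, str] = {}
    for seq_id, prot_row in protein_alignment.items():
        if seq_id not in cds_by_id:
            raise CodonValidationError(f"{seq_id}: no CDS provided")
        cds = cds_by_id[seq_id].upper().replace("U", "T")
        if len(cds) % 3:
            raise CodonValidationError(f"{seq_id}: CDS length {len(cds)} not a multiple of 3")
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        protein = prot_row.replace("-", "")
        if len(cds) != 3 * len(protein):
            raise CodonValidationError(
                f"{seq_id}: CDS has {len(cds) // 3} codons for {len(protein)} residues"
            )
        for i, aa in enumerate(protein):
            codon = cds[3 * i:3 * i + 3]
            trans = translate_codon(codon, code)
            if trans != aa:
                raise CodonValidationError(
                    f"{seq_id}: CDS translation mismatch at residue {i + 1} "
                    f"(codon {codon} -> {trans}, protein has {aa})"
                )
        row = []
        pos = 0
        for aa in prot_row:
            if aa == "-":
                row.append("---")
            else:
                row.append(cds[3 * pos:3 * pos + 3])
                pos += 1
        out[seq_id] = "".join(row)
    return out


# ---------------------------------------------------------------------------
# Clique-level averaging


def clique_dnds(
    codon_alignment: Mapping[str, str],
    code: Mapping[str, str] | None = None,
) -> tuple[float | None, list[tuple[str, str, NG86Result]], int]:
    """Average pairwise omega over a clique's codon alignment.

    Returns ``(avg_omega, per_pair_results, n_excluded_pairs)``; pairs with
    undefined omega are excluded from the mean and counted.  The average is
    None when no pair has a defined omega.
    """
    ids = sorted(codon_alignment)
    if len(ids) < 2:
        raise CodonValidationError("clique dN/dS needs at least 2 sequences")
    pairs: list[tuple[str, str, NG86Result]] = []
    omegas: list[float] = []
    excluded = 0
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            res = ng86_pair(codon_alignment[a], codon_alignment[b], code)
            pairs.append((a, b, res))
            if res.omega is None:
                excluded += 1
            else:
                omegas.append(res.omega)
    avg = sum(omegas) / len(omegas) if omegas else None
    return avg, pairs, excluded


def write_dnds_table(pairs: Sequence[tuple[str, str, NG86Result]], path: str | Path) -> None:
    lines = ["id_a\tid_b\tS\tN\tSd\tNd\tdS\tdN\tomega\tflags"]
    fmt = lambda x: "" if x is None else f"{x:.6f}"
    for a, b, r in pairs:
        lines.append("\t".join([
            a, b, f"{r.S:.4f}", f"{r.N:.4f}", f"{r.Sd:.4f}", f"{r.Nd:.4f}",
            fmt(r.dS), fmt(r.dN), fmt(r.omega), ",".join(r.flags),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
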