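"""Pairwise similarity hits: parsing, computing, and rescaling.

Hits come from one of two engines: tab-separated BLAST-style hit tables
(12-column ``outfmt 6`` or the 14-column ``std qlen slen`` dialect), or the
built-in Smith–Waterman local aligner for desk-scale datasets.  Downstream
code is agnostic to the engine; everything is normalised to
:class:`SimilarityHit`.

The quantity the network pipeline actually thresholds is the
*coverage-rescaled identity* (:func:`adjusted_identity`): the percent
identity of the local alignment multiplied by the fraction of the shorter
sequence the alignment covers.  Rescaling penalises short, locally good
matches between sequences that are otherwise unrelated, so a fragment cannot
look like a full-length homolog.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence, TextIO

from Bio import Align
from Bio.Align import substitution_matrices

from .records import SequenceRecord

HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class HitTableError(ValueError):
    """Malformed hit table (wrong column count, non-numeric field)."""


class LengthResolutionError(ValueError):
    """A hit references ids with no known sequence length."""

    def __init__(self, ids: Sequence[str]):
        self.ids = sorted(set(ids))
        super().__init__(f"no length known for ids: {', '.join(self.ids)}")


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise local-alignment result in BLAST tabular terms."""

    query_id: str
    subject_id: str
    pident: float          # percent identity over aligned columns, (0, 100]
    aln_len: int           # aligned columns, gap columns included
    mismatch: int = 0
    gapopen: int = 0
    qstart: int = 1        # 1-based inclusive
    qend: int = 1
    sstart: int = 1
    send: int = 1
    evalue: float = 0.0
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if self.qend < self.qstart or self.send < self.sstart:
            raise ValueError("alignment end before start")
        if not 0 < self.pident <= 100:
            raise ValueError("pident must be in (0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")

    @property
    def is_self(self) -> bool:
        return self.query_id == self.subject_id

    def swapped(self) -> "SimilarityHit":
        """The same alignment read from the subject's side."""
        return replace(
            self,
            query_id=self.subject_id,
            subject_id=self.query_id,
            qstart=self.sstart,
            qend=self.send,
            sstart=self.qstart,
            send=self.qend,
        )


def adjusted_identity(hit: SimilarityHit, len_q: int, len_s: int) -> float:
    """Percent identity rescaled by alignment coverage of the shorter sequence.

    ``pident * min(aln_len / min(len_q, len_s), 1.0)``.  The coverage factor
    is capped at 1 so gap-inflated alignment lengths (or malformed
    coordinates) cannot push the result above the raw identity.
    """
    if len_q <= 0 or len_s <= 0:
        raise ValueError("sequence lengths must be positive")
    coverage = min(hit.aln_len / min(len_q, len_s), 1.0)
    return hit.pident * coverage


def mutual_coverage(hit: SimilarityHit, len_q: int, len_s: int) -> tuple[float, float]:
    """Fraction of each sequence spanned by the alignment, ``(cov_q, cov_s)``."""
    if len_q <= 0 or len_s <= 0:
        raise ValueError("sequence lengths must be positive")
    if hit.qend > len_q or hit.send > len_s:
        raise ValueError(
            f"hit {hit.query_id}/{hit.subject_id}: alignment coordinates exceed "
            f"declared lengths ({hit.qend}>{len_q} or {hit.send}>{len_s})"
        )
    return (hit.qend - hit.qstart + 1) / len_q, (hit.send - hit.sstart + 1) / len_s


# ---------------------------------------------------------------------------
# Hit-table I/O


def parse_hit_table(
    stream: TextIO | str | Path,
    length_map: Mapping[str, int] | None = None,
) -> tuple[list[SimilarityHit], dict[str, int]]:
    """Parse a 12- or 14-column BLAST-style tab-separated hit table.

    The 14-column dialect appends ``qlen slen``; those lengths are merged
    into (a copy of) ``length_map``.  Returns ``(hits, lengths)`` with a
    length resolvable for every id referenced by a hit.

    Raises
    ------
    HitTableError
        On a malformed row, naming the line number.
    LengthResolutionError
        If any id ends up without a length, listing the ids.
    """
    if isinstance(stream, (str, Path)):
        with open(stream) as fh:
            return parse_hit_table(fh, length_map)
    lengths: dict[str, int] = dict(length_map or {})
    hits: list[SimilarityHit] = []
    unresolved: list[str] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (12, 14):
            raise HitTableError(
                f"line {lineno}: expected 12 or 14 tab-separated columns, got {len(parts)}"
            )
        try:
            hit = SimilarityHit(
                query_id=parts[0],
                subject_id=parts[1],
                pident=float(parts[2]),
                aln_len=int(parts[3]),
                mismatch=int(parts[4]),
                gapopen=int(parts[5]),
                qstart=int(parts[6]),
                qend=int(parts[7]),
                sstart=int(parts[8]),
                send=int(parts[9]),
                evalue=float(parts[10]),
                bitscore=float(parts[11]),
            )
            if len(parts) == 14:
                lengths[parts[0]] = int(parts[12])
                lengths[parts[1]] = int(parts[13])
        except ValueError as exc:
            raise HitTableError(f"line {lineno}: {exc}") from exc
        hits.append(hit)
        for sid in (hit.query_id, hit.subject_id):
            if sid not in lengths:
                unresolved.append(sid)
    unresolved = [i for i in unresolved if i not in lengths]
    if unresolved:
        raise LengthResolutionError(unresolved)
    return hits, lengths


def _fmt(x: float) -> str:
    return format(x, ".17g")


def write_hit_table(
    hits: Iterable[SimilarityHit],
    dest: TextIO | str | Path,
    lengths: Mapping[str, int] | None = None,
) -> None:
    """Write hits in the 12-column dialect, or 14-column when ``lengths`` given."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_hit_table(hits, fh, lengths)
        return
    for h in hits:
        row = [
            h.query_id, h.subject_id, _fmt(h.pident), str(h.aln_len),
            str(h.mismatch), str(h.gapopen), str(h.qstart), str(h.qend),
            str(h.sstart), str(h.send), _fmt(h.evalue), _fmt(h.bitscore),
        ]
        if lengths is not None:
            row += [str(lengths[h.query_id]), str(lengths[h.subject_id])]
        dest.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Built-in local aligner


class LocalAligner:
    """Smith–Waterman local alignment with affine gaps and a BLOSUM62 default.

    The e-value attached to each hit is a Karlin–Altschul-style surrogate,
    ``E = K * m * n * exp(-lambda * S)`` with fixed default parameters; it is
    rank-consistent with the raw score and comparable across a run, but it is
    not a database-calibrated BLAST e-value.

    Parameters
    ----------
    matrix_name : str
        A substitution matrix name loadable by Biopython (protein) or "NUC"
        for a simple match/mismatch nucleotide scheme.
    gap_open, gap_extend : int
        Affine gap penalties; a gap of length k costs ``gap_open + k * gap_extend``.
    min_score : float
        Hits scoring below this are discarded (``align`` returns None).
    ka_lambda, ka_k : float
        Karlin–Altschul surrogate parameters (defaults are the conventional
        gapped-BLOSUM62 values, 0.267 and 0.041).
    search_space : float
        Effective database length the e-value is scaled to,
        ``E = K * m * search_space * exp(-lambda * S)``.  A pairwise score
        is only meaningful relative to the size of the search it came from;
        the default emulates a large-scale database search (for a typical
        200-residue query, significance at 1e-5 then demands a raw score
        near 180, roughly 70 bits), so marginal local matches between
        unrelated sequences do not look significant.
    """

    def __init__(
        self,
        matrix_name: str = "BLOSUM62",
        gap_open: int = 11,
        gap_extend: int = 1,
        min_score: float = 40.0,
        ka_lambda: float = 0.267,
        ka_k: float = 0.041,
        search_space: float = 1e15,
    ):
        self.min_score = min_score
        self.ka_lambda = ka_lambda
        self.ka_k = ka_k
        self.search_space = search_space
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        if matrix_name == "NUC":
            self._aligner.match_score = 2
            self._aligner.mismatch_score = -3
            self.alphabet = "dna"
        else:
            self._aligner.substitution_matrix = substitution_matrices.load(matrix_name)
            self.alphabet = "protein"
        # Biopython scores the first gap position with open+extend.
        self._aligner.open_gap_score = -(gap_open + gap_extend)
        self._aligner.extend_gap_score = -gap_extend

    def score(self, a: str, b: str) -> float:
        return self._aligner.score(a, b)

    def evalue_surrogate(self, score: float, m: int, n: int) -> float:
        n = max(n, self.search_space)
        return self.ka_k * m * n * math.exp(-self.ka_lambda * score)

    def bitscore(self, score: float) -> float:
        return (self.ka_lambda * score - math.log(self.ka_k)) / math.log(2)

    def align(self, a: SequenceRecord, b: SequenceRecord) -> SimilarityHit | None:
        """Best local alignment of ``a`` (query) vs ``b`` (subject), or None.

        Percent identity is identical columns over aligned columns, gap
        columns included (the BLAST denominator).
        """
        if a.alphabet != b.alphabet:
            raise ValueError(
                f"alphabet mismatch: {a.id} is {a.alphabet}, {b.id} is {b.alphabet}"
            )
        if a.alphabet != self.alphabet:
            raise ValueError(
                f"aligner scores {self.alphabet} sequences, got {a.alphabet}"
            )
        score = self._aligner.score(a.residues, b.residues)
        if score < self.min_score:
            return None
        best = self._aligner.align(a.residues, b.residues)[0]
        counts = best.counts()
        aln_cols = best.shape[1]
        identities = counts.identities
        if aln_cols == 0 or identities == 0:
            return None
        coords = best.coordinates
        return SimilarityHit(
            query_id=a.id,
            subject_id=b.id,
            pident=100.0 * identities / aln_cols,
            aln_len=aln_cols,
            mismatch=counts.mismatches,
            gapopen=counts.open_internal_insertions + counts.open_internal_deletions,
            qstart=int(coords[0, 0]) + 1,
            qend=int(coords[0, -1]),
            sstart=int(coords[1, 0]) + 1,
            send=int(coords[1, -1]),
            evalue=self.evalue_surrogate(score, a.length, b.length),
            bitscore=self.bitscore(score),
        )

    # make the aligner directly usable as an all_vs_all engine
    __call__ = align


Engine = Callable[[SequenceRecord, SequenceRecord], SimilarityHit | None]


def local_align(
    a: SequenceRecord,
    b: SequenceRecord,
    aligner: LocalAligner | None = None,
) -> SimilarityHit | None:
    """Convenience wrapper: best local alignment under default scoring."""
    return (aligner or LocalAligner()).align(a, b)


def best_hit_per_pair(hits: Iterable[SimilarityHit]) -> dict[tuple[str, str], SimilarityHit]:
    """Best hit per *ordered* (query, subject) pair: highest bitscore, then
    lowest e-value.  Self-hits are dropped."""
    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        if h.is_self:
            continue
        key = (h.query_id, h.subject_id)
        cur = best.get(key)
        if cur is None or (h.bitscore, -h.evalue) > (cur.bitscore, -cur.evalue):
            best[key] = h
    return best


def all_vs_all(
    seqs: Sequence[SequenceRecord],
    engine: Engine | Iterable[SimilarityHit],
    max_hits_per_query: int = 5000,
) -> list[SimilarityHit]:
    """All-against-all similarity search with a per-query hit cap.

    ``engine`` is either a callable ``(query, subject) -> hit-or-None`` (the
    built-in aligner) or a pre-parsed iterable of hits.  Per query, at most
    ``max_hits_per_query`` subjects are retained, ranked by descending
    bitscore, then ascending e-value, then subject id (lexicographic) for a
    deterministic result.  Self-hits are excluded.
    """
    ids = [s.id for s in seqs]
    per_query: dict[str, list[SimilarityHit]] = {i: [] for i in ids}
    if callable(engine):
        for i, a in enumerate(seqs):
            for b in seqs[i + 1:]:
                hit = engine(a, b)
                if hit is not None:
                    per_query[a.id].append(hit)
                    per_query[b.id].append(hit.swapped())
    else:
        known = set(ids)
        for key, hit in best_hit_per_pair(engine).items():
            if key[0] in known and key[1] in known:
                per_query[key[0]].append(hit)
    out: list[SimilarityHit] = []
    for qid in ids:
        ranked = sorted(
            per_query[qid], key=lambda h: (-h.bitscore, h.evalue, h.subject_id)
        )
        out.extend(ranked[:max_hits_per_query])
    return out
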