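"""Local alignment of peptide queries against six-frame translations.

A deterministic affine-gap Smith-Waterman stands in for a translated
nucleotide search: no seeding heuristics, no E-values, raw-score
thresholding only. Defaults are BLOSUM62 with gap open 11 / extend 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seq_core import NucleotideRecord, six_frame_translate

__all__ = [
    "Scoring",
    "Alignment",
    "SearchHit",
    "align_local",
    "search_transcripts",
    "write_hits_table",
    "DEFAULT_MIN_SCORE",
]

DEFAULT_MIN_SCORE = 50.0

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class Scoring:
    """Substitution matrix plus affine gap penalties.

    A gap of length k costs ``gap_open + k * gap_extend``. Residues
    outside the matrix alphabet are scored as 'X'.
    """

    matrix: object = field(default_factory=lambda: _BLOSUM62)
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def score(self, a: str, b: str) -> float:
        alph = self.matrix.alphabet
        a = a if a in alph else "X"
        b = b if b in alph else "X"
        return float(self.matrix[a, b])


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class Alignment:
    """A gapped local alignment between two protein strings."""

    score: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    aligned_query: str
    aligned_subject: str

    @property
    def identity_fraction(self) -> float:
        if not self.aligned_query:
            return 0.0
        matches = sum(
            1
            for a, b in zip(self.aligned_query, self.aligned_subject)
            if a == b and a != "-"
        )
        return matches / len(self.aligned_query)

    @property
    def is_empty(self) -> bool:
        return not self.aligned_query


EMPTY_ALIGNMENT = Alignment(0.0, 0, 0, 0, 0, "", "")


def _encode(seq: str, alphabet: str) -> np.ndarray:
    x_idx = alphabet.index("X")
    lut = np.full(128, x_idx, dtype=np.int8)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
    return lut[np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)]


def align_local(
    query: str, subject: str, scoring: Scoring = DEFAULT_SCORING
) -> Alignment:
    """Optimal local alignment with affine gaps (Smith-Waterman-Gotoh).

    Deterministic traceback: on equal cell scores the move preference is
    diagonal > up (gap in subject) > left (gap in query); among equal-score
    terminal cells the alignment with the smallest subject start, then the
    smallest query start, wins. Empty inputs or a best score of 0 return
    the empty alignment.
    """
    if not query or not subject:
        return EMPTY_ALIGNMENT

    alphabet = str(scoring.matrix.alphabet)
    q = _encode(query, alphabet)
    s = _encode(subject, alphabet)
    sub = np.asarray(scoring.matrix)[np.ix_(q, s)]
    go, ge = scoring.gap_open, scoring.gap_extend
    n, m = len(q), len(s)

    NEG = -1e30
    # M: ends in a match/mismatch; Ix: gap in subject (consumes query);
    # Iy: gap in query (consumes subject)
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    for i in range(1, n + 1):
        Mi, Mp = M[i], M[i - 1]
        row = sub[i - 1]
        # gap in subject: previous query row, same subject column
        Ix[i][1:] = np.maximum(Mp[1:] - go - ge, Ix[i - 1][1:] - ge)
        # diagonal: all inputs come from the completed previous row
        prev_best = np.maximum(np.maximum(Mp[:-1], Ix[i - 1][:-1]), Iy[i - 1][:-1])
        Mi[1:] = np.maximum(prev_best + row, 0.0)
        # gap in query: in-row recurrence
        Iyi = Iy[i]
        for j in range(1, m + 1):
            Iyi[j] = max(Mi[j - 1] - go - ge, Iyi[j - 1] - ge)

    best = max(M.max(), Ix.max(), Iy.max())
    if best <= 0:
        return EMPTY_ALIGNMENT

    # candidate end cells at the best score, in every layer
    ends: list[tuple[int, int, str]] = []
    for layer_name, layer in (("M", M), ("Ix", Ix), ("Iy", Iy)):
        for i, j in zip(*np.nonzero(layer == best)):
            ends.append((int(i), int(j), layer_name))

    def traceback(i: int, j: int, layer: str) -> Alignment:
        aq: list[str] = []
        asub: list[str] = []
        qi, sj = i, j
        while True:
            if layer == "M":
                val = M[qi][sj]
                if val <= 0:
                    break
                d = sub[qi - 1][sj - 1]
                prevs = (
                    ("M", M[qi - 1][sj - 1]),
                    ("Ix", Ix[qi - 1][sj - 1]),
                    ("Iy", Iy[qi - 1][sj - 1]),
                )
                aq.append(query[qi - 1])
                asub.append(subject[sj - 1])
                qi -= 1
                sj -= 1
                if val == d:  # local start
                    break
                for name, pv in prevs:
                    if pv + d == val:
                        layer = name
                        break
                else:  # numerical fallback
                    layer = max(prevs, key=lambda t: t[1])[0]
            elif layer == "Ix":
                aq.append(query[qi - 1])
                asub.append("-")
                val = Ix[qi][sj]
                if M[qi - 1][sj] - scoring.gap_open - scoring.gap_extend == val:
                    layer = "M"
                else:
                    layer = "Ix"
                qi -= 1
            else:  # Iy
                aq.append("-")
                asub.append(subject[sj - 1])
                val = Iy[qi][sj]
                if M[qi][sj - 1] - scoring.gap_open - scoring.gap_extend == val:
                    layer = "M"
                else:
                    layer = "Iy"
                sj -= 1
        return Alignment(
            score=float(best),
            query_start=qi,
            query_end=i,
            subject_start=sj,
            subject_end=j,
            aligned_query="".join(reversed(aq)),
            aligned_subject="".join(reversed(asub)),
        )

    candidates = [traceback(i, j, layer) for i, j, layer in ends]
    candidates.sort(key=lambda a: (a.subject_start, a.query_start))
    return candidates[0]


@dataclass(frozen=True)
class SearchHit:
    """Best local alignment of a query within one frame of one record."""

    query_name: str
    transcript_id: str
    frame: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    nt_span: tuple[int, int]
    score: float
    identity_fraction: float
    aligned_query: str
    aligned_subject: str


def search_transcripts(
    query_name: str,
    query_sequence: str,
    records: Sequence[NucleotideRecord],
    min_score: float = DEFAULT_MIN_SCORE,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[SearchHit]:
    """Align a mature-peptide query against six-frame translations.

    Returns the best hit per (record, frame) scoring at least ``min_score``,
    sorted by descending score, then transcript id, then frame.
    """
    hits: list[SearchHit] = []
    for rec in records:
        if len(rec.sequence) < 3:
            continue
        for ft in six_frame_translate(rec):
            if not ft.protein:
                continue
            aln = align_local(query_sequence, ft.protein, scoring)
            if aln.is_empty or aln.score < min_score:
                continue
            nt_span = ft.protein_interval_to_nt(
                aln.subject_start, aln.subject_end
            )
            hits.append(
                SearchHit(
                    query_name=query_name,
                    transcript_id=rec.id,
                    frame=ft.frame,
                    query_span=(aln.query_start, aln.query_end),
                    subject_span=(aln.subject_start, aln.subject_end),
                    nt_span=nt_span,
                    score=aln.score,
                    identity_fraction=aln.identity_fraction,
                    aligned_query=aln.aligned_query,
                    aligned_subject=aln.aligned_subject,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.transcript_id, h.frame))
    return hits


_HIT_COLUMNS = (
    "qid\ttid\tframe\tpident\tscore\tqstart\tqend\ttstart\ttend"
    "\tnt_start\tnt_end"
)


def write_hits_table(hits: Iterable[SearchHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_HIT_COLUMNS + "\n")
        for h in hits:
            fh.write(
                f"{h.query_name}\t{h.transcript_id}\t{h.frame:+d}"
                f"\t{h.identity_fraction:.4f}\t{h.score:g}"
                f"\t{h.query_span[0]}\t{h.query_span[1]}"
                f"\t{h.subject_span[0]}\t{h.subject_span[1]}"
                f"\t{h.nt_span[0]}\t{h.nt_span[1]}\n"
            )
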