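"""Sequence I/O, six-frame translation and ORF extraction primitives.

All coordinates are 0-based half-open intervals on the forward strand of
the stored sequence, including for minus-frame features (the frame sign
records the strand). Translation uses the standard genetic code; ``N``
translates to ``X``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "NucleotideRecord",
    "OrfRecord",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "translate",
    "six_frame_translate",
    "FrameTranslation",
    "extract_orfs",
    "write_orf_table",
]

DNA_ALPHABET = frozenset("ACGTN")
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # {TAA, TAG, TGA}

_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    _CODON_TABLE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FRAMES = (1, 2, 3, -1, -2, -3)

DEFAULT_MIN_PROTEIN_LEN = 50


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; carries the offending line number."""


@dataclass(frozen=True)
class NucleotideRecord:
    """A named DNA sequence, normalized to uppercase {A,C,G,T,N}."""

    id: str
    sequence: str
    source_sample: str | None = None

    def __post_init__(self) -> None:
        norm = self.sequence.upper().replace("U", "T")
        if not norm:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(norm) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid nucleotide(s) {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", norm)

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "NucleotideRecord":
        return NucleotideRecord(
            id=self.id,
            sequence=reverse_complement(self.sequence),
            source_sample=self.source_sample,
        )


@dataclass(frozen=True)
class OrfRecord:
    """A Met-initiated open reading frame located on a transcript.

    ``nt_start``/``nt_end`` span the coding codons (excluding the stop
    codon) on the forward strand; ``frame`` carries the strand sign.
    ``stop_codon`` is empty when the ORF runs off the sequence end.
    """

    transcript_id: str
    nt_start: int
    nt_end: int
    frame: int
    protein: str
    stop_codon: str = ""

    def __post_init__(self) -> None:
        if (self.nt_end - self.nt_start) % 3 != 0:
            raise ValueError("ORF nucleotide span must be divisible by 3")
        if not self.protein or self.protein[0] != "M":
            raise ValueError("ORF protein must start with M")
        if self.stop_codon not in ("", "TAA", "TAG", "TGA"):
            raise ValueError(f"invalid stop codon {self.stop_codon!r}")
        if self.frame not in FRAMES:
            raise ValueError(f"invalid frame {self.frame}")


def reverse_complement(seq: str) -> str:
    return seq.upper().replace("U", "T").translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a DNA string codon-by-codon; trailing partial codon dropped.

    Stops render as ``*``; any codon containing ``N`` renders as ``X``
    unless it is unambiguous regardless of the N (we do not attempt that:
    every N-containing codon becomes X).
    """
    seq = seq.upper().replace("U", "T")
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(_CODON_TABLE.get(codon, "X"))
    return "".join(out)


@dataclass(frozen=True)
class FrameTranslation:
    """One reading frame: protein string plus a forward-strand coordinate map.

    ``codon_interval(p)`` returns the 0-based half-open forward-strand
    nucleotide interval of protein position ``p``.
    """

    frame: int
    protein: str
    seq_length: int

    @property
    def offset(self) -> int:
        return abs(self.frame) - 1

    def codon_interval(self, protein_pos: int) -> tuple[int, int]:
        if not 0 <= protein_pos < len(self.protein):
            raise IndexError(f"protein position {protein_pos} out of range")
        start = self.offset + 3 * protein_pos
        if self.frame > 0:
            return (start, start + 3)
        # minus frames index into the reverse complement; map back
        return (self.seq_length - start - 3, self.seq_length - start)

    def protein_interval_to_nt(self, p_start: int, p_end: int) -> tuple[int, int]:
        """Forward-strand nt interval covering protein span [p_start, p_end)."""
        if p_end <= p_start:
            raise ValueError("empty protein interval")
        first = self.codon_interval(p_start)
        last = self.codon_interval(p_end - 1)
        lo = min(first[0], last[0])
        hi = max(first[1], last[1])
        return (lo, hi)


def six_frame_translate(record: NucleotideRecord) -> list[FrameTranslation]:
    """Translate all six reading frames of a record.

    Frames +1..+3 read the forward strand at offsets 0..2; -1..-3 read the
    reverse complement at offsets 0..2. Sequences shorter than 3 nt yield
    empty frames with a warning.
    """
    seq = record.sequence
    if len(seq) < 3:
        warnings.warn(
            f"record {record.id!r} shorter than 3 nt; all frames empty",
            stacklevel=2,
        )
    rc = reverse_complement(seq)
    frames = []
    for off in range(3):
        frames.append(FrameTranslation(off + 1, translate(seq[off:]), len(seq)))
    for off in range(3):
        frames.append(FrameTranslation(-(off + 1), translate(rc[off:]), len(seq)))
    return frames


def extract_orfs(
    record: NucleotideRecord,
    min_protein_len: int = DEFAULT_MIN_PROTEIN_LEN,
    all_starts: bool = False,
) -> list[OrfRecord]:
    """Extract Met-initiated ORFs from all six frames.

    For each stop (or frame end), the longest ORF (leftmost M since the
    previous stop) is reported by default; ``all_starts=True`` reports one
    ORF per M codon.
    """
    if min_protein_len < 1:
        raise ValueError("min_protein_len must be >= 1")
    orfs: list[OrfRecord] = []
    for ft in six_frame_translate(record):
        prot = ft.protein
        segment_start = 0  # first position after the previous stop
        i = 0
        n = len(prot)
        while i <= n:
            at_end = i == n
            if at_end or prot[i] == "*":
                starts = [
                    j for j in range(segment_start, i) if prot[j] == "M"
                ]
                if not all_starts:
                    starts = starts[:1]
                for j in starts:
                    protein = prot[j:i]
                    if len(protein) < min_protein_len:
                        continue
                    if at_end:
                        stop = ""
                        p_end = i
                    else:
                        stop_iv = ft.codon_interval(i)
                        if ft.frame > 0:
                            stop = record.sequence[stop_iv[0] : stop_iv[1]]
                        else:
                            stop = reverse_complement(
                                record.sequence[stop_iv[0] : stop_iv[1]]
                            )
                        p_end = i
                    nt_lo, nt_hi = ft.protein_interval_to_nt(j, p_end)
                    orfs.append(
                        OrfRecord(
                            transcript_id=record.id,
                            nt_start=nt_lo,
                            nt_end=nt_hi,
                            frame=ft.frame,
                            protein=protein,
                            stop_codon=stop,
                        )
                    )
                segment_start = i + 1
            i += 1
    return orfs


def read_fasta(path: str | Path) -> list[NucleotideRecord]:
    """Parse a FASTA file into normalized nucleotide records.

    Hand-rolled rather than SeqIO so malformed input (a header with no
    sequence) can be reported with its line number.
    """
    path = Path(path)
    records: list[NucleotideRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"{path}: header at line {header_line} has no sequence"
            )
        records.append(NucleotideRecord(id=header, sequence=seq))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise FastaParseError(f"{path}: empty header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[NucleotideRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def write_orf_table(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tframe\tnt_start\tnt_end\tstop_codon\tprotein\n")
        for o in orfs:
            fh.write(
                f"{o.transcript_id}\t{o.frame:+d}\t{o.nt_start}\t{o.nt_end}"
                f"\t{o.stop_codon}\t{o.protein}\n"
            )
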