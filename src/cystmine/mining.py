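"""Candidate validation and precursor-architecture annotation.

Raw translated-search hits are cleaned, screened against the family's
cysteine spacing framework, located within their ORF, and segmented into
signal / leader / core, with validation flags for the junction residue,
stop codon, leader-length class and 3' UTR.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .seq_core import NucleotideRecord, OrfRecord
from .translated_search import DEFAULT_SCORING, Scoring, align_local

__all__ = [
    "MaturePeptide",
    "CysFramework",
    "PrecursorAnnotation",
    "Candidate",
    "clean_hit_sequence",
    "framework_of",
    "matches_framework",
    "locate_core",
    "annotate_precursor",
    "dedupe_candidates",
    "write_candidate_table",
    "annotation_to_gff",
    "DEFAULT_SIGNAL_LEN",
    "SIGNAL_MOTIF_RE",
    "POLYA_MIN_RUN",
]

DEFAULT_SIGNAL_LEN = 19

# observed signal-peptide consensus for the family
SIGNAL_MOTIF_RE = re.compile(r"MA[TI]KVALL[VA]VSALIAVAAA")

# trailing adenine run treated as a poly-A tail (shared with origin_evidence)
POLYA_MIN_RUN = 8

EXPECTED_LEADER_LENS = {19: "short", 105: "long", 112: "long"}


@dataclass(frozen=True)
class MaturePeptide:
    """A named mature peptide with optional disulfide topology.

    ``cys_positions`` and ``disulfide_pairs`` are 1-based residue
    positions; pairs must partition a subset of the cysteines.
    """

    name: str
    sequence: str
    disulfide_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        for pos in self.cys_positions:
            if self.sequence[pos - 1] != "C":
                raise ValueError(f"{self.name}: position {pos} is not Cys")
        seen: set[int] = set()
        for a, b in self.disulfide_pairs:
            for pos in (a, b):
                if pos not in self.cys_positions:
                    raise ValueError(
                        f"{self.name}: disulfide position {pos} is not a Cys"
                    )
                if pos in seen:
                    raise ValueError(
                        f"{self.name}: Cys {pos} in more than one disulfide"
                    )
                seen.add(pos)

    @property
    def cys_positions(self) -> tuple[int, ...]:
        return tuple(
            i + 1 for i, aa in enumerate(self.sequence) if aa == "C"
        )

    @property
    def n_disulfides(self) -> int:
        return len(self.disulfide_pairs)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CysFramework:
    """Inter-cysteine spacing pattern (number of residues between
    consecutive cysteines)."""

    gap_lengths: tuple[int, ...]

    @property
    def n_cys(self) -> int:
        return len(self.gap_lengths) + 1

    def __str__(self) -> str:
        return "C" + "".join(f"-x{g}-C" for g in self.gap_lengths)


def clean_hit_sequence(raw: str) -> str:
    """Strip alignment artifacts ('*' and '-') from a hit sequence."""
    return raw.replace("*", "").replace("-", "")


def framework_of(peptide: MaturePeptide | str) -> CysFramework:
    """Spacings between consecutive cysteines of a peptide (needs >= 2 Cys)."""
    seq = peptide.sequence if isinstance(peptide, MaturePeptide) else peptide
    positions = [i for i, aa in enumerate(seq) if aa == "C"]
    if len(positions) < 2:
        raise ValueError(f"need >= 2 Cys to define a framework, got {len(positions)}")
    gaps = tuple(
        positions[k + 1] - positions[k] - 1 for k in range(len(positions) - 1)
    )
    return CysFramework(gap_lengths=gaps)


def matches_framework(
    candidate_seq: str, framework: CysFramework, slack: int = 0
) -> bool:
    """True iff the candidate contains consecutive cysteines whose spacings
    match the framework (within +/- ``slack`` per gap), at any offset."""
    positions = [i for i, aa in enumerate(candidate_seq) if aa == "C"]
    need = framework.n_cys
    if len(positions) < need:
        return False
    for off in range(len(positions) - need + 1):
        window = positions[off : off + need]
        ok = all(
            abs((window[k + 1] - window[k] - 1) - framework.gap_lengths[k])
            <= slack
            for k in range(need - 1)
        )
        if ok:
            return True
    return False


def locate_core(
    orf_protein: str,
    query: MaturePeptide,
    min_score: float = 30.0,
    scoring: Scoring = DEFAULT_SCORING,
    max_shift: int = 5,
) -> tuple[int, int] | None:
    """Locate the mature-core span within an ORF protein.

    The core is anchored at the best local alignment of the query and takes
    the query's length by default; if the cysteine framework does not match
    at that anchor, nearby offsets (up to ``max_shift``) are tried. Returns
    a 0-based half-open span, or None when no alignment reaches
    ``min_score``.
    """
    aln = align_local(query.sequence, orf_protein, scoring)
    if aln.is_empty or aln.score < min_score:
        return None
    length = len(query.sequence)
    anchor = aln.subject_start - aln.query_start
    try:
        fw = framework_of(query)
    except ValueError:
        fw = None

    def clamp(start: int) -> tuple[int, int] | None:
        if start < 0 or start + length > len(orf_protein):
            return None
        return (start, start + length)

    if fw is not None:
        for delta in sorted(range(-max_shift, max_shift + 1), key=abs):
            span = clamp(anchor + delta)
            if span and matches_framework(orf_protein[span[0] : span[1]], fw):
                # require exact framework at the window head, not merely
                # contained, so the span is anchored on the first Cys block
                return span
    span = clamp(anchor)
    if span is None:
        span = clamp(max(0, min(anchor, len(orf_protein) - length)))
    return span


@dataclass(frozen=True)
class PrecursorAnnotation:
    """Signal / leader / core segmentation of a precursor ORF."""

    orf: OrfRecord
    signal: str
    leader: str
    core: str
    stop_codon: str
    utr3: str
    flags: frozenset[str]

    @property
    def junction_residue(self) -> str:
        return self.leader[-1] if self.leader else ""

    @property
    def leader_len_class(self) -> str:
        return EXPECTED_LEADER_LENS.get(len(self.leader), "other")


def annotate_precursor(
    orf: OrfRecord,
    core_span: tuple[int, int],
    transcript: NucleotideRecord | None = None,
    signal_len: int = DEFAULT_SIGNAL_LEN,
    check_signal_motif: bool = False,
) -> PrecursorAnnotation:
    """Segment an ORF protein into signal, leader and core.

    Flags record observations, not filters: ``junction_is_Ala``,
    ``stop_is_TGA``, ``leader_short``/``leader_long``/``leader_other``,
    ``trailing_residues`` (protein continues past the core),
    ``signal_motif`` (when requested) and ``core_at_signal`` never occurs —
    a core overlapping the signal segment is a malformed precursor and
    raises instead.
    """
    protein = orf.protein
    c_start, c_end = core_span
    if not 0 <= c_start < c_end <= len(protein):
        raise ValueError(f"core span {core_span} outside ORF protein")
    if c_start < signal_len:
        raise ValueError(
            f"core span {core_span} overlaps the {signal_len}-residue "
            "signal segment: malformed precursor"
        )
    signal = protein[:signal_len]
    leader = protein[signal_len:c_start]
    core = protein[c_start:c_end]

    flags = set()
    if leader and leader[-1] == "A":
        flags.add("junction_is_Ala")
    if orf.stop_codon == "TGA":
        flags.add("stop_is_TGA")
    flags.add(f"leader_{EXPECTED_LEADER_LENS.get(len(leader), 'other')}")
    if c_end != len(protein):
        flags.add("trailing_residues")
    if check_signal_motif and SIGNAL_MOTIF_RE.fullmatch(signal):
        flags.add("signal_motif")

    utr3 = ""
    if transcript is not None and orf.stop_codon:
        seq = transcript.sequence
        if orf.frame > 0:
            tail = seq[orf.nt_end + 3 :]
        else:
            # 3' of a minus-strand ORF lies before nt_start on the forward
            # strand; read it 5'->3' on the coding strand
            from .seq_core import reverse_complement

            tail = reverse_complement(seq[: orf.nt_start - 3])
        # trim a trailing poly-A run before measuring the UTR
        stripped = tail.rstrip("A")
        if len(tail) - len(stripped) >= POLYA_MIN_RUN:
            tail = stripped
        utr3 = tail

    return PrecursorAnnotation(
        orf=orf,
        signal=signal,
        leader=leader,
        core=core,
        stop_codon=orf.stop_codon,
        utr3=utr3,
        flags=frozenset(flags),
    )


@dataclass(frozen=True)
class Candidate:
    """A deduplicated mature-core candidate with its supporting evidence."""

    name: str
    core_sequence: str
    framework: CysFramework
    supporting_transcripts: tuple[str, ...]
    samples: tuple[str, ...]
    flags: frozenset[str]


def dedupe_candidates(
    annotations: Sequence[PrecursorAnnotation],
    samples: Sequence[str | None] | None = None,
    name_prefix: str = "candidate",
) -> list[Candidate]:
    """Collapse annotations with identical core sequences.

    Names are assigned deterministically in first-seen order
    (``<prefix>-1``, ``<prefix>-2``, ...). Flags are unioned across
    supporting annotations.
    """
    if samples is None:
        samples = [None] * len(annotations)
    if len(samples) != len(annotations):
        raise ValueError("samples must parallel annotations")
    order: list[str] = []
    groups: dict[str, list[tuple[PrecursorAnnotation, str | None]]] = {}
    for ann, sample in zip(annotations, samples):
        if ann.core not in groups:
            groups[ann.core] = []
            order.append(ann.core)
        groups[ann.core].append((ann, sample))
    out: list[Candidate] = []
    for idx, core in enumerate(order, start=1):
        members = groups[core]
        transcripts = tuple(
            dict.fromkeys(a.orf.transcript_id for a, _ in members)
        )
        smp = tuple(dict.fromkeys(s for _, s in members if s))
        flags = frozenset().union(*(a.flags for a, _ in members))
        out.append(
            Candidate(
                name=f"{name_prefix}-{idx}",
                core_sequence=core,
                framework=framework_of(core)
                if core.count("C") >= 2
                else CysFramework(()),
                supporting_transcripts=transcripts,
                samples=smp,
                flags=flags,
            )
        )
    return out


def write_candidate_table(
    candidates: Iterable[Candidate], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("name\tcore_seq\tframework\ttranscripts\tsamples\tflags\n")
        for c in candidates:
            fh.write(
                f"{c.name}\t{c.core_sequence}\t{c.framework}"
                f"\t{','.join(c.supporting_transcripts)}"
                f"\t{','.join(c.samples)}"
                f"\t{','.join(sorted(c.flags))}\n"
            )


def annotation_to_gff(ann: PrecursorAnnotation) -> list[str]:
    """Render an annotation as GFF3-like feature lines on transcript
    coordinates (1-based inclusive, as GFF3 requires)."""
    orf = ann.orf
    strand = "+" if orf.frame > 0 else "-"
    lines = []

    def feat(ftype: str, p_lo: int, p_hi: int) -> str:
        # protein span [p_lo, p_hi) -> nt on forward strand
        if orf.frame > 0:
            nt_lo = orf.nt_start + 3 * p_lo
            nt_hi = orf.nt_start + 3 * p_hi
        else:
            nt_hi = orf.nt_end - 3 * p_lo
            nt_lo = orf.nt_end - 3 * p_hi
        return (
            f"{orf.transcript_id}\tcystmine\t{ftype}\t{nt_lo + 1}\t{nt_hi}"
            f"\t.\t{strand}\t.\tID={ftype}"
        )

    s = len(ann.signal)
    l = s + len(ann.leader)
    c = l + len(ann.core)
    lines.append(feat("signal_peptide", 0, s))
    if ann.leader:
        lines.append(feat("leader_peptide", s, l))
    lines.append(feat("core_peptide", l, c))
    if ann.stop_codon:
        if orf.frame > 0:
            lines.append(
                f"{orf.transcript_id}\tcystmine\tstop_codon"
                f"\t{orf.nt_end + 1}\t{orf.nt_end + 3}\t.\t+\t.\tID=stop_codon"
            )
        else:
            lines.append(
                f"{orf.transcript_id}\tcystmine\tstop_codon"
                f"\t{orf.nt_start - 2}\t{orf.nt_start}\t.\t-\t.\tID=stop_codon"
            )
    return lines
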