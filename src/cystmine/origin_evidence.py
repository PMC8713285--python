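"""Eukaryote-vs-prokaryote origin heuristics.

Three independent lines of evidence on assembled records: terminal poly-A
tails, introns recovered by anchor chaining of a transcript onto its
genomic copy (classified by length against the 500-800 bp band typical of
prokaryotic group II introns), and bimodality of per-record GC content as
a contamination signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seq_core import NucleotideRecord, reverse_complement

__all__ = [
    "IntronCall",
    "GcSummary",
    "detect_polya",
    "find_introns",
    "classify_intron_length",
    "gc_bimodality",
    "gc_fraction",
    "write_intron_table",
    "DEFAULT_POLYA_MIN_RUN",
    "DEFAULT_ANCHOR_K",
    "DEFAULT_MIN_INTRON",
    "GROUP_II_MIN",
    "GROUP_II_MAX",
]

DEFAULT_POLYA_MIN_RUN = 8
DEFAULT_ANCHOR_K = 21
DEFAULT_MIN_INTRON = 50

# length band typical of prokaryotic group II introns (inclusive)
GROUP_II_MIN = 500
GROUP_II_MAX = 800


def detect_polya(sequence: str, min_run: int = DEFAULT_POLYA_MIN_RUN) -> int:
    """Length of the terminal adenine run if it reaches min_run, else 0.

    Only the 3' terminus counts; internal A-runs are ignored.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    seq = sequence.upper()
    run = len(seq) - len(seq.rstrip("A"))
    return run if run >= min_run else 0


def classify_intron_length(length: int) -> str:
    """Band an intron length: <500 short_spliceosomal_like, 500-800
    group_II_candidate (inclusive), >800 long."""
    if length < 1:
        raise ValueError("intron length must be >= 1")
    if length < GROUP_II_MIN:
        return "short_spliceosomal_like"
    if length <= GROUP_II_MAX:
        return "group_II_candidate"
    return "long"


@dataclass(frozen=True)
class IntronCall:
    genomic_id: str
    transcript_id: str
    genomic_span: tuple[int, int]
    splice_motif: str

    @property
    def length(self) -> int:
        return self.genomic_span[1] - self.genomic_span[0]

    @property
    def intron_class(self) -> str:
        return classify_intron_length(self.length)


def _canonicalize_splice(
    genomic: str, span: tuple[int, int], max_shift: int = 3
) -> tuple[int, int]:
    """Slide an intron window to a GT..AG placement when the spliced
    product is unchanged (classic boundary ambiguity of exact aligners)."""
    start, end = span

    def equivalent(shift: int) -> bool:
        if shift > 0:
            return genomic[start : start + shift] == genomic[end : end + shift]
        if shift < 0:
            return (
                genomic[start + shift : start] == genomic[end + shift : end]
            )
        return True

    for shift in sorted(range(-max_shift, max_shift + 1), key=abs):
        s, e = start + shift, end + shift
        if s < 0 or e > len(genomic):
            continue
        if not equivalent(shift):
            continue
        if genomic[s : s + 2] == "GT" and genomic[e - 2 : e] == "AG":
            return (s, e)
    return span


class NoAlignmentError(ValueError):
    """Anchor chain covers too little of the transcript to call introns."""


def _anchor_blocks(
    transcript: str, genomic: str, k: int
) -> list[tuple[int, int, int]]:
    """Maximal co-linear exact match blocks as (t_start, g_start, length).

    Seeds are unique-in-genome k-mers of the transcript, extended to
    maximal exact blocks and chained by longest-increasing-subsequence on
    (transcript, genomic) position.
    """
    index: dict[str, list[int]] = {}
    for i in range(len(genomic) - k + 1):
        index.setdefault(genomic[i : i + k], []).append(i)
    seeds = []
    for t in range(len(transcript) - k + 1):
        hits = index.get(transcript[t : t + k])
        if hits and len(hits) == 1:
            seeds.append((t, hits[0]))
    # merge seeds on the same diagonal into maximal blocks
    blocks: dict[tuple[int, int], int] = {}  # (diag, block_start_t) -> end_t
    seen: set[tuple[int, int]] = set()
    merged: list[tuple[int, int, int]] = []
    for t, g in seeds:
        if (t, g) in seen:
            continue
        # extend left/right
        lo_t, lo_g = t, g
        while lo_t > 0 and lo_g > 0 and transcript[lo_t - 1] == genomic[lo_g - 1]:
            lo_t -= 1
            lo_g -= 1
        hi_t, hi_g = t + k, g + k
        while (
            hi_t < len(transcript)
            and hi_g < len(genomic)
            and transcript[hi_t] == genomic[hi_g]
        ):
            hi_t += 1
            hi_g += 1
        for tt in range(lo_t, hi_t - k + 1):
            seen.add((tt, lo_g + (tt - lo_t)))
        merged.append((lo_t, lo_g, hi_t - lo_t))
    merged = sorted(set(merged))
    if not merged:
        return []
    # chain: increasing starts, non-decreasing diagonal (introns only add
    # genomic sequence); blocks may overlap slightly at splice junctions
    # where the downstream block extends past the boundary by chance
    n = len(merged)
    best_len = [b[2] for b in merged]
    prev = [-1] * n
    for i in range(n):
        ti, gi, li = merged[i]
        for j in range(i):
            tj, gj, lj = merged[j]
            if tj < ti and gj < gi and ti - tj <= gi - gj:
                cand = best_len[j] + li - max(0, tj + lj - ti)
                if cand > best_len[i]:
                    best_len[i] = cand
                    prev[i] = j
    end = int(np.argmax(best_len))
    chain = []
    while end != -1:
        chain.append(merged[end])
        end = prev[end]
    return chain[::-1]


def find_introns(
    transcript: NucleotideRecord,
    genomic: NucleotideRecord,
    anchor_k: int = DEFAULT_ANCHOR_K,
    min_intron: int = DEFAULT_MIN_INTRON,
    max_transcript_gap: int = 5,
    min_coverage: float = 0.5,
) -> list[IntronCall]:
    """Call introns by chaining exact anchors of a transcript onto its
    genomic copy.

    The orientation with better anchor coverage is used. Genomic gaps of at
    least ``min_intron`` between chained blocks whose transcript-side gap
    is <= ``max_transcript_gap`` are reported as introns with their
    terminal dinucleotides. Raises :class:`NoAlignmentError` when the chain
    covers less than ``min_coverage`` of the transcript.
    """
    t_fwd = transcript.sequence
    g = genomic.sequence
    chain_fwd = _anchor_blocks(t_fwd, g, anchor_k)
    chain_rev = _anchor_blocks(reverse_complement(t_fwd), g, anchor_k)
    cov_fwd = sum(b[2] for b in chain_fwd)
    cov_rev = sum(b[2] for b in chain_rev)
    chain = chain_fwd if cov_fwd >= cov_rev else chain_rev
    coverage = max(cov_fwd, cov_rev) / len(t_fwd)
    if coverage < min_coverage:
        raise NoAlignmentError(
            f"anchor chain covers {coverage:.0%} of {transcript.id!r} "
            f"on {genomic.id!r} (< {min_coverage:.0%})"
        )
    calls: list[IntronCall] = []
    for (t0, g0, l0), (t1, g1, _) in zip(chain, chain[1:]):
        # trim any junction overlap off the downstream block
        overlap = max(0, (t0 + l0) - t1)
        t1 += overlap
        g1 += overlap
        t_gap = t1 - (t0 + l0)
        g_gap = g1 - (g0 + l0)
        if g_gap >= min_intron and t_gap <= max_transcript_gap:
            span = _canonicalize_splice(g, (g0 + l0, g1))
            intron_seq = g[span[0] : span[1]]
            motif = f"{intron_seq[:2]}..{intron_seq[-2:]}"
            calls.append(
                IntronCall(
                    genomic_id=genomic.id,
                    transcript_id=transcript.id,
                    genomic_span=span,
                    splice_motif=motif,
                )
            )
    return calls


@dataclass(frozen=True)
class GcSummary:
    per_record_gc: tuple[float, ...]
    split_point: float
    low_mode_frac: float
    high_mode_frac: float
    bimodality_flag: bool


def gc_fraction(sequence: str) -> float:
    seq = sequence.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def gc_bimodality(
    records: Sequence[NucleotideRecord],
    min_records: int = 10,
    min_mode_frac: float = 0.10,
) -> GcSummary:
    """Two-cluster split of per-record GC content.

    The split point is the threshold minimizing total within-cluster
    variance (exhaustive over midpoints of consecutive sorted values). The
    distribution is flagged bimodal when the between-mode separation is at
    least twice the pooled within-mode standard deviation, each mode holds
    at least ``min_mode_frac`` of records, and the separation is non-zero.
    """
    if len(records) < min_records:
        raise ValueError(
            f"need >= {min_records} records for a bimodality call, "
            f"got {len(records)}"
        )
    gc = np.array(sorted(gc_fraction(r.sequence) for r in records))
    n = len(gc)
    best = None  # (wcss, split_idx)
    for i in range(1, n):
        if gc[i] == gc[i - 1]:
            continue
        left, right = gc[:i], gc[i:]
        wcss = left.var() * len(left) + right.var() * len(right)
        if best is None or wcss < best[0]:
            best = (wcss, i)
    if best is None:  # all values identical
        return GcSummary(
            per_record_gc=tuple(gc),
            split_point=float(gc[0]),
            low_mode_frac=1.0,
            high_mode_frac=0.0,
            bimodality_flag=False,
        )
    i = best[1]
    left, right = gc[:i], gc[i:]
    split = float((gc[i - 1] + gc[i]) / 2)
    sep = float(right.mean() - left.mean())
    pooled_sd = float(np.sqrt((left.var() * len(left) + right.var() * len(right)) / n))
    low_frac = len(left) / n
    high_frac = len(right) / n
    flag = (
        sep > 0
        and sep >= 2 * pooled_sd
        and min(low_frac, high_frac) >= min_mode_frac
    )
    return GcSummary(
        per_record_gc=tuple(float(x) for x in gc),
        split_point=split,
        low_mode_frac=low_frac,
        high_mode_frac=high_frac,
        bimodality_flag=bool(flag),
    )


def write_intron_table(calls: Iterable[IntronCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "genomic_id\ttranscript_id\tstart\tend\tlength\tsplice_motif"
            "\tclass\n"
        )
        for c in calls:
            fh.write(
                f"{c.genomic_id}\t{c.transcript_id}\t{c.genomic_span[0]}"
                f"\t{c.genomic_span[1]}\t{c.length}\t{c.splice_motif}"
                f"\t{c.intron_class}\n"
            )


def plot_gc_histogram(summary: GcSummary, path: str | Path, bins: int = 40) -> None:
    """Optional GC histogram; requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(summary.per_record_gc, bins=bins, color="steelblue")
    ax.axvline(summary.split_point, color="firebrick", linestyle="--")
    ax.set_xlabel("GC fraction")
    ax.set_ylabel("records")
    ax.set_title(f"bimodal: {summary.bimodality_flag}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
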