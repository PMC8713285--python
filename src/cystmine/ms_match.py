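"""Peak-list loading, ion matching, and the sample x peptide evidence matrix.

Presence is called purely on m/z: a peptide is present in a sample when at
least ``min_charges`` distinct charge states have a peak within tolerance,
and flagged ambiguous when every supporting match is shared with an
isobaric peptide.
"""

from __future__ import annotations

import bisect
import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .peptide_mass import TheoreticalIonSet

__all__ = [
    "PeakList",
    "IonMatch",
    "PresenceCall",
    "PresenceMatrix",
    "PeakListParseError",
    "read_peak_list",
    "match_ions",
    "presence_call",
    "build_presence_matrix",
    "DEFAULT_TOLERANCE_DA",
    "DEFAULT_MIN_CHARGES",
]

DEFAULT_TOLERANCE_DA = 0.05
DEFAULT_MIN_CHARGES = 1

CHARGES = (1, 2, 3, 4)


class PeakListParseError(ValueError):
    pass


@dataclass(frozen=True)
class PeakList:
    """An m/z-sorted peak list for one sample."""

    sample: str
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for mz_val, _ in self.peaks:
            if mz_val <= 0:
                raise ValueError(f"non-positive m/z {mz_val}")
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=lambda p: p[0]))
        )

    @property
    def mz_values(self) -> list[float]:
        return [p[0] for p in self.peaks]


def read_peak_list(
    path: str | Path,
    fmt: Literal["csv", "mgf", "auto"] = "auto",
    sample: str | None = None,
) -> PeakList:
    """Load a peak list from a two-column CSV (mz,intensity) or an MGF file.

    The sample label defaults to the file stem. CSV may carry a header row
    (detected by a non-numeric first field).
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "mgf" if path.suffix.lower() == ".mgf" else "csv"
    if sample is None:
        sample = path.stem
    peaks: list[tuple[float, float]] = []
    if fmt == "csv":
        with open(path, newline="") as fh:
            for lineno, row in enumerate(csv.reader(fh), start=1):
                if not row or not "".join(row).strip():
                    continue
                try:
                    mz_val = float(row[0])
                except ValueError:
                    if lineno == 1:  # header row
                        continue
                    raise PeakListParseError(
                        f"{path}: non-numeric m/z at line {lineno}: {row[0]!r}"
                    ) from None
                intensity = float(row[1]) if len(row) > 1 and row[1] else 0.0
                peaks.append((mz_val, intensity))
    elif fmt == "mgf":
        in_block = False
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.upper() == "BEGIN IONS":
                    in_block = True
                    continue
                if line.upper() == "END IONS":
                    in_block = False
                    continue
                if not in_block or "=" in line:
                    continue
                fields = line.split()
                try:
                    mz_val = float(fields[0])
                except ValueError:
                    raise PeakListParseError(
                        f"{path}: non-numeric m/z at line {lineno}: "
                        f"{fields[0]!r}"
                    ) from None
                intensity = float(fields[1]) if len(fields) > 1 else 0.0
                peaks.append((mz_val, intensity))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return PeakList(sample=sample, peaks=tuple(peaks))


@dataclass(frozen=True)
class IonMatch:
    """One theoretical ion matched to its nearest in-tolerance peak."""

    peptide_name: str
    charge: int
    theoretical_mz: float
    observed_mz: float
    intensity: float
    error_da: float
    error_ppm: float
    ambiguous_with: tuple[str, ...] = ()


def _within(theoretical: float, observed: float, tol: float, mode: str) -> bool:
    if mode == "da":
        return abs(theoretical - observed) <= tol
    return abs(theoretical - observed) / theoretical * 1e6 <= tol


def _nearest_peak(
    sorted_peaks: Sequence[tuple[float, float]],
    mz_values: Sequence[float],
    target: float,
) -> tuple[float, float] | None:
    """Nearest peak to target; equidistant ties resolve to the lower m/z."""
    if not sorted_peaks:
        return None
    i = bisect.bisect_left(mz_values, target)
    best = None
    for k in (i - 1, i):
        if 0 <= k < len(sorted_peaks):
            cand = sorted_peaks[k]
            if best is None or abs(cand[0] - target) < abs(best[0] - target):
                best = cand
    return best


def match_ions(
    ion_sets: Sequence[TheoreticalIonSet],
    peak_list: PeakList,
    tolerance: float = DEFAULT_TOLERANCE_DA,
    mode: Literal["da", "ppm"] = "da",
    charges: Sequence[int] = CHARGES,
) -> list[IonMatch]:
    """Match every (peptide, charge) theoretical m/z to the peak list.

    A match is emitted when the nearest peak lies within tolerance.
    ``ambiguous_with`` lists every other peptide with a theoretical m/z (at
    any charge) within tolerance of the same observed peak.
    """
    mz_values = peak_list.mz_values
    matches: list[IonMatch] = []
    for ion in ion_sets:
        for z in charges:
            t = ion.mz_at(z)
            peak = _nearest_peak(peak_list.peaks, mz_values, t)
            if peak is None or not _within(t, peak[0], tolerance, mode):
                continue
            observed = peak[0]
            others = tuple(
                sorted(
                    other.peptide_name
                    for other in ion_sets
                    if other.peptide_name != ion.peptide_name
                    and any(
                        _within(other.mz_at(zz), observed, tolerance, mode)
                        for zz in charges
                    )
                )
            )
            matches.append(
                IonMatch(
                    peptide_name=ion.peptide_name,
                    charge=z,
                    theoretical_mz=t,
                    observed_mz=observed,
                    intensity=peak[1],
                    error_da=observed - t,
                    error_ppm=(observed - t) / t * 1e6,
                    ambiguous_with=others,
                )
            )
    return matches


@dataclass(frozen=True)
class PresenceCall:
    peptide_name: str
    present: bool
    ambiguous: bool
    charges: tuple[int, ...] = ()


def presence_call(
    matches: Sequence[IonMatch],
    peptide_names: Sequence[str],
    min_charges: int = DEFAULT_MIN_CHARGES,
) -> list[PresenceCall]:
    """Per-peptide presence: >= min_charges distinct matched charge states.

    A present peptide is ambiguous when every one of its supporting
    matches is shared with an isobaric alternative.
    """
    if min_charges < 1:
        raise ValueError("min_charges must be >= 1")
    calls = []
    for name in peptide_names:
        mine = [m for m in matches if m.peptide_name == name]
        charges = tuple(sorted({m.charge for m in mine}))
        present = len(charges) >= min_charges
        ambiguous = present and all(m.ambiguous_with for m in mine)
        calls.append(
            PresenceCall(
                peptide_name=name,
                present=present,
                ambiguous=ambiguous,
                charges=charges if present else (),
            )
        )
    return calls


EVIDENCE_FLAGS = (
    "sequence_evidence",
    "genome_evidence",
    "ms_evidence",
    "ms_ambiguous",
)


@dataclass
class PresenceMatrix:
    """Samples x peptides multi-flag evidence matrix."""

    samples: list[str]
    peptides: list[str]
    cells: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def flag(self, sample: str, peptide: str, flag: str) -> None:
        if flag not in EVIDENCE_FLAGS:
            raise ValueError(f"unknown flag {flag!r}")
        if sample not in self.samples:
            raise ValueError(f"unknown sample {sample!r}")
        if peptide not in self.peptides:
            raise ValueError(f"unknown peptide {peptide!r}")
        self.cells.setdefault((sample, peptide), set()).add(flag)

    def flags_at(self, sample: str, peptide: str) -> set[str]:
        return set(self.cells.get((sample, peptide), set()))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tpeptide\t" + "\t".join(EVIDENCE_FLAGS) + "\n")
            for sample in self.samples:
                for peptide in self.peptides:
                    flags = self.flags_at(sample, peptide)
                    fh.write(
                        f"{sample}\t{peptide}\t"
                        + "\t".join(
                            "1" if f in flags else "0" for f in EVIDENCE_FLAGS
                        )
                        + "\n"
                    )

    def render_glyphs(self) -> str:
        """Compact text rendering: ● sequence, ○ MS, ◌ ambiguous MS,
        ◆ genome, · absent."""
        lines = ["\t".join(["sample"] + self.peptides)]
        for sample in self.samples:
            row = [sample]
            for peptide in self.peptides:
                flags = self.flags_at(sample, peptide)
                glyphs = ""
                if "sequence_evidence" in flags:
                    glyphs += "●"
                if "genome_evidence" in flags:
                    glyphs += "◆"
                if "ms_ambiguous" in flags:
                    glyphs += "◌"
                elif "ms_evidence" in flags:
                    glyphs += "○"
                row.append(glyphs or "·")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def build_presence_matrix(
    sequence_evidence: dict[str, set[str]],
    ms_calls: dict[str, Sequence[PresenceCall]],
    peptides: Sequence[str],
    samples: Sequence[str],
    genome_evidence: dict[str, set[str]] | None = None,
) -> PresenceMatrix:
    """Merge sequence hits, genome hits and MS presence calls.

    ``sequence_evidence`` / ``genome_evidence`` map sample -> peptide-name
    set; ``ms_calls`` maps sample -> presence calls. Unknown sample labels
    raise.
    """
    matrix = PresenceMatrix(samples=list(samples), peptides=list(peptides))
    for source, flag in (
        (sequence_evidence, "sequence_evidence"),
        (genome_evidence or {}, "genome_evidence"),
    ):
        for sample, names in source.items():
            for name in names:
                matrix.flag(sample, name, flag)
    for sample, calls in ms_calls.items():
        for call in calls:
            if call.present:
                matrix.flag(sample, call.peptide_name, "ms_evidence")
                if call.ambiguous:
                    matrix.flag(sample, call.peptide_name, "ms_ambiguous")
    return matrix


def write_matches_table(matches: Iterable[IonMatch], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "peptide\tcharge\ttheoretical_mz\tobserved_mz\tintensity"
            "\terror_da\terror_ppm\tambiguous_with\n"
        )
        for m in matches:
            fh.write(
                f"{m.peptide_name}\t{m.charge}\t{m.theoretical_mz:.4f}"
                f"\t{m.observed_mz:.4f}\t{m.intensity:g}"
                f"\t{m.error_da:+.4f}\t{m.error_ppm:+.2f}"
                f"\t{','.join(m.ambiguous_with)}\n"
            )
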