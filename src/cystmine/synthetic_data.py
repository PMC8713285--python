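"""Ground-truthed synthetic inputs for every pipeline stage.

A single seed drives named substreams (precursors, codons, decoys, peaks,
genome) so each artifact can be regenerated independently and the whole
bundle is byte-reproducible. The truth manifest records planted cores, ORF
spans, frames, intron spans, poly-A lengths and planted peaks, and is
sufficient to score every stage exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .known import BARRETTIDE_C, SIGNAL_PEPTIDES
from .mining import MaturePeptide
from .ms_match import PeakList
from .peptide_mass import monoisotopic_mass, mz
from .seq_core import NucleotideRecord, reverse_complement

__all__ = [
    "SimConfig",
    "TruthManifest",
    "PlantedTranscript",
    "PlantedPeak",
    "make_precursor",
    "encode_transcript",
    "make_genomic",
    "make_peak_list",
    "simulate",
    "SimBundle",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# codons per amino acid, standard code
_CODONS: dict[str, tuple[str, ...]] = {}
_BASES = "TCAG"
_AA_BY_CODON = {}
_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_TABLE):
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    _AA_BY_CODON[_codon] = _aa
    if _aa != "*":
        _CODONS.setdefault(_aa, tuple())
_CODONS = {
    aa: tuple(c for c, a in sorted(_AA_BY_CODON.items()) if a == aa)
    for aa in set(_TABLE) - {"*"}
}

#: fixed 33-nt 3' UTR shared by all simulated precursor transcripts
CONSERVED_UTR3 = "TTCAGCCTAGTTGAACCATGGATCCGATTAGCC"
assert len(CONSERVED_UTR3) == 33


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset (seed is mandatory)."""

    seed: int
    n_decoys: int = 50
    n_precursors: int = 3
    leader_mode: str = "mixed"  # short | long105 | long112 | mixed
    core_template: MaturePeptide = BARRETTIDE_C
    core_mutation_rate: float = 0.0
    preserve_framework: bool = True
    intron_lengths: tuple[int, ...] = (300,)
    polya_geometric_mean: float = 15.0
    polya_min: int = 8
    peak_noise_count: int = 100
    mz_jitter_sd: float = 0.0
    peak_charges: tuple[int, ...] = (2, 3)
    gc_decoy_modes: tuple[tuple[float, float], ...] = ((0.38, 0.5), (0.62, 0.5))
    decoy_len_range: tuple[int, int] = (300, 900)
    sample: str = "sim01"
    scan_range: tuple[float, float] = (50.0, 1500.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.core_mutation_rate <= 1.0:
            raise ValueError("core_mutation_rate must be in [0,1]")
        if abs(sum(f for _, f in self.gc_decoy_modes) - 1.0) > 1e-9:
            raise ValueError("gc_decoy_modes fractions must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream derived from the global seed."""
        ss = np.random.SeedSequence(
            self.seed, spawn_key=(abs(hash_stream(stream)),)
        )
        return np.random.default_rng(ss)


def hash_stream(name: str) -> int:
    # stable across processes (unlike builtin hash)
    h = 2166136261
    for ch in name.encode():
        h = (h ^ ch) * 16777619 % (1 << 32)
    return h


@dataclass
class PlantedTranscript:
    transcript_id: str
    peptide_name: str
    core_sequence: str
    protein: str
    signal: str
    leader: str
    orf_nt_span: tuple[int, int]
    frame: int
    polya_len: int
    mutations: tuple[tuple[int, str, str], ...] = ()
    intron_spans: tuple[tuple[int, int], ...] = ()
    genomic_id: str | None = None


@dataclass
class PlantedPeak:
    peptide_name: str
    charge: int
    true_mz: float


@dataclass
class TruthManifest:
    """Everything needed to score pipeline output exactly."""

    config: dict
    transcripts: list[PlantedTranscript] = field(default_factory=list)
    peaks: list[PlantedPeak] = field(default_factory=list)

    def planted_cores(self) -> set[str]:
        return {t.core_sequence for t in self.transcripts}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "transcripts": [dataclasses.asdict(t) for t in self.transcripts],
            "peaks": [dataclasses.asdict(p) for p in self.peaks],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        man = cls(config=payload["config"])
        for t in payload["transcripts"]:
            t = dict(t)
            t["orf_nt_span"] = tuple(t["orf_nt_span"])
            t["mutations"] = tuple(tuple(m) for m in t["mutations"])
            t["intron_spans"] = tuple(tuple(s) for s in t["intron_spans"])
            man.transcripts.append(PlantedTranscript(**t))
        for p in payload["peaks"]:
            man.peaks.append(PlantedPeak(**p))
        return man


def _leader_length(config: SimConfig, rng: np.random.Generator) -> int:
    mode = config.leader_mode
    if mode == "short":
        return 19
    if mode == "long105":
        return 105
    if mode == "long112":
        return 112
    if mode == "mixed":
        return int(rng.choice([19, 105, 112]))
    raise ValueError(f"unknown leader_mode {mode!r}")


def make_precursor(
    config: SimConfig, rng: np.random.Generator
) -> tuple[str, dict]:
    """Build precursor protein = signal + leader(ends in A) + core.

    With ``preserve_framework`` mutations never touch a cysteine and never
    introduce one, so the spacing framework of the core is invariant.
    Returns the protein and a provenance dict (signal, leader, core,
    mutations as (position, from, to) with 0-based core positions).
    """
    signal = SIGNAL_PEPTIDES[int(rng.integers(len(SIGNAL_PEPTIDES)))]
    llen = _leader_length(config, rng)
    leader = "".join(
        AA20[int(i)] for i in rng.integers(len(AA20), size=llen - 1)
    ) + "A"
    template = config.core_template.sequence
    core = list(template)
    mutations: list[tuple[int, str, str]] = []
    if config.core_mutation_rate > 0:
        for i, aa in enumerate(template):
            if rng.random() >= config.core_mutation_rate:
                continue
            if config.preserve_framework and aa == "C":
                continue
            choices = [
                x
                for x in AA20
                if x != aa and not (config.preserve_framework and x == "C")
            ]
            new = choices[int(rng.integers(len(choices)))]
            core[i] = new
            mutations.append((i, aa, new))
    core_str = "".join(core)
    protein = signal + leader + core_str
    return protein, {
        "signal": signal,
        "leader": leader,
        "core": core_str,
        "mutations": tuple(mutations),
    }


def _random_codon(aa: str, rng: np.random.Generator) -> str:
    codons = _CODONS[aa]
    return codons[int(rng.integers(len(codons)))]


def _random_nt(
    n: int, rng: np.random.Generator, gc: float = 0.5
) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=n, p=p)]) if n else ""


def encode_transcript(
    protein: str,
    provenance: dict,
    config: SimConfig,
    rng: np.random.Generator,
    transcript_id: str,
    peptide_name: str,
) -> tuple[NucleotideRecord, PlantedTranscript]:
    """Reverse-translate a precursor into a transcript with truth entry.

    Layout: random 5' UTR + in-frame upstream stop + ORF + TGA + shared
    33-nt 3' UTR + geometric poly-A tail. Strand is flipped with
    probability 0.5 (truth records the resulting frame).
    """
    cds = "".join(_random_codon(aa, rng) for aa in protein)
    utr5_len = int(rng.integers(10, 61))
    utr5 = _random_nt(utr5_len, rng)
    # in-frame stop right before ATG prevents upstream ORF extension
    utr5 = utr5 + "TAA"
    polya_len = 0
    if config.polya_geometric_mean > 0:
        p = min(1.0, 1.0 / config.polya_geometric_mean)
        polya_len = max(config.polya_min, int(rng.geometric(p)))
    forward = utr5 + cds + "TGA" + CONSERVED_UTR3 + "A" * polya_len
    orf_start = len(utr5)
    orf_end = orf_start + len(cds)
    frame = (orf_start % 3) + 1
    flip = bool(rng.random() < 0.5)
    if flip:
        seq = reverse_complement(forward)
        L = len(forward)
        # minus frame offset indexes into revcomp(stored) == forward
        frame = -((orf_start % 3) + 1)
        orf_span = (L - orf_end, L - orf_start)
    else:
        seq = forward
        orf_span = (orf_start, orf_end)
    record = NucleotideRecord(id=transcript_id, sequence=seq,
                              source_sample=config.sample)
    truth = PlantedTranscript(
        transcript_id=transcript_id,
        peptide_name=peptide_name,
        core_sequence=provenance["core"],
        protein=protein,
        signal=provenance["signal"],
        leader=provenance["leader"],
        orf_nt_span=orf_span,
        frame=frame,
        polya_len=polya_len,
        mutations=provenance["mutations"],
    )
    return record, truth


def make_genomic(
    transcript_truth: PlantedTranscript,
    transcript: NucleotideRecord,
    config: SimConfig,
    rng: np.random.Generator,
    anchor_k: int = 21,
) -> tuple[NucleotideRecord, PlantedTranscript]:
    """Insert GT..AG introns into a genomic copy of a transcript.

    The genomic copy is the (forward-oriented) transcript without its
    poly-A tail. Insertion points keep every exon at least
    ``max(30, 2*anchor_k)`` nt long and fall inside the ORF at least 30 nt
    from its ends. Returns the genomic record and an updated truth entry
    with intron spans in genomic coordinates.
    """
    if not config.intron_lengths:
        raise ValueError("intron_lengths must be non-empty")
    seq = transcript.sequence
    if transcript_truth.frame < 0:
        seq = reverse_complement(seq)
        L = len(seq)
        a, b = transcript_truth.orf_nt_span
        orf_start, orf_end = L - b, L - a
    else:
        orf_start, orf_end = transcript_truth.orf_nt_span
    stripped = seq.rstrip("A") if transcript_truth.polya_len else seq
    min_exon = max(30, 2 * anchor_k)
    lo = orf_start + 30
    hi = orf_end - 30
    n_introns = len(config.intron_lengths)
    if hi - lo < (n_introns + 1) * min_exon:
        raise ValueError("ORF too short for requested introns")
    # deterministic, well-spaced insertion points, jittered
    points = []
    for i in range(n_introns):
        base = lo + (i + 1) * (hi - lo) // (n_introns + 1)
        jitter = int(rng.integers(-10, 11))
        points.append(max(lo, min(hi, base + jitter)))
    points.sort()
    pieces = []
    spans = []
    prev = 0
    offset = 0
    for point, length in zip(points, config.intron_lengths):
        if length < 4:
            raise ValueError("intron length must be >= 4 (GT..AG)")
        body = _random_nt(length - 4, rng)
        intron = "GT" + body + "AG"
        pieces.append(stripped[prev:point])
        spans.append((point + offset, point + offset + length))
        pieces.append(intron)
        offset += length
        prev = point
    pieces.append(stripped[prev:])
    genomic_id = f"g_{transcript_truth.transcript_id}"
    genomic = NucleotideRecord(
        id=genomic_id, sequence="".join(pieces), source_sample=config.sample
    )
    truth = dataclasses.replace(
        transcript_truth,
        intron_spans=tuple(spans),
        genomic_id=genomic_id,
    )
    return genomic, truth


def make_decoys(config: SimConfig, rng: np.random.Generator) -> list[NucleotideRecord]:
    """Random decoy transcripts drawn from the configured GC modes."""
    decoys = []
    modes = config.gc_decoy_modes
    fracs = np.array([f for _, f in modes])
    for i in range(config.n_decoys):
        mode = int(rng.choice(len(modes), p=fracs))
        gc = modes[mode][0]
        length = int(rng.integers(*config.decoy_len_range))
        decoys.append(
            NucleotideRecord(
                id=f"decoy_{i + 1:04d}",
                sequence=_random_nt(length, rng, gc=gc),
                source_sample=config.sample,
            )
        )
    return decoys


def make_peak_list(
    peptides: Sequence[MaturePeptide],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[PeakList, list[PlantedPeak]]:
    """Peaks for each planted peptide at the configured charges, with
    Gaussian m/z jitter and log-normal intensities, plus uniform noise
    peaks across the scan range."""
    lo, hi = config.scan_range
    peaks: list[tuple[float, float]] = []
    planted: list[PlantedPeak] = []
    for pep in peptides:
        mass = monoisotopic_mass(pep.sequence, pep.n_disulfides)
        for z in config.peak_charges:
            true_mz = mz(mass, z)
            observed = true_mz + (
                rng.normal(0.0, config.mz_jitter_sd)
                if config.mz_jitter_sd > 0
                else 0.0
            )
            intensity = float(rng.lognormal(mean=6.0, sigma=1.0))
            peaks.append((observed, intensity))
            planted.append(
                PlantedPeak(peptide_name=pep.name, charge=z, true_mz=true_mz)
            )
    for _ in range(config.peak_noise_count):
        peaks.append(
            (float(rng.uniform(lo, hi)), float(rng.lognormal(5.0, 1.0)))
        )
    return PeakList(sample=config.sample, peaks=tuple(peaks)), planted


@dataclass
class SimBundle:
    """One complete synthetic dataset."""

    config: SimConfig
    transcripts: list[NucleotideRecord]
    genomic: list[NucleotideRecord]
    peak_list: PeakList
    manifest: TruthManifest


def simulate(config: SimConfig) -> SimBundle:
    """Generate transcripts (precursors + decoys), genomic copies with
    introns, a peak list, and the truth manifest."""
    rng_prec = config.rng("precursors")
    rng_codon = config.rng("codons")
    rng_decoy = config.rng("decoys")
    rng_genome = config.rng("genome")
    rng_peaks = config.rng("peaks")

    manifest = TruthManifest(config=_config_dict(config))
    transcripts: list[NucleotideRecord] = []
    genomic: list[NucleotideRecord] = []
    planted_peptides: list[MaturePeptide] = []

    for i in range(config.n_precursors):
        name = f"planted-{i + 1}"
        protein, prov = make_precursor(config, rng_prec)
        rec, truth = encode_transcript(
            protein, prov, config, rng_codon,
            transcript_id=f"precursor_{i + 1:03d}", peptide_name=name,
        )
        transcripts.append(rec)
        grec, truth = make_genomic(truth, rec, config, rng_genome)
        genomic.append(grec)
        manifest.transcripts.append(truth)
        planted_peptides.append(
            MaturePeptide(
                name=name,
                sequence=prov["core"],
                disulfide_pairs=config.core_template.disulfide_pairs
                if prov["core"] == config.core_template.sequence
                else (),
            )
        )

    transcripts.extend(make_decoys(config, rng_decoy))
    peak_list, planted_peaks = make_peak_list(
        planted_peptides, config, rng_peaks
    )
    manifest.peaks.extend(planted_peaks)
    return SimBundle(
        config=config,
        transcripts=transcripts,
        genomic=genomic,
        peak_list=peak_list,
        manifest=manifest,
    )


def _config_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["core_template"] = {
        "name": config.core_template.name,
        "sequence": config.core_template.sequence,
        "disulfide_pairs": list(
            list(p) for p in config.core_template.disulfide_pairs
        ),
    }
    return d


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA / CSV / JSON artifacts of a bundle; returns the paths."""
    from .seq_core import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample = bundle.config.sample
    # transcript FASTA and peak CSV share the sample stem so downstream
    # stages attribute them to the same sample
    paths = {
        "transcripts": outdir / f"{sample}.fasta",
        "genomic": outdir / f"{sample}_genome.fasta",
        "peaks": outdir / f"{sample}.csv",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(bundle.transcripts, paths["transcripts"])
    write_fasta(bundle.genomic, paths["genomic"])
    with open(paths["peaks"], "w") as fh:
        fh.write("mz,intensity\n")
        for mz_val, inten in bundle.peak_list.peaks:
            fh.write(f"{mz_val:.6f},{inten:.3f}\n")
    bundle.manifest.to_json(paths["manifest"])
    return paths
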