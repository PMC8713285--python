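"""End-to-end orchestration: search -> mine -> ions -> match -> evidence.

Every stage writes a plain-text artifact (TSV/CSV/JSON) into the output
directory so runs can be inspected or resumed stage by stage, and a run
log captures the effective configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .mining import (
    DEFAULT_SIGNAL_LEN,
    MaturePeptide,
    PrecursorAnnotation,
    annotate_precursor,
    dedupe_candidates,
    framework_of,
    locate_core,
    matches_framework,
    write_candidate_table,
)
from .ms_match import (
    DEFAULT_MIN_CHARGES,
    DEFAULT_TOLERANCE_DA,
    build_presence_matrix,
    match_ions,
    presence_call,
    read_peak_list,
    write_matches_table,
)
from .peptide_mass import ion_table, write_ion_table
from .seq_core import NucleotideRecord, extract_orfs, read_fasta
from .translated_search import (
    DEFAULT_MIN_SCORE,
    search_transcripts,
    write_hits_table,
)

logger = logging.getLogger("cystmine")


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run."""

    queries: list[Path]
    assemblies: list[Path]
    peak_lists: list[Path] = field(default_factory=list)
    genome_assemblies: list[Path] = field(default_factory=list)
    out_dir: Path = Path("cystmine_out")
    min_score: float = DEFAULT_MIN_SCORE
    tolerance: float = DEFAULT_TOLERANCE_DA
    tolerance_mode: str = "da"
    signal_len: int = DEFAULT_SIGNAL_LEN
    framework_slack: int = 0
    min_charges: int = DEFAULT_MIN_CHARGES
    min_protein_len: int = 50
    n_disulfides: int = 2
    candidate_prefix: str = "candidate"
    seed: int | None = None

    def validate(self) -> None:
        for p in [*self.queries, *self.assemblies, *self.peak_lists,
                  *self.genome_assemblies]:
            if not Path(p).exists():
                raise PipelineConfigError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("queries", "assemblies", "peak_lists", "genome_assemblies"):
            if key in data:
                data[key] = [Path(p) for p in data[key]]
        if "out_dir" in data:
            data["out_dir"] = Path(data["out_dir"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
            elif isinstance(v, list):
                d[k] = [str(x) for x in v]
        return d


def read_queries(paths: Sequence[Path], n_disulfides: int = 2) -> list[MaturePeptide]:
    """Load mature-peptide queries from FASTA-like protein files.

    Disulfide pairs are not inferable from sequence; queries carry only the
    configured bond count via nested I-IV/II-III style pairing over their
    cysteines when possible.
    """
    peptides: list[MaturePeptide] = []
    for path in paths:
        name = None
        chunks: list[str] = []

        def flush() -> None:
            if name is None:
                return
            seq = "".join(chunks)
            pairs = _nested_pairs(seq, n_disulfides)
            peptides.append(
                MaturePeptide(name=name, sequence=seq, disulfide_pairs=pairs)
            )

        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    flush()
                    name = line[1:].split()[0]
                    chunks = []
                else:
                    chunks.append(line)
        flush()
    return peptides


def _nested_pairs(seq: str, n_disulfides: int) -> tuple[tuple[int, int], ...]:
    """I-IV / II-III nested pairing over the first 2*n cysteines."""
    cys = [i + 1 for i, aa in enumerate(seq) if aa == "C"]
    if len(cys) < 2 * n_disulfides:
        return ()
    used = cys[: 2 * n_disulfides]
    return tuple(
        (used[i], used[2 * n_disulfides - 1 - i]) for i in range(n_disulfides)
    )


@dataclass
class PipelineResult:
    candidates: list
    annotations: list[PrecursorAnnotation]
    matrix: object
    paths: dict[str, Path]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and write the report bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    queries = read_queries(config.queries, config.n_disulfides)
    if not queries:
        raise PipelineConfigError("no query peptides loaded")
    framework = framework_of(queries[0])

    # --- translated search over all assemblies -------------------------
    all_hits = []
    assemblies: dict[str, list[NucleotideRecord]] = {}
    for path in config.assemblies + config.genome_assemblies:
        sample = Path(path).stem
        records = read_fasta(path)
        assemblies[sample] = records
        for q in queries:
            hits = search_transcripts(
                q.name, q.sequence, records, min_score=config.min_score
            )
            for h in hits:
                all_hits.append((sample, h))
    write_hits_table([h for _, h in all_hits], out / "hits.tsv")
    logger.info("search: %d hits across %d assemblies",
                len(all_hits), len(assemblies))

    # --- mining: ORFs, framework filter, precursor annotation ----------
    genome_samples = {Path(p).stem for p in config.genome_assemblies}
    annotations: list[PrecursorAnnotation] = []
    ann_samples: list[str] = []
    hit_keys = {(s, h.transcript_id) for s, h in all_hits}
    record_by_id = {
        (sample, r.id): r
        for sample, records in assemblies.items()
        for r in records
    }
    for sample, tid in sorted(hit_keys):
        record = record_by_id[(sample, tid)]
        for orf in extract_orfs(record, min_protein_len=config.min_protein_len):
            for q in queries:
                span = locate_core(orf.protein, q)
                if span is None:
                    continue
                core = orf.protein[span[0] : span[1]]
                if not matches_framework(core, framework,
                                         slack=config.framework_slack):
                    continue
                try:
                    ann = annotate_precursor(
                        orf, span, transcript=record,
                        signal_len=config.signal_len,
                    )
                except ValueError:
                    continue
                annotations.append(ann)
                ann_samples.append(sample)
                break
    candidates = dedupe_candidates(
        annotations, ann_samples, name_prefix=config.candidate_prefix
    )
    write_candidate_table(candidates, out / "candidates.tsv")
    logger.info("mining: %d candidates from %d annotations",
                len(candidates), len(annotations))

    # --- theoretical ions ----------------------------------------------
    ion_inputs = [(q.name, q.sequence, q.n_disulfides) for q in queries]
    ion_inputs += [
        (c.name, c.core_sequence, config.n_disulfides) for c in candidates
    ]
    # candidates duplicating a query sequence keep the query's name
    seen_seqs: dict[str, str] = {}
    unique_inputs = []
    for name, seq, nss in ion_inputs:
        if seq in seen_seqs:
            continue
        seen_seqs[seq] = name
        unique_inputs.append((name, seq, nss))
    ions = ion_table(unique_inputs)
    write_ion_table(ions, out / "ions.tsv")

    # --- MS matching ----------------------------------------------------
    peptide_names = [i.peptide_name for i in ions]
    ms_calls = {}
    all_matches = []
    for path in config.peak_lists:
        pl = read_peak_list(path)
        matches = match_ions(
            ions, pl, tolerance=config.tolerance, mode=config.tolerance_mode
        )
        all_matches.extend(matches)
        ms_calls[pl.sample] = presence_call(
            matches, peptide_names, min_charges=config.min_charges
        )
    write_matches_table(all_matches, out / "matches.tsv")

    # --- evidence matrix -------------------------------------------------
    seq_ev: dict[str, set[str]] = {}
    gen_ev: dict[str, set[str]] = {}
    for cand in candidates:
        name = seen_seqs.get(cand.core_sequence, cand.name)
        for sample in cand.samples:
            target = gen_ev if sample in genome_samples else seq_ev
            target.setdefault(sample, set()).add(name)
    samples = sorted(
        set(assemblies) | set(ms_calls) | set(seq_ev) | set(gen_ev)
    )
    matrix = build_presence_matrix(
        seq_ev, ms_calls, peptides=peptide_names, samples=samples,
        genome_evidence=gen_ev,
    )
    matrix.write_tsv(out / "presence_matrix.tsv")
    (out / "presence_glyphs.txt").write_text(matrix.render_glyphs())

    # --- run log ---------------------------------------------------------
    log = {
        "version": __version__,
        "config": config.to_dict(),
        "n_hits": len(all_hits),
        "n_candidates": len(candidates),
        "n_matches": len(all_matches),
        "samples": samples,
        "peptides": peptide_names,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))

    paths = {
        "hits": out / "hits.tsv",
        "candidates": out / "candidates.tsv",
        "ions": out / "ions.tsv",
        "matches": out / "matches.tsv",
        "presence_matrix": out / "presence_matrix.tsv",
        "run_log": out / "run_log.json",
    }
    return PipelineResult(
        candidates=candidates,
        annotations=annotations,
        matrix=matrix,
        paths=paths,
    )
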