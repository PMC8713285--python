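# cystmine

Mining cysteine-framework peptide families from nucleotide assemblies.

`cystmine` re-creates an in-silico peptide discovery workflow as a reusable,
fully offline pipeline: it searches transcriptome/genome FASTA files for
homologs of a mature peptide query by local alignment against six-frame
translations, filters hits by the family's cysteine spacing framework,
segments precursor ORFs into signal / leader / core, computes
disulfide-corrected theoretical ion m/z, cross-validates predictions against
MS peak lists, and scores eukaryote-vs-prokaryote origin evidence (poly-A
tails, intron length bands, GC-content bimodality). A ground-truthed
simulator generates every input format, so the whole pipeline is testable
without external data.

## Quick start

```sh
# generate a synthetic dataset with a truth manifest
cystmine simulate --seed 7 --out simdata

# write a query FASTA (the built-in reference peptide)
python - <<'EOF'
from cystmine.known import BARRETTIDE_C
open("queries.fasta", "w").write(f">{BARRETTIDE_C.name}\n{BARRETTIDE_C.sequence}\n")
EOF

# full pipeline: search -> mine -> ions -> MS match -> evidence matrix
cystmine run --queries queries.fasta \
    --assemblies simdata/sim01.fasta \
    --peaks simdata/sim01.csv \
    --out report

cat report/presence_glyphs.txt
```

Stages are also available individually (`search`, `mine`, `ions`, `match`,
`report`), exchanging plain TSV/CSV/JSON. `cystmine reference-ions` prints
the theoretical charge-state m/z of the built-in reference peptide.

## Package layout

| module | role |
| --- | --- |
| `seq_core` | FASTA I/O, six-frame translation with coordinate maps, ORF extraction |
| `translated_search` | deterministic affine-gap Smith-Waterman vs six-frame translations |
| `mining` | hit cleanup, cysteine-framework filter, precursor annotation, candidate dedup |
| `peptide_mass` | monoisotopic masses from elemental composition, disulfide correction, m/z, isobaric keys |
| `ms_match` | peak-list loading (CSV/MGF), tolerance matching, presence matrix |
| `origin_evidence` | poly-A detection, intron calling by anchor chaining, length bands, GC bimodality |
| `synthetic_data` | seeded simulator with truth manifest for every stage |
| `pipeline` / `cli` | orchestration, config, reports |

Mass constants are documented in `peptide_mass.py`: monoisotopic atomic
masses (H 1.0078250319, C 12, N 14.0030740052, O 15.9949146221,
S 31.97207069), proton 1.007276466 Da; each disulfide bond removes two
hydrogen atoms.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis) and an independent
brute-force alignment oracle; `tests/test_acceptance.py` holds the
acceptance criteria.

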