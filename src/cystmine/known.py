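"""Built-in reference data for the barrettide peptide family."""

from __future__ import annotations

from .mining import MaturePeptide, framework_of

#: Mature barrettide C: 31 residues, cysteines at 5/7/18/23, two disulfide
#: bonds with I-IV / II-III connectivity.
BARRETTIDE_C = MaturePeptide(
    name="barrettide-C",
    sequence="NVVPCFCVEDETSGAKTCIPDNCDASRGTNP",
    disulfide_pairs=((5, 23), (7, 18)),
)

#: The family's cysteine spacing framework, C-x1-C-x10-C-x4-C.
BARRETTIDE_FRAMEWORK = framework_of(BARRETTIDE_C)

#: Signal-peptide variants observed on family precursors (19 residues).
SIGNAL_PEPTIDES = (
    "MATKVALLVVSALIAVAAA",
    "MAIKVALLAVSALIAVAAA",
)

#: Leader lengths observed between signal and core.
LEADER_LENGTHS = (19, 105, 112)
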