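"""Monoisotopic masses and charge-state m/z for disulfide-bonded peptides.

Residue masses are derived from elemental composition using CODATA-style
monoisotopic atomic masses (H 1.0078250319, C 12 exactly, N 14.0030740052,
O 15.9949146221, S 31.97207069) rather than a rounded residue table, so
multi-kDa peptides stay exact at 4-decimal table rendering. Each disulfide
bond removes two hydrogen atoms from the reduced peptide mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "MASS_PROTON",
    "MASS_HYDROGEN",
    "MASS_WATER",
    "RESIDUE_MASSES",
    "TheoreticalIonSet",
    "monoisotopic_mass",
    "mz",
    "ion_table",
    "isobaric_key",
    "are_isobaric",
    "write_ion_table",
]

# monoisotopic atomic masses (Da)
_H = 1.0078250319
_C = 12.0
_N = 14.0030740052
_O = 15.9949146221
_S = 31.97207069

MASS_PROTON = 1.007276466
MASS_HYDROGEN = _H
MASS_WATER = 2 * _H + _O

# residue (= amino acid minus water) elemental compositions: C, H, N, O, S
_RESIDUE_FORMULAS: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

RESIDUE_MASSES: Mapping[str, float] = {
    aa: c * _C + h * _H + n * _N + o * _O + s * _S
    for aa, (c, h, n, o, s) in _RESIDUE_FORMULAS.items()
}


def monoisotopic_mass(sequence: str, n_disulfides: int = 0) -> float:
    """Neutral monoisotopic mass of a peptide with the given number of
    disulfide bonds (each bond subtracts 2 H from the reduced mass)."""
    if n_disulfides < 0:
        raise ValueError("n_disulfides must be >= 0")
    total = MASS_WATER
    n_cys = 0
    for i, aa in enumerate(sequence):
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(
                f"nonstandard residue {aa!r} at position {i + 1}"
            ) from None
        n_cys += aa == "C"
    if 2 * n_disulfides > n_cys:
        raise ValueError(
            f"{n_disulfides} disulfides need {2 * n_disulfides} Cys, "
            f"sequence has {n_cys}"
        )
    return total - 2 * n_disulfides * MASS_HYDROGEN


def mz(neutral_mass: float, z: int) -> float:
    """m/z of the [M+zH]z+ adduct."""
    if z <= 0:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + z * MASS_PROTON) / z


@dataclass(frozen=True)
class TheoreticalIonSet:
    """Oxidized monoisotopic mass of one peptide plus m/z at charges 1-4."""

    peptide_name: str
    sequence: str
    neutral_mass_oxidized: float
    n_disulfides: int

    @property
    def mz_by_charge(self) -> dict[int, float]:
        return {z: mz(self.neutral_mass_oxidized, z) for z in (1, 2, 3, 4)}

    def mz_at(self, z: int) -> float:
        return mz(self.neutral_mass_oxidized, z)


def ion_table(
    peptides: Iterable[tuple[str, str, int]]
) -> list[TheoreticalIonSet]:
    """Build ion sets from (name, sequence, n_disulfides) triples."""
    return [
        TheoreticalIonSet(
            peptide_name=name,
            sequence=seq,
            neutral_mass_oxidized=monoisotopic_mass(seq, n_ss),
            n_disulfides=n_ss,
        )
        for name, seq, n_ss in peptides
    ]


def isobaric_key(sequence: str) -> str:
    """Canonical form under Leu/Ile mass equivalence (I -> L)."""
    return sequence.replace("I", "L")


def are_isobaric(a: str, b: str, tol: float = 1e-9) -> bool:
    """True iff the two sequences have equal monoisotopic mass within tol."""
    return abs(monoisotopic_mass(a) - monoisotopic_mass(b)) <= tol


def _round4(x: float) -> float:
    # Python's round is round-half-to-even, matching table rendering policy
    return round(x, 4)


def write_ion_table(ion_sets: Iterable[TheoreticalIonSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tMH1\tMH2\tMH3\tMH4\tn_disulfides\n")
        for s in ion_sets:
            fh.write(
                f"{s.peptide_name}"
                + "".join(f"\t{_round4(s.mz_at(z)):.4f}" for z in (1, 2, 3, 4))
                + f"\t{s.n_disulfides}\n"
            )
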