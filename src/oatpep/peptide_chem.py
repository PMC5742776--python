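"""Peptide physicochemical property calculators.

Masses follow the ExPASy residue-mass convention (isotope-abundance-weighted
average and monoisotopic), which is what the UniProt molecular masses of the
packaged fixtures were computed with.  Solubility uses the charged-residue
heuristic of the PepCalc-style screen: a peptide is predicted water-soluble
("good") when it carries at least one charged residue (D, E, K, R) per five
residues.  Histidine and the free termini are not counted as charged.
"""

from __future__ import annotations

from dataclasses import dataclass

#: ExPASy average residue masses (Da).
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

#: ExPASy monoisotopic residue masses (Da).
MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_AVERAGE_DA = 18.0153
WATER_MONOISOTOPIC_DA = 18.010565

CHARGED_RESIDUES = frozenset("DEKR")

#: Hydrophobic set used for composition reporting; matches the hydrophobic
#: N-terminal group of the renin selection criteria (Ala, Gly, Val, Leu, Ile,
#: Pro, Phe, Met, Trp).
HYDROPHOBIC_RESIDUES = frozenset("AGVLIPFMW")

#: Charged fraction at or above which a peptide is called water-soluble:
#: one charged residue per five residues.
SOLUBILITY_THRESHOLD = 0.2


class UnsupportedResidueError(ValueError):
    """Mass requested for a sequence containing a residue with no defined mass."""


def _mass(sequence: str, table: dict[str, float], water: float) -> float:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    total = water
    for residue in sequence:
        try:
            total += table[residue]
        except KeyError:
            raise UnsupportedResidueError(
                f"no mass defined for residue {residue!r}"
            ) from None
    return total


def average_mass(sequence: str) -> float:
    """Average molecular mass in daltons (residue masses + one water)."""
    return _mass(sequence, AVERAGE_RESIDUE_MASS, WATER_AVERAGE_DA)


def monoisotopic_mass(sequence: str) -> float:
    """Monoisotopic molecular mass in daltons."""
    return _mass(sequence, MONOISOTOPIC_RESIDUE_MASS, WATER_MONOISOTOPIC_DA)


def charged_fraction(sequence: str) -> float:
    """Fraction of residues in {D, E, K, R}; 'X' counts toward length only."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    return sum(r in CHARGED_RESIDUES for r in sequence) / len(sequence)


def hydrophobic_fraction(sequence: str) -> float:
    """Fraction of residues in the hydrophobic set {A,G,V,L,I,P,F,M,W}."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    return sum(r in HYDROPHOBIC_RESIDUES for r in sequence) / len(sequence)


def predict_solubility(sequence: str) -> tuple[str, str]:
    """Water-solubility call, "good" or "poor", with a one-line rationale.

    "good" iff charged_fraction >= 0.2, i.e. at least one D/E/K/R per five
    residues; free termini and histidine are ignored.
    """
    frac = charged_fraction(sequence)
    call = "good" if frac >= SOLUBILITY_THRESHOLD else "poor"
    n = sum(r in CHARGED_RESIDUES for r in sequence)
    rationale = (
        f"{n} charged residue(s) in {len(sequence)} "
        f"(fraction {frac:.2f} {'>=' if call == 'good' else '<'} {SOLUBILITY_THRESHOLD})"
    )
    return call, rationale


@dataclass(frozen=True)
class PeptideProperties:
    """Bundle of the calculator outputs for one peptide.

    Masses are ``None`` for sequences containing 'X' (an undetermined residue
    has no mass convention, so mass computation is refused rather than
    guessed); the composition fractions count 'X' toward length only.
    """

    length: int
    average_mass_da: float | None
    monoisotopic_mass_da: float | None
    charged_fraction: float
    hydrophobic_fraction: float
    solubility_call: str
    solubility_rationale: str


def peptide_properties(sequence: str) -> PeptideProperties:
    """Compute all properties of one peptide."""
    call, rationale = predict_solubility(sequence)
    has_x = "X" in sequence
    return PeptideProperties(
        length=len(sequence),
        average_mass_da=None if has_x else average_mass(sequence),
        monoisotopic_mass_da=None if has_x else monoisotopic_mass(sequence),
        charged_fraction=charged_fraction(sequence),
        hydrophobic_fraction=hydrophobic_fraction(sequence),
        solubility_call=call,
        solubility_rationale=rationale,
    )
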