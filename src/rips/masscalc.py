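"""Oligonucleotide mass arithmetic for CMC adducts and protection products.

Masses are computed from elemental composition: each residue contributes its
ribonucleoside formula, each internucleotide phosphodiester bridge adds HPO3
and removes one water, and a 5'-monophosphate adds one further HPO3.  Ψ is a
C-glycoside isomer of uridine and contributes exactly the mass of U.

The carbodiimide label is modeled as the addition of the intact CMC-derived
cation, C14H26N3O+ (the methylated N-cyclohexyl-N'-(2-morpholinoethyl)
carbodiimide moiety), with no proton correction: its monoisotopic mass is
252.2 Da to one decimal, and adding it to an unlabeled fragment mass
reproduces the observed mass of the singly-labeled product (e.g. a 5855.7 Da
16-mer labels to 6107.9 Da).  The electron mass (~0.5 mDa) is ignored.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal

from .templates import PSI_CHARS, RnaTemplate

Mode = Literal["monoisotopic", "average"]

#: Monoisotopic atomic masses (u), CODATA/IUPAC values.
MONOISOTOPIC = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048,
                "O": 15.9949146196, "P": 30.97376163}
#: Standard atomic weights (u), isotope-abundance weighted.
AVERAGE = {"C": 12.0107, "H": 1.00794, "N": 14.0067, "O": 15.9994, "P": 30.973762}

#: Ribonucleoside elemental formulas; Ψ is isomeric with U.
NUCLEOSIDES: dict[str, Counter] = {
    "A": Counter({"C": 10, "H": 13, "N": 5, "O": 4}),
    "C": Counter({"C": 9, "H": 13, "N": 3, "O": 5}),
    "G": Counter({"C": 10, "H": 13, "N": 5, "O": 5}),
    "U": Counter({"C": 9, "H": 12, "N": 2, "O": 6}),
}
HPO3 = Counter({"H": 1, "P": 1, "O": 3})
H2O = Counter({"H": 2, "O": 1})
CMC_CATION = Counter({"C": 14, "H": 26, "N": 3, "O": 1})


class MassError(ValueError):
    pass


@dataclass(frozen=True)
class MassSpec:
    """An RNA species whose mass is to be predicted."""

    sequence: str
    five_prime: Literal["OH", "monophosphate"] = "OH"
    n_cmc_adducts: int = 0
    mode: Mode = "monoisotopic"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise MassError("empty sequence")
        if self.n_cmc_adducts < 0:
            raise MassError("n_cmc_adducts must be >= 0")
        if self.five_prime not in ("OH", "monophosphate"):
            raise MassError(f"unknown 5' chemistry {self.five_prime!r}")
        if self.mode not in ("monoisotopic", "average"):
            raise MassError(f"unknown mode {self.mode!r}")


def formula_mass(formula: Counter, mode: Mode = "monoisotopic") -> float:
    table = MONOISOTOPIC if mode == "monoisotopic" else AVERAGE
    return sum(table[el] * n for el, n in formula.items())


def oligo_formula(sequence: str, five_prime: str = "OH", n_cmc_adducts: int = 0) -> Counter:
    """Elemental formula of a linear RNA oligo (3'-OH)."""
    total: Counter = Counter()
    n = 0
    for c in sequence.upper().replace("T", "U"):
        base = "U" if c in PSI_CHARS else c
        if base not in NUCLEOSIDES:
            raise MassError(f"invalid base {c!r} in sequence")
        total += NUCLEOSIDES[base]
        n += 1
    for _ in range(n - 1):  # phosphodiester bridges
        total += HPO3
        total -= H2O
    if five_prime == "monophosphate":
        total += HPO3
    for _ in range(n_cmc_adducts):
        total += CMC_CATION
    return total


def cmc_adduct_mass(mode: Mode = "monoisotopic") -> float:
    """Mass added per stable CMC adduct (the intact C14H26N3O+ cation)."""
    return formula_mass(CMC_CATION, mode)


def rna_mass(spec: MassSpec) -> float:
    """Predicted mass (Da) of an RNA oligo with optional CMC adducts."""
    return formula_mass(
        oligo_formula(spec.sequence, spec.five_prime, spec.n_cmc_adducts), spec.mode
    )


@dataclass(frozen=True)
class ProtectionProduct:
    """The XRN1-protected fragment of a labeled template: [Ψ, 3'-end]."""

    sequence: str
    length: int
    mass: float


def predicted_protection_product(
    template: RnaTemplate,
    psi: int,
    mode: Mode = "monoisotopic",
    five_prime: str = "monophosphate",
) -> ProtectionProduct:
    """Sequence, length and singly-labeled mass of the protection product.

    Digestion halts at the CMC-labeled Ψ, so the fragment runs from the Ψ to
    the 3' end; XRN1 leaves a 5'-monophosphate on the product (overridable
    for comparison with synthetic 5'-OH standards).  A 19-mer with Ψ at
    position 4 yields the 16-nucleotide product [4, 19].
    """
    if psi not in template.psi_positions:
        raise MassError(f"position {psi} is not an annotated Ψ in template {template.id!r}")
    frag = template.sequence[psi - 1 :]
    mass = rna_mass(MassSpec(frag, five_prime=five_prime, n_cmc_adducts=1, mode=mode))
    return ProtectionProduct(frag, len(frag), mass)
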