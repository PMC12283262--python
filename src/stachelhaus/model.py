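"""Core domain types for adenylation-domain specificity codes.

Nonribosomal peptide synthetase (NRPS) adenylation (A) domains select the
amino-acid moiety that a module incorporates into the growing peptide.
Substrate choice is largely determined by ten residues lining the binding
pocket — the "specificity-conferring code" or Stachelhaus code — read at
positions 235, 236, 239, 278, 299, 301, 322, 330, 331 and 517 of the
GrsA phenylalanine-activating domain reference numbering.

This module defines the code itself, the controlled vocabulary of substrate
moieties (20 proteinogenic plus 16 nonproteinogenic amino-acid moieties),
the tailoring-modification tags attached to substrate annotations, and the
catalogue entry tying a code to one or more annotated substrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CODE_LENGTH",
    "AMINO_ACIDS",
    "CODE_ALPHABET",
    "GRSA_POSITIONS",
    "PROTEINOGENIC",
    "NONPROTEINOGENIC",
    "SUBSTRATES",
    "MODIFICATION_TAGS",
    "ELONGATING_TAGS",
    "StachelhausError",
    "InvalidCodeError",
    "VocabularyError",
    "SignatureCode",
    "substrate_class",
    "validate_substrate",
    "validate_modification",
    "is_elongating",
    "SubstrateAnnotation",
    "CatalogueEntry",
    "is_promiscuous",
    "canonical_check",
]

#: Length of a specificity code.
CODE_LENGTH = 10

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues permitted in a signature code; 'X' marks an unresolved slot
#: (e.g. a signature position that aligned to a gap).
CODE_ALPHABET = frozenset(AMINO_ACIDS) | {"X"}

#: 1-based positions of the ten signature residues in GrsA numbering.
GRSA_POSITIONS = (235, 236, 239, 278, 299, 301, 322, 330, 331, 517)

#: The 20 proteinogenic substrate moieties (three-letter names).
PROTEINOGENIC = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

#: The 16 nonproteinogenic substrate moieties:
#: Abu  alpha-aminobutyrate
#: AMA  alpha-aminoadipic acid
#: ANPA alpha-amino-delta-nitropentanoic acid
#: AZC  azetidine alpha-carboxylic acid
#: Cya-3  beta-cyano-alanine
#: Dab  alpha,gamma-diaminobutyric acid
#: Dap  alpha,beta-diaminopropionic acid
#: Dha  dehydroalanine
#: Dhb  dehydrobutyrine
#: Dhv  dehydrovaline
#: End  enduracididine
#: Har  homoarginine
#: Hpg  gamma-hydroxy-phenylglycine
#: Hse/Hsl  homoserine / homoserine lactone
#: Orn  ornithine
#: Pip  pipecolic acid (cyclic lysine)
NONPROTEINOGENIC = (
    "Abu", "AMA", "ANPA", "AZC", "Cya-3", "Dab", "Dap", "Dha", "Dhb", "Dhv",
    "End", "Har", "Hpg", "Hse/Hsl", "Orn", "Pip",
)

#: Closed vocabulary of the 36 substrate moiety names.
SUBSTRATES = PROTEINOGENIC + NONPROTEINOGENIC

#: Tailoring modifications that lengthen the A domain itself: the tailoring
#: unit (N-methyltransferase, oxidase or monooxygenase) is embedded between
#: the A8 and A9 core motifs, so the domain carries an insertion.
ELONGATING_TAGS = frozenset({"N-Me", "N,O-diMe", "Ox", "MOX"})

#: Controlled vocabulary of modification tags. Tags outside
#: :data:`ELONGATING_TAGS` (beta-hydroxylation and the N-delta-series on
#: ornithine, halogenations, etc.) are installed by enzymes acting in trans
#: and leave the A-domain length unchanged.
MODIFICATION_TAGS = ELONGATING_TAGS | frozenset({
    "beta-OH", "gamma-Cl", "beta-Cl", "beta-Cl-beta-OH", "epsilon-OH",
    "beta-OH-delta-Me-O-Me", "beta-OH-p-NO2",
    "Nd-OH", "Nd-acetyl", "Nd-formyl", "Nd-butyryl", "Nd-nitroso",
    "cyclo-Nd-OH", "none",
})


class StachelhausError(Exception):
    """Base class for errors raised by this package."""


class InvalidCodeError(StachelhausError, ValueError):
    """A signature code violates the length-10 / alphabet invariants."""


class VocabularyError(StachelhausError, ValueError):
    """A substrate or modification name is outside the controlled vocabulary."""


class SignatureCode(str):
    """A 10-residue specificity code.

    Subclasses :class:`str`; construction normalises to uppercase and
    enforces the invariants (length exactly 10, characters drawn from the
    20 standard residues plus 'X' for unresolved slots).
    """

    __slots__ = ()

    def __new__(cls, residues: str) -> "SignatureCode":
        residues = str(residues).upper()
        if len(residues) != CODE_LENGTH:
            raise InvalidCodeError(
                f"signature code must have exactly {CODE_LENGTH} residues, "
                f"got {len(residues)}: {residues!r}"
            )
        bad = set(residues) - CODE_ALPHABET
        if bad:
            raise InvalidCodeError(
                f"signature code contains non-amino-acid characters "
                f"{sorted(bad)}: {residues!r}"
            )
        return super().__new__(cls, residues)


def substrate_class(name: str) -> str:
    """Return ``"proteinogenic"`` or ``"nonproteinogenic"`` for a moiety name."""
    if name in PROTEINOGENIC:
        return "proteinogenic"
    if name in NONPROTEINOGENIC:
        return "nonproteinogenic"
    raise VocabularyError(f"unknown substrate moiety name: {name!r}")


def validate_substrate(name: str) -> str:
    if name not in SUBSTRATES:
        raise VocabularyError(f"unknown substrate moiety name: {name!r}")
    return name


def validate_modification(tag: str) -> str:
    if tag not in MODIFICATION_TAGS:
        raise VocabularyError(f"unknown modification tag: {tag!r}")
    return tag


def is_elongating(tag: str) -> bool:
    """Whether a modification tag implies an elongated (inserted) A domain."""
    return tag in ELONGATING_TAGS


@dataclass(frozen=True)
class SubstrateAnnotation:
    """One substrate assignment of a code, with modification tags and a
    domain-occurrence count ``n`` (how many A domains carried this code for
    this substrate).

    ``substrate`` is usually one of the 36 controlled names; loaders decide
    whether an out-of-vocabulary name is an error (strict) or a warning.
    """

    substrate: str
    modifications: frozenset = frozenset()
    n: int = 1
    species: tuple = ()
    iterative: bool = False
    source: str = ""

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"occurrence count n must be >= 1, got {self.n}")
        object.__setattr__(self, "modifications", frozenset(self.modifications))
        object.__setattr__(self, "species", tuple(self.species))

    @property
    def key(self) -> tuple:
        """Identity of the annotation within an entry: (substrate, modifications)."""
        return (self.substrate, self.modifications)


@dataclass
class CatalogueEntry:
    """A signature code with all substrate annotations observed for it."""

    code: SignatureCode
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        self.code = SignatureCode(self.code)
        if not self.annotations:
            raise ValueError(f"catalogue entry {self.code} has no annotations")
        keys = [a.key for a in self.annotations]
        if len(keys) != len(set(keys)):
            raise ValueError(
                f"catalogue entry {self.code} has duplicate "
                f"(substrate, modifications) annotations"
            )

    def substrates(self) -> frozenset:
        """Distinct substrate names across all annotations."""
        return frozenset(a.substrate for a in self.annotations)

    def total_n(self) -> int:
        return sum(a.n for a in self.annotations)


def is_promiscuous(entry: CatalogueEntry) -> bool:
    """A code is promiscuous when it is associated with two or more distinct
    substrate moieties (modification variants of one moiety do not count)."""
    return len(entry.substrates()) >= 2


def canonical_check(code: SignatureCode) -> list:
    """Warn about departures from the empirically conserved anchor residues.

    Nearly all amino-acid-activating A domains carry Asp at position 235 and
    Lys at position 517, i.e. codes begin with 'D' and end with 'K'. The
    conservation is empirical, so departures are warnings, not errors.
    """
    code = SignatureCode(code)
    warnings = []
    if code[0] != "D":
        warnings.append(
            f"first residue is {code[0]!r}, expected conserved Asp (D) at position 235"
        )
    if code[-1] != "K":
        warnings.append(
            f"last residue is {code[-1]!r}, expected conserved Lys (K) at position 517"
        )
    return warnings
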