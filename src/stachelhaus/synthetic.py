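"""Synthetic A-domain and assembly-line generator with ground-truth manifests.

Every pipeline stage (domain scanning, code extraction, elongation flagging,
substrate prediction) can be exercised on sequences generated here, with a
manifest recording exactly what was planted where. The generator emulates
the geometry of real NRPS subunits — 530-residue A-domain-like units with a
10-residue code at fixed reference positions, optional tailoring-unit
insertions between the A8 and A9 motifs, inter-module linkers, and iterative
module reuse — not their phylogenetic structure: backgrounds are i.i.d.
residues, and divergence is modelled as uniform point substitution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .model import AMINO_ACIDS, SignatureCode
from .reference import ReferenceProfile

__all__ = [
    "UNIFORM_FREQS",
    "SWISSPROT_FREQS",
    "ScaffoldSpec",
    "ModuleSpec",
    "ModuleRecord",
    "TruthManifest",
    "AssemblyLine",
    "make_scaffold",
    "plant_code",
    "mutate",
    "random_peptide",
    "build_assembly_line",
]

#: Uniform background over the 20 residues (the default: maximally
#: transparent for tests).
UNIFORM_FREQS = {aa: 1.0 / 20 for aa in AMINO_ACIDS}

#: Swiss-Prot-like average residue frequencies, for users who want a more
#: protein-like background composition.
SWISSPROT_FREQS = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

_DEFAULT_POSITIONS = (235, 236, 239, 278, 299, 301, 322, 330, 331, 517)
_DEFAULT_INTERVAL = (340, 510)


def _freq_arrays(distribution):
    distribution = distribution or UNIFORM_FREQS
    letters = np.array(list(AMINO_ACIDS))
    probs = np.array([distribution.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("residue distribution has zero total mass")
    return letters, probs / probs.sum()


@dataclass(frozen=True)
class ScaffoldSpec:
    """Background sequence specification for one A-domain-like scaffold."""

    length: int = 530
    seed: int = 0
    residue_distribution: dict | None = None

    def __post_init__(self):
        if self.length < _DEFAULT_POSITIONS[-1]:
            raise ValueError(
                f"scaffold length {self.length} is below the last signature "
                f"position {_DEFAULT_POSITIONS[-1]}"
            )


@dataclass(frozen=True)
class ModuleSpec:
    """One module to plant in an assembly line."""

    code: SignatureCode
    substrate: str = ""
    insertion_length: int = 0
    mutation_rate: float = 0.0
    protect_signature: bool = True
    iterative_copies: int = 1

    def __post_init__(self):
        object.__setattr__(self, "code", SignatureCode(self.code))
        if self.insertion_length < 0:
            raise ValueError("insertion_length must be >= 0")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.iterative_copies < 1:
            raise ValueError("iterative_copies must be >= 1")


@dataclass(frozen=True)
class ModuleRecord:
    """Ground truth for one planted module (coordinates 0-based half-open)."""

    start: int
    end: int
    code: SignatureCode
    substrate: str
    insertion_length: int
    iterative: bool


@dataclass
class TruthManifest:
    """Ground truth for a synthetic assembly line."""

    modules: list = field(default_factory=list)
    seed: int = 0
    linker_length: int = 50

    def __post_init__(self):
        prev_end = -1
        for m in self.modules:
            if m.start <= prev_end:
                raise ValueError("manifest modules must be non-overlapping and ascending")
            prev_end = m.end

    def to_tsv(self) -> str:
        lines = [f"# seed: {self.seed}", f"# linker_length: {self.linker_length}",
                 "start\tend\tcode\tsubstrate\tinsertion_length\titerative"]
        for m in self.modules:
            lines.append(
                f"{m.start}\t{m.end}\t{m.code}\t{m.substrate}"
                f"\t{m.insertion_length}\t{str(m.iterative).lower()}"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "linker_length": self.linker_length,
            "modules": [dict(asdict(m), code=str(m.code)) for m in self.modules],
        }, indent=2) + "\n"


@dataclass(frozen=True)
class AssemblyLine:
    """A synthetic multi-module protein, its manifest, and the profile of the
    base scaffold all modules were derived from."""

    sequence: str
    manifest: TruthManifest
    profile: ReferenceProfile


def make_scaffold(spec: ScaffoldSpec = ScaffoldSpec()):
    """Generate a background scaffold and its derived reference profile.

    Deterministic for a fixed seed. The derived profile uses the standard
    signature positions and an A8–A9 interval of (340, 510).
    """
    letters, probs = _freq_arrays(spec.residue_distribution)
    rng = np.random.default_rng(spec.seed)
    seq = "".join(rng.choice(letters, size=spec.length, p=probs))
    profile = ReferenceProfile(
        sequence=seq,
        signature_positions=_DEFAULT_POSITIONS,
        a8_a9_interval=_DEFAULT_INTERVAL,
        name=f"scaffold-seed{spec.seed}",
    )
    return seq, profile


def plant_code(scaffold: str, profile: ReferenceProfile, code) -> str:
    """Overwrite the scaffold's residues at the signature positions with the
    given code. Later plants overwrite earlier ones slot by slot."""
    code = SignatureCode(code)
    out = list(scaffold)
    for slot, pos in enumerate(profile.signature_positions):
        out[pos - 1] = code[slot]
    return "".join(out)


def mutate(sequence: str, rate: float, seed: int,
           protected_positions=()) -> str:
    """Independently substitute each unprotected position with probability
    ``rate``, drawing uniformly from the 19 other residues.

    ``protected_positions`` are 0-based indices left untouched.
    Deterministic for a fixed seed.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    protected = frozenset(protected_positions)
    out = list(sequence)
    draws = rng.random(len(sequence))
    for i, (aa, u) in enumerate(zip(sequence, draws)):
        if u < rate and i not in protected:
            choices = [c for c in AMINO_ACIDS if c != aa]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def random_peptide(length: int, seed: int, distribution=None) -> str:
    """A background-composition random sequence (used for linkers)."""
    letters, probs = _freq_arrays(distribution)
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(letters, size=length, p=probs))


def _build_module(base: str, profile: ReferenceProfile, spec: ModuleSpec,
                  seed: int) -> str:
    seq = plant_code(base, profile, spec.code)
    if spec.mutation_rate > 0:
        protected = ()
        if spec.protect_signature:
            protected = tuple(p - 1 for p in profile.signature_positions)
        seq = mutate(seq, spec.mutation_rate, seed, protected)
    if spec.insertion_length > 0:
        lo, hi = profile.a8_a9_interval
        mid = (lo + hi) // 2  # 1-based; insert after this residue
        ins = random_peptide(spec.insertion_length, seed + 1)
        seq = seq[:mid] + ins + seq[mid:]
    return seq


def build_assembly_line(modules, linker_length: int = 50, seed: int = 0,
                        scaffold_spec: ScaffoldSpec | None = None) -> AssemblyLine:
    """Concatenate planted modules into one synthetic NRPS-like protein.

    All modules share one base scaffold (so they are homologous, as real
    modules are); each module applies its own code, mutations and A8–A9
    insertion. ``iterative_copies`` > 1 repeats a module, flagged as
    iterative in the manifest. Linkers of background composition are placed
    before, between and after modules. Deterministic for a fixed seed.
    """
    modules = list(modules)
    if not modules:
        raise ValueError("at least one module is required")
    if scaffold_spec is None:
        scaffold_spec = ScaffoldSpec(seed=seed)
    base, profile = make_scaffold(scaffold_spec)
    rng = np.random.default_rng(seed)

    parts, records = [], []
    offset = 0

    def add_linker():
        nonlocal offset
        if linker_length > 0:
            linker = random_peptide(linker_length, int(rng.integers(2**31)),
                                    scaffold_spec.residue_distribution)
            parts.append(linker)
            offset += len(linker)

    add_linker()
    for spec in modules:
        iterative = spec.iterative_copies > 1
        for _ in range(spec.iterative_copies):
            mod_seed = int(rng.integers(2**31))
            mod = _build_module(base, profile, spec, mod_seed)
            records.append(ModuleRecord(
                start=offset, end=offset + len(mod), code=spec.code,
                substrate=spec.substrate,
                insertion_length=spec.insertion_length,
                iterative=iterative,
            ))
            parts.append(mod)
            offset += len(mod)
            add_linker()

    manifest = TruthManifest(modules=records, seed=seed,
                             linker_length=linker_length)
    return AssemblyLine(sequence="".join(parts), manifest=manifest,
                        profile=profile)
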