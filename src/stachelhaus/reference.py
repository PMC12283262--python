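"""Locating A domains and reading specificity codes off a reference alignment.

The extraction strategy is positional: a query protein (or a candidate
domain region of one) is aligned globally to a reference A domain of known
numbering, and the query residues that land in the columns of the ten
signature positions are read off as the code. Insertions between the A8 and
A9 core motifs — where N-methyltransferase, oxidase and monooxygenase units
are embedded — are measured from the same alignment and flagged as domain
elongation when they exceed a threshold.

Pairwise alignment is delegated to :mod:`biotite.sequence.align`
(Needleman–Wunsch / Smith–Waterman with affine gaps). A gap of length L
costs ``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import biotite.sequence as _bseq
import biotite.sequence.align as _balign

from .model import AMINO_ACIDS, GRSA_POSITIONS, SignatureCode, StachelhausError

__all__ = [
    "AlignmentParams",
    "ReferenceProfile",
    "PairwiseAlignment",
    "ADomainHit",
    "AlignmentInputError",
    "ExtractionError",
    "MeasurementError",
    "global_align",
    "local_align",
    "extract_signature",
    "measure_elongation",
    "scan_protein",
    "load_reference_profile",
    "default_reference_profile",
]

_VALID_QUERY = frozenset(AMINO_ACIDS) | {"X"}

#: Default insertion size (residues, within the A8–A9 interval) above which a
#: domain is called elongated. Tailoring-unit insertions run to hundreds of
#: residues (the largest characterised is 342), while alignment noise stays
#: in the single digits; 50 separates the regimes.
DEFAULT_ELONGATION_THRESHOLD = 50

#: Minimum local-alignment score, as a fraction of the reference
#: self-alignment score, for a region to count as an A-domain hit.
DEFAULT_MIN_SCORE_FRACTION = 0.4


class AlignmentInputError(StachelhausError, ValueError):
    """A sequence contains characters outside the amino-acid alphabet."""


class ExtractionError(StachelhausError):
    """The alignment does not cover one or more signature positions."""


class MeasurementError(StachelhausError):
    """The alignment does not cover the A8–A9 interval."""


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for pairwise alignment.

    Defaults are the standard protein settings: BLOSUM62 with affine gap
    penalties 11 (open) / 1 (extend).
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    mode: str = "global"

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        if self.mode not in ("global", "local"):
            raise ValueError(f"mode must be 'global' or 'local', got {self.mode!r}")

    def gap_cost(self, length: int) -> int:
        """Total penalty of a single gap of the given length (positive)."""
        if length <= 0:
            return 0
        return self.gap_open + (length - 1) * self.gap_extend

    def substitution_matrix(self) -> "_balign.SubstitutionMatrix":
        alph = _bseq.ProteinSequence.alphabet
        return _balign.SubstitutionMatrix(alph, alph, self.matrix)


@dataclass(frozen=True)
class ReferenceProfile:
    """Reference A domain plus the coordinates read off it.

    ``signature_positions`` are 1-based positions of the ten specificity
    residues in the reference sequence (GrsA numbering by default).
    ``a8_a9_interval`` brackets, in the same 1-based coordinates, the
    inter-motif region between core motifs A8 and A9 where tailoring-unit
    insertions occur; it must lie after the ninth signature position and
    before the tenth.
    """

    sequence: str
    signature_positions: tuple = GRSA_POSITIONS
    a8_a9_interval: tuple = (340, 510)
    name: str = "reference"

    def __post_init__(self):
        seq = str(self.sequence).upper()
        _check_protein(seq, "reference")
        object.__setattr__(self, "sequence", seq)
        pos = tuple(int(p) for p in self.signature_positions)
        if len(pos) != 10:
            raise ValueError("exactly 10 signature positions are required")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("signature positions must be strictly increasing")
        if pos[0] < 1 or pos[-1] > len(seq):
            raise ValueError("signature positions must lie within the sequence")
        object.__setattr__(self, "signature_positions", pos)
        lo, hi = (int(x) for x in self.a8_a9_interval)
        if not (pos[-2] < lo < hi < pos[-1]):
            raise ValueError(
                "a8_a9_interval must lie strictly between the 9th and 10th "
                "signature positions"
            )
        object.__setattr__(self, "a8_a9_interval", (lo, hi))

    @property
    def signature_residues(self) -> SignatureCode:
        """The reference's own code at the signature positions."""
        return SignatureCode(
            "".join(self.sequence[p - 1] for p in self.signature_positions)
        )


@dataclass(frozen=True)
class PairwiseAlignment:
    """A pairwise query/reference alignment.

    ``trace`` is a list of (query_index, reference_index) column pairs,
    0-based, with -1 marking a gap on that side.
    """

    query: str
    reference: str
    score: int
    trace: tuple

    @property
    def aligned_strings(self) -> tuple:
        q, r = [], []
        for qi, ri in self.trace:
            q.append(self.query[qi] if qi >= 0 else "-")
            r.append(self.reference[ri] if ri >= 0 else "-")
        return "".join(q), "".join(r)


@dataclass(frozen=True)
class ADomainHit:
    """One located A domain in a query protein.

    Coordinates are 0-based half-open in the query. ``gap_positions`` holds
    the signature slot indices (0-based, 0..9) that aligned to a query gap
    and were reported as 'X'. ``insertion_length`` counts query residues
    inserted within the reference A8–A9 interval.
    """

    protein_id: str
    start: int
    end: int
    score: int
    code: SignatureCode
    gap_positions: tuple = ()
    insertion_length: int = 0
    elongation_flag: bool = False

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")


def _check_protein(seq: str, what: str) -> str:
    bad = set(seq) - _VALID_QUERY
    if bad or not seq:
        raise AlignmentInputError(
            f"{what} sequence is empty or contains non-amino-acid "
            f"characters {sorted(bad)}"
        )
    return seq


def _biotite_align(query, reference, params, local, terminal_penalty=True):
    qs = _bseq.ProteinSequence(query)
    rs = _bseq.ProteinSequence(reference)
    matrix = params.substitution_matrix()
    alns = _balign.align_optimal(
        qs, rs, matrix,
        gap_penalty=(-params.gap_open, -params.gap_extend),
        terminal_penalty=terminal_penalty,
        local=local,
        max_number=1,
    )
    aln = alns[0]
    trace = tuple((int(a), int(b)) for a, b in aln.trace)
    return PairwiseAlignment(query=query, reference=reference,
                             score=int(aln.score), trace=trace)


def global_align(query: str, reference, params: AlignmentParams | None = None,
                 terminal_penalty: bool = True) -> PairwiseAlignment:
    """Optimal global (Needleman–Wunsch, affine-gap) alignment of a query to
    the reference sequence. Deterministic: ties are broken by a fixed
    traceback order, so identical inputs give identical alignments.
    """
    params = params or AlignmentParams()
    refseq = reference.sequence if isinstance(reference, ReferenceProfile) else reference
    query = _check_protein(str(query).upper(), "query")
    _check_protein(str(refseq).upper(), "reference")
    return _biotite_align(query, refseq, params, local=False,
                          terminal_penalty=terminal_penalty)


def local_align(query: str, reference, params: AlignmentParams | None = None) -> PairwiseAlignment:
    """Optimal local (Smith–Waterman, affine-gap) alignment."""
    params = params or AlignmentParams()
    refseq = reference.sequence if isinstance(reference, ReferenceProfile) else reference
    query = _check_protein(str(query).upper(), "query")
    return _biotite_align(query, refseq, params, local=True)


def _signature_from_alignment(aln: PairwiseAlignment, profile: ReferenceProfile):
    """Read the code out of an existing alignment.

    Signature positions aligned to an internal query gap yield 'X' and are
    recorded; positions falling outside the query's aligned span (terminal
    gaps) are treated as uncovered and raise :class:`ExtractionError`.
    """
    wanted = {p - 1: slot for slot, p in enumerate(profile.signature_positions)}
    # query residue (or -1 for a gap) aligned to each wanted reference index
    aligned_q = {}
    if not any(qi >= 0 for qi, _ in aln.trace):
        raise ExtractionError("alignment contains no query residues")
    first = next(i for i, (qi, _) in enumerate(aln.trace) if qi >= 0)
    last = len(aln.trace) - 1 - next(
        i for i, (qi, _) in enumerate(reversed(aln.trace)) if qi >= 0)
    for col, (qi, ri) in enumerate(aln.trace):
        if ri in wanted:
            if first <= col <= last:
                aligned_q[ri] = qi
            # else: terminal gap region; leave uncovered
    uncovered = [p for p in profile.signature_positions if (p - 1) not in aligned_q]
    if uncovered:
        raise ExtractionError(
            f"alignment does not cover signature positions {uncovered}"
        )
    residues, gap_slots = [], []
    for slot, p in enumerate(profile.signature_positions):
        qi = aligned_q[p - 1]
        if qi < 0:
            residues.append("X")
            gap_slots.append(slot)
        else:
            residues.append(aln.query[qi])
    return SignatureCode("".join(residues)), tuple(gap_slots)


def extract_signature(query: str, profile: ReferenceProfile,
                      params: AlignmentParams | None = None):
    """Extract the 10-residue specificity code of a query A domain.

    The query is aligned globally to the reference and the residues in the
    ten signature columns are returned in order, together with the slots (if
    any) that aligned to gaps and were reported as 'X'.
    """
    aln = global_align(query, profile, params)
    return _signature_from_alignment(aln, profile)


def measure_elongation(aln: PairwiseAlignment, profile: ReferenceProfile,
                       threshold: int = DEFAULT_ELONGATION_THRESHOLD):
    """Measure A-domain elongation from a query/reference alignment.

    Returns ``(insertion_length, elongation_flag)`` where the length is the
    number of query residues aligned to reference gaps whose position falls
    within the profile's A8–A9 interval, and the flag is
    ``insertion_length >= threshold``.
    """
    lo, hi = profile.a8_a9_interval
    max_ref = max((ri for _, ri in aln.trace if ri >= 0), default=-1)
    if max_ref + 1 < hi:
        raise MeasurementError(
            f"alignment covers the reference only up to position {max_ref + 1}, "
            f"short of the A8-A9 interval end {hi}"
        )
    inserted = 0
    ref_consumed = 0  # 1-based position of the last reference residue seen
    for qi, ri in aln.trace:
        if ri >= 0:
            ref_consumed = ri + 1
        elif qi >= 0 and lo <= ref_consumed < hi:
            inserted += 1
    return inserted, inserted >= threshold


def _self_score(profile: ReferenceProfile, params: AlignmentParams) -> int:
    return _biotite_align(profile.sequence, profile.sequence, params,
                          local=False).score


def scan_protein(protein: str, profile: ReferenceProfile,
                 params: AlignmentParams | None = None,
                 min_score_fraction: float = DEFAULT_MIN_SCORE_FRACTION,
                 elongation_threshold: int = DEFAULT_ELONGATION_THRESHOLD,
                 protein_id: str = "query",
                 _min_segment: int = 50,
                 _pad: int = 30) -> list:
    """Locate all A-domain regions in a (possibly multi-modular) protein.

    Candidate regions are found by repeated local alignment against the
    reference: the best-scoring region is accepted if its score reaches
    ``min_score_fraction`` of the reference self-alignment score, the
    flanking segments are then searched recursively, so hits never overlap.
    Each accepted region is re-aligned to the full reference with free
    terminal gaps for code extraction and elongation measurement. Hits are
    returned in ascending coordinate order.
    """
    params = params or AlignmentParams()
    protein = _check_protein(str(protein).upper(), "protein")
    min_score = min_score_fraction * _self_score(profile, params)

    regions = []
    stack = [(0, len(protein))]
    while stack:
        s, e = stack.pop()
        if e - s < _min_segment:
            continue
        aln = _biotite_align(protein[s:e], profile.sequence, params, local=True)
        if aln.score < min_score or not aln.trace:
            continue
        q_cols = [qi for qi, _ in aln.trace if qi >= 0]
        qstart, qend = s + q_cols[0], s + q_cols[-1] + 1
        regions.append((qstart, qend, aln.score, s, e))
        stack.append((s, qstart))
        stack.append((qend, e))

    hits = []
    for qstart, qend, score, seg_s, seg_e in sorted(regions):
        ps = max(seg_s, qstart - _pad)
        pe = min(seg_e, qend + _pad)
        sub = protein[ps:pe]
        aln = _biotite_align(sub, profile.sequence, params, local=False,
                             terminal_penalty=False)
        try:
            code, gap_slots = _signature_from_alignment(aln, profile)
        except ExtractionError:
            continue
        try:
            ins, elong = measure_elongation(aln, profile, elongation_threshold)
        except MeasurementError:
            ins, elong = 0, False
        # span of the query actually aligned to reference residues
        span = [qi for qi, ri in aln.trace if qi >= 0 and ri >= 0]
        start, end = ps + span[0], ps + span[-1] + 1
        hits.append(ADomainHit(
            protein_id=protein_id, start=start, end=end, score=score,
            code=code, gap_positions=gap_slots,
            insertion_length=ins, elongation_flag=elong,
        ))
    return sorted(hits, key=lambda h: h.start)


# ---------------------------------------------------------------------------
# Packaged reference profile

def load_reference_profile(fasta_path, config_path=None) -> ReferenceProfile:
    """Load a reference profile from FASTA plus a key=value side-car config.

    The config (``<fasta stem>.cfg`` by default) may set
    ``signature_positions`` (comma-separated, 1-based) and
    ``a8_a9_interval`` (two comma-separated 1-based positions).
    """
    from Bio import SeqIO

    fasta_path = Path(fasta_path)
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    kwargs = {"sequence": str(record.seq), "name": record.id}
    if config_path is None:
        candidate = fasta_path.with_suffix(".cfg")
        config_path = candidate if candidate.exists() else None
    if config_path is not None:
        for line in Path(config_path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            values = [int(v) for v in re.split(r"[,\s]+", value.strip()) if v]
            if key == "signature_positions":
                kwargs["signature_positions"] = tuple(values)
            elif key == "a8_a9_interval":
                kwargs["a8_a9_interval"] = tuple(values)
    return ReferenceProfile(**kwargs)


def default_reference_profile() -> ReferenceProfile:
    """The packaged default reference profile.

    This is a synthetic 530-residue GrsA-like scaffold (see the data file's
    header): a randomly generated background carrying the canonical
    phenylalanine code DAWTIAAICK at the GrsA signature positions. It stands
    in for the true GrsA phenylalanine-activating domain, which is not
    bundled; users analysing real proteins should supply the genuine domain
    via ``--profile``.
    """
    from importlib.resources import files

    data = files("stachelhaus.data")
    return load_reference_profile(
        data / "reference_grsa_like.synthetic.fasta",
        data / "reference_grsa_like.synthetic.cfg",
    )
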