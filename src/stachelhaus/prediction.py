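"""Substrate prediction by nearest-catalogue-code matching, and the
end-to-end protein -> annotated-modules pipeline.

A query code is compared against every catalogue code; each substrate is
scored by the *best* identity over the codes annotated with it (each
catalogued code is an independent specificity witness, so one strong match
outweighs many weak ones). Predictions are ranked by identity, then by the
total occurrence count n behind the matched code (frequency as salience),
then by substrate name. Confidence tiers follow the recurring identity
strata of the underlying survey: exact (100), high (>= 80), moderate
(>= 70), low otherwise — heuristic labels, not probabilities.

Modification tags are reported associatively: the tags carried by the
matched catalogue annotation are surfaced as-is. The only sequence-derived
modification evidence is the A8–A9 elongation flag; beta-hydroxylated and
similar in-trans variants are indistinguishable from their parent moieties
at the signature level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalogue import Catalogue
from .model import SignatureCode, is_promiscuous
from .reference import (
    AlignmentParams,
    DEFAULT_ELONGATION_THRESHOLD,
    DEFAULT_MIN_SCORE_FRACTION,
    ReferenceProfile,
    scan_protein,
)
from .similarity import code_identity

__all__ = [
    "Prediction",
    "ModuleReport",
    "PipelineConfig",
    "confidence_tier",
    "predict_substrate",
    "annotate_protein",
]


def confidence_tier(identity: int) -> str:
    """Map identity to a confidence label: exact / high / moderate / low."""
    if identity >= 100:
        return "exact"
    if identity >= 80:
        return "high"
    if identity >= 70:
        return "moderate"
    return "low"


@dataclass(frozen=True)
class Prediction:
    """One ranked substrate call for a query code."""

    substrate: str
    identity: int
    supporting_code: SignatureCode
    n_support: int
    modifications: frozenset = frozenset()
    tier: str = "low"


@dataclass(frozen=True)
class ModuleReport:
    """Everything the pipeline knows about one located module."""

    hit: object  # ADomainHit
    predictions: tuple
    flags: tuple


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the end-to-end annotation pipeline."""

    params: AlignmentParams = AlignmentParams()
    min_score_fraction: float = DEFAULT_MIN_SCORE_FRACTION
    elongation_threshold: int = DEFAULT_ELONGATION_THRESHOLD
    min_identity: int = 60
    top_k: int = 3


def predict_substrate(code, cat: Catalogue, min_identity: int = 0,
                      top_k: int | None = None) -> list:
    """Rank candidate substrates for a query code.

    Per substrate, the best identity over that substrate's catalogue codes
    is kept (ties resolved toward higher supporting n, then the smaller
    code). Substrates below ``min_identity`` are dropped and at most
    ``top_k`` predictions are returned. An exact match to a promiscuous code
    yields all of its substrates at identity 100. An empty catalogue yields
    an empty list.
    """
    code = SignatureCode(code)
    if not 0 <= min_identity <= 100:
        raise ValueError("min_identity must be in [0, 100]")
    best: dict = {}
    for cat_code, ann in cat.rows():
        ident = code_identity(code, cat_code)
        n_support = sum(a.n for a in cat.entries[cat_code].annotations
                        if a.substrate == ann.substrate)
        cand = (ident, n_support, cat_code, ann.modifications)
        cur = best.get(ann.substrate)
        if cur is None or (-cand[0], -cand[1], cand[2]) < (-cur[0], -cur[1], cur[2]):
            best[ann.substrate] = cand
    preds = [
        Prediction(substrate=s, identity=ident, supporting_code=sc,
                   n_support=n, modifications=mods,
                   tier=confidence_tier(ident))
        for s, (ident, n, sc, mods) in best.items()
        if ident >= min_identity
    ]
    preds.sort(key=lambda p: (-p.identity, -p.n_support, p.substrate))
    if top_k is not None:
        preds = preds[:top_k]
    return preds


def annotate_protein(record, profile: ReferenceProfile, cat: Catalogue,
                     config: PipelineConfig = PipelineConfig()) -> list:
    """Run the full pipeline on one protein record.

    ``record`` is anything with ``.id`` and ``.seq`` (a Biopython SeqRecord)
    or a plain (id, sequence) pair. Each located A domain is scanned,
    its code extracted, elongation measured, and substrates predicted;
    flags mark promiscuous matches, elongated domains, gapped codes and
    no-match modules.
    """
    if hasattr(record, "id") and hasattr(record, "seq"):
        protein_id, sequence = str(record.id), str(record.seq)
    else:
        protein_id, sequence = record

    hits = scan_protein(
        sequence, profile, config.params,
        min_score_fraction=config.min_score_fraction,
        elongation_threshold=config.elongation_threshold,
        protein_id=protein_id,
    )
    reports = []
    for hit in hits:
        preds = tuple(predict_substrate(hit.code, cat,
                                        min_identity=config.min_identity,
                                        top_k=config.top_k))
        flags = []
        if preds:
            top = preds[0]
            entry = cat.get(top.supporting_code)
            if entry is not None and is_promiscuous(entry):
                flags.append("promiscuous-match")
        else:
            flags.append("no-match")
        if hit.elongation_flag:
            flags.append("elongated-domain")
        if hit.gap_positions:
            flags.append("gap-in-code")
        reports.append(ModuleReport(hit=hit, predictions=preds,
                                    flags=tuple(flags)))
    return reports
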