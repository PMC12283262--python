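"""Loading, validating and summarising the specificity-code catalogue.

A catalogue maps each signature code to the substrate moieties it has been
observed to activate, with modification tags, per-(code, substrate)
occurrence counts n, source species and an iterative-use flag. The packaged
``catalogue_paper.tsv`` holds the codes transcribed from a published survey
of 2051 bacterial A domains; it is a partial transcription (codes quoted in
the running text, not the full supplementary dataset), which its
``complete: false`` header records, so survey-level totals are only asserted
against a catalogue flagged complete.

File formats: UTF-8 TSV with a header line and optional ``# key: value``
metadata lines, or an equivalent JSON document. Rows with the same code are
merged into one entry on load; rows with identical (code, substrate,
modifications) have their counts summed.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

from .model import (
    CatalogueEntry,
    SignatureCode,
    StachelhausError,
    SubstrateAnnotation,
    canonical_check,
    is_promiscuous,
    validate_modification,
    validate_substrate,
)

__all__ = [
    "Catalogue",
    "CatalogueStats",
    "CatalogueFormatError",
    "load_catalogue",
    "save_catalogue",
    "catalogue_stats",
    "filter_catalogue",
    "paper_catalogue",
]

logger = logging.getLogger(__name__)

_COLUMNS = ("code", "substrate", "modifications", "n", "species",
            "iterative", "source")


class CatalogueFormatError(StachelhausError, ValueError):
    """A catalogue file is malformed."""


@dataclass
class Catalogue:
    """An in-memory catalogue: one entry per unique code."""

    entries: dict = field(default_factory=dict)  # SignatureCode -> CatalogueEntry
    complete: bool = False
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.codes())

    def codes(self) -> list:
        return sorted(self.entries)

    def get(self, code) -> CatalogueEntry | None:
        return self.entries.get(SignatureCode(code))

    def add(self, code, annotation: SubstrateAnnotation) -> None:
        """Add one annotation, merging by code and by
        (substrate, modifications) key (counts are summed)."""
        code = SignatureCode(code)
        entry = self.entries.get(code)
        if entry is None:
            self.entries[code] = CatalogueEntry(code, [annotation])
            return
        for i, existing in enumerate(entry.annotations):
            if existing.key == annotation.key:
                merged = SubstrateAnnotation(
                    substrate=existing.substrate,
                    modifications=existing.modifications,
                    n=existing.n + annotation.n,
                    species=tuple(dict.fromkeys(existing.species + annotation.species)),
                    iterative=existing.iterative or annotation.iterative,
                    source=existing.source or annotation.source,
                )
                entry.annotations[i] = merged
                return
        entry.annotations.append(annotation)

    def rows(self) -> list:
        """Flat, deterministically ordered (code, annotation) rows."""
        out = []
        for code in self.codes():
            anns = sorted(self.entries[code].annotations,
                          key=lambda a: (a.substrate, sorted(a.modifications)))
            out.extend((code, a) for a in anns)
        return out


def _parse_row(row: dict, lineno: int, strict: bool) -> tuple:
    try:
        code = SignatureCode(row["code"].strip())
    except (KeyError, ValueError) as exc:
        raise CatalogueFormatError(f"line {lineno}: bad code: {exc}") from exc
    substrate = row.get("substrate", "").strip()
    if not substrate:
        raise CatalogueFormatError(f"line {lineno}: missing substrate")
    try:
        validate_substrate(substrate)
    except StachelhausError:
        if strict:
            raise
        logger.warning("line %d: substrate %r outside the controlled vocabulary",
                       lineno, substrate)
    mods = frozenset(
        m.strip() for m in row.get("modifications", "").split(";") if m.strip()
    )
    for m in mods:
        try:
            validate_modification(m)
        except StachelhausError:
            if strict:
                raise
            logger.warning("line %d: modification %r outside the controlled "
                           "vocabulary", lineno, m)
    try:
        n = int(row.get("n", "1") or 1)
    except ValueError as exc:
        raise CatalogueFormatError(f"line {lineno}: bad count n: {exc}") from exc
    species = tuple(s.strip() for s in row.get("species", "").split(";") if s.strip())
    iterative = row.get("iterative", "false").strip().lower() in ("true", "1", "yes")
    source = row.get("source", "").strip()
    try:
        ann = SubstrateAnnotation(substrate=substrate, modifications=mods, n=n,
                                  species=species, iterative=iterative,
                                  source=source)
    except ValueError as exc:
        raise CatalogueFormatError(f"line {lineno}: {exc}") from exc
    return code, ann


def load_catalogue(path, strict: bool = False) -> Catalogue:
    """Load a catalogue from TSV or JSON (decided by file extension).

    Rows sharing a code merge into one entry. Codes violating the
    Asp235/Lys517 conservation are logged as warnings. In strict mode, a
    substrate or modification outside the controlled vocabulary aborts the
    load; otherwise it is kept with a warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _load_json(path, strict)
    return _load_tsv(path, strict)


def _finish(cat: Catalogue) -> Catalogue:
    for code in cat.codes():
        for w in canonical_check(code):
            logger.warning("code %s: %s", code, w)
    return cat


def _load_tsv(path: Path, strict: bool) -> Catalogue:
    cat = Catalogue(provenance=str(path))
    with open(path, encoding="utf-8") as fh:
        meta = {}
        pos = fh.tell()
        header_offset = 0
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            header_offset += 1
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return cat  # empty file
        missing = {"code", "substrate"} - set(reader.fieldnames)
        if missing:
            raise CatalogueFormatError(
                f"{path}: missing required columns {sorted(missing)}"
            )
        for i, row in enumerate(reader):
            lineno = header_offset + i + 2
            if row.get("code") is None or all(
                    (v or "").strip() == "" for v in row.values()):
                continue
            code, ann = _parse_row(row, lineno, strict)
            cat.add(code, ann)
    cat.complete = meta.get("complete", "false").lower() == "true"
    return _finish(cat)


def _load_json(path: Path, strict: bool) -> Catalogue:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    cat = Catalogue(provenance=str(path), complete=bool(doc.get("complete", False)))
    for i, row in enumerate(doc.get("rows", [])):
        row = {k: (";".join(v) if isinstance(v, list) else
                   (str(v).lower() if isinstance(v, bool) else str(v)))
               for k, v in row.items()}
        code, ann = _parse_row(row, i + 1, strict)
        cat.add(code, ann)
    return _finish(cat)


def save_catalogue(cat: Catalogue, path) -> None:
    """Write a catalogue to TSV or JSON (by extension), deterministically
    ordered so that load→save→load is a fixed point."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {"complete": cat.complete, "rows": []}
        for code, a in cat.rows():
            doc["rows"].append({
                "code": str(code), "substrate": a.substrate,
                "modifications": sorted(a.modifications), "n": a.n,
                "species": list(a.species), "iterative": a.iterative,
                "source": a.source,
            })
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
        return
    buf = io.StringIO()
    buf.write(f"# complete: {str(cat.complete).lower()}\n")
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(_COLUMNS)
    for code, a in cat.rows():
        writer.writerow([
            str(code), a.substrate, ";".join(sorted(a.modifications)),
            a.n, ";".join(a.species), str(a.iterative).lower(), a.source,
        ])
    path.write_text(buf.getvalue(), encoding="utf-8")


@dataclass(frozen=True)
class CatalogueStats:
    """Summary statistics of a catalogue.

    ``specific_fraction`` is the percentage of codes with exactly one
    substrate (None for an empty catalogue); ``code_substrate_pairs`` is the
    alternative tally where each (code, substrate) pair counts once;
    ``iterative_modules`` sums occurrence counts over iterative annotations.
    """

    total_codes: int
    promiscuous_codes: int
    specific_fraction: float | None
    per_substrate_counts: dict
    total_domain_occurrences: int
    iterative_modules: int
    code_substrate_pairs: int
    complete: bool

    @property
    def specific_fraction_exact(self) -> Fraction | None:
        if self.total_codes == 0:
            return None
        return Fraction(
            100 * (self.total_codes - self.promiscuous_codes), self.total_codes
        )


def catalogue_stats(cat: Catalogue) -> CatalogueStats:
    """Compute headline statistics: code and promiscuity counts, the
    single-specificity percentage, per-substrate code tallies, total domain
    occurrences (sum of n) and iterative-module occurrences."""
    total = len(cat.entries)
    prom = sum(1 for e in cat.entries.values() if is_promiscuous(e))
    per_substrate: dict = {}
    pairs = 0
    occurrences = 0
    iterative = 0
    for entry in cat.entries.values():
        for s in sorted(entry.substrates()):
            per_substrate[s] = per_substrate.get(s, 0) + 1
            pairs += 1
        for a in entry.annotations:
            occurrences += a.n
            if a.iterative:
                iterative += a.n
    fraction = None
    if total > 0:
        fraction = float(Fraction(100 * (total - prom), total))
    return CatalogueStats(
        total_codes=total,
        promiscuous_codes=prom,
        specific_fraction=fraction,
        per_substrate_counts=dict(sorted(per_substrate.items())),
        total_domain_occurrences=occurrences,
        iterative_modules=iterative,
        code_substrate_pairs=pairs,
        complete=cat.complete,
    )


def filter_catalogue(cat: Catalogue, substrate: str | None = None,
                     modification: str | None = None,
                     species: str | None = None,
                     predicate=None) -> Catalogue:
    """Subset a catalogue.

    Filtering by substrate/modification/species keeps only matching
    annotations (entries left with none are dropped); ``predicate`` is an
    arbitrary annotation filter applied on top.
    """
    out = Catalogue(complete=False, provenance=f"filtered({cat.provenance})")
    for code, ann in cat.rows():
        if substrate is not None and ann.substrate != substrate:
            continue
        if modification is not None and modification not in ann.modifications:
            continue
        if species is not None and species not in ann.species:
            continue
        if predicate is not None and not predicate(ann):
            continue
        out.add(code, ann)
    if substrate is None and modification is None and species is None \
            and predicate is None:
        out.complete = cat.complete
    return out


def paper_catalogue() -> Catalogue:
    """The packaged catalogue of published signature codes.

    A partial transcription (the codes quoted in the survey's running text);
    its ``complete`` flag is False, so survey-level totals are not asserted
    against it.
    """
    from importlib.resources import files

    return load_catalogue(files("stachelhaus.data") / "catalogue_paper.tsv")
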