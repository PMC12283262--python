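"""Percent-identity comparison and clustering of specificity codes.

Identity between two 10-residue codes is exact positional identity: the
percentage of the ten slots carrying the same residue, so values are always
multiples of 10 and ``100 - identity`` is ten times the Hamming distance.
An 'X' (unresolved slot) matches nothing, including another 'X'.

Clustering at a threshold t groups codes whose identity chains reach t:
single linkage (the default) places two codes in one cluster iff they are
connected by a chain of pairs each >= t; complete linkage requires every
within-cluster pair to reach t and is built agglomeratively with
deterministic, lexicographic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CODE_LENGTH, GRSA_POSITIONS, SignatureCode

__all__ = [
    "code_identity",
    "IdentityMatrix",
    "pairwise_matrix",
    "ClusterSet",
    "cluster_at",
    "neighbors_above",
    "ConservationProfile",
    "conservation_profile",
    "shared_codes",
]


def code_identity(a, b) -> int:
    """Percent identity between two codes: 10 x (number of matching slots).

    'X' never matches. Raises for codes that are not exactly 10 residues.
    """
    a, b = SignatureCode(a), SignatureCode(b)
    matches = sum(
        1 for x, y in zip(a, b) if x == y and x != "X"
    )
    return 100 * matches // CODE_LENGTH


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric percent-identity matrix over an ordered code list."""

    codes: tuple
    values: np.ndarray

    def to_tsv(self) -> str:
        lines = ["code\t" + "\t".join(self.codes)]
        for code, row in zip(self.codes, self.values):
            lines.append(code + "\t" + "\t".join(str(int(v)) for v in row))
        return "\n".join(lines) + "\n"


def pairwise_matrix(codes) -> IdentityMatrix:
    """All-pairs identity matrix (symmetric, diagonal 100 for X-free codes)."""
    codes = tuple(SignatureCode(c) for c in codes)
    n = len(codes)
    values = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i, n):
            v = code_identity(codes[i], codes[j])
            values[i, j] = values[j, i] = v
    return IdentityMatrix(codes=codes, values=values)


@dataclass(frozen=True)
class ClusterSet:
    """A partition of codes at an identity threshold."""

    threshold: int
    linkage: str
    clusters: tuple  # tuple of tuples of codes, each sorted; clusters ordered
                     # by their lexicographically smallest member

    def __len__(self) -> int:
        return len(self.clusters)

    def cluster_of(self, code) -> tuple:
        code = SignatureCode(code)
        for c in self.clusters:
            if code in c:
                return c
        raise KeyError(code)


def _dedupe(codes):
    return list(dict.fromkeys(SignatureCode(c) for c in codes))


def _single_linkage(codes, threshold):
    parent = list(range(len(codes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            if code_identity(codes[i], codes[j]) >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict = {}
    for i in range(len(codes)):
        groups.setdefault(find(i), []).append(codes[i])
    return list(groups.values())


def _complete_linkage(codes, threshold):
    # Agglomerative: repeatedly merge the pair of clusters whose complete-
    # linkage distance (minimum pairwise identity) still meets the threshold,
    # preferring the highest identity and then the lexicographically smallest
    # pair of cluster representatives.
    clusters = [frozenset([c]) for c in codes]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                ident = min(code_identity(a, b)
                            for a in clusters[i] for b in clusters[j])
                if ident < threshold:
                    continue
                key = (-ident, min(clusters[i]), min(clusters[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return [sorted(c) for c in clusters]


def cluster_at(codes, threshold: int, linkage: str = "single") -> ClusterSet:
    """Partition codes at an inclusive identity threshold (>= threshold)."""
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must be in [0, 100]")
    if linkage not in ("single", "complete"):
        raise ValueError("linkage must be 'single' or 'complete'")
    codes = _dedupe(codes)
    raw = (_single_linkage(codes, threshold) if linkage == "single"
           else _complete_linkage(codes, threshold))
    clusters = tuple(sorted((tuple(sorted(c)) for c in raw),
                            key=lambda c: c[0]))
    return ClusterSet(threshold=threshold, linkage=linkage, clusters=clusters)


def neighbors_above(query, codes, threshold: int) -> list:
    """Catalogue codes with identity >= threshold to the query, sorted by
    identity (descending), then lexicographically."""
    query = SignatureCode(query)
    hits = [(SignatureCode(c), code_identity(query, c)) for c in codes]
    hits = [(c, v) for c, v in hits if v >= threshold]
    return sorted(hits, key=lambda cv: (-cv[1], cv[0]))


@dataclass(frozen=True)
class ConservationProfile:
    """Per-slot residue tallies over a code set.

    ``counts`` holds, per slot, residue -> count ('X' excluded, tallied in
    ``missing``); ``modal`` is the most frequent residue per slot (ties
    broken lexicographically and recorded in ``ties``). Slots are labelled
    with the GrsA position numbers.
    """

    positions: tuple
    counts: tuple          # tuple of dicts, one per slot
    modal: tuple
    ties: tuple            # per slot: tuple of residues sharing the maximum
    missing: tuple         # per slot: number of 'X' observations
    n_codes: int

    @property
    def consensus(self) -> SignatureCode:
        return SignatureCode("".join(self.modal))

    def frequencies(self, slot: int) -> dict:
        total = sum(self.counts[slot].values())
        return {aa: c / total for aa, c in self.counts[slot].items()}

    def to_tsv(self) -> str:
        lines = ["position\tresidue\tcount\tfrequency"]
        for slot, pos in enumerate(self.positions):
            total = sum(self.counts[slot].values())
            for aa, c in sorted(self.counts[slot].items(),
                                key=lambda kv: (-kv[1], kv[0])):
                lines.append(f"{pos}\t{aa}\t{c}\t{100 * c / total:.1f}")
        return "\n".join(lines) + "\n"


def conservation_profile(codes) -> ConservationProfile:
    """Residue-frequency table and consensus over a non-empty code list."""
    codes = [SignatureCode(c) for c in codes]
    if not codes:
        raise ValueError("conservation profile requires at least one code")
    counts, modal, ties, missing = [], [], [], []
    for slot in range(CODE_LENGTH):
        tally: dict = {}
        miss = 0
        for code in codes:
            aa = code[slot]
            if aa == "X":
                miss += 1
            else:
                tally[aa] = tally.get(aa, 0) + 1
        if tally:
            top = max(tally.values())
            tied = tuple(sorted(aa for aa, c in tally.items() if c == top))
        else:
            tied = ("X",)
        counts.append(dict(sorted(tally.items())))
        modal.append(tied[0])
        ties.append(tied if len(tied) > 1 else ())
        missing.append(miss)
    return ConservationProfile(
        positions=GRSA_POSITIONS, counts=tuple(counts), modal=tuple(modal),
        ties=tuple(ties), missing=tuple(missing), n_codes=len(codes),
    )


def shared_codes(cat) -> dict:
    """Codes associated with two or more distinct substrates, mapped to their
    substrate sets; deterministically ordered by code."""
    out = {}
    for code in cat.codes():
        subs = cat.entries[code].substrates()
        if len(subs) >= 2:
            out[code] = subs
    return out
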