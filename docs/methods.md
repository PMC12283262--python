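# Methods

## The model

An NRPS adenylation domain's substrate choice is summarised by ten binding
pocket residues read in GrsA phenylalanine-activating-domain numbering:
positions 235, 236, 239, 278, 299, 301, 322, 330, 331 and 517 of the
530-residue reference. The package treats this 10-mer (the specificity code)
as the unit of analysis throughout. Two empirical anchors — Asp235 and
Lys517 — hold across amino-acid-activating domains; the package checks them
as warnings, never errors, because the conservation is observational.

Everything downstream rests on three operations:

1. **Positional extraction.** A query is aligned to the reference and the
   query residues in the ten signature columns are the code. The alignment
   is Needleman–Wunsch with affine gaps; a signature column aligned to a
   query gap yields `'X'` (degenerate or dormant domains stay reportable),
   while signature columns falling outside the query's aligned span raise an
   extraction error naming the uncovered positions.
2. **Positional identity.** "Identity", "similarity" and "homology" between
   codes are all implemented as exact positional identity on the 10-mers
   (matches × 10 percent). Every checkable published percentage is
   reproduced by this definition and not by substitution-matrix similarity,
   which is therefore available only as alignment scoring, never as the
   code metric. `'X'` matches nothing, including another `'X'`; consequently
   identity is only a true (scaled Hamming) metric on X-free codes, and
   clustering of gapped codes should be interpreted with care.
3. **Elongation measurement.** Tailoring units embedded between the A8 and
   A9 core motifs lengthen the domain. Insertion length is the number of
   query residues aligned to reference gaps inside the profile's A8–A9
   interval; the domain is flagged elongated when that length reaches a
   threshold.

## Parameters, defaults and rationale

| parameter | default | why |
|---|---|---|
| substitution matrix | BLOSUM62 | standard protein default; the source survey names alignment tools but no scoring, so everything is configurable |
| gap open / extend | 11 / 1 | standard BLOSUM62 companion penalties; a gap of length L costs `open + (L−1)·extend` |
| `a8_a9_interval` | (340, 510), 1-based | must lie strictly between the 9th (331) and 10th (517) signature positions; exact A8/A9 motif boundaries are not recoverable from the source, so the interval is a profile property |
| elongation threshold | 50 residues | tailoring-unit insertions run to hundreds of residues (largest characterised: 342) while alignment noise stays in single digits; 50 separates the regimes |
| scan `min_score_fraction` | 0.4 | a planted domain at 10% divergence scores ≈ 0.85 of the reference self-score; random local matches score ≈ 0.02–0.05; 0.4 splits the gap with wide margins either side |
| prediction `min_identity` / `top_k` | 60 / 3 | below 60% a match carries no tier; three candidates cover the observed promiscuity (≤ 3 substrates per code) |
| confidence tiers | 100 / 80 / 70 | the identity strata that recur in published pairwise statements; heuristic labels, not calibrated probabilities |

Coordinates are 0-based half-open internally and in JSON/TSV machine
output; 1-based GrsA numbering is used for signature positions, profile
configs and human-readable labels.

## Domain scanning

`scan_protein` finds the best local (Smith–Waterman) hit of the reference
in the query, accepts it if its score reaches `min_score_fraction` of the
reference self-alignment score, and recurses on the flanking segments, so
hits are non-overlapping by construction. Each accepted region, padded by
30 residues, is re-aligned to the full reference with free terminal gaps
(semi-global) for code extraction and elongation measurement; the reported
hit span is the query interval actually aligned to reference residues.
Segments shorter than 50 residues are not searched.

## Prediction semantics

Each substrate is scored by the **maximum** identity over the catalogue
codes annotated with it — each catalogued code is an independent
specificity witness, so one exact witness beats many mediocre ones —
and predictions are ranked by identity, then total supporting occurrence
count *n*, then substrate name (a deterministic, admittedly arbitrary,
final tie-break). An exact match to a promiscuous code returns all of its
substrates tied at 100. Modification tags are surfaced associatively from
the matched annotation; apart from the elongation flag, no modification is
inferred from sequence — β-hydroxylated and similar in-trans variants are
indistinguishable from their parents at the signature level.

## Clustering

Single linkage (default) is computed as union-find over all pairs at
`identity ≥ threshold`, i.e. exactly the connected components of the
thresholded identity graph; thresholds are inclusive, matching the "≥ 70%",
"≥ 80%" usage in the literature. Complete linkage is a naive agglomerative
merge (highest-identity pair first, lexicographic tie-break on cluster
representatives); because identities are multiples of 10, ties are common
and complete-linkage partitions are only as canonical as that documented
tie-break. Cluster output is deterministic: members sorted, clusters
ordered by smallest member.

## The synthetic-data generator

The generator emulates the *geometry* of NRPS subunits: 530-residue
A-domain-like units carrying a planted code at the GrsA positions, optional
insertions placed at the midpoint of the A8–A9 interval (unambiguously
between the 9th and 10th signature positions), point mutations at a
controllable rate (uniform substitution to one of the 19 other residues,
optionally protecting the signature positions), inter-module linkers
(default 50 residues, long enough that hit counting is unambiguous), and
iterative module reuse by repetition. Backgrounds are i.i.d. residues —
uniform by default for transparency, with a Swiss-Prot-like preset — and
all modules of one assembly line share a single base scaffold, so they are
homologous as real modules are.

What it does **not** emulate: real A-domain sequence composition and the
conserved A1–A10 motif architecture, phylogenetic correlation between
modules, condensation/PCP/thioesterase domains (linkers are random, not
realistic inter-domain sequence), or insertion sequences with tailoring
homology. Passing recovery tests on this ground truth therefore
demonstrates that the alignment-extraction-prediction machinery is correct
and robust to the modelled perturbations; it does not by itself validate
scan thresholds against the full diversity of natural NRPS proteins.

All generators are deterministic given their seeds (byte-identical FASTA
and manifests), and manifests record exact module coordinates, planted
codes, substrates, insertion lengths and iterative flags.

## Numerical and degenerate-input choices

- Alignment traceback is deterministic (single optimal alignment requested
  from the aligner), so identical inputs give identical outputs.
- Known boundary behaviour of positional extraction: an insertion abutting
  a signature position can optimally capture that column when the planted
  residue mismatches the reference background, changing the extracted slot.
  The insertion-invariance property is therefore guaranteed only for
  insertions with some margin (tests use 15 residues) from the signature
  positions; the A8–A9 midpoint used for tailoring insertions is far from
  both flanking positions.
- Statistics use exact rational arithmetic before formatting, so
  `specific_fraction + 100·promiscuous/total = 100` holds exactly.
- Empty catalogue: statistics report counts of zero and an undefined
  (`None`) specific fraction; prediction returns an empty list, not an
  error.
- Catalogue rows sharing (code, substrate, modifications) merge by summing
  *n*; rows sharing only the code merge into one (possibly promiscuous)
  entry. Saved catalogues are deterministically ordered, making
  load→save→load a byte-level fixed point.

## The packaged catalogue and reference

The packaged catalogue is a **partial transcription**: the 53 codes (67
code–substrate rows) quoted in the running text of a published survey of
2051 bacterial A domains. Its `complete: false` header gates survey-level
totals (508 codes, 89 promiscuous, 2051 occurrences, 41 iterative modules),
which are asserted only against a catalogue flagged complete. Occurrence
counts are n=1 except where the text ties a count to a specific code
(DILQLGMIWK, n=4), and no transcribed row carries the iterative flag
because the text names no iterative code. Statistics reports always state
the transcribed entry count alongside.

The packaged reference profile is a synthetic GrsA-like stand-in (seeded
random 530-mer with the canonical Phe code DAWTIAAICK planted), labelled
synthetic in its filename and FASTA header. It exercises every code path
identically to a real profile, but real-protein annotation should use the
genuine GrsA phenylalanine-activating domain supplied by the user.

## Problem sizes used in tests and the acceptance script

Alignment-oracle agreement uses 25 random pairs of ≤ 40-residue sequences
against an exhaustive Gotoh dynamic program; clustering agreement uses 100
random 15-code sets at thresholds 70/80/90 against brute-force connected
components; planted-code and substrate recovery use 40 five-module assembly
lines (200 modules) at 5% background mutation with protected signatures;
elongation error rates use 50 unmodified and 50 insertion-342 modules.
These sizes give exact expectations (100% recovery, zero flag errors) at
negligible runtime; the generator scales to arbitrarily many modules.

## Known limitations

- Identity with `'X'` slots is not a metric; conservation profiles exclude
  `'X'` and record it as missing.
- The scanner assumes domains are separated by ≥ 50 residues of
  non-domain sequence; fused or heavily overlapping domains would merge.
- Complete-linkage partitions under identity ties depend on the documented
  tie-break.
- Substrate prediction inherits every bias of the catalogue: moieties with
  no transcribed code cannot be predicted, and promiscuity beyond the
  transcription is invisible.
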