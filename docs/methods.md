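# Methods

This note documents the models and procedures implemented in `varmine`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices made where the design was
genuinely open.

## Coordinates and conventions

All nucleotide and residue coordinates are 1-based with closed intervals
(`p260` is the 260th residue). Sequences are uppercased on ingestion;
nucleotide records may contain `N`, and any mutation call involving `N`
is classified "ambiguous" and excluded from silent/missense tallies and
alt-base preference spectra. Translation uses the standard genetic code
with the first codon translated literally (no bacterial start-codon
special-casing): every downstream comparison is reference-anchored, so a
GTG/TTG start would affect reference and variant identically.

## Mutation profiling

Same-length variant/reference pairs are compared position-by-position;
unequal lengths are first aligned globally and gap columns removed from
the comparable set. Identity percent is matches over comparable (both
non-gap) columns with terminal gap columns excluded — the most common
convention where none is specified — and is configurable in the sense
that the aligned strings are returned for any other denominator.

Codon effects are assigned in the reference frame: the reference codon is
translated with and without the single substituted base; equal residues →
silent, a stop gained → nonsense, otherwise missense. When an internal
gap run has a length not divisible by 3, the reading frame downstream is
no longer the reference frame, so every codon effect in that profile is
flagged "ambiguous" rather than guessed; such sequences are normally
removed upstream by the repository filters anyway. Two substitutions in
one codon are each classified independently against the reference codon
(the same rule the generator uses, so round trips are exact).

Per-line mutation densities use 60-nt lines (the FASTA wrap width); the
terminal line uses its true length as denominator. Region assignment
(active domain / envelope / other) is an interval lookup; the "envelope"
of an active domain is not a defined quantity in the source literature,
so it is constructed as ±30 nt flanks of each domain interval, with the
flank width a parameter.

## Repository filters

Members are removed, in order and recording the first matching rule,
when: identity to the reference is strictly above 99% or strictly below
75% (a member at exactly 99.0% or 75.0% is kept); an in-frame stop codon
occurs before the terminal codon; or the member duplicates an earlier
member at the nucleotide level or at the translated-protein level
(translation up to the first stop, because downstream analysis is
protein-level). The reference is never removed. Filtering is idempotent.
Whether duplicate removal preceded or followed similarity filtering in
the original workflow is unstated; the order above is fixed and
documented.

## Hotspots and pattern motifs

Hotspots are keyed by (position, alt base) and require support from at
least `min_share` sequences, default 4 (inclusive). Pattern motifs
require support from at least `min_support` sequences, default 5 (a
strict "more than four"). The two defaults differ deliberately because
the two rules are stated differently in the source method. Both are
CLI-configurable, and lowering either threshold never removes a
previously reported item.

Motif enumeration is per sequence and greedy left-to-right: mutated
positions join the current group while the gap to the previous position
is ≤ `max_gap` (default 4 nt) and the group's span stays ≤ `max_span`
(default 10 nt, bounding enumeration at the scale of the longest quoted
motifs); groups of ≥ 2 positions are canonicalised to (offsets from the
first position, alt bases). Motif identity deliberately excludes the
reference context: motifs are described by their substituted bases and
spacing. Two support counters are reported — sequences carrying the motif
anywhere, and the maximum number of sequences sharing it at one identical
reference start — because "shared location" support is recoverable under
either reading. Reports are sorted by support descending, then leftmost
position ascending.

## Global alignment

Needleman–Wunsch with a symmetric substitution matrix. The default
nucleotide scheme is match +1 / mismatch −3 — mirroring the
match/mismatch ratio the source search strategy used — with a linear gap
penalty of −2; the actual custom matrix values used in the original
workflow were never published, so these defaults are a declared stand-in
and any matrix can be supplied as a whitespace-delimited table with
header symbols. An affine model (Gotoh three-state recursion, gap of
length L costing `open + (L−1)·extend`, including transitions between
the two gap states) is available when the two penalties differ.
Traceback ties are broken deterministically: diagonal over up (gap in the
second sequence) over left. Scores are verified in the test suite against
exhaustive enumeration of all global alignments (lengths ≤ 6) and against
an independent aligner implementation.

## Protein-level analysis

Substitutions between equal-length reference and variant proteins are
annotated with: the structural element at that position (precedence
helix/sheet > turn > loop > primary — an artifact decision, since
overlapping annotations have no canonical priority), the active domain,
the Kyte–Doolittle hydropathy delta, the formal charge delta at pH 7
(D/E −1, K/R +1, H 0 by default and configurable — histidine's
protonation state near neutral pH is genuinely ambiguous), and the
polarity class pair (nonpolar / polar / acidic / basic).

The packaged RhlB annotation and binding-site tables transcribe residue
sets stated in the source material (e.g., lipid-substrate loop contacts
228/229/231/233 plus 330; sugar-donor contacts 9, 10, 13, 231, 259, 260,
306, 309, 324, 325, 346, 347; ATP contacts shared with the sugar donor
10, 13, 260, 306, 346, 347). Active-domain boundaries are shown there
only graphically, so the fixture's domain intervals are approximate and
explicitly user-editable. Product-ligand sites are carried as annotation
only and never trigger exclusion, since product binding was excluded as a
selection parameter.

### Proximity codes

For each substitution and ligand class, the distance *d* to the nearest
site residue maps to a heatmap code: −1 at *d* = 0 (and exclusion of the
sequence as potentially dysfunctional when the site is a substrate site),
−(d+1) for 1 ≤ d ≤ window, else 0. The −(d+1) mapping makes the code
span −2…−4 over the 3-residue energy-nucleotide window, matching the
published heatmap legend. The substrate window defaults to 5 residues
(the Methods-level definition) rather than 3 (a Results-level phrase);
both the substrate and nucleotide windows are parameters and are recorded
in the penalty-matrix metadata.

### Candidate ranking

Deterministic sort: non-excluded first, then count of
adjacent-to-binding-site substitutions (descending), hotspot overlap
(descending), identity (ascending — more divergent but intact sequences
widen the next search cycle), with a stable id tie-break. Each candidate
also carries its majority mutation-region group (active domain /
envelope / other).

### Charge patterning (FCR, NCPR, κ)

κ follows the blob-deviation construction: σ = NCPR²/FCR (0 where a blob
has no charges) over sliding blobs of g ∈ {5, 6}; δ_g is the mean squared
deviation of blob σ from the whole-sequence σ; κ averages δ_g/δ_max,g
over the two blob sizes. δ_max is the δ of the most segregated
arrangement of the same composition. A single "all negatives, all
neutrals, all positives" arrangement is the textbook choice but is *not*
an upper bound: blobs truncated at the sequence ends under-cover
edge-anchored charge blocks, and for compositions with few, same-sign
charges a dispersed placement can exceed every block arrangement. δ_max
is therefore taken as the maximum δ over (a) a family of block
arrangements with the neutral residues split before/between/after the
two charge blocks — exhaustively for ≤ 24 neutrals, on a 9-point
fraction grid otherwise — and (b) the observed arrangement itself. This
keeps κ = 1 exactly for fully segregated sequences, κ ≈ 0 for well-mixed
ones, and guarantees κ ∈ [0, 1] for every input. Sequences with no
charged residues (or degenerate δ_max = 0, e.g. uniformly charged) report
κ = 0 with a flag rather than an error. The implementation is
cross-checked in the tests against an independent loop-level
transcription of the same definition; blob sizes, and the histidine
charge, are parameters.

## Assay quantification

The standard curve is ordinary least squares absorbance = S·c + b over
≥ 3 distinct concentrations. σ in LOD = 3.3·σ/S is the regression
residual standard deviation (n−2 denominator) by default — the source
defines σ only as "standard deviation of the response" — with a
blank-replicate σ accepted as an override (the bundled examples use
σ = 0.0024, which with S = 0.0009 gives the 8.8 µg/mL detection limit).
MAPE is the mean absolute percentage error of back-predicted standards.
Quantification inverts the curve, censors below the LOD, and flags
concentrations above the calibrated range as extrapolated but still
returns them. Fold changes take an explicit decimals/rounding-mode pair
(`round` or `truncate`) because published fold changes mix both
conventions. Contact angles use θ = 2·arctan(H/R) in degrees.

## Synthetic data generator

The generator emulates the study conditions of the worked rhlB case and
is the package's test substrate: a 1,281-nt reference CDS (ATG start,
single terminal stop, no internal stops, GC within 0.5 points of the
67.9% target), 20 independent variants per repository at 95–99.2%
identity, ~75% silent substitutions, and an alt-base spectrum of
5% A / 35% C / 35% G / 25% T (G/C-dominant with A rarest). Identity is
targeted by mutation count (identity = 1 − n_mut/length), not rejection
sampling. Silent mutations are synonymous single-base codon edits,
missense non-synonymous non-stop edits, at most one mutation per codon,
never in the start or stop codon; premature stops are introduced only via
an explicit injection flag used to test the filters. Motif templates are
planted at one shared position across their carrying variants, with a
5-nt exclusion buffer so that random background mutations cannot merge
into (or split) a planted group during mining. Every emitted mutation is
recorded in a truth table whose effect labels are computed by the same
single-base-in-reference-codon rule the profiler uses, making round
trips exact.

What the generator does **not** emulate: phylogenetic correlation between
variants (each is an independent draw from the reference — no
tree-structured evolution, no shared ancestral mutations except planted
motifs), insertions/deletions, sequencing error, or context-dependent
mutational signatures. Green round-trip tests therefore demonstrate
bookkeeping correctness of the profiler/miner on the assumed statistical
structure, not robustness to real-repository artifacts such as
misannotated CDS boundaries or indel-rich alignments.

## Pipeline orchestration

A mining cycle runs cleanse → profile → hotspot/pattern mining →
protein-level scoring (when annotations and binding sites are supplied) →
candidate ranking, writes every artifact (FASTA, TSV/CSV reports, penalty
matrix, parameter log, manifest) and carries the top `depth` candidates
forward; the default four-cycle schedule is 25, 25, 40, 25. New-sequence
acquisition is an injectable source interface; the bundled source draws
from the synthetic generator with a cycle-derived seed, replacing the
original workflow's per-cycle external homology search (250 hits per
cycle, kept as the default draw) with the same control flow and no
network dependency. All stage parameters are logged to `params.json`
because hyperparameter provenance is otherwise unrecoverable from the
outputs. Two runs with the same seed and configuration produce
byte-identical reports; the determinism and round-trip test sizes
(e.g., 60-sequence draws in the four-cycle determinism check) are the
package's chosen test problem sizes.

## Known limitations

- External homology searching, PSSM construction, docking, cavity
  detection, structure prediction and phylogenetics are out of scope;
  their outputs enter only as configuration data (binding-site and
  annotation tables).
- The real reference protein's κ (published as 0.17 for the 426-residue
  RhlB) cannot be recomputed without the actual sequence, which is not
  bundled; the κ machinery is instead validated by its invariants and an
  independent oracle.
- Identity for unequal-length pairs depends on the stand-in substitution
  matrix defaults; published identity percentages obtained with an
  unpublished matrix may differ at the margins.
- VCF emission is out of scope (positions are CDS-relative), as is any
  statistical enrichment testing of motifs.
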