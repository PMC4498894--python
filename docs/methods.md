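# Methods

## Fingerprint model

Family membership is decided purely by degenerate motif content. A pattern
is an ordered list of positions, each either a wildcard or a non-empty set
of allowed residues; syntax is uppercase residue letters, `x`, and
slash-separated bracket groups (`[A/G]`). The registry carries the five
motifs of the Class B literature: the Rossmann motif `GxGxx[G/A]`, the two
BVMO fingerprints `[A/G]GxWxxxx[F/Y]P[G/M]xxxD` and `FxGxxxHxxxW[P/D]`, the
Thr-refined variant `FxGxxxHTxxW[P/D]`, and the FMO motif
`FxGxxxHxxxY[K/R]`.

Decisions that the notation leaves open:

- **Coordinates** are 1-based inclusive on ungapped sequences; alignment
  columns are 1-based. Gapped input to the scanner is an error, never
  silently stripped.
- **Ambiguity codes** (B, Z, X, U, O) satisfy wildcard positions only; a
  constrained position never matches them. This is the conservative choice
  for curation: a sequence is only called a BVMO when the diagnostic
  residues are actually present.
- **Architecture witness**: when several hit quadruples satisfy
  rossmann < fp1 < fp2 < rossmann, the greedy left-to-right chain is
  reported. Because hits of one pattern all share its length, the earliest
  eligible hit also ends earliest, so greedy selection is exact and
  independent of input order.
- **Precedence**: BVMO evidence (two fingerprints) beats FMO evidence (one
  motif); a sequence with both is labelled BVMO with `ambiguous=True`.
- **Spacing** between motifs is not constrained (only order and
  non-overlap); the source literature gives no spacing rule.
- Curation uses the original second fingerprint by default; the Thr-refined
  variant is opt-in (`strict_thr`) because that residue is only partially
  conserved in divergent datasets.

The scanner compiles each pattern to a regular expression inside a
lookahead so overlapping occurrences are all reported; correctness is
checked against an exhaustive all-windows oracle that shares no code with
it.

## Local alignment and iterative mining

`local_align` is Smith–Waterman with affine gaps (Gotoh recursion), exact
and deterministic: among equal-scoring optima the alignment ending at the
smallest (row, column) is returned, and traceback prefers substitution,
then a gap in the second sequence, then in the first. Scoring defaults to
BLOSUM62 with open 11 / extend 1; a gap of length *g* costs
open + *g*·extend (the convention of the search tool this emulates). The
dynamic-programming fill is a numba-compiled kernel; scores are validated
against two independent routes — exhaustive enumeration of every local
alignment (tiny inputs) and Biopython's PairwiseAligner (longer pairs).

`pattern_anchored_search` mirrors pattern-anchored database search
semantics: the query must contain the anchor motif, targets lacking it are
excluded regardless of similarity, and a hit's alignment must cover one
motif occurrence in both sequences. If the single optimal alignment does
not cover the motif the target is dropped; suboptimal anchored alignments
are not enumerated (in practice the motif region is the conserved core and
is always covered).

`iterative_mine` runs the anchored search from the seeds, then uses each
newly recruited sequence as a plain local-alignment query until no round
adds a sequence. Growth is monotone and bounded by the database size, and
the result is independent of seed order. The default acceptance score
(120) was calibrated once on the synthetic surveys: unrelated background
pairs score below ~50 while same-survey homologs score in the hundreds, so
the threshold has wide margins on both sides. It is configuration, not a
claim about real databases.

## Alignment editing, identity, distances

- `trim_to_core` keeps the contiguous column range from the median (over
  rows with ≥ 2 Rossmann hits) of the first-anchor start columns to the
  median of the last-anchor end columns; low/high medians are used so the
  cut always sits on an observed vote. Rows without two hits are trimmed
  along but warned about; fewer than 50% voting rows is an error.
- `drop_gap_columns` removes columns whose gap fraction exceeds the
  threshold (default 0.0 — the strictest reading of "eliminate gaps") and
  is idempotent.
- Identity uses pairwise deletion: matches divided by shared non-gap
  columns. Computing over full alignment length instead is a documented
  alternative, not the default; for the gap-free synthetic alignments the
  two coincide.
- Distances: p = 1 − identity/100, optionally Poisson-corrected
  (−ln(1−p)); saturated pairs (p ≥ 1) are capped at 5.0 with a warning.

## Tree inference and monophyly

Neighbor joining follows the Saitou–Nei Q-criterion with ties broken by the
lowest index pair and negative branch-length estimates clamped to zero. On
additive matrices NJ provably recovers the generating topology; the tests
verify this on 100 random tree-induced matrices and check the three-taxon
closed form to 1e-12. Maximum-likelihood or Bayesian engines are not
implemented; their Newick output can be fed to the same rooting and
monophyly operations.

Bootstrap support resamples columns with replacement, rebuilds
distances + NJ, and annotates each internal edge of the point tree with the
percentage of replicates containing its split (internal-node labels in
Newick). Alignments with fewer than four rows have no internal splits and
yield no supports. The display threshold used in reports (45) is a filter,
not part of the computation.

Rooting places the root at the midpoint of the edge separating the outgroup
when one exists; otherwise the edge maximising (outgroup − non-outgroup)
leaves on its far side is used, with a warning.

Monophyly of a family is MRCA-exactness. For non-monophyletic families the
package distinguishes *paraphyletic* — every intruding leaf under the MRCA
belongs to a family that is itself monophyletic (complete nested clades,
the configuration where BVMO and NMO clades sit inside an FMO grade) — from
*polyphyletic* (anything else). This operational definition is a package
decision; an alternative (complement monophyly) exists in the literature
but is not implemented as the default verdict.

## Contamination screen

The screen reduces genomic-context analysis to taxonomy concordance:
labels (superkingdom of the best hit per flanking gene) are inputs, and a
contig is suspect when ≥ `min_flank` (default 2) labelled flanking genes
exist and the discordant fraction is ≥ `threshold` (default 0.8).
`unassigned` genes count on neither side. Both knobs are explicit
configuration — the original judgement they model was qualitative.
Verdicts depend only on the label multiset, never on gene order.

## Synthetic surveys

The generator emulates exactly the statistical structure the analysis
assumes: family-specific conserved fingerprints on a shared phylogeny.

- **Topology**: Yule-type random joins; every edge length i.i.d.
  exponential. In the default *nested* layout the tree is
  (ClassA, (FMO-a, (BVMO, (FMO-b, (NMO, FMO-c))))), which makes BVMO and
  NMO monophyletic and FMO paraphyletic by construction; a *separate*
  layout puts each family in its own clade.
- **Sequences**: one ancestral 250-residue sequence carries the two
  Rossmann motifs; each family clade root installs its fingerprints
  (modelling motif gain on the stem). Constrained motif positions
  substitute only within their allowed sets, so every leaf retains its
  architecture; wildcard positions — including the Thr of the refined
  second fingerprint, which is installed at the BVMO root but left
  unconstrained — erode freely, which is why the refined fingerprint is
  only partially conserved among the synthetic BVMOs (typically 60–90%).
- **Substitution**: site-independent Poisson-type process — along a branch
  of length b each site changes with probability 1 − exp(−rate·b) and
  draws a uniformly random different residue. No indels, so the true
  alignment is the site matrix; an optional gap-column injector exercises
  gap editing and pairwise-deletion identity. No empirical exchange matrix
  and no among-site rate variation beyond the motif constraints: distances
  computed downstream with the matching p/Poisson corrections make NJ
  recovery provable in the long-alignment limit.
- **Backgrounds** are i.i.d. sequences rejection-sampled until they contain
  no registered motif at all; family root sequences are rejection-sampled
  so no fingerprint occurs outside its planted window. Truth labels and
  motif classification therefore agree with probability 1 at the root, and
  to extremely high probability at the leaves (an accidental full
  fingerprint arising by drift has per-sequence probability ≪ 1e-3).
- **Defaults** (chosen once as a realistic desk-scale image of a deeply
  diverged superfamily, then frozen): 10/12/8 BVMO/FMO/NMO, 4 outgroup,
  16 background sequences; within-family edge mean 0.06
  substitutions/site, family stems 0.25, spine edges 0.12, outgroup stem
  0.5, rate 1.0, uniform residue frequencies. These produce pairwise
  identities spanning roughly 15–99%, i.e. the broad spread seen in real
  curated Class B datasets.

What passing synthetic tests does **not** show: robustness to indels and
alignment error (the true alignment is used), to compositional bias or
heterotachy (the process is homogeneous), or to the database-snapshot
idiosyncrasies of a live survey. Those remain the user's responsibility
when running in real mode.

## Problem sizes used in verification

Scanner–oracle agreement is measured on 1,000 random 200-residue sequences
× 5 patterns; aligner agreement on 40 small pairs (enumeration oracle —
the full cross-product of short sequences is combinatorially out of reach,
so a seeded sample is used) plus 100 pairs up to length 50 (independent
DP); NJ recovery on 100 additive matrices of 8–12 taxa; the end-to-end
check on 20 replicate surveys (~50 sequences each); bootstrap behaviour on
20 runs of a 12-taxon, 1,000-column alignment with a 4-leaf clade on a 0.4
stem. These sizes are the package's verification design and are shared by
the test suite and `scripts/acceptance.py`.

## Known limitations

- NMOs cannot be recognised from sequence (no published fingerprint);
  they require label tables.
- The NJ engine is the implemented inference method; ML/Bayesian results
  must be imported as Newick.
- PHI-style search checks motif coverage only on the single optimal local
  alignment per pair.
- E-value statistics are not computed; acceptance is by raw score
  threshold.
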