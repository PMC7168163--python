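# Methods

This note documents the models and numerical choices behind `mytikit`, what
the synthetic benchmarks emulate, and where the design was genuinely open.

## The precursor model

Mytilin precursors are treated as strictly tripartite: signal peptide (SP),
mature peptide, C-terminal extension, contiguous and in that order, with
1-based inclusive coordinates throughout. The C-tail may be absent
(truncated precursors). Mature peptides called by any automatic method must
fall in 30–45 aa; this sanity band brackets the observed 32–38 aa family
range with margin, and violations raise rather than truncate.

### Signal-peptide cleavage heuristic

No neural signal-peptide predictor is used. Candidate cleavage positions
(the last SP residue) are scanned over 15–30 and scored as

```
score(p) = #hydrophobic{A,I,L,V,F,M,W} in residues p-11..p-1
         + 2·[residue p in {A,G,S,C}]          (the -1 position)
         + 1·[residue p-2 in {A,G,S,V,C}]      (the -3 position)
```

The maximum wins; ties break toward position 20 (the typical mytilin SP
length), then toward the shorter peptide. A call requires score ≥ 5 —
roughly a third of a hydrophobic window plus one anchor — otherwise the
sequence is declared to have no plausible signal peptide. This reproduces
the von Heijne (-3,-1) small-residue rule plus h-region hydrophobicity
without a trained model; it is deliberately simple and is only claimed to
work on sequences with a genuine SP-like architecture.

### Mature/C-tail boundary

There is no ab initio C-tail caller. The boundary is always transferred
from a reference precursor of known segmentation through a global alignment
(BLOSUM62, gap open 11 / extend 1). Reference boundary columns that land in
query gaps snap to the nearest query residue *toward the mature region*
(rightward for the mature start, leftward for the mature end), so the
transferred mature interval never grows across a deletion. Alignments below
25 % identity are refused — boundary transfer across that divergence is
guesswork.

## Physicochemistry

Net charge uses the counting rule K,R = +1; D,E = −1; everything else
(including H, C, Y and the termini) 0. This is the unique simple rule
consistent with all 30 bundled reference values, which the test suite
checks exhaustively.

Isoelectric points titrate side chains D, E, C, Y, H, K, R plus free
termini with the EMBOSS pKa set (N-term 8.6, C-term 3.6, C 8.5, D 3.9,
E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1), exposed as a module constant so an
alternative set can be swapped in. The charge curve is strictly decreasing
in pH and the termini guarantee a sign change on [0, 14], so bisection is
run to a bracket of 1e−9 pH units; converging on |charge| alone is not
enough because the curve is nearly flat for peptides with few ionizable
groups. Sliding pI profiles are leading-edge indexed (window i covers
residues i..i+w−1, default w = 15); sequences shorter than the window yield
a single whole-sequence value.

## Cysteine arrays and disulfide topology

Classification is a backtracking search for the leftmost 8-cysteine subset
matching a spacing template, where a spacer position may itself be a
cysteine (several real peptides carry extra non-structural cysteines
inside the array):

* **canonical** — gaps (3, 3, 2–5, 11, 1, 0–2, 2) between consecutive
  structural cysteines. The flexible third and sixth gaps are required by
  real family members (C3–C4 spans 2–5 across the reference set; the CCC
  insertion widens C6–C7 bookkeeping).
* **alternative** — C1–C2 gap 2–8 (the loop can stretch to 7 aa), C2–C3
  gap 3, C3–C4 gap 2–5, a displaced C5 (C4–C5 gap 1–10, C5–C6 gap 1–15),
  and the terminal C6-x(0-2)-C7-x2-C8 block. This is an operational
  definition: the alternative array is described in the literature by
  example rather than formula, and these bounds cover every known case
  without admitting the decoy families.
* **noncanonical** — everything else. A sequence matching the canonical
  template minus its final cysteine gets an explicit `missing_c8` flag
  (one known *P. viridis* peptide is truncated this way) instead of an
  error.

Topology assignment pairs the structural eight as C1–C5, C2–C6, C3–C7,
C4–C8; extra cysteines are listed unpaired. The central residue of a CCC
triplet is never structural. For nine-cysteine *alternative* arrays whose
extra free cysteine also lies in the C4..C6 span, both C5 choices are
sterically defensible and both pairings are reported.

## Alignment

Pairwise global and local alignment delegate to Biopython's
`PairwiseAligner` with BLOSUM62 and the protein-BLAST gap model (a length-k
gap costs 11 + k). Traceback determinism is the library's first-alignment
order. Percent identity divides matches by *all* aligned columns, gap
columns included — the literature rarely states its denominator, so this
package picks the conservative one and says so.

The multiple aligner is classic progressive alignment: UPGMA guide tree
over pairwise global-alignment identity distances (ties broken by smallest
index pair), then profile–profile merging leaf-to-root with sum-of-pairs
column scores (residue-vs-gap inside a built profile scores −1; new gaps
pay the full affine cost; traceback prefers match over query-gap over
target-gap). No iterative refinement: at the scale of ≤ 60 short peptides
the progressive result is stable and deterministic for a fixed input order.

## Redundancy reduction

Pairwise distance is `1 − S(a,b)/min(S(a,a), S(b,b))` with S the
affine-gap global BLOSUM62 score, clipped to [0, 1]; normalizing by the
smaller self-score makes identical sequences 0 and keeps the measure
symmetric. Hobohm algorithm 2 then repeatedly deletes the vertex with the
most neighbours under the threshold (default 0.1, exposed as
`--redundancy-threshold`), breaking ties toward the lexicographically
greatest id for reproducibility; the retained set is hard-asserted to
contain no sub-threshold pair. Greedy, not optimal, by design.

## Profile HMM

Architecture: match/insert/delete states per node, begin/end treated as
match states of nodes 0 and M+1. Match columns are alignment columns with
gap fraction strictly below 0.5. Sequences get Henikoff position-based
weights. Match emissions are weighted counts plus background-proportional
pseudocounts of total strength 1; `X` spreads its weight over the
background; insert states emit the background itself (log-odds 0).
Transitions are weighted per-row path counts with Laplace smoothing of 1
split across the three destinations. All emission rows and outgoing
transition triplets are asserted to sum to 1 after building. The background
is the Robinson–Robinson amino-acid frequency set.

Scoring runs the standard global profile recursions in log2 space; the
reported bit score is log-odds against an i.i.d. background of the same
length, so forward ≥ Viterbi always. Note that Henikoff weighting damps
but does not nullify duplication: duplicating a *single* row does shift
weighted emissions slightly (doubling the entire alignment leaves them
exactly unchanged); the test suite asserts exactly these two properties.

Calibration fits a Gumbel to the Viterbi scores of `n_null` random
background sequences (lengths resampled from the training lengths):
λ from moment matching (π/(√6·sd)) and the location anchored at the
empirical null median (μ = median + ln ln 2 / λ) so the survival function
is exactly centred — a pure moment-matched μ leaves the median mapping to
P ≈ 0.42–0.48 because the true null is only approximately Gumbel.
E-values are `n_db · P(S ≥ s)` under the fitted curve; they are honest
near the decision region and approximate in the far tail, which is all the
screening use requires. Family screens should always be run pairwise
(`dual_screen`): a mytilin model alone will weakly attract the
structurally similar myticin family, and letting the better-fitting model
claim each hit removes those false positives.

## Transcript screen

Translated BLAST is replaced by exhaustive six-frame translation plus
Smith–Waterman. Complete ATG..stop ORFs of ≥ 60 codons are enumerated on
all six frames (reverse-strand ORFs reported in forward coordinates with
negative frame); nested same-frame ORFs collapse to the longest one. Each
ORF's best local score against the current seed list converts to an
e-value-like statistic `K·m·n·exp(−λS)` with fixed constants K = 0.041,
λ = 0.267 — Karlin–Altschul-shaped and approximately BLOSUM62-scaled, used
only as a monotone acceptance statistic (default threshold 1e−3).
Accepted ORFs must additionally pass the *mytilin gate*: a plausible
signal peptide and a canonical or alternative cysteine array in the
post-SP region. Gated hits join the seed list and the search repeats until
a pass adds nothing (hard cap 20 iterations, logged). The novelty filter
marks hits whose best global percent identity against every known peptide
is strictly below 95 %.

## Phylogeny

Distances over an MSA are p-distances on columns where neither row is
gapped, optionally Poisson-corrected (−ln(1−p)). Neighbor joining follows
Saitou–Nei with the Q criterion, deterministic tie-breaks by smallest id
pair, and negative branch lengths clamped to zero. NJ is exact on additive
matrices, which is the tested guarantee; on real data it is a fast
topology sketch, not a substitute for model-based inference — posterior
supports and rate-model selection are out of scope.

## Synthetic data: what it emulates and what it does not

The generator produces precursors with the family's statistical signature:
a hydrophobic-core SP with small residues at −3/−1 (the −3 anchor is V,
which is in the −3 small set but not the −1 set — a G there would create a
tied decoy cleavage site two positions upstream), mature regions built on
exact array templates (canonical (3,3,4,11,1,1,2); alternative
(2,3,4,4,8,1,2); CCC (3,3,4,11,1,0,0,2)) with cationic-weighted fillers
deterministically adjusted to an exact target net charge (+4..+10 by
default), and anionic C-tails (−8..−3). Decoy families use spacings whose
C2–C3 gap differs from 3, so no mytilin template can ever match them.
Back-translation uses a fixed most-frequent-codon table; 5′ UTRs are
scrubbed of ATG so no upstream ORF can engulf an embedded one; a
configurable fraction embeds on the reverse strand. Everything is driven
by one integer seed and is byte-identical across runs.

Family-structured cohorts (an ancestor plus members with 20 % of
non-structural positions remutated) are used wherever homology matters —
HMM training/held-out splits, segmentation transfer, guide trees — because
real training sets are families of paralogs, not independent draws from
the motif. Independent-draw cohorts exist too and are used where only the
array/charge statistics matter.

The **chained-divergence corpus** for the screen is an explicit
construction: seed → close homologs scramble the first half of the mature
filler positions into BLOSUM62-dissimilar residues (score ≤ −2 against
the original); close → remote scrambles the complementary half plus the
C-tail. Parent and child always share one intact contiguous block (local
e-values ~1e−20 or better) while seed and remote share none (floor
~1e−5 to 1e−9). The corpus ships with its own e-value threshold, 1e−12,
because that is the regime its divergence scale was built for; at the
pipeline's default 1e−3 even ~35 %-identity homologs are directly
detectable and iteration is unnecessary. The benchmark therefore
demonstrates the *mechanism* of iterative seeding, not the claim that the
default threshold needs it on easy corpora.

What passing these benchmarks does **not** show: robustness to assembly
errors, frameshifts, sequencing noise or realistic codon usage (not
modelled); discrimination against real myticins/defensins (the decoys are
templates, not real sequences); correctness of alignment-transferred
boundaries across deep divergence (the cohorts stay within ~80 %
identity); or agreement with production HMM/BLAST statistics (both the
e-value-like screen statistic and the Gumbel calibration are documented
approximations).

## Benchmark problem sizes

The shipped experiments use 30-sequence training and held-out sets with 60
decoys for HMM separation, 50 precursors for segmentation recovery, 100
random 20-vertex graphs for the reduction post-condition, 25 random 4–6
taxon trees for NJ recovery, 72 short pairs for the alignment oracle, and
a 17-transcript chained corpus for the screen; each completes in seconds
and the whole acceptance script in a few seconds on one CPU.

## Known limitations

* The cleavage heuristic has no notion of transmembrane segments and will
  happily call one hydrophobic helix an SP.
* `Mcal mytilin 6` (nine cysteines, widened C3–C4 loop) classifies
  canonical only because of the flexible gap bounds; genuinely novel
  spacings outside those bounds fall to `noncanonical` even if a
  structural biologist would call them mytilins.
* Nine-cysteine two-candidate C5 topologies are exercised only on
  synthetic mimics; the real K-isoform sequence is not bundled.
* The Hobohm-2 reduced-set size for the real family is not reproducible
  here because the historical input set includes sequences not in the
  bundled table.
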