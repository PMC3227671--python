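# Methods

## Model and procedure

An ultramicro inversion is an inverted segment short enough (5–125 bp) that a
local aligner absorbs it into one alignment rather than breaking it into
separate strand-discordant blocks. Inside the alignment it leaves only an
unusually dense patch of mismatches and gaps, so detection proceeds in two
stages: a *statistical* stage that flags difference-dense windows, and an
*alignment* stage that asks whether each window is better explained by an
inversion than by independent substitutions and indels.

### Null model for difference density

Each alignment column independently carries a difference event (a mismatch
column, or the first column of a maximal one-row gap block) with probability
`p_d`; gap blocks alone occur with probability `p_g`. Given a first event, the
probability that the next two events fall within the following `n−1` columns is

    P_trio(n) = 1 − (1−p_d)^(n−1) − (n−1)·p_d·(1−p_d)^(n−2),

the complement of seeing zero or one event in `n−1` Bernoulli trials; likewise
`P_duo(n) = 1 − (1−p_g)^(n−1)` for a second gap block. Spatial autocorrelation
of real substitutions is deliberately not modelled: the i.i.d. null is what
makes a clustered signature significant. Windows with `P < alpha` (default
0.05) are single-linkage merged per kind and padded by `extension` (default 50)
columns. `n` is measured in alignment columns, first event start to last event
end inclusive — columns are the only well-defined site unit once gaps exist.
Trio compositions are exactly {3 mismatches; 2 mismatches + 1 gap block;
1 mismatch + 2 gap blocks on different rows}; three gap blocks never qualify,
and the two-different-rows constraint applies to duos as well. `N` never
matches anything, including `N`.

Operating points: `p_d = 0.0136`, `p_g = 0.00150` measured on human–chimpanzee
whole-genome alignments; `p_d = 0.0100`, `p_g = 0.00150` for the simulation
conditions. `estimate_rates` recomputes both densities from data and refuses
difference-free input (the model needs `p ∈ (0,1)`).

### Inverted-homology search

Within each candidate region the reverse complement of the species-B segment is
searched against the species-A segment. The engine replaces an external blastn
binary but keeps its semantics:

* exact `word_size`-mer seeding (default 5) — no shared word, no hit; every
  reported alignment must itself contain a gap-free identity run of that
  length;
* two enumeration routes, merged and deduplicated: maximal-scoring ungapped
  segments along every seeded diagonal (so a strong hit never shadows weaker
  ones elsewhere, as with blastn's per-seed extension), and optimal gapped
  local alignments (Smith–Waterman via Biopython's C `PairwiseAligner`) found
  best-first with iterative masking of the target;
* legacy blastn default scoring: match +1, mismatch −3, gap open 5, extend 2;
* a gapped alignment is only reported if it contains an ungapped core of raw
  score ≥ `gap_trigger` (default 11, the legacy ~22-bit gap trigger);
* reporting threshold by Karlin–Altschul E-value over the raw search space
  `m·n` with λ = 1.374, K = 0.711 (the +1/−3 parameters), compared against
  `expect` (default 10) after dividing by `1 − gap_decay`. `gap_decay = 0.5`
  reproduces the legacy blastall convention of weighting single-HSP E-values by
  the gap decay constant; set it to 0 for modern blastn+-equivalent reporting.
  Near the boundary this one conventions' difference decides whether raw-score
  5–6 hits (i.e. most 5–6 bp inversions and most chance palindromic matches)
  are reported at all.
* among co-optimal alignments the engine prefers the hit pairing homologous
  positions (target span vs un-reversed query span); chance repeats of the same
  word elsewhere in the segment otherwise win ties and mis-place the b-side
  coordinates of ~10 % of 5 bp calls.

Admission criteria. For trio regions (criterion i): the hit's A-side and B-side
column footprints must overlap (an inversion happens *in place*; a hit linking
two different parts of the forward alignment is a chance repeat); >80 % of the
hit's A positions must be forwardly aligned, the remainder sitting opposite
gaps; inverted similarity (identities / columns, gaps non-identical) must
exceed `0.95` strictly and `1.25×` the forward similarity of the same column
window; and that window must contain a qualifying trio. For duo regions
(criterion ii, partially palindromic inversions): perfect inverted similarity,
the hit covering the entire identically aligned gap-sandwiched stretch, and
that stretch exceeding 50 % of the segment. Overlapping trio/duo calls are
merged keeping the higher similarity; call length is the A-side length of the
inverted alignment, bounded to [5, 125].

AT filters: a call whose two segments both match `A^i T^j` (mononucleotide
stretch/shrink) or are both phases of an `AT` dinucleotide repeat is discarded;
AT-exclusivity (segments containing only A/T, judged on both species — the
stricter reading) is reported per call.

### Lineage assignment

"Fewer than two" differences is implemented as ≤1 and "three or more" as ≥3;
a count of exactly 2 on either side is deliberately inconclusive
(`unresolved`). Differences are mismatch columns plus maximal gap blocks in
either row, the same unit as `p_d`. Gorilla is the deciding outgroup when
present; orangutan breaks the tie between a species-tree event and incomplete
lineage sorting by revealing which state is ancestral (without orangutan, the
species-tree-consistent single-inversion explanation is preferred, and
orangutan-only profiles cannot produce ILS calls). Outgroup alignments are
gathered per call by overlap on human coordinates (best-covering alignment per
species) and star-aligned around the human row with 20 bp flanks.

## Simulator

A root sequence (default 5,000 bp; the validation study uses 1,500 bp, see
below) is drawn i.i.d. from the stated base composition and evolved down two
branches of `subs_per_site/2` expected substitutions each. Substitutions are
applied exactly by sampling each site from the HKY85 transition matrix
`expm(Q·t·r_k)` of its rate category; per-site categories are drawn once at the
root and shared by both branches (site effects, not branch effects). The five
category rates are the equal-probability discrete-gamma means (shape 0.65),
normalized to mean 1. Indel events arrive as a Poisson count with mean
`indel_sub_ratio · t · L` per branch (0.159), insertions and deletions equally
likely, lengths from the bounded Lavalette law `P(l) ∝ (l·M/(M−l+1))^(−a)`
with a = 2, M = 50, insertion content drawn from the stationary composition.
Indels are applied sequentially after the substitution pass rather than
interleaved event-by-event; at ~1 % divergence the two orderings are
statistically indistinguishable and the exact matrix-exponential substitution
step avoids jump-chain approximation error. The AT-exclusive condition
(g_A = g_T = 0.5, g_C = g_G = 0) reduces HKY to a two-state A↔T chain;
normalization then runs over the two live states.

**Divergence calibration.** The printed simulation parameters are
self-inconsistent at face value ("substitutions per site at 1.00" alongside
`p_d = 0.0100`); the reconciliation adopted here is that the simulated pairs
must *realize* the scan's operating density. `subs_per_site = 0.0090` (total,
both branches) was calibrated once so that re-aligned, inversion-free pairs
show `p_d ≈ 0.0100` and `p_g ≈ 0.00150` — the calibration lands both targets
simultaneously, which is itself a consistency check of the 0.159
indel/substitution ratio.

One inversion of fixed length is planted per pair at a uniform position
(reverse complement in place; planting is an involution and the truth interval
is recorded), and the ungapped pair is re-aligned.

## Re-aligner

A deterministic optimal global aligner with affine gaps (cost
`gap_open + gap_extend·L`) stands in for MAFFT. Its default scores (match +1,
mismatch −1, gap open 4, extend 1) were calibrated against MAFFT itself on
simulated diverged pairs with planted 5–50 bp inversions: the quantity that
matters downstream is whether a short inverted segment is rendered as clustered
mismatches (criterion i territory) or as staggered gap pairs (criterion ii
territory), and these scores reproduce MAFFT's rendering profile
(≈98 % mismatch-style at 6–10 bp, ≈75 % at 20 bp) where a sharper
mismatch penalty would gap out most inversions above 10 bp. Multiple
alignments for profiling are built by reference-star merging of pairwise
alignments around the human row — for 3–4 sequences at great-ape divergence a
guide-tree progressive scheme adds nothing the count-based thresholds would
notice.

## Validation study conditions

`scripts/acceptance.py` and the acceptance tests run the same study: size
classes 5, 6, 10, 20, 50 bp under the human–chimp composition (1,000 pairs
each) and 5, 50 bp under the AT-exclusive composition (1,700 pairs each, so the
pooled AT alignment exceeds 5 Mb), root length 1,500 bp, scan at
`p_d = 0.0100 / p_g = 0.00150`. The 1,500 bp root keeps the full study at a few
minutes on one CPU; recovery of a planted inversion depends only on its ~100
column neighbourhood, and a spot check (root 1,000 vs 2,000 bp) confirms the
flank-length insensitivity. A planted inversion counts as detected when a
call's b-side interval overlaps the planted window within a 5 bp boundary
margin: inverted alignments are maximal, so called boundaries legitimately
extend wherever the flank happens to continue the inverted repeat, and in
repetitive context the same inversion admits several boundary placements
(observed shifts are 0–1 bp). A stricter rule additionally demanding length
agreement within ±50 % is available (`strict_match_rule`) but would brand
boundary-extended recoveries of 5 bp plants as false positives by the
thousands per 100k pairs, which no false-positive accounting of this detector
supports. False-positive rates are extrapolated as one-sided 99 % lower
confidence bounds (Poisson), so "0 observed" reports 0 and small counts report
the smallest rate the data cannot exclude.

What the simulation does *not* emulate: real genomes' repeat landscape
(transposable elements, segmental duplications), regional mutation-rate
variation beyond gamma site effects, alignment-pipeline artifacts of
chain/net-style genome alignment, and sequencing/assembly error. Passing the
study therefore certifies the detector's behaviour under its own null and
signal model, not its false-positive rate on a real genome — the AT-exclusive
condition in particular shows that two-letter sequence pushes every part of
the chain (alignment rendering, chance palindromic hits, reporting thresholds)
into a harsher regime.

### Known behavioural differences from the legacy toolchain

The method's published operating point was established with early-2010s
blastall and MAFFT. Three behaviours of that chain are not exactly
reproducible, and swap-in experiments (running the actual modern blastn, and
the actual MAFFT 7.526, inside this package's pipeline) bracket their effect:

* **Short-hit reporting.** Whether a raw-score 5–6 inverted hit is reported
  decides 5–6 bp sensitivity and the chance-hit (false-positive) rate. The
  `gap_decay` default emulates the legacy single-HSP convention; modern blastn
  reports about one score-unit deeper, and this package's exhaustive hit
  enumeration recovers marginal hits even blastn's heuristic extension misses.
  Sensitivity at 6 bp is accordingly somewhat above, and in the AT-exclusive
  condition (where chance palindromic words are 32× more frequent) both 5 bp
  sensitivity and the chance-hit rate sit well above, the published values.
* **Alignment rendering of AT-only inversions.** With modern MAFFT swapped in,
  AT-exclusive 50 bp sensitivity lands at ≈0.83 versus ≈0.96 with the internal
  aligner — the internal aligner preserves two-letter inversion signatures more
  cleanly. The internal aligner is kept: modern MAFFT simultaneously *drops*
  standard-composition 50 bp sensitivity to ≈0.65, i.e. it no longer matches
  the alignments the method was validated on either.
* **AT simple-repeat exclusion.** Only the two printed filter patterns are
  implemented; a broader repeat screen would be needed to push the AT
  chance-hit rate to the published level.

## Numerical choices and degenerate inputs

Seeded determinism end-to-end: every stochastic component takes a NumPy
`Generator` or an integer seed; per-pair streams are spawned via
`SeedSequence` so studies parallelize conceptually without reseeding hazards.
Candidate regions of fewer than `word_size` ungapped bases are skipped.
Empirical p-values use the add-one convention `(1+k)/(n+1)` and therefore
never report 0. Degenerate detector inputs (empty hit lists, palindromic
planted segments — invisible by construction, difference-free alignments)
return empty call sets rather than errors. Ties everywhere break
deterministically: hits by (score, a_start, b_start), co-optimal alignments by
positional consistency then coordinates, merged calls by similarity then
leftmost start.

## Limitations

* The 5–6 bp classes sit at the edge of detectability; their sensitivity is a
  property of the reporting convention as much as of the data.
* The trio scan cannot see inversions that align forward with fewer than three
  differences (near-palindromes) — a structural blind spot shared with the
  original method.
* Lineage assignment trusts single best-overlap outgroup alignments; paralogy
  or alignment error in the outgroup propagates into the profile.
* The internal re-aligner emulates MAFFT's rendering statistically, not
  per-alignment; residual disagreement concentrates in repetitive and AT-rich
  regions.
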