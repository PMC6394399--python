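# Methods

## Model and score conventions

A mosaic path copies the query from a sequence of reference segments.  Its
score is m·ρ + Σ μ_i over mismatching sites, where **m counts every
segment including the first**, so a perfect single-segment copy scores ρ.
This convention is applied uniformly across `score_path`, `score_pair`, the
branch-and-bound decoders and the DP oracles, and the test suite asserts
their mutual consistency.  Internally the branch-and-bound accumulators
start at 0 (the first segment's ρ is not yet paid while the suffix is being
extended), so the public functions add ρ (haploid) or 2ρ (diploid) to the
internal optimum on return and the tracebacks subtract it again; traceback
records are stored on the internal scale.

ρ and μ are negated log odds of the per-site recombination and mutation
probabilities, so integer- or rational-scaled values are natural and keep
all arithmetic exact.  μ may vary per site in the haploid decoder; ρ may
not: the pruning argument postpones a recombination at equal cost, which
requires a constant recombination score.  The diploid decoder additionally
restricts μ to a scalar — the pruning theorem has not been extended to
per-site μ for path pairs, so a vector μ is rejected at the API boundary
rather than silently producing unproven results.

Both decoders require ρ > 0.  At ρ = 0 the bound "extensions scoring
≥ minimum + ρ can be dropped" degenerates (nothing may extend), and the
undercutting argument that justifies pruning no longer terminates.  The DP
oracles accept ρ ≥ 0.

## PBWT index

`build_pbwt` runs a stable counting sort per site, back to front: a^{n−1}
is the identity and a^{i−1} re-sorts a^i by the allele at site i.  Slot t
of the stored permutation array holds a^{t−1}; slot 0 is therefore the
extra permutation a^{−1} (rows ordered by their full allele sequence),
which both tracebacks need to name the first segment's row.  Rank tables
are stored as full (H+1)-length cumulative arrays per site and allele —
O(Hn|A|) memory, the uncompressed representation; run-length compression
is out of scope.  `lf(k, a, i) = r_i^a(k) + Σ_{c<a} f_i^c` maps block-i
offsets to block-(i−1) offsets; `fl` inverts it by binary search over `lf`
(O(log H)), first selecting the allele from the cumulative frequency block
containing the offset.  Construction and LF support arbitrary alphabets;
the LS decoders themselves are specified for the binary alphabet only and
reject multiallelic indexes.

## Classical-BWT reference

The lifted sequence interleaves a position symbol after every allele, with
the final position symbol specialized per haplotype to pin the initial
ordering; symbols are ordered triples (class, position, haplotype) so that
p_0 < … < p_{n−1}^0 < … < p_{n−1}^{H−1} < 0 < 1 < … without inventing a
character encoding.  `build_bwt_naive` sorts all 2Hn rotations outright
(byte-encoded keys; O((Hn)² log Hn) worst case) — it exists purely as an
oracle establishing that the counting-sort PBWT is the first Hn symbols of
the classical BWT and that the second half is fixed by the allele
frequencies.  One caveat the tests respect: a single-character pattern with
no leading position symbol has no positional anchor in the classical BWT
(it matches rotations at every locus), so the search-width equivalence is
asserted only for anchored patterns (offset ≥ 1 or length ≥ 2).

## Branch-and-bound decoding

States are (interval, suffix score) pairs — interval pairs for the diploid
case, kept as unordered pairs via canonical interval ordering.  Pruning
implements the full-suffix-set conditions: match extensions are kept only
below (current minimum + ρ) (haploid) or below the per-group minima + ρ and
global minimum + 2ρ (diploid); one recombination state per site is added
only when no minimum-score state extends with the matching allele; the
diploid case gates single recombinations on genotype compatibility
(a₁+a₂ = 1 at heterozygous sites, recombining allele = g/2 at homozygous
sites) and allows one double recombination per site.

Two bookkeeping details deserve emphasis because they are easy to get
wrong, and both are pinned down by the exact-equivalence suites:

* the next-iteration minimum gm′ (and the diploid per-group minima lm′) is
  updated when a recombination state is appended, not only for match
  extensions.  gm′ must be the minimum over the whole new state set: a
  concrete two-row instance (single live state whose group fails to match
  the query allele, μ > ρ) shows that omitting the recombination term lets
  gm′ overestimate it, which corrupts later bounds and the final score;
* in the diploid single-recombination record, the recombining path's stored
  row offset is the start of its *incoming* interval (the group the path
  continues from at later sites).  The traceback consumes each record after
  walking past its locus, at which point walker offsets live in that same
  block, mirroring the haploid record, which stores the s-offset of the
  first minimum-score incoming state (any representative of the minimal
  group is valid; first-encountered is the tie-break).

Final minima are reported deterministically: the smallest s (haploid) or
lexicographically smallest (s₁, s₂) (diploid) among minimum-score states.

## Redundancy removal

Identical or dominated states (contained interval, no better score) can
accumulate without affecting correctness.  `dedupe_states` removes them —
domination uses interval containment with score ≤, a conservative rule —
every 32 sites and whenever the live list grows past 4× its size after the
last pass.  The diploid pass removes exact duplicate pairs (compared as
unordered pairs) on the same cadence.  Both passes, and the diploid
canonical interval ordering, are A/B-tested to leave every returned score
unchanged.

## Traceback

The forward walk uses FL to follow one haplotype (a pair for the diploid
case) through the per-site orderings, subtracting μ_i at mismatches, and
follows a recorded recombination greedily whenever the remaining score
matches the record (diploid single recombinations additionally require the
non-recombining walker offset to lie inside the recorded interval; a
double-recombination record, encoded by end = −1, resets both walkers).
Greedy following is always safe: a feasible recombination can be taken
immediately without loss.  The walk must end with residual score exactly
zero; anything else raises an internal-consistency error.  Reconstructed
paths are rescored against the optimum in every randomized test.

## Score comparisons

Scores are floats; the minimum-state and traceback equality checks use a
1e−9 relative tolerance (exact for integer-scaled parameters, which the
CLI and tests favor).  Pruning inequalities are plain float comparisons.

## Synthetic data

`generate_mosaic_panel` draws a small founder set i.i.d. Bernoulli(0.5) and
builds every other row and the query as founder mosaics: per-site switch
probability to a uniformly chosen founder, per-site allele-flip noise.
This produces exactly the shared-segment structure the LS model assumes —
panels where rows are recombinants of common ancestors — which is what
makes the flat-in-H state count observable.  It does **not** emulate other
features of real cohorts: no mutation/recombination rate heterogeneity
along the genome, no allele-frequency spectrum from genealogy, no
linkage-disequilibrium decay calibrated to a demographic model, and no
genotyping error structure.  Passing tests therefore certify exactness of
the algorithms and the qualitative scaling on LS-structured data, not
population-genetic realism.  The scaling sweep uses panels of n = 2000
sites, 20 founders, switch 0.01, flip 0.002, H ∈ {50, 200, 800}, with
ρ = 2, μ = 3 (the μ < 2ρ regime, where mismatch states survive pruning and
the state set is largest); randomized exactness suites use panels up to
H = 30, n = 60 (haploid) and H = 12, n = 40 (diploid) against the O(Hn)
and O(H²n) DPs, sizes at which the oracles are instant while still
exercising every pruning rule.

## Degenerate inputs and edge cases

Monomorphic sites disagreeing with the query need no special-casing: the
matching extension has an empty interval and is simply not appended, so the
mismatch/recombination machinery covers it.  H = 1 and n = 1 panels are
supported.  A recombination state can never be appended at the first site
(the initial state spans all rows, so a nonempty match extension also marks
the minimum as extended); the implementation asserts this.  Multiallelic
VCF records are skipped with a logged count, not split, since the decoders
are binary; unphased or missing GT fields are errors (no imputation), with
an explicit opt-in flag for unphased data.

## Limitations

No posterior/forward-backward probabilities, no path sampling, no
run-length-compressed index, no set-maximal match reporting, and no
position-dependent ρ (unsupported by the pruning argument).  The diploid
double-recombination bookkeeping (one per site, gated on the `extended`
set) has tie-breaking among multiple minimum-score pairs that is certified
here by the randomized oracle-equivalence suite rather than by a separate
proof; a counterexample found by that suite should be escalated, not
patched silently.
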