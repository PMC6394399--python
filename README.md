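# fastls

Exact haplotype matching and Li & Stephens mosaic decoding over a positional
Burrows-Wheeler transform (PBWT), with decoding cost empirically independent
of the reference-panel size.

## The problem

The Li & Stephens (LS) model describes a new haplotype as an imperfect mosaic
of haplotypes already in a reference cohort: at each of *n* polymorphic sites
the query copies one of *H* reference rows, occasionally switching rows
(recombination) or disagreeing with the copied allele (mutation).  Writing
ρ and μ for the negated log odds of recombination and mutation, the score of
a mosaic path π with *m* segments and mismatch set *M* is

    s(π) = m·ρ + Σ_{i ∈ M} μ_i        (haploid)

and for an unphased genotype sequence g ∈ {0,1,2}ⁿ explained by an unordered
pair of paths {α, β},

    s(α, β) = ρ·m(α) + ρ·m(β) + μ·Σ_i |α[i] + β[i] − g[i]|   (diploid).

Minimizing these scores is Viterbi decoding of the LS hidden Markov model:
O(Hn) for a haploid query and O(H²n) for a genotype, which is intractable on
modern reference cohorts.  This package instead tracks *groups* of partial
mosaics sharing a matched segment — each group is one contiguous interval of
PBWT-sorted rows — and prunes groups that a recombination out of a
minimum-score group would always undercut.  The resulting live-state count
per site is empirically flat in *H*, so decoding costs about the same
against 800 reference haplotypes as against 50, while remaining *exact*:
every score equals the textbook Viterbi optimum, as the test suite verifies
instance by instance.

The package also contains the supporting machinery as first-class, tested
modules: PBWT construction by per-site counting sort (with the extra
permutation a⁻¹ needed for traceback), LF/FL rank mappings, exact anchored
subsequence search, a literal classical-BWT construction on the "lifted"
2Hn-symbol sequence that certifies the PBWT ↔ BWT equivalence, standard
Viterbi DPs and an exhaustive enumerator as independent oracles, and a
synthetic founder-mosaic panel generator so no data download is ever needed.

## Worked example

Simulate a panel of 100 haplotypes over 60 sites built from 8 founders, with
a query that is itself a founder mosaic with 3% allele-flip noise, then
decode it (ρ=1, μ=4) and cross-check against the Viterbi DP:

```text
$ fastls simulate --H 100 --n 60 --founders 8 --switch 0.04 --flip 0.03 \
    --seed 5 --panel-out panel.txt --query-out query.txt
$ fastls haploid --panel panel.txt --query @query.txt --rho 1 --mu 4 --oracle
score 3  path 0:30 20:15 28:2
viterbi oracle score 3: agree
```

The optimum costs 3: a three-segment mosaic (panel rows 30, 15 and 2,
switching at sites 20 and 28) with zero mismatches, i.e. m·ρ = 3·1 — cheaper
than any path that pays μ=4 for a mismatch.  The diploid decoder reports a
pair of paths the same way:

```text
$ fastls diploid --panel panel.txt --genotypes 2101... --rho 1 --mu 4 --oracle
score 5
path1 0:92 7:4 50:5
path2 0:27 29:24
viterbi oracle score 5: agree
```

Exact search works from the same panel; matching the first 12 alleles of
row 0 anchored at its prefix:

```text
$ fastls search --panel panel.txt --query 101000110000
full match at sites [0, 12): rows [8, 80, 79, 85, 30, 24, 72, 36, 0, 42, ...]
```

Library use mirrors the CLI: `build_pbwt(panel)` makes the index,
`fastls_haploid(index, query, ScoreParams(rho, mu))` returns the optimum plus
traceback data, and `traceback_haploid(...)` recovers the mosaic path.
Panels come from `read_panel_text`, `read_panel_vcf` (phased GT) or
`generate_mosaic_panel`.

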