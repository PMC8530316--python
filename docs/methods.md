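# Methods

## The estimation problem

A Hi-C library is a mixture: a fraction ρ of read pairs derive from
proximity-ligation (PL) fragments — two restriction-digested, end-filled,
blunt-ligated free ends — and the remainder from protocol failure modes that
produce ordinary contiguous fragments.  Every PL fragment contains a
ligation-junction motif whose sequence is fixed by the digest chemistry: the
end-filled terminus of the upstream fragment concatenated with the end-filled
terminus of the downstream one.  For a single palindromic enzyme with site
`s` cut at offset `o`, each terminus contributes `len(s) − o` bases, so the
junction is the recognition context with a duplicated overhang
(DpnII `^GATC` → `GATCGATC`, 8 bp; HindIII `A^AGCTT` → `AAGCTAGCTT`, 10 bp).
Dual digests yield all four ordered end combinations.  Junction length
l_LA is defined throughout as the length of the searchable motif sequence.
Only palindromic 5′-overhang chemistry is modelled; blunt cutters (no
duplication, nothing to detect) and 3′-overhang enzymes are rejected with
explicit errors.

Simply counting junction motifs badly over-counts ρ: an 8 bp motif occurs
natively every ~4^8 bp.  The discriminating signal is *local k-mer
frequency*: k-mers spanning a junction created by ligating two essentially
random loci are unique or near-unique in the library's k-mer spectrum,
whereas a native occurrence of the motif has ordinary local coverage.

## Observation model

For each sampled fragment (read pair, or single pre-merged read):

1. Reads are searched for any concrete junction sequence
   (ambiguity-expanded, reverse-complement closed; expansion capped at 256).
   The leftmost hit whose start x lies in the **feasible window**
   [k+1, l_read − l_LA − k − 1] sets λ = 1.  The window guarantees all nine
   k-mers below fit inside the read.
2. Otherwise one read is chosen uniformly and x is drawn uniformly from its
   feasible window (λ = 0).  Drawing directly from the feasible window is
   distributionally equivalent to drawing from the wider motif-placement
   range and rejecting positions whose flanking k-mers cannot be extracted.
3. Nine k-mer counts are queried from a canonical-k-mer database built from
   the same readset: inner set starting at {x−1, x, x+1}, outer set at
   {x−(k+1), x−k, x−(k−1)} and {x+l_LA−1, x+l_LA, x+l_LA+1}.  The outer
   starts are chosen so the outer set stays fully inside native sequence
   even at a real junction (the junction's first/last bases belong to the
   flanking fragments' native sequence).
4. φ = GM(inner)/GM(outer).  Any missing k-mer abandons the fragment.
   GM(outer) < f̄/2.5 (f̄ = mean frequency over distinct stored k-mers,
   singletons included, no abundance trimming) is rejected as low native
   coverage; the inner set is deliberately unconstrained, since a true
   junction is *expected* to have minimal inner coverage.

A junction found only outside the feasible window is tallied separately and
the fragment falls through to the null draw (step 2) rather than being
discarded.  This choice pairs with the window-aware unobserved-fraction mask
below: together they make the corrected estimator consistent,
E[ρ̂_lib] ≈ ρ, for junction offsets uniform on the insert.  Discarding such
fragments instead would inflate the λ = 1 share of the accepted table in a
signal-dependent way that no single multiplicative correction can undo.

## From observations to ρ_lib

Unique λ = 0 frequencies in ascending order receive empirical rank p-values
p̂(φ) = (r(φ)+1)/(n+1), r(φ) = number of unique values ≤ φ; a query below
the table floor returns 1/(n+1), continuing the rank formula at r = 0.
Junction observations receive the p-value of the nearest-not-greater entry.

Each bootstrap resample t_b of the observation table (with replacement,
equal size, default 100 resamples) yields

ρ_b = Σ_{λ=1} (1 − p̂_i) / |t_b|.

The 1 − p̂ direction makes each junction observation contribute its
probability of not being explainable as a native-frequency site: a true
chimeric junction has φ below every null value, p̂ = 1/(n+1), and contributes
≈ 1, while a native motif occurrence has p̂ uniform on (0, 1] and contributes
½ on average — exactly the false-discovery mass the rank test expects.  A
`literal_sum` variant (summing p̂ itself) is retained behind a flag for
comparison; on synthetic libraries it tracks the native-coincidence mass,
not the PL mass.

The per-fragment unobserved fraction α_i enters the same resamples:
α_b = mean α_i over t_b, and ρ_lib is computed **per resample** as
ρ_b/(1 − α_b), clamped to [0, 1], then summarised (mean point estimate,
[2.5%, 97.5%] quantile interval) so the ρ–α correlation propagates into the
CI.  A table with no λ = 1 rows reports ρ = 0 with a zero-width CI and a
"no junctions observed" flag instead of failing.

### Unobserved-fraction masks

Two masks are provided by `alpha_fragment`:

* **Plain mask** (`account_flanks=False`): observable extent is what the
  reads sequence minus the l_LA − 1 junction-match blind spot at each 3′
  end.  Merged fragment: α = 1 − (l − l_LA)/l.  Pair against the
  user-supplied mean insert L̄: read 1 observes [0, l1 − (l_LA − 1)),
  read 2 observes [L̄ − l2 + (l_LA − 1), L̄), union counted once.  This is
  the correction the reference-based mode applies to the read-through rate.
* **Window-aware mask** (`account_flanks=True`, used by the reference-free
  estimator): observable positions are junction *starts* detectable given
  the feasible window — each read contributes l − l_LA − 2k − 1 usable
  starts — normalised by the L̄ − l_LA + 1 possible starts.  For 150 bp
  pairs, k = 24, l_LA = 8, L̄ = 300 this gives α = 1 − 186/293 ≈ 0.365,
  versus 14/300 ≈ 0.047 for the plain mask.  Using the plain mask in the
  estimator would leave the k-sized flanks uncorrected and bias ρ_lib low
  by roughly 2k/L̄ (~25–30% relative at these settings).

Both masks are exercised against base-by-base boolean-array oracles in the
test suite.  α_i uses the *fixed* L̄ for every pair; for Gaussian insert
lengths centred on L̄ the curvature of α(L) is mild and the induced bias is
well below the bootstrap CI width at the validation settings.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| k | 24 (accepted 16–32) | flank specificity vs usable read interior; counting kernel supports k ≤ 31 |
| mean insert L̄ | user-supplied, bp | drives the paired unobserved mask; use the reference-based mode's sigma-clipped estimate when available |
| n_boot | 100 | bootstrap resamples for the 95% CI |
| max_observations | 20 000 | s.e.(ρ_obs) ≈ 0.3 pp — ample for a QC verdict at desk-scale runtime |
| outer-coverage gate | f̄/2.5 | rejects φ computed on unreliable native coverage |
| min_quality | 0 | optional Phred mask during counting; masked bases break reads into segments |

Reference-based mode: mapq filter default 10 (60 is too strict for
repeat-heavy genomes); duplicates and secondary alignments are excluded;
supplementary alignments matter only insofar as the primary retains the 3′
clip that read-through detection inspects (clip ≥ ⌈l_LA/2⌉ ending within
±1 bp of a cut site — the field reports no canonical thresholds, so both are
configurable).  Separation is the outermost-coordinate span, matching the
insert-length reading of the sub-1 kb peak; sigma-clipping iterates
mean ± 3σ on separations < 1000 bp (≤ 10 rounds, ≥ 100 values required).
Dangling ends are mates on one fragment pointing toward each other and
self-circles pointing away, the standard read-level convention; coordinates
are 0-based half-open internally.

## Synthetic data generator

The generator emulates exactly the features the estimator's model assumes:
i.i.d. random genome at a set GC, restriction digestion, PL inserts joining
two uniformly chosen cut-derived blunt ends with the junction offset
u ~ U(0, L − l_LA), a Bernoulli(hic_fraction) PL indicator per pair,
truncated-Normal insert lengths (≥ read length), fixed-length reads from the
insert ends, and i.i.d. substitutions at rate 0.001 (a realistic
post-clean-up Illumina substitution rate; Q40 written uniformly).  Default
conditions mirror the validation regime: 500 kb genome, DpnII, 150 bp reads,
300 ± 50 bp inserts.

What it does **not** emulate — and what passing tests therefore do not
demonstrate — includes: repeat structure and uneven coverage (a random
genome has an essentially flat k-mer spectrum, so the f̄/2.5 gate rejects
far fewer observations than on a real genome), distance decay and chromatin
structure (irrelevant to the estimator, which ignores pair separation),
position-dependent machine error profiles, adapter contamination, and
duplicate reads.  Real libraries also violate the uniform-junction-offset
assumption if shearing is biased; a centre-biased offset density would make
α under-estimated and ρ_lib under-estimated in turn.

## Validation scale and results

The acceptance suite runs the full pipeline at 60× coverage (500 kb genome,
100 000 pairs): signal contents {0.10, 0.25, 0.50} × 3 seeds must each be
recovered within ±25% relative with median |deviation| ≤ 10% (observed:
≤ ~5% and ~2–4% respectively); five null libraries must report
ρ_lib < 0.02 (observed ≤ 0.006); 20 replicate libraries at 0.25 must have
the 95% CI cover truth in ≥ 14/20.  These problem sizes were chosen as the
smallest at which the k-mer spectrum is reliably sampled, keeping the whole
suite at desk scale.

## Numerical and degenerate-input choices

* Canonical k-mer codes are 2-bit packed into 64-bit integers (k ≤ 31);
  counts live in sorted parallel arrays with binary-search lookup.  Missing
  is a distinct outcome (None / −1), never conflated with count 0.
* A p-value table needs ≥ 2 unique null values; fewer is an error at table
  construction, and a degenerate bootstrap resample contributes ρ_b = 0.
* Mean-over-resamples is clamped into its own quantile interval (constant
  inputs can place the float mean an ulp outside a zero-width CI).
* Reads shorter than 2k + l_LA + 2 are counted and reported as unusable.
* Fragments are consumed in input order up to `max_observations`; input
  order is assumed exchangeable, as it is for the generator and for
  unsorted sequencer output.
* The text database format doubles as an import path for external
  `KMER<TAB>COUNT` dumps; records that canonicalise together are merged by
  summing.

## Known limitations

* Signal detection quality degrades below ~3× coverage of the dominant
  genome: the spectrum no longer separates introduced from native k-mers.
* The reference-free correction trusts the user-supplied L̄; a wrong L̄
  scales ρ_lib roughly linearly through 1 − α.
* Read-through adjustment in the reference-based mode divides the observed
  rate by 1 − α using the plain mask; like the original statistic it is a
  per-read proxy, not a pair-level PL probability.
* The estimator classifies libraries, not individual pairs; per-pair PL
  filtering is out of scope.
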