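# Methods

## Reporter model

The reporter is modelled as a single-strand, 0-based half-open coordinate
construct with seven ordered features: promoter (1200 bp), Alu1, a spacer
tiled by `neoR`, a polyA terminator (≤200 bp) and the 18-bp I-SceI
recognition site, Alu2, and `puroR` (600 bp). The two Alus are direct
repeats; reverse-strand geometry is out of scope. With the 300-bp default Alu
and an 1100-bp spacer the construct is 3500 bp and every single crossover
between the Alus deletes exactly `alu2.start − alu1.start` = 1400 bp. Filler
sequence (promoter, `neoR`, polyA, `puroR`) is seeded-random DNA; only its
length and the I-SceI site content matter to the model.

A product is *selectable* (yields a puromycin-resistant colony) iff some
breakpoint placement within its microhomology-equivalence window removes the
entire polyA and I-SceI features, leaves promoter and `puroR` intact, and the
deletion size lies in the detectable window, default 897–1881 bp. The window
is configurable; its default follows the main-text deletion-size range
(a supplementary legend gives 1901 bp as the upper bound instead).

## Diverged pairs and homology intervals

`generate_diverged_alu` places `k = round(L·d/100)` substitutions for
divergence `d` on length `L`. Evenly spaced placement uses positions
`round((i+1)·L/k) − 1`; for 5% on 300 bp this is exactly one substitution
every 20 bp (sites 19, 39, …, 299). Proportional placement was chosen over a
fixed stride `round(100/d)` because a fixed stride overflows the element for
divergences such as 15% on 300 bp. Requested and realized divergence agree
within the 100/L-percent resolution of the element. Substituted bases are
drawn seeded-uniformly from the three alternatives; the scrambled control is
a seeded permutation of the consensus, which against the original shows ~75%
positional mismatch.

Pairs are compared positionally when equal-length (and `align_pair` falls
back to positional comparison whenever the gapless alignment attains the
optimal global-alignment score, so substitution-only pairs always reduce to
it); otherwise a global alignment (match +1, mismatch −1, gap open −4, gap
extend −1 — typical for 70–100% identical repeats, configurable) defines the
columns. Each maximal indel run collapses to one diagnostic site, and
divergence is (mismatch columns + indel runs) / total columns: an indel run
bounds junction mappability exactly like one diagnostic substitution.

The element is tiled by `n_sites + 1` homology intervals cut at each
diagnostic site. Reporting segments are `⌈L/segment_length⌉` spans (default
three 100-bp segments; the last is truncated for shorter elements, e.g. a
real ~281-bp consensus), and an interval belongs to the segment containing
its midpoint.

## Simulator

Three event classes are generated with exact truth records:

* **Single crossover** in interval `i`: the product keeps parent-1 alleles at
  sites `< i` and parent-2 alleles from site `i` on; equivalently it is the
  pure deletion `cassette[:left] + cassette[right:]` with the cut at the
  interval. Truth breakpoints are leftmost-normalized and the microhomology
  window (at least the homology-interval length) recorded.
* **Complex chimera**: a per-site parent-of-origin vector with ≥2 switches,
  modelling mismatch-processing patches of the annealed heteroduplex. No
  single deletion interval exists, so truth breakpoints are the nominal
  Alu-anchored span with microhomology 0.
* **NHEJ deletion**: two breakpoints straddling the I-SceI break, by default
  uniform over the legal span; junction microhomology is *not* imposed — it
  emerges from the cassette sequence and is recorded after leftmost
  normalization. An optional microhomology-seeking mode picks among candidate
  draws with weight 2^mh (capped at 25 nt) to emulate MMEJ preference.
  Untemplated insertions default to absent.

`simulate_colony_set` draws the event class first and then rejection-samples
positions until the product is selectable, counting rejections (the analogue
of undetected repair). The class mixture therefore describes the composition
of the *detected* colony set, matching how pathway splits are measured
(proportions among sequenced colonies); whole-event rejection would skew the
mixture because NHEJ draws fail the size window far more often than
recombination draws. NHEJ draws whose product is base-for-base identical to a
single-crossover product (in-register junctions between the Alus) are
resampled: such colonies are operationally recombination products and no
caller could, even in principle, label them otherwise. A single RNG stream is
used with a fixed draw order (class, then positions, then bases), so output
is byte-reproducible given the seed.

The crossover-position distribution is a two-component mixture: with weight
`w` an interval from the first reporting segment, else uniform over all
intervals (`w = 0` is the null; a 5'-bias preset solves `w` from the target
first-segment probability).

## Caller

A product is anchored to the cassette by its longest exact prefix and suffix
matches (each must reach 30 bp, configurable); products equal to the cassette
or with shorter anchors are UNRESOLVED. When prefix + suffix cover the
product, the junction is a pure deletion and `measure_microhomology` returns
the maximal `m` such that shifting both breakpoints by any offset in `[0, m]`
rebuilds the identical product, together with the leftmost placement
(VCF-style normalization); ambiguity is reported, never midpoint-assigned.

Classification: if some equivalent placement leaves *both* parental Alus
untouched the deletion is spacer-only and the product (two intact Alus) is
NHEJ. Otherwise, a product whose net length change equals
`alu2.start − alu1.start` is genotyped at the alu1 frame: each diagnostic
site is called parent 1, parent 2 or missing, and ≥99% of non-diagnostic
positions must match the shared parental base (tolerance for simulated
sequencing noise; the patchy-chimera case is why the test keys on net length
change rather than on the anchored deletion span). A monotone genotype vector
is a single crossover, located to the interval immediately left of the first
parent-2 site (all-parent-1 maps to the last interval, all-parent-2 to the
first); ≥2 switches, or any parent2→parent1 switch first, is a complex
chimera; >10% missing genotypes is UNRESOLVED. Everything else is an NHEJ
deletion, annotated with microhomology and breakpoint topology (`both_Alus`,
`one_Alu`, `no_Alu`, judged on leftmost placements by default, with an
any-placement mode since published convention is unstated).

Per-site genotyping requires an ungapped (equal-length, substitution-only)
pair. For gapped pairs the caller resolves single crossovers by exact
comparison against the enumerated candidate chimera products; patchy chimeras
on gapped pairs are reported as per-site information only (a known
limitation — conversion-tract boundaries under indel ambiguity have no
canonical representation).

## Statistics

Expected junction counts per segment default to *per-interval* weighting
(`E_i = n · I_i / I` with intervals assigned to segments by midpoint),
because junctions are observable only at interval resolution; *per-bp*
weighting (`E_i ∝` segment length) is provided since "random throughout the
element" is ambiguous, and the two coincide when interval boundaries align
evenly with segments. The goodness-of-fit is Pearson's chi-square with
`df = segments − 1`; per-segment flags come from a post-hoc
one-segment-vs-rest chi-square at α = 0.05 with no multiple-testing
correction. Fold decrease is `reference/test`, rounded to one decimal below 2
and to the nearest integer otherwise (the rounding convention of the
published series); adjusted colony counts split a count by pathway
percentages. ANOVA/t-tests on colony counts are deliberately not implemented;
colony tables are pass-through inputs.

## Problem sizes and calibration checks

The acceptance script and test suite use the standard study conditions:
300-bp consensus, 5% evenly spaced divergence (15 sites, 16 intervals),
default geometry. Round-trip recovery runs 1,000 selectable products per
event class; the microhomology oracle check runs 1,000 random junctions
against a brute-force shift-equivalence scan (±30 bp); the crossover locator
is checked exhaustively against a monotone-consistency oracle over all 3^n
genotype vectors up to length 8. Chi-square calibration draws 2,000 null
datasets and 500 biased datasets of 169 junctions each directly from the
interval sampler (the sequence-level round trip is already covered by the
recovery suite, so the calibration exercises the sampling + statistics layers
at full replication cheaply).

## What the generator does and does not emulate

The simulator reproduces the *structure* of real repair products — chimeric
Alus with interval-resolution junctions, patchy conversion tracts, deletion
junctions with emergent microhomology, and the selection window's censoring —
with exact, noise-free sequences. It does not model sequencing error or PCR
artefacts (the 99% shared-match tolerance and the 10% missing-genotype
threshold exist for users who add noise), resection kinetics, Rad52 binding,
heteroduplex rejection or mismatch-repair mechanisms (pathway biology enters
only through the class-mixture presets), multi-copy integration, or
subfamily-specific Alu sequence (the synthetic consensus is random DNA, so
microhomology statistics reflect a 25% per-base match rate rather than true
Alu composition). Passing round-trip tests therefore demonstrate correctness
of the calling logic on clean products, not robustness to noisy reads.
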