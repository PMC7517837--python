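# Methods

## Quantification model

The unit of observation is a peptide abundance in one sample; the design
is paired, one pooled sample per subject (dog) per timepoint, so the
biological replicates for cohort-level ratios are the dogs, never
technical replicates. Ratios are built bottom-up:

1. **Ratio combinations.** For one peptide group, all |D7|×|D0|
   cross-ratios between replicate abundances, in numerator-major order.
   Cross-pairing is deliberate: pairing within a timepoint would center
   every ratio at 1 and could never express a fold change.
2. **Geometric median.** For scalars the geometric median reduces to the
   ordinary median in log space, `exp(median(log x))`; with an even count
   this is the geometric mean of the two central values. It is invariant
   to reciprocal relabeling (swapping D0/D7 maps every FC to its exact
   reciprocal) and to multiplicative rescaling of one side (scaling all D7
   abundances by c scales every FC by exactly c) — both properties are
   enforced by tests.
3. **Protein ratio.** The geometric median of the present peptide-group
   ratios. A peptide group with no detected abundance on either side is
   absent, not zero.

**Significance.** The underlying acquisition software does not document its
test, so the package uses a two-sided one-sample t-test of the log2
peptide-group ratios against zero, with no multiple-testing correction —
matching the raw "p < .05" convention of the workflow it reimplements.
A p-value requires ≥2 finite ratios spanning ≥2 dogs. Degenerate
zero-variance inputs use the convention p = 1 when the common log-ratio is
0 (zero t statistic) and p = 0 otherwise; SciPy would return NaN there.
The null calibration of this test (fraction of p < .05 within [0.03,
0.07] on a 2000-protein no-effect cohort) is checked in the acceptance
suite.

**Filters.** A protein is detected in a sample iff ≥1 of its peptides is
present. "Detected in over 50% of samples" is a strict majority (4 of 7).
The 2-fold rule uses exclusive boundaries: FC of exactly 0.5 or 2 is
unchanged. Per-dog comparisons contribute one ratio per peptide group and
never carry a p-value. Percentages in per-dog summaries round
half-away-from-zero to one decimal and drop a trailing ".0" (266/299 →
"89", 210/211 → "99.5"). All tables sort by (p ascending, accession) for
determinism.

## Ortholog chain

Three stages, each a plain mapping file (2 or 3 columns; the optional
third is a confidence score), primary consulted before fallback. Mapping
tables are static inputs, not live database queries — the reference
databases drift over time and reproducibility requires frozen tables.
One-to-many hops resolve by highest confidence (absent = 0), then
lexicographically smallest target. Duplicate human genes after mapping
keep the score of largest magnitude (tie → lexicographically smaller
source accession), preserving the strongest signal as common collapse
conventions do. The bookkeeping identity `ranked + unmapped + collapsed =
input` is asserted in tests.

## Preranked enrichment

Weight exponent 1 (the standard "weighted" scheme), exposed in
configuration. When every member of a set has score exactly 0, hit
increments fall back to the unweighted 1/N_H (the w→0 limit) instead of
dividing by zero. The ES is the running-sum element of largest magnitude,
first index on an exact tie; an exact max/min magnitude tie resolves to
the earlier list position. The vectorized permutation path constructs full
running sums with the same accumulation order as the observed-set path, so
the two agree bit-for-bit.

The null is gene-tag permutation — n_perm (default 1000) size-matched
random sets per gene set — because phenotype permutation does not exist
for preranked input. Each set's permutation stream derives from (seed,
set index in sorted-name order), making results independent of input
ordering. Nominal p uses the add-one rule (k+1)/(m+1) against the
same-signed null half, so p is never 0 and "p < .001" scales with n_perm.
For the FDR, each set's null ES are first normalized by that set's
same-sign null means, pooled across sets, and q = (same-signed pooled-null
exceedance fraction) / (observed exceedance fraction), clipped to [0, 1]
and monotonized by a reverse cumulative minimum within each sign (most
extreme first), so q never increases with |NES|.

Sets are restricted to ranked-list members with an inclusive minimum size
of 10 and no maximum cap; a restricted set covering the *entire* ranked
list carries no information and is skipped by the orchestrator (the
low-level scorer raises on it). Significance filtering is strict on both
thresholds (p < .01 AND q < 0.1).

**Redundancy collapse is a package construction.** The source workflow
reports "nonredundant" sets without stating a criterion. Here: visit
significant sets by |NES| descending and retain a set iff the Jaccard
similarity of its leading edge with every already-retained leading edge is
≤ 0.5. This is deterministic and matches the intuition that sets driven by
the same genes should be reported once, but any specific threshold is a
choice; it is exposed as a parameter.

## Immunoblot concordance

NER D7/D0 = (band/actin at D7) / (band/actin at D0). Direction calls use a
5% flat band around 1 (configurable): the source analysis treats
direction qualitatively, and densitometry ratios within a few percent of
unity should not be called either way. The band is multiplicative — up
above 1.05, down below 1/1.05 — because an additive band would break the
reciprocal-transform invariance of the call near the boundary. A call is concordant/discordant
only when both the NER and the MS fold change fall outside the band;
otherwise ambiguous. The call is invariant under simultaneous reciprocal
transform of both ratios.

## Synthetic cohort generator

The generator emulates the statistical structure of a 7-dog paired FNA
study: 915 proteins, 1–10 peptides each (uniform), log-normal protein
baselines, per-peptide ionization efficiencies, a per-dog multiplicative
offset applied to both timepoints, a true ±2 log2 effect on 5% of proteins
(sign random per protein), log-normal measurement noise, and logistic
detection dropout in ln-abundance at the peptide level. One sample per dog
per timepoint, mirroring the pooled-aspirate design. Ortholog coverage is
514/915 by construction: unmappable accessions break at one of the three
stages (round-robin), and ~20% of surviving hops live in fallback tables
to exercise that path.

No noise magnitudes are published for the emulated study, so the defaults
are realistic label-free values chosen once: peptide CV 0.2, per-dog log2
offset sd 0.25, baseline ln-mean 13.8 / ln-sd 1.5, dropout midpoint 9.5
and slope 1.2 (≈97% overall detection). All are configuration fields, not
constants. Per-dog RNG sub-streams derive from (seed, dog index), so a
dog's data are invariant to the cohort size — partial cohorts reproduce
exactly.

Gene-set fixtures: sizes are drawn log-scale with a squared-uniform
exponent over 10–155, putting the median restricted size near the low
twenties. Sets flagged as enriched are sized to about twice the
same-direction mapped effect-gene pool (clamped to the configured range)
with roughly half their members drawn from that pool — a set labelled
enriched must actually be enriched, and with only a few dozen mapped
effect genes a 150-member "enriched" set would not be. The blot fixture
sets band volumes so the implied NER equals the target's true fold change
times log-normal noise against a constant actin control.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: shared/razor peptides and protein inference,
between-run normalization drift, correlated peptide noise within a
protein, heavy-tailed or missing-not-at-random artifacts beyond the
logistic dropout, interfering co-eluting species, and real ortholog
ambiguity (the fixture chain is one-to-one). Recovery rates measured here
are upper bounds for comparable real cohorts.

## Problem sizes and runtime

Default analyses run at the emulated study scale (7 dogs, 915 proteins,
50 gene sets, 1000 permutations), which completes in seconds; the type-I
study uses 2000 proteins. The test suite and the acceptance script each
finish in about a minute on one CPU.

## Known limitations

- The t-test stands in for an undocumented vendor procedure; with 1-peptide
  proteins no p-value exists, capping cohort sensitivity.
- FDR q at small set counts is coarse (pool granularity 1/(n_sets·n_perm)).
- The redundancy-collapse criterion is a construction of this package (see
  above).
- Mapping assumes acyclic, namespace-ordered tables; it does not detect
  chains that loop.
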