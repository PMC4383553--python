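# Methods

## The procedure

`retromod` models a genetic-modifier screen over intronic IAP (LTR
retroelement) insertions. The pipeline runs in the order the analysis would
run on real data:

1. **Census.** A genome is scanned with a panel of 35-bp seed sequences; all
   windows on either strand within a Hamming-distance budget are reported,
   same-strand hits within `max_gap` (default 2000 bp) are chained into
   candidate elements, and a simplified RepeatMasker-style table can be
   merged in (elements with ≥50% reciprocal overlap collapse to their union
   interval). Elements fully inside an intron are oriented sense/antisense
   against the host gene; exon-overlapping elements are flagged
   non-intronic and removed by curation, as are elements lying between
   annotated duplicate gene copies. The census statistic is a 2×2
   orientation × size table (default cut 1 kb) with a two-sided Fisher's
   exact p (minimum-likelihood definition, which is what reproduces the
   published 7.3×10⁻⁴ on the 210/323 vs 525/969 census).
2. **Classification.** Each element is mapped onto a full-length consensus
   divided into LTR, seg2, gag, prt, pol, seg6, RTE and ppt segments, and
   classified by a fixed cascade: solo LTR (non-LTR coverage < 5%), full
   length (length > 7000 bp and every segment ≥ 95% covered), IΔ1 (single
   deletion matching the canonical IΔ1 interval within ±100 bp), Δpol (pol
   coverage ≤ 0.5 and prt coverage > 0.5), else other. The shared core of a
   set of suppressed elements is the intersection of their covered
   intervals.
3. **Quantification.** Technical qPCR replicates are averaged on the Cq
   scale; NRQ = E^(mean reference Cq − target Cq) with per-cycle efficiency
   E (default 2.0). U/I ratios (uninserted vs inserted strains) use a
   two-tailed Mann-Whitney test on unpaired samples; C/B ratios (suppressing
   vs background genotype) use a one-tailed Wilcoxon signed-rank test on
   littermate-paired log ratios. Point estimates are medians, matching the
   rank tests. q-values are Benjamini-Hochberg within structural classes;
   Fisher's combined probability (χ² with 2k df) merges p-values across
   experiments; heterozygous-edited samples are compared to background
   homozygotes with a one-tailed unpaired test.
4. **Splicing screen.** Per array event and littermate pair,
   r = inclusion/exclusion; the separation score is the mean over pairs of
   log2(r_C/r_B). Events are significant when |score| > 0.5 (≈1.4-fold) and
   BH q < 0.05. Gel-band assays reduce to per-sample two-band ratios and the
   same paired signed-rank machinery.

## The synthetic generator

The generator defines the study conditions under which everything is
tested. A genome is a single random-sequence chromosome carrying `n_genes`
multi-exon genes on both strands (3–5 exons of 100–300 bp, introns
1500–4000 bp, intergenic gaps 2500–6000 bp). The consensus is a random
7500-bp sequence with segment proportions 350/400/2000/900/2900/300/200/100
plus an identical 350-bp 3' LTR copy; it is synthetic by construction — the
pipeline tests logic, not homology to real IAP sequence. Planted elements
are the consensus minus class-defining deletions (IΔ1: 3' half of gag
through prt; Δpol: 60% of pol; solo LTR: everything outside one LTR),
reverse-complemented whole when antisense; no internal rearrangement is
simulated. Insertion leaves total sequence conserved: length after planting
equals before plus the summed element lengths.

Measurements follow qPCR practice: noise is Gaussian on the Cq (log) scale
— lognormal on quantities — with sd 0.4 cycles by default, per-assay
baseline Cq drawn in [18, 28], a per-sample loading offset applied to all
assays (removed exactly by reference normalization), 3 technical replicates,
10 littermate pairs for the paired contrast and 5 animals per strain for
the unpaired one. Planted effects default to the observed ranges (U/I
1.2–1000-fold, C/B 1.1–7.8-fold). Array intensities are lognormal with a
default coefficient of variation of 0.2 and 3 littermate pairs; a planted
separation score tilts the C-genotype inclusion/exclusion ratio by
2^score, so the score is realized exactly at zero noise and in expectation
otherwise. Everything is deterministic given the seed.

What the generator does *not* emulate: sequencing reads, probe-level array
artifacts (including probe-sequence polymorphisms, which in real data
masquerade as separation signal), reference-gene instability, biological
IAP sequence divergence, and between-animal biological variance beyond the
lognormal noise. Passing tests therefore demonstrate correctness of the
statistical and interval machinery under the stated noise model, not
robustness to those real-data failure modes.

## Numerical choices

- **Coordinates** are 0-based half-open internally; GFF3 (1-based
  inclusive) and BED are converted only at file boundaries.
- **Deletion canonicalisation.** A deletion can slide across repeated
  context without changing the derived sequence, so deletion sets are
  left-normalised (maximal left shift, fusing adjacent deletions) exactly
  as VCF indel normalisation does. The generator records planted deletions
  in this canonical form and the mapper normalises recovered gaps the same
  way, making recovered == planted a well-defined equality.
- **Consensus mapping.** Orientation is chosen by unit-cost global edit
  distance (forward preferred on ties — short elements embed as scattered
  subsequences in either orientation, so the distance alone is
  orientation-blind for them). If the edit distance equals the length
  difference the element is a pure deletion derivative and its deletion set
  is recovered exactly by greedy anchored matching (32-bp re-sync anchors,
  validated by reconstructing the element). Otherwise a global alignment
  with affine gaps (match 1, mismatch −3, open −20, extend −0.05) is used;
  the high open cost keeps deletions contiguous unless ≥20 consecutive
  chance matches argue otherwise.
- **Normalization anchoring.** NRQ is computed without a calibrator anchor.
  Anchoring each assay to its minimum Cq (a common software convention)
  rescales every sample by the same per-assay constant, so ratios and tests
  are identical either way, but the anchor-free form is strictly invariant
  to per-sample Cq shifts — the property reference-gene normalization is
  meant to provide.
- **Exact vs approximate rank tests.** Signed-rank p-values are exact
  (conditional sign-flip enumeration, valid with tied magnitudes) up to
  n = 25 and normal-approximated with continuity correction beyond; the
  pooled group-wise test always uses the approximation (pooled n is large
  and tied). Mann-Whitney is exact only without ties, as the unconditional
  exact null assumes a continuous distribution. All-zero paired log ratios
  return p = 1.
- **Degenerate inputs.** Empty Fisher margins yield an undefined p reported
  as missing; constant context features report a missing correlation, never
  0; single-pair array events are left uncalled; samples missing a
  reference assay and saturated gel lanes are excluded with logged
  warnings; p = 0 is rejected by the meta-analysis (callers must floor).
- **Array event p-values** use a paired t-test on per-pair log2 ratios — a
  deliberate substitution for the unpublished array-pipeline statistic,
  flagged in the output (`p_value_method` column). With three pairs a
  zero-variance nonzero shift is treated as maximal evidence.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `max_mismatch` | 0 | bases | exact seed recovery on synthetic data |
| `max_gap` | 2000 | bp | larger than within-element hit spacing, smaller than between-element distances |
| size threshold | 1000 | bp | census cut for the orientation bias test |
| full-length floor | 7000 bp, 95% coverage | — | the >7 kb class with tolerance for alignment edge effects |
| IΔ1 tolerance | ±100 | bp | positional slack around the canonical deletion |
| `efficiency` | 2.0 | fold/cycle | ideal amplification; per-assay values accepted |
| `cq_noise_sd` | 0.4 | cycles | makes 1.2–2-fold effects detectable at n = 10 pairs without being trivial |
| score threshold / q | 0.5 / 0.05 | log2 / prob | ≈1.4-fold isoform-ratio change at controlled FDR |

## Design choices made where the design was open

The canonical IΔ1 interval is a configuration parameter because the
subfamily's exact breakpoints are an empirical matter; the synthetic
default (3' half of gag through prt) must be overridden for real elements.
Ratio point estimates use medians rather than means, consistent with the
rank tests. Both the paired signed-rank and the unpaired rank-sum
conventions exist in the field for paired suppression data; the signed-rank
is the default and the rank-sum is available through the same interface.
Curation is rule-based and logged — judgment calls that cannot be encoded
remain flagged rather than silently dropped. The seed panel is designed
(tiling step 250 bp plus seeds flush against segment boundaries and the
canonical IΔ1 edges) so that derivative elements of every class retain
seeds at their exact ends, which is what makes interval recovery exact.

## Check sizes

The test suite and acceptance script use deliberately small problem sizes:
genomes of 5–12 genes (~80–200 kb), 100 seeded consensus sequences × 5
classes for classifier recovery, 5 genomes × 5 planted elements for scan
recovery, 200 simulation seeds for effect recovery, 2000 replicates for
type-I error, 2000 events for the null call-rate check and 40 seeds for the
false-discovery-proportion check. These sizes give binomial error bars well
inside the asserted bounds.

## Known limitations

Gapped/diverged seed matching is out of scope (the scanner is exact
Hamming); rearranged or inverted elements are not detected by the
deletion-oriented consensus mapper; the array screen starts from
inclusion/exclusion intensities, not probe-level data; curation rules
approximate, but cannot reproduce, expert manual curation; and with three
pairs and the default noise the substitute t-test has limited power, so
genuinely shifted events may stay below the significance conjunction.
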