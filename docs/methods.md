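# Methods

## Signal model and assumptions

A tiling array interrogates the genome with 25-mer probes at roughly
constant spacing (35 bp by default here). For each sample, two channels are
hybridized in duplicate: the methyl-CpG-affinity-captured fraction M and
the total input T. The analysis works entirely on the log2 scale. Per
probe, replicate log2 intensities are averaged within each channel and the
log-ratio is their difference; duplicate averaging is a hard requirement —
a missing replicate is an error, never imputed.

The central assumption is biological: somatic DNA methylation occurs at
CpG dinucleotides, and the affinity capture does not retain CpG-free
fragments. Probes whose surrounding 1000 bp window (centered on the probe
midpoint) holds fewer than 4 CpGs per 1000 bp — strictly fewer — therefore
cannot carry genuine enrichment and are designated **null probes**. Both
the window size and the density cutoff are configurable
(`null_window_bp`, `null_density_threshold`): published descriptions of
this class of null-probe selection vary between ~4/kbp and ~0.5/kbp
equivalents, so the threshold is exposed rather than hard-coded. Null
probes are selected genome-wide by this density rule rather than by naming
specific chromosomal regions, which makes the selection reproducible on
any design. A minimum null-set size (default 500) guards against
configurations that would leave the null model undetermined.

## GC strata

Null-probe log-ratios are binned by the probe's integer G+C count
(0–25 for 25-mers). Per bin: location = median, scale = 1.4826 × MAD.
Bins with fewer than `min_bin_size` (default 200) null probes are merged
with their nearest populated neighbor until the floor is met; GC values
never observed among null probes map to the nearest populated bin. If a
bin's MAD is zero the scale falls back to the bin SD, then to the global
robust scale, then to the global SD (a strictly positive scale is an
invariant). The robust estimators resist contamination by any residual
enrichment that leaks into the null set.

The per-bin median is the **probe effect**; subtracting it from every
probe (by that probe's GC count) gives the adjusted log-ratio. Because the
probe effect is a deterministic function of GC content, and local GC
composition varies smoothly along chromosomes, this single subtraction
both centers unmethylated signal at zero and removes the positional
autocorrelation of the raw track — a property the test suite checks
directly on simulated data with a strong planted GC effect.

## Smoothing and Z-scores

The adjusted track is smoothed with a centered running median over k = 7
consecutive probes on the same chromosome (k must be odd; at chromosome
ends the window shrinks symmetrically so the estimator stays centered and
no probe is dropped; windows never cross chromosome boundaries). At 35 bp
tiling, 7 probes ≈ 250 bp, the modal fragment length, so the window
matches the physical footprint of a captured fragment.

The probe Z-score is

    z_i = (smoothed_i − m_g(i)) / s_g(i)

where the strata are re-estimated on the **adjusted, pre-smoothing** track
(their medians are zero there by construction, so no baseline is
subtracted twice) and s_g is the unsmoothed per-bin robust SD. Measuring
the smoothed value in unsmoothed-SD units is a deliberate choice: the
running median shrinks the null spread by roughly half, so a smoothed
value three raw SDs from zero requires several concordant probes and is
far stronger evidence than one noisy probe. Standardizing by the smoothed
scale instead would let the correlation introduced by overlapping
smoothing windows turn isolated noise excursions into seed clusters, and
the replicate-input FDR (below) degrades by an order of magnitude — the
package's simulations show ~14% versus ~0% under the spec conditions.
Under this scaling the nominal standard-normal tail bound for the region
threshold (P(Z > 4) < 3.2e-5) is conservative.

## Region calling

Probes with Z > 3 (strict) are seeds. Consecutive seeds whose start-to-
start distance is < 250 bp (strict) chain into a segment spanning from the
first seed's start to the last seed's end. The segment's **additive Z**
sums z over *all* probes in the span, not only seeds (`sum_seeds_only`
gives the alternative reading); segments with additive Z > 4 are called
and ranked by additive Z descending, ties broken by (chrom, start). The
all-probes summation is the adopted reconciliation of the two published
phrasings of this statistic (sum "across all probes within 250 bp
windows" versus sum over "the segment"); both are unit-tested against a
brute-force enumeration oracle.

**FDR.** The identical pipeline — null selection, strata, adjustment,
smoothing, Z, calling — is run on log2(T_rep1/T_rep2), which carries no
methylation signal. Every region called there is a false discovery;
FDR = null calls / sample calls. Null-side calls are counted without a
length filter. The denominator is per-sample (one FDR per sample).

**Differential calls.** Regions called in either of two samples are
union-merged (strict overlap; abutting intervals stay separate). For each
merged interval the additive Z is recomputed over the spanned probes in
each sample; the interval is a differential call when Z > 4 in one sample,
Z < 1 in the other, and the interval length exceeds 500 bp (all strict).
These criteria are intentionally stringent — on simulated two-sample data
with 30 planted sample-A-only regions, typically under half pass the
Z < 1 filter, because the additive Z of a ~25-probe span of pure noise has
a spread of several units. Every call that is emitted, however, overlaps a
planted differential interval with the correct direction.

**Cutoff sensitivity.** `cutoff_sensitivity` re-calls regions over a grid
of seed thresholds (e.g. 3 vs 2.57, the standard-normal 99.5th percentile)
and counts regions longer than 200 bp that overlap no reference-cutoff
region; on simulated data the new-region fraction at 2.57 stays below
10%, so calling is insensitive to the seed cutoff in the neighborhood of
the default.

## Annotation and enrichment

Five compartments are derived from gene models: strand-oriented 2 kbp
upstream and downstream windows, exons, introns, and intergenic space.
A region's label is the compartment with the largest bp overlap, with
precedence upstream > downstream > exon > intron on exact ties. A region
overlapping no compartment is intergenic only if it lies more than 3 kbp
from every gene; a gene-proximal region with no window overlap takes the
nearest-side label by the nearest gene's strand (the published tooling
this mirrors does not document its tie rules; ours are deterministic and
stated here). The 2 kbp window and 3 kbp proximity scales are independent,
deliberately, and both configurable.

Overlap statistics: summed bp overlap with an interval track; count of
regions touching the track; CpG dinucleotides per kbp of region sequence;
and bp overlapping conservation-score intervals with score strictly
greater than 0.8.

**Matched random sets.** Each of Q (default 500) random sets reproduces
the observed multiset of region lengths, placed in rank order by rejection
sampling: proposals are uniform over probe starts; a placement is accepted
if the interval is fully covered by probes with no inter-probe gap above
250 bp (the array-coverage criterion) and overlaps no region already
placed in that set; 10,000 retries per region before erroring. The
enrichment p-value is N(random > observed)/Q with strict inequality, so
ties favor significance — at Q = 500 the smallest resolvable nonzero p is
0.002, and p = 0 means "beyond all 500 randoms".

**Intron metagene profile.** Each intron in a length class (short:
[842, 2715) bp; long: [2715, 11673] bp — the half-open short class
resolves the boundary duplication at 2715) is rescaled to 0–100% of its
length, oriented in the direction of transcription. Probe values are
averaged per bin within each intron, then across introns, so long,
probe-dense introns do not dominate the profile. Junction overlap counts a
region once if it covers at least one internal exon boundary.

## The synthetic-data generator

`simulate` emulates what the analysis must survive, not sequencing-level
realism:

- **Sequence.** Per-base draws with a slowly varying GC probability
  (sinusoid, default mean 0.40 ± 0.06 over 60 kb); CG dinucleotides are
  thinned to ~2/kbp in the background (a CpG desert, so most of the array
  is null-eligible) and ~25/kbp inside islands (GC 0.55). Window CpG
  counts are therefore Poisson-like: background windows straddling the
  4/kbp threshold are expected and simply drop out of the null set.
- **Annotations.** 130 islands per Mb-scale chromosome (≈ half at gene
  promoters), 18 multi-exon genes per chromosome with intron lengths
  drawn from the short/long classes above, conservation blocks and TFBS
  over intergenic space.
- **Truth.** Methylation is planted on CpG-dense intervals (islands),
  because a CpG-count-driven capture cannot see methylation where there
  are no CpGs; planting it on CpG-free background would make recovery
  impossible by construction, not by method failure.
- **Arrays.** T = probe affinity (N(10, 0.5), shared across channels and
  replicates) + N(0, 0.3) noise per replicate. M adds a GC-bias term
  (default 0.04 log2 per GC count; 0.16 with short-period GC variation in
  the `biased` scenario, which raises the raw-track lag-1 autocorrelation
  above 0.3) and the enrichment response: a Hill curve in the number of
  methylated CpGs within a 250 bp fragment window centered on the probe
  (floor 0 at zero CpGs, half-saturation at 4 CpGs, Hill coefficient 2,
  ceiling 2.0 log2) — a saturating, monotone response with no signal from
  unmethylated or CpG-free DNA. Fragmentation is otherwise summarized by
  `sample_fragment_lengths`, a gamma model with mode 250 bp, rather than
  explicit restriction-site digestion.
- **Scenarios.** `null` (no methylation), `basic` (two 1 Mb chromosomes,
  ~57,000 probes, 200 planted regions), `biased` (strong GC artifact),
  `differential` (two samples, an A-only subset), `island_enriched`
  (~90% of planted methylation in islands). Everything is a pure function
  of (params, seed); text outputs are byte-identical across runs.

What passing tests on these data do **not** show: robustness to
non-Gaussian intensity noise, dye effects, batch or spatial array
artifacts, repeat-driven cross-hybridization, partial (fractional)
methylation, or copy-number differences between samples — none of which
the generator models. Fractional methylation estimation is explicitly out
of scope.

## Problem sizes and numerical choices

The operating-characteristic checks run on the `basic` study (2 × 1 Mb,
~57k probes, 200 planted regions, noise SD 0.3): replicate-input FDR
evaluates to 0% against 5% claimed, recall and precision of planted
regions are ≥ 0.9 (typically 0.99/1.00), and the island-enrichment p is 0
at Q = 500. Unit tests use 100–300 kb genomes; oracle equality suites use
1,000 random tracks of ≤ 500 probes. The full suite runs in well under a
minute on one CPU.

Degenerate inputs are handled explicitly: constant null tracks fall back
through the scale chain (MAD → bin SD → global robust → global SD → 1.0);
an all-identical replicate pair yields a zero null track and FDR 0; an
empty Z track yields an empty region set (not an error); FDR with zero
called regions is an error, not 0/0. Region coordinates are 0-based
half-open everywhere, and the probe "position" used for gap and merge
logic is the probe start (configurable in principle to the midpoint; the
start is the documented default).
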