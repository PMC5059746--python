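# Methods

## The synthetic ZW study

`strataviper.simzw` generates everything a two-individual resequencing study
of a female-heterogametic (ZW) genome produces, at the resolution the
analyses consume, with full ground truth and byte-identical output under a
fixed seed (each product draws from an independent named substream of the
seed).

**Genome layout.** Autosomes and a Z chromosome are tiled into scaffolds
(1 Mb by default). The Z carries evolutionary strata: contiguous blocks that
stopped recombining with the W at different times. The viper-like default is
a 77-Mb Z with boundaries at 42 and 56 Mb and positional layout S2 (0–42 Mb),
S1 (42–56 Mb, oldest), S3 (56–77 Mb, youngest); target Z–W divergences
(p-distance) default to S1 = 0.25, S2 = 0.15, S3 = 0.05, monotone in age
rank rather than chromosome position. An optional pseudoautosomal region
(PAR) occupies the distal `par_fraction` of the Z (0 by default — the
modelled system is almost fully differentiated). Identifiable W-derived
fragments are placed on Z coordinates per stratum with density 0.50 / 0.15 /
0.05 for S3 / S2 / S1 (younger strata retain more alignable W sequence);
fragment lengths are exponential with mean 50 kb, clipped to 5–200 kb, and
placement uses random spacings so the per-stratum coverage is hit exactly.

**Depths.** Window depth (1-kb granularity; all consumers use windowed
statistics) is Poisson with mean `copy_number/2 × mean_depth`:
autosomes diploid in both sexes, Z diploid in males and hemizygous in
females, W female-limited. Both sexes default to 80× — a deliberately
even-handed design; real studies with unequal effort are handled by the
per-sex normalization downstream. Optional `mismap_rate` adds male noise
depth on the W to exercise the <20% male-coverage rule's robustness.

**Variants.** True heterozygous sites arise at `het_auto = 0.1%` per site on
diploid sequence (the commonly observed vertebrate-scale value and the
autosomal rate reported for such studies) and at `het_z_male = 0.08%` on the
male Z (male-biased Z transmission gives it a slightly different diversity
than autosomes); the hemizygous female Z and the single-copy W carry none.
Sequencing error produces apparent heterozygotes at `seq_error = 0.1%` per
site with low qualities (N(40, 15)) while true variants draw N(250, 40), so
the published quality ≥ 100 filter separates them almost perfectly. The
generator makes no attempt to reproduce any particular residual female-Z het
rate — that number conflates error models we do not claim to emulate.
Per-variant depth is Poisson as above. The emitted VCF is 1-based; all
internal coordinates and BED output are 0-based half-open.

**Gametologs.** Each gene is an intact ORF (ATG + non-stop codons + TAA,
1200 bp by default). For a stratum with target p-distance `p`, the Z and W
copies split at age `T = d(p)/2` where `d(p) = −3/4·ln(1 − 4p/3)` (the
Jukes–Cantor distance), and the species split more recently inside each
clade (caterpillar species tree; default three species with splits at
0.008–0.012 substitutions/site, all younger than the youngest stratum —
the shared-strata condition). Sequence evolution is one-step Jukes–Cantor
with the exact expected p-distance `3/4(1 − e^{−4d/3})`; substitutions that
would create an internal in-frame stop are reverted and the start/terminal
codons are frozen, modelling purifying selection on intact reading frames —
without this, neutral mutation at p ≈ 0.2 would pseudogenize nearly every W
copy by accident and a zero-disruption-rate control would be impossible.
W copies then acquire `Poisson(rate × p)` deliberate disruptions
(`w_disruption_rate = 4` per unit divergence, giving a realistic ~40–50%
pseudogene fraction at the default divergences), each with equal probability
a single-base deletion (frameshift, rendered as an alignment gap) or a stop
substitution, at distinct interior codons; types and Z positions are
recorded as ground truth.

**Intergenic Z/W alignments** (the divergence-track input) are one ungapped
pair per W fragment, capped at 2 kb, with per-site difference probability
equal to the stratum target, anchored at the fragment's Z interval.

**Repeats.** Gypsy (and half-density CR1) intervals are placed with density
0.35 / 0.15 / 0.08 and divergence-from-consensus N(0.18 / 0.10 / 0.06, 0.03)
for S1 / S2 / S3; autosomes and PAR get the youngest-stratum baseline. This
encodes the expectation that the longest-suppressed stratum accumulates the
most, and the most diverged, TEs.

**K-mer spectrum.** With per-base error `e` and k = 17, a fraction
`1 − (1−e)^k` of k-mer instances is corrupted; the genomic peak is Poisson
at the correspondingly reduced effective depth and the corrupted instances
form a near-singleton error spike, conserving total instances ≈ G × depth.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: mapping bias and mismapping structure beyond
a flat noise term, GC- or repeat-dependent coverage, indel/SV variation,
within-individual recombination, codon-usage or selection heterogeneity
among sites, assembly fragmentation correlated with repeat content, and any
specific error-quality calibration. Results on real data depend on the
upstream mapping and calling pipeline matching the published filters.

## Analysis choices

**Scaled M:F ratio.** `R = (d_M/norm_M)/(d_F/norm_F)` with per-sex autosomal
median depth as the norm, so autosomes expect 1 and fully sex-linked Z
scaffolds expect 2 under any sequencing-effort imbalance. Normalization is
two-pass: pass 1 finds provisionally autosomal scaffolds with no norm at
all — after setting aside W-like scaffolds by the coverage-fraction rule,
raw M:F depth ratios cluster at the effort ratio (autosomes) and twice it
(Z), so scaffolds within the AUTO tolerance of the lower-quartile ratio are
provisionally autosomal; pass 2 takes each sex's median depth over that set.
A plain overall-median pass 1 silently fails whenever sex-linked scaffolds
make up half or more of the input, which is exactly the regime a
sex-chromosome study cares about. The assumption is only that ≥ ~25% of
eligible scaffolds are autosomal. The AUTO window [0.8, 1.2] mirrors the
published ±20% Z tolerance; Z-window boundaries are inclusive. The W rule is
evaluated before the length/coverage eligibility filter because W scaffolds
fail male coverage by construction.

**K-mer peak.** The error cutoff is the first local minimum of the 3-bin
smoothed spectrum (first strict rise scanning upward); if the spectrum opens
flat or rising there is no error spike and the cutoff is the lowest bin. The
peak is located as the smoothed argmax above the cutoff, then refined to the
rounded count-weighted mean depth within ±50% of the argmax — the *expected*
depth of the main peak. A raw argmax is a coin flip between λ−1 and λ for a
Poisson-shaped peak with near-integer rate and would alone inject a ~1/λ
relative bias into G. Ties resolve to the lower depth. `K_num` counts only
instances above the cutoff: including the error spike inflates G.

**Heterozygosity.** Callable sites (the rate denominator) are sites whose
depth lies in the same [10, 120] bounds as the variant filter — scaffold
length would deflate rates wherever coverage fails the filters. All filter
bounds are inclusive and configurable. The signed-rank pairing unit is 1-Mb
windows. Zero differences are excluded (Wilcoxon's original rule); the null
is exact (DP convolution over sign assignments, mid-ranks doubled to
integers) for n ≤ 25 and a tie-corrected normal approximation with
continuity correction beyond.

**Segmentation.** Tracks are z-scored so each contributes equally (weights
configurable); NaN windows are imputed from the nearest informative window
for segmentation only, never for reporting. Breakpoint count defaults to
k = 2 (a three-stratum model) and can instead be selected by a BIC-style
penalty (`2·n_tracks·ln n` per breakpoint). Binary segmentation is the
default; the exact O(k·n²) dynamic program serves as an oracle for ≤ ~200
windows. Greedy binary segmentation can land one window off the exact
optimum on noisy boundaries and can miss narrow "bump" segments whose width
is small relative to their neighbours — strata tens of windows wide, as
here, are safely in its regime; use `method="dp"` when in doubt at small n.
Divergence defaults to p-distance (K2P optional). PAR labelling uses a
depth-ratio band of [0.8, 1.2] around 1; remaining segments rank S1, S2, …
by mean divergence descending, and an all-NaN segment is UNRANKED.

**ORF scanning.** The Z partner must itself be an intact ORF. Frameshifts
are maximal indel runs whose net length is not divisible by 3 (each changes
the reading-frame offset); the cumulative offset is tracked so a
multiple-of-3 indel never flags anything downstream. Premature stops are
read off the W sequence at each Z codon's alignment columns — the Z reading
frame — before the terminal codon, skipping gapped codons. Positions are
0-based Z CDS coordinates. Alignment cleaning removes every column with a
gap or ambiguity in any sequence (a stricter stand-in for the usual
block-filtering tools) and pairs with ≤ 300 bp left are set aside, not
errored.

**Trees.** Neighbor joining with negative branch lengths clamped to zero
and deterministic tie-breaking by taxon-name order (so topology is
input-order invariant); distances use pairwise deletion on cleaned columns.
The chromosome-clustering test asks whether the Z-tip set is edge-separable
on the unrooted tree (`by_chromosome`), or every species' {Z, W} pair is
(`by_species`), else `unresolved`. NJ suffices here because the decision
surface is monophyly at simulated divergence scales, not branch support.

## Problem sizes and tolerances

The default test suite and the acceptance script run at desk scale by
design: a 7.7-Mb Z "small" preset for unit/integration work, the full 77-Mb
Z preset (tracks only, 1-Mb windows) for strata recovery, 100 + 100 × 1 Mb
scaffolds for the ratio contract, and 10 Mb per sex for heterozygosity
recovery. Stochastic contracts are checked at 3 standard errors of their
estimator; divergence calibration at ±20% of target over ≥20 genes of
≥900 bp; genome-size recovery at ±2%. All randomness flows from explicit
seeds.

## Known limitations

- The W-fragment densities, repeat densities and disruption rate are
  plausible round numbers chosen once, not fitted to any dataset.
- Binary segmentation is greedy (see above); the DP oracle is quadratic and
  not meant for chromosome-scale window counts.
- K2P saturates (raises) at high divergence; p-distance is the default
  everywhere for that reason.
- The pipeline's track stage takes W-fragment anchors and scaffold
  placements from ground truth; on real data these come from homology
  mapping, which is out of scope.
- Scaffold FASTA sequences in the bundle are random and carry no homology
  signal; they exist to exercise I/O and pseudo-chromosome construction.
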