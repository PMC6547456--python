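# Methods

`oriturn` implements a comparative analysis of replication origins mapped by
short-nascent-strand (SNS) sequencing: origin detection from read 5'
positions, base-pair localization of initiation peaks, compositional and
polymorphism signatures around those peaks, background-aware motif
enrichment, and cross-species functional conservation against randomization
nulls. This note records the models, the defaults and why they were chosen,
the numerical conventions, and the limits of what the synthetic-data tests
demonstrate.

## Coordinate and data conventions

All coordinates are 0-based half-open (BED convention), on every type and in
every function. Records from 1-based inclusive sources pass through
`io_formats.from_one_based` exactly once at the parser boundary. Reads are
represented by their 5' position only; fragment extent is not modeled, which
matches the per-window counting the analysis is built on. Homology maps are
simplified to ungapped co-linear segment pairs (equal A/B lengths,
orientation +/-, non-overlapping on the A side); this supports exact
interval mapping at the kb resolution the conservation analysis works at,
without chain/net parsing.

## Origin detection

Reads are counted in fixed windows (default 500 bp, the resolution at which
SNS enrichment is crisp). Windows with less than half their bases mappable
are excluded from testing — the mask gives no per-window rule, so the 50%
threshold is our choice; it only matters for heavily masked genomes.

The null model for window counts is Poisson or negative binomial (NB with
Var = mu + a mu^2), fitted by method of moments on included windows after
discarding the top 1% of counts so origin signal does not inflate the
background. When the trimmed variance does not exceed the mean the model
falls back to Poisson. The per-window expectation scales with the window's
mappable bases. Note a deliberate conservatism: on genomes where origins
occupy more than 1% of windows, the trimmed fit still absorbs some origin
signal into the dispersion, which costs power on weak origins but never
inflates the false-discovery proportion — the direction of error we prefer.

"Multiple error rate of 1%" is operationalized as Benjamini–Hochberg FDR
control at alpha = 0.01 across all included windows genome-wide; Bonferroni
is available via `CallerConfig(method="bonferroni")` for users who read the
requirement as family-wise control. Runs of significant windows separated by
at most `merge_gap` (default 1) non-significant windows merge into one
origin whose bounds are the outer window edges.

The SNS peak of an origin is the argmax over integer bp inside the origin of
a Gaussian-kernel density of read 5' positions, bandwidth sqrt(500) ~ 22.4
bp, evaluated with reads up to three bandwidths outside the origin; ties
break leftmost. Intensity is RPKM: reads in the origin per kb per million
mapped reads. Depth equalization across datasets is uniform subsampling
without replacement to a target reads-per-mappable-kb (the comparative
analyses assume 28 reads/kb, and the pipeline equalizes before any
cross-species call).

## Sequence signatures

GC and AT skews are S_GC = (G−C)/(G+C) and S_AT = (A−T)/(A+T), computed on
counts pooled over all anchors per offset bin (default 25 bp over +-2.5 kb).
Pooling rather than per-anchor averaging keeps the estimator stable at low
coverage; it is associative, so batching anchors cannot change the result.
Origins are unoriented and are not flipped. The inversion point is the
linearly interpolated zero crossing between bin midpoints nearest offset 0;
bins with an empty denominator are NaN and skipped.

G-quadruplex motifs follow the pattern G3 N1-7 G3 N1-7 G3 N1-7 G3 (lengths
12–33 bp), scanned on each strand independently with leftmost
non-overlapping greedy-spacer semantics — the convention of standard regex
scanners; a flag switches to one match per start position for users who
want overlap counting. N never matches. Each motif is summarized by its
middle nucleotide, and the anchored G4 profile reports total counts per 5-bp
bin (not per-anchor means), matching how such profiles are usually drawn.

## Polymorphism and the core region

SNPs are polarized (ancestral/derived given as input) and stratified by
derived allele frequency: rare (DAF < 1%) variants track the mutation
process; common (DAF > 10%) variants additionally feel selection and
GC-biased gene conversion. Boundaries are strict; a DAF exactly at a
boundary is intermediate. Mutation classes {G,C}->{A,T}, {A,T}->{G,C} and
GC-conservative separate gBGC (directional) from selection (not).

The core-depletion statistic is the ratio of common-variant density in the
40-bp core ([peak−20, peak+20)) to the density in flanks (100–500 bp each
side; the flank window is configurable because no canonical choice exists).
The 95% CI is a percentile bootstrap (default 1000 resamples, seeded) over
*anchors*, not variants: variant counts within one origin are dependent, so
resampling origins is the unit that respects the dependence structure.

## Background clustering and motif enrichment

Motif enrichment is confounded by compositional heterogeneity (isochores,
CpG islands), so comparisons are made within compositional strata: random
40-bp segments are sampled uniformly on mappable sequence (as many as there
are origin cores), their overlapping 5-mer counts (N-containing windows
skipped) are reduced by NMF to 6 non-negative axes, and k-means (10
restarts, best inertia) groups the loadings into 6 background clusters.
Six axes and six clusters are fixed defaults — the original rule-of-thumb
selection is not reproducible — and both are exposed as parameters. Origin
cores are then assigned by a maximum-a-posteriori rule: spherical Gaussian
per cluster in the reduced space, per-cluster variance estimated from its
members, empirical priors; ties break to the larger prior, then the lower
index. Fold enrichment of a supplied list of short literal motifs (defaults
CG, CCC, GAG, AC; reverse complements included by scanning both strands,
overlaps counted) is computed cluster-wise as core rate / random-segment
rate with a Fisher exact p-value; clusters with <20 random segments are
flagged unstable and zero-rate denominators are flagged degenerate rather
than silently dropped. De-novo motif discovery is out of scope by design:
the contribution is the background-adjusted enrichment logic, not a
rediscovery of a published discovery tool.

## Conservation and turnover

Landscape concentration is a Lorenz-style curve over 100-kb windows tiled
from chromosome starts (last partial window dropped): windows sorted by
read count, cumulative read fraction vs window fraction, with a helper for
"share of reads in the top x% of windows".

Element-level conservation is assessed on the top 25% most active origins
(RPKM >= 75th percentile, ties kept) because detection sensitivity and
cell-type specificity would otherwise confound the comparison. An origin
*overlaps a CGS* if it intersects >= 1 bp of a conserved genomic segment;
it is *functionally conserved* if additionally its mapped interval (clipped
to the CGS with the largest overlap, orientation-aware) intersects >= 1 bp
of an origin called in the sister genome. One bp is the weakest defensible
threshold and is exposed as the place to tighten; by construction the
functionally conserved set is a subset of the CGS-overlapping set, and an
origin conserved via several sister origins counts once.

The random expectation preserves what matters: each of the (default 10)
random sets keeps the per-chromosome origin counts and draws each segment
length uniformly from the observed per-chromosome size distribution, placed
uniformly on mappable sequence. Fold enrichment is observed/mean(random);
its CI treats the observed value as one more draw from the null spread
(se = sd_random * sqrt(1 + 1/n_sets) / mean_random), which calibrates to
~95% coverage under null placement. TSS controls extend each TSS on its 5'
side (strand-aware) by a length resampled from the origin size
distribution, then run through the identical logic.

Homologous SNS profiles map each A-side peak point through the CGS map and
bin sister-genome reads in a 3-kb window (50-bp bins), flipping offsets for
'-' segments; the uniform-coverage expectation is depth x bin. Conservation
score profiles consume a bedGraph track, average per offset bin over
anchors, orientation-flip oriented anchors, and exclude unscored bases from
the means.

## The synthetic study system

`synthetic_data` generates every input the pipeline consumes, with planted,
recoverable effect sizes. Defaults are the study conditions the analyses
assume: 50 origins/Mb (inside the observed 34–84/Mb vertebrate range),
28 reads/kb depth, log-normal origin activities (sigma = 1) so the top
quartile is meaningful, read displacement around the initiation site
truncated-normal with sd 100 bp (the true SNS displacement law is
uncharacterized; only symmetry and unimodality matter for peak recovery,
and the law is exposed in config), skew amplitude 0.2 holding over 2 kb per
side then decaying linearly over 500 bp, a 40-bp core with 25% thinning of
common variants only, and a DAF mixture with rare/intermediate/common
weights 0.762/0.143/0.095 (the 1000-Genomes proportions), each component
drawn inside its class so planted class labels are exact.

The sister genome is a block shuffle: 10-kb blocks of genome A are copied
(randomly oriented) into random positions of a same-size random genome B,
and an exact rounded fraction of the top-quartile origins whose center
lies in a CGS gets a sister origin planted at the homologous position.
Sister-specific origins are placed outside the CGS images, so the planted
conserved fraction is exactly what interval arithmetic can recover — a
sharp truth value for calibration. Consequences to keep in mind: B is not
an evolved sequence (no substitutions or indels within CGS), homology is
exact, and accidental overlap between random sister origins and mapped
intervals is excluded by construction. Real data would add alignment error
and background coincidence on top of the logic tested here.

Passing the synthetic recovery tests therefore shows the estimators are
correct and calibrated under the stated generative assumptions — symmetric
unimodal pileups, homogeneous Poisson SNPs, exact homology. They do not
certify robustness to PCR artifacts, mappability-correlated noise,
ancestral-allele mispolarization, or alignment error; those failure modes
are outside the generator by design.

## Problem sizes and determinism

The test suite and the acceptance script run the experiments at desk scale,
chosen as the smallest sizes at which the planted effects are measured with
comfortable margin: 50-Mb single-chromosome genomes for the null
error-rate, concentration and depletion experiments (20, 1 and 100
replicates respectively; ~5000 origins for the depletion coverage study),
~500 origins for peak recovery, 1000 random 200-bp sequences for the G4
oracle, 3000 segments for motif-fold recovery, 2000 origins for
conservation recovery, and a 1.5-Mb system for the byte-determinism check.
Every stochastic stage takes an explicit seed; `SimConfig.seed` fans out to
independent child streams per generator, so regenerating any one artifact
never perturbs the others. Two pipeline runs with the same config and seed
are byte-identical.

## Known limitations

* The caller's power (not its error control) degrades when origins occupy
  well over 1% of windows, via background inflation; raise `trim_fraction`
  if the signal occupancy is known to be high.
* `plant_origins` places centers by greedy rejection under the 3-kb minimum
  spacing; above ~50% packing it refuses rather than distorting the spatial
  distribution.
* The skew generator rewrites local base composition to a symmetric
  quarter-composition baseline inside skew windows; nucleotide-content
  profiles inside +-2.5 kb of planted origins reflect that, not the
  regime composition.
* `concentration_curve.share(x)` interpolates at whole windows; for very
  small window counts the granularity of x is 1/n_windows.
* Variant simulation can place two variants at the same position (it is a
  marginal Poisson process); downstream statistics are count-based and
  unaffected.
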