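# oriturn

Comparative analysis of vertebrate DNA replication origins from
short-nascent-strand (SNS) sequencing: origin calling with controlled error
rate, base-pair localization of initiation peaks, sequence and selection
signatures around the origin core, and cross-species functional
conservation against randomization nulls.

## The problem

SNS-seq maps replication origins genome-wide: λ-exonuclease-resistant
nascent DNA piles up at initiation sites, so origins appear as windows of
significant read enrichment. Comparing origin maps across species (and
cell types) raises questions this package answers quantitatively:

* **Where are the origins, and how precisely?** Scanning 500-bp windows are
  tested against a Poisson/negative-binomial background with the multiple
  error rate controlled at 1% (Benjamini–Hochberg across all tested
  windows; Bonferroni optional). Within each origin the *SNS peak* — the
  argmax of a Gaussian-kernel-smoothed read density, bandwidth √500 ≈ 22.4
  bp — proxies the initiation site; intensity is RPKM (reads per kb per
  million mapped).
* **What does the sequence look like around the initiation site?**
  Nucleotide-content profiles; GC/AT skews, S_GC = (G−C)/(G+C) and
  S_AT = (A−T)/(A+T), which invert at the initiation site; and
  G-quadruplex motifs G₃N₁₋₇G₃N₁₋₇G₃N₁₋₇G₃ scanned on both strands.
* **Is the core under selection?** SNPs stratified by derived allele
  frequency (rare < 1% tracks mutation; common > 10% additionally feels
  selection and gBGC) give a core-vs-flank density ratio in the ~40-bp
  window around the peak, with an anchor-level bootstrap CI. Motif
  enrichment in cores is tested within compositionally homogeneous strata
  (5-mer counts → NMF (6 axes) → k-means (6 clusters), cores assigned by a
  MAP rule).
* **Are origins conserved between species?** Top-quartile origins are
  intersected with conserved genomic segments (CGS) and mapped through a
  pairwise homology map; an origin is *functionally conserved* when its
  homologous interval carries an origin in the sister genome. Enrichment is
  measured against 10 random sets preserving per-chromosome counts and
  size distributions.

A first-class synthetic-data module (`oriturn.synthetic_data`) generates
genomes, read tracks, variant tables and homology maps with planted,
recoverable effect sizes, so the entire pipeline is testable end to end
without any downloads.

## Worked example

```python
from oriturn.synthetic_data import (SimConfig, make_genome, plant_origins,
                                    simulate_skew, simulate_reads,
                                    simulate_variants, simulate_homology)
from oriturn import origin_calling as oc, sequence_features as sf
from oriturn import polymorphism as pm, conservation_turnover as ct

cfg = SimConfig(genome_length=10_000_000, seed=7)
genome = make_genome(cfg)
truth = plant_origins(genome, cfg)
genome = simulate_skew(genome, truth, cfg)
reads = simulate_reads(genome, truth, cfg)

caller = oc.OriginCaller(alpha=0.01)
origins = caller.fit_predict(reads, genome)

sgc, _ = sf.skew_profile(origins, genome)
inv = sf.find_skew_inversion(sgc)

variants = pm.classify_variants(simulate_variants(genome, truth, cfg))
dep = pm.core_depletion(origins, variants, freq_class="common", seed=7)

hmap, genome_b, origins_b, _ = simulate_homology(genome, truth, cfg)
top = ct.select_top_quartile(origins)
rep = ct.functional_conservation(top, origins_b, hmap)
base = ct.randomized_baseline(top, genome, hmap, origins_b, seed=7)
```

This prints (via the obvious f-strings):

```
planted 485 origins; depth 36.8 reads/kb
called 305 origins (background: negative-binomial, mean 15.3 reads/window)
GC-skew inversion at -1.7 bp from the SNS peak
common-variant core/flank ratio 0.81 [95% CI 0.32, 1.43]
top-quartile origins: 51.9% in CGS, 14.3% functionally conserved (x55.0 vs random)
```

Reading the numbers: the caller recovers the strong half of the 485
planted origins at this depth (weak origins are below the 1%-controlled
detection limit); the skew inversion localizes the initiation site to
within ~2 bp of the called peak; the common-variant core ratio is
consistent with the planted 25% depletion (the CI is wide because only a
few hundred origins contribute core variants at this scale); and about
half the strongest origins fall in conserved segments, with conservation
far above the random expectation because the synthetic sister genome
plants its conserved origins at exactly homologous positions.

The same workflow is available from the shell:

```bash
oriturn all --seed 7 --outdir run7          # simulate → call → … → conserve
oriturn call --reads reads.bed --genome g.fa --mask m.bed -o origins.tsv
oriturn conserve --origins-a a.tsv --origins-b b.tsv --map cgs.tsv \
        --genome-a g.fa --random-sets 10 --seed 7
```

`oriturn all` writes a report directory (plain-text BED/TSV/FASTA/JSON
artifacts plus a checksum manifest); two runs with the same seed are
byte-identical, and completed stages are skipped on re-runs.

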