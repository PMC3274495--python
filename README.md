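# metachip

Strand-aware composite ("averaged gene") profiling of two-channel tiling-array
chromatin signal, built around the analysis design used for mapping
co-transcriptional histone marks — H2B monoubiquitylation in budding yeast
being the motivating case — where the immunoprecipitated (IP) channel is
compared against a total-histone control channel so that the log2(IP/control)
ratio measures modification level independent of nucleosome density.

## What it computes

**Normalization.** For probe *i* and replicate *r* with perfect-match
intensities IP<sub>ir</sub> and C<sub>ir</sub>, per-replicate log ratios
log2(IP<sub>ir</sub>/C<sub>ir</sub>) are quantile-normalized across
replicates and averaged:

    value_i = ½ [ log2(IP_i1 / C_i1) + log2(IP_i2 / C_i2) ]

(generalized to the mean over R ≥ 2 replicates). A pairwise helper expresses
one IP/Input ratio relative to a reference locus for qPCR-style validation.

**Averaged gene.** Every gene's 5′ intergenic flank, ORF and 3′ flank are
scaled onto 20 / 40 / 20 bins (bin 1 is always 5′-most in transcription
orientation; a bp at offset *o* in a region of length *L* with *B* bins goes
to bin ⌊o·B/L⌋). Probes are averaged within each bin of each gene, then bin
means are averaged across genes with equal weight, and the profile is
smoothed with a 5-bin moving window. Profiles can be stratified by
transcription-rate class (five classes; the top class is strictly
> 16 mRNA/hour) or ORF-length octile, and summarized per region class
(ORF, intergenic, telomeric windows, rDNA, silent HM loci).

**Exon–intron composites.** Each intron-containing gene is decomposed into
exon1/intron/exon2 units (one per intron, in transcription orientation),
binned 10 / 30 / 40 and concatenated to 80 bins; units are averaged within
genes, then across genes. Smoothing runs per segment, leaving the first and
last two bins of each segment untouched. The same machinery profiles per-bp
nucleosome occupancy (0–100 %), and segment-class occupancy is
length-weighted across genes: Σ len<sub>g</sub>·mean<sub>g</sub> / Σ len<sub>g</sub>.

**Synthetic data.** `metachip.simulate` generates a yeast-like genome
(non-overlapping ORFs, ~5 % with one 5′-proximal intron), probes at 5 bp
spacing with two replicate (IP, control) pairs under multiplicative noise,
and an occupancy track — with every signal feature planted explicitly
(rate- and length-dependent ORF enrichment, intergenic baseline, intron
depletion, a 3′ intron–exon boundary bump, exon/intron occupancy plateaus)
so each downstream stage can be validated against known truth.

## Worked example

```sh
metachip simulate --out data --seed 1
metachip normalize --probes data/probes.tsv --out data/signal.tsv
metachip metagene --track data/signal.tsv --genes data/genes.bed \
    --chrom-sizes data/chrom.sizes --rates data/rates.tsv --by rate --out profiles
```

Or through the library, as in the numbered drivers under `analysis/`
(`01_simulate_data.py` … `04_intron_exon_profiles.py`), which write their
tables to `results/`. Running them prints, for the bundled study design:

```
all 600 genes: ORF mean +0.244 log2, 5' flank -0.498 -> composite_all_genes.tsv
rate-class ORF means (slow -> fast): [-0.0389, 0.1857, 0.3982, 0.6138, 0.9229]  monotone=True
region means: {'genome': 0.096, 'ORF': 0.284, 'intergenic': -0.499, 'telomere': -0.219, 'HM': -0.507, 'rDNA': -0.496}
200 intron-containing genes: exon mean +0.250, intron mean -0.206, depletion 0.455 log2
length-weighted occupancy: {'exon1': 77.742, 'intron': 40.88, 'exon2': 79.882}
```

Read: enrichment is confined to coding regions (ORF mean ≈ +0.28 vs the
planted intergenic baseline −0.5, recovered at −0.499); composite ORF level
rises strictly with transcription-rate class; introns are depleted relative
to their flanking exons; and the length-weighted occupancy recovers the
planted exon (80 %) and intron (40 %) plateaus.

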