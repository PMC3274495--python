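# Methods

## Signal model and normalization

The package analyzes two-channel tiling-array chromatin data in which each
probe carries an immunoprecipitated intensity (IP, the modified-histone
pull-down) and a control intensity (total histone). The quantity of interest
is the per-probe log2(IP/control) ratio, which cancels nucleosome density
and leaves the modification level.

Normalization runs in a fixed order: per-replicate log2(IP/C) ratios are
computed first, the replicate log-ratio columns are quantile-normalized,
and replicates are then averaged arithmetically. Quantile normalization
replaces each column's values by the vector of row means of the
column-sorted matrix, assigned back by within-column rank; tied values
receive the mean of the reference values over their tied ranks, which makes
the operation permutation-invariant. With that tie convention, exact
distribution identity across columns and exact idempotence hold on tie-free
data — the realistic case for continuous fluorescence ratios — and are
asserted there; under ties, equal inputs map to equal outputs instead. An
alternative mode quantile-normalizes raw intensities before forming ratios;
it normalizes within each channel type (IP replicates together, control
replicates together), because normalizing IP and control columns jointly
would erase the IP/control contrast itself. Probes present in only a subset
of replicates are dropped with a logged count, not imputed.

## Coordinates and binning

All coordinates are 0-based half-open; GFF3 input is converted on read.
A region of length L split into B bins assigns the bp at
transcription-oriented offset o to bin ⌊o·B/L⌋, so bin widths differ by at
most one bp and bin 1 is always 5′-most regardless of strand. Probes are
treated as point positions (probe centres); at 5 bp spacing interval
overlap handling would add nothing. When a segment is shorter than its bin
count (yeast first exons can be a single bp), the floor rule still decides
which bins receive probes and the remaining bins are missing (NaN), never
zero; missing bins propagate as gaps through averaging and smoothing.
Minus-strand handling uses the transcription-oriented offset
(end − 1 − pos) rather than reversing bin vectors, which makes
strand symmetry exact: mirroring every coordinate and strand of the genome
reproduces identical profiles (the `mirror_genome` utility exists to assert
this).

## Averaged-gene composites

The default layout is 20 bins of 5′ intergenic flank, 40 of ORF, 20 of 3′
flank. Averaging is two-level: probes → per-gene bin means → unweighted
mean across genes, so every gene contributes equally regardless of length
or probe density (a probe-count-weighted mode exists behind a flag but is
off by default). Intergenic flanks run to the neighbouring gene but are
capped at the 1000 bp nearest the gene (configurable), since uncapped gaps
make flank bins incomparable across genes; the flank of a gene overlapped
by its neighbour is empty. Smoothing uses a 5-bin moving window across the
whole 80-bin profile with the outermost two bins left unsmoothed; windows
skip missing bins.

Region summaries report the mean probe signal per class — whole genome,
ORF (union of gene bodies), intergenic (complement), telomeric windows
(terminal 20 kb of both ends of each chromosome by default; the window is
configurable and the both-ends reading was the design choice), and any
named special regions (rDNA, silent HM loci) supplied in the config. A
probe may count in several classes.

Stratification: transcription-rate classes default to boundaries
(2, 4, 8, 16) mRNA/hour, giving five classes with the top class strictly
above 16 and lower intervals half-open (lo, hi]; genes without a rate are
excluded as undetectable. The exact lower boundaries are a configurable
default, not a claim about any particular dataset. Length classes default
to empirical quantiles (octiles for 8 classes) with class sizes differing
by at most one; fixed boundaries may be supplied. A rate predicate can
pre-filter genes before length classing (e.g. only genes below
16 mRNA/hour).

## Exon–intron composites and occupancy

Each intron yields one exon1/intron/exon2 unit in transcription
orientation; multi-intron genes contribute one unit per intron, averaged
within the gene first so they are not over-weighted. Segments are binned
10/30/40 and concatenated to 80 bins; bin centres sit at the bin midpoints
(bin 3 plots at 2.5). Smoothing is per segment, with the first and last two
bins of each of the three segments left unsmoothed, so segment boundaries
are never blurred. Nucleosome occupancy (percent of molecules bound,
0–100) is profiled by the same machinery using per-bp means, and the
per-segment summary is length-weighted across genes
(Σ len·mean / Σ len), equivalent to pooling all bp of that segment class.

## Synthetic data generator

The generator emulates the structure of the real study system — a small
budding-yeast-like genome — not its sequence. Defaults: 2 chromosomes,
200 genes with log-normal ORF lengths (median ≈ 1.3 kb), log-normal
intergenic gaps (median ≈ 400 bp), 5 % of genes with a single 5′-proximal
intron (short first exon, median ≈ 55 bp; intron median ≈ 200 bp),
log-normal transcription rates (median ≈ 2.7 mRNA/h), probes every 5 bp,
two replicates. Planted signal: intergenic baseline −0.5 log2; ORF level =
baseline + 0.25·log2(1+rate) + 0.15·(ORF kb); introns depleted by
0.5 log2; a Gaussian bump (height 0.3, σ 30 bp) on each 3′ intron–exon
junction. Noise is multiplicative per replicate (σ = 0.2 on the log2
scale, independently on IP and control), so the expected log ratio equals
the planted enrichment exactly. Occupancy has exon/intron plateaus at
80 %/40 % (intergenic 65 %), linear boundary ramps of half-width 10 bp,
additive Gaussian noise (σ = 8) clipped to [0, 100]. Gene-free rDNA and HM
intervals are appended past the last gene of the first and last
chromosome. One seed drives per-stage child streams, so a bundle is
bit-reproducible and later stages never perturb earlier draws.

What the generator does not emulate: hybridization chemistry, probe GC or
cross-hybridization bias, replicate-specific distortions that quantile
normalization exists to fix (replicates differ only by i.i.d. noise), real
gene-structure correlations (rate–length coupling, intron-rich ribosomal
protein genes as a class), and spatial autocorrelation of occupancy.
Passing recovery tests therefore demonstrates correctness of the
computation under the planted model, not robustness to array artefacts.

## Validation design

Exact (1e-9) recovery is asserted in the noise-free limit with a single
constant planted ORF level (rate spread, length slope, boundary bump,
occupancy ramp and all noise off), where every composite bin has a known
value. Parameter recovery under noise uses 200 intron-containing genes with
the bump off so the measured exon-minus-intron difference isolates the
planted 0.5 log2 depletion; the occupancy check keeps the default ramp and
noise (the ramp biases the weighted intron mean upward by under one point
at the default geometry). Monotone stratification is checked on two
dedicated simulations of 300 genes, isolating the rate effect (length
slope 0) and the length effect (rate slope 0) — with both slopes active the
secondary covariate adds random class-level variation that an ordering
assertion on modest gene numbers would conflate with failure. The
bin-allocation rule is compared against an independent brute-force oracle
(bin b holds offsets in [⌈bL/B⌉, ⌈(b+1)L/B⌉)) over every interval length up
to 1000 and every bin count up to 80.

The bundled analyses (`analysis/01`–`04`) run two study arms: a
genome-wide arm (600 genes, 4 chromosomes, realistic 5 % intron frequency)
for averaged-gene profiling and stratification, and an intron-focused arm
(200 intron-containing genes) for the exon–intron analyses, mirroring a
design that pools all intron-containing genes. Problem sizes were chosen
so class occupancy and per-bin gene counts are adequate at desk scale.

## Degenerate inputs and numerical choices

Empty gene lists, zero-length segments on one side of an overlapped gene,
classes with no members, bins with no probes, windows longer than the
profile, single-replicate normalization, and intronless genes in the unit
decomposition all have defined non-crashing behaviour (error, warning, or
empty/missing output as documented per function). Equal-length genes
collapse into one length class with a warning. The smoothing window must
be odd. Composite equality across strata is tested to 1e-12 where
summation order may differ (floating-point non-associativity), and exactly
where it cannot.

## Limitations

The pipeline consumes extracted perfect-match probe intensities; probe-level
signal extraction from raw arrays is upstream and out of scope, as are
background correction and dye-bias modelling. The "gene" is the ORF — no
UTRs or isoforms. Group membership lists (e.g. ribosomal-protein genes) are
inputs, not inferred. Statistical testing of profile differences and peak
calling are out of scope; the composites are descriptive.
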