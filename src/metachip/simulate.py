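"""Synthetic tiling-array study generator with planted ground truth.

Emulates the structure of a two-channel high-resolution tiling-array
chromatin experiment on a small budding-yeast-like genome: non-overlapping
ORFs separated by intergenic gaps, a minority of genes carrying a single
5'-proximal intron, probes every few bp, two replicate (IP, control)
intensity pairs with multiplicative noise, and a per-bp nucleosome
occupancy track. Every signal feature downstream stages are meant to
detect is planted explicitly:

* ORF enrichment rises with log-transcription-rate and with ORF length;
* intergenic baseline is a constant log2 level;
* introns are depleted relative to flanking exons by a fixed log2 delta;
* a Gaussian bump sits on each 3' intron-exon boundary;
* occupancy expectation differs between exons and introns.

All draws come from per-stage child streams of one seed, so the same seed
reproduces the bundle bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    GenomeLayout,
    write_chrom_sizes,
    write_gene_annotation,
    write_rate_table,
)
from .intron_exon import OccupancyTrack
from .normalize import write_probe_table


@dataclass
class SimulationParams:
    """Knobs of the synthetic study; defaults approximate the real system.

    Gene lengths and transcription rates are log-normal (lognormal params
    are given on the natural-log scale). About 5% of budding-yeast genes
    carry an intron, almost always a single 5'-proximal one with a short
    first exon; defaults mirror that. Probe spacing defaults to the
    array's 5 bp resolution. Enrichment slopes are planted log2 units per
    log2(1+rate) and per kb of ORF. Noise is per-replicate multiplicative
    (log-normal on intensities), so the expected log2(IP/control) equals
    the planted enrichment.
    """

    n_chroms: int = 2
    n_genes: int = 200
    gene_length_meanlog: float = 7.2   # ~1340 bp median ORF
    gene_length_sdlog: float = 0.45
    min_gene_length: int = 300
    fraction_intron_containing: float = 0.05
    intron_length_meanlog: float = 5.3  # ~200 bp median intron
    intron_length_sdlog: float = 0.4
    min_intron_length: int = 50
    exon1_meanlog: float = 4.0          # short 5'-proximal first exon (~55 bp)
    exon1_sdlog: float = 0.6
    min_exon1_length: int = 1
    intergenic_gap_meanlog: float = 6.0  # ~400 bp median gap
    intergenic_gap_sdlog: float = 0.4
    min_intergenic_gap: int = 100
    rate_meanlog: float = 1.0           # ~2.7 mRNA/h median
    rate_sdlog: float = 1.2
    probe_spacing: int = 5
    enrichment_slope_rate: float = 0.25   # log2 per log2(1+rate)
    enrichment_slope_length: float = 0.15  # log2 per kb of ORF
    intergenic_baseline: float = -0.5
    intron_exon_delta: float = 0.5
    boundary_bump_height: float = 0.3
    boundary_bump_width: float = 30.0
    occupancy_exon_mean: float = 80.0
    occupancy_intron_mean: float = 40.0
    occupancy_baseline_mean: float = 65.0
    occupancy_transition_bp: int = 10
    occupancy_noise_sd: float = 8.0
    noise_sd: float = 0.2
    control_intensity: float = 100.0
    telomere_pad: int = 500
    seed: int = 0

    def validate(self) -> list[str]:
        issues = []
        if self.probe_spacing < 1:
            issues.append("probe_spacing must be >= 1")
        if not 0 <= self.fraction_intron_containing <= 1:
            issues.append("fraction_intron_containing must be in [0, 1]")
        for name in ("occupancy_exon_mean", "occupancy_intron_mean", "occupancy_baseline_mean"):
            if not 0 <= getattr(self, name) <= 100:
                issues.append(f"{name} must be in [0, 100]")
        if self.noise_sd < 0 or self.occupancy_noise_sd < 0:
            issues.append("noise standard deviations must be >= 0")
        if self.n_genes < 1 or self.n_chroms < 1:
            issues.append("n_genes and n_chroms must be >= 1")
        return issues


def _stage_rng(params: SimulationParams, stage: int) -> np.random.Generator:
    # per-stage child stream: later stages never perturb earlier draws
    return np.random.default_rng(np.random.SeedSequence(params.seed).spawn(stage + 1)[stage])


def simulate_genome(params: SimulationParams) -> tuple[GenomeLayout, list[GeneModel], dict[str, float]]:
    """Lay out non-overlapping genes on small chromosomes; returns layout,
    gene models (rates attached) and the rate table."""
    issues = params.validate()
    if issues:
        raise ValueError("; ".join(issues))
    rng = _stage_rng(params, 0)
    genes: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    per_chrom = [params.n_genes // params.n_chroms] * params.n_chroms
    for k in range(params.n_genes % params.n_chroms):
        per_chrom[k] += 1
    gid = 0
    for c in range(params.n_chroms):
        chrom = f"chr{c + 1}"
        cursor = params.telomere_pad + int(rng.lognormal(params.intergenic_gap_meanlog,
                                                         params.intergenic_gap_sdlog))
        for _ in range(per_chrom[c]):
            gid += 1
            length = max(params.min_gene_length,
                         int(rng.lognormal(params.gene_length_meanlog, params.gene_length_sdlog)))
            strand = "+" if rng.random() < 0.5 else "-"
            has_intron = rng.random() < params.fraction_intron_containing
            start, end = cursor, cursor + length
            if has_intron:
                e1 = max(params.min_exon1_length,
                         int(rng.lognormal(params.exon1_meanlog, params.exon1_sdlog)))
                il = max(params.min_intron_length,
                         int(rng.lognormal(params.intron_length_meanlog, params.intron_length_sdlog)))
                if e1 + il + 50 > length:  # grow the gene rather than lose the intron
                    length = e1 + il + 50
                    end = start + length
                if strand == "+":
                    exons = [(start, start + e1), (start + e1 + il, end)]
                else:  # 5'-proximal means nearest the transcription start (genomic right)
                    exons = [(start, end - e1 - il), (end - e1, end)]
            else:
                exons = [(start, end)]
            genes.append(GeneModel(gene_id=f"g{gid:04d}", chrom=chrom, start=start,
                                   end=end, strand=strand, exons=exons))
            gap = max(params.min_intergenic_gap,
                      int(rng.lognormal(params.intergenic_gap_meanlog, params.intergenic_gap_sdlog)))
            cursor = end + gap
        chrom_sizes[chrom] = cursor + params.telomere_pad
    # gene-free special regions appended past the last gene of chr1 / last chrom
    special: dict[str, list[tuple[str, int, int]]] = {}
    first = "chr1"
    rdna_start = chrom_sizes[first]
    chrom_sizes[first] = rdna_start + 2500
    special["rDNA"] = [(first, rdna_start + 250, rdna_start + 2250)]
    last = f"chr{params.n_chroms}"
    hm_start = chrom_sizes[last]
    chrom_sizes[last] = hm_start + 4000
    special["HM"] = [(last, hm_start + 250, hm_start + 1750),
                     (last, hm_start + 2250, hm_start + 3750)]
    layout = GenomeLayout(chrom_sizes=chrom_sizes, special_regions=special)
    rates = {g.gene_id: float(np.round(rng.lognormal(params.rate_meanlog, params.rate_sdlog), 4))
             for g in genes}
    for g in genes:
        g.transcription_rate = rates[g.gene_id]
    return layout, genes, rates


def true_enrichment(layout: GenomeLayout, genes: list[GeneModel],
                    params: SimulationParams) -> dict[str, np.ndarray]:
    """Planted per-bp log2 enrichment for every chromosome."""
    tracks = {c: np.full(size, params.intergenic_baseline, dtype=float)
              for c, size in layout.chrom_sizes.items()}
    for g in genes:
        arr = tracks[g.chrom]
        level = gene_orf_level(g, params)
        arr[g.start:g.end] = level
        for a, b in g.introns:
            arr[a:b] = level - params.intron_exon_delta
        if params.boundary_bump_height != 0:
            for a, b in g.introns:
                center = b if g.strand == "+" else a  # 3' intron-exon junction
                w = params.boundary_bump_width
                lo = max(0, int(center - 4 * w))
                hi = min(len(arr), int(center + 4 * w) + 1)
                x = np.arange(lo, hi)
                arr[lo:hi] += params.boundary_bump_height * np.exp(
                    -0.5 * ((x - center) / w) ** 2)
    return tracks


def gene_orf_level(gene: GeneModel, params: SimulationParams) -> float:
    """Planted exon-level log2 enrichment of one ORF."""
    rate = gene.transcription_rate or 0.0
    return (params.intergenic_baseline
            + params.enrichment_slope_rate * float(np.log2(1 + rate))
            + params.enrichment_slope_length * (gene.length / 1000.0))


def simulate_probe_arrays(layout: GenomeLayout, genes: list[GeneModel],
                          params: SimulationParams, n_replicates: int = 2) -> pd.DataFrame:
    """Probe table with ``n_replicates`` (IP, control) pairs at every
    ``probe_spacing`` bp; E[log2(IP/C)] equals the planted enrichment."""
    rng = _stage_rng(params, 1)
    truth = true_enrichment(layout, genes, params)
    rows = {"chrom": [], "pos": []}
    true_vals = []
    for chrom in layout.chrom_sizes:
        pos = np.arange(0, layout.chrom_sizes[chrom], params.probe_spacing)
        rows["chrom"].append(np.repeat(chrom, len(pos)))
        rows["pos"].append(pos)
        true_vals.append(truth[chrom][pos])
    chroms = np.concatenate(rows["chrom"])
    positions = np.concatenate(rows["pos"])
    true_vals = np.concatenate(true_vals)
    table = {"chrom": chroms, "pos": positions}
    base = np.log2(params.control_intensity)
    for r in range(1, n_replicates + 1):
        eps_ip = rng.normal(0.0, params.noise_sd, len(positions))
        eps_c = rng.normal(0.0, params.noise_sd, len(positions))
        table[f"IP_{r}"] = 2.0 ** (base + true_vals + eps_ip)
        table[f"C_{r}"] = 2.0 ** (base + eps_c)
    df = pd.DataFrame(table)
    # interleave IP_r/C_r pairs for readability
    cols = ["chrom", "pos"] + [c for r in range(1, n_replicates + 1) for c in (f"IP_{r}", f"C_{r}")]
    return df[cols]


def simulate_occupancy_track(layout: GenomeLayout, genes: list[GeneModel],
                             params: SimulationParams) -> OccupancyTrack:
    """Per-bp occupancy: exon/intron plateaus with linear boundary ramps,
    additive Gaussian noise, clipped to [0, 100]."""
    rng = _stage_rng(params, 2)
    data = {}
    for chrom, size in layout.chrom_sizes.items():
        expect = np.full(size, params.occupancy_baseline_mean, dtype=float)
        data[chrom] = expect
    for g in genes:
        expect = data[g.chrom]
        expect[g.start:g.end] = params.occupancy_exon_mean
        for a, b in g.introns:
            expect[a:b] = params.occupancy_intron_mean
    t = params.occupancy_transition_bp
    if t > 0:
        # moving-average ramp of width 2t+1 smooths every plateau boundary
        kernel = np.ones(2 * t + 1) / (2 * t + 1)
        for chrom in data:
            data[chrom] = np.convolve(np.pad(data[chrom], t, mode="edge"), kernel, mode="valid")
    for chrom in data:
        if params.occupancy_noise_sd > 0:
            data[chrom] = data[chrom] + rng.normal(0.0, params.occupancy_noise_sd, len(data[chrom]))
        np.clip(data[chrom], 0.0, 100.0, out=data[chrom])
    return OccupancyTrack(data)


def mirror_genome(layout: GenomeLayout, genes: list[GeneModel], track: "pd.DataFrame"):
    """Reverse every coordinate and strand of a genome and its signal track.

    Validation utility: composite profiling is strand-aware, so mirroring
    the whole genome must leave every profile unchanged.
    """
    sizes = layout.chrom_sizes
    mirrored_genes = []
    for g in genes:
        size = sizes[g.chrom]
        exons = sorted((size - b, size - a) for a, b in g.exons)
        mirrored_genes.append(GeneModel(g.gene_id, g.chrom, size - g.end, size - g.start,
                                        "-" if g.strand == "+" else "+", exons=exons,
                                        transcription_rate=g.transcription_rate))
    mirrored_track = track.copy()
    mirrored_track["pos"] = [sizes[c] - 1 - p for c, p in zip(track["chrom"], track["pos"])]
    return GenomeLayout(chrom_sizes=dict(sizes)), mirrored_genes, mirrored_track


def simulate_bundle(params: SimulationParams, out_dir: str | Path | None = None):
    """Run all three stages; optionally write the standard file bundle.

    Writes: genes.bed (BED12), chrom.sizes, rates.tsv, probes.tsv,
    occupancy.bedgraph, special_regions.yaml — the same formats the
    readers consume.
    """
    layout, genes, rates = simulate_genome(params)
    probes = simulate_probe_arrays(layout, genes, params)
    occupancy = simulate_occupancy_track(layout, genes, params)
    if out_dir is not None:
        import yaml

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_gene_annotation(genes, out / "genes.bed", format="bed12")
        write_chrom_sizes(layout.chrom_sizes, out / "chrom.sizes")
        write_rate_table(rates, out / "rates.tsv")
        write_probe_table(probes, out / "probes.tsv")
        occupancy.to_bedgraph(out / "occupancy.bedgraph")
        with open(out / "special_regions.yaml", "w") as fh:
            yaml.safe_dump({name: [list(r) for r in regions]
                            for name, regions in layout.special_regions.items()}, fh)
    return layout, genes, rates, probes, occupancy
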