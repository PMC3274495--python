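"""Exon1-intron-exon2 composite profiles and length-weighted occupancy.

Intron-containing genes are decomposed into exon1/intron/exon2 units in
transcription orientation (one unit per intron), each unit's segments are
binned independently onto a 10/30/40 layout and concatenated into an
80-bin vector, units are averaged within genes and then genes averaged
with equal weight. Smoothing (window 5) is applied per segment, leaving
the first two and last two bins of each of exon1, intron and exon2
unsmoothed. The same machinery runs on per-bp nucleosome-occupancy tracks
in place of probe signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, Interval
from .metagene import CompositeProfile, TrackIndex, bin_region, smooth_per_segment

logger = logging.getLogger(__name__)

DEFAULT_UNIT_LAYOUT: tuple[tuple[str, int], ...] = (("exon1", 10), ("intron", 30), ("exon2", 40))


@dataclass
class ExonIntronUnit:
    """One exon1/intron/exon2 triple of a gene, in transcription orientation.

    Intervals are genomic (0-based half-open); for a minus-strand gene
    exon1 is the genomically rightmost of the three.
    """

    gene_id: str
    chrom: str
    strand: str
    exon1: Interval
    intron: Interval
    exon2: Interval
    unit_index: int = 0

    def segment(self, name: str) -> Interval:
        return {"exon1": self.exon1, "intron": self.intron, "exon2": self.exon2}[name]


class OccupancyTrack:
    """Per-bp nucleosome occupancy in percent (0-100), one array per chromosome."""

    def __init__(self, data: dict[str, np.ndarray]):
        self.data = {c: np.asarray(v, dtype=float) for c, v in data.items()}
        for chrom, arr in self.data.items():
            if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 100):
                raise ValueError(f"occupancy on {chrom} outside [0, 100]")

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.data[chrom][start:end]

    def to_bedgraph(self, path: str | Path) -> None:
        """Write run-length-merged bedGraph (adjacent equal values collapsed)."""
        with open(path, "w") as fh:
            for chrom, arr in self.data.items():
                if not arr.size:
                    continue
                breaks = np.flatnonzero(np.diff(arr) != 0) + 1
                starts = np.r_[0, breaks]
                ends = np.r_[breaks, len(arr)]
                for a, b in zip(starts, ends):
                    fh.write(f"{chrom}\t{a}\t{b}\t{arr[a]:.4f}\n")

    @classmethod
    def from_bedgraph(cls, path: str | Path, chrom_sizes: dict[str, int]) -> "OccupancyTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
        data = {c: np.full(size, np.nan) for c, size in chrom_sizes.items()}
        for row in df.itertuples(index=False):
            data[row.chrom][row.start:row.end] = row.value
        return cls(data)


def exon_intron_units(gene: GeneModel) -> list[ExonIntronUnit]:
    """One unit per intron: (exon k, intron k, exon k+1) in transcription order.

    Intronless genes yield an empty list. For multi-intron genes the units
    overlap in their shared exons, mirroring alignment by each intron.
    """
    if gene.n_introns == 0:
        return []
    exons = list(gene.exons)
    introns = gene.introns
    if gene.strand == "-":
        exons = exons[::-1]
        introns = introns[::-1]
    return [
        ExonIntronUnit(gene_id=gene.gene_id, chrom=gene.chrom, strand=gene.strand,
                       exon1=exons[k], intron=introns[k], exon2=exons[k + 1], unit_index=k)
        for k in range(len(introns))
    ]


def _unit_vector(unit: ExonIntronUnit, index: TrackIndex,
                 layout: tuple[tuple[str, int], ...]) -> np.ndarray:
    parts = [bin_region(unit.segment(name), unit.strand, n_bins, index, unit.chrom,
                        allow_short=True)
             for name, n_bins in layout]
    return np.concatenate(parts)


def _composite_over_units(
    gene_unit_vectors: list[np.ndarray],
    layout: tuple[tuple[str, int], ...],
    smooth_window: int | None,
) -> CompositeProfile:
    vectors = np.array(gene_unit_vectors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(vectors, axis=0)
    n_genes = np.sum(~np.isnan(vectors), axis=0)
    profile = CompositeProfile(segments=tuple(layout), values=values, n_genes=n_genes)
    if smooth_window:
        profile.smoothed_values = smooth_per_segment(profile, window=smooth_window)
    return profile


def composite_exon_intron(
    track: pd.DataFrame | TrackIndex,
    genes: Iterable[GeneModel],
    layout: tuple[tuple[str, int], ...] = DEFAULT_UNIT_LAYOUT,
    smooth_window: int | None = 5,
) -> CompositeProfile:
    """Exon1/intron/exon2 composite of probe signal over intron-containing genes.

    Two-level averaging: units are averaged within each gene first (so
    multi-intron genes are not over-weighted), then genes averaged with
    equal weight.
    """
    index = track if isinstance(track, TrackIndex) else TrackIndex(track)
    per_gene = []
    for gene in genes:
        units = exon_intron_units(gene)
        if not units:
            continue
        unit_vecs = np.array([_unit_vector(u, index, layout) for u in units])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_gene.append(np.nanmean(unit_vecs, axis=0))
    if not per_gene:
        raise ValueError("no intron-containing genes")
    return _composite_over_units(per_gene, layout, smooth_window)


def _occupancy_bin_means(unit: ExonIntronUnit, occupancy: OccupancyTrack,
                         layout: tuple[tuple[str, int], ...]) -> np.ndarray:
    parts = []
    for name, n_bins in layout:
        a, b = unit.segment(name)
        vals = occupancy.values(unit.chrom, a, b)
        length = b - a
        offsets = np.arange(length) if unit.strand == "+" else np.arange(length)[::-1]
        bins = (offsets.astype(np.int64) * n_bins) // length
        good = ~np.isnan(vals)
        sums = np.bincount(bins[good], weights=vals[good], minlength=n_bins)
        counts = np.bincount(bins[good], minlength=n_bins)
        parts.append(np.where(counts > 0, sums / np.maximum(counts, 1), np.nan))
    return np.concatenate(parts)


def composite_occupancy(
    occupancy: OccupancyTrack,
    genes: Iterable[GeneModel],
    layout: tuple[tuple[str, int], ...] = DEFAULT_UNIT_LAYOUT,
    smooth_window: int | None = 5,
) -> CompositeProfile:
    """Exon1/intron/exon2 composite of per-bp occupancy (bin mean over bp)."""
    per_gene = []
    for gene in genes:
        units = exon_intron_units(gene)
        if not units:
            continue
        unit_vecs = np.array([_occupancy_bin_means(u, occupancy, layout) for u in units])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_gene.append(np.nanmean(unit_vecs, axis=0))
    if not per_gene:
        raise ValueError("no intron-containing genes")
    return _composite_over_units(per_gene, layout, smooth_window)


def weighted_occupancy(
    occupancy: OccupancyTrack,
    units: Sequence[ExonIntronUnit],
    segment: str,
) -> float:
    """Length-weighted mean occupancy of one segment class over many genes.

    Returns sum(len_g * mean_g) / sum(len_g) over the chosen segment
    (exon1, intron or exon2) of every unit: a segment contributes in
    proportion to its length, which for per-bp data equals pooling all bp.
    """
    if segment not in ("exon1", "intron", "exon2"):
        raise ValueError(f"unknown segment: {segment}")
    if not units:
        raise ValueError("no units supplied")
    total_len = 0
    total_sum = 0.0
    for unit in units:
        a, b = unit.segment(segment)
        vals = occupancy.values(unit.chrom, a, b)
        good = vals[~np.isnan(vals)]
        if not good.size:
            continue
        mean = good.mean()
        total_len += b - a
        total_sum += (b - a) * mean
    if total_len == 0:
        raise ValueError(f"zero total length for segment {segment}")
    return float(total_sum / total_len)


def gene_group_split(
    genes: Sequence[GeneModel], group_ids: Iterable[str]
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Partition intron-containing genes into a listed group and its complement.

    Listed ids absent from the annotation are skipped with a warning;
    duplicates in the list are ignored.
    """
    intronic = [g for g in genes if g.n_introns > 0]
    known = {g.gene_id for g in intronic}
    wanted = set()
    for gid in group_ids:
        gid = gid.strip()
        if not gid:
            continue
        if gid not in known:
            logger.warning("group id %s not an intron-containing gene in the annotation; skipped", gid)
            continue
        wanted.add(gid)
    group = [g for g in intronic if g.gene_id in wanted]
    complement = [g for g in intronic if g.gene_id not in wanted]
    return group, complement


def read_group_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]
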