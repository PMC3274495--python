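"""Composite ("averaged gene") profiles, region summaries and stratification.

The averaged gene scales every gene and its flanks onto a fixed bin
layout — by default 20 bins of 5' intergenic flank, 40 bins of ORF and 20
bins of 3' flank — and averages the normalized signal across genes in two
levels: probes are averaged within each bin of each gene first, then the
per-gene bin means are averaged across genes with equal weight, so a long
probe-dense gene counts no more than a short one.

Binning is strand-aware: bin 1 is always 5'-most in transcription
orientation. A bp at transcription-oriented offset o in a region of length
L with B bins goes to bin floor(o*B/L).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeLayout, Interval

logger = logging.getLogger(__name__)

DEFAULT_GENE_LAYOUT: tuple[tuple[str, int], ...] = (
    ("5p_intergenic", 20), ("ORF", 40), ("3p_intergenic", 20))


@dataclass
class CompositeProfile:
    """Binned cross-gene average signal with per-bin contributing-gene counts.

    ``values`` holds one mean per bin (NaN where no gene had data);
    ``n_genes`` counts contributing genes per bin; ``segments`` names the
    bin ranges. Bin centres for plotting sit at the bin mid-points
    (0.5, 1.5, ... on the 0-based bin axis, i.e. bin 3 plots at 2.5).
    """

    segments: tuple[tuple[str, int], ...]
    values: np.ndarray
    n_genes: np.ndarray
    smoothed_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        total = sum(n for _, n in self.segments)
        if len(self.values) != total or len(self.n_genes) != total:
            raise ValueError("values/n_genes length does not match segment layout")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def segment_labels(self) -> np.ndarray:
        return np.array([name for name, n in self.segments for _ in range(n)])

    @property
    def bin_centers(self) -> np.ndarray:
        return np.arange(self.n_bins) + 0.5

    def segment_slice(self, name: str) -> slice:
        start = 0
        for seg, n in self.segments:
            if seg == name:
                return slice(start, start + n)
            start += n
        raise KeyError(name)

    def segment_mean(self, name: str) -> float:
        return float(np.nanmean(self.values[self.segment_slice(name)]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "bin": np.arange(1, self.n_bins + 1),
            "bin_center": self.bin_centers,
            "segment": self.segment_labels,
            "mean": self.values,
            "n_genes": self.n_genes,
        })
        if self.smoothed_values is not None:
            df["smoothed_mean"] = self.smoothed_values
        return df


@dataclass
class RegionSummary:
    """Mean signal per genomic region class (ORF, intergenic, telomere, ...)."""

    means: dict[str, float] = field(default_factory=dict)
    n_probes: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "region": list(self.means),
            "mean": list(self.means.values()),
            "n_probes": [self.n_probes[k] for k in self.means],
        })


class TrackIndex:
    """Per-chromosome sorted position/value arrays for fast interval lookup."""

    def __init__(self, track: pd.DataFrame):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in track.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy(int)
            val = sub["value"].to_numpy(float)
            order = np.argsort(pos, kind="mergesort")
            self.by_chrom[str(chrom)] = (pos[order], val[order])

    def in_interval(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self.by_chrom:
            return np.empty(0, int), np.empty(0, float)
        pos, val = self.by_chrom[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        return pos[lo:hi], val[lo:hi]


def bin_region(
    interval: Interval,
    strand: str,
    n_bins: int,
    track: pd.DataFrame | TrackIndex,
    chrom: str,
    allow_short: bool = False,
    return_counts: bool = False,
):
    """Per-bin probe means over one genomic interval, strand-aware.

    The interval is split into ``n_bins`` contiguous sub-intervals whose bp
    lengths differ by at most one; each probe lands in exactly one bin by
    the floor rule on its transcription-oriented offset. Bins without
    probes are NaN. When ``allow_short`` is set, intervals shorter than the
    bin count are permitted (probes fall in the bins the floor rule
    selects; the rest stay missing) — needed for tiny 5' exons.
    """
    start, end = interval
    length = end - start
    if length < 1 or n_bins < 1:
        raise ValueError("interval length and n_bins must be >= 1")
    if n_bins > length and not allow_short:
        raise ValueError(f"n_bins={n_bins} exceeds interval length {length}")
    index = track if isinstance(track, TrackIndex) else TrackIndex(track)
    pos, val = index.in_interval(chrom, start, end)
    offsets = (pos - start) if strand == "+" else (end - 1 - pos)
    bins = (offsets.astype(np.int64) * n_bins) // length
    sums = np.bincount(bins, weights=val, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return (means, counts) if return_counts else means


def cap_interval(interval: Interval, cap: int | None, proximal: str) -> Interval:
    """Clip an intergenic interval to its ``cap`` bp nearest the gene.

    ``proximal`` says which genomic side touches the gene: "right" for an
    interval ending at the gene, "left" for one starting at it.
    """
    if cap is None:
        return interval
    a, b = interval
    if b - a <= cap:
        return interval
    return (b - cap, b) if proximal == "right" else (a, a + cap)


def _gene_bin_vector(
    gene: GeneModel,
    intergenic: tuple[Interval, Interval],
    index: TrackIndex,
    layout: tuple[tuple[str, int], ...],
    intergenic_cap: int | None,
) -> tuple[np.ndarray, np.ndarray]:
    """One gene's concatenated (bin means, probe counts) in transcription orientation."""
    five, three = intergenic
    # genomic side of the gene that each flank touches, by strand
    if gene.strand == "+":
        five = cap_interval(five, intergenic_cap, proximal="right")
        three = cap_interval(three, intergenic_cap, proximal="left")
    else:
        five = cap_interval(five, intergenic_cap, proximal="left")
        three = cap_interval(three, intergenic_cap, proximal="right")
    segment_intervals = {"5p_intergenic": five, "ORF": (gene.start, gene.end), "3p_intergenic": three}
    parts, count_parts = [], []
    for name, n_bins in layout:
        iv = segment_intervals[name]
        if iv[1] - iv[0] < 1:
            parts.append(np.full(n_bins, np.nan))
            count_parts.append(np.zeros(n_bins, dtype=int))
        else:
            means, counts = bin_region(iv, gene.strand, n_bins, index, gene.chrom,
                                       allow_short=True, return_counts=True)
            parts.append(means)
            count_parts.append(counts)
    return np.concatenate(parts), np.concatenate(count_parts)


def composite_average_gene(
    track: pd.DataFrame | TrackIndex,
    genes: list[GeneModel],
    intergenic: dict[str, tuple[Interval, Interval]],
    layout: tuple[tuple[str, int], ...] = DEFAULT_GENE_LAYOUT,
    intergenic_cap: int | None = 1000,
    smooth_window: int | None = 5,
    weight_by_probe_count: bool = False,
) -> CompositeProfile:
    """Averaged-gene composite: per-gene bin means, then unweighted cross-gene mean.

    Each gene contributes equally regardless of its length or probe count
    (with ``weight_by_probe_count`` genes instead contribute per bin in
    proportion to their probes there — off by default). Intergenic flanks
    are capped at ``intergenic_cap`` bp nearest the gene so megabase gaps
    cannot dominate the flank bins. Smoothing (window 5) runs across the
    whole profile with the outermost two bins on each side left unsmoothed.
    """
    if not genes:
        raise ValueError("no genes to average")
    index = track if isinstance(track, TrackIndex) else TrackIndex(track)
    pairs = [_gene_bin_vector(g, intergenic[g.gene_id], index, layout, intergenic_cap)
             for g in genes]
    vectors = np.array([p[0] for p in pairs])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        if weight_by_probe_count:
            counts = np.array([p[1] for p in pairs])
            weighted = np.where(np.isnan(vectors), 0.0, vectors) * counts
            total = counts.sum(axis=0)
            values = np.where(total > 0, weighted.sum(axis=0) / np.maximum(total, 1), np.nan)
        else:
            values = np.nanmean(vectors, axis=0)
    n_genes = np.sum(~np.isnan(vectors), axis=0)
    profile = CompositeProfile(segments=tuple(layout), values=values, n_genes=n_genes)
    if smooth_window:
        profile.smoothed_values = smooth_moving_window(values, window=smooth_window)
    return profile


def smooth_moving_window(
    values: np.ndarray, window: int = 5, edge_policy: str = "keep_edges"
) -> np.ndarray:
    """Moving-window mean: element i becomes the mean of its window.

    ``edge_policy="keep_edges"`` (default) leaves the first and last
    window//2 elements unsmoothed; ``"shrink"`` averages over whatever part
    of the window is in range. Missing (NaN) values are excluded from each
    window mean; a window of only NaNs stays NaN.
    """
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    n = len(values)
    if window > n:
        warnings.warn("smoothing window exceeds profile length; returned unsmoothed")
        return values.copy()
    half = window // 2
    out = values.copy()
    lo_edge = half if edge_policy == "keep_edges" else 0
    hi_edge = n - half if edge_policy == "keep_edges" else n
    for i in range(lo_edge, hi_edge):
        win = values[max(0, i - half): i + half + 1]
        good = win[~np.isnan(win)]
        out[i] = good.mean() if len(good) else np.nan
    return out


def smooth_per_segment(profile: CompositeProfile, window: int = 5) -> np.ndarray:
    """Smooth each segment independently, keeping the first and last two
    bins of every segment unsmoothed (the exon1/intron/exon2 convention)."""
    out = np.empty_like(profile.values)
    start = 0
    for name, n in profile.segments:
        seg = profile.values[start:start + n]
        out[start:start + n] = smooth_moving_window(seg, window=window, edge_policy="keep_edges")
        start += n
    return out


def region_summary(
    track: pd.DataFrame,
    genes: list[GeneModel],
    layout: GenomeLayout,
    telomere_window: int = 20_000,
) -> RegionSummary:
    """Mean signal by region class: genome, ORF, intergenic, telomere, rDNA, HM.

    The telomere class covers the terminal ``telomere_window`` bp at both
    ends of every chromosome. A probe may contribute to more than one class
    (a telomeric ORF counts in both). Classes with no probes are reported
    as NaN with a warning.
    """
    chrom_arr = track["chrom"].to_numpy()
    pos = track["pos"].to_numpy(int)
    val = track["value"].to_numpy(float)

    def region_mask(regions: list[tuple[str, int, int]]) -> np.ndarray:
        mask = np.zeros(len(pos), dtype=bool)
        for chrom, a, b in regions:
            mask |= (chrom_arr == chrom) & (pos >= a) & (pos < b)
        return mask

    orf_mask = region_mask([(g.chrom, g.start, g.end) for g in genes])
    classes = {
        "genome": np.ones(len(pos), dtype=bool),
        "ORF": orf_mask,
        "intergenic": ~orf_mask,
        "telomere": region_mask(layout.telomere_regions(telomere_window)),
    }
    for name, regions in layout.special_regions.items():
        classes[name] = region_mask(regions)
    summary = RegionSummary()
    for name, mask in classes.items():
        n = int(mask.sum())
        summary.n_probes[name] = n
        if n == 0:
            logger.warning("region class %s has no probes", name)
            summary.means[name] = float("nan")
        else:
            summary.means[name] = float(val[mask].mean())
    return summary


def stratified_profiles(
    track: pd.DataFrame | TrackIndex,
    genes: list[GeneModel],
    class_map: dict[str, str],
    intergenic: dict[str, tuple[Interval, Interval]],
    rate_filter=None,
    class_order: list[str] | None = None,
    **composite_kwargs,
) -> dict[str, CompositeProfile]:
    """One composite profile per gene class, ordered by ``class_order``.

    ``rate_filter`` (a predicate on transcription rate) pre-selects genes
    before classing, reproducing designs like "genes below 16 mRNA/hour,
    split by length". Classes left with no genes are omitted with a warning.
    """
    if not class_map:
        raise ValueError("empty class map")
    index = track if isinstance(track, TrackIndex) else TrackIndex(track)
    selected = [g for g in genes if g.gene_id in class_map]
    if rate_filter is not None:
        selected = [g for g in selected if g.transcription_rate is not None
                    and rate_filter(g.transcription_rate)]
    by_class: dict[str, list[GeneModel]] = {}
    for g in selected:
        by_class.setdefault(class_map[g.gene_id], []).append(g)
    order = class_order if class_order is not None else sorted(by_class)
    out = {}
    for label in order:
        members = by_class.get(label, [])
        if not members:
            logger.warning("class %s has no genes; omitted", label)
            continue
        out[label] = composite_average_gene(index, members, intergenic, **composite_kwargs)
    return out
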