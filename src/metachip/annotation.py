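"""Gene models, genome layout, intergenic derivation and gene classification.

Coordinates are 0-based, half-open throughout the package. GFF3 input
(1-based, inclusive) is converted on read; BED12 is native.

A "gene" here is the coding interval (ORF) with its exon block structure;
introns are the gaps between consecutive exons. Transcription rate, where
known, is attached in mRNA copies per hour and drives the activity
stratification used by the composite profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass
class GeneModel:
    """One gene: ORF coordinates, strand, exon structure, optional rate.

    Exons are stored in genomic order as 0-based half-open intervals,
    non-overlapping, contained in [start, end). Introns are derived as the
    gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[Interval] = field(default_factory=list)
    transcription_rate: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.end < self.start:
            raise AnnotationError(f"gene {self.gene_id}: end < start")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if a < self.start or b > self.end:
                raise AnnotationError(f"gene {self.gene_id}: exon ({a},{b}) outside gene bounds")
            if b <= a:
                raise AnnotationError(f"gene {self.gene_id}: empty exon ({a},{b})")
            if prev_end is not None and a <= prev_end:
                raise AnnotationError(f"gene {self.gene_id}: exons overlap or touch without intron")
            prev_end = b
        if self.exons[0][0] != self.start or self.exons[-1][1] != self.end:
            raise AnnotationError(f"gene {self.gene_id}: exons do not span gene bounds")

    @property
    def length(self) -> int:
        """ORF (coding-region) length in bp, introns included."""
        return self.end - self.start

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, genomic order."""
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass
class GenomeLayout:
    """Chromosome sizes plus named special regions (telomere, rDNA, HM)."""

    chrom_sizes: dict[str, int]
    special_regions: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, regions in self.special_regions.items():
            for chrom, a, b in regions:
                if chrom not in self.chrom_sizes:
                    raise AnnotationError(f"special region {name}: unknown chromosome {chrom}")
                if a < 0 or b > self.chrom_sizes[chrom]:
                    raise AnnotationError(f"special region {name}: ({chrom},{a},{b}) outside chromosome")

    def telomere_regions(self, window: int = 20_000) -> list[tuple[str, int, int]]:
        """Terminal ``window`` bp at both ends of every chromosome."""
        out = []
        for chrom, size in self.chrom_sizes.items():
            w = min(window, size)
            out.append((chrom, 0, w))
            if size > w:
                out.append((chrom, size - w, size))
        return out


# ---------------------------------------------------------------------------
# Readers / writers


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], comment="#")
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_rate_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV (gene_id, mRNA/hour). Blank / NA rates are dropped."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "rate"], comment="#")
    df = df.dropna()
    return dict(zip(df["gene_id"].astype(str), df["rate"].astype(float)))


def write_rate_table(rates: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, rate in rates.items():
            fh.write(f"{gid}\t{rate:.6g}\n")


def attach_rates(genes: Iterable[GeneModel], rates: dict[str, float]) -> list[GeneModel]:
    """Return copies of ``genes`` with transcription rates filled from a table."""
    return [replace(g, exons=list(g.exons), transcription_rate=rates.get(g.gene_id, g.transcription_rate))
            for g in genes]


def _parse_bed12_line(line: str, lineno: int) -> GeneModel:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise AnnotationError(f"line {lineno}: BED12 requires 12 fields, got {len(fields)}")
    try:
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        strand = fields[5]
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: malformed BED12 record ({exc})") from None
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise AnnotationError(f"line {lineno}: blockCount does not match block lists")
    exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
    return GeneModel(gene_id=name, chrom=chrom, start=start, end=end, strand=strand, exons=exons)


def _read_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            genes.append(_parse_bed12_line(line, lineno))
    return genes


def _read_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes = []
    for feat in db.features_of_type("gene", order_by="start"):
        exons = [(e.start - 1, e.end) for e in db.children(feat, featuretype="exon", order_by="start")]
        gene = GeneModel(
            gene_id=feat.id,
            chrom=feat.seqid,
            start=feat.start - 1,
            end=feat.end,
            strand=feat.strand,
            exons=exons or [(feat.start - 1, feat.end)],
        )
        genes.append(gene)
    return genes


def read_gene_annotation(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read gene models from BED12 or GFF3.

    ``format`` is inferred from the file suffix when not given. GFF3
    coordinates are converted to 0-based half-open on read.
    """
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "gff3" if suffix in (".gff", ".gff3") else "bed12"
    if format == "bed12":
        return _read_bed12(path)
    if format == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation format: {format}")


def write_gene_annotation(genes: Sequence[GeneModel], path: str | Path, format: str = "bed12") -> None:
    if format == "bed12":
        with open(path, "w") as fh:
            for g in genes:
                sizes = ",".join(str(b - a) for a, b in g.exons)
                offs = ",".join(str(a - g.start) for a, b in g.exons)
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                         f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{offs}\n")
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in genes:
                fh.write(f"{g.chrom}\tmetachip\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
                for k, (a, b) in enumerate(g.exons, start=1):
                    fh.write(f"{g.chrom}\tmetachip\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                             f"ID={g.gene_id}.exon{k};Parent={g.gene_id}\n")
    else:
        raise ValueError(f"unknown annotation format: {format}")


# ---------------------------------------------------------------------------
# Intergenic regions


def derive_intergenic_regions(
    genes: Sequence[GeneModel], layout: GenomeLayout
) -> dict[str, tuple[Interval, Interval]]:
    """Map each gene to its (5' intergenic, 3' intergenic) intervals.

    The 5' interval runs from the end of the nearest upstream gene (or the
    chromosome start) to the gene's transcription-oriented start; the 3'
    interval is symmetric. For a minus-strand gene "upstream" is to its
    genomic right. Where a neighbouring gene overlaps, the interval on that
    side is empty (zero length), never negative.
    """
    out: dict[str, tuple[Interval, Interval]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, glist in by_chrom.items():
        size = layout.chrom_sizes[chrom]
        glist = sorted(glist, key=lambda g: (g.start, g.end))
        # running max of ends handles nested/overlapping neighbours
        left_bounds = []
        running = 0
        for g in glist:
            left_bounds.append(running)
            running = max(running, g.end)
        right_bounds = []
        running = size
        for g in reversed(glist):
            right_bounds.append(running)
            running = min(running, g.start)
        right_bounds.reverse()
        for g, lb, rb in zip(glist, left_bounds, right_bounds):
            if lb > g.start or rb < g.end:
                logger.warning("gene %s overlaps a neighbour; emitting empty intergenic interval", g.gene_id)
            left = (min(lb, g.start), g.start)
            right = (g.end, max(rb, g.end))
            if g.strand == "+":
                out[g.gene_id] = (left, right)
            else:
                out[g.gene_id] = (right, left)
    return out


# ---------------------------------------------------------------------------
# Gene classification


def classify_by_rate(
    genes: Iterable[GeneModel], boundaries: Sequence[float] = (2, 4, 8, 16)
) -> dict[str, str]:
    """Partition rated genes into activity classes by transcription rate.

    ``boundaries`` are ascending thresholds; with k boundaries there are
    k+1 classes. The top class is strictly ``rate > boundaries[-1]`` and
    lower classes are half-open ``(lo, hi]``. Genes without a rate (their
    transcription is not detectable) are excluded from the output.
    """
    boundaries = list(boundaries)
    if not boundaries:
        raise ValueError("boundaries must be non-empty")
    if sorted(boundaries) != boundaries:
        raise ValueError("boundaries must be ascending")
    labels = rate_class_labels(boundaries)
    out = {}
    for g in genes:
        r = g.transcription_rate
        if r is None or (isinstance(r, float) and np.isnan(r)):
            continue
        idx = int(np.searchsorted(boundaries, r, side="left"))  # (lo, hi]: r <= b -> class of b
        out[g.gene_id] = labels[idx]
    return out


def rate_class_labels(boundaries: Sequence[float] = (2, 4, 8, 16)) -> list[str]:
    """Ordered class labels for :func:`classify_by_rate` (slowest first)."""
    bs = [f"{b:g}" for b in boundaries]
    labels = [f"1:<={bs[0]}"]
    labels += [f"{i + 2}:({bs[i]},{bs[i + 1]}]" for i in range(len(bs) - 1)]
    labels.append(f"{len(bs) + 1}:>{bs[-1]}")
    return labels


def classify_by_length(genes: Sequence[GeneModel], n_classes: int = 8,
                       boundaries: Sequence[float] | None = None) -> dict[str, str]:
    """Partition genes into ``n_classes`` classes by ORF length.

    Default boundaries are empirical length quantiles, giving class sizes
    that differ by at most one; fixed ``boundaries`` may be supplied
    instead (half-open ``(lo, hi]``, top class strictly above the last).
    """
    genes = list(genes)
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if boundaries is not None:
        labels = length_class_labels(n_classes)
        bl = list(boundaries)
        if len(bl) != n_classes - 1:
            raise ValueError("need n_classes - 1 fixed boundaries")
        return {g.gene_id: labels[int(np.searchsorted(bl, g.length, side="left"))] for g in genes}
    if len(genes) < n_classes:
        raise ValueError(f"cannot split {len(genes)} genes into {n_classes} classes")
    lengths = np.array([g.length for g in genes])
    if np.all(lengths == lengths[0]):
        warnings.warn("all genes have equal length; one degenerate length class")
        return {g.gene_id: length_class_labels(n_classes)[0] for g in genes}
    # sort by length (gene_id tiebreak for determinism) and split into
    # near-equal contiguous chunks: class sizes differ by <= 1
    order = sorted(genes, key=lambda g: (g.length, g.gene_id))
    labels = length_class_labels(n_classes)
    out = {}
    n = len(order)
    for k in range(n_classes):
        lo = (k * n) // n_classes
        hi = ((k + 1) * n) // n_classes
        for g in order[lo:hi]:
            out[g.gene_id] = labels[k]
    return out


def length_class_labels(n_classes: int = 8) -> list[str]:
    """Ordered class labels for :func:`classify_by_length` (shortest first)."""
    return [f"L{k + 1}" for k in range(n_classes)]
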