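"""End-to-end orchestration from a single YAML config, with manifest and log.

Stages: normalize -> averaged-gene composite (all genes + stratified) ->
region summary -> exon-intron composites (+ occupancy). Identical config
and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import (
    GenomeLayout,
    attach_rates,
    classify_by_length,
    classify_by_rate,
    derive_intergenic_regions,
    length_class_labels,
    rate_class_labels,
    read_chrom_sizes,
    read_gene_annotation,
    read_rate_table,
)
from .intron_exon import (
    OccupancyTrack,
    composite_exon_intron,
    composite_occupancy,
    exon_intron_units,
    gene_group_split,
    read_group_list,
    weighted_occupancy,
)
from .metagene import (
    TrackIndex,
    composite_average_gene,
    region_summary,
    stratified_profiles,
)
from .normalize import normalize_probe_table, read_probe_table, write_signal_track

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and knobs of one reproducible pipeline run."""

    annotation: str = ""
    chrom_sizes: str = ""
    probes: str = ""
    rates: str | None = None
    occupancy: str | None = None
    groups: str | None = None
    out_dir: str = "results"
    normalization_mode: str = "log_ratios"
    gene_layout: list = field(default_factory=lambda: [["5p_intergenic", 20], ["ORF", 40], ["3p_intergenic", 20]])
    unit_layout: list = field(default_factory=lambda: [["exon1", 10], ["intron", 30], ["exon2", 40]])
    rate_boundaries: list = field(default_factory=lambda: [2, 4, 8, 16])
    n_length_classes: int = 8
    smooth_window: int = 5
    intergenic_cap: int = 1000
    weight_by_probe_count: bool = False
    telomere_window: int = 20000
    special_regions: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every violation (not just the first); empty list means valid."""
    issues = []
    for name in ("annotation", "chrom_sizes", "probes"):
        path = getattr(config, name)
        if not path:
            issues.append(f"{name}: required path missing")
        elif not Path(path).exists():
            issues.append(f"{name}: file not found: {path}")
    for name in ("rates", "occupancy", "groups"):
        path = getattr(config, name)
        if path and not Path(path).exists():
            issues.append(f"{name}: file not found: {path}")
    if config.smooth_window < 1 or config.smooth_window % 2 == 0:
        issues.append("smooth_window must be odd and >= 1")
    for layout_name in ("gene_layout", "unit_layout"):
        layout = getattr(config, layout_name)
        if any(int(n) < 1 for _, n in layout):
            issues.append(f"{layout_name}: bin counts must be positive")
    if config.rate_boundaries != sorted(config.rate_boundaries) or not config.rate_boundaries:
        issues.append("rate_boundaries must be non-empty and ascending")
    if config.intergenic_cap is not None and config.intergenic_cap < 1:
        issues.append("intergenic_cap must be >= 1 (or null)")
    if config.normalization_mode not in ("log_ratios", "intensities"):
        issues.append(f"unknown normalization_mode: {config.normalization_mode}")
    return issues


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _profile_header(config: PipelineConfig, extra: dict) -> str:
    params = {**config.to_dict(), **extra}
    lines = [f"# {k} = {v}" for k, v in sorted(params.items())]
    return "\n".join(lines) + "\n"


def _write_profile(profile, path: Path, config: PipelineConfig, **extra) -> None:
    with open(path, "w") as fh:
        fh.write(_profile_header(config, extra))
        profile.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6f")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to the out dir)."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setLevel(logging.INFO)
    logging.getLogger("metachip").addHandler(log_handler)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "outputs": [],
        "completed_stages": [],
    }
    gene_layout = tuple((str(n), int(b)) for n, b in config.gene_layout)
    unit_layout = tuple((str(n), int(b)) for n, b in config.unit_layout)

    def record(path: Path) -> None:
        manifest["outputs"].append(str(path))

    try:
        stage = "load_annotation"
        chrom_sizes = read_chrom_sizes(config.chrom_sizes)
        special = {name: [tuple(r) for r in regions]
                   for name, regions in config.special_regions.items()}
        layout = GenomeLayout(chrom_sizes=chrom_sizes, special_regions=special)
        genes = read_gene_annotation(config.annotation)
        if config.rates:
            genes = attach_rates(genes, read_rate_table(config.rates))
        intergenic = derive_intergenic_regions(genes, layout)
        manifest["completed_stages"].append(stage)

        stage = "normalize"
        probes = read_probe_table(config.probes)
        track = normalize_probe_table(probes, mode=config.normalization_mode)
        write_signal_track(track, out / "signal.tsv")
        record(out / "signal.tsv")
        index = TrackIndex(track)
        manifest["completed_stages"].append(stage)

        stage = "metagene"
        composite = composite_average_gene(index, genes, intergenic, layout=gene_layout,
                                           intergenic_cap=config.intergenic_cap,
                                           smooth_window=config.smooth_window,
                                           weight_by_probe_count=config.weight_by_probe_count)
        _write_profile(composite, out / "composite_all_genes.tsv", config, stratum="all")
        record(out / "composite_all_genes.tsv")
        if config.rates:
            rate_classes = classify_by_rate(genes, config.rate_boundaries)
            for label, prof in stratified_profiles(
                    index, genes, rate_classes, intergenic,
                    class_order=rate_class_labels(config.rate_boundaries),
                    layout=gene_layout, intergenic_cap=config.intergenic_cap,
                    smooth_window=config.smooth_window).items():
                fname = out / f"composite_rate_{label.split(':')[0]}.tsv"
                _write_profile(prof, fname, config, stratum=f"rate {label}")
                record(fname)
        rated = [g for g in genes if g.transcription_rate is not None] if config.rates else genes
        if len(rated) >= config.n_length_classes:
            length_classes = classify_by_length(rated, config.n_length_classes)
            for label, prof in stratified_profiles(
                    index, rated, length_classes, intergenic,
                    class_order=length_class_labels(config.n_length_classes),
                    layout=gene_layout, intergenic_cap=config.intergenic_cap,
                    smooth_window=config.smooth_window).items():
                fname = out / f"composite_length_{label}.tsv"
                _write_profile(prof, fname, config, stratum=f"length {label}")
                record(fname)
        manifest["completed_stages"].append(stage)

        stage = "region_summary"
        summary = region_summary(track, genes, layout, telomere_window=config.telomere_window)
        with open(out / "region_summary.tsv", "w") as fh:
            fh.write(_profile_header(config, {}))
            summary.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6f")
        record(out / "region_summary.tsv")
        manifest["completed_stages"].append(stage)

        stage = "intron_exon"
        intronic = [g for g in genes if g.n_introns > 0]
        if intronic:
            prof = composite_exon_intron(index, intronic, layout=unit_layout,
                                         smooth_window=config.smooth_window)
            _write_profile(prof, out / "exon_intron_signal.tsv", config, stratum="all intronic")
            record(out / "exon_intron_signal.tsv")
            groups = {}
            if config.groups:
                members, rest = gene_group_split(genes, read_group_list(config.groups))
                groups = {"group": members, "complement": rest}
            for gname, gset in groups.items():
                if not gset:
                    continue
                prof = composite_exon_intron(index, gset, layout=unit_layout,
                                             smooth_window=config.smooth_window)
                _write_profile(prof, out / f"exon_intron_signal_{gname}.tsv", config, stratum=gname)
                record(out / f"exon_intron_signal_{gname}.tsv")
            if config.occupancy:
                occ = OccupancyTrack.from_bedgraph(config.occupancy, chrom_sizes)
                prof = composite_occupancy(occ, intronic, layout=unit_layout,
                                           smooth_window=config.smooth_window)
                _write_profile(prof, out / "exon_intron_occupancy.tsv", config, stratum="all intronic")
                record(out / "exon_intron_occupancy.tsv")
                units = [u for g in intronic for u in exon_intron_units(g)]
                rows = [{"segment": seg, "weighted_occupancy": weighted_occupancy(occ, units, seg)}
                        for seg in ("exon1", "intron", "exon2")]
                import pandas as pd

                with open(out / "weighted_occupancy.tsv", "w") as fh:
                    fh.write(_profile_header(config, {}))
                    pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, float_format="%.6f")
                record(out / "weighted_occupancy.tsv")
        else:
            logger.info("no intron-containing genes; exon-intron stage skipped")
        manifest["completed_stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logging.getLogger("metachip").removeHandler(log_handler)
        log_handler.close()
        raise StageError(stage, exc) from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logging.getLogger("metachip").removeHandler(log_handler)
    log_handler.close()
    return manifest
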