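"""Per-probe replicate normalization to a single averaged log2(IP/control) track.

The two-channel design measures the modification level of a histone
independent of histone density: each probe carries an immunoprecipitated
(IP) intensity and a control (total histone) intensity per replicate. The
pipeline is: per-replicate log2(IP/C) ratios -> quantile normalization of
the replicate columns -> arithmetic mean across replicates, yielding one
signal value per probe.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ProbeTableError(ValueError):
    pass


def read_probe_table(path: str | Path) -> pd.DataFrame:
    """Read a probe TSV: chrom, pos, then IP_r / C_r column pairs.

    Positions must be unique and ascending per chromosome; intensities
    must be positive.
    """
    df = pd.read_csv(path, sep="\t")
    validate_probe_table(df)
    return df


def validate_probe_table(df: pd.DataFrame) -> None:
    ip_cols, c_cols = replicate_columns(df)
    if len(ip_cols) < 1:
        raise ProbeTableError("no IP_r/C_r replicate column pairs found")
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ProbeTableError(f"probe positions not strictly ascending on {chrom}")
    vals = df[ip_cols + c_cols].to_numpy(float)
    if not np.all(vals > 0):
        i = int(np.argwhere(~(vals > 0))[0][0])
        raise ProbeTableError(
            f"non-positive intensity at probe {df['chrom'].iat[i]}:{df['pos'].iat[i]}")


def write_probe_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def replicate_columns(df: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Matched (IP_r, C_r) column name lists, ordered by replicate index."""
    ips = sorted((c for c in df.columns if c.startswith("IP_")), key=lambda c: int(c.split("_")[1]))
    cs = sorted((c for c in df.columns if c.startswith("C_")), key=lambda c: int(c.split("_")[1]))
    if [c.split("_")[1] for c in ips] != [c.split("_")[1] for c in cs]:
        raise ProbeTableError("IP_r and C_r replicate columns do not match")
    return ips, cs


def probe_log_ratios(table: pd.DataFrame) -> np.ndarray:
    """Per-probe, per-replicate log2(IP/C) matrix (probes x replicates)."""
    ip_cols, c_cols = replicate_columns(table)
    ip = table[ip_cols].to_numpy(float)
    c = table[c_cols].to_numpy(float)
    if not (np.all(ip > 0) and np.all(c > 0)):
        bad = np.argwhere(~((ip > 0) & (c > 0)))
        i = int(bad[0][0])
        raise ProbeTableError(
            f"non-positive intensity at probe {table['chrom'].iat[i]}:{table['pos'].iat[i]}")
    return np.log2(ip) - np.log2(c)


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of a probes x replicates matrix.

    Every output column has the identical value multiset: the vector of
    row means of the column-sorted matrix, assigned back by within-column
    rank. Tied values within a column receive the mean of the reference
    values over their tied ranks, which makes the operation
    permutation-invariant and idempotent.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D probes x replicates matrix")
    if np.isnan(matrix).any():
        raise ValueError("quantile normalization requires complete data")
    n, r = matrix.shape
    if r < 2:
        logger.warning("quantile_normalize: single column, returned unchanged")
        return matrix.copy()
    reference = np.sort(matrix, axis=0).mean(axis=1)
    out = np.empty_like(matrix)
    for j in range(r):
        col = matrix[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty(n)
        ranked[order] = reference
        # average reference values over runs of tied input values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        for lo, hi in zip(np.r_[0, boundaries], np.r_[boundaries, n]):
            if hi - lo > 1:
                ranked[order[lo:hi]] = reference[lo:hi].mean()
        out[:, j] = ranked
    return out


def average_replicates(matrix: np.ndarray) -> np.ndarray:
    """Mean across replicate columns: ½[log2(IP1/C1)+log2(IP2/C2)] for R=2,
    generalized to the arithmetic mean for R >= 2."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D probes x replicates matrix")
    return matrix.mean(axis=1)


def normalize_probe_table(table: pd.DataFrame, mode: str = "log_ratios") -> pd.DataFrame:
    """Full normalization: ProbeTable -> SignalTrack (chrom, pos, value).

    ``mode="log_ratios"`` (default) quantile-normalizes the per-replicate
    log2(IP/C) columns; ``mode="intensities"`` quantile-normalizes the raw
    replicate intensities within each channel type (IP arrays together,
    control arrays together — normalizing across channel types would erase
    the IP/control contrast itself) before forming ratios.
    """
    if mode == "log_ratios":
        ratios = quantile_normalize(probe_log_ratios(table))
    elif mode == "intensities":
        ip_cols, c_cols = replicate_columns(table)
        ip = quantile_normalize(table[ip_cols].to_numpy(float))
        c = quantile_normalize(table[c_cols].to_numpy(float))
        ratios = np.log2(ip) - np.log2(c)
    else:
        raise ValueError(f"unknown normalization mode: {mode}")
    value = average_replicates(ratios)
    return pd.DataFrame({"chrom": table["chrom"], "pos": table["pos"], "value": value})


def merge_replicate_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Inner-join probe tables on (chrom, pos); probes present in only some
    replicates are dropped with a logged count, not imputed."""
    merged = tables[0]
    for t in tables[1:]:
        merged = merged.merge(t, on=["chrom", "pos"], how="inner")
    dropped = max(len(t) for t in tables) - len(merged)
    if dropped:
        logger.info("dropped %d probes absent from some replicates", dropped)
    return merged


def normalize_to_reference(target_ip_over_input: float, reference_ip_over_input: float) -> float:
    """Relative enrichment of a target ratio against a reference locus ratio.

    Pairwise helper for qPCR-style validation: an IP/Input ratio is divided
    by the IP/Input ratio of a reference sequence, or one mark's signal is
    expressed relative to another's.
    """
    if reference_ip_over_input <= 0:
        raise ValueError("reference ratio must be positive")
    return target_ip_over_input / reference_ip_over_input


# ---------------------------------------------------------------------------
# SignalTrack I/O


def read_signal_track(path: str | Path) -> pd.DataFrame:
    """Read a SignalTrack from TSV (chrom, pos, value) or bedGraph."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if set(df.columns) >= {"chrom", "pos", "value"}:
        return df[["chrom", "pos", "value"]]
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    return pd.DataFrame({"chrom": df["chrom"], "pos": df["start"], "value": df["value"]})


def write_signal_track(track: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    if format == "tsv":
        track.to_csv(path, sep="\t", index=False, float_format="%.6f")
    elif format == "bedgraph":
        out = pd.DataFrame({"chrom": track["chrom"], "start": track["pos"],
                            "end": track["pos"] + 1, "value": track["value"]})
        out.to_csv(path, sep="\t", index=False, header=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown track format: {format}")
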