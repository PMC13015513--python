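"""BigWig coverage-track access: per-region signal matrices, aggregate
profiles, genome-wide binned values, and track writing.

Missing/NaN track data is coverage-semantics zero; each extraction logs a
per-chromosome NaN count at DEBUG level. Windows that run off a chromosome
end are clipped and the clipped bins set to 0.
"""

from __future__ import annotations

import contextlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pyBigWig

from .errors import ConfigError, DataError
from .regions import GenomeBins, GenomicRegion

__all__ = [
    "SignalMatrix",
    "open_bigwig",
    "extract_signal",
    "aggregate_profile",
    "bin_track",
    "write_bigwig",
    "track_total_signal",
]

logger = logging.getLogger(__name__)


@dataclass
class SignalMatrix:
    """Per-region, per-bin signal extracted around region centers.

    ``values`` has one row per region and ``n_bins`` columns; each cell is
    the mean track value in one equal-width bin of the region's
    ``center ± flank`` window. Minus-strand rows are stored reversed so all
    rows share orientation. All values are finite and >= 0.
    """

    regions: list[GenomicRegion]
    values: np.ndarray
    flank: int
    anchor: str = "center"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.regions):
            raise DataError("SignalMatrix needs one row per region")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise DataError("SignalMatrix values must be finite and >= 0")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_width(self) -> float:
        return 2 * self.flank / self.n_bins

    def subset(self, indices: np.ndarray) -> "SignalMatrix":
        """Row subset sharing window geometry (used after outlier removal)."""
        idx = np.asarray(indices, dtype=int)
        return SignalMatrix(
            [self.regions[i] for i in idx], self.values[idx], self.flank, self.anchor
        )


@contextlib.contextmanager
def open_bigwig(track):
    """Yield an opened pyBigWig handle from a path or pass a handle through."""
    if isinstance(track, (str, Path)):
        path = str(track)
        if not Path(path).exists():
            raise DataError(f"BigWig file not found: {path}")
        bw = pyBigWig.open(path)
        if bw is None:  # pragma: no cover - pyBigWig raises first in practice
            raise DataError(f"could not open BigWig: {path}")
        try:
            yield bw
        finally:
            bw.close()
    else:
        yield track


def _check_chroms(bw, regions: list[GenomicRegion]) -> dict[str, int]:
    chrom_table = bw.chroms()
    missing = sorted({r.chrom for r in regions} - set(chrom_table))
    if missing:
        raise DataError(
            "chromosome(s) absent from track: " + ", ".join(missing)
            + " (names are matched exactly; use an explicit alias map for chr1-vs-1 mismatches)"
        )
    return chrom_table


def extract_signal(track, regions: list[GenomicRegion], n_bins: int = 40,
                   flank: int = 1000) -> SignalMatrix:
    """Extract a center-anchored signal matrix from a coverage track.

    Each region contributes one row: the mean track value in each of
    ``n_bins`` equal-width bins spanning ``[center - flank, center + flank)``.
    Minus-strand rows are reversed. NaN (no data) counts as 0; windows are
    clipped at chromosome boundaries with clipped bins set to 0.
    """
    if n_bins < 1:
        raise ConfigError(f"n_bins must be >= 1, got {n_bins}")
    if flank < 1:
        raise ConfigError(f"flank must be >= 1, got {flank}")
    width = 2 * flank
    if n_bins > width:
        raise ConfigError(f"n_bins={n_bins} exceeds window width {width} bp")
    edges = np.round(np.linspace(0, width, n_bins + 1)).astype(np.int64)
    counts = np.diff(edges).astype(float)

    with open_bigwig(track) as bw:
        chrom_table = _check_chroms(bw, regions)
        out = np.zeros((len(regions), n_bins), dtype=float)
        nan_per_chrom: dict[str, int] = {}
        for i, region in enumerate(regions):
            chrom_len = chrom_table[region.chrom]
            w_start = region.center - flank
            w_end = region.center + flank
            lo = max(0, w_start)
            hi = min(chrom_len, w_end)
            window = np.zeros(width, dtype=float)
            if hi > lo:
                vals = np.asarray(bw.values(region.chrom, lo, hi, numpy=True), dtype=float)
                n_nan = int(np.isnan(vals).sum())
                if n_nan:
                    nan_per_chrom[region.chrom] = nan_per_chrom.get(region.chrom, 0) + n_nan
                    vals = np.nan_to_num(vals, nan=0.0)
                window[lo - w_start: hi - w_start] = vals
            row = np.add.reduceat(window, edges[:-1]) / counts
            if region.strand == "-":
                row = row[::-1]
            out[i] = row
    if nan_per_chrom:
        logger.debug("NaN track values imputed as 0: %s", nan_per_chrom)
    return SignalMatrix(list(regions), out, flank)


def aggregate_profile(matrix: SignalMatrix) -> np.ndarray:
    """Column-wise mean across regions (the aggregate/meta profile)."""
    if len(matrix.regions) == 0:
        raise DataError("cannot aggregate an empty signal matrix")
    return matrix.values.mean(axis=0)


def bin_track(track, bins: GenomeBins) -> dict[str, np.ndarray]:
    """Mean track value per genome bin, chromosome by chromosome.

    Returns ``{chrom: values}`` with one value per tile of ``bins``.
    Chromosomes present in ``bins`` must exist in the track.
    """
    with open_bigwig(track) as bw:
        chrom_table = bw.chroms()
        missing = sorted(set(bins.chroms) - set(chrom_table))
        if missing:
            raise DataError("chromosome(s) absent from track: " + ", ".join(missing))
        out: dict[str, np.ndarray] = {}
        for chrom in bins.chroms:
            length = min(bins.chrom_sizes[chrom], chrom_table[chrom])
            vals = np.asarray(bw.values(chrom, 0, length, numpy=True), dtype=float)
            vals = np.nan_to_num(vals, nan=0.0)
            if length < bins.chrom_sizes[chrom]:
                vals = np.pad(vals, (0, bins.chrom_sizes[chrom] - length))
            starts, ends = bins.edges(chrom)
            sums = np.add.reduceat(vals, starts)
            out[chrom] = sums / (ends - starts)
    return out


def write_bigwig(bins: GenomeBins, values: dict[str, np.ndarray],
                 path: str | Path) -> None:
    """Write per-bin values as a BigWig track.

    One interval per tile of ``bins``; values must be finite, >= 0, and one
    per bin. Read-back of any bin returns the written value within float32
    precision.
    """
    for chrom in bins.chroms:
        if chrom not in values:
            raise DataError(f"no values supplied for chromosome {chrom}")
        v = np.asarray(values[chrom], dtype=float)
        if v.shape != (bins.n_bins(chrom),):
            raise DataError(
                f"{chrom}: expected {bins.n_bins(chrom)} values, got {v.shape}"
            )
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise DataError(f"{chrom}: values must be finite and >= 0")
    path = str(path)
    try:
        bw = pyBigWig.open(path, "w")
        bw.addHeader([(c, int(bins.chrom_sizes[c])) for c in bins.chroms])
        for chrom in bins.chroms:
            starts, ends = bins.edges(chrom)
            bw.addEntries(
                [chrom] * len(starts),
                [int(s) for s in starts],
                ends=[int(e) for e in ends],
                values=[float(x) for x in np.asarray(values[chrom], dtype=float)],
            )
        bw.close()
    except (OSError, RuntimeError) as exc:
        raise DataError(f"failed to write BigWig {path}: {exc}") from exc


def track_total_signal(track) -> float:
    """Total signal of a track: sum over bases of the coverage value."""
    total = 0.0
    with open_bigwig(track) as bw:
        for chrom, length in bw.chroms().items():
            s = bw.stats(chrom, 0, length, type="sum", exact=True)[0]
            if s is not None:
                total += float(s)
    return total
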