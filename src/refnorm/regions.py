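"""Genomic intervals, BED/chrom.sizes I/O, and genome binning.

All coordinates are 0-based, half-open ([start, end)), matching BED.
Chromosome names are never harmonized implicitly: ``chr1`` and ``1`` are
different chromosomes unless the caller maps them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import BedParseError, ConfigError, DataError

__all__ = [
    "GenomicRegion",
    "GenomeBins",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "bin_genome",
]


@dataclass
class GenomicRegion:
    """A half-open interval [start, end) on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name (must match the coverage track's naming).
    start, end : int
        0-based half-open coordinates in bp; ``end > start >= 0``.
    name : str, optional
        Feature label (BED column 4).
    strand : str
        One of ``+``, ``-``, ``.`` (default ``.``).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise DataError(f"region start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise DataError(
                f"region end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise DataError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.length


def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read a BED3/BED6 file into a list of :class:`GenomicRegion`.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped. Extra
    columns beyond the sixth are ignored. Malformed lines raise
    :class:`BedParseError` naming the 1-based line number.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"BED file not found: {path}")
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from None
            if end <= start or start < 0:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] != "" else None
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            regions.append(GenomicRegion(chrom, start, end, name=name, strand=strand))
    return regions


def write_bed(regions: list[GenomicRegion], path: str | Path,
              scores: "np.ndarray | list[float] | None" = None) -> None:
    """Write regions as BED6 (or BED3 when no name/strand/score is present).

    ``scores`` fills BED column 5 (clamped to the format's [0, 1000] range,
    rounded to int); when omitted the score column is 0.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            if scores is None and r.name is None and r.strand == ".":
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            else:
                score = 0
                if scores is not None:
                    score = int(np.clip(round(float(scores[i])), 0, 1000))
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\t{score}\t{r.strand}\n"
                )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table into an ordered dict."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"chrom.sizes file not found: {path}")
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise DataError(f"{path}:{lineno}: expected 'chrom length'")
            try:
                length = int(parts[1])
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from None
            if length < 1:
                raise DataError(f"{path}:{lineno}: chromosome length must be >= 1")
            sizes[parts[0]] = length
    return sizes


@dataclass
class GenomeBins:
    """A fixed-width tiling of every chromosome.

    Tiles are non-overlapping, sorted, and jointly cover ``[0, length)``;
    the last tile of each chromosome may be shorter than ``bin_size``.
    """

    chrom_sizes: dict[str, int]
    bin_size: int
    _n_bins: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ConfigError(f"bin_size must be >= 1, got {self.bin_size}")
        for chrom, length in self.chrom_sizes.items():
            if length < 1:
                raise DataError(f"chromosome {chrom} has non-positive length {length}")
        self._n_bins = {
            chrom: -(-length // self.bin_size) for chrom, length in self.chrom_sizes.items()
        }

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        return self._n_bins[chrom]

    @property
    def total_bins(self) -> int:
        return sum(self._n_bins.values())

    def edges(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (starts, ends) arrays for one chromosome's tiles."""
        length = self.chrom_sizes[chrom]
        starts = np.arange(0, length, self.bin_size, dtype=np.int64)
        ends = np.minimum(starts + self.bin_size, length)
        return starts, ends

    def iter_regions(self) -> Iterator[GenomicRegion]:
        for chrom in self.chroms:
            starts, ends = self.edges(chrom)
            for s, e in zip(starts, ends):
                yield GenomicRegion(chrom, int(s), int(e))


def bin_genome(chrom_sizes: dict[str, int], bin_size: int) -> GenomeBins:
    """Tile each chromosome with ``bin_size``-bp bins (last bin may be short)."""
    return GenomeBins(dict(chrom_sizes), bin_size)
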