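"""Genome definitions, binned enrichment tracks, interval sets, and text I/O.

Coordinate convention
---------------------
Everything in this package is **0-based, half-open** — ``[start, end)`` —
the native convention of BED and bedGraph. There is no strand handling
anywhere: all inputs are strand-less coverage or interval data.

Binning convention: bin *i* of a track with width *w* covers
``[i*w, min((i+1)*w, chrom_length))``; the final bin of each chromosome may
be partial (bins clip at chromosome ends, no padding). Positions not covered
by any bedGraph record count as 0 enrichment, not missing: fold-enrichment
tracks are dense, and absence of signal means no enrichment.

All readers transparently accept gzip-compressed files (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass(frozen=True)
class GenomeDef:
    """Ordered chromosome names with lengths: the coordinate universe.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_bp)`` pairs; names must be unique and
        lengths positive.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if not all(l > 0 for _, l in chroms):
            raise ValueError("chromosome lengths must be positive")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def total_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def n_bins(self, chrom: str, bin_width: int) -> int:
        return math.ceil(self.length(chrom) / bin_width)


@dataclass
class BinnedTrack:
    """Fixed-width binned fold-enrichment values for one mark.

    ``values`` maps each chromosome to a float array of length
    ``ceil(length / bin_width)``; all values are non-negative.
    """

    genome: GenomeDef
    bin_width: int
    values: dict[str, np.ndarray]
    mark_name: str = ""

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        vals = {}
        for chrom in self.genome.names:
            if chrom not in self.values:
                raise ValueError(f"missing values for chromosome {chrom!r}")
            v = np.asarray(self.values[chrom], dtype=float)
            n = self.genome.n_bins(chrom, self.bin_width)
            if v.shape != (n,):
                raise ValueError(
                    f"{chrom!r}: expected {n} bins, got {v.shape}"
                )
            if np.any(v < 0):
                raise ValueError(f"{chrom!r}: negative enrichment values")
            vals[chrom] = v
        extra = set(self.values) - set(self.genome.names)
        if extra:
            raise ValueError(f"values for unknown chromosomes: {sorted(extra)}")
        self.values = vals

    def bin_midpoints(self, chrom: str) -> np.ndarray:
        """Midpoint coordinate (bp) of every bin; partial final bin included."""
        n = self.genome.n_bins(chrom, self.bin_width)
        starts = np.arange(n, dtype=float) * self.bin_width
        ends = np.minimum(starts + self.bin_width, self.genome.length(chrom))
        return (starts + ends) / 2.0

    def concat(self) -> np.ndarray:
        """All bin values, chromosomes in genome order."""
        return np.concatenate([self.values[c] for c in self.genome.names])

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.genome == other.genome and self.bin_width == other.bin_width
        )


_BED_COLS = ["chrom", "start", "end", "label"]


@dataclass(frozen=True)
class IntervalSet:
    """Strand-less genomic intervals (0-based half-open) with optional labels.

    Canonical form is sorted by (chrom, start) with no overlaps within a
    chromosome; operations that require or produce canonical form say so.
    """

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_BED_COLS)
    )

    def __post_init__(self):
        df = self.df.copy()
        if "label" not in df.columns:
            df["label"] = None
        df = df[_BED_COLS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["end"] <= df["start"]).any():
            bad = df[df["end"] <= df["start"]].iloc[0]
            raise ValueError(
                f"empty/inverted interval {bad.chrom}:{bad.start}-{bad.end}"
            )
        object.__setattr__(self, "df", df)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple]
    ) -> "IntervalSet":
        """Build from ``(chrom, start, end[, label])`` tuples."""
        rows = []
        for rec in records:
            chrom, start, end = rec[0], rec[1], rec[2]
            label = rec[3] if len(rec) > 3 else None
            rows.append((chrom, start, end, label))
        return cls(pd.DataFrame(rows, columns=_BED_COLS))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[tuple]:
        for row in self.df.itertuples(index=False):
            yield (row.chrom, int(row.start), int(row.end), row.label)

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def total_bp(self) -> int:
        return int(self.lengths().sum())

    def sort(self) -> "IntervalSet":
        df = self.df.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)
        return IntervalSet(df)

    def is_canonical(self) -> bool:
        df = self.df
        if not df.equals(self.sort().df):
            return False
        for _, sub in df.groupby("chrom", sort=False):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                return False
        return True

    def validate_against(self, genome: GenomeDef) -> "IntervalSet":
        """Raise if any interval leaves the genome bounds; return self."""
        for chrom, start, end, _ in self:
            if chrom not in genome:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if start < 0 or end > genome.length(chrom):
                raise ValueError(
                    f"interval {chrom}:{start}-{end} outside chromosome bounds"
                )
        return self

    def to_pyranges(self):
        import pyranges as pr

        df = self.df.rename(
            columns={"chrom": "Chromosome", "start": "Start", "end": "End"}
        )
        return pr.PyRanges(df[["Chromosome", "Start", "End"]])

    @classmethod
    def from_pyranges(cls, gr) -> "IntervalSet":
        df = gr.df
        if len(df) == 0:
            return cls()
        df = df.rename(
            columns={"Chromosome": "chrom", "Start": "start", "End": "end"}
        )
        df["chrom"] = df["chrom"].astype(str)
        df["label"] = None
        return cls(df[_BED_COLS]).sort()

    def merge(self, gap: int = 0) -> "IntervalSet":
        """Canonical union: merge intervals separated by ≤ ``gap`` bp.

        Labels are dropped (merged intervals have no single label).
        """
        rows = []
        for chrom, sub in self.sort().df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s - cur_e <= gap:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e, None))
                    cur_s, cur_e = s, e
            rows.append((chrom, cur_s, cur_e, None))
        if not rows:
            return IntervalSet()
        return IntervalSet(pd.DataFrame(rows, columns=_BED_COLS))

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Set intersection (canonical output); labels dropped."""
        if len(self) == 0 or len(other) == 0:
            return IntervalSet()
        gr = self.to_pyranges().set_intersect(other.to_pyranges())
        return IntervalSet.from_pyranges(gr)

    def overlap_bp_with(self, other: "IntervalSet") -> np.ndarray:
        """Per-interval overlap (bp) of *self*'s intervals with *other*."""
        out = np.zeros(len(self), dtype=np.int64)
        if len(self) == 0 or len(other) == 0:
            return out
        omerged = other.merge()
        for i, (chrom, start, end, _) in enumerate(self):
            sub = omerged.df[omerged.df["chrom"] == chrom]
            if len(sub):
                ov = np.minimum(sub["end"].to_numpy(), end) - np.maximum(
                    sub["start"].to_numpy(), start
                )
                out[i] = int(np.clip(ov, 0, None).sum())
        return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> GenomeDef:
    """Parse a two-column ``chrom.sizes`` file (name, length) in file order."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"line {lineno}: expected 2 columns")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise FormatError(
                    f"line {lineno}: non-integer length {parts[1]!r}"
                ) from None
            if length <= 0:
                raise FormatError(f"line {lineno}: non-positive length {length}")
            if name in seen:
                raise FormatError(f"line {lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            chroms.append((name, length))
    if not chroms:
        raise FormatError("no chromosomes")
    return GenomeDef(tuple(chroms))


def write_chrom_sizes(genome: GenomeDef, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_bedgraph(path, genome: GenomeDef, bin_width: int,
                  mark_name: str = "") -> BinnedTrack:
    """Average a 4-column bedGraph into fixed-width bins.

    Each record's value is spread over the positions it covers; a bin's value
    is the coverage-weighted mean over the bin's span, with uncovered
    positions contributing 0. The sum of value·length is therefore conserved
    between records and bins.
    """
    sums = {
        c: np.zeros(genome.n_bins(c, bin_width)) for c in genome.names
    }
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"line {lineno}: expected 4 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
                value = float(parts[3])
            except ValueError:
                raise FormatError(f"line {lineno}: malformed record") from None
            if chrom not in genome:
                raise FormatError(
                    f"line {lineno}: unknown chromosome {chrom!r}"
                )
            if start < 0 or end > genome.length(chrom) or start >= end:
                raise FormatError(
                    f"line {lineno}: interval {start}-{end} out of bounds"
                )
            if value < 0:
                raise FormatError(f"line {lineno}: negative value {value}")
            s = sums[chrom]
            i0, i1 = start // bin_width, (end - 1) // bin_width
            if i0 == i1:
                s[i0] += value * (end - start)
            else:
                s[i0] += value * ((i0 + 1) * bin_width - start)
                if i1 > i0 + 1:
                    s[i0 + 1 : i1] += value * bin_width
                s[i1] += value * (end - i1 * bin_width)
    values = {}
    for chrom in genome.names:
        n = genome.n_bins(chrom, bin_width)
        starts = np.arange(n, dtype=np.int64) * bin_width
        spans = np.minimum(starts + bin_width, genome.length(chrom)) - starts
        values[chrom] = sums[chrom] / spans
    return BinnedTrack(genome, bin_width, values, mark_name)


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Emit one record per run of constant bin value; zero runs are skipped."""
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            v = track.values[chrom]
            length = track.genome.length(chrom)
            w = track.bin_width
            if len(v) == 0:
                continue
            changes = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], changes))
            ends = np.concatenate((changes, [len(v)]))
            for i0, i1 in zip(starts, ends):
                val = v[i0]
                if val == 0:
                    continue
                fh.write(
                    f"{chrom}\t{i0 * w}\t{min(i1 * w, length)}\t{val:g}\n"
                )


def read_bed(path, genome: GenomeDef | None = None) -> IntervalSet:
    """Parse BED3/BED4; column 4 (if present) becomes the label."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: expected ≥3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"line {lineno}: malformed coordinates") from None
            if start >= end:
                raise FormatError(
                    f"line {lineno}: start {start} ≥ end {end}"
                )
            label = parts[3] if len(parts) > 3 else None
            rows.append((chrom, start, end, label))
    iv = IntervalSet(pd.DataFrame(rows, columns=_BED_COLS))
    if genome is not None:
        iv.validate_against(genome)
    return iv


def write_bed(interval_set: IntervalSet, path) -> None:
    """Write BED3 (or BED4 where labels are present)."""
    with open(path, "w") as fh:
        for chrom, start, end, label in interval_set:
            if label is None or (isinstance(label, float) and math.isnan(label)):
                fh.write(f"{chrom}\t{start}\t{end}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")
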