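"""Heterochromatin-like domain/complex calling and census.

A heterochromatin-like domain/complex is a genomic interval co-enriched for
at least one HP1 isoform *and* H3K9me3, outside (or including) constitutive
heterochromatin. Calls are classified into three size classes:

========  ==================  =========================
class     length (bp)         biological reading
========  ==================  =========================
complex       [10 kb, 100 kb)   oligo-gene scale complexes
domain        [100 kb, 1 Mb)    domains
large_domain  [1 Mb, ∞)         very large domains
========  ==================  =========================

Size classes are half-open so the touching published bounds resolve
deterministically. The pipeline is: threshold each track into enriched
runs, union the HP1 isoforms, intersect with H3K9me3, optionally remove
calls overlapping the constitutive-heterochromatin mask, then length-filter
and classify.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import BinnedTrack, IntervalSet
from .synthetic import _midpoint_mask

SIZE_CLASSES = ("complex", "domain", "large_domain")
CALL_MODES = ("whole_genome", "exclude_mask")
MASK_POLICIES = ("half", "midpoint", "any")
HP1_COMBINE = ("union", "intersection")


@dataclass(frozen=True)
class CallerParams:
    """Tunables of the caller.

    ``enrich_threshold`` (τ) is the fold-enrichment cutoff defining an
    enriched bin (default 2.0-fold over background; recorded in all
    outputs). ``merge_gap`` of ``None`` means one bin width — the smallest
    gap distinguishable at track resolution. ``mask_policy`` decides when a
    call counts as inside constitutive heterochromatin: overlapping ≥ 50%
    of its length (``half``, default), by midpoint, or by any overlap.
    """

    enrich_threshold: float = 2.0
    merge_gap: int | None = None
    min_size: int = 10_000
    size_bounds: tuple[int, int] = (100_000, 1_000_000)
    mask_policy: str = "half"
    hp1_combine: str = "union"

    def __post_init__(self):
        if self.enrich_threshold <= 0:
            raise ValueError("enrich_threshold must be positive")
        if self.merge_gap is not None and self.merge_gap < 0:
            raise ValueError("merge_gap must be ≥ 0")
        lo, hi = self.size_bounds
        if not (self.min_size < lo < hi):
            raise ValueError("require min_size < lower bound < upper bound")
        if self.mask_policy not in MASK_POLICIES:
            raise ValueError(f"unknown mask policy {self.mask_policy!r}")
        if self.hp1_combine not in HP1_COMBINE:
            raise ValueError(f"unknown hp1_combine {self.hp1_combine!r}")


@dataclass(frozen=True)
class DomainCall:
    """One called heterochromatin-like interval."""

    chrom: str
    start: int
    end: int
    size_class: str
    marks_present: tuple[str, ...]
    mean_enrichment: dict[str, float]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SurveySummary:
    """Census counts per size class per region mode, plus the small-complex share."""

    counts: pd.DataFrame  # index size_class, columns region modes
    fraction_10_30kb: float  # NaN when undefined
    fraction_defined: bool


def size_class(length: int, size_bounds: tuple[int, int] = (100_000, 1_000_000),
               min_size: int = 10_000) -> str | None:
    """Half-open classification; lengths below ``min_size`` return None."""
    lo, hi = size_bounds
    if length < min_size:
        return None
    if length < lo:
        return "complex"
    if length < hi:
        return "domain"
    return "large_domain"


def enriched_intervals(
    track: BinnedTrack,
    enrich_threshold: float,
    merge_gap: int | None = None,
    min_size: int = 0,
) -> IntervalSet:
    """Maximal runs of bins ≥ τ as bp intervals, gap-merged and length-filtered.

    Runs separated by ≤ ``merge_gap`` bp are merged (default: one bin
    width). Output is canonical (sorted, non-overlapping).
    """
    if enrich_threshold <= 0:
        raise ValueError("enrich_threshold must be positive")
    w = track.bin_width
    gap = w if merge_gap is None else merge_gap
    rows = []
    for chrom in track.genome.names:
        v = track.values[chrom]
        hot = v >= enrich_threshold
        if not hot.any():
            continue
        padded = np.concatenate(([False], hot, [False])).astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        length = track.genome.length(chrom)
        cur_s, cur_e = starts[0] * w, min(ends[0] * w, length)
        for i0, i1 in zip(starts[1:], ends[1:]):
            s, e = i0 * w, min(i1 * w, length)
            if s - cur_e <= gap:
                cur_e = e
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    iv = IntervalSet.from_records(rows)
    if min_size > 0 and len(iv):
        iv = IntervalSet(iv.df[iv.lengths() >= min_size])
    return iv.sort()


def _mask_overlap_keep(
    calls: IntervalSet, mask: IntervalSet, policy: str
) -> np.ndarray:
    """Boolean keep-vector for calls under the exclude-mask rule."""
    if len(mask) == 0:
        return np.ones(len(calls), dtype=bool)
    ov = calls.overlap_bp_with(mask)
    lengths = calls.lengths()
    if policy == "half":
        return ov < 0.5 * lengths
    if policy == "any":
        return ov == 0
    # midpoint: drop when the call midpoint falls inside the mask
    keep = np.ones(len(calls), dtype=bool)
    merged = mask.merge()
    for i, (chrom, start, end, _) in enumerate(calls):
        mid = (start + end) / 2
        sub = merged.df[merged.df["chrom"] == chrom]
        if ((sub["start"] <= mid) & (mid < sub["end"])).any():
            keep[i] = False
    return keep


def call_domains(
    hp1_tracks: list[BinnedTrack],
    k9_track: BinnedTrack,
    params: CallerParams = CallerParams(),
    mask: IntervalSet | None = None,
    mode: str = "whole_genome",
) -> list[DomainCall]:
    """Call co-enriched intervals and classify them by size.

    HP1 isoforms are combined by union by default (a call needs at least
    one isoform); ``params.hp1_combine = 'intersection'`` requires all.
    The combined HP1 set is intersected with the H3K9me3 enriched set.
    Under ``exclude_mask``, calls inside constitutive heterochromatin
    (per ``params.mask_policy``) are dropped.
    """
    if not hp1_tracks:
        raise ValueError("at least one HP1 track required")
    if mode not in CALL_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    for t in hp1_tracks:
        if not t.same_grid(k9_track):
            raise ValueError("tracks must share genome and bin width")
    tau, gap = params.enrich_threshold, params.merge_gap
    hp1_sets = [enriched_intervals(t, tau, gap) for t in hp1_tracks]
    if params.hp1_combine == "union":
        combined = IntervalSet(
            pd.concat([s.df for s in hp1_sets], ignore_index=True)
        ).merge(0) if any(len(s) for s in hp1_sets) else IntervalSet()
    else:
        combined = hp1_sets[0]
        for s in hp1_sets[1:]:
            combined = combined.intersect(s)
    k9_set = enriched_intervals(k9_track, tau, gap)
    cand = combined.intersect(k9_set)
    if len(cand) == 0:
        return []
    if mode == "exclude_mask" and mask is not None:
        keep = _mask_overlap_keep(cand, mask, params.mask_policy)
        cand = IntervalSet(cand.df[keep])
    if len(cand) == 0:
        return []
    cand = IntervalSet(cand.df[cand.lengths() >= params.min_size]).sort()

    calls: list[DomainCall] = []
    genome, w = k9_track.genome, k9_track.bin_width
    all_tracks = list(hp1_tracks) + [k9_track]
    for chrom, start, end, _ in cand:
        cls = size_class(end - start, params.size_bounds, params.min_size)
        if cls is None:
            continue
        iv = IntervalSet.from_records([(chrom, start, end)])
        bins = _midpoint_mask(genome, w, chrom, iv)
        means = {
            t.mark_name: float(t.values[chrom][bins].mean())
            for t in all_tracks
        }
        # marks present: the isoform's enriched set overlaps the call
        present = [
            t.mark_name
            for t, s in zip(hp1_tracks, hp1_sets)
            if int(iv.overlap_bp_with(s)[0]) > 0
        ] + [k9_track.mark_name]
        calls.append(
            DomainCall(chrom, start, end, cls, tuple(present), means)
        )
    return calls


def calls_to_intervalset(calls: list[DomainCall]) -> IntervalSet:
    """Calls as a labelled IntervalSet (label = size class), e.g. for BED output."""
    return IntervalSet.from_records(
        [(c.chrom, c.start, c.end, c.size_class) for c in calls]
    ).sort()


def summarize(calls_by_mode: dict[str, list[DomainCall]]) -> SurveySummary:
    """Census table: counts per size class per mode, plus the 10–30 kb share.

    ``fraction_10_30kb`` is the share of complexes with length in the
    closed interval [10 kb, 30 kb], computed over the ``exclude_mask``
    calls when present (the published convention), else over the single
    provided mode; NaN with ``fraction_defined=False`` when there are no
    complexes.
    """
    modes = list(calls_by_mode)
    counts = pd.DataFrame(0, index=list(SIZE_CLASSES), columns=modes)
    for mode, calls in calls_by_mode.items():
        for c in calls:
            counts.loc[c.size_class, mode] += 1
    ref_mode = "exclude_mask" if "exclude_mask" in calls_by_mode else modes[0]
    complexes = [
        c for c in calls_by_mode[ref_mode] if c.size_class == "complex"
    ]
    if complexes:
        n_small = sum(1 for c in complexes if 10_000 <= c.length <= 30_000)
        frac = n_small / len(complexes)
        defined = True
    else:
        frac, defined = math.nan, False
    return SurveySummary(counts=counts, fraction_10_30kb=frac,
                         fraction_defined=defined)
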