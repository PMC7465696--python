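"""Synthetic multi-mark fold-enrichment tracks with planted ground truth.

Emulates the statistical structure of HP1/H3K9me3 ChIP-seq surveys: a set of
co-enriched intervals planted in three size classes (large domains > 1 Mb,
domains 0.1–1 Mb, complexes 10–100 kb), a constitutive-heterochromatin mask
that is strongly enriched in every mark, tunable co-localization between
marks, and multiplicative log-normal noise. Noise is multiplicative (not
additive Gaussian) because fold enrichment is a ratio and must stay
non-negative.

Co-localization is modelled at interval granularity: with probability
``coloc`` a planted interval carries *all* marks; otherwise it carries a
single mark chosen uniformly. This matches domain-level intersection logic
downstream, where a call requires joint HP1/H3K9me3 enrichment.

Everything is deterministic given the seed. One ``SeedSequence`` per bundle
is spawned into one stream for mark assignment plus one per chromosome for
noise, so adding chromosomes does not perturb earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .genomic_io import BinnedTrack, GenomeDef, IntervalSet

#: Size-class names and bp ranges: large domains 1–4 Mb, domains 0.1–1 Mb,
#: complexes 10–100 kb.
DEFAULT_SIZE_RANGES: dict[str, tuple[int, int]] = {
    "large_domain": (1_000_000, 4_000_000),
    "domain": (100_000, 1_000_000),
    "complex": (10_000, 100_000),
}

DEFAULT_MARKS = ("HP1a", "HP1b", "HP1g", "H3K9me3")


@dataclass(frozen=True)
class TrackSimParams:
    """Parameters of one simulated bundle.

    ``enrich_mean`` is the mean fold enrichment inside planted intervals and
    inside the heterochromatin mask (default 8, a typical ChIP fold
    enrichment for strong HP1/H3K9me3 territory); ``background_mean``
    (default 1: no enrichment over input) applies everywhere else.
    ``coloc`` is the fraction of planted intervals carrying all marks;
    ``noise_cv`` the coefficient of variation of bin-wise multiplicative
    log-normal noise.

    ``mask_profile_cv`` gives the constitutive-heterochromatin mask a
    spatial fine structure *shared by all marks*: inside the mask every
    mark is multiplied by one common log-normal field with this CV. Real
    pericentric territories have repeat-driven coverage structure that
    every heterochromatin mark sees alike — it is what makes correlations
    restricted to heterochromatin approach unity — whereas a uniform
    plateau would carry no signal variance at all. Set to 0 for a flat
    mask.
    """

    genome: GenomeDef
    bin_width: int
    truth: IntervalSet
    het_mask: IntervalSet
    marks: tuple[str, ...] = DEFAULT_MARKS
    enrich_mean: float = 8.0
    background_mean: float = 1.0
    coloc: float = 0.8
    noise_cv: float = 0.3
    mask_profile_cv: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (self.enrich_mean > self.background_mean):
            raise ValueError("enrich_mean must exceed background_mean")
        if not (0.0 <= self.coloc <= 1.0):
            raise ValueError("coloc must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.mask_profile_cv < 0:
            raise ValueError("mask_profile_cv must be non-negative")
        if self.background_mean < 0:
            raise ValueError("background_mean must be non-negative")
        if not self.marks:
            raise ValueError("at least one mark required")
        object.__setattr__(self, "marks", tuple(self.marks))


@dataclass(frozen=True)
class SimBundle:
    """One simulated dataset: tracks per mark plus the planted ground truth."""

    tracks: dict[str, BinnedTrack]
    truth: IntervalSet
    het_mask: IntervalSet
    params: TrackSimParams

    def __post_init__(self):
        grids = {(t.genome, t.bin_width) for t in self.tracks.values()}
        if len(grids) > 1:
            raise ValueError("tracks disagree on genome or bin width")


class PackingError(RuntimeError):
    """Requested intervals could not be placed; message reports achieved counts."""


def _free_segments(genome: GenomeDef, exclude: IntervalSet | None,
                   min_gap: int) -> dict[str, list[tuple[int, int]]]:
    segs = {c: [(0, genome.length(c))] for c in genome.names}
    if exclude is None or len(exclude) == 0:
        return segs
    for chrom, start, end, _ in exclude.merge():
        if chrom not in segs:
            continue
        lo, hi = max(0, start - min_gap), end + min_gap
        new = []
        for s, e in segs[chrom]:
            if hi <= s or lo >= e:
                new.append((s, e))
            else:
                if s < lo:
                    new.append((s, lo))
                if hi < e:
                    new.append((hi, e))
        segs[chrom] = new
    return segs


def plant_truth(
    genome: GenomeDef,
    counts_per_class: dict[str, int],
    size_ranges: dict[str, tuple[int, int]] | None = None,
    min_gap: int = 50_000,
    seed: int = 0,
    exclude: IntervalSet | None = None,
    snap_bp: int | None = None,
) -> IntervalSet:
    """Plant non-overlapping labelled intervals, sizes uniform per class.

    Intervals are separated by at least ``min_gap`` bp from each other and
    from ``exclude`` (e.g. a heterochromatin mask). With ``snap_bp`` set,
    starts and lengths are rounded to that grid (typically the track bin
    width) so planted boundaries coincide with bin edges. Placement is
    largest-first into uniformly chosen free gaps; deterministic given seed.

    Raises
    ------
    PackingError
        If the requested intervals do not fit; the message reports how many
        of each class were achieved.
    """
    size_ranges = dict(size_ranges or DEFAULT_SIZE_RANGES)
    unknown = set(counts_per_class) - set(size_ranges)
    if unknown:
        raise ValueError(f"no size range for classes {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    # draw all sizes first, then place largest-first (better packing)
    wanted: list[tuple[int, str]] = []
    for cls, count in counts_per_class.items():
        lo, hi = size_ranges[cls]
        for _ in range(int(count)):
            # half-open [lo, hi): sizes never collide with the next class
            size = int(rng.integers(lo, hi))
            if snap_bp:
                lo_s = -(-lo // snap_bp) * snap_bp
                hi_s = ((hi - 1) // snap_bp) * snap_bp
                size = round(size / snap_bp) * snap_bp
                size = int(min(max(size, lo_s, snap_bp), max(hi_s, lo_s)))
            wanted.append((size, cls))
    wanted.sort(key=lambda t: -t[0])

    free = _free_segments(genome, exclude, min_gap)
    placed: list[tuple[str, int, int, str]] = []
    achieved = {cls: 0 for cls in counts_per_class}
    for size, cls in wanted:
        # candidate gaps able to hold the interval
        cands = [
            (chrom, i, s, e)
            for chrom, segs in free.items()
            for i, (s, e) in enumerate(segs)
            if e - s >= size
        ]
        if not cands:
            raise PackingError(
                f"could not place a {size} bp {cls!r} interval; achieved "
                f"{achieved} of requested {dict(counts_per_class)}"
            )
        chrom, i, s, e = cands[int(rng.integers(len(cands)))]
        start = int(rng.integers(s, e - size + 1))
        if snap_bp:
            start = min(
                (start // snap_bp) * snap_bp,
                ((e - size) // snap_bp) * snap_bp,
            )
            start = max(start, s)
        end = start + size
        placed.append((chrom, start, end, cls))
        achieved[cls] += 1
        # split the consumed gap, keeping min_gap clearance
        segs = free[chrom]
        s0, e0 = segs.pop(i)
        if start - min_gap > s0:
            segs.append((s0, start - min_gap))
        if end + min_gap < e0:
            segs.append((end + min_gap, e0))
        segs.sort()
    return IntervalSet.from_records(placed).sort()


def _midpoint_mask(genome: GenomeDef, bin_width: int, chrom: str,
                   intervals: IntervalSet) -> np.ndarray:
    """Boolean per-bin vector: bin midpoint falls inside *intervals*."""
    n = genome.n_bins(chrom, bin_width)
    starts = np.arange(n, dtype=float) * bin_width
    ends = np.minimum(starts + bin_width, genome.length(chrom))
    mids = (starts + ends) / 2.0
    mask = np.zeros(n, dtype=bool)
    sub = intervals.df[intervals.df["chrom"] == chrom]
    for s, e in zip(sub["start"], sub["end"]):
        mask |= (mids >= s) & (mids < e)
    return mask


def simulate_tracks(params: TrackSimParams) -> SimBundle:
    """Generate one bundle of per-mark tracks from planted truth.

    A bin belongs to an interval iff its midpoint lies inside it (consistent
    with the masking rule used downstream). Inside the heterochromatin mask
    every mark is enriched; inside a truth interval the marks assigned to
    that interval are enriched; everywhere else the track sits at
    ``background_mean``. Log-normal noise with unit mean and CV ``noise_cv``
    multiplies every bin.
    """
    p = params
    p.truth.validate_against(p.genome)
    p.het_mask.validate_against(p.genome)
    ss = np.random.SeedSequence(p.seed)
    n_chrom = len(p.genome.names)
    children = ss.spawn(1 + 2 * n_chrom)  # assignment, noise/chrom, mask/chrom
    rng_assign = np.random.default_rng(children[0])

    truth_sorted = p.truth.sort()
    assignments: list[tuple[str, int, int, tuple[str, ...]]] = []
    for chrom, start, end, _ in truth_sorted:
        if rng_assign.random() < p.coloc:
            marks = p.marks
        else:
            marks = (p.marks[int(rng_assign.integers(len(p.marks)))],)
        assignments.append((chrom, start, end, marks))

    if p.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + p.noise_cv**2))
        mu = -0.5 * sigma**2
    tracks: dict[str, BinnedTrack] = {}
    values_by_mark = {
        m: {c: np.full(p.genome.n_bins(c, p.bin_width), p.background_mean)
            for c in p.genome.names}
        for m in p.marks
    }
    for ci, chrom in enumerate(p.genome.names):
        mask_bins = _midpoint_mask(p.genome, p.bin_width, chrom, p.het_mask)
        for m in p.marks:
            values_by_mark[m][chrom][mask_bins] = p.enrich_mean
        if p.mask_profile_cv > 0 and mask_bins.any():
            # one spatial field shared by every mark inside the mask
            sig_m = math.sqrt(math.log(1.0 + p.mask_profile_cv**2))
            rng_mask = np.random.default_rng(children[1 + n_chrom + ci])
            shared = rng_mask.lognormal(
                -0.5 * sig_m**2, sig_m, size=int(mask_bins.sum())
            )
            for m in p.marks:
                values_by_mark[m][chrom][mask_bins] *= shared
        for ch, start, end, marks in assignments:
            if ch != chrom:
                continue
            sub = IntervalSet.from_records([(ch, start, end)])
            bins = _midpoint_mask(p.genome, p.bin_width, chrom, sub)
            for m in marks:
                values_by_mark[m][chrom][bins] = p.enrich_mean
    for ci, chrom in enumerate(p.genome.names):
        rng_noise = np.random.default_rng(children[1 + ci])
        for m in p.marks:
            v = values_by_mark[m][chrom]
            if p.noise_cv > 0:
                v *= rng_noise.lognormal(mu, sigma, size=v.shape)
    for m in p.marks:
        tracks[m] = BinnedTrack(p.genome, p.bin_width, values_by_mark[m], m)
    return SimBundle(tracks, truth_sorted, p.het_mask.sort(), p)


def default_genome(n_chrom: int = 2, chrom_len: int = 20_000_000) -> GenomeDef:
    """A small multi-chromosome genome for simulation studies."""
    return GenomeDef(
        tuple((f"chr{i + 1}", chrom_len) for i in range(n_chrom))
    )


def make_bundle(
    genome: GenomeDef | None = None,
    bin_width: int = 5_000,
    counts: dict[str, int] | None = None,
    mask_counts: dict[str, int] | None = None,
    marks: tuple[str, ...] = DEFAULT_MARKS,
    enrich_mean: float = 8.0,
    background_mean: float = 1.0,
    coloc: float = 0.8,
    noise_cv: float = 0.3,
    mask_profile_cv: float = 2.0,
    seed: int = 0,
) -> SimBundle:
    """Convenience constructor: plant a mask and truth, then simulate.

    The mask is planted first (as ``large_domain``-sized blocks emulating
    pericentric territories), the truth second with the mask excluded, and
    both are snapped to the bin grid so planted boundaries are observable at
    track resolution.
    """
    genome = genome or default_genome()
    counts = counts if counts is not None else {
        "large_domain": 1, "domain": 3, "complex": 10,
    }
    mask_counts = mask_counts if mask_counts is not None else {
        "large_domain": 1,
    }
    ss = np.random.SeedSequence(seed)
    s_mask, s_truth, s_tracks = [int(c.generate_state(1)[0] % 2**31)
                                 for c in ss.spawn(3)]
    het_mask = plant_truth(
        genome, mask_counts, min_gap=500_000, seed=s_mask, snap_bp=bin_width
    )
    truth = plant_truth(
        genome, counts, min_gap=50_000, seed=s_truth,
        exclude=het_mask, snap_bp=bin_width,
    )
    params = TrackSimParams(
        genome=genome, bin_width=bin_width, truth=truth, het_mask=het_mask,
        marks=marks, enrich_mean=enrich_mean, background_mean=background_mean,
        coloc=coloc, noise_cv=noise_cv, mask_profile_cv=mask_profile_cv,
        seed=s_tracks,
    )
    return simulate_tracks(params)
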