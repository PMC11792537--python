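"""Prophage-evidence signal tracks over bacterial contigs.

Five lines of evidence distinguish an integrated prophage from its host
contig: ORF organization (prophages encode shorter genes with shorter
intergenic spaces and rarely switch coding strand), nucleotide composition,
external predictor calls, and the breadth and depth of coverage by
virus-like-particle (VLP) reads.  This module computes those tracks with the
3,001-nt / 500-nt-step bacterial windowing convention, applies the
sample-contamination filter, quantifies induction as a prophage/background
coverage-depth ratio, combines the tracks into candidate prophage regions,
and calls transposable-phage termini from split-read junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    BOUNDARY_EPS,
    DepthProfile,
    GenomeRecord,
    InputError,
    Interval,
    OrfRecord,
    Thresholds,
    DEFAULT_THRESHOLDS,
    WindowSpec,
    WindowTrack,
)

__all__ = [
    "enumerate_windows",
    "nucleotide_content_track",
    "orf_organization_track",
    "depth_breadth_tracks",
    "contamination_filter",
    "coverage_ratio",
    "call_candidate_regions",
    "call_transposable_termini",
    "RegionCallConfig",
    "CandidateRegion",
    "CoverageRatio",
    "TerminusCall",
]


def enumerate_windows(length: int, spec: WindowSpec, contig_id: str = "") -> list[Interval]:
    """Enumerate sliding windows 5'->3' along a sequence of ``length`` nt.

    Windows start at 1, 1+S, 1+2S, ... while they fit entirely; the final
    window is extended to the sequence end when the uncovered 3' tail is at
    most ``spec.terminal_extension`` nt.  A sequence shorter than the window
    yields the single window [1, length].
    """
    if length < 1:
        raise InputError(f"nonpositive sequence length {length}")
    if length < spec.window:
        return [Interval(contig_id, 1, length)]
    starts = range(1, length - spec.window + 2, spec.step)
    windows = [Interval(contig_id, s, s + spec.window - 1) for s in starts]
    tail = length - windows[-1].end
    if 0 < tail <= spec.terminal_extension:
        windows[-1] = Interval(contig_id, windows[-1].start, length)
    return windows


def nucleotide_content_track(genome: GenomeRecord, spec: WindowSpec) -> WindowTrack:
    """Per-window fraction of each nucleotide among non-N positions.

    A window consisting entirely of N yields missing values for all four
    fractions.
    """
    if genome.length == 0:
        raise InputError(f"empty genome {genome.id}")
    seq = genome.seq.upper()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_base = {b: codes == ord(b) for b in "ACGTN"}
    known = is_base["A"] | is_base["C"] | is_base["G"] | is_base["T"] | is_base["N"]
    if not known.all():
        pos = int(np.argmin(known)) + 1
        raise InputError(
            f"sequence {genome.id}: invalid character {seq[pos - 1]!r} at position {pos}"
        )
    cum = {b: np.concatenate(([0], np.cumsum(is_base[b]))) for b in "ACGT"}
    windows = enumerate_windows(genome.length, spec, genome.id)
    values = {f"frac_{b.lower()}": np.empty(len(windows)) for b in "ACGT"}
    for i, w in enumerate(windows):
        counts = {b: cum[b][w.end] - cum[b][w.start - 1] for b in "ACGT"}
        denom = sum(counts.values())
        for b in "ACGT":
            values[f"frac_{b.lower()}"][i] = counts[b] / denom if denom else np.nan
    return WindowTrack(genome.id, spec, windows, values)


def orf_organization_track(
    orfs: list[OrfRecord], contig_len: int, spec: WindowSpec, contig_id: str = ""
) -> WindowTrack:
    """Quantify ORF organization per window.

    An ORF belongs to the windows that contain its midpoint.  Per window:
    median ORF length, median intergenic gap between consecutive member
    ORFs, number of strand switches between consecutive member ORFs, and
    coding density (fraction of window positions covered by any ORF).
    Windows with fewer than two member ORFs report missing medians and
    switch counts; density is always defined.
    """
    for orf in orfs:
        if orf.start < 1 or orf.end > contig_len:
            raise InputError(
                f"ORF {orf.contig_id}:{orf.start}-{orf.end} outside contig of "
                f"length {contig_len}"
            )
    orfs = sorted(orfs, key=lambda o: (o.start, o.end))
    coded = np.zeros(contig_len + 1, dtype=np.int32)  # diff array, 1-based
    for orf in orfs:
        coded[orf.start - 1] += 1
        coded[orf.end] -= 1
    covered = np.cumsum(coded[:-1]) > 0
    cum_cov = np.concatenate(([0], np.cumsum(covered)))

    windows = enumerate_windows(contig_len, spec, contig_id)
    n = len(windows)
    med_len = np.full(n, np.nan)
    med_gap = np.full(n, np.nan)
    switches = np.full(n, np.nan)
    density = np.empty(n)
    mids = np.array([o.midpoint for o in orfs]) if orfs else np.empty(0, dtype=int)
    for i, w in enumerate(windows):
        density[i] = (cum_cov[w.end] - cum_cov[w.start - 1]) / w.length
        if len(orfs) == 0:
            continue
        lo = int(np.searchsorted(mids, w.start, side="left"))
        hi = int(np.searchsorted(mids, w.end, side="right"))
        members = orfs[lo:hi]
        if len(members) < 2:
            continue
        med_len[i] = float(np.median([o.length for o in members]))
        gaps = [b.start - a.end - 1 for a, b in zip(members, members[1:])]
        med_gap[i] = float(np.median(gaps))
        switches[i] = float(
            sum(a.strand != b.strand for a, b in zip(members, members[1:]))
        )
    return WindowTrack(
        contig_id,
        spec,
        windows,
        {
            "orf_median_len": med_len,
            "orf_median_gap": med_gap,
            "orf_strand_switches": switches,
            "coding_density": density,
        },
    )


def depth_breadth_tracks(depth: DepthProfile, contig_len: int, spec: WindowSpec) -> WindowTrack:
    """Per-window mean coverage depth and breadth (fraction of positions
    with depth > 0)."""
    if len(depth.depth) != contig_len:
        raise InputError(
            f"depth array length {len(depth.depth)} != contig length {contig_len} "
            f"for {depth.contig_id}"
        )
    d = np.asarray(depth.depth, dtype=float)
    cum_d = np.concatenate(([0.0], np.cumsum(d)))
    cum_b = np.concatenate(([0], np.cumsum(d > 0)))
    windows = enumerate_windows(contig_len, spec, depth.contig_id)
    mean_depth = np.empty(len(windows))
    breadth = np.empty(len(windows))
    for i, w in enumerate(windows):
        mean_depth[i] = (cum_d[w.end] - cum_d[w.start - 1]) / w.length
        breadth[i] = (cum_b[w.end] - cum_b[w.start - 1]) / w.length
    return WindowTrack(
        depth.contig_id, spec, windows, {"depth_mean": mean_depth, "breadth": breadth}
    )


@dataclass(frozen=True)
class SampleDecision:
    sample_id: str
    breadth: float
    excluded: bool


def contamination_filter(
    depths: dict[str, list[DepthProfile]],
    thr: Thresholds = DEFAULT_THRESHOLDS,
) -> list[SampleDecision]:
    """Flag virome samples likely contaminated with host DNA.

    ``depths`` maps sample id to the depth profiles over *all* contigs of
    one strain.  A sample is excluded when reads cover strictly more than
    ``contamination_breadth_max`` (default 25%) of the cumulative contig
    length.
    """
    decisions = []
    for sample_id in sorted(depths):
        profiles = depths[sample_id]
        if not profiles:
            raise InputError(f"sample {sample_id}: no depth profiles")
        total = sum(len(p.depth) for p in profiles)
        covered = sum(int(np.count_nonzero(np.asarray(p.depth) > 0)) for p in profiles)
        breadth = covered / total
        decisions.append(
            SampleDecision(sample_id, breadth, breadth > thr.contamination_breadth_max)
        )
    return decisions


@dataclass(frozen=True)
class CoverageRatio:
    ratio: float
    infinite: bool
    mean_inside: float
    mean_outside: float


def coverage_ratio(depth: DepthProfile, prophage: Interval) -> CoverageRatio:
    """Mean depth over the prophage region divided by mean depth over the
    rest of the contig.

    An elevated ratio indicates active (induced) replication of the
    prophage.  A zero background is reported as an infinite ratio with a
    flag rather than an exception.
    """
    n = len(depth.depth)
    if prophage.start < 1 or prophage.end > n:
        raise InputError(f"prophage interval outside contig of length {n}")
    if prophage.length >= n:
        raise InputError("prophage region must not cover the whole contig")
    d = np.asarray(depth.depth, dtype=float)
    mask = np.zeros(n, dtype=bool)
    mask[prophage.start - 1 : prophage.end] = True
    inside = float(d[mask].mean())
    outside = float(d[~mask].mean())
    if outside == 0.0:
        return CoverageRatio(float("inf"), True, inside, outside)
    return CoverageRatio(inside / outside, False, inside, outside)


# --- candidate-region calling -------------------------------------------

# Expected direction of each signal inside a prophage relative to host
# background: +1 elevated, -1 depressed, 0 unsigned (absolute deviation).
SIGNAL_ORIENTATION: dict[str, int] = {
    "depth_mean": +1,
    "breadth": +1,
    "coding_density": +1,
    "orf_median_len": -1,
    "orf_median_gap": -1,
    "orf_strand_switches": -1,
    "gc_content": 0,
}

_CONTENT_COLS = ("frac_a", "frac_c", "frac_g", "frac_t")


@dataclass(frozen=True)
class RegionCallConfig:
    z_cutoff: float = 3.0
    min_region_len: int = 15_000
    max_gap_windows: int = 1
    predictor_weight: float = 2.0


@dataclass
class CandidateRegion:
    interval: Interval
    n_windows: int
    mean_score: float
    signal_means: dict[str, float] = field(default_factory=dict)


_Z_CLIP = 20.0


def _robust_z(x: np.ndarray) -> np.ndarray:
    """Robust z-score: median-centred, MAD-scaled.

    Discrete or saturated signals can have zero MAD while still varying;
    the scale then falls back to the mean absolute deviation.  A truly
    constant signal is uninformative (z = 0), and extreme scores are
    clipped so that no single signal dominates the evidence sum."""
    med = np.nanmedian(x)
    dev = x - med
    scale = 1.4826 * np.nanmedian(np.abs(dev))
    if scale == 0 or np.isnan(scale):
        scale = 1.2533 * np.nanmean(np.abs(dev))
    if scale == 0 or np.isnan(scale):
        return np.where(np.isnan(dev), np.nan, 0.0)
    return np.clip(dev / scale, -_Z_CLIP, _Z_CLIP)


def call_candidate_regions(
    tracks: list[WindowTrack],
    predictor_intervals: list[Interval] | None = None,
    config: RegionCallConfig = RegionCallConfig(),
) -> list[CandidateRegion]:
    """Combine evidence tracks into candidate prophage regions.

    Each signal column is converted to a robust z-score (median/MAD over the
    contig) and oriented so that the prophage-like direction is positive;
    nucleotide-content columns are collapsed into a single unsigned
    GC-deviation signal.  Windows whose summed oriented z-score exceeds
    ``z_cutoff`` are merged when adjacent or separated by at most
    ``max_gap_windows`` windows, and merged regions shorter than
    ``min_region_len`` are dropped.  Optional external predictor intervals
    add ``predictor_weight`` to the score of every window they cover.
    """
    if not tracks:
        raise InputError("no tracks supplied")
    contig = tracks[0].contig_id
    spec = tracks[0].spec
    windows = tracks[0].windows
    for t in tracks[1:]:
        if t.contig_id != contig:
            raise InputError(
                f"tracks on different contigs: {contig!r} vs {t.contig_id!r}"
            )
        if t.spec != spec or len(t.windows) != len(windows):
            raise InputError("tracks use different window conventions")

    signals: dict[str, np.ndarray] = {}
    for t in tracks:
        if all(c in t.values for c in _CONTENT_COLS):
            signals["gc_content"] = t.values["frac_g"] + t.values["frac_c"]
            for name, col in t.values.items():
                if name not in _CONTENT_COLS:
                    signals[name] = col
        else:
            signals.update(t.values)

    n = len(windows)
    score = np.zeros(n)
    zscores: dict[str, np.ndarray] = {}
    for name, col in signals.items():
        orient = SIGNAL_ORIENTATION.get(name, 0)
        z = _robust_z(np.asarray(col, dtype=float))
        z = np.abs(z) if orient == 0 else orient * z
        zscores[name] = z
        score += np.where(np.isnan(z), 0.0, z)

    if predictor_intervals:
        for i, w in enumerate(windows):
            if any(w.overlaps(p) for p in predictor_intervals):
                score[i] += config.predictor_weight

    above = score > config.z_cutoff
    regions: list[CandidateRegion] = []
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        last_hit = i
        while j + 1 < n:
            nxt = j + 1
            if above[nxt]:
                j = nxt
                last_hit = nxt
            elif nxt - last_hit <= config.max_gap_windows:
                j = nxt
            else:
                break
        j = last_hit
        interval = Interval(contig, windows[i].start, windows[j].end)
        if interval.length >= config.min_region_len:
            member = slice(i, j + 1)
            regions.append(
                CandidateRegion(
                    interval,
                    j - i + 1,
                    float(np.mean(score[member])),
                    {
                        name: float(np.nanmean(z[member]))
                        if not np.all(np.isnan(z[member]))
                        else float("nan")
                        for name, z in zscores.items()
                    },
                )
            )
        i = j + 1
    return regions


@dataclass(frozen=True)
class TerminusCall:
    left: int | None
    right: int | None
    support_left: int
    support_right: int
    total: int

    @property
    def explained_fraction(self) -> float:
        return (self.support_left + self.support_right) / self.total


def call_transposable_termini(
    junctions: list[tuple[int, int]] | list[int],
) -> TerminusCall:
    """Call the two genome termini of a transposable prophage from
    split-read junction positions.

    Junctions are aggregated per exact position; the two modal positions
    (highest support) are the termini, reported left/right by coordinate
    with their support counts.  Ties are broken toward the smaller
    coordinate.  A single observed position yields one terminus with the
    second reported missing.
    """
    if not junctions:
        raise InputError("no junction records")
    counts: dict[int, int] = {}
    for rec in junctions:
        if isinstance(rec, tuple):
            pos, c = rec
        else:
            pos, c = int(rec), 1
        if c < 0:
            raise InputError("negative junction count")
        counts[pos] = counts.get(pos, 0) + c
    total = sum(counts.values())
    # modal positions, ties toward smaller coordinate
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) == 1:
        (pos, sup), = ranked
        return TerminusCall(pos, None, sup, 0, total)
    (p1, s1), (p2, s2) = ranked[0], ranked[1]
    if p1 > p2:
        (p1, s1), (p2, s2) = (p2, s2), (p1, s1)
    return TerminusCall(p1, p2, s1, s2, total)
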