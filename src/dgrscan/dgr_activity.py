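"""Quantifying DGR activity from cognate-genome MSAs and read pileups.

Activity of a diversity-generating retroelement leaves two measurable
footprints: across near-identical (cognate) genomes, variable regions show
a spike in per-column nucleotide variation together with a loss of adenine
conservation; within a single host culture, mapped reads show elevated
minor-allele fractions at VR positions.  Both signals are summarized with
the phage windowing convention (101-nt window, 20-nt step, 50-nt terminal
extension).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_scan import enumerate_windows
from .types import (
    BOUNDARY_EPS,
    DEFAULT_THRESHOLDS,
    GenomeRecord,
    InputError,
    Interval,
    PHAGE_WINDOWS,
    PileupCounts,
    Thresholds,
    WindowSpec,
    WindowTrack,
)

__all__ = [
    "MsaColumnStats",
    "msa_column_stats",
    "variation_track",
    "adenine_conservation_track",
    "pileup_variation",
    "pileup_variation_track",
    "sample_inclusion",
    "vr_activity_call",
    "VrActivity",
]

# symbol codes; argmax order implements the A < C < G < T < gap < other
# tie-break for the most frequent symbol
_SYMBOLS = "ACGT-"
_CODE = {c: i for i, c in enumerate(_SYMBOLS)}
_OTHER = 5


def _encode_rows(rows: list[str]) -> np.ndarray:
    table = np.full(256, _OTHER, dtype=np.uint8)
    for c, i in _CODE.items():
        table[ord(c)] = i
        table[ord(c.lower())] = i
    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return table[arr].reshape(len(rows), -1)


@dataclass
class MsaColumnStats:
    """Per-reference-position column statistics of a cognate-genome MSA.

    Columns where the reference holds a gap are excluded; the remaining
    columns are indexed by reference position 1..L.  ``variation`` is the
    proportion of symbols different from the most frequent one;
    ``conserved`` marks columns whose most frequent symbol reaches the
    conservation threshold (>=90% by default); ``conserved_a`` marks
    conserved columns whose most frequent symbol is adenine.
    """

    reference_id: str
    n_rows: int
    counts: np.ndarray  # (6, L): A, C, G, T, gap, other
    variation: np.ndarray
    mode_symbol: np.ndarray  # symbol codes
    conserved: np.ndarray
    conserved_a: np.ndarray

    @property
    def length(self) -> int:
        return self.counts.shape[1]


def msa_column_stats(
    msa: list[GenomeRecord],
    reference_id: str,
    thr: Thresholds = DEFAULT_THRESHOLDS,
) -> MsaColumnStats:
    """Column variation and conservation of an MSA relative to a reference
    row.

    Gap symbols of non-reference rows count as a fifth symbol in the
    column tallies; ties for the most frequent symbol are broken by the
    fixed order A < C < G < T < gap.
    """
    if not msa:
        raise InputError("empty alignment")
    lengths = {len(r.seq) for r in msa}
    if len(lengths) != 1:
        raise InputError("ragged alignment: rows differ in length")
    ref_rows = [r for r in msa if r.id == reference_id]
    if not ref_rows:
        raise InputError(f"reference {reference_id!r} absent from alignment")
    arr = _encode_rows([r.seq for r in msa])
    ref = _encode_rows([ref_rows[0].seq])[0]
    keep = ref != _CODE["-"]
    arr = arr[:, keep]
    n, L = arr.shape
    counts = np.stack([(arr == c).sum(axis=0) for c in range(6)]).astype(np.int64)
    max_count = counts[:5].max(axis=0)  # ties resolved by symbol order
    mode = counts[:5].argmax(axis=0).astype(np.uint8)
    # 'other' symbols can in principle outnumber real symbols; they never
    # become the mode but they do count toward the column size
    variation = 1.0 - max_count / n
    conserved = max_count / n >= thr.conserved_col_min - BOUNDARY_EPS
    conserved_a = conserved & (mode == _CODE["A"])
    return MsaColumnStats(reference_id, n, counts, variation, mode, conserved, conserved_a)


def variation_track(
    variation: np.ndarray | MsaColumnStats,
    spec: WindowSpec = PHAGE_WINDOWS,
    contig_id: str = "",
) -> WindowTrack:
    """Windowed arithmetic mean of per-position variation.

    Accepts either an :class:`MsaColumnStats` or a raw per-position array
    (possibly containing NaN for undefined positions, which are skipped;
    all-NaN windows are missing).
    """
    if isinstance(variation, MsaColumnStats):
        contig_id = contig_id or variation.reference_id
        variation = variation.variation
    v = np.asarray(variation, dtype=float)
    if v.size == 0:
        raise InputError("empty variation array")
    windows = enumerate_windows(len(v), spec, contig_id)
    means = np.empty(len(windows))
    for i, w in enumerate(windows):
        chunk = v[w.start - 1 : w.end]
        means[i] = np.nanmean(chunk) if not np.all(np.isnan(chunk)) else np.nan
    return WindowTrack(contig_id, spec, windows, {"variation": means})


def adenine_conservation_track(
    stats: MsaColumnStats,
    spec: WindowSpec = PHAGE_WINDOWS,
) -> WindowTrack:
    """Percent of conserved adenine columns among all conserved columns in
    each sliding window; windows with no conserved column are missing."""
    if stats.length == 0:
        raise InputError("empty column statistics")
    cum_c = np.concatenate(([0], np.cumsum(stats.conserved)))
    cum_a = np.concatenate(([0], np.cumsum(stats.conserved_a)))
    windows = enumerate_windows(stats.length, spec, stats.reference_id)
    vals = np.empty(len(windows))
    for i, w in enumerate(windows):
        n_cons = cum_c[w.end] - cum_c[w.start - 1]
        n_a = cum_a[w.end] - cum_a[w.start - 1]
        vals[i] = 100.0 * n_a / n_cons if n_cons else np.nan
    return WindowTrack(
        stats.reference_id, spec, windows, {"adenine_conservation": vals}
    )


def pileup_variation(pileup: PileupCounts) -> np.ndarray:
    """Per-position proportion of read nucleotides different from the most
    frequent one; positions with zero depth are missing (NaN)."""
    depth = pileup.depth.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = 1.0 - pileup.counts.max(axis=0) / depth
    var[depth == 0] = np.nan
    return var


def pileup_variation_track(
    pileup: PileupCounts, spec: WindowSpec = PHAGE_WINDOWS
) -> WindowTrack:
    return variation_track(pileup_variation(pileup), spec, pileup.genome_id)


@dataclass(frozen=True)
class InclusionDecision:
    sample_id: str
    breadth_at_min_depth: float
    included: bool


def sample_inclusion(
    pileup: PileupCounts, thr: Thresholds = DEFAULT_THRESHOLDS
) -> InclusionDecision:
    """Keep a sample only when coverage depth >= ``pileup_min_depth`` holds
    along >= ``pileup_min_breadth`` of the genome length (both boundaries
    inclusive)."""
    depth = pileup.depth
    breadth = float(np.count_nonzero(depth >= thr.pileup_min_depth)) / pileup.length
    return InclusionDecision(
        pileup.sample_id, breadth, breadth >= thr.pileup_min_breadth - BOUNDARY_EPS
    )


@dataclass
class VrActivity:
    vr: Interval
    active: bool
    effect_size: float
    vr_mean: float
    genome_median: float
    genome_mad: float


def vr_activity_call(
    track: WindowTrack,
    vrs: list[Interval],
    k: float = 5.0,
    column: str = "variation",
) -> list[VrActivity]:
    """Flag variable regions whose windowed variation stands out from the
    genome background.

    A VR is active when the mean value of windows intersecting it exceeds
    the genome-wide median by more than ``k`` median absolute deviations;
    the effect size is (VR mean - median) / MAD.
    """
    vals = track.values[column]
    genome_end = track.windows[-1].end
    med = float(np.nanmedian(vals))
    mad = float(np.nanmedian(np.abs(vals - med)))
    out = []
    for vr in vrs:
        if vr.start < 1 or vr.end > genome_end:
            raise InputError(f"VR {vr.start}-{vr.end} outside genome")
        member = [
            vals[i] for i, w in enumerate(track.windows) if w.overlaps(
                Interval(w.contig_id, vr.start, vr.end)
            )
        ]
        member = [v for v in member if not np.isnan(v)]
        vr_mean = float(np.mean(member)) if member else float("nan")
        if mad > 0:
            effect = (vr_mean - med) / mad
        else:
            effect = float("inf") if vr_mean > med else 0.0
        active = bool(vr_mean > med + k * mad)
        out.append(VrActivity(vr, active, effect, vr_mean, med, mad))
    return out
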