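"""Core domain types shared by every stage of the pipeline.

Coordinates are 1-based inclusive everywhere in the public API and in every
report; the only exception is BED output, converted centrally in
:mod:`dgrscan.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NUCLEOTIDES = "ACGT"
VALID_CHARS = frozenset("ACGTN")


class InputError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 1-based inclusive on a named sequence."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise InputError(
                f"invalid interval {self.contig_id}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_len(self, other: "Interval") -> int:
        if self.contig_id != other.contig_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def overlaps(self, other: "Interval") -> bool:
        return self.overlap_len(other) > 0

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def gap_to(self, other: "Interval") -> int:
        """Distance in nt between two intervals; 0 when they touch or overlap."""
        if self.overlaps(other):
            return 0
        if other.start > self.end:
            return other.start - self.end - 1
        return self.start - other.end - 1


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence over the alphabet {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("empty sequence identifier")

    @property
    def length(self) -> int:
        return len(self.seq)

    def validate_alphabet(self) -> None:
        for i, ch in enumerate(self.seq):
            if ch.upper() not in VALID_CHARS:
                raise InputError(
                    f"sequence {self.id}: invalid character {ch!r} at position {i + 1}"
                )


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window convention: width W, step S, 3'-terminal extension E.

    The bacterial-contig convention is (3001, 500, 1500); the phage-genome
    convention is (101, 20, 50).
    """

    window: int
    step: int
    terminal_extension: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.step < 1 or self.terminal_extension < 0:
            raise InputError(f"invalid window spec {self}")
        if self.step > self.window:
            raise InputError("step must not exceed window size")


BACTERIAL_WINDOWS = WindowSpec(3001, 500, 1500)
PHAGE_WINDOWS = WindowSpec(101, 20, 50)


@dataclass(frozen=True)
class OrfRecord:
    """A predicted ORF on a contig (1-based inclusive, stranded)."""

    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise InputError(
                f"invalid ORF {self.contig_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def interval(self) -> Interval:
        return Interval(self.contig_id, self.start, self.end)


@dataclass
class DepthProfile:
    """Per-base read depth along one contig for one sample."""

    contig_id: str
    sample_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise InputError("depth must be one-dimensional")
        if np.any(self.depth < 0):
            raise InputError(f"negative depth for contig {self.contig_id}")


@dataclass
class PileupCounts:
    """Per-position counts of mapped-read nucleotides on one genome.

    ``counts`` is a (4, L) array in A, C, G, T order.
    """

    genome_id: str
    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise InputError("pileup counts must have shape (4, L)")
        if np.any(self.counts < 0):
            raise InputError(f"negative pileup count for {self.genome_id}")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass
class WindowTrack:
    """Per-window values of one or more named signals along a sequence."""

    contig_id: str
    spec: WindowSpec
    windows: list[Interval]
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (len(self.windows),):
                raise InputError(
                    f"track column {name!r}: {arr.shape} values for "
                    f"{len(self.windows)} windows"
                )
            self.values[name] = arr

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def to_dataframe(self):
        import pandas as pd

        data = {
            "contig": [w.contig_id for w in self.windows],
            "win_start": [w.start for w in self.windows],
            "win_end": [w.end for w in self.windows],
        }
        data.update({k: v for k, v in self.values.items()})
        return pd.DataFrame(data)


@dataclass(frozen=True)
class Thresholds:
    """Every numeric cutoff used by the pipeline, with its default.

    Defaults follow the study conventions: contamination if a virome sample
    covers >25% of a strain's cumulative contig length; detection at >=75%
    read breadth (metagenome) or >=95% hit coverage (isolate / cognate);
    DGR repeats at alignment length >=90, identity >=50%, >=5 mismatches,
    >=75% adenine-mismatch fraction; RT annotation at >=100 aa envelope
    coverage; pileup samples at depth >=10 over >=95% of the genome;
    species clustering at ANI >=95% with >=85% coverage of the shorter
    genome; 12-nt seed words for the self-comparison.
    """

    contamination_breadth_max: float = 0.25
    metagenome_detect_breadth: float = 0.75
    isolate_detect_cov: float = 0.95
    cognate_cov: float = 0.95
    cp_db_match_cov: float = 0.30
    spacer_identity_min: float = 0.95
    dgr_min_aln_len: int = 90
    dgr_min_pid: float = 50.0
    dgr_min_mismatch: int = 5
    dgr_min_a_fraction: float = 0.75
    conserved_col_min: float = 0.90
    rt_min_cov: int = 100
    pileup_min_depth: int = 10
    pileup_min_breadth: float = 0.95
    ani_min: float = 95.0
    tcov_min: float = 85.0
    seed_word: int = 12


DEFAULT_THRESHOLDS = Thresholds()

# Tolerance for inclusive fraction boundaries computed from counts
# (e.g. 9/10 >= 0.9 must hold despite binary rounding of 0.9 * 10).
BOUNDARY_EPS = 1e-9
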