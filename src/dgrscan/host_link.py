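"""Phage-host linking, database detection, and species-level clustering.

Phages are linked to bacterial hosts either by near-complete genome
coverage of the phage by hits to a host contig (>=95%) or by CRISPR
spacer-protospacer matches (>=95% identity over the full spacer).
Presence in a read set uses coverage breadth (>=75% for metagenomes),
and similarity to database genomes uses merged-hit coverage fractions.
Species-level taxonomic units are formed by greedy clustering at
ANI >=95% with >=85% coverage of the shorter genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import (
    BOUNDARY_EPS,
    DEFAULT_THRESHOLDS,
    GenomeRecord,
    InputError,
    Thresholds,
    reverse_complement,
)

__all__ = [
    "HitInterval",
    "SpacerMatch",
    "SpeciesCluster",
    "merged_coverage_fraction",
    "detect",
    "match_spacers",
    "greedy_species_clusters",
]


@dataclass(frozen=True)
class HitInterval:
    """One pairwise alignment hit projected onto the query sequence."""

    query_id: str
    subject_id: str
    qstart: int
    qend: int
    pident: float = 100.0
    length: int = 0
    reverse: bool = False

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise InputError(
                f"hit {self.query_id}->{self.subject_id}: qstart > qend "
                "(normalize reversed hits with the strand flag)"
            )


def merged_coverage_fraction(hits: list[HitInterval], query_len: int) -> float:
    """Fraction of the query covered by the union of hit intervals."""
    if query_len < 1:
        raise InputError(f"nonpositive query length {query_len}")
    ivs = []
    for h in hits:
        if h.qend > query_len:
            raise InputError(
                f"hit {h.qstart}-{h.qend} beyond query length {query_len}"
            )
        ivs.append((h.qstart, h.qend))
    if not ivs:
        return 0.0
    ivs.sort()
    covered = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    covered += cur_e - cur_s + 1
    return covered / query_len


DETECT_MODES = {
    "metagenome": "metagenome_detect_breadth",
    "isolate": "isolate_detect_cov",
    "cp_db": "cp_db_match_cov",
    "cognate": "cognate_cov",
}


def detect(
    fraction: float, mode: str, thr: Thresholds = DEFAULT_THRESHOLDS
) -> bool:
    """Threshold a coverage or breadth fraction for one detection mode.

    Modes: ``metagenome`` (read breadth >=75%), ``isolate`` (hit coverage
    >=95%), ``cp_db`` (database-genome match, >=30% region coverage),
    ``cognate`` (cognate-genome identification, >=95%).  All boundaries
    inclusive.
    """
    if mode not in DETECT_MODES:
        raise InputError(f"unknown detection mode {mode!r}")
    if not 0.0 <= fraction <= 1.0:
        raise InputError(f"fraction {fraction} outside [0, 1]")
    threshold = getattr(thr, DETECT_MODES[mode])
    return fraction >= threshold - BOUNDARY_EPS


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    genome_id: str
    position: int  # 1-based start of the match on the forward strand
    strand: str
    mismatches: int
    identity: float


def match_spacers(
    spacers: list[GenomeRecord],
    genome: GenomeRecord,
    thr: Thresholds = DEFAULT_THRESHOLDS,
) -> list[SpacerMatch]:
    """Find protospacers: gap-free matches of CRISPR spacers on either
    strand of a genome.

    A spacer of length L may mismatch at up to floor((1 - identity_min) * L)
    positions (<=2 for typical 25-45 nt spacers at the 95% identity
    threshold), making an exhaustive Hamming scan both faithful and
    complete.  Matches are ordered by genome position, then strand (+ < -).
    Spacers containing N are skipped with a warning.
    """
    g = np.frombuffer(genome.seq.upper().encode("ascii"), dtype=np.uint8)
    n = len(g)
    out = []
    for spacer in spacers:
        if len(spacer.seq) < 20:
            raise InputError(f"spacer {spacer.id} shorter than 20 nt")
        if "N" in spacer.seq.upper():
            warnings.warn(f"spacer {spacer.id} contains N; skipped")
            continue
        L = len(spacer.seq)
        max_mm = int((1.0 - thr.spacer_identity_min) * L + BOUNDARY_EPS)
        for strand, query in (
            ("+", spacer.seq.upper()),
            ("-", reverse_complement(spacer.seq.upper())),
        ):
            if n < L:
                continue
            q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
            mm = np.zeros(n - L + 1, dtype=np.int32)
            for k in range(L):
                mm += g[k : n - L + 1 + k] != q[k]
            for pos in np.nonzero(mm <= max_mm)[0]:
                out.append(
                    SpacerMatch(
                        spacer.id,
                        genome.id,
                        int(pos) + 1,
                        strand,
                        int(mm[pos]),
                        1.0 - int(mm[pos]) / L,
                    )
                )
    out.sort(key=lambda m: (m.position, m.strand, m.spacer_id))
    return out


@dataclass
class SpeciesCluster:
    representative: str
    members: list[str]


def greedy_species_clusters(
    genomes: list[tuple[str, int]],
    pairwise: list[tuple[str, str, float, float]],
    thr: Thresholds = DEFAULT_THRESHOLDS,
) -> list[SpeciesCluster]:
    """Greedy species-level clustering of genomes from an ANI table.

    Genomes are sorted by length descending (ties by id); each genome
    joins the first existing cluster whose representative it matches at
    ANI >= ``ani_min`` and coverage of the shorter genome >=
    ``tcov_min``, else it founds a new cluster.  Pairwise values are
    symmetrized by taking the maximum of the two directions.
    """
    ids = {g[0] for g in genomes}
    table: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b, ani, tcov in pairwise:
        if a not in ids or b not in ids:
            unknown = a if a not in ids else b
            raise InputError(f"unknown genome id {unknown!r} in pair list")
        for key in ((a, b), (b, a)):
            prev = table.get(key)
            if prev is None:
                table[key] = (ani, tcov)
            else:
                table[key] = (max(prev[0], ani), max(prev[1], tcov))
    order = sorted(genomes, key=lambda g: (-g[1], g[0]))
    clusters: list[SpeciesCluster] = []
    for gid, _length in order:
        placed = False
        for cl in clusters:
            pair = table.get((gid, cl.representative))
            if pair is None:
                continue
            ani, tcov = pair
            if ani >= thr.ani_min - BOUNDARY_EPS and tcov >= thr.tcov_min - BOUNDARY_EPS:
                cl.members.append(gid)
                placed = True
                break
        if not placed:
            clusters.append(SpeciesCluster(gid, [gid]))
    return clusters
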