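"""Seeded synthetic data with the statistical structure each stage assumes.

Every simulator emulates one class of study input: a bacterial contig with
an embedded prophage of distinct gene architecture and nucleotide
composition; a DGR with a template repeat, adenine-diversified variable
repeats and an RT gene; sets of cognate genomes diversified at the VRs;
per-base depth profiles with elevated prophage coverage; read pileups with
VR minor-allele mixtures; CRISPR spacers; and split-read junctions at
prophage borders.  All ground truth (coordinates and parameters) is
recorded so recovery can be asserted, and identical seeds yield identical
outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any, Optional

import numpy as np

from .types import (
    DepthProfile,
    GenomeRecord,
    InputError,
    Interval,
    OrfRecord,
    PileupCounts,
)

__all__ = [
    "SimTruth",
    "simulate_host_with_prophage",
    "plant_dgr",
    "simulate_cognate_set",
    "simulate_depth_profile",
    "simulate_pileup",
    "simulate_spacers",
    "simulate_junctions",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {c: i for i, c in enumerate("ACGT")}


@dataclass
class SimTruth:
    """Ground truth recorded by a simulator run."""

    seed: int
    params: dict[str, Any] = field(default_factory=dict)
    prophage: Optional[Interval] = None
    tr: Optional[Interval] = None
    vrs: list[Interval] = field(default_factory=list)
    tr_a_offsets: list[int] = field(default_factory=list)
    vr_substitutions: list[list[int]] = field(default_factory=list)
    vr_target_positions: list[int] = field(default_factory=list)
    rt_orf: Optional[OrfRecord] = None
    coverage_ratio: Optional[float] = None
    spacers: list[dict[str, Any]] = field(default_factory=list)
    junction_borders: Optional[tuple[int, int]] = None
    adenine_rate: Optional[float] = None
    background_rate: Optional[float] = None

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        for key in ("prophage", "tr", "rt_orf"):
            if d[key] is not None:
                pass  # asdict already converted the dataclass
        return d


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    p = np.array([at, gc / 2.0, gc / 2.0, at])
    return rng.choice(_BASES, size=length, p=p)


def _to_str(codes: np.ndarray) -> str:
    return codes.tobytes().decode("ascii")


def _layout_orfs(
    rng: np.random.Generator,
    contig_id: str,
    region_start: int,
    region_end: int,
    gene_mean: float,
    gene_sd: float,
    gap_mean: float,
    switch_p: float,
    min_gene_len: int = 150,
) -> list[OrfRecord]:
    orfs = []
    pos = region_start
    strand = "+" if rng.random() < 0.5 else "-"
    while True:
        pos += int(round(rng.exponential(gap_mean))) + 1
        length = max(min_gene_len, int(round(rng.normal(gene_mean, gene_sd))))
        end = pos + length - 1
        if end > region_end:
            break
        orfs.append(OrfRecord(contig_id, pos, end, strand))
        if rng.random() < switch_p:
            strand = "+" if strand == "-" else "-"
        pos = end
    return orfs


def simulate_host_with_prophage(
    seed: int,
    host_len: int = 120_000,
    prophage_len: int = 40_000,
    host_gc: float = 0.56,
    prophage_gc: float = 0.48,
    host_gene_mean: float = 900.0,
    host_gene_sd: float = 300.0,
    prophage_gene_mean: float = 450.0,
    prophage_gene_sd: float = 150.0,
    host_gap_mean: float = 120.0,
    prophage_gap_mean: float = 40.0,
    host_switch_p: float = 0.35,
    prophage_switch_p: float = 0.08,
    contig_id: str = "contig_1",
) -> tuple[GenomeRecord, list[OrfRecord], SimTruth]:
    """A bacterial contig with an embedded prophage region.

    Host and prophage regions differ in GC content, gene-length and
    intergenic-gap distributions, and strand-switch probability,
    reproducing the organizational contrasts that make prophages visible
    in the evidence tracks.
    """
    if prophage_len >= host_len:
        raise InputError("prophage must be shorter than the host contig")
    rng = np.random.default_rng(seed)
    codes = _random_seq(rng, host_len, host_gc)
    margin = min(2000, (host_len - prophage_len) // 4)
    pro_start = int(
        rng.integers(1 + margin, host_len - prophage_len - margin + 2)
    )
    pro_end = pro_start + prophage_len - 1
    codes[pro_start - 1 : pro_end] = _random_seq(rng, prophage_len, prophage_gc)
    prophage = Interval(contig_id, pro_start, pro_end)

    orfs: list[OrfRecord] = []
    if pro_start > 300:
        orfs += _layout_orfs(
            rng, contig_id, 1, pro_start - 1,
            host_gene_mean, host_gene_sd, host_gap_mean, host_switch_p,
        )
    orfs += _layout_orfs(
        rng, contig_id, pro_start, pro_end,
        prophage_gene_mean, prophage_gene_sd, prophage_gap_mean, prophage_switch_p,
    )
    if host_len - pro_end > 300:
        orfs += _layout_orfs(
            rng, contig_id, pro_end + 1, host_len,
            host_gene_mean, host_gene_sd, host_gap_mean, host_switch_p,
        )
    truth = SimTruth(
        seed,
        params=dict(
            host_len=host_len, prophage_len=prophage_len,
            host_gc=host_gc, prophage_gc=prophage_gc,
        ),
        prophage=prophage,
    )
    return GenomeRecord(contig_id, _to_str(codes)), orfs, truth


_SEED_RUN = 12


def _anchored(offsets: np.ndarray, tr_len: int) -> bool:
    """True when a repeat pair mutated at ``offsets`` is fully recoverable:
    every alignment prefix and suffix scores strictly positive under +2/-3
    scoring (a local aligner can neither trim nor shift the planted
    extent), and at least one unmutated run of seed-word length remains
    (a word-seeded self-comparison can discover the pair at all)."""
    for i, o in enumerate(offsets):
        if 2 * (int(o) + 1) - 5 * (i + 1) <= 0:
            return False
    for i, o in enumerate(offsets[::-1]):
        if 2 * (tr_len - int(o)) - 5 * (i + 1) <= 0:
            return False
    if len(offsets):
        bounds = np.concatenate(([-1], offsets, [tr_len]))
        if np.max(np.diff(bounds)) - 1 < _SEED_RUN:
            return False
    return True


def plant_dgr(
    seed: int,
    genome: GenomeRecord,
    tr_len: int = 120,
    n_vr: int = 1,
    adenine_sub_count: Optional[int] = 8,
    adenine_sub_rate: Optional[float] = None,
    rt_orf: bool = True,
    min_separation: int = 300,
) -> tuple[GenomeRecord, list[OrfRecord], SimTruth]:
    """Plant a DGR: a template repeat copied to VR sites with
    adenine-targeted substitutions.

    A genome segment is designated the TR; each VR site receives an exact
    copy mutated only at interior positions (>= 3 nt from either repeat
    end) where the TR holds A (a fixed count or a per-position rate,
    substituting to C/G/T uniformly).  Interior placement plus an 8-nt
    mismatching flank barrier on each side of every VR make the planted
    repeat extent the unique optimal local alignment, so the mismatch
    count of the recovered alignment equals the planted count (a terminal
    substitution could otherwise be trimmed or gap-shifted away).  An
    optional placeholder RT ORF is placed next to the TR.
    """
    if tr_len < 90:
        raise InputError("tr_len must be >= 90")
    if adenine_sub_rate is not None:
        if not 0.0 <= adenine_sub_rate <= 1.0:
            raise InputError("adenine_sub_rate outside [0, 1]")
        adenine_sub_count = None  # rate mode overrides the count default
    elif adenine_sub_count is None:
        raise InputError("specify adenine_sub_count or adenine_sub_rate")
    rng = np.random.default_rng(seed)
    codes = np.frombuffer(genome.seq.upper().encode("ascii"), dtype=np.uint8).copy()
    n = len(codes)
    flank = 8
    edge = 3  # substitutions stay >= this far from either repeat end
    slot = tr_len + 2 * flank
    need = (n_vr + 1) * (slot + min_separation)
    if n < need:
        raise InputError(f"genome of {n} nt too short for {n_vr} VRs of {tr_len} nt")

    required = adenine_sub_count if adenine_sub_count is not None else 1
    # demand a surplus of adenine targets so an anchored substitution
    # arrangement (see _anchored) is sampleable even at high counts
    pool_size = required + max(4, required // 3)
    tr_start = None
    for _ in range(200):
        cand = int(rng.integers(flank + 1, n - slot))
        seg = codes[cand - 1 : cand - 1 + tr_len]
        a_int = np.nonzero(seg[edge : tr_len - edge] == ord("A"))[0] + edge
        if len(a_int) >= pool_size:
            tr_start = cand
            break
    if tr_start is None:
        raise InputError("could not place a template repeat with enough adenines")
    tr = Interval(genome.id, tr_start, tr_start + tr_len - 1)
    tr_seq = codes[tr.start - 1 : tr.end].copy()
    a_offsets = np.nonzero(tr_seq == ord("A"))[0]
    a_interior = a_offsets[(a_offsets >= edge) & (a_offsets < tr_len - edge)]
    codes[tr.start - 1 - flank : tr.start - 1] = ord("C")
    codes[tr.end : tr.end + flank] = ord("C")

    occupied = [(tr.start - flank, tr.end + flank)]
    vr_starts: list[int] = []
    for _ in range(n_vr):
        placed = False
        for _ in range(500):
            cand = int(rng.integers(flank + 1, n - slot))
            span = (cand - flank - min_separation, cand + tr_len - 1 + flank + min_separation)
            if all(span[1] < s or span[0] > e for s, e in occupied):
                occupied.append((cand - flank, cand + tr_len - 1 + flank))
                vr_starts.append(cand)
                placed = True
                break
        if not placed:
            raise InputError("could not place all variable repeats")

    others = {b: np.array([x for x in _BASES if x != b]) for b in _BASES}
    vrs = []
    vr_subs: list[list[int]] = []
    for vs in sorted(vr_starts):
        vr_seq = tr_seq.copy()
        chosen = None
        for _ in range(1000):
            if adenine_sub_count is not None:
                cand_subs = rng.choice(a_interior, size=adenine_sub_count, replace=False)
            else:
                cand_subs = a_interior[rng.random(len(a_interior)) < adenine_sub_rate]
            if _anchored(np.sort(cand_subs), tr_len):
                chosen = cand_subs
                break
        if chosen is None:
            raise InputError(
                "could not place substitutions with positive terminal anchors"
            )
        for off in np.sort(chosen):
            vr_seq[off] = rng.choice(others[ord("A")])
        codes[vs - 1 : vs - 1 + tr_len] = vr_seq
        # homopolymer barrier: VR flanks all-G vs TR flanks all-C mismatch
        # at every gap phasing, so local extension stops at the boundary
        codes[vs - 1 - flank : vs - 1] = ord("G")
        codes[vs - 1 + tr_len : vs - 1 + tr_len + flank] = ord("G")
        vrs.append(Interval(genome.id, vs, vs + tr_len - 1))
        vr_subs.append(sorted(int(vs + off) for off in np.asarray(chosen)))

    orfs = []
    rt = None
    if rt_orf:
        rt_len = 900
        if tr.end + 50 + rt_len <= n:
            rt = OrfRecord(genome.id, tr.end + 51, tr.end + 50 + rt_len, "+")
        elif tr.start - 50 - rt_len >= 1:
            rt = OrfRecord(genome.id, tr.start - 50 - rt_len, tr.start - 51, "+")
        if rt is not None:
            orfs.append(rt)

    truth = SimTruth(
        seed,
        params=dict(
            tr_len=tr_len, n_vr=n_vr,
            adenine_sub_count=adenine_sub_count, adenine_sub_rate=adenine_sub_rate,
        ),
        tr=tr,
        vrs=vrs,
        tr_a_offsets=[int(o) for o in a_offsets],
        vr_substitutions=vr_subs,
        vr_target_positions=sorted(
            int(vr.start + off) for vr in vrs for off in a_offsets
        ),
        rt_orf=rt,
    )
    return GenomeRecord(genome.id, _to_str(codes)), orfs, truth


def simulate_cognate_set(
    seed: int,
    genome: GenomeRecord,
    truth: SimTruth,
    n: int = 30,
    vr_adenine_rate: float = 0.3,
    background_rate: float = 0.002,
) -> tuple[list[GenomeRecord], SimTruth]:
    """Substitution-only cognate genomes diversified at the planted VRs.

    Each of ``n`` copies receives i.i.d. background substitutions
    genome-wide plus independent substitutions at the VR adenine-target
    positions at ``vr_adenine_rate``.  Because the cognates are
    substitution-only, the identity alignment is the true MSA; the
    reference genome is the first returned record.
    """
    if n < 2:
        raise InputError("need at least two cognate genomes")
    for rate in (vr_adenine_rate, background_rate):
        if not 0.0 <= rate <= 1.0:
            raise InputError(f"rate {rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    ref = np.frombuffer(genome.seq.upper().encode("ascii"), dtype=np.uint8)
    L = len(ref)
    targets = np.array(truth.vr_target_positions, dtype=int) - 1
    records = [GenomeRecord(genome.id, genome.seq.upper())]
    others = {b: np.array([x for x in _BASES if x != b]) for b in _BASES}
    for i in range(n):
        g = ref.copy()
        bg = np.nonzero(rng.random(L) < background_rate)[0]
        for pos in bg:
            g[pos] = rng.choice(others[g[pos]])
        if len(targets):
            hit = targets[rng.random(len(targets)) < vr_adenine_rate]
            for pos in hit:
                g[pos] = rng.choice(others[ref[pos]])
        records.append(GenomeRecord(f"cognate_{i + 1:03d}", _to_str(g)))
    out_truth = SimTruth(
        seed,
        params=dict(n=n),
        tr=truth.tr,
        vrs=list(truth.vrs),
        vr_target_positions=list(truth.vr_target_positions),
        adenine_rate=vr_adenine_rate,
        background_rate=background_rate,
    )
    return records, out_truth


def simulate_depth_profile(
    seed: int,
    contig_len: int,
    prophage: Optional[Interval],
    base_depth: float = 5.0,
    ratio: float = 50.0,
    sample_id: str = "sim",
    contig_id: str = "contig_1",
) -> tuple[DepthProfile, SimTruth]:
    """Poisson per-base depth, elevated ``ratio``-fold over the prophage."""
    rng = np.random.default_rng(seed)
    depth = rng.poisson(base_depth, size=contig_len)
    if prophage is not None:
        depth[prophage.start - 1 : prophage.end] = rng.poisson(
            base_depth * ratio, size=prophage.length
        )
    truth = SimTruth(
        seed,
        params=dict(base_depth=base_depth, ratio=ratio, contig_len=contig_len),
        prophage=prophage,
        coverage_ratio=ratio,
    )
    return DepthProfile(contig_id, sample_id, depth), truth


def simulate_pileup(
    seed: int,
    genome: GenomeRecord,
    depth: np.ndarray | DepthProfile,
    vr_target_positions: list[int],
    minor_fraction: float = 0.3,
    error_rate: float = 0.002,
    sample_id: str = "sim",
) -> tuple[PileupCounts, SimTruth]:
    """Read pileup counts with a planted minor allele at VR adenine targets.

    At every position the reference base dominates with a per-base
    sequencing error of ``error_rate`` spread uniformly over the other
    three bases; at VR target positions one fixed alternative base is
    present at ``minor_fraction`` of the reads.
    """
    rng = np.random.default_rng(seed)
    if isinstance(depth, DepthProfile):
        depth = depth.depth
    depth = np.asarray(depth, dtype=np.int64)
    seq = genome.seq.upper()
    if len(depth) != len(seq):
        raise InputError("depth array length differs from genome length")
    ref = np.array([_CODE.get(c, 0) for c in seq], dtype=np.int64)
    L = len(seq)
    counts = np.zeros((4, L), dtype=np.int64)

    targets = np.array(sorted(set(vr_target_positions)), dtype=int) - 1
    minor = np.zeros(L, dtype=np.int64)
    alt_codes = np.full(L, -1, dtype=np.int64)
    if len(targets):
        minor[targets] = rng.binomial(depth[targets], minor_fraction)
        for pos in targets:
            choices = [c for c in range(4) if c != ref[pos]]
            alt_codes[pos] = rng.choice(choices)
    err = rng.binomial(depth - minor, error_rate)
    counts[ref, np.arange(L)] = depth - minor - err
    for pos in np.nonzero(err)[0]:
        others = [c for c in range(4) if c != ref[pos]]
        split = rng.multinomial(err[pos], [1 / 3] * 3)
        for c, e in zip(others, split):
            counts[c, pos] += e
    for pos in targets:
        if minor[pos]:
            counts[alt_codes[pos], pos] += minor[pos]
    truth = SimTruth(
        seed,
        params=dict(minor_fraction=minor_fraction, error_rate=error_rate),
        vr_target_positions=sorted(int(p) + 1 for p in targets),
    )
    return PileupCounts(genome.id, sample_id, counts), truth


def simulate_spacers(
    seed: int,
    genome: GenomeRecord,
    n: int = 10,
    spacer_len: int = 34,
    mismatches: int = 0,
) -> tuple[list[GenomeRecord], SimTruth]:
    """CRISPR spacers excised from recorded genome positions and strands
    with exactly the requested number of substitutions each."""
    from .types import reverse_complement

    rng = np.random.default_rng(seed)
    L = genome.length
    if L < spacer_len:
        raise InputError("genome shorter than spacer length")
    if mismatches > spacer_len:
        raise InputError("more mismatches than spacer positions")
    spacers = []
    truth = SimTruth(seed, params=dict(n=n, spacer_len=spacer_len, mismatches=mismatches))
    others = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    for i in range(n):
        pos = int(rng.integers(1, L - spacer_len + 2))
        strand = "+" if rng.random() < 0.5 else "-"
        seg = genome.seq[pos - 1 : pos - 1 + spacer_len].upper()
        if strand == "-":
            seg = reverse_complement(seg)
        seg = list(seg)
        offs = sorted(rng.choice(spacer_len, size=mismatches, replace=False))
        for off in offs:
            seg[off] = others[seg[off]][int(rng.integers(3))]
        sid = f"spacer_{i + 1:03d}"
        spacers.append(GenomeRecord(sid, "".join(seg)))
        truth.spacers.append(
            dict(id=sid, position=pos, strand=strand, mismatch_offsets=[int(o) for o in offs])
        )
    return spacers, truth


def simulate_junctions(
    seed: int,
    contig_len: int,
    borders: tuple[int, int],
    n: int = 2000,
    noise_fraction: float = 0.1,
) -> tuple[list[int], SimTruth]:
    """Split-read junction positions: drawn at the two prophage borders
    with probability 1 - ``noise_fraction``, else uniformly."""
    if not 0.0 <= noise_fraction <= 1.0:
        raise InputError("noise_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    left, right = borders
    positions = []
    for _ in range(n):
        if rng.random() < noise_fraction:
            positions.append(int(rng.integers(1, contig_len + 1)))
        else:
            positions.append(left if rng.random() < 0.5 else right)
    truth = SimTruth(
        seed,
        params=dict(n=n, noise_fraction=noise_fraction, contig_len=contig_len),
        junction_borders=(left, right),
    )
    return positions, truth
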