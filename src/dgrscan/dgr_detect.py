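"""Detection of diversity-generating retroelements (DGRs) in phage genomes.

A DGR comprises a template repeat (TR), one or more variable repeats (VRs)
that receive adenine-targeted substitutions through error-prone reverse
transcription, and a reverse-transcriptase (RT) gene.  Detection proceeds
by genome self-comparison: near-identical repeat pairs are found with a
seed-and-extend local aligner (exact 12-nt seed words, gapped extension
with match +2 / mismatch -3 / gap open -5 / gap extend -2, both
orientations), then classified as DGR repeats when the alignment is >=90
columns long with >=50% identity, >=5 mismatches, and >=75% of mismatch
columns holding adenine on one side -- that side is the template repeat.
RT genes are recognized from profile-search domain tables by merged
envelope coverage, and repeat pairs sharing a template are assembled into
multi-VR loci with VR spans mapped onto target-protein coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio import Align

from .types import (
    DEFAULT_THRESHOLDS,
    GenomeRecord,
    InputError,
    Interval,
    OrfRecord,
    Thresholds,
    reverse_complement,
)

__all__ = [
    "RepeatAlignment",
    "RepeatPair",
    "Rejection",
    "DomainHit",
    "MergedCoverage",
    "ProteinAnnotation",
    "DgrVr",
    "DgrLocus",
    "find_repeat_alignments",
    "classify_dgr_pair",
    "merge_domain_envelopes",
    "annotate_proteins",
    "assemble_loci",
    "alignments_from_hit_table",
]

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2

# seed words occurring more often than this are treated as low-complexity
# and skipped during seeding
MAX_SEED_OCCURRENCES = 50
SEED_BAND = 20
SEED_JOIN_DIST = 200
EXTENSION_MARGIN = 150
RT_FAR_DISTANCE = 10_000


@dataclass
class RepeatAlignment:
    """A gapped local alignment between two genomic repeats.

    ``aligned_1`` reads the forward strand of ``interval_1``; for
    orientation ``"opposite"``, ``aligned_2`` reads the reverse complement
    of ``interval_2`` (i.e. its minus strand from ``interval_2.end``
    downward), so that column pairs are the aligned symbols.
    """

    interval_1: Interval
    interval_2: Interval
    orientation: str  # "same" | "opposite"
    aligned_1: str
    aligned_2: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.aligned_1) != len(self.aligned_2):
            raise InputError("aligned strings differ in length")
        if self.orientation not in ("same", "opposite"):
            raise InputError(f"invalid orientation {self.orientation!r}")

    @property
    def aln_len(self) -> int:
        return len(self.aligned_1)

    def _column_counts(self) -> tuple[int, int, int, int]:
        ident = mism = g1 = g2 = 0
        for a, b in zip(self.aligned_1, self.aligned_2):
            if a == "-":
                g1 += 1
            elif b == "-":
                g2 += 1
            elif a == b:
                ident += 1
            else:
                mism += 1
        return ident, mism, g1, g2

    @property
    def identities(self) -> int:
        return self._column_counts()[0]

    @property
    def mismatches(self) -> int:
        return self._column_counts()[1]

    @property
    def gaps_1(self) -> int:
        return self._column_counts()[2]

    @property
    def gaps_2(self) -> int:
        return self._column_counts()[3]

    @property
    def pid(self) -> float:
        return 100.0 * self.identities / self.aln_len if self.aln_len else 0.0

    def column_positions(self) -> list[tuple[Optional[int], Optional[int]]]:
        """Genome position (1-based) of each alignment column on both
        sides; None where the side has a gap."""
        out = []
        p1 = self.interval_1.start
        p2 = self.interval_2.start if self.orientation == "same" else self.interval_2.end
        step2 = 1 if self.orientation == "same" else -1
        for a, b in zip(self.aligned_1, self.aligned_2):
            q1 = q2 = None
            if a != "-":
                q1 = p1
                p1 += 1
            if b != "-":
                q2 = p2
                p2 += step2
            out.append((q1, q2))
        return out

    def swapped(self) -> "RepeatAlignment":
        """The same alignment with sides 1 and 2 exchanged."""
        if self.orientation == "same":
            a1, a2 = self.aligned_2, self.aligned_1
        else:
            a1 = reverse_complement(self.aligned_2)
            a2 = reverse_complement(self.aligned_1)
        return RepeatAlignment(
            self.interval_2, self.interval_1, self.orientation, a1, a2, self.score
        )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _gapped_rows(alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def _seed_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if "N" in word:
            continue
        index.setdefault(word, []).append(i)
    return index


def _cluster_hits(hits: list[tuple[int, int]]) -> list[tuple[int, int, int, int]]:
    """Cluster seed hits (i, j) on nearby diagonals into candidate segment
    pairs (imin, imax, jmin, jmax), 0-based inclusive of seed starts."""
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: (h[1] - h[0], h[0]))
    clusters = []
    cur = [hits[0]]
    for h in hits[1:]:
        prev = cur[-1]
        if abs((h[1] - h[0]) - (prev[1] - prev[0])) <= SEED_BAND and (
            0 <= h[0] - prev[0] <= SEED_JOIN_DIST
        ):
            cur.append(h)
        else:
            clusters.append(cur)
            cur = [h]
    clusters.append(cur)
    out = []
    for cl in clusters:
        iis = [h[0] for h in cl]
        jjs = [h[1] for h in cl]
        out.append((min(iis), max(iis), min(jjs), max(jjs)))
    return out


def _build_alignment(
    seq: str,
    n: int,
    s1_off: int,
    s2_off: int,
    alignment,
    orientation: str,
    contig_id: str,
) -> Optional[RepeatAlignment]:
    """Map a local alignment of two extracted windows back to forward-strand
    genome coordinates and canonicalize side order."""
    blocks = alignment.aligned
    if len(blocks[0]) == 0:
        return None
    t0, t1 = int(blocks[0][0][0]), int(blocks[0][-1][1])
    q0, q1 = int(blocks[1][0][0]), int(blocks[1][-1][1])
    a1, a2 = _gapped_rows(alignment)
    int1 = Interval(contig_id, s1_off + t0 + 1, s1_off + t1)
    if orientation == "same":
        int2 = Interval(contig_id, s2_off + q0 + 1, s2_off + q1)
    else:
        # s2 window was cut from the reverse complement; map back
        rc_start, rc_end = s2_off + q0, s2_off + q1  # 0-based half-open in rc space
        int2 = Interval(contig_id, n - rc_end + 1, n - rc_start)
    if int1.start == int2.start and int1.end == int2.end:
        return None  # trivial self-identity
    rep = RepeatAlignment(int1, int2, orientation, a1, a2, float(alignment.score))
    if (int2.start, int2.end) < (int1.start, int1.end):
        rep = rep.swapped()
    return rep


def find_repeat_alignments(
    genome: GenomeRecord, thr: Thresholds = DEFAULT_THRESHOLDS
) -> list[RepeatAlignment]:
    """Find repeat pairs by comparing a genome to itself in both
    orientations.

    Exact seed words of length ``thr.seed_word`` are clustered along
    diagonals and extended by gapped local alignment; the trivial
    self-identity and mirror duplicates are removed, alignments shorter
    than ``thr.dgr_min_aln_len`` or below ``thr.dgr_min_pid`` percent
    identity are discarded, and overlapping alignments are reduced to the
    highest-scoring representative per locus pair.  Output is sorted by
    (interval_1.start, interval_2.start).
    """
    seq = genome.seq.upper()
    n = len(seq)
    if n == 0:
        raise InputError(f"empty genome {genome.id}")
    if n < thr.dgr_min_aln_len:
        return []
    k = thr.seed_word
    aligner = _make_aligner()
    index = _seed_positions(seq, k)
    candidates: list[RepeatAlignment] = []

    # forward orientation: pairs of occurrences of the same word
    hits_fwd: list[tuple[int, int]] = []
    for word, positions in index.items():
        if len(positions) < 2 or len(positions) > MAX_SEED_OCCURRENCES:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                hits_fwd.append((positions[ai], positions[bi]))

    rcseq = reverse_complement(seq)
    hits_rc: list[tuple[int, int]] = []
    rc_index = _seed_positions(rcseq, k)
    for word, positions in index.items():
        rcpos = rc_index.get(word)
        if rcpos is None:
            continue
        if len(positions) > MAX_SEED_OCCURRENCES or len(rcpos) > MAX_SEED_OCCURRENCES:
            continue
        for i in positions:
            for j in rcpos:
                if i <= n - j - k:  # canonical representative of the mirror pair
                    hits_rc.append((i, j))

    for orientation, hits, target in (
        ("same", hits_fwd, seq),
        ("opposite", hits_rc, rcseq),
    ):
        for imin, imax, jmin, jmax in _cluster_hits(hits):
            if orientation == "same":
                # keep extraction windows disjoint so the extension cannot
                # collapse onto the self-identity diagonal
                margin = min(EXTENSION_MARGIN, max(0, (jmin - imax - k) // 2))
            else:
                margin = EXTENSION_MARGIN
            s1_off = max(0, imin - margin)
            s1 = seq[s1_off : min(n, imax + k + margin)]
            s2_off = max(0, jmin - margin)
            s2 = target[s2_off : min(n, jmax + k + margin)]
            if not s1 or not s2:
                continue
            alns = aligner.align(s1, s2)
            if alns.score <= 0:
                continue
            rep = _build_alignment(
                seq, n, s1_off, s2_off, alns[0], orientation, genome.id
            )
            if rep is None:
                continue
            if rep.aln_len < thr.dgr_min_aln_len or rep.pid < thr.dgr_min_pid:
                continue
            candidates.append(rep)

    # reduce overlapping alignments to the best representative per locus pair
    candidates.sort(
        key=lambda r: (-r.score, r.interval_1.start, r.interval_2.start)
    )
    accepted: list[RepeatAlignment] = []
    for rep in candidates:
        redundant = any(
            rep.orientation == acc.orientation
            and rep.interval_1.overlaps(acc.interval_1)
            and rep.interval_2.overlaps(acc.interval_2)
            for acc in accepted
        )
        if not redundant:
            accepted.append(rep)
    accepted.sort(key=lambda r: (r.interval_1.start, r.interval_2.start))
    return accepted


@dataclass
class RepeatPair:
    """An accepted DGR repeat pair with TR/VR role assignment.

    ``tr_strand`` is the strand of the DGR cassette relative to the
    alignment's own reading: ``"+"`` when the template-side mismatches hold
    adenine as read, ``"-"`` when they hold thymine (the cassette lies on
    the complementary strand)."""

    alignment: RepeatAlignment
    a_mismatch_fraction_1: float
    a_mismatch_fraction_2: float
    tr_side: int  # 1 or 2
    tr_strand: str  # "+" | "-"
    mismatch_positions_1: list[int]
    mismatch_positions_2: list[int]

    @property
    def tr(self) -> Interval:
        return self.alignment.interval_1 if self.tr_side == 1 else self.alignment.interval_2

    @property
    def vr(self) -> Interval:
        return self.alignment.interval_2 if self.tr_side == 1 else self.alignment.interval_1

    @property
    def vr_mismatch_positions(self) -> list[int]:
        return self.mismatch_positions_2 if self.tr_side == 1 else self.mismatch_positions_1


@dataclass(frozen=True)
class Rejection:
    reason: str


def classify_dgr_pair(
    aln: RepeatAlignment, thr: Thresholds = DEFAULT_THRESHOLDS
) -> RepeatPair | Rejection:
    """Decide whether a repeat alignment is a DGR TR/VR pair.

    Acceptance requires alignment length >= ``dgr_min_aln_len``, percent
    identity >= ``dgr_min_pid``, at least ``dgr_min_mismatch`` mismatch
    columns, and >= ``dgr_min_a_fraction`` of mismatch columns holding the
    adenine of the template on one side; that side is the template repeat.
    Because a self-comparison reads each repeat on an arbitrary strand,
    adenine bias is tested in both readings of both sides (A as given, T
    when the cassette lies on the complementary strand).  Gap columns are
    neither mismatches nor part of the bias denominator.  Ties in the bias
    fraction assign the template to side 1 and the forward reading.
    """
    if aln.aln_len < thr.dgr_min_aln_len:
        return Rejection(f"aln_len {aln.aln_len} < {thr.dgr_min_aln_len}")
    if aln.pid < thr.dgr_min_pid:
        return Rejection(f"pid {aln.pid:.1f} < {thr.dgr_min_pid}")
    mism_cols = []
    positions = aln.column_positions()
    for idx, (a, b) in enumerate(zip(aln.aligned_1, aln.aligned_2)):
        if a != "-" and b != "-" and a != b:
            mism_cols.append(idx)
    if len(mism_cols) < thr.dgr_min_mismatch:
        return Rejection(f"mismatches {len(mism_cols)} < {thr.dgr_min_mismatch}")
    n = len(mism_cols)
    frac = {
        (side, base): sum(1 for idx in mism_cols if row[idx] == base) / n
        for side, row in ((1, aln.aligned_1), (2, aln.aligned_2))
        for base in "AT"
    }
    best = max(frac.values())
    if best < thr.dgr_min_a_fraction:
        return Rejection(f"a_fraction {best:.3f} < {thr.dgr_min_a_fraction}")
    for side, base in ((1, "A"), (2, "A"), (1, "T"), (2, "T")):
        if frac[(side, base)] == best:
            tr_side, tr_strand = side, "+" if base == "A" else "-"
            break
    pos1 = [positions[idx][0] for idx in mism_cols]
    pos2 = [positions[idx][1] for idx in mism_cols]
    return RepeatPair(
        aln, frac[(1, "A")], frac[(2, "A")], tr_side, tr_strand, pos1, pos2
    )


# --- domain-hit post-processing -----------------------------------------


@dataclass(frozen=True)
class DomainHit:
    """One per-domain hit of a profile search against a protein."""

    protein_id: str
    profile_id: str
    env_start: int  # 1-based aa, inclusive
    env_end: int
    evalue: float

    def __post_init__(self) -> None:
        if self.env_start > self.env_end:
            raise InputError(
                f"domain hit {self.protein_id}/{self.profile_id}: "
                f"start {self.env_start} > end {self.env_end}"
            )
        if self.evalue < 0:
            raise InputError("negative e-value")


@dataclass
class MergedCoverage:
    protein_id: str
    profile_id: str
    coverage: int  # residues in the union of envelopes
    intervals: list[tuple[int, int]]
    min_evalue: float


def merge_domain_envelopes(hits: list[DomainHit]) -> dict[tuple[str, str], MergedCoverage]:
    """Union overlapping or adjacent envelope intervals per (protein,
    profile) pair and report the covered residue count."""
    groups: dict[tuple[str, str], list[DomainHit]] = {}
    for h in hits:
        groups.setdefault((h.protein_id, h.profile_id), []).append(h)
    out = {}
    for key, members in groups.items():
        ivs = sorted((h.env_start, h.env_end) for h in members)
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        coverage = sum(e - s + 1 for s, e in merged)
        out[key] = MergedCoverage(
            key[0],
            key[1],
            coverage,
            [(s, e) for s, e in merged],
            min(h.evalue for h in members),
        )
    return out


@dataclass(frozen=True)
class ProteinAnnotation:
    protein_id: str
    profile_id: str
    coverage: int
    evalue: float
    is_rt: bool


RT_PROFILE = "RVT_1"


def annotate_proteins(
    hits: list[DomainHit],
    thr: Thresholds = DEFAULT_THRESHOLDS,
    rt_profile: str = RT_PROFILE,
) -> dict[str, ProteinAnnotation]:
    """Choose one profile per protein from merged envelope coverages.

    Profiles covering fewer than ``thr.rt_min_cov`` residues are dropped;
    the maximal-coverage survivor wins, ties broken by smaller e-value then
    lexicographic profile id.  Proteins whose chosen profile is the
    reverse-transcriptase profile are flagged as RT genes.
    """
    merged = merge_domain_envelopes(hits)
    per_protein: dict[str, list[MergedCoverage]] = {}
    for (protein, _), cov in merged.items():
        if cov.coverage >= thr.rt_min_cov:
            per_protein.setdefault(protein, []).append(cov)
    annotations = {}
    for protein, covs in per_protein.items():
        best = min(covs, key=lambda c: (-c.coverage, c.min_evalue, c.profile_id))
        annotations[protein] = ProteinAnnotation(
            protein, best.profile_id, best.coverage, best.min_evalue,
            best.profile_id == rt_profile,
        )
    return annotations


# --- locus assembly ------------------------------------------------------


@dataclass
class VrTarget:
    orf: OrfRecord
    aa_start: int
    aa_end: int
    partial: bool


@dataclass
class DgrVr:
    interval: Interval
    orientation: str
    mismatch_positions: list[int]
    target: Optional[VrTarget] = None
    intergenic: bool = False


@dataclass
class DgrLocus:
    tr: Interval
    vrs: list[DgrVr]
    rt_orf: Optional[OrfRecord] = None
    rt_distance: Optional[int] = None
    rt_far: bool = False
    rt_missing: bool = False
    pairs: list[RepeatPair] = field(default_factory=list)


def _reciprocal_overlap(a: Interval, b: Interval) -> float:
    ov = a.overlap_len(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def _map_vr_to_protein(vr: Interval, orf: OrfRecord) -> VrTarget:
    ov_start = max(vr.start, orf.start)
    ov_end = min(vr.end, orf.end)
    if orf.strand == "+":
        aa_start = (ov_start - orf.start) // 3 + 1
        aa_end = (ov_end - orf.start) // 3 + 1
    else:
        aa_start = (orf.end - ov_end) // 3 + 1
        aa_end = (orf.end - ov_start) // 3 + 1
    partial = vr.start < orf.start or vr.end > orf.end
    return VrTarget(orf, aa_start, aa_end, partial)


def _interval_distance(
    a: Interval, b: Interval, genome_length: Optional[int], circular: bool
) -> int:
    d = a.gap_to(b)
    if circular and genome_length:
        span = max(a.end, b.end) - min(a.start, b.start) + 1
        d = min(d, max(0, genome_length - span))
    return d


def assemble_loci(
    pairs: list[RepeatPair],
    rt_orfs: list[OrfRecord],
    orfs: list[OrfRecord],
    genome_length: Optional[int] = None,
    circular: bool = False,
) -> list[DgrLocus]:
    """Group repeat pairs sharing a template repeat into DGR loci.

    Pairs whose TRs reciprocally overlap by at least 50% share one locus;
    the locus TR is the union of member TRs.  The nearest RT ORF is
    attached with its distance (circular distance when requested); VRs
    overlapping an ORF are mapped to 1-based protein coordinates (codons
    overlapped, respecting strand), VRs outside any ORF are flagged
    intergenic, and VRs extending past an ORF boundary are flagged partial.
    """
    if not pairs:
        return []
    n = len(pairs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _reciprocal_overlap(pairs[i].tr, pairs[j].tr) >= 0.5:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[RepeatPair]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(pairs[i])

    loci = []
    for members in groups.values():
        contig = members[0].tr.contig_id
        tr = Interval(
            contig,
            min(p.tr.start for p in members),
            max(p.tr.end for p in members),
        )
        vrs = []
        for p in sorted(members, key=lambda p: (p.vr.start, p.vr.end)):
            overlapping = [o for o in orfs if o.interval.overlaps(p.vr)]
            vr = DgrVr(p.vr, p.alignment.orientation, sorted(p.vr_mismatch_positions))
            if overlapping:
                best = max(o.interval.overlap_len(p.vr) for o in overlapping)
                target_orf = next(
                    o for o in overlapping if o.interval.overlap_len(p.vr) == best
                )
                vr.target = _map_vr_to_protein(p.vr, target_orf)
            else:
                vr.intergenic = True
            vrs.append(vr)
        locus = DgrLocus(tr, vrs, pairs=members)
        if rt_orfs:
            dists = [
                (_interval_distance(tr, o.interval, genome_length, circular), o)
                for o in rt_orfs
            ]
            d, orf = min(dists, key=lambda t: (t[0], t[1].start))
            locus.rt_orf = orf
            locus.rt_distance = d
            locus.rt_far = d > RT_FAR_DISTANCE
        else:
            locus.rt_missing = True
        loci.append(locus)
    loci.sort(key=lambda l: (l.tr.start, l.tr.end))
    return loci


def alignments_from_hit_table(
    genome: GenomeRecord,
    hits: list[dict],
    thr: Thresholds = DEFAULT_THRESHOLDS,
) -> list[RepeatAlignment]:
    """Build repeat alignments from a precomputed 12-column self-hit table.

    Tabular hits carry no per-column detail, so the segments named by the
    hit coordinates are re-aligned locally under the standard scoring to
    recover mismatch columns; trivial self-hits and mirror duplicates are
    removed and the usual length/identity gates applied.
    """
    seq = genome.seq.upper()
    n = len(seq)
    aligner = _make_aligner()
    out = []
    seen = set()
    for h in hits:
        if h["qseqid"] != genome.id or h["sseqid"] != genome.id:
            continue
        qs, qe = int(h["qstart"]), int(h["qend"])
        ss, se = int(h["sstart"]), int(h["send"])
        opposite = ss > se
        if opposite:
            ss, se = se, ss
        if (qs, qe) == (ss, se) and not opposite:
            continue  # trivial self-identity
        key = (min((qs, qe), (ss, se)), max((qs, qe), (ss, se)), opposite)
        if key in seen:
            continue
        seen.add(key)
        s1 = seq[qs - 1 : qe]
        seg2 = seq[ss - 1 : se]
        s2 = reverse_complement(seg2) if opposite else seg2
        alns = aligner.align(s1, s2)
        if alns.score <= 0:
            continue
        s2_off = (n - se) if opposite else (ss - 1)
        rep = _build_alignment(
            seq, n, qs - 1, s2_off, alns[0],
            "opposite" if opposite else "same", genome.id,
        )
        if rep is None:
            continue
        if rep.aln_len < thr.dgr_min_aln_len or rep.pid < thr.dgr_min_pid:
            continue
        out.append(rep)
    out.sort(key=lambda r: (r.interval_1.start, r.interval_2.start))
    return out
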