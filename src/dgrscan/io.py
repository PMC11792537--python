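"""Readers and writers for the interchange formats used by the pipeline.

All tabular and report coordinates are 1-based inclusive; BED output is
0-based half-open, converted only here.  Malformed lines raise
:class:`~dgrscan.types.InputError` naming the file and line number.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dgr_detect import DgrLocus, DomainHit
from .host_link import HitInterval
from .simulate import SimTruth
from .types import (
    DepthProfile,
    GenomeRecord,
    InputError,
    Interval,
    OrfRecord,
    PileupCounts,
    WindowTrack,
)

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# --- FASTA ---------------------------------------------------------------


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    records = [
        GenomeRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputError(f"{path}: no FASTA records")
    return records


def write_fasta(records: list[GenomeRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def read_alignment_fasta(path: str | Path) -> list[GenomeRecord]:
    """Aligned FASTA: every row must have the same length."""
    rows = read_fasta(path)
    if len({len(r.seq) for r in rows}) != 1:
        raise InputError(f"{path}: aligned FASTA rows differ in length")
    return rows


# --- GFF3 ----------------------------------------------------------------


def read_gff3(path: str | Path) -> list[OrfRecord]:
    orfs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise InputError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, _type, start, end, _score, strand, _phase, _attr = fields[:9]
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-integer coordinates")
            if e < s:
                raise InputError(f"{path}:{lineno}: end {e} < start {s}")
            if strand not in ("+", "-"):
                raise InputError(f"{path}:{lineno}: invalid strand {strand!r}")
            orfs.append(OrfRecord(seqid, s, e, strand))
    return orfs


def write_gff3(orfs: list[OrfRecord], path: str | Path, source: str = "dgrscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, o in enumerate(orfs, 1):
            fh.write(
                f"{o.contig_id}\t{source}\tCDS\t{o.start}\t{o.end}\t.\t"
                f"{o.strand}\t0\tID=orf_{i}\n"
            )


# --- depth & pileup tables ----------------------------------------------


def read_depth_table(
    path: str | Path, contig_lengths: dict[str, int], sample_id: str = "sample"
) -> dict[str, DepthProfile]:
    """Three-column (contig, 1-based position, depth) table; positions
    absent from the file are depth 0."""
    arrays = {c: np.zeros(n, dtype=np.int64) for c, n in contig_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: expected 3 columns")
            contig, pos_s, depth_s = fields[0], fields[1], fields[2]
            if contig not in arrays:
                raise InputError(f"{path}:{lineno}: unknown contig {contig!r}")
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-integer position or depth")
            if not 1 <= pos <= contig_lengths[contig]:
                raise InputError(f"{path}:{lineno}: position {pos} out of range")
            if depth < 0:
                raise InputError(f"{path}:{lineno}: negative depth")
            arrays[contig][pos - 1] = depth
    return {c: DepthProfile(c, sample_id, a) for c, a in arrays.items()}


def write_depth_table(profiles: list[DepthProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in profiles:
            for i, d in enumerate(p.depth, 1):
                fh.write(f"{p.contig_id}\t{i}\t{int(d)}\n")


def read_pileup_table(
    path: str | Path, genome_len: int, sample_id: str = "sample"
) -> PileupCounts:
    """Per-position nucleotide-count table: genome, position, A, C, G, T."""
    counts = np.zeros((4, genome_len), dtype=np.int64)
    genome_id = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise InputError(f"{path}:{lineno}: expected 6 columns")
            gid = fields[0]
            if genome_id is None:
                genome_id = gid
            elif gid != genome_id:
                raise InputError(f"{path}:{lineno}: multiple genomes in one pileup")
            try:
                pos = int(fields[1])
                vals = [int(x) for x in fields[2:6]]
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-integer value")
            if not 1 <= pos <= genome_len:
                raise InputError(f"{path}:{lineno}: position {pos} out of range")
            counts[:, pos - 1] = vals
    if genome_id is None:
        raise InputError(f"{path}: empty pileup table")
    return PileupCounts(genome_id, sample_id, counts)


def write_pileup_table(pileup: PileupCounts, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#genome\tpos\tA\tC\tG\tT\n")
        for i in range(pileup.length):
            a, c, g, t = (int(x) for x in pileup.counts[:, i])
            fh.write(f"{pileup.genome_id}\t{i + 1}\t{a}\t{c}\t{g}\t{t}\n")


# --- alignment hit tables ------------------------------------------------


def read_hit_table(path: str | Path) -> list[dict]:
    """12-column tabular pairwise-alignment hits (blast outfmt 6 order)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise InputError(f"{path}:{lineno}: expected 12 columns")
            row = dict(zip(BLAST_COLUMNS, fields))
            try:
                for key in ("length", "mismatch", "gapopen", "qstart", "qend",
                            "sstart", "send"):
                    row[key] = int(row[key])
                for key in ("pident", "evalue", "bitscore"):
                    row[key] = float(row[key])
            except ValueError:
                raise InputError(f"{path}:{lineno}: malformed numeric field")
            rows.append(row)
    return rows


def hits_to_query_intervals(rows: list[dict]) -> list[HitInterval]:
    """Project tabular hits onto their query coordinates (reversed subject
    hits are normalized with the strand flag)."""
    out = []
    for row in rows:
        qs, qe = row["qstart"], row["qend"]
        reverse = row["sstart"] > row["send"]
        if qs > qe:
            qs, qe = qe, qs
            reverse = not reverse
        out.append(
            HitInterval(
                row["qseqid"], row["sseqid"], qs, qe,
                row["pident"], row["length"], reverse,
            )
        )
    return out


def read_domain_table(path: str | Path) -> list[DomainHit]:
    """Per-domain tabular output of a profile search (whitespace-delimited;
    target = protein in column 1, profile = query in column 4, independent
    e-value in column 13, envelope coordinates in columns 20-21)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise InputError(f"{path}:{lineno}: expected >=22 columns")
            try:
                hits.append(
                    DomainHit(
                        fields[0], fields[3],
                        int(fields[19]), int(fields[20]), float(fields[12]),
                    )
                )
            except ValueError:
                raise InputError(f"{path}:{lineno}: malformed numeric field")
    return hits


def read_ani_table(path: str | Path) -> list[tuple[str, str, float, float]]:
    """ANI table: id_a, id_b, ani percent, coverage-of-shorter percent."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise InputError(f"{path}:{lineno}: expected 4 columns")
            try:
                rows.append((fields[0], fields[1], float(fields[2]), float(fields[3])))
            except ValueError:
                raise InputError(f"{path}:{lineno}: malformed numeric field")
    return rows


def read_junction_table(path: str | Path) -> list[tuple[int, int]]:
    """Split-read junction table: contig, position, count."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: expected 3 columns")
            try:
                rows.append((int(fields[1]), int(fields[2])))
            except ValueError:
                raise InputError(f"{path}:{lineno}: malformed numeric field")
    return rows


def write_junction_table(
    positions: list[int], contig_id: str, path: str | Path
) -> None:
    counts: dict[int, int] = {}
    for p in positions:
        counts[p] = counts.get(p, 0) + 1
    with open(path, "w") as fh:
        for p in sorted(counts):
            fh.write(f"{contig_id}\t{p}\t{counts[p]}\n")


# --- track / region / locus output --------------------------------------


def write_track(track: WindowTrack, path: str | Path) -> None:
    track.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA")


def interval_to_bed(interval: Interval) -> tuple[str, int, int]:
    """1-based inclusive -> BED 0-based half-open."""
    return interval.contig_id, interval.start - 1, interval.end


def write_bed(intervals: list[Interval], path: str | Path, names=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            chrom, s, e = interval_to_bed(iv)
            name = names[i] if names else f"region_{i + 1}"
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def write_regions_tsv(regions, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tn_windows\tmean_score\n")
        for r in regions:
            fh.write(
                f"{r.interval.contig_id}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.n_windows}\t{r.mean_score:.3f}\n"
            )


def _locus_dict(locus: DgrLocus) -> dict:
    return {
        "tr": {"contig": locus.tr.contig_id, "start": locus.tr.start, "end": locus.tr.end},
        "vrs": [
            {
                "start": vr.interval.start,
                "end": vr.interval.end,
                "orientation": vr.orientation,
                "mismatch_positions": vr.mismatch_positions,
                "intergenic": vr.intergenic,
                "target": None
                if vr.target is None
                else {
                    "orf_start": vr.target.orf.start,
                    "orf_end": vr.target.orf.end,
                    "strand": vr.target.orf.strand,
                    "aa_start": vr.target.aa_start,
                    "aa_end": vr.target.aa_end,
                    "partial": vr.target.partial,
                },
            }
            for vr in locus.vrs
        ],
        "rt_orf": None
        if locus.rt_orf is None
        else {"start": locus.rt_orf.start, "end": locus.rt_orf.end, "strand": locus.rt_orf.strand},
        "rt_distance": locus.rt_distance,
        "rt_far": locus.rt_far,
        "rt_missing": locus.rt_missing,
        "pairs": [
            {
                "a_fraction_1": p.a_mismatch_fraction_1,
                "a_fraction_2": p.a_mismatch_fraction_2,
                "tr_side": p.tr_side,
                "aln_len": p.alignment.aln_len,
                "mismatches": p.alignment.mismatches,
                "pid": p.alignment.pid,
            }
            for p in locus.pairs
        ],
    }


def write_loci(loci: list[DgrLocus], prefix: str | Path) -> None:
    prefix = str(prefix)
    with open(f"{prefix}.json", "w") as fh:
        json.dump([_locus_dict(l) for l in loci], fh, indent=2)
    with open(f"{prefix}.tsv", "w") as fh:
        fh.write(
            "locus\ttr_start\ttr_end\tvr_start\tvr_end\torientation\t"
            "n_mismatches\trt_start\trt_end\trt_distance\taa_start\taa_end\n"
        )
        for i, locus in enumerate(loci, 1):
            for vr in locus.vrs:
                rt_s = locus.rt_orf.start if locus.rt_orf else "NA"
                rt_e = locus.rt_orf.end if locus.rt_orf else "NA"
                aa_s = vr.target.aa_start if vr.target else "NA"
                aa_e = vr.target.aa_end if vr.target else "NA"
                fh.write(
                    f"locus_{i}\t{locus.tr.start}\t{locus.tr.end}\t"
                    f"{vr.interval.start}\t{vr.interval.end}\t{vr.orientation}\t"
                    f"{len(vr.mismatch_positions)}\t{rt_s}\t{rt_e}\t"
                    f"{locus.rt_distance if locus.rt_distance is not None else 'NA'}\t"
                    f"{aa_s}\t{aa_e}\n"
                )
    intervals = []
    names = []
    for i, locus in enumerate(loci, 1):
        intervals.append(locus.tr)
        names.append(f"locus_{i}_TR")
        for j, vr in enumerate(locus.vrs, 1):
            intervals.append(vr.interval)
            names.append(f"locus_{i}_VR{j}")
    write_bed(intervals, f"{prefix}.bed", names)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, default=str)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
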