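"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: windowed statistics
are recomputed by slicing literal window positions, spacer matching by a
position-by-position Hamming scan, and repeat detection by an exhaustive
affine-gap Smith-Waterman over the full genome-vs-genome matrix with the
trivial self-identity diagonal forbidden.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 2
MIS = -3
OPEN = -5
EXT = -2
NEG = -(10**9)


@njit(cache=True)
def _sw_fill(a, b, forbid_diag):
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in a
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in b
    ptr = np.zeros((n + 1, m + 1, 3), dtype=np.int8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + OPEN
            e_ext = E[i, j - 1] + EXT
            if e_open >= e_ext:
                E[i, j] = e_open
                ptr[i, j, 1] = 0
            else:
                E[i, j] = e_ext
                ptr[i, j, 1] = 1
            f_open = H[i - 1, j] + OPEN
            f_ext = F[i - 1, j] + EXT
            if f_open >= f_ext:
                F[i, j] = f_open
                ptr[i, j, 2] = 0
            else:
                F[i, j] = f_ext
                ptr[i, j, 2] = 1
            s = MATCH if a[i - 1] == b[j - 1] else MIS
            h = H[i - 1, j - 1] + s
            p = 0
            if E[i, j] > h:
                h = E[i, j]
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if h <= 0:
                h = 0
                p = 3
            if forbid_diag and i == j:
                h = 0
                p = 3
                E[i, j] = NEG
                F[i, j] = NEG
            H[i, j] = h
            ptr[i, j, 0] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, ptr, best, bi, bj


def sw_best_local(seq1: str, seq2: str, forbid_diag: bool = False):
    """Best affine-gap local alignment (match +2 / mismatch -3 / gap open
    -5 / extend -2, the first gap position costing the open score).

    Returns (score, (a_start, a_end), (b_start, b_end), gapped_a, gapped_b)
    with 0-based half-open sequence ranges, or None when the best score is
    not positive.
    """
    a = np.frombuffer(seq1.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq2.encode("ascii"), dtype=np.uint8)
    H, E, F, ptr, best, bi, bj = _sw_fill(a, b, forbid_diag)
    if best <= 0:
        return None
    out_a = []
    out_b = []
    i, j, state = bi, bj, 0
    while True:
        if state == 0:
            p = ptr[i, j, 0]
            if p == 3 or H[i, j] == 0:
                break
            if p == 0:
                out_a.append(seq1[i - 1])
                out_b.append(seq2[j - 1])
                i -= 1
                j -= 1
            elif p == 1:
                state = 1
            else:
                state = 2
        elif state == 1:  # gap in a, consumes b
            p = ptr[i, j, 1]
            out_a.append("-")
            out_b.append(seq2[j - 1])
            j -= 1
            state = 0 if p == 0 else 1
        else:  # gap in b, consumes a
            p = ptr[i, j, 2]
            out_a.append(seq1[i - 1])
            out_b.append("-")
            i -= 1
            state = 0 if p == 0 else 2
    return (
        int(best),
        (i, bi),
        (j, bj),
        "".join(reversed(out_a)),
        "".join(reversed(out_b)),
    )


# --- windowed brute force ------------------------------------------------


def window_positions(length, window, step, extension):
    """Enumerate (start, end) 1-based window coordinates independently of
    the package."""
    if length < window:
        return [(1, length)]
    out = []
    s = 1
    while s + window - 1 <= length:
        out.append((s, s + window - 1))
        s += step
    last_s, last_e = out[-1]
    if 0 < length - last_e <= extension:
        out[-1] = (last_s, length)
    return out


def brute_content(seq, start, end):
    chunk = seq[start - 1 : end].upper()
    known = [c for c in chunk if c != "N"]
    if not known:
        return (np.nan,) * 4
    return tuple(known.count(b) / len(known) for b in "ACGT")


def brute_depth_breadth(depth, start, end):
    chunk = np.asarray(depth[start - 1 : end], dtype=float)
    return chunk.mean(), np.mean(chunk > 0)


def brute_window_mean(values, start, end):
    chunk = np.asarray(values[start - 1 : end], dtype=float)
    if np.all(np.isnan(chunk)):
        return np.nan
    return np.nanmean(chunk)


def brute_adenine_conservation(conserved, conserved_a, start, end):
    c = int(np.sum(conserved[start - 1 : end]))
    a = int(np.sum(conserved_a[start - 1 : end]))
    return 100.0 * a / c if c else np.nan


def brute_msa_column(column_symbols):
    """(variation, conserved, conserved_a) for one MSA column, counting
    gaps as a fifth symbol, ties by A<C<G<T<gap."""
    n = len(column_symbols)
    counts = {s: 0 for s in "ACGT-"}
    for s in column_symbols:
        counts[s] = counts.get(s, 0) + 1
    order = "ACGT-"
    mode = max(order, key=lambda s: (counts[s], -order.index(s)))
    mx = counts[mode]
    variation = 1.0 - mx / n
    conserved = mx / n >= 0.90 - 1e-9
    return variation, conserved, conserved and mode == "A"


def brute_pileup_variation(a, c, g, t):
    depth = a + c + g + t
    if depth == 0:
        return np.nan
    return 1.0 - max(a, c, g, t) / depth


def hamming_spacer_scan(spacer, genome, max_mm):
    """All gap-free matches of a spacer on both strands, by direct
    position-by-position comparison."""
    from dgrscan.types import reverse_complement

    L = len(spacer)
    out = []
    for strand, query in (("+", spacer), ("-", reverse_complement(spacer))):
        for pos in range(len(genome) - L + 1):
            mm = sum(1 for x, y in zip(genome[pos : pos + L], query) if x != y)
            if mm <= max_mm:
                out.append((pos + 1, strand, mm))
    return sorted(out)
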