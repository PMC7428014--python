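"""Numba kernels: error-tolerant adapter search and exhaustive local alignment.

Sequences are encoded as uint8 (A=0, C=1, G=2, T=3, N=4) before entering a
kernel.  The reference is tiny (at most a few hundred entries of <=100 nt),
so exhaustive dynamic programming per read is the contract here, not a
heuristic; numba keeps a 100k-read library in the tens of seconds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to the uint8 alphabet used by the kernels."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


@njit(cache=True)
def adapter_match(read, adapter, error_rate, min_overlap, prefer_late):
    """Best semi-global match of ``adapter`` against ``read`` (5'-mode frame).

    The adapter may sit anywhere in the read (free read prefix) or hang off
    the read's 5' end (free adapter prefix, but only when the alignment
    starts at read position 0).  Cost is unit for substitutions and indels;
    adapter N (code 4) matches any base at zero cost.  A candidate is valid
    when cost <= floor(error_rate * matched_adapter_length) and the matched
    adapter length is at least ``min_overlap``.  Among valid candidates the
    one with the fewest errors wins; ties go to the latest end position when
    ``prefer_late`` (most bases removed in 5'-trim terms), else the
    earliest.

    Returns (start, end, errors, matched_len) in read coordinates, with
    start == -1 when there is no valid match.
    """
    m = adapter.shape[0]
    n = read.shape[0]
    BIG = np.int32(1 << 20)
    D = np.empty((m + 1, n + 1), np.int32)   # edit cost
    S = np.empty((m + 1, n + 1), np.int32)   # adapter row where path started
    C = np.empty((m + 1, n + 1), np.int32)   # read column where path started
    for i in range(m + 1):
        D[i, 0] = 0
        S[i, 0] = i
        C[i, 0] = 0
    for j in range(1, n + 1):
        D[0, j] = 0
        S[0, j] = 0
        C[0, j] = j
    for i in range(1, m + 1):
        ai = adapter[i - 1]
        for j in range(1, n + 1):
            sub = 0 if (ai == 4 or ai == read[j - 1]) else 1
            best = D[i - 1, j - 1] + sub
            s = S[i - 1, j - 1]
            c = C[i - 1, j - 1]
            alt = D[i - 1, j] + 1  # adapter base unmatched (deletion in read)
            if alt < best:
                best, s, c = alt, S[i - 1, j], C[i - 1, j]
            alt = D[i, j - 1] + 1  # read base unmatched (insertion in read)
            if alt < best:
                best, s, c = alt, S[i, j - 1], C[i, j - 1]
            D[i, j] = best
            S[i, j] = s
            C[i, j] = c

    best_cost = BIG
    best_j = -1
    best_start = -1
    best_len = 0
    for j in range(1, n + 1):
        cost = D[m, j]
        mlen = m - S[m, j]
        if mlen < min_overlap:
            continue
        if cost > int(error_rate * mlen):
            continue
        take = False
        if cost < best_cost:
            take = True
        elif cost == best_cost:
            if prefer_late and j > best_j:
                take = True
            elif (not prefer_late) and best_j == -1:
                take = True
        if take:
            best_cost = cost
            best_j = j
            best_start = C[m, j]
            best_len = mlen
    if best_j < 0:
        return -1, -1, 0, 0
    return best_start, best_j, int(best_cost), int(best_len)


@njit(cache=True)
def sw_all_scores(read, refcat, starts, ends, match, mismatch, npen, go, ge):
    """Best local-alignment score of ``read`` against every reference entry.

    ``refcat`` concatenates all entry sequences; ``starts``/``ends`` delimit
    them.  Affine gaps cost go+ge for the first gapped base and ge for each
    extension (both read and reference gaps use the same prices here).
    Returns an int32 array of per-entry maxima (floored at 0).
    """
    n = read.shape[0]
    ne = starts.shape[0]
    out = np.zeros(ne, np.int32)
    NEG = np.int32(-(1 << 20))
    for e in range(ne):
        lo, hi = starts[e], ends[e]
        L = hi - lo
        Hprev = np.zeros(L + 1, np.int32)
        Hcur = np.zeros(L + 1, np.int32)
        Ins = np.full(L + 1, NEG, np.int32)  # gap in reference (vertical)
        best = np.int32(0)
        for i in range(1, n + 1):
            ri = read[i - 1]
            Hcur[0] = 0
            dh = NEG  # gap in read (horizontal), reset per row
            for j in range(1, L + 1):
                rj = refcat[lo + j - 1]
                if ri == 4 or rj == 4:
                    s = -npen
                elif ri == rj:
                    s = match
                else:
                    s = -mismatch
                op = Hprev[j] - go - ge
                ext = Ins[j] - ge
                Ins[j] = op if op > ext else ext
                op = Hcur[j - 1] - go - ge
                ext = dh - ge
                dh = op if op > ext else ext
                h = Hprev[j - 1] + s
                if Ins[j] > h:
                    h = Ins[j]
                if dh > h:
                    h = dh
                if h < 0:
                    h = 0
                Hcur[j] = h
                if h > best:
                    best = h
            tmp = Hprev
            Hprev = Hcur
            Hcur = tmp
        out[e] = best
    return out


@njit(cache=True)
def sw_traceback(read, ref, match, mismatch, npen, go, ge):
    """Full local alignment of one (read, ref) pair with traceback.

    Ties in the DP break deterministically (diagonal > vertical insertion >
    horizontal deletion; the first maximal cell in row-major order anchors
    the traceback), so repeated runs give byte-identical alignments.

    Returns (score, read_start, read_end, ref_start, ref_end, ops, lens,
    n_ops) with ops as CIGAR codes 0=M, 1=I, 2=D over the aligned span
    (ends exclusive, 0-based; soft clips are the caller's business).
    """
    n = read.shape[0]
    L = ref.shape[0]
    NEG = np.int32(-(1 << 20))
    H = np.zeros((n + 1, L + 1), np.int32)
    I = np.full((n + 1, L + 1), NEG, np.int32)
    Dm = np.full((n + 1, L + 1), NEG, np.int32)
    PH = np.zeros((n + 1, L + 1), np.uint8)  # 0 stop, 1 diag, 2 ins, 3 del
    PI = np.zeros((n + 1, L + 1), np.uint8)  # 1 opened from H
    PD = np.zeros((n + 1, L + 1), np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ri = read[i - 1]
        for j in range(1, L + 1):
            rj = ref[j - 1]
            if ri == 4 or rj == 4:
                s = -npen
            elif ri == rj:
                s = match
            else:
                s = -mismatch
            op = H[i - 1, j] - go - ge
            ext = I[i - 1, j] - ge
            if op >= ext:
                I[i, j] = op
                PI[i, j] = 1
            else:
                I[i, j] = ext
                PI[i, j] = 0
            op = H[i, j - 1] - go - ge
            ext = Dm[i, j - 1] - ge
            if op >= ext:
                Dm[i, j] = op
                PD[i, j] = 1
            else:
                Dm[i, j] = ext
                PD[i, j] = 0
            h = H[i - 1, j - 1] + s
            p = np.uint8(1)
            if I[i, j] > h:
                h = I[i, j]
                p = np.uint8(2)
            if Dm[i, j] > h:
                h = Dm[i, j]
                p = np.uint8(3)
            if h <= 0:
                h = 0
                p = np.uint8(0)
            H[i, j] = h
            PH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j

    ops = np.empty(n + L + 2, np.uint8)
    lens = np.empty(n + L + 2, np.int32)
    n_ops = 0
    i, j = bi, bj
    state = 0  # 0 in H, 1 in I, 2 in D
    while True:
        if state == 0:
            p = PH[i, j]
            if p == 0:
                break
            if p == 1:
                code = 0
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
                continue
            else:
                state = 2
                continue
        elif state == 1:
            code = 1
            opened = PI[i, j] == 1
            i -= 1
            if opened:
                state = 0
        else:
            code = 2
            opened = PD[i, j] == 1
            j -= 1
            if opened:
                state = 0
        if n_ops > 0 and ops[n_ops - 1] == code:
            lens[n_ops - 1] += 1
        else:
            ops[n_ops] = code
            lens[n_ops] = 1
            n_ops += 1
    # reverse into alignment order
    for k in range(n_ops // 2):
        ops[k], ops[n_ops - 1 - k] = ops[n_ops - 1 - k], ops[k]
        lens[k], lens[n_ops - 1 - k] = lens[n_ops - 1 - k], lens[k]
    return int(best), i, bi, j, bj, ops[:n_ops], lens[:n_ops], n_ops
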