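"""Numba kernels: Smith-Waterman DP, banded read mapping, QC, read synthesis.

All sequence arguments are uint8 code arrays (A=0..T=3, N=4, 5=blocked by
Waterman-Eggert masking).  Scores are integers; gaps are affine with a
gap of length L costing ``gap_open + L * gap_extend`` (both negative).
"""

from __future__ import annotations

import numba as nb
import numpy as np

NEG = -(10**9)
BLOCK_PENALTY = -(10**7)


@nb.njit(cache=True, inline="always")
def _sub_score(a, b, match, mismatch):
    if a > 4 or b > 4:
        return BLOCK_PENALTY
    if a == 4 or b == 4:
        return 0
    if a == b:
        return match
    return mismatch


@nb.njit(cache=True)
def sw_align(q, s, match, mismatch, go, ge):
    """Full affine-gap local alignment with traceback.

    Returns (score, q_start, q_end, s_start, s_end, matches, columns,
    gap_columns); intervals are 0-based half-open.  Score 0 means no
    positive-scoring local alignment exists.
    """
    m = q.size
    n = s.size
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = E[i, j - 1] + ge
            eo = H[i, j - 1] + go + ge
            if eo > e:
                e = eo
            E[i, j] = e
            f = F[i - 1, j] + ge
            fo = H[i - 1, j] + go + ge
            if fo > f:
                f = fo
            F[i, j] = f
            h = H[i - 1, j - 1] + _sub_score(qi, s[j - 1], match, mismatch)
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0, 0
    # traceback
    i = bi
    j = bj
    matches = 0
    cols = 0
    gaps = 0
    state = 0  # 0=H, 1=E (gap in query), 2=F (gap in subject)
    while True:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            diag = H[i - 1, j - 1] + _sub_score(q[i - 1], s[j - 1], match, mismatch)
            if h == diag:
                cols += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            gaps += 1
            ext = E[i, j - 1] + ge
            here = E[i, j]
            j -= 1
            if here != ext:
                state = 0
        else:
            cols += 1
            gaps += 1
            ext = F[i - 1, j] + ge
            here = F[i, j]
            i -= 1
            if here != ext:
                state = 0
    return best, i, bi, j, bj, matches, cols, gaps


@nb.njit(cache=True)
def banded_score(q, s, dlo, dhi, match, mismatch, go, ge):
    """Score-only banded affine local alignment.

    The band restricts subject position j to ``i + dlo .. i + dhi`` for
    read position i; cells outside the band are unreachable.
    """
    m = q.size
    n = s.size
    W = dhi - dlo + 1
    Hp = np.full(W + 2, NEG, dtype=np.int64)  # previous row, padded by 1
    Fp = np.full(W + 2, NEG, dtype=np.int64)
    Hc = np.empty(W + 2, dtype=np.int64)
    Fc = np.empty(W + 2, dtype=np.int64)
    best = 0
    for i in range(m):
        Hc[0] = NEG
        Hc[W + 1] = NEG
        Fc[0] = NEG
        Fc[W + 1] = NEG
        qi = q[i]
        e = NEG
        for b in range(W):
            j = i + dlo + b
            if j < 0 or j >= n:
                Hc[b + 1] = NEG
                Fc[b + 1] = NEG
                e = NEG
                continue
            # E: horizontal from (i, j-1) -> band b-1 of current row
            eo = Hc[b] + go + ge
            e = e + ge
            if eo > e:
                e = eo
            # F: vertical from (i-1, j) -> band b+1 of previous row
            f = Fp[b + 2] + ge
            fo = Hp[b + 2] + go + ge
            if fo > f:
                f = fo
            Fc[b + 1] = f
            # diagonal from (i-1, j-1) -> band b of previous row
            diag = Hp[b + 1]
            if diag < 0:
                if i == 0 or j == 0:
                    diag = 0
                else:
                    diag = NEG
            h = diag + _sub_score(qi, s[j], match, mismatch) if diag > NEG // 2 else NEG
            if i == 0 or j == 0:
                h0 = _sub_score(qi, s[j], match, mismatch)
                if h0 > h:
                    h = h0
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Hc[b + 1] = h
            if h > best:
                best = h
        Hp, Hc = Hc, Hp
        Fp, Fc = Fc, Fp
    return best


@nb.njit(cache=True)
def collect_kmers(codes, offsets, k):
    """Enumerate all N-free k-mers of the packed sequences.

    Returns (kmers, global_positions); positions index into ``codes``.
    """
    nseq = offsets.size - 1
    total = 0
    for si in range(nseq):
        L = offsets[si + 1] - offsets[si]
        if L >= k:
            total += L - k + 1
    kmers = np.empty(total, dtype=np.int64)
    gpos = np.empty(total, dtype=np.int64)
    mask = (np.int64(1) << (2 * k)) - 1
    out = 0
    for si in range(nseq):
        lo = offsets[si]
        hi = offsets[si + 1]
        km = np.int64(0)
        valid = 0
        for g in range(lo, hi):
            c = codes[g]
            if c >= 4:
                valid = 0
                km = np.int64(0)
                continue
            km = ((km << 2) | np.int64(c)) & mask
            valid += 1
            if valid >= k:
                kmers[out] = km
                gpos[out] = g - k + 1
                out += 1
    return kmers[:out], gpos[:out]


@nb.njit(cache=True)
def _read_kmer_seeds(read, k, stride, cap, out_kmer, out_pos):
    """Seed k-mers of one read at positions 0, stride, 2*stride, ..."""
    L = read.size
    mask = (np.int64(1) << (2 * k)) - 1
    cnt = 0
    p = 0
    while p + k <= L and cnt < cap:
        km = np.int64(0)
        ok = True
        for t in range(k):
            c = read[p + t]
            if c >= 4:
                ok = False
                break
            km = ((km << 2) | np.int64(c)) & mask
        if ok:
            out_kmer[cnt] = km
            out_pos[cnt] = p
            cnt += 1
        p += stride
    return cnt


@nb.njit(cache=True)
def map_batch(
    rseq,
    roff,
    ref_codes,
    ref_off,
    kmer_sorted,
    pos_sorted,
    k,
    stride,
    match,
    mismatch,
    go,
    ge,
    floor_frac,
    margin,
    max_occ,
    band_pad,
):
    """Map every read of a packed library against the reference index.

    Returns (best_contig, best_score, second_score, unique) arrays; a
    read with no seeded candidate has best_contig -1 and scores 0.
    best_contig of non-unique reads is the lowest-index contig attaining
    the best score (references are indexed in lexicographic id order).
    """
    n = roff.size - 1
    best_contig = np.full(n, -1, dtype=np.int64)
    best_score = np.zeros(n, dtype=np.int64)
    second_score = np.zeros(n, dtype=np.int64)
    unique = np.zeros(n, dtype=np.uint8)

    maxlen = 0
    for r in range(n):
        L = roff[r + 1] - roff[r]
        if L > maxlen:
            maxlen = L
    if maxlen == 0:
        return best_contig, best_score, second_score, unique

    seed_cap = maxlen // stride + 2
    skm = np.empty(seed_cap, dtype=np.int64)
    spos = np.empty(seed_cap, dtype=np.int64)
    cand_cap = 512
    cand_key = np.empty(cand_cap, dtype=np.int64)  # contig * 2^24 + (diag + 2^22)
    rc = np.empty(maxlen, dtype=np.uint8)
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    DIAG_OFF = np.int64(1) << 22
    KEY_SHIFT = np.int64(1) << 24

    for r in range(n):
        lo = roff[r]
        hi = roff[r + 1]
        L = hi - lo
        if L < k:
            continue
        fwd = rseq[lo:hi]
        for t in range(L):
            rc[L - 1 - t] = comp[fwd[t]]
        rbest = np.int64(0)
        rsecond = np.int64(0)
        rcontig = np.int64(-1)
        for ori in range(2):
            read = fwd if ori == 0 else rc[:L]
            nseeds = _read_kmer_seeds(read, k, stride, seed_cap, skm, spos)
            ncand = 0
            for si in range(nseeds):
                a = np.searchsorted(kmer_sorted, skm[si], side="left")
                b = np.searchsorted(kmer_sorted, skm[si], side="right")
                if b - a > max_occ:
                    continue
                for t in range(a, b):
                    if ncand >= cand_cap:
                        break
                    g = pos_sorted[t]
                    ci = np.searchsorted(ref_off, g, side="right") - 1
                    diag = (g - ref_off[ci]) - spos[si]
                    cand_key[ncand] = ci * KEY_SHIFT + (diag + DIAG_OFF)
                    ncand += 1
            if ncand == 0:
                continue
            keys = np.sort(cand_key[:ncand])
            # walk contig groups, clustering nearby diagonals
            gstart = 0
            while gstart < ncand:
                ci = keys[gstart] // KEY_SHIFT
                gend = gstart
                while gend < ncand and keys[gend] // KEY_SHIFT == ci:
                    gend += 1
                slo = ref_off[ci]
                shi = ref_off[ci + 1]
                subj = ref_codes[slo:shi]
                cstart = gstart
                cscore = np.int64(0)
                while cstart < gend:
                    dlo = keys[cstart] % KEY_SHIFT - DIAG_OFF
                    cend = cstart
                    dhi = dlo
                    while cend + 1 < gend:
                        nd = keys[cend + 1] % KEY_SHIFT - DIAG_OFF
                        if nd - dhi > 16:
                            break
                        dhi = nd
                        cend += 1
                    sc = banded_score(
                        read,
                        subj,
                        dlo - band_pad,
                        dhi + band_pad,
                        match,
                        mismatch,
                        go,
                        ge,
                    )
                    if sc > cscore:
                        cscore = sc
                    cstart = cend + 1
                # merge this contig's score into read-level best/second
                if cscore > 0:
                    if ci == rcontig:
                        if cscore > rbest:
                            rbest = cscore
                    elif cscore > rbest:
                        rsecond = rbest
                        rbest = cscore
                        rcontig = ci
                    elif cscore == rbest and ci != rcontig:
                        if ci < rcontig:
                            rcontig = ci
                        if cscore > rsecond:
                            rsecond = cscore
                    elif cscore > rsecond:
                        rsecond = cscore
                gstart = gend
        best_contig[r] = rcontig
        best_score[r] = rbest
        second_score[r] = rsecond
        floor = floor_frac * L * match
        if rcontig >= 0 and rbest >= floor and rbest - rsecond >= margin:
            unique[r] = 1
    return best_contig, best_score, second_score, unique


@nb.njit(cache=True)
def qc_batch(seq, qual, off, trim_thr, mask_thr, min_len, trim5, trim3):
    """Two-rule QC on a packed library: end trimming then internal masking.

    Returns (out_seq, out_qual, out_off, keep, n_masked, n_trimmed_bases).
    """
    n = off.size - 1
    out_seq = np.empty(seq.size, dtype=np.uint8)
    out_qual = np.empty(seq.size, dtype=np.uint8)
    out_off = np.zeros(n + 1, dtype=np.int64)
    keep = np.zeros(n, dtype=np.uint8)
    n_masked = 0
    n_trimmed = 0
    wp = 0
    kept = 0
    for r in range(n):
        lo = off[r]
        hi = off[r + 1]
        a = lo
        b = hi - 1
        if trim5:
            while a <= b and qual[a] < trim_thr:
                a += 1
        if trim3:
            while b >= a and qual[b] < trim_thr:
                b -= 1
        length = b - a + 1
        n_trimmed += (hi - lo) - max(length, 0)
        if length < min_len or length <= 0:
            continue
        keep[r] = 1
        for g in range(a, b + 1):
            qv = qual[g]
            if qv < mask_thr:
                out_seq[wp] = 4
                if seq[g] != 4:  # bases already N are not re-counted
                    n_masked += 1
            else:
                out_seq[wp] = seq[g]
            out_qual[wp] = qv
            wp += 1
        kept += 1
        out_off[kept] = wp
    return out_seq[:wp], out_qual[:wp], out_off[: kept + 1], keep, n_masked, n_trimmed


@nb.njit(cache=True)
def make_reads(
    src_codes,
    src_off,
    src_idx,
    req_len,
    starts,
    strands,
    sub_rate,
    indel_rate,
    q_mean,
    q_decay,
    q_sd,
    seed,
):
    """Synthesize error-bearing reads from source sequences.

    Per base: with prob ``indel_rate`` a 1-nt indel (insertion or deletion,
    equal odds), else with prob ``sub_rate`` a substitution to a different
    base.  Phred scores decline linearly from ``q_mean`` at the 5' end by
    ``q_decay`` toward the 3' end, with gaussian noise ``q_sd``, clipped
    to [2, 40].
    """
    np.random.seed(seed)
    n = src_idx.size
    total = 0
    for r in range(n):
        total += req_len[r] + 16
    out_seq = np.empty(total, dtype=np.uint8)
    out_qual = np.empty(total, dtype=np.uint8)
    out_off = np.zeros(n + 1, dtype=np.int64)
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    wp = 0
    for r in range(n):
        si = src_idx[r]
        slo = src_off[si]
        L = req_len[r]
        start = starts[r]
        rstart = wp
        extra = 0
        for t in range(L):
            if strands[r] == 0:
                base = src_codes[slo + start + t]
            else:
                base = comp[src_codes[slo + start + L - 1 - t]]
            u = np.random.random()
            if u < indel_rate:
                if np.random.random() < 0.5 or extra >= 14:
                    continue  # deletion: skip this source base
                out_seq[wp] = np.uint8(np.random.randint(0, 4))
                wp += 1
                extra += 1
                out_seq[wp] = base
                wp += 1
            elif u < indel_rate + sub_rate:
                shift = 1 + np.random.randint(0, 3)
                out_seq[wp] = np.uint8((base + shift) % 4)
                wp += 1
            else:
                out_seq[wp] = base
                wp += 1
        rlen = wp - rstart
        for t in range(rlen):
            frac = t / max(rlen - 1, 1)
            qv = q_mean - q_decay * frac + np.random.normal(0.0, q_sd)
            if qv < 2.0:
                qv = 2.0
            if qv > 40.0:
                qv = 40.0
            out_qual[rstart + t] = np.uint8(qv + 0.5)
        out_off[r + 1] = wp
    return out_seq[:wp], out_qual[:wp], out_off
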