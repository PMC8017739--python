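"""Compiled hot loops for the xtc coordinate codec.

These kernels are the optimized read path: a word-buffered bit reader,
mixed-radix integer coding via the byte-array algorithm, and a single
"walk" kernel that can fully decode a payload, scan only its control bits,
or decode a worker's assigned run groups while skipping everyone else's.
Everything operates on quantized int64 lattice coordinates; float
conversion happens outside in numpy so that serial and parallel decodes
share one conversion path bit-for-bit.

The pure-Python naive transcription in :mod:`xtcio.reference` is the
differential oracle for every kernel here.
"""

import numpy as np
from numba import njit

# Geometrically spaced range table of the codec: MAGICINTS[i] ~ 2**(i/3),
# arranged so that MAGICINTS[i]**3 <= 2**i (a small-difference triple at
# index i always fits in exactly i bits).
MAGICINTS = np.array([
    0, 0, 0, 0, 0, 0, 0, 0, 0, 8, 10, 12, 16, 20, 25, 32, 40, 50, 64,
    80, 101, 128, 161, 203, 256, 322, 406, 512, 645, 812, 1024, 1290,
    1625, 2048, 2580, 3250, 4096, 5060, 6501, 8192, 10321, 13003,
    16384, 20642, 26007, 32768, 41285, 52015, 65536, 82570, 104031,
    131072, 165140, 208063, 262144, 330280, 416127, 524287, 660561,
    832255, 1048576, 1321122, 1664510, 2097152, 2642245, 3329021,
    4194304, 5284491, 6658042, 8388607, 10568983, 13316085, 16777216,
], dtype=np.int64)

FIRSTIDX = 9
LASTIDX = 73  # one past the last valid table index

# walk modes
MODE_DECODE = 0
MODE_SCAN = 1
MODE_MASKED = 2

_JIT = dict(cache=True, nogil=True)


@njit(**_JIT)
def _rd(data, pos, acc, nacc, nbits):
    """Read ``nbits`` MSB-first from the accumulator, refilling bytewise."""
    while nacc < nbits:
        acc = (acc << 8) | np.int64(data[pos])
        pos += 1
        nacc += 8
    nacc -= nbits
    val = (acc >> nacc) & ((1 << nbits) - 1)
    acc &= (1 << nacc) - 1
    return val, pos, acc, nacc


@njit(**_JIT)
def _skip(data, pos, acc, nacc, nbits):
    if nbits <= nacc:
        nacc -= nbits
        acc &= (1 << nacc) - 1
        return pos, acc, nacc
    nbits -= nacc
    pos += nbits >> 3
    rem = nbits & 7
    acc = 0
    nacc = 0
    if rem:
        acc = np.int64(data[pos])
        pos += 1
        nacc = 8 - rem
        acc &= (1 << nacc) - 1
    return pos, acc, nacc


@njit(**_JIT)
def _decodeints3(data, pos, acc, nacc, nbits, s1, s2, scratch):
    """Mixed-radix decode of one triple occupying exactly ``nbits`` bits."""
    scratch[0] = 0
    scratch[1] = 0
    scratch[2] = 0
    scratch[3] = 0
    nb = 0
    while nbits > 8:
        v, pos, acc, nacc = _rd(data, pos, acc, nacc, 8)
        scratch[nb] = v
        nb += 1
        nbits -= 8
    if nbits > 0:
        v, pos, acc, nacc = _rd(data, pos, acc, nacc, nbits)
        scratch[nb] = v
        nb += 1
    num = 0
    for j in range(nb - 1, -1, -1):
        num = (num << 8) | scratch[j]
        p = num // s2
        scratch[j] = p
        num -= p * s2
    v2 = num
    num = 0
    for j in range(nb - 1, -1, -1):
        num = (num << 8) | scratch[j]
        p = num // s1
        scratch[j] = p
        num -= p * s1
    v1 = num
    v0 = scratch[0] | (scratch[1] << 8) | (scratch[2] << 16) | (scratch[3] << 24)
    return v0, v1, v2, pos, acc, nacc


@njit(**_JIT)
def _walk(data, natoms, bitsize, bs0, bs1, bs2, s1, s2,
          m0, m1, m2, smallidx0, mode, owned,
          out_ints, g_start, g_count, g_smallidx, g_end, scratch):
    """Walk the run-group stream of one compressed payload.

    mode 0: decode every group into ``out_ints``.
    mode 1: scan control bits only; payload widths are skipped.
    mode 2: decode groups with ``owned[g] == 1``, skip the rest.

    Returns ``(status, final_bit, ngroups, ndecoded)`` where status is
    0 = ok, 1 = atom count overflow, 2 = small-index state out of range.
    Group bookkeeping arrays are always filled (ngroups entries).
    """
    pos = 0
    acc = 0
    nacc = 0
    smallidx = smallidx0
    smallnum = MAGICINTS[smallidx] // 2
    t = smallidx - 1
    if t < FIRSTIDX:
        t = FIRSTIDX
    smaller = MAGICINTS[t] // 2
    run = 0
    i = 0
    g = 0
    ndecoded = 0
    p0 = 0
    p1 = 0
    p2 = 0
    while i < natoms:
        gstart = pos * 8 - nacc
        sidx_in = smallidx
        own = (mode == MODE_DECODE) or (mode == MODE_MASKED and owned[g] == 1)
        i0 = i
        if own:
            if bitsize == 0:
                a0, pos, acc, nacc = _rd(data, pos, acc, nacc, bs0)
                a1, pos, acc, nacc = _rd(data, pos, acc, nacc, bs1)
                a2, pos, acc, nacc = _rd(data, pos, acc, nacc, bs2)
            else:
                a0, a1, a2, pos, acc, nacc = _decodeints3(
                    data, pos, acc, nacc, bitsize, s1, s2, scratch)
            a0 += m0
            a1 += m1
            a2 += m2
            p0 = a0
            p1 = a1
            p2 = a2
            out_ints[3 * i] = a0
            out_ints[3 * i + 1] = a1
            out_ints[3 * i + 2] = a2
            ndecoded += 1
        else:
            nb_abs = bitsize if bitsize != 0 else bs0 + bs1 + bs2
            pos, acc, nacc = _skip(data, pos, acc, nacc, nb_abs)
        i += 1
        flag, pos, acc, nacc = _rd(data, pos, acc, nacc, 1)
        is_smaller = 0
        if flag == 1:
            h, pos, acc, nacc = _rd(data, pos, acc, nacc, 5)
            is_smaller = h % 3
            run = h - is_smaller
            is_smaller -= 1
        if run > 0:
            ntrip = run // 3
            if i + ntrip > natoms:
                return 1, pos * 8 - nacc, g, ndecoded
            if own:
                ss = MAGICINTS[smallidx]
                for k in range(ntrip):
                    d0, d1, d2, pos, acc, nacc = _decodeints3(
                        data, pos, acc, nacc, smallidx, ss, ss, scratch)
                    t0 = d0 + p0 - smallnum
                    t1 = d1 + p1 - smallnum
                    t2 = d2 + p2 - smallnum
                    if k == 0:
                        # pair swap: the first small triple is emitted
                        # before the absolutely-coded atom (water pairs)
                        out_ints[3 * i0] = t0
                        out_ints[3 * i0 + 1] = t1
                        out_ints[3 * i0 + 2] = t2
                        out_ints[3 * (i0 + 1)] = p0
                        out_ints[3 * (i0 + 1) + 1] = p1
                        out_ints[3 * (i0 + 1) + 2] = p2
                    else:
                        out_ints[3 * (i0 + 1 + k)] = t0
                        out_ints[3 * (i0 + 1 + k) + 1] = t1
                        out_ints[3 * (i0 + 1 + k) + 2] = t2
                    p0 = t0
                    p1 = t1
                    p2 = t2
                    ndecoded += 1
            else:
                pos, acc, nacc = _skip(data, pos, acc, nacc, ntrip * smallidx)
            i += ntrip
        # small-index state update, driven purely by the run header
        smallidx += is_smaller
        if smallidx < FIRSTIDX or smallidx >= LASTIDX:
            return 2, pos * 8 - nacc, g, ndecoded
        if is_smaller < 0:
            smallnum = smaller
            if smallidx > FIRSTIDX:
                smaller = MAGICINTS[smallidx - 1] // 2
            else:
                smaller = 0
        elif is_smaller > 0:
            smaller = smallnum
            smallnum = MAGICINTS[smallidx] // 2
        g_start[g] = gstart
        g_count[g] = i - i0
        g_smallidx[g] = sidx_in
        g_end[g] = pos * 8 - nacc
        g += 1
    return 0, pos * 8 - nacc, g, ndecoded


@njit(**_JIT)
def _wr(out, cnt, lastbits, lastbyte, nbits, value):
    """MSB-first bit append with the codec's 32-bit rolling accumulator."""
    while nbits >= 8:
        lastbyte = ((lastbyte << 8) | ((value >> (nbits - 8)) & 0xFF)) & 0xFFFFFFFF
        out[cnt] = (lastbyte >> lastbits) & 0xFF
        cnt += 1
        nbits -= 8
    if nbits > 0:
        lastbyte = ((lastbyte << nbits) | (value & ((1 << nbits) - 1))) & 0xFFFFFFFF
        lastbits += nbits
        if lastbits >= 8:
            lastbits -= 8
            out[cnt] = (lastbyte >> lastbits) & 0xFF
            cnt += 1
    return cnt, lastbits, lastbyte


@njit(**_JIT)
def _wints3(out, cnt, lastbits, lastbyte, nbits, s1, s2, v0, v1, v2, scratch):
    """Mixed-radix encode of one triple into exactly ``nbits`` bits.

    The combined value ((v0*s1)+v1)*s2+v2 is built as a little-endian byte
    array (it may exceed 64 bits), then emitted low byte first with the
    remainder bits last -- the codec's wire ordering.
    """
    nb = 0
    tmp = v0
    while True:
        scratch[nb] = tmp & 0xFF
        nb += 1
        tmp >>= 8
        if tmp == 0:
            break
    tmp = v1
    for j in range(nb):
        tmp = scratch[j] * s1 + tmp
        scratch[j] = tmp & 0xFF
        tmp >>= 8
    bc = nb
    while tmp != 0:
        scratch[bc] = tmp & 0xFF
        bc += 1
        tmp >>= 8
    nb = bc
    tmp = v2
    for j in range(nb):
        tmp = scratch[j] * s2 + tmp
        scratch[j] = tmp & 0xFF
        tmp >>= 8
    bc = nb
    while tmp != 0:
        scratch[bc] = tmp & 0xFF
        bc += 1
        tmp >>= 8
    nb = bc
    if nbits >= nb * 8:
        for j in range(nb):
            cnt, lastbits, lastbyte = _wr(out, cnt, lastbits, lastbyte, 8, scratch[j])
        cnt, lastbits, lastbyte = _wr(out, cnt, lastbits, lastbyte, nbits - nb * 8, 0)
    else:
        for j in range(nb - 1):
            cnt, lastbits, lastbyte = _wr(out, cnt, lastbits, lastbyte, 8, scratch[j])
        cnt, lastbits, lastbyte = _wr(
            out, cnt, lastbits, lastbyte, nbits - (nb - 1) * 8, scratch[nb - 1])
    return cnt, lastbits, lastbyte


@njit(**_JIT)
def _encode(ints, natoms, m0, m1, m2, s1, s2, bitsize, bs0, bs1, bs2,
            smallidx0, out, scratch):
    """Run-length encode quantized coordinates; ``ints`` is mutated (swaps).

    Returns ``(nbytes, bit_length)`` with the trailing partial byte
    already materialised in ``out`` and counted in ``nbytes``.
    """
    tmpc = np.empty(30, dtype=np.int64)
    cnt = 0
    lastbits = 0
    lastbyte = 0
    smallidx = smallidx0
    maxidx = smallidx + 8
    if maxidx > LASTIDX - 1:
        maxidx = LASTIDX - 1  # clamp to the table (see methods note)
    minidx = maxidx - 8
    t = smallidx - 1
    if t < FIRSTIDX:
        t = FIRSTIDX
    smaller = MAGICINTS[t] // 2
    smallnum = MAGICINTS[smallidx] // 2
    larger = MAGICINTS[maxidx] // 2
    prevrun = -1
    p0 = 0
    p1 = 0
    p2 = 0
    i = 0
    while i < natoms:
        is_small = 0
        b = 3 * i
        c0 = ints[b]
        c1 = ints[b + 1]
        c2 = ints[b + 2]
        if (smallidx < maxidx and i >= 1
                and abs(c0 - p0) < larger and abs(c1 - p1) < larger
                and abs(c2 - p2) < larger):
            is_smaller = 1
        elif smallidx > minidx:
            is_smaller = -1
        else:
            is_smaller = 0
        if i + 1 < natoms:
            if (abs(c0 - ints[b + 3]) < smallnum
                    and abs(c1 - ints[b + 4]) < smallnum
                    and abs(c2 - ints[b + 5]) < smallnum):
                # swap with the next atom so the closely spaced partner is
                # carried as a cheap difference (water optimisation)
                ints[b] = ints[b + 3]
                ints[b + 3] = c0
                ints[b + 1] = ints[b + 4]
                ints[b + 4] = c1
                ints[b + 2] = ints[b + 5]
                ints[b + 5] = c2
                c0 = ints[b]
                c1 = ints[b + 1]
                c2 = ints[b + 2]
                is_small = 1
        if bitsize == 0:
            cnt, lastbits, lastbyte = _wr(out, cnt, lastbits, lastbyte, bs0, c0 - m0)
            cnt, lastbits, lastbyte = _wr(out, cnt, lastbits, lastbyte, bs1, c1 - m1)
            cnt, lastbits, lastbyte = _wr(out, cnt, lastbits, lastbyte, bs2, c2 - m2)
        else:
            cnt, lastbits, lastbyte = _wints3(
                out, cnt, lastbits, lastbyte, bitsize, s1, s2,
                c0 - m0, c1 - m1, c2 - m2, scratch)
        p0 = c0
        p1 = c1
        p2 = c2
        i += 1
        run = 0
        if is_small == 0 and is_smaller == -1:
            is_smaller = 0
        while is_small == 1 and run < 24:
            b = 3 * i
            d0 = ints[b] - p0
            d1 = ints[b + 1] - p1
            d2 = ints[b + 2] - p2
            if is_smaller == -1 and d0 * d0 + d1 * d1 + d2 * d2 >= smaller * smaller:
                is_smaller = 0
            tmpc[run] = d0 + smallnum
            tmpc[run + 1] = d1 + smallnum
            tmpc[run + 2] = d2 + smallnum
            run += 3
            p0 = ints[b]
            p1 = ints[b + 1]
            p2 = ints[b + 2]
            i += 1
            is_small = 0
            if i < natoms:
                b = 3 * i
                if (abs(ints[b] - p0) < smallnum
                        and abs(ints[b + 1] - p1) < smallnum
                        and abs(ints[b + 2] - p2) < smallnum):
                    is_small = 1
        if run != prevrun or is_smaller != 0:
            prevrun = run
            cnt, lastbits, lastbyte = _wr(out, cnt, lastbits, lastbyte, 1, 1)
            cnt, lastbits, lastbyte = _wr(out, cnt, lastbits, lastbyte, 5,
                                          run + is_smaller + 1)
        else:
            cnt, lastbits, lastbyte = _wr(out, cnt, lastbits, lastbyte, 1, 0)
        ss = MAGICINTS[smallidx]
        for k in range(0, run, 3):
            cnt, lastbits, lastbyte = _wints3(
                out, cnt, lastbits, lastbyte, smallidx, ss, ss,
                tmpc[k], tmpc[k + 1], tmpc[k + 2], scratch)
        if is_smaller != 0:
            smallidx += is_smaller
            if is_smaller < 0:
                smallnum = smaller
                smaller = MAGICINTS[smallidx - 1] // 2
            else:
                smaller = smallnum
                smallnum = MAGICINTS[smallidx] // 2
    bitlen = cnt * 8 + lastbits
    if lastbits != 0:
        out[cnt] = (lastbyte << (8 - lastbits)) & 0xFF
        cnt += 1
    return cnt, bitlen
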