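"""Naive transcription of the canonical GROMACS xtc coordinate codec.

This module is the in-package differential oracle: a deliberately simple,
byte-at-a-time, scalar implementation of the 3dfcoord algorithm whose
structure mirrors the classic xdrfile routines statement for statement.
The optimized kernels must agree with it bit-for-bit -- coordinates,
quantized integers and final bit-cursor alike -- on every input; any
divergence is a test failure.  It is intentionally slow and must never be
called from the production read path.

The decoder is *instrumented*: it records the bit cursor and small-index
state at every run-group boundary, which is the ground truth the
control-bit scanner is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bitstream import BitReader, BitWriter
from .codec import (CoordBlock, FIRSTIDX, LASTIDX, MAGICINTS, MAXABS,
                    decodeints, encodeints, inverse_precision, sizeofint,
                    sizeofints)
from .errors import XtcCorruptionError, XtcRangeError


@dataclass
class RefDecodeResult:
    coords: np.ndarray            # (natoms, 3) float32
    ints: np.ndarray              # (natoms, 3) int64
    final_bit: int
    group_start_bits: list
    group_atom_counts: list
    group_smallidx_in: list
    group_end_bits: list


def ref_quantize_one(x, precision) -> int:
    """Scalar quantization in 32-bit float semantics."""
    xf = np.float32(x)
    prod = np.float32(xf * np.float32(precision))
    if xf >= 0:
        lf = np.float32(prod + np.float32(0.5))
    else:
        lf = np.float32(prod - np.float32(0.5))
    if abs(float(lf)) > MAXABS:
        raise XtcRangeError("coordinate overflows working range")
    return int(lf)  # truncation toward zero


def ref_decompress(block: CoordBlock, natoms: int) -> RefDecodeResult:
    """Byte-at-a-time decode; structure follows the classic routine."""
    sizeint = list(block.sizeint)
    if (sizeint[0] | sizeint[1] | sizeint[2]) > 0xFFFFFF:
        bitsizeint = [sizeofint(s) for s in sizeint]
        bitsize = 0
    else:
        bitsizeint = [0, 0, 0]
        bitsize = sizeofints(sizeint)
    smallidx = block.smallidx0
    tmp = max(smallidx - 1, FIRSTIDX)
    smaller = int(MAGICINTS[tmp]) // 2
    smallnum = int(MAGICINTS[smallidx]) // 2
    sizesmall = [int(MAGICINTS[smallidx])] * 3
    minint = list(block.minint)

    reader = BitReader(block.padded_payload, buffered=False)
    inv = inverse_precision(block.precision)
    ints = np.zeros((natoms, 3), dtype=np.int64)
    coords = np.zeros((natoms, 3), dtype=np.float32)
    out_row = 0

    def emit(triple):
        nonlocal out_row
        coords[out_row, 0] = np.float32(np.float32(triple[0]) * inv)
        coords[out_row, 1] = np.float32(np.float32(triple[1]) * inv)
        coords[out_row, 2] = np.float32(np.float32(triple[2]) * inv)
        ints[out_row] = triple
        out_row += 1

    g_start, g_count, g_small, g_end = [], [], [], []
    run = 0
    i = 0
    while i < natoms:
        g_start.append(reader.bit_position)
        g_small.append(smallidx)
        i_at_entry = i
        if bitsize == 0:
            thiscoord = [reader.read_bits(bitsizeint[0]),
                         reader.read_bits(bitsizeint[1]),
                         reader.read_bits(bitsizeint[2])]
        else:
            thiscoord = list(decodeints(reader, sizeint, bitsize))
        i += 1
        thiscoord = [thiscoord[d] + minint[d] for d in range(3)]
        prevcoord = list(thiscoord)

        flag = reader.read_bits(1)
        is_smaller = 0
        if flag == 1:
            run = reader.read_bits(5)
            is_smaller = run % 3
            run -= is_smaller
            is_smaller -= 1
        if run > 0:
            if i + run // 3 > natoms:
                raise XtcCorruptionError("atom count overflow in reference decode")
            for k in range(0, run, 3):
                this = list(decodeints(reader, sizesmall, smallidx))
                i += 1
                this = [this[d] + prevcoord[d] - smallnum for d in range(3)]
                if k == 0:
                    # swap: emit the diff-coded partner before the
                    # absolutely-coded atom (water pairs)
                    this, prevcoord = prevcoord, this
                    emit(prevcoord)
                else:
                    prevcoord = list(this)
                emit(this)
        else:
            emit(thiscoord)
        smallidx += is_smaller
        if not FIRSTIDX <= smallidx < LASTIDX:
            raise XtcCorruptionError("small-index out of range in reference decode")
        if is_smaller < 0:
            smallnum = smaller
            smaller = int(MAGICINTS[smallidx - 1]) // 2 if smallidx > FIRSTIDX else 0
        elif is_smaller > 0:
            smaller = smallnum
            smallnum = int(MAGICINTS[smallidx]) // 2
        sizesmall = [int(MAGICINTS[smallidx])] * 3
        g_count.append(i - i_at_entry)
        g_end.append(reader.bit_position)

    return RefDecodeResult(coords=coords, ints=ints,
                           final_bit=reader.bit_position,
                           group_start_bits=g_start,
                           group_atom_counts=g_count,
                           group_smallidx_in=g_small,
                           group_end_bits=g_end)


def ref_compress(coords, precision) -> CoordBlock:
    """Scalar, loop-by-loop encoder transcription (natoms > 9)."""
    x = np.asarray(coords, dtype=np.float32)
    natoms = x.shape[0]
    if natoms <= 9:
        raise XtcRangeError("reference compression applies to natoms > 9")
    if precision <= 0:
        precision = 1000.0
    prec = np.float32(precision)

    ints = []
    minint = [2**31 - 1] * 3
    maxint = [-(2**31)] * 3
    mindiff = 2**31 - 1
    old = [0, 0, 0]
    for a in range(natoms):
        cur = [ref_quantize_one(x[a, d], prec) for d in range(3)]
        for d in range(3):
            minint[d] = min(minint[d], cur[d])
            maxint[d] = max(maxint[d], cur[d])
        if a >= 1:
            diff = sum(abs(old[d] - cur[d]) for d in range(3))
            mindiff = min(mindiff, diff)
        old = cur
        ints.append(cur)

    for d in range(3):
        if np.float32(maxint[d]) - np.float32(minint[d]) >= np.float32(MAXABS):
            raise XtcRangeError("coordinate spread too large for the codec")
    sizeint = [maxint[d] - minint[d] + 1 for d in range(3)]
    if (sizeint[0] | sizeint[1] | sizeint[2]) > 0xFFFFFF:
        bitsizeint = [sizeofint(s) for s in sizeint]
        bitsize = 0
    else:
        bitsizeint = [0, 0, 0]
        bitsize = sizeofints(sizeint)

    smallidx = FIRSTIDX
    while smallidx < LASTIDX and MAGICINTS[smallidx] < mindiff:
        smallidx += 1
    if smallidx >= LASTIDX:
        smallidx = LASTIDX - 1
    smallidx0 = smallidx
    maxidx = min(smallidx + 8, LASTIDX - 1)
    minidx = maxidx - 8
    smaller = int(MAGICINTS[max(smallidx - 1, FIRSTIDX)]) // 2
    smallnum = int(MAGICINTS[smallidx]) // 2
    sizesmall = [int(MAGICINTS[smallidx])] * 3
    larger = int(MAGICINTS[maxidx]) // 2

    w = BitWriter()
    prevrun = -1
    prevcoord = [0, 0, 0]
    i = 0
    while i < natoms:
        is_small = 0
        thiscoord = ints[i]
        if (smallidx < maxidx and i >= 1
                and all(abs(thiscoord[d] - prevcoord[d]) < larger for d in range(3))):
            is_smaller = 1
        elif smallidx > minidx:
            is_smaller = -1
        else:
            is_smaller = 0
        if i + 1 < natoms:
            if all(abs(thiscoord[d] - ints[i + 1][d]) < smallnum for d in range(3)):
                ints[i], ints[i + 1] = ints[i + 1], ints[i]
                thiscoord = ints[i]
                is_small = 1
        tmpcoord = [thiscoord[d] - minint[d] for d in range(3)]
        if bitsize == 0:
            for d in range(3):
                w.write_bits(tmpcoord[d], bitsizeint[d])
        else:
            encodeints(w, tmpcoord, sizeint, bitsize)
        prevcoord = list(thiscoord)
        i += 1

        run = 0
        if is_small == 0 and is_smaller == -1:
            is_smaller = 0
        runvals = []
        while is_small and run < 8 * 3:
            this = ints[i]
            tmpsum = sum((this[d] - prevcoord[d]) ** 2 for d in range(3))
            if is_smaller == -1 and tmpsum >= smaller * smaller:
                is_smaller = 0
            runvals.append([this[d] - prevcoord[d] + smallnum for d in range(3)])
            run += 3
            prevcoord = list(this)
            i += 1
            is_small = 0
            if i < natoms and all(abs(ints[i][d] - prevcoord[d]) < smallnum
                                  for d in range(3)):
                is_small = 1
        if run != prevrun or is_smaller != 0:
            prevrun = run
            w.write_bits(1, 1)
            w.write_bits(run + is_smaller + 1, 5)
        else:
            w.write_bits(0, 1)
        for triple in runvals:
            encodeints(w, triple, sizesmall, smallidx)
        if is_smaller != 0:
            smallidx += is_smaller
            if is_smaller < 0:
                smallnum = smaller
                smaller = int(MAGICINTS[smallidx - 1]) // 2
            else:
                smaller = smallnum
                smallnum = int(MAGICINTS[smallidx]) // 2
            sizesmall = [int(MAGICINTS[smallidx])] * 3

    payload = w.getvalue()
    return CoordBlock(precision=float(prec),
                      minint=tuple(minint), maxint=tuple(maxint),
                      smallidx0=smallidx0, nbytes=w.nbytes, payload=payload)
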