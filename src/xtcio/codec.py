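"""The xtc coordinate codec: fixed-point quantization, mixed-radix integer
coding and run-length encoding of small inter-atom differences.

The compressed payload of a frame is a stream of *run groups*: one
absolutely-coded atom followed by a run of up to eight atom triples coded
as small differences in a moving radix.  A 1-bit flag plus an optional
5-bit run header per group are the *control bits*; they fully determine
both the payload bit widths and the evolution of the small-difference
radix (the ``smallidx`` index into :data:`MAGICINTS`).  This is what makes
skipping and block-parallel decoding possible: a scanner that reads only
control bits can tile the payload into independently decodable groups.

The hot paths are compiled (see :mod:`xtcio._kernels`); the Python-level
operations here (``sizeofints``, ``encodeints``/``decodeints``...) are the
reference semantics used by the naive oracle in :mod:`xtcio.reference`
and exposed for inspection and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import FIRSTIDX, LASTIDX, MAGICINTS
from .bitstream import BitReader, BitWriter
from .errors import XtcCorruptionError, XtcRangeError
from .instrumentation import counters

__all__ = [
    "MAGICINTS", "FIRSTIDX", "LASTIDX", "MAXABS",
    "magicints", "sizeofint", "sizeofints", "encodeints", "decodeints",
    "quantize", "dequantize", "inverse_precision",
    "CoordBlock", "RunGroupRecord", "ScanResult", "DecodeResult",
    "compress_coords", "decompress_coords", "scan_groups",
]

#: Largest magnitude the codec's working integers may take (guard used by
#: the reference implementation: values near the signed 32-bit limit are
#: rejected so files stay portable).
MAXABS = 2147483645  # INT32_MAX - 2


def magicints(i: int) -> int:
    """Entry ``i`` of the frozen range table (0 below FIRSTIDX)."""
    if not 0 <= i < LASTIDX:
        raise XtcRangeError(f"magicints index {i} outside 0..{LASTIDX - 1}")
    return int(MAGICINTS[i])


def sizeofint(size: int) -> int:
    """Smallest bit width ``b`` with ``2**b > size`` (capped at 32)."""
    if size < 1:
        raise XtcRangeError(f"size must be >= 1, got {size}")
    num = 1
    num_of_bits = 0
    while size >= num and num_of_bits < 32:
        num_of_bits += 1
        num <<= 1
    return num_of_bits


def sizeofints(sizes) -> int:
    """Bit width of a mixed-radix triple, via the byte-array product.

    This deliberately follows the codec's byte-array algorithm rather than
    ``ceil(log2(prod(sizes)))``: the two differ (the byte-array result is
    the width of the *product itself*, not of product-1), and the wire
    format is defined by the former.
    """
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise XtcRangeError(f"all radices must be >= 1, got {sizes}")
    bytes_ = [1]
    for s in sizes:
        tmp = 0
        for j in range(len(bytes_)):
            tmp = bytes_[j] * s + tmp
            bytes_[j] = tmp & 0xFF
            tmp >>= 8
        while tmp != 0:
            bytes_.append(tmp & 0xFF)
            tmp >>= 8
    num = 1
    num_of_bits = 0
    top = bytes_[-1]
    while top >= num:
        num_of_bits += 1
        num *= 2
    return num_of_bits + (len(bytes_) - 1) * 8


def encodeints(writer: BitWriter, values, sizes, nbits: int) -> None:
    """Pack three non-negative ints of radices ``sizes`` into ``nbits`` bits.

    The combined value ``((v0*s1)+v1)*s2+v2`` goes on the wire as its
    little-endian byte decomposition, low byte first, remainder bits last.
    """
    values = [int(v) for v in values]
    sizes = [int(s) for s in sizes]
    for v, s in zip(values[1:], sizes[1:]):
        if not 0 <= v < s:
            raise XtcRangeError(f"value {v} outside radix {s}")
    if values[0] < 0:
        raise XtcRangeError("values must be non-negative")
    bytes_ = []
    tmp = values[0]
    while True:
        bytes_.append(tmp & 0xFF)
        tmp >>= 8
        if tmp == 0:
            break
    for v, s in zip(values[1:], sizes[1:]):
        tmp = v
        for j in range(len(bytes_)):
            tmp = bytes_[j] * s + tmp
            bytes_[j] = tmp & 0xFF
            tmp >>= 8
        while tmp != 0:
            bytes_.append(tmp & 0xFF)
            tmp >>= 8
    nb = len(bytes_)
    if nbits >= nb * 8:
        for j in range(nb):
            writer.write_bits(bytes_[j], 8)
        pad = nbits - nb * 8
        while pad > 32:
            writer.write_bits(0, 32)
            pad -= 32
        writer.write_bits(0, pad)
    else:
        for j in range(nb - 1):
            writer.write_bits(bytes_[j], 8)
        writer.write_bits(bytes_[nb - 1], nbits - (nb - 1) * 8)


def decodeints(reader: BitReader, sizes, nbits: int):
    """Exact inverse of :func:`encodeints`; consumes exactly ``nbits`` bits."""
    counters.decodeints_calls += 1
    sizes = [int(s) for s in sizes]
    bytes_ = [0, 0, 0, 0]
    nb = 0
    while nbits > 8:
        v = reader.read_bits(8)
        if nb < len(bytes_):
            bytes_[nb] = v
        else:
            bytes_.append(v)
        nb += 1
        nbits -= 8
    if nbits > 0:
        v = reader.read_bits(nbits)
        if nb < len(bytes_):
            bytes_[nb] = v
        else:
            bytes_.append(v)
        nb += 1
    nums = [0, 0, 0]
    for i in (2, 1):
        num = 0
        for j in range(nb - 1, -1, -1):
            num = (num << 8) | bytes_[j]
            p = num // sizes[i]
            bytes_[j] = p
            num -= p * sizes[i]
        nums[i] = num
    nums[0] = bytes_[0] | (bytes_[1] << 8) | (bytes_[2] << 16) | (bytes_[3] << 24)
    return tuple(nums)


# ---------------------------------------------------------------------------
# quantization (32-bit float semantics, round half away from zero)
# ---------------------------------------------------------------------------

def quantize(coords, precision):
    """Coordinates (nm) -> lattice integers, ``round(x * precision)``.

    Rounding is half away from zero computed in 32-bit float arithmetic
    (multiply, add +-0.5, truncate), matching the canonical writer so the
    quantized lattice is identical.  Raises :class:`XtcRangeError` naming
    the first offending atom if any scaled coordinate leaves the working
    integer range.
    """
    x = np.asarray(coords, dtype=np.float32)
    p = np.float32(precision)
    prod = x * p
    half = np.float32(0.5)
    lf = np.where(x >= 0, prod + half, prod - half)
    bad = np.abs(lf) > np.float32(MAXABS)
    if np.any(bad):
        flat = int(np.flatnonzero(np.atleast_1d(bad).reshape(-1))[0])
        idx = flat // 3 if x.ndim == 2 else flat
        raise XtcRangeError(
            f"coordinate * precision overflows the working range at atom {idx}")
    return lf.astype(np.int64)


def dequantize(ints, precision):
    """Lattice integers -> nm, ``i * (1/precision)`` in 32-bit floats."""
    return np.asarray(ints).astype(np.float32) * inverse_precision(precision)


def inverse_precision(precision) -> np.float32:
    # 1.0 / precision evaluated as double then narrowed, as in the codec
    return np.float32(1.0 / np.float64(np.float32(precision)))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoordBlock:
    """One frame's compressed coordinate payload plus its side parameters."""

    precision: float
    minint: tuple
    maxint: tuple
    smallidx0: int
    nbytes: int
    payload: bytes  # exactly nbytes bytes (unpadded)

    def __post_init__(self):
        if not FIRSTIDX <= self.smallidx0 < LASTIDX:
            raise XtcRangeError(
                f"smallidx0 {self.smallidx0} outside [{FIRSTIDX}, {LASTIDX})")
        if self.nbytes < 0 or len(self.payload) != self.nbytes:
            raise XtcRangeError("payload length does not match nbytes")

    @property
    def sizeint(self) -> tuple:
        return tuple(int(a) - int(b) + 1 for a, b in zip(self.maxint, self.minint))

    @property
    def padded_payload(self) -> bytes:
        pad = (-self.nbytes) % 4
        return self.payload + b"\x00" * pad


@dataclass(frozen=True)
class RunGroupRecord:
    """Scan-derived descriptor of one independently decodable run group."""

    start_bit: int
    atom_count: int
    smallidx_in: int
    end_bit: int


@dataclass
class ScanResult:
    """Run-group tiling of a payload (arrays, one entry per group)."""

    start_bit: np.ndarray
    atom_count: np.ndarray
    smallidx_in: np.ndarray
    end_bit: np.ndarray
    final_bit: int

    def __len__(self) -> int:
        return len(self.start_bit)

    @property
    def records(self):
        return [RunGroupRecord(int(s), int(c), int(m), int(e))
                for s, c, m, e in zip(self.start_bit, self.atom_count,
                                      self.smallidx_in, self.end_bit)]


@dataclass
class DecodeResult:
    coords: np.ndarray          # (natoms, 3) float32, nm
    ints: np.ndarray            # (natoms, 3) int64 lattice coordinates
    final_bit: int
    ngroups: int
    groups: ScanResult | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# block-level compress / decompress / scan
# ---------------------------------------------------------------------------

def _block_geometry(block: CoordBlock):
    """Shared derivation of (bitsize, per-axis widths, sizeint) for a block."""
    sizeint = block.sizeint
    if any(s < 1 for s in sizeint):
        raise XtcCorruptionError(f"non-positive coordinate range {sizeint}")
    if (sizeint[0] | sizeint[1] | sizeint[2]) > 0xFFFFFF:
        bs = tuple(sizeofint(s) for s in sizeint)
        bitsize = 0
    else:
        bs = (0, 0, 0)
        bitsize = sizeofints(sizeint)
    return bitsize, bs, sizeint


def _guarded_payload(block: CoordBlock) -> np.ndarray:
    # 128 zero guard bytes: a corrupt stream may over-read by at most one
    # run group (<= ~86 bytes) before the atom-count check trips; the
    # guard keeps that read in-bounds, the final-cursor check catches it.
    raw = block.padded_payload + b"\x00" * 128
    return np.frombuffer(raw, dtype=np.uint8)


def compress_coords(coords, precision) -> CoordBlock:
    """Full coordinate compression of one frame (natoms > 9)."""
    x = np.ascontiguousarray(coords, dtype=np.float32)
    if x.ndim != 2 or x.shape[1] != 3:
        raise XtcRangeError("coords must have shape (natoms, 3)")
    natoms = x.shape[0]
    if natoms <= 9:
        raise XtcRangeError("compression applies to frames with natoms > 9")
    if precision <= 0:
        precision = 1000.0
    counters.encode_calls += 1
    ints = quantize(x, precision)
    minint = ints.min(axis=0)
    maxint = ints.max(axis=0)
    spread = maxint.astype(np.float32) - minint.astype(np.float32)
    if np.any(spread >= np.float32(MAXABS)):
        raise XtcRangeError("coordinate spread too large for the codec")
    mindiff = int(np.abs(np.diff(ints, axis=0)).sum(axis=1).min())
    smallidx = FIRSTIDX
    while smallidx < LASTIDX and MAGICINTS[smallidx] < mindiff:
        smallidx += 1
    if smallidx >= LASTIDX:
        smallidx = LASTIDX - 1  # clamp: keep the index on the table
    sizeint = (maxint - minint + 1).astype(np.int64)
    if (int(sizeint[0]) | int(sizeint[1]) | int(sizeint[2])) > 0xFFFFFF:
        bs0, bs1, bs2 = (sizeofint(int(s)) for s in sizeint)
        bitsize = 0
    else:
        bs0 = bs1 = bs2 = 0
        bitsize = sizeofints(tuple(int(s) for s in sizeint))
    out = np.zeros(natoms * 16 + 128, dtype=np.uint8)
    scratch = np.zeros(64, dtype=np.int64)
    work = np.ascontiguousarray(ints.reshape(-1).copy())
    nbytes, _bitlen = _kernels._encode(
        work, natoms,
        int(minint[0]), int(minint[1]), int(minint[2]),
        int(sizeint[1]), int(sizeint[2]),
        bitsize, bs0, bs1, bs2, smallidx, out, scratch)
    return CoordBlock(
        precision=float(np.float32(precision)),
        minint=tuple(int(v) for v in minint),
        maxint=tuple(int(v) for v in maxint),
        smallidx0=int(smallidx),
        nbytes=int(nbytes),
        payload=out[:nbytes].tobytes(),
    )


def _run_walk(block: CoordBlock, natoms: int, mode: int, owned=None):
    bitsize, bs, sizeint = _block_geometry(block)
    data = _guarded_payload(block)
    if owned is None:
        owned = np.ones(1, dtype=np.uint8)
    out_ints = np.zeros(3 * natoms, dtype=np.int64)
    g_start = np.zeros(natoms, dtype=np.int64)
    g_count = np.zeros(natoms, dtype=np.int64)
    g_small = np.zeros(natoms, dtype=np.int64)
    g_end = np.zeros(natoms, dtype=np.int64)
    scratch = np.zeros(64, dtype=np.int64)
    status, final_bit, ngroups, ndecoded = _kernels._walk(
        data, natoms, bitsize, bs[0], bs[1], bs[2],
        int(sizeint[1]), int(sizeint[2]),
        block.minint[0], block.minint[1], block.minint[2],
        block.smallidx0, mode, owned,
        out_ints, g_start, g_count, g_small, g_end, scratch)
    if status == 1:
        raise XtcCorruptionError(
            f"decoded atom count exceeds natoms={natoms} at group {ngroups}")
    if status == 2:
        raise XtcCorruptionError("small-index state left the valid table range")
    padded_bits = 8 * len(block.padded_payload)
    if final_bit > padded_bits:
        raise XtcCorruptionError(
            f"payload exhausted: cursor {final_bit} past {padded_bits} bits")
    scan = ScanResult(g_start[:ngroups].copy(), g_count[:ngroups].copy(),
                      g_small[:ngroups].copy(), g_end[:ngroups].copy(),
                      int(final_bit))
    return out_ints, scan, int(final_bit), int(ndecoded)


def decompress_coords(block: CoordBlock, natoms: int, *,
                      full_result: bool = False):
    """Decode a compressed payload back to (natoms, 3) nm coordinates.

    The optimized decoder; bit-identical to the naive transcription in
    :mod:`xtcio.reference` (a tested invariant, including the final
    cursor position).
    """
    if natoms < 1:
        raise XtcRangeError("natoms must be >= 1")
    counters.decompress_calls += 1
    out_ints, scan, final_bit, _nd = _run_walk(block, natoms, _kernels.MODE_DECODE)
    ints = out_ints.reshape(natoms, 3)
    coords = (ints.astype(np.float32)
              * inverse_precision(block.precision)).reshape(natoms, 3)
    if full_result:
        return DecodeResult(coords=coords, ints=ints, final_bit=final_bit,
                            ngroups=len(scan), groups=scan)
    return coords


def scan_groups(block: CoordBlock, natoms: int) -> ScanResult:
    """Tile the payload into run groups by walking only control bits.

    No integer decoding is performed: payload widths are derived from the
    block geometry and the per-smallidx bit-width rule and skipped.  The
    resulting tiling is contiguous, complete and atom-count conserving,
    and the small-index entry states equal the full decoder's.
    """
    if natoms < 1:
        raise XtcRangeError("natoms must be >= 1")
    _ints, scan, _fb, ndecoded = _run_walk(block, natoms, _kernels.MODE_SCAN)
    assert ndecoded == 0
    if int(scan.atom_count.sum()) != natoms:
        raise XtcCorruptionError("run groups do not tile the frame")
    return scan
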