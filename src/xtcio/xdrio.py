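"""XDR-level primitives and xtc frame framing.

An xtc file is a sequence of XDR-framed records, one per frame:

====================  =======  =====================================
section               bytes    contents
====================  =======  =====================================
header                16       magic (1995), natoms, step, time
box                   36       3x3 box vectors, nm, float32
natoms echo           4        must equal the header's natoms
coordinates           var.     natoms <= 9: 12*natoms raw float32;
                               else the compressed section below
====================  =======  =====================================

Compressed section: precision (float32), minint[3], maxint[3],
smallidx, byte count, then the payload padded to a 4-byte boundary.
Every multi-byte scalar is big-endian; every frame length is a multiple
of four.  Atom counts must stay below the signed 32-bit limit, which in
practice caps the format at ~1e8 particles.

All readers restore the stream position to the frame start before
raising, so callers can salvage partially written files.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field

import numpy as np

from .codec import CoordBlock, compress_coords, decompress_coords
from .errors import XtcFormatError, XtcRangeError, XtcTruncationError
from .instrumentation import counters

XTC_MAGIC = 1995
HEADER_BYTES = 16

_INT = struct.Struct(">i")
_FLOAT = struct.Struct(">f")


# ---------------------------------------------------------------------------
# XDR scalar and opaque codecs
# ---------------------------------------------------------------------------

def encode_int32(value: int) -> bytes:
    """Signed 32-bit big-endian encoding."""
    try:
        return _INT.pack(value)
    except struct.error as exc:
        raise XtcRangeError(f"{value} outside signed 32-bit range") from exc


def decode_int32(data: bytes) -> int:
    if len(data) < 4:
        raise XtcTruncationError(f"int32 needs 4 bytes, got {len(data)}")
    return _INT.unpack(data[:4])[0]


def encode_float32(value) -> bytes:
    return _FLOAT.pack(float(np.float32(value)))


def decode_float32(data: bytes) -> float:
    if len(data) < 4:
        raise XtcTruncationError(f"float32 needs 4 bytes, got {len(data)}")
    return _FLOAT.unpack(data[:4])[0]


def encode_opaque(payload: bytes) -> bytes:
    """XDR opaque: the bytes followed by zero padding to a 4-byte boundary."""
    pad = (-len(payload)) % 4
    return payload + b"\x00" * pad


def decode_opaque(data: bytes, n: int) -> bytes:
    padded = n + ((-n) % 4)
    if len(data) < padded:
        raise XtcTruncationError(f"opaque of {n} bytes needs {padded}, got {len(data)}")
    return data[:n]


def _read_exact(stream, n: int, what: str) -> bytes:
    data = stream.read(n)
    if len(data) != n:
        raise XtcTruncationError(
            f"EOF inside {what}: wanted {n} bytes, got {len(data)}",
            offset=stream.tell() - len(data))
    return data


def read_int32(stream) -> int:
    return decode_int32(_read_exact(stream, 4, "int32"))


def read_float32(stream) -> float:
    return decode_float32(_read_exact(stream, 4, "float32"))


# ---------------------------------------------------------------------------
# frame containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameHeader:
    magic: int
    natoms: int
    step: int
    time: float

    def __post_init__(self):
        if self.magic != XTC_MAGIC:
            raise XtcFormatError(f"bad magic {self.magic}", value=self.magic)
        if self.natoms < 1:
            raise XtcFormatError(f"natoms must be >= 1, got {self.natoms}")


@dataclass(frozen=True)
class Box:
    """3x3 matrix of box vectors in nm (float32 on the wire)."""

    m: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.m, dtype=np.float32).reshape(3, 3)
        if not np.all(np.isfinite(m)):
            raise XtcRangeError("box entries must be finite")
        object.__setattr__(self, "m", m)


@dataclass
class Frame:
    """One trajectory frame: header, box, coordinates (nm), precision."""

    header: FrameHeader
    box: Box
    coords: np.ndarray
    precision: float = 1000.0
    block: CoordBlock | None = field(default=None, repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float32).reshape(-1, 3)
        if self.coords.shape[0] != self.header.natoms:
            raise XtcFormatError(
                f"coords rows {self.coords.shape[0]} != natoms {self.header.natoms}")

    @classmethod
    def create(cls, coords, *, step: int = 0, time: float = 0.0,
               box=None, precision: float = 1000.0) -> "Frame":
        coords = np.asarray(coords, dtype=np.float32).reshape(-1, 3)
        if box is None:
            box = np.zeros((3, 3), dtype=np.float32)
        header = FrameHeader(XTC_MAGIC, coords.shape[0], int(step),
                             float(np.float32(time)))
        return cls(header=header, box=Box(np.asarray(box)), coords=coords,
                   precision=precision)

    @property
    def natoms(self) -> int:
        return self.header.natoms

    @property
    def step(self) -> int:
        return self.header.step

    @property
    def time(self) -> float:
        return self.header.time


# ---------------------------------------------------------------------------
# frame reading / writing / skipping
# ---------------------------------------------------------------------------

def read_frame_header(stream) -> FrameHeader | None:
    """Read a 16-byte frame header; None on clean EOF at a frame boundary."""
    start = stream.tell()
    data = stream.read(HEADER_BYTES)
    if len(data) == 0:
        return None  # end of trajectory
    if len(data) < HEADER_BYTES:
        stream.seek(start)
        raise XtcTruncationError(
            f"EOF inside frame header at offset {start}", offset=start)
    magic = decode_int32(data[0:4])
    if magic != XTC_MAGIC:
        stream.seek(start)
        raise XtcFormatError(
            f"bad magic {magic} (expected {XTC_MAGIC}) at offset {start}",
            offset=start, value=magic)
    natoms = decode_int32(data[4:8])
    step = decode_int32(data[8:12])
    time = decode_float32(data[12:16])
    if natoms < 1:
        stream.seek(start)
        raise XtcFormatError(f"invalid natoms {natoms} at offset {start}",
                             offset=start, value=natoms)
    return FrameHeader(magic, natoms, step, time)


def _read_coord_section(stream, natoms: int):
    """After the box: returns either raw float32 coords or a CoordBlock."""
    echo = read_int32(stream)
    if echo != natoms:
        raise XtcFormatError(
            f"natoms mismatch inside coordinate section: {echo} != {natoms}")
    if natoms <= 9:
        raw = _read_exact(stream, 12 * natoms, "uncompressed coordinates")
        coords = np.frombuffer(raw, dtype=">f4").astype(np.float32).reshape(natoms, 3)
        return coords
    precision = read_float32(stream)
    minint = tuple(read_int32(stream) for _ in range(3))
    maxint = tuple(read_int32(stream) for _ in range(3))
    smallidx = read_int32(stream)
    nbytes = read_int32(stream)
    if nbytes < 0:
        raise XtcFormatError(f"negative payload length {nbytes}")
    padded = nbytes + ((-nbytes) % 4)
    payload = _read_exact(stream, padded, "compressed payload")[:nbytes]
    return CoordBlock(precision=precision, minint=minint, maxint=maxint,
                      smallidx0=smallidx, nbytes=nbytes, payload=payload)


def read_frame_raw(stream):
    """Read one frame without decompressing.

    Returns ``(header, box, payload)`` where payload is a float32 array
    for small frames or a :class:`~xtcio.codec.CoordBlock` otherwise;
    None at clean EOF.  The stream is left at the next frame boundary.
    """
    start = stream.tell()
    try:
        header = read_frame_header(stream)
        if header is None:
            return None
        raw = _read_exact(stream, 36, "box")
        box = Box(np.frombuffer(raw, dtype=">f4").astype(np.float32).reshape(3, 3))
        payload = _read_coord_section(stream, header.natoms)
    except Exception:
        stream.seek(start)
        raise
    return header, box, payload


def read_frame(stream) -> Frame | None:
    """Read and fully decode one frame; None at clean EOF."""
    out = read_frame_raw(stream)
    if out is None:
        return None
    header, box, payload = out
    if isinstance(payload, CoordBlock):
        coords = decompress_coords(payload, header.natoms)
        return Frame(header=header, box=box, coords=coords,
                     precision=payload.precision, block=payload)
    return Frame(header=header, box=box, coords=payload, precision=0.0)


def write_frame(stream, frame: Frame) -> int:
    """Serialize a frame; returns bytes written (always a multiple of 4)."""
    natoms = frame.natoms
    parts = [encode_int32(XTC_MAGIC), encode_int32(natoms),
             encode_int32(frame.step), encode_float32(frame.time)]
    box = np.asarray(frame.box.m, dtype=np.float32)
    parts.append(box.astype(">f4").tobytes())
    parts.append(encode_int32(natoms))
    if natoms <= 9:
        parts.append(frame.coords.astype(">f4").tobytes())
    else:
        block = compress_coords(frame.coords, frame.precision)
        parts.append(encode_float32(block.precision))
        for v in (*block.minint, *block.maxint):
            parts.append(encode_int32(int(v)))
        parts.append(encode_int32(block.smallidx0))
        parts.append(encode_int32(block.nbytes))
        parts.append(encode_opaque(block.payload))
    data = b"".join(parts)
    stream.write(data)
    return len(data)


def write_block_frame(stream, header: FrameHeader, box: Box,
                      block: CoordBlock) -> int:
    """Re-emit an already-compressed frame verbatim (no re-encode)."""
    parts = [encode_int32(XTC_MAGIC), encode_int32(header.natoms),
             encode_int32(header.step), encode_float32(header.time),
             np.asarray(box.m, dtype=np.float32).astype(">f4").tobytes(),
             encode_int32(header.natoms), encode_float32(block.precision)]
    for v in (*block.minint, *block.maxint):
        parts.append(encode_int32(int(v)))
    parts.append(encode_int32(block.smallidx0))
    parts.append(encode_int32(block.nbytes))
    parts.append(encode_opaque(block.payload))
    data = b"".join(parts)
    stream.write(data)
    return len(data)


def _stream_size(stream) -> int:
    cur = stream.tell()
    end = stream.seek(0, io.SEEK_END)
    stream.seek(cur)
    return end


def skip_frame(stream) -> FrameHeader | None:
    """Advance past one frame without decompressing; returns its header.

    For compressed frames only the declared byte count is read and the
    padded payload is seeked over.  None at clean EOF; on truncation the
    position is restored to the frame start.
    """
    start = stream.tell()
    try:
        header = read_frame_header(stream)
        if header is None:
            return None
        counters.skip_frame_calls += 1
        natoms = header.natoms
        size = _stream_size(stream)
        if natoms <= 9:
            # box + echo + raw floats
            end = stream.tell() + 36 + 4 + 12 * natoms
            if end > size:
                raise XtcTruncationError(
                    f"EOF inside small frame at offset {start}", offset=start)
            stream.seek(end)
        else:
            stream.seek(36, io.SEEK_CUR)  # box
            echo_off = stream.tell()
            if echo_off + 4 > size:
                raise XtcTruncationError(
                    f"EOF inside frame at offset {start}", offset=start)
            echo = read_int32(stream)
            if echo != natoms:
                raise XtcFormatError(
                    f"natoms mismatch inside coordinate section: {echo} != {natoms}",
                    offset=echo_off)
            stream.seek(32, io.SEEK_CUR)  # precision, minint, maxint, smallidx
            if stream.tell() + 4 > size:
                raise XtcTruncationError(
                    f"EOF inside frame at offset {start}", offset=start)
            nbytes = read_int32(stream)
            if nbytes < 0:
                raise XtcFormatError(f"negative payload length {nbytes}")
            end = stream.tell() + nbytes + ((-nbytes) % 4)
            if end > size:
                raise XtcTruncationError(
                    f"EOF inside compressed payload at offset {start}", offset=start)
            stream.seek(end)
    except Exception:
        stream.seek(start)
        raise
    return header


def iter_frames(stream):
    """Yield decoded frames until clean EOF; enforces uniform natoms."""
    natoms = None
    while True:
        frame = read_frame(stream)
        if frame is None:
            return
        if natoms is None:
            natoms = frame.natoms
        elif frame.natoms != natoms:
            raise XtcFormatError(
                f"non-uniform atom count: {frame.natoms} != {natoms}")
        yield frame
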