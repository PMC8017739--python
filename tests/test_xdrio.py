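"""XDR primitives, frame framing, skipping, and error contracts."""

import io

import numpy as np
import pytest

from xtcio import (Frame, XTC_MAGIC, XtcFormatError, XtcTruncationError,
                   micro_fixture, read_frame, read_frame_header, skip_frame,
                   write_frame)
from xtcio.synth import SyntheticSpec, gen_frames
from xtcio.xdrio import (decode_int32, decode_opaque, encode_float32,
                         encode_int32, encode_opaque, decode_float32)

MICRO_GOLDEN_HEX = (
    "000007cb00000005000000073fc0000040200000000000000000000000000000"
    "4020000000000000000000000000000040200000000000053f0000003e800000"
    "3f8000003fc000003f4000003e000000400000003f8000003f00000000000000"
    "bf000000402000003fa00000401000003d800000"
)


@pytest.mark.parametrize("value,wire", [
    (1995, bytes.fromhex("000007cb")),
    (0, b"\x00\x00\x00\x00"),
    (-1, b"\xff\xff\xff\xff"),
])
def test_int32_big_endian(value, wire):
    assert encode_int32(value) == wire
    assert decode_int32(wire) == value


@pytest.mark.parametrize("value,wire", [
    (1.0, bytes.fromhex("3f800000")),
    (0.0, b"\x00\x00\x00\x00"),
])
def test_float32_big_endian(value, wire):
    assert encode_float32(value) == wire
    assert decode_float32(wire) == value


def test_float32_roundtrip_bit_identical():
    for v in (0.1, -3.25, 1e-8, 12345.678):
        v32 = float(np.float32(v))
        assert decode_float32(encode_float32(v32)) == v32


@pytest.mark.parametrize("n,total", [(5, 8), (4, 4), (0, 0)])
def test_opaque_padding(n, total):
    payload = bytes(range(1, n + 1))
    wire = encode_opaque(payload)
    assert len(wire) == total
    assert wire[:n] == payload
    assert all(b == 0 for b in wire[n:])
    assert decode_opaque(wire, n) == payload


def test_truncated_scalar_raises():
    with pytest.raises(XtcTruncationError):
        decode_int32(b"\x00\x01")
    with pytest.raises(XtcTruncationError):
        decode_opaque(b"\x00" * 4, 5)


# ---------------------------------------------------------------------------

def test_header_roundtrip_and_eof():
    frame = Frame.create(np.zeros((3, 3)), step=0, time=0.0)
    buf = io.BytesIO()
    write_frame(buf, frame)
    buf.seek(0)
    header = read_frame_header(buf)
    assert (header.magic, header.natoms, header.step, header.time) == \
        (XTC_MAGIC, 3, 0, 0.0)
    assert buf.tell() == 16
    assert read_frame_header(io.BytesIO()) is None  # clean EOF, not an error


def test_corrupt_magic_reports_value_and_restores_position():
    buf = io.BytesIO(b"\x00\x00\x00\x2a" + b"\x00" * 12)
    with pytest.raises(XtcFormatError) as err:
        read_frame_header(buf)
    assert err.value.value == 42
    assert buf.tell() == 0


def test_micro_fixture_golden_bytes():
    frame, blob = micro_fixture()
    assert blob == bytes.fromhex(MICRO_GOLDEN_HEX)
    assert len(blob) == 116  # 16 header + 36 box + 4 echo + 60 coords
    back = read_frame(io.BytesIO(blob))
    assert np.array_equal(back.coords, frame.coords)
    assert np.array_equal(back.box.m, frame.box.m)
    assert (back.step, back.time) == (7, 1.5)


def test_small_frame_roundtrip_bit_exact():
    rng = np.random.default_rng(0)
    coords = rng.uniform(-5, 5, size=(5, 3)).astype(np.float32)
    frame = Frame.create(coords, step=3, time=0.25, box=np.eye(3))
    buf = io.BytesIO()
    n = write_frame(buf, frame)
    assert n % 4 == 0
    buf.seek(0)
    back = read_frame(buf)
    assert np.array_equal(back.coords, coords)          # bit-exact, no codec
    assert np.array_equal(back.box.m, frame.box.m)


def test_compressed_roundtrip_within_half_quantum():
    spec = SyntheticSpec(natoms=300, nframes=1, model="water_like", seed=9)
    frame = next(iter(gen_frames(spec)))
    buf = io.BytesIO()
    write_frame(buf, frame)
    buf.seek(0)
    back = read_frame(buf)
    bound = 0.5 / frame.precision + np.abs(frame.coords).max() * 2.0 ** -20
    assert np.max(np.abs(back.coords - frame.coords)) <= bound
    assert np.array_equal(back.box.m, frame.box.m)      # box is bit-exact
    assert back.precision == frame.precision


def test_two_concatenated_frames_read_in_order():
    spec = SyntheticSpec(natoms=30, nframes=2, model="random_walk", seed=1)
    frames = list(gen_frames(spec))
    buf = io.BytesIO()
    for fr in frames:
        write_frame(buf, fr)
    buf.seek(0)
    for fr in frames:
        back = read_frame(buf)
        assert back.step == fr.step
    assert read_frame(buf) is None


def test_skip_walk_matches_read_walk_offsets(water_file):
    with open(water_file, "rb") as fh:
        skip_offsets = []
        while True:
            skip_offsets.append(fh.tell())
            if skip_frame(fh) is None:
                break
        size = fh.seek(0, io.SEEK_END)
        fh.seek(0)
        read_offsets = []
        while True:
            read_offsets.append(fh.tell())
            if read_frame(fh) is None:
                break
    assert skip_offsets == read_offsets
    assert skip_offsets[-1] == size       # framing conservation
    assert len(skip_offsets) - 1 == 50


def test_skip_on_truncated_frame_restores_position(water_file):
    blob = water_file.read_bytes()
    with open(water_file, "rb") as fh:
        skip_frame(fh)
        first_len = fh.tell()
    buf = io.BytesIO(blob[:first_len + 60])  # second frame cut short
    skip_frame(buf)
    pos = buf.tell()
    with pytest.raises(XtcTruncationError):
        skip_frame(buf)
    assert buf.tell() == pos
    with pytest.raises(XtcTruncationError):
        read_frame(buf)
    assert buf.tell() == pos


def test_natoms_echo_mismatch_is_format_error(water_file):
    blob = bytearray(water_file.read_bytes())
    # corrupt the echoed natoms of the first frame (offset 16+36)
    blob[52:56] = (301).to_bytes(4, "big")
    with pytest.raises(XtcFormatError):
        read_frame(io.BytesIO(bytes(blob)))
    with pytest.raises(XtcFormatError):
        skip_frame(io.BytesIO(bytes(blob)))


def test_coordinate_overflow_names_atom():
    from xtcio.errors import XtcRangeError
    coords = np.zeros((12, 3), dtype=np.float32)
    coords[7, 1] = 3.0e6  # * precision 1000 overflows the working range
    frame = Frame.create(coords, precision=1000.0)
    with pytest.raises(XtcRangeError, match="atom 7"):
        write_frame(io.BytesIO(), frame)
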