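"""Codec primitives and block-level compress/decompress/scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xtcio.bitstream import BitReader, BitWriter
from xtcio.codec import (FIRSTIDX, LASTIDX, MAGICINTS, compress_coords,
                         decodeints, decompress_coords, dequantize,
                         encodeints, magicints, quantize, scan_groups,
                         sizeofint, sizeofints)
from xtcio.errors import XtcCorruptionError, XtcRangeError
from xtcio.instrumentation import counters


# ---------------------------------------------------------------------------
# table and width primitives
# ---------------------------------------------------------------------------

def test_magic_table_shape():
    assert len(MAGICINTS) == LASTIDX
    assert all(magicints(i) == 0 for i in range(FIRSTIDX))
    assert magicints(FIRSTIDX) == 8
    assert magicints(FIRSTIDX + 3) == 16
    tail = MAGICINTS[FIRSTIDX:]
    assert np.all(np.diff(tail) > 0)
    # the property the codec relies on: a triple at index i fits in i bits
    assert all(int(MAGICINTS[i]) ** 3 <= 2 ** i for i in range(FIRSTIDX, LASTIDX))
    with pytest.raises(XtcRangeError):
        magicints(LASTIDX)


@pytest.mark.parametrize("size,bits", [(1, 1), (8, 4), (2 ** 24, 25)])
def test_sizeofint_examples(size, bits):
    assert sizeofint(size) == bits


def test_sizeofint_is_doubling_loop():
    for size in [1, 2, 3, 7, 255, 1000, 2 ** 20 - 1]:
        b = sizeofint(size)
        assert 2 ** b > size >= 2 ** (b - 1) - (1 if b else 0)
    with pytest.raises(XtcRangeError):
        sizeofint(0)


@pytest.mark.parametrize("sizes,bits", [
    ((8, 8, 8), 10),       # product 512: 8 low bits + sizeofint(2)
    ((2, 2, 2), 4),        # sizeofint(8)
    ((1, 1, 1), sizeofint(1)),
])
def test_sizeofints_examples(sizes, bits):
    assert sizeofints(sizes) == bits


def test_sizeofints_width_of_product_not_product_minus_one():
    # the byte-array algorithm measures the product itself, which for
    # power-of-two products is one bit wider than ceil(log2(product))
    for sizes in [(8, 8, 8), (16, 16, 16), (100, 100, 100), (5, 7, 11)]:
        prod = sizes[0] * sizes[1] * sizes[2]
        assert sizeofints(sizes) == prod.bit_length()
    assert sizeofints((8, 8, 8)) == 10 != (512 - 1).bit_length()


# ---------------------------------------------------------------------------
# mixed-radix coding
# ---------------------------------------------------------------------------

def test_encodeints_known_value():
    # (3,1,2) in radices (4,3,3): combined (3*3+1)*3+2 = 32
    sizes = (4, 3, 3)
    nbits = sizeofints(sizes)
    w = BitWriter()
    encodeints(w, (3, 1, 2), sizes, nbits)
    assert w.bit_length == nbits
    assert decodeints(BitReader(w.getvalue()), sizes, nbits) == (3, 1, 2)


def test_encodeints_zero_is_all_zero_bits():
    sizes = (50, 60, 70)
    nbits = sizeofints(sizes)
    w = BitWriter()
    encodeints(w, (0, 0, 0), sizes, nbits)
    assert w.getvalue() == b"\x00" * len(w.getvalue())


def test_encodeints_out_of_radix_rejected():
    with pytest.raises(XtcRangeError):
        encodeints(BitWriter(), (0, 3, 0), (4, 3, 3), 6)


@settings(derandomize=True, max_examples=150)
@given(st.tuples(*[st.integers(min_value=1, max_value=0xFFFFFF)] * 3),
       st.data())
def test_encodeints_decodeints_inverse(sizes, data):
    values = tuple(data.draw(st.integers(min_value=0, max_value=s - 1))
                   for s in sizes)
    nbits = sizeofints(sizes)
    w = BitWriter()
    encodeints(w, values, sizes, nbits)
    r = BitReader(w.getvalue())
    assert decodeints(r, sizes, nbits) == values
    assert r.bit_position == nbits        # consumes exactly nbits


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def test_quantize_examples():
    assert quantize(np.float32(2.0), 1000) == 2000
    assert quantize(np.float32(-0.0025), 1000) == -3   # half away from zero
    assert quantize(np.float32(0.0025), 1000) == 3


@settings(derandomize=True, max_examples=200)
@given(st.floats(min_value=-1000, max_value=1000, allow_nan=False,
                 width=32),
       st.sampled_from([100.0, 1000.0, 10000.0]))
def test_quantization_bound(x, precision):
    # half a quantum plus the float32 representation error of x*precision
    i = quantize(np.float32(x), precision)
    back = float(dequantize(i, precision))
    bound = 0.5 / precision + abs(float(np.float32(x))) * 2.0 ** -20
    assert abs(back - float(np.float32(x))) <= bound


def test_quantize_overflow_raises():
    with pytest.raises(XtcRangeError):
        quantize(np.float32(3.0e6), 1000)


# ---------------------------------------------------------------------------
# block-level operations
# ---------------------------------------------------------------------------

def test_roundtrip_all_fixtures(codec_fixtures):
    for name, (frame, block) in codec_fixtures.items():
        coords = decompress_coords(block, frame.natoms)
        bound = 0.5 / frame.precision + np.abs(frame.coords).max() * 2.0 ** -20
        err = np.max(np.abs(coords - frame.coords))
        assert err <= bound, name


def test_compress_is_idempotent_on_the_lattice(codec_fixtures):
    """decompress(compress(x)) re-compresses to the identical payload.

    Holds whenever the lattice integers are exactly representable in
    float32 (|i| < 2^24); the wide-axis fixture exceeds that on purpose
    and is excluded, as its dequantized values cannot carry the lattice.
    """
    for name, (frame, block) in codec_fixtures.items():
        if name == "wide_axis":
            continue
        coords = decompress_coords(block, frame.natoms)
        block2 = compress_coords(coords, frame.precision)
        assert block2.payload == block.payload, name
        assert block2.minint == block.minint, name
        assert block2.smallidx0 == block.smallidx0, name


def test_water_fixture_contains_runs(codec_fixtures):
    frame, block = codec_fixtures["water_small"]
    scan = scan_groups(block, frame.natoms)
    assert np.any(scan.atom_count > 1)      # run-length path exercised


def test_sparse_atoms_give_single_atom_groups():
    # atoms kept further apart than the largest small radix on every axis:
    # no run can ever start, every group is one absolutely-coded atom
    n = 60
    step = 9_000_000  # lattice units at precision 10 -> 900000 nm apart
    coords = np.zeros((n, 3), dtype=np.float64)
    for i in range(n):
        coords[i, i % 3] = ((i // 3) % 2) * step / 10.0 + i * 17.0
        coords[i, (i + 1) % 3] = (i % 7) * step / 10.0
    block = compress_coords(coords, 10.0)
    scan = scan_groups(block, n)
    assert len(scan) == n
    assert np.all(scan.atom_count == 1)


def test_wide_axis_path_roundtrip(codec_fixtures):
    frame, block = codec_fixtures["wide_axis"]
    assert max(block.sizeint) > 0xFFFFFF    # per-axis wide coding in use
    coords = decompress_coords(block, frame.natoms)
    bound = 0.5 / frame.precision + np.abs(frame.coords).max() * 2.0 ** -20
    assert np.max(np.abs(coords - frame.coords)) <= bound


def test_scan_tiling_is_contiguous_and_conserving(codec_fixtures):
    for name, (frame, block) in codec_fixtures.items():
        scan = scan_groups(block, frame.natoms)
        assert int(scan.atom_count.sum()) == frame.natoms, name
        assert np.all(scan.start_bit[1:] == scan.end_bit[:-1]), name
        assert scan.start_bit[0] == 0, name
        assert scan.final_bit == scan.end_bit[-1], name


def test_scan_performs_zero_integer_decodes(codec_fixtures):
    frame, block = codec_fixtures["water_medium"]
    counters.reset()
    scan_groups(block, frame.natoms)
    assert counters.decodeints_calls == 0
    assert counters.decompress_calls == 0


def test_decode_wrong_natoms_is_corruption(codec_fixtures):
    frame, block = codec_fixtures["water_small"]
    with pytest.raises(XtcCorruptionError):
        decompress_coords(block, frame.natoms - 10)


def test_truncated_payload_is_corruption(codec_fixtures):
    from dataclasses import replace
    frame, block = codec_fixtures["walk"]
    cut = block.nbytes // 3
    bad = replace(block, nbytes=cut, payload=block.payload[:cut])
    with pytest.raises(XtcCorruptionError):
        decompress_coords(bad, frame.natoms)
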