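"""MSB-first bit-level reading and writing over in-memory byte buffers.

The xtc coordinate codec packs integers most-significant-bit first into a
byte stream.  ``BitWriter`` reproduces the canonical GROMACS packing
exactly, including the convention that a trailing partial byte is
materialised with its bits left-aligned and zero padding on the right.

``BitReader`` offers two read paths with identical observable behaviour:

* a *buffered* fast path that refills a wide (up to 64-bit) accumulator
  from several bytes at a time, so most reads are a shift and a mask;
* a *naive* byte-at-a-time path transcribed from the classic decoder,
  kept as the in-package oracle for the fast path.

Equivalence of the two paths at every cursor state is a tested property,
not an assumption; callers may rely on either.
"""

from __future__ import annotations

from .errors import BitstreamUnderrun, XtcRangeError

_MASK32 = 0xFFFFFFFF


class BitWriter:
    """Append-only MSB-first bit packer."""

    __slots__ = ("_buf", "_lastbits", "_lastbyte")

    def __init__(self) -> None:
        self._buf = bytearray()
        self._lastbits = 0   # bits pending in _lastbyte, 0..7
        self._lastbyte = 0   # 32-bit rolling accumulator, as in the C codec

    def write_bits(self, value: int, nbits: int) -> None:
        """Append the ``nbits`` most-significant-first bits of ``value``.

        ``nbits`` may be 0 (no-op, used by the mixed-radix encoder when a
        value happens to fill whole bytes).
        """
        if not 0 <= nbits <= 32:
            raise XtcRangeError(f"nbits must be in 0..32, got {nbits}")
        if value < 0 or (nbits < 32 and value >> nbits):
            raise XtcRangeError(f"value {value} does not fit in {nbits} bits")
        buf = self._buf
        lastbits = self._lastbits
        lastbyte = self._lastbyte
        while nbits >= 8:
            lastbyte = ((lastbyte << 8) | ((value >> (nbits - 8)) & 0xFF)) & _MASK32
            buf.append((lastbyte >> lastbits) & 0xFF)
            nbits -= 8
        if nbits > 0:
            lastbyte = ((lastbyte << nbits) | (value & ((1 << nbits) - 1))) & _MASK32
            lastbits += nbits
            if lastbits >= 8:
                lastbits -= 8
                buf.append((lastbyte >> lastbits) & 0xFF)
        self._lastbits = lastbits
        self._lastbyte = lastbyte

    @property
    def bit_length(self) -> int:
        return len(self._buf) * 8 + self._lastbits

    @property
    def nbytes(self) -> int:
        """Byte count of :meth:`getvalue` (partial trailing byte included)."""
        return len(self._buf) + (1 if self._lastbits else 0)

    def getvalue(self) -> bytes:
        out = bytes(self._buf)
        if self._lastbits:
            out += bytes(((self._lastbyte << (8 - self._lastbits)) & 0xFF,))
        return out


class BitCursor:
    """Read-only view of a reader's position (byte offset + bit offset)."""

    __slots__ = ("byte_offset", "bit_offset")

    def __init__(self, byte_offset: int, bit_offset: int):
        self.byte_offset = byte_offset
        self.bit_offset = bit_offset

    @property
    def bit_position(self) -> int:
        return 8 * self.byte_offset + self.bit_offset

    def __repr__(self) -> str:  # pragma: no cover
        return f"BitCursor(byte={self.byte_offset}, bit={self.bit_offset})"


class BitReader:
    """MSB-first bit reader over a bytes-like buffer.

    Parameters
    ----------
    data:
        The byte buffer.  Reads never mutate it.
    buffered:
        If True (default) use the wide-word accumulator fast path; if
        False use the byte-at-a-time naive path.  Both paths return
        bit-identical values and positions.
    """

    __slots__ = ("_data", "_nbits", "_buffered",
                 "_pos", "_acc", "_nacc",
                 "_cnt", "_lastbits", "_lastbyte")

    def __init__(self, data, *, buffered: bool = True) -> None:
        self._data = bytes(data)
        self._nbits = 8 * len(self._data)
        self._buffered = buffered
        # fast-path state
        self._pos = 0       # next byte to load
        self._acc = 0       # accumulator, top bits are next to read
        self._nacc = 0      # valid bits in accumulator
        # naive-path state (transcription of the classic decoder)
        self._cnt = 0
        self._lastbits = 0
        self._lastbyte = 0

    # -- position ---------------------------------------------------------

    @property
    def bit_position(self) -> int:
        if self._buffered:
            return self._pos * 8 - self._nacc
        return self._cnt * 8 - self._lastbits

    @property
    def bits_remaining(self) -> int:
        return self._nbits - self.bit_position

    @property
    def cursor(self) -> BitCursor:
        p = self.bit_position
        return BitCursor(p // 8, p % 8)

    # -- reading ----------------------------------------------------------

    def read_bits(self, nbits: int) -> int:
        if not 0 <= nbits <= 32:
            raise XtcRangeError(f"nbits must be in 0..32, got {nbits}")
        if nbits > self.bits_remaining:
            raise BitstreamUnderrun(
                f"requested {nbits} bits, only {self.bits_remaining} remain")
        if nbits == 0:
            return 0
        if self._buffered:
            return self._read_fast(nbits)
        return self._read_naive(nbits)

    def _read_fast(self, nbits: int) -> int:
        acc, nacc, pos, data = self._acc, self._nacc, self._pos, self._data
        n = len(data)
        while nacc < nbits:
            # wide refill: take four bytes at once when we can
            if nacc <= 32 and n - pos >= 4:
                acc = (acc << 32) | int.from_bytes(data[pos:pos + 4], "big")
                pos += 4
                nacc += 32
            else:
                acc = (acc << 8) | data[pos]
                pos += 1
                nacc += 8
        nacc -= nbits
        value = (acc >> nacc) & ((1 << nbits) - 1)
        acc &= (1 << nacc) - 1
        self._acc, self._nacc, self._pos = acc, nacc, pos
        return value

    def _read_naive(self, nbits: int) -> int:
        # byte-at-a-time transcription with the 32-bit rolling accumulator
        data = self._data
        cnt, lastbits, lastbyte = self._cnt, self._lastbits, self._lastbyte
        mask = (1 << nbits) - 1
        num = 0
        while nbits >= 8:
            lastbyte = ((lastbyte << 8) | data[cnt]) & _MASK32
            cnt += 1
            num |= ((lastbyte >> lastbits) & 0xFF) << (nbits - 8)
            nbits -= 8
        if nbits > 0:
            if lastbits < nbits:
                lastbits += 8
                lastbyte = ((lastbyte << 8) | data[cnt]) & _MASK32
                cnt += 1
            lastbits -= nbits
            num |= (lastbyte >> lastbits) & ((1 << nbits) - 1)
        num &= mask
        self._cnt, self._lastbits, self._lastbyte = cnt, lastbits, lastbyte
        return num

    # -- skipping ---------------------------------------------------------

    def skip_bits(self, nbits: int) -> None:
        """Advance exactly ``nbits``; subsequent reads equal read-and-discard."""
        if nbits < 0:
            raise XtcRangeError("cannot skip a negative number of bits")
        if nbits > self.bits_remaining:
            raise BitstreamUnderrun(
                f"requested skip of {nbits} bits, only {self.bits_remaining} remain")
        self._seek_bit(self.bit_position + nbits)

    def _seek_bit(self, bitpos: int) -> None:
        data = self._data
        if self._buffered:
            byte, rem = divmod(bitpos, 8)
            if rem == 0:
                self._pos, self._acc, self._nacc = byte, 0, 0
            else:
                self._pos = byte + 1
                self._nacc = 8 - rem
                self._acc = data[byte] & ((1 << self._nacc) - 1)
        else:
            byte, rem = divmod(bitpos, 8)
            if rem == 0:
                self._cnt, self._lastbits, self._lastbyte = byte, 0, 0
            else:
                self._cnt = byte + 1
                self._lastbits = 8 - rem
                self._lastbyte = data[byte]
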