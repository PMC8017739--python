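"""Random access over multi-frame xtc files.

Index construction is a single skip-walk over the file -- headers and
declared payload lengths only, zero decompression -- and the resulting
:class:`FrameIndex` supports binary-search time lookup for trajectories
with monotonically increasing frame times (the format's usual case, and
the precondition of the search algorithm: non-monotonic files fail
loudly rather than degrade).

The optional sidecar persistence is a plain tab-separated text file; it
is an addition of this package, always regenerable from the xtc alone.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import (IndexCorruptionError, MonotonicityError, PastEndError,
                     XtcFormatError, XtcTruncationError)
from .xdrio import Frame, read_frame, skip_frame

_SIDECAR_HEADER = "# frame\tbyte_offset\ttime\tstep\tnatoms"


@dataclass(frozen=True)
class IndexEntry:
    frame: int
    byte_offset: int
    time: float
    step: int
    natoms: int


@dataclass
class FrameIndex:
    """Per-frame byte offsets, times and steps of one trajectory."""

    byte_offsets: np.ndarray   # int64
    times: np.ndarray          # float32 (wire-exact)
    steps: np.ndarray          # int64
    natoms: int
    truncated: bool = False    # a trailing partial frame was dropped

    def __len__(self) -> int:
        return len(self.byte_offsets)

    @property
    def n_frames(self) -> int:
        return len(self.byte_offsets)

    @property
    def monotonic(self) -> bool:
        return bool(np.all(np.diff(self.times) >= 0)) if len(self) > 1 else True

    @property
    def entries(self):
        return [IndexEntry(i, int(o), float(t), int(s), self.natoms)
                for i, (o, t, s) in enumerate(
                    zip(self.byte_offsets, self.times, self.steps))]

    # -- sidecar persistence (plain text) ------------------------------

    def save(self, path) -> None:
        lines = [_SIDECAR_HEADER]
        for e in self.entries:
            # repr of the float64 value round-trips the float32 time exactly
            lines.append(f"{e.frame}\t{e.byte_offset}\t{float(np.float32(e.time))!r}"
                         f"\t{e.step}\t{e.natoms}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "FrameIndex":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("#"):
            raise XtcFormatError(f"not a frame-index sidecar: {path}")
        rows = [ln.split("\t") for ln in lines[1:] if ln.strip()]
        if not rows:
            raise XtcFormatError(f"empty frame-index sidecar: {path}")
        offsets = np.array([int(r[1]) for r in rows], dtype=np.int64)
        times = np.array([np.float32(r[2]) for r in rows], dtype=np.float32)
        steps = np.array([int(r[3]) for r in rows], dtype=np.int64)
        natoms = int(rows[0][4])
        return cls(offsets, times, steps, natoms)


@contextmanager
def _as_stream(source):
    if hasattr(source, "read"):
        yield source
    else:
        with open(source, "rb") as fh:
            yield fh


def build_index(source) -> FrameIndex:
    """One skip-walk pass over the file; no coordinate decompression.

    A truncated trailing frame is dropped and flagged.  Mid-file
    corruption raises :class:`IndexCorruptionError` carrying the last
    good offset and the partial index (salvage contract).
    """
    offsets, times, steps = [], [], []
    natoms = None
    with _as_stream(source) as fh:
        fh.seek(0)
        truncated = False
        while True:
            offset = fh.tell()
            try:
                header = skip_frame(fh)
            except XtcTruncationError:
                truncated = True
                break
            except XtcFormatError as exc:
                partial = _make_index(offsets, times, steps, natoms, False)
                raise IndexCorruptionError(
                    f"corrupt frame at offset {offset}: {exc}",
                    last_good_offset=offset, partial_index=partial) from exc
            if header is None:
                break
            if natoms is None:
                natoms = header.natoms
            elif header.natoms != natoms:
                partial = _make_index(offsets, times, steps, natoms, False)
                raise IndexCorruptionError(
                    f"non-uniform atom count {header.natoms} != {natoms} "
                    f"at offset {offset}",
                    last_good_offset=offset, partial_index=partial)
            offsets.append(offset)
            times.append(header.time)
            steps.append(header.step)
    return _make_index(offsets, times, steps, natoms, truncated)


def _make_index(offsets, times, steps, natoms, truncated) -> FrameIndex:
    return FrameIndex(
        byte_offsets=np.array(offsets, dtype=np.int64),
        times=np.array(times, dtype=np.float32),
        steps=np.array(steps, dtype=np.int64),
        natoms=natoms if natoms is not None else 0,
        truncated=truncated)


def seek_time(source, t) -> int:
    """Smallest frame number whose time is >= ``t``.

    ``source`` may be a :class:`FrameIndex` (binary search) or a path /
    stream (skip-scan).  Comparison uses exact float32 ordering.  Raises
    :class:`PastEndError` when ``t`` lies beyond the last frame and
    :class:`MonotonicityError` when the times are not non-decreasing.
    """
    t32 = np.float32(t)
    if isinstance(source, FrameIndex):
        if not source.monotonic:
            raise MonotonicityError("frame times are not monotonically increasing")
        k = int(np.searchsorted(source.times, t32, side="left"))
        if k >= len(source):
            raise PastEndError(f"time {t} lies beyond the last frame")
        return k
    with _as_stream(source) as fh:
        fh.seek(0)
        prev = None
        k = 0
        while True:
            header = skip_frame(fh)
            if header is None:
                raise PastEndError(f"time {t} lies beyond the last frame")
            time32 = np.float32(header.time)
            if prev is not None and time32 < prev:
                raise MonotonicityError(
                    f"frame {k} time {header.time} < previous {float(prev)}")
            if time32 >= t32:
                return k
            prev = time32
            k += 1


def read_frames_strided(source, start: int, stop: int | None,
                        stride: int = 1) -> list[Frame]:
    """Frames ``[start, stop)`` with ``stride``; skipped frames never decode.

    A ``start`` past EOF yields an empty list.  ``stop=None`` reads to
    the end of the file.
    """
    if start < 0:
        raise ValueError("start must be >= 0")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames: list[Frame] = []
    with _as_stream(source) as fh:
        fh.seek(0)
        k = 0
        while stop is None or k < stop:
            if k >= start and (k - start) % stride == 0 and (stop is None or k < stop):
                frame = read_frame(fh)
                if frame is None:
                    break
                frames.append(frame)
            else:
                header = skip_frame(fh)
                if header is None:
                    break
            k += 1
    return frames
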