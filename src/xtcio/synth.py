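"""Deterministic synthetic trajectories exercising every codec path.

Real MD data is unnecessary for correctness testing: what matters is
which branches of the codec a frame drives.  Three models cover them:

``water_like``
    Atom triplets (~0.1 nm internal spacing, roughly a water geometry)
    on a jittered lattice.  Intra-molecule differences are small, so the
    run-length path and the pair-swap heuristic fire constantly.
``random_walk``
    Atoms spread through the box taking small steps between frames.
    Consecutive atoms are far apart, so absolute coding dominates.  With
    a huge ``box_edge`` the per-axis wide coding path (coordinate range
    above 2^24 lattice units) is reached as well.
``adversarial_mix``
    Alternating tight clusters and wide scatters, forcing the
    small-difference radix to oscillate up and down within a frame.

Generation is a pure function of :class:`SyntheticSpec`; the RNG is
numpy's PCG64 so identical specs give byte-identical files on every
platform.  Frame times are ``frame * dt`` (monotonic by construction)
and steps ``frame * 1000``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import XtcRangeError
from .xdrio import Frame, write_frame

MODELS = ("water_like", "random_walk", "adversarial_mix")


@dataclass(frozen=True)
class SyntheticSpec:
    natoms: int
    nframes: int = 10
    box_edge: float | None = None   # nm; None derives ~100 atoms/nm^3
    precision: float = 1000.0
    model: str = "water_like"
    seed: int = 0
    dt: float = 10.0                # ps between frames

    def __post_init__(self):
        if self.natoms < 1:
            raise XtcRangeError("natoms must be >= 1")
        if self.nframes < 1:
            raise XtcRangeError("nframes must be >= 1")
        if self.dt <= 0:
            raise XtcRangeError("dt must be > 0 (times must increase)")
        if self.model not in MODELS:
            raise XtcRangeError(f"model must be one of {MODELS}")

    @property
    def edge(self) -> float:
        if self.box_edge is not None:
            return float(self.box_edge)
        # liquid-water-like number density, ~100 atoms per nm^3
        return max(2.0, (self.natoms / 100.0) ** (1.0 / 3.0))


def _water_like_frame(spec: SyntheticSpec, rng) -> np.ndarray:
    nmol = spec.natoms // 3
    natoms = nmol * 3
    edge = spec.edge
    side = int(np.ceil(nmol ** (1.0 / 3.0)))
    spacing = edge / max(side, 1)
    idx = np.arange(side ** 3)[:nmol]
    grid = np.stack([idx // (side * side), (idx // side) % side, idx % side], axis=1)
    centers = (grid + 0.5) * spacing
    centers += rng.uniform(-0.15, 0.15, size=centers.shape) * spacing
    # two bonded partners at ~0.1 nm, like water O-H vectors
    d1 = np.array([0.1, 0.0, 0.0]) + rng.uniform(-0.01, 0.01, size=(nmol, 3))
    d2 = np.array([-0.033, 0.094, 0.0]) + rng.uniform(-0.01, 0.01, size=(nmol, 3))
    coords = np.empty((natoms, 3))
    coords[0::3] = centers
    coords[1::3] = centers + d1
    coords[2::3] = centers + d2
    return coords


def _random_walk_state(spec: SyntheticSpec, rng) -> np.ndarray:
    return rng.uniform(0.0, spec.edge, size=(spec.natoms, 3))


def _random_walk_step(coords, spec: SyntheticSpec, rng) -> np.ndarray:
    step = rng.normal(0.0, 0.02, size=coords.shape)
    return np.clip(coords + step, 0.0, spec.edge)


def _adversarial_frame(spec: SyntheticSpec, rng) -> np.ndarray:
    """Tight 24-atom clusters alternating with widely scattered atoms."""
    coords = np.empty((spec.natoms, 3))
    i = 0
    tight = True
    while i < spec.natoms:
        if tight:
            n = min(24, spec.natoms - i)
            center = rng.uniform(0.2, spec.edge - 0.2, size=3)
            coords[i:i + n] = center + rng.uniform(-0.02, 0.02, size=(n, 3))
        else:
            n = min(8, spec.natoms - i)
            coords[i:i + n] = rng.uniform(0.0, spec.edge, size=(n, 3))
        i += n
        tight = not tight
    return coords


def gen_frames(spec: SyntheticSpec):
    """Yield the frames of a synthetic trajectory (pure function of spec)."""
    natoms = spec.natoms
    if spec.model == "water_like" and natoms % 3 != 0:
        natoms = (natoms // 3) * 3
        if natoms == 0:
            raise XtcRangeError("water_like needs at least 3 atoms")
        warnings.warn(f"water_like natoms rounded down to {natoms} (triplets)",
                      stacklevel=2)
        spec = replace(spec, natoms=natoms)
    rng = np.random.default_rng(np.random.PCG64(spec.seed))
    box = np.diag([spec.edge] * 3).astype(np.float32)
    walker = None
    for f in range(spec.nframes):
        if spec.model == "water_like":
            coords = _water_like_frame(spec, rng)
        elif spec.model == "random_walk":
            walker = _random_walk_state(spec, rng) if walker is None \
                else _random_walk_step(walker, spec, rng)
            coords = walker
        else:
            coords = _adversarial_frame(spec, rng)
        yield Frame.create(coords, step=f * 1000, time=np.float32(f * spec.dt),
                           box=box, precision=spec.precision)


def gen_trajectory(spec: SyntheticSpec, path) -> int:
    """Write the trajectory to ``path``; returns the frame count."""
    n = 0
    with open(path, "wb") as fh:
        for frame in gen_frames(spec):
            write_frame(fh, frame)
            n += 1
    return n


# ---------------------------------------------------------------------------
# frozen micro fixture (uncompressed path, hand-checkable)
# ---------------------------------------------------------------------------

def micro_fixture():
    """A frozen 5-atom frame and its exact 116-byte serialization.

    Layout: 16-byte header + 36-byte box + 4-byte natoms echo + 60 bytes
    of raw float32 coordinates (5 atoms x 3 x 4 bytes).  All values are
    exactly representable in float32, so the frame is a byte-level
    regression anchor.
    """
    coords = np.array([
        [0.5, 0.25, 1.0],
        [1.5, 0.75, 0.125],
        [2.0, 1.0, 0.5],
        [0.0, -0.5, 2.5],
        [1.25, 2.25, 0.0625],
    ], dtype=np.float32)
    frame = Frame.create(coords, step=7, time=1.5,
                         box=np.diag([2.5, 2.5, 2.5]), precision=0.0)
    buf = io.BytesIO()
    write_frame(buf, frame)
    return frame, buf.getvalue()


def parse_spec_config(path) -> SyntheticSpec:
    """Read a ``key = value`` config file into a :class:`SyntheticSpec`."""
    kwargs = {}
    casts = {"natoms": int, "nframes": int, "box_edge": float,
             "precision": float, "model": str, "seed": int, "dt": float}
    for raw in open(path):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise XtcRangeError(f"bad config line: {raw.strip()!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in casts:
            raise XtcRangeError(f"unknown config key: {key}")
        kwargs[key] = casts[key](value)
    if "natoms" not in kwargs:
        raise XtcRangeError("config must set natoms")
    return SyntheticSpec(**kwargs)
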