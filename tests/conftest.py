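import io

import numpy as np
import pytest

from xtcio import SyntheticSpec, gen_trajectory
from xtcio.instrumentation import counters
from xtcio.synth import gen_frames
from xtcio.xdrio import write_frame


@pytest.fixture(autouse=True)
def _reset_counters():
    counters.reset()
    yield


@pytest.fixture(scope="session")
def water_file(tmp_path_factory):
    """50-frame water-like trajectory, 300 atoms (runs + pair swaps)."""
    path = tmp_path_factory.mktemp("data") / "water300.xtc"
    gen_trajectory(SyntheticSpec(natoms=300, nframes=50, model="water_like",
                                 seed=11, dt=2.0), path)
    return path


@pytest.fixture(scope="session")
def medium_water_file(tmp_path_factory):
    """Water-like 8000-atom system, a handful of frames."""
    path = tmp_path_factory.mktemp("data") / "water8000.xtc"
    gen_trajectory(SyntheticSpec(natoms=8001, nframes=3, model="water_like",
                                 seed=7), path)
    return path


def frame_bytes(frame) -> bytes:
    buf = io.BytesIO()
    write_frame(buf, frame)
    return buf.getvalue()


def one_frame(spec: SyntheticSpec):
    return next(iter(gen_frames(spec)))


@pytest.fixture(scope="session")
def codec_fixtures():
    """Representative single frames for every codec branch, with blocks."""
    from xtcio import compress_coords

    specs = {
        "water_small": SyntheticSpec(natoms=300, nframes=1, model="water_like",
                                     seed=3),
        "water_medium": SyntheticSpec(natoms=8001, nframes=1, model="water_like",
                                      seed=4),
        "walk": SyntheticSpec(natoms=2000, nframes=1, model="random_walk",
                              seed=5),
        "adversarial": SyntheticSpec(natoms=1500, nframes=1,
                                     model="adversarial_mix", seed=6),
        "wide_axis": SyntheticSpec(natoms=600, nframes=1, model="random_walk",
                                   seed=8, box_edge=40000.0),
    }
    out = {}
    for name, spec in specs.items():
        frame = one_frame(spec)
        out[name] = (frame, compress_coords(frame.coords, frame.precision))
    return out
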