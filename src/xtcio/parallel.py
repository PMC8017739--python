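"""Block-parallel decompression of a single frame.

The compressed payload of a frame is a chain of run groups whose decode
state (small-difference radix, persisted run length) evolves only through
the control bits.  Each worker therefore walks the *control* bits of the
whole payload -- cheap -- and fully decodes only the run groups assigned
to it, skipping everyone else's payload bits.  Because the plan is a pure
function of the scan and the configuration, and workers write disjoint
atom ranges, the merged output is bit-identical to a sequential decode
for every worker count and every execution order.

Batch sizing: a data block is a maximal prefix of whole run groups
reaching the target atom count, assigned round-robin to workers.  For
small systems the batch size is shrunk adaptively until the measured
workload disbalance D = (W_max - W_min) / W_mean drops below the
configured bound (~20% by default); for large systems a fixed batch size
is used, since granularity has little effect there.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .codec import CoordBlock, ScanResult, inverse_precision, scan_groups
from .errors import XtcCorruptionError, XtcRangeError
from .instrumentation import counters


@dataclass(frozen=True)
class PlanConfig:
    """Tunables of the block planner (atoms unless stated otherwise)."""

    small_system_threshold: int = 10_000
    large_system_threshold: int = 100_000
    max_disbalance: float = 0.20
    fixed_batch_size: int = 1000
    min_blocks_per_worker: int = 8

    def __post_init__(self):
        if not 0 < self.max_disbalance < 1:
            raise XtcRangeError("max_disbalance must be in (0, 1)")
        if self.fixed_batch_size < 1:
            raise XtcRangeError("fixed_batch_size must be >= 1")
        if self.small_system_threshold <= 0 or self.large_system_threshold <= 0:
            raise XtcRangeError("thresholds must be positive")


@dataclass(frozen=True)
class BlockAssignment:
    first_group: int
    last_group: int          # inclusive
    worker: int
    atom_count: int


@dataclass
class BlockPlan:
    """Deterministic partition of run groups into worker-assigned blocks."""

    blocks: list
    n_workers: int
    batch_size: int
    disbalance: float
    target_met: bool = True
    worker_atoms: np.ndarray = field(default=None, repr=False)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def disbalance(plan: BlockPlan) -> float:
    """D = (W_max - W_min) / W_mean over per-worker atom totals."""
    return _disbalance_of(plan.worker_atoms)


def _disbalance_of(worker_atoms: np.ndarray) -> float:
    if len(worker_atoms) <= 1:
        return 0.0
    mean = worker_atoms.mean()
    if mean == 0:
        return 0.0
    return float((worker_atoms.max() - worker_atoms.min()) / mean)


def _tile(atom_count: np.ndarray, natoms: int, n_workers: int, batch_size: int):
    """Greedy tiling into blocks of whole groups reaching >= batch_size."""
    blocks = []
    worker_atoms = np.zeros(n_workers, dtype=np.int64)
    first = 0
    acc = 0
    b = 0
    ngroups = len(atom_count)
    for g in range(ngroups):
        acc += int(atom_count[g])
        if acc >= batch_size or g == ngroups - 1:
            w = b % n_workers
            blocks.append(BlockAssignment(first, g, w, acc))
            worker_atoms[w] += acc
            b += 1
            first = g + 1
            acc = 0
    return blocks, worker_atoms


def plan_blocks(groups, natoms: int, n_workers: int,
                config: PlanConfig | None = None) -> BlockPlan:
    """Partition run groups into worker-assigned data blocks.

    ``groups`` is a :class:`~xtcio.codec.ScanResult` or a sequence of
    run-group records.  The plan depends only on its inputs -- no timing,
    no scheduling -- so identical inputs give identical plans.
    """
    if n_workers < 1:
        raise XtcRangeError("n_workers must be >= 1")
    config = config or PlanConfig()
    if isinstance(groups, ScanResult):
        atom_count = groups.atom_count
    else:
        atom_count = np.array([g.atom_count for g in groups], dtype=np.int64)
    if int(atom_count.sum()) != natoms:
        raise XtcCorruptionError("groups do not tile natoms")

    if natoms >= config.large_system_threshold:
        blocks, wa = _tile(atom_count, natoms, n_workers, config.fixed_batch_size)
        return BlockPlan(blocks, n_workers, config.fixed_batch_size,
                         _disbalance_of(wa), True, wa)

    # adaptive mode; mid-range systems keep a floor on the batch size
    floor = 1 if natoms < config.small_system_threshold \
        else max(1, config.fixed_batch_size // 4)
    batch = max(floor, natoms // (config.min_blocks_per_worker * n_workers))
    best = None
    while True:
        blocks, wa = _tile(atom_count, natoms, n_workers, batch)
        d = _disbalance_of(wa)
        if best is None or d < best[2]:
            best = (blocks, batch, d, wa)
        if d <= config.max_disbalance or batch <= floor:
            break
        batch = max(floor, batch // 2)
    blocks, batch, d, wa = best
    return BlockPlan(blocks, n_workers, batch, d,
                     target_met=d <= config.max_disbalance, worker_atoms=wa)


def _owned_masks(plan: BlockPlan, ngroups: int) -> list:
    masks = [np.zeros(ngroups, dtype=np.uint8) for _ in range(plan.n_workers)]
    for blk in plan.blocks:
        masks[blk.worker][blk.first_group:blk.last_group + 1] = 1
    return masks


def decode_blocks(block: CoordBlock, natoms: int, plan: BlockPlan, *,
                  groups: ScanResult | None = None,
                  executor: str = "serial", order=None) -> np.ndarray:
    """Multi-worker decode; bit-identical to a sequential decompress.

    executor:
        "serial"  -- run workers one after another in ``order`` (default
                     worker 0..n-1; any permutation gives the same output);
        "threads" -- a thread pool (the kernels release the GIL).
    """
    counters.decompress_calls += 1
    if groups is None:
        groups = scan_groups(block, natoms)
    ngroups = len(groups)
    covered = sum(blk.last_group - blk.first_group + 1 for blk in plan.blocks)
    if covered != ngroups or int(groups.atom_count.sum()) != natoms:
        raise XtcCorruptionError("plan does not match this block's group tiling")

    from .codec import _block_geometry, _guarded_payload
    bitsize, bs, sizeint = _block_geometry(block)
    data = _guarded_payload(block)
    out_ints = np.zeros(3 * natoms, dtype=np.int64)
    masks = _owned_masks(plan, ngroups)
    dummy = np.zeros(natoms, dtype=np.int64)

    def run_worker(w: int) -> int:
        scratch = np.zeros(64, dtype=np.int64)
        status, _fb, _ng, ndecoded = _kernels._walk(
            data, natoms, bitsize, bs[0], bs[1], bs[2],
            int(sizeint[1]), int(sizeint[2]),
            block.minint[0], block.minint[1], block.minint[2],
            block.smallidx0, _kernels.MODE_MASKED, masks[w],
            out_ints, dummy, dummy, dummy, dummy, scratch)
        if status != 0:
            raise XtcCorruptionError(f"worker {w} hit corrupt payload ({status})")
        return ndecoded

    decoded_per_worker = [0] * plan.n_workers
    if executor == "threads" and plan.n_workers > 1:
        with ThreadPoolExecutor(max_workers=plan.n_workers) as pool:
            for w, nd in enumerate(pool.map(run_worker, range(plan.n_workers))):
                decoded_per_worker[w] = nd
    else:
        seq = list(order) if order is not None else list(range(plan.n_workers))
        if sorted(seq) != list(range(plan.n_workers)):
            raise XtcRangeError("order must be a permutation of the workers")
        for w in seq:
            decoded_per_worker[w] = run_worker(w)
    if sum(decoded_per_worker) != natoms:
        raise XtcCorruptionError("workers decoded a wrong total atom count")
    plan_counts = np.asarray(plan.worker_atoms)
    if not np.array_equal(np.asarray(decoded_per_worker), plan_counts):
        raise XtcCorruptionError("per-worker decode counts disagree with the plan")
    ints = out_ints.reshape(natoms, 3)
    return ints.astype(np.float32) * inverse_precision(block.precision)
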