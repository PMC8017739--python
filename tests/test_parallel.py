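"""Block planning and order-independent parallel decoding."""

import numpy as np
import pytest

from xtcio.codec import RunGroupRecord, compress_coords, decompress_coords, scan_groups
from xtcio.errors import XtcRangeError
from xtcio.parallel import (BlockPlan, PlanConfig, decode_blocks, disbalance,
                            plan_blocks)
from xtcio.synth import SyntheticSpec, gen_frames


def _groups_of(block, natoms):
    return scan_groups(block, natoms)


def test_disbalance_formula():
    plan = BlockPlan(blocks=[], n_workers=2, batch_size=1, disbalance=0.0,
                     worker_atoms=np.array([2000, 1000]))
    assert disbalance(plan) == pytest.approx(2.0 / 3.0)
    plan.worker_atoms = np.array([500, 500, 500])
    assert disbalance(plan) == 0.0
    plan.worker_atoms = np.array([1234])
    assert disbalance(plan) == 0.0          # single worker


def test_single_worker_owns_everything(codec_fixtures):
    frame, block = codec_fixtures["water_small"]
    groups = _groups_of(block, frame.natoms)
    plan = plan_blocks(groups, frame.natoms, 1)
    assert plan.disbalance == 0.0
    assert all(b.worker == 0 for b in plan.blocks)
    assert sum(b.atom_count for b in plan.blocks) == frame.natoms


def test_plan_requires_positive_workers(codec_fixtures):
    frame, block = codec_fixtures["water_small"]
    groups = _groups_of(block, frame.natoms)
    with pytest.raises(XtcRangeError):
        plan_blocks(groups, frame.natoms, 0)


def test_plan_blocks_tile_groups_in_order(codec_fixtures):
    for name, (frame, block) in codec_fixtures.items():
        groups = _groups_of(block, frame.natoms)
        for nw in (1, 3, 8):
            plan = plan_blocks(groups, frame.natoms, nw)
            # blocks are contiguous, in order, round-robin assigned
            expected_first = 0
            for b, blk in enumerate(plan.blocks):
                assert blk.first_group == expected_first, name
                assert blk.worker == b % nw, name
                expected_first = blk.last_group + 1
            assert expected_first == len(groups), name


def test_adaptive_disbalance_bound_small_system():
    """The planner keeps D <= 20% on a small water-like system, 2-8 workers."""
    spec = SyntheticSpec(natoms=8001, nframes=1, model="water_like", seed=42)
    frame = next(iter(gen_frames(spec)))
    block = compress_coords(frame.coords, frame.precision)
    groups = _groups_of(block, frame.natoms)
    config = PlanConfig()
    for nw in (2, 3, 4, 8):
        plan = plan_blocks(groups, frame.natoms, nw, config)
        assert plan.target_met
        assert plan.disbalance <= config.max_disbalance


def test_exact_divisibility_gives_zero_disbalance():
    # synthetic single-atom groups: natoms divisible by workers * batch
    natoms = 4 * 4 * 100
    groups = [RunGroupRecord(i, 1, 20, i + 1) for i in range(natoms)]
    plan = plan_blocks(groups, natoms, 4,
                       PlanConfig(min_blocks_per_worker=4))
    assert plan.disbalance == 0.0


def test_plan_is_deterministic(codec_fixtures):
    frame, block = codec_fixtures["adversarial"]
    groups = _groups_of(block, frame.natoms)
    a = plan_blocks(groups, frame.natoms, 5)
    b = plan_blocks(groups, frame.natoms, 5)
    assert a.blocks == b.blocks
    assert a.batch_size == b.batch_size
    assert a.disbalance == b.disbalance


def test_infeasible_bound_reported_not_silently_exceeded():
    # two giant groups cannot be balanced over 4 workers
    groups = [RunGroupRecord(0, 500, 20, 1), RunGroupRecord(1, 500, 20, 2)]
    plan = plan_blocks(groups, 1000, 4, PlanConfig())
    assert not plan.target_met
    assert plan.disbalance > PlanConfig().max_disbalance


@pytest.mark.parametrize("n_workers", [1, 2, 3, 4, 8])
def test_parallel_decode_bit_identical(codec_fixtures, n_workers):
    for name, (frame, block) in codec_fixtures.items():
        sequential = decompress_coords(block, frame.natoms)
        groups = _groups_of(block, frame.natoms)
        plan = plan_blocks(groups, frame.natoms, n_workers)
        merged = decode_blocks(block, frame.natoms, plan, groups=groups)
        assert np.array_equal(merged, sequential), (name, n_workers)


def test_execution_order_independence(codec_fixtures):
    frame, block = codec_fixtures["water_medium"]
    sequential = decompress_coords(block, frame.natoms)
    groups = _groups_of(block, frame.natoms)
    plan = plan_blocks(groups, frame.natoms, 4)
    rng = np.random.default_rng(0)
    orders = [list(range(4)), [3, 2, 1, 0]] + \
        [list(rng.permutation(4)) for _ in range(3)]
    for order in orders:
        merged = decode_blocks(block, frame.natoms, plan, groups=groups,
                               order=order)
        assert np.array_equal(merged, sequential), order


def test_thread_executor_matches_serial(codec_fixtures):
    frame, block = codec_fixtures["water_medium"]
    sequential = decompress_coords(block, frame.natoms)
    groups = _groups_of(block, frame.natoms)
    plan = plan_blocks(groups, frame.natoms, 4)
    merged = decode_blocks(block, frame.natoms, plan, groups=groups,
                           executor="threads")
    assert np.array_equal(merged, sequential)


def test_skip_economy_workers_decode_only_their_atoms(codec_fixtures):
    """Each worker's decode count equals its planned atom total.

    decode_blocks verifies the per-worker instrumented counts against the
    plan and raises on any mismatch, so a successful call is the assertion;
    here we additionally check the plan totals are a partition.
    """
    frame, block = codec_fixtures["water_small"]
    groups = _groups_of(block, frame.natoms)
    for nw in (2, 5):
        plan = plan_blocks(groups, frame.natoms, nw)
        assert int(np.sum(plan.worker_atoms)) == frame.natoms
        decode_blocks(block, frame.natoms, plan, groups=groups)
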