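# Methods

This note documents what `xtcio` computes and why its design choices
were made, at the level a maintainer or a careful user needs.

## Wire format

An xtc file is a sequence of XDR-framed records (big-endian, every
frame a multiple of 4 bytes):

| section      | bytes | contents                                         |
|--------------|-------|--------------------------------------------------|
| header       | 16    | magic = 1995, natoms, step (int32), time (f32)   |
| box          | 36    | 3×3 box vectors, nm, float32                     |
| natoms echo  | 4     | must equal the header natoms                     |
| coordinates  | var.  | natoms ≤ 9: `12·natoms` raw float32; else below  |

Compressed coordinate section: precision (f32), minint[3], maxint[3]
(int32), smallidx (int32), nbytes (int32), payload (nbytes bytes,
zero-padded to 4).  The 116-byte golden serialization of a 5-atom frame
is frozen in the test suite as the byte-level regression anchor, so the
format definition does not depend on any external source.

Constraints inherited from the format: natoms is a signed 32-bit
quantity (practical ceiling ~10⁸ particles); coordinates are float32;
`|x·precision|` must stay below 2³¹−2 ("working range").

## The 3dfcoord codec

Quantization maps nm to lattice integers with round-half-away-from-zero
evaluated in float32 (`x·precision ± 0.5`, then truncate).  Decoding
multiplies by `1/precision` (float32).  The round-trip error bound is
therefore `0.5/precision + 2⁻²⁰·|x|`: half a quantum plus the float32
representation error of the product (2⁻²⁰ is a safe bound for
`≈ 8·2⁻²³·|x|` accumulated over multiply and narrow).  Lattice
re-compression is byte-idempotent whenever the integers stay below
2²⁴, i.e. whenever float32 can carry the lattice exactly.

The payload is a chain of **run groups**:

* one atom coded absolutely: per-axis offsets from `minint` packed as a
  mixed-radix triple in `sizeofints(sizeint)` bits (the byte-array
  width of the *product* of the per-axis ranges — one bit more than
  `ceil(log2 ∏sizes)` when the product is a power of two; the wire
  format is defined by the byte-array algorithm, not the logarithm).
  When any axis range reaches 2²⁴ the triple is instead coded per axis
  in `sizeofint` widths ("wide path", flagged by width 0);
* a 1-bit flag; if set, a 5-bit header `run + is_smaller + 1` where
  `run ≤ 24` is three times the number of difference-coded atoms that
  follow and `is_smaller ∈ {−1,0,+1}` adjusts the small index *after*
  the group.  If the flag is clear, the previous run length persists;
* `run/3` difference triples, each in exactly `smallidx` bits with all
  three radices `magicints[smallidx]`.  The table satisfies
  `magicints[i]³ ≤ 2^i`, which is why the width equals the index.

The encoder's pair-swap ("water") heuristic exchanges an atom with its
successor when all axis differences are below the current small range,
so one partner rides along as a cheap difference; the decoder undoes the
swap at the first triple of a run.  All of this — including the exact
update order of `smallnum`/`smaller` and the run-header persistence —
is pinned by differential tests against `xtcio.reference`, a naive
byte-at-a-time transcription of the canonical codec, rather than restated
as prose: any divergence in coordinates, quantized integers or final
bit-cursor on randomized/adversarial frames is a test failure.
Interoperability is additionally pinned against the compiled C codec
shipped inside mdtraj (read *and* byte-identical re-encode).

Edge behaviour chosen deliberately (and ledger-worthy): the classic C
encoder indexes its range table out of bounds when `smallidx ≥ 65`
(only reachable when the *minimum* inter-atom jump exceeds ~2²⁴ lattice
units).  `xtcio` clamps `smallidx` and the adaptation window to the
table instead; decoders raise a corruption error if a stream walks the
index off the table.  Streams produced under the clamp remain valid
for any conforming decoder.  Difference arithmetic is int64 throughout,
where the C reference could overflow int32 on pathological spreads.

## Bit-level I/O

Bits are packed MSB-first within bytes.  The reader has two paths with
contractually identical observable behaviour: a byte-at-a-time
transcription of the classic decoder (the oracle) and a buffered path
that refills a wide accumulator four bytes at a time so most reads are
one shift and one mask — the "fast bit reading" optimization.  The word
width is an internal choice, not API; equivalence at every cursor state
is a property test.  Reads past the declared `nbytes` but within the
4-byte padding are permitted (the canonical decoder does the same);
reads past the padded buffer raise an underrun error.

## Scanning, planning, parallel decode

Because control bits fully determine payload widths and state, a
scanner can walk a payload reading only `1 + (5)` bits per group and
skipping everything else, producing the run-group tiling
(start/end bit, atom count, small-index state at entry) at a small
fraction of decode cost and with **zero** integer decodes (counted).

A *data block* is a maximal prefix of whole run groups reaching the
target batch size in atoms — a run group is the smallest unit decodable
independently given entry state, so blocks must align to group
boundaries.  Blocks are assigned to workers round-robin by block
ordinal; interleaving rather than contiguous chunking is what keeps
per-worker totals balanced when group sizes drift.  Workload disbalance
is measured as `D = (W_max − W_min)/W_mean` with `W_i` = atoms decoded
by worker *i* (atom count is the hardware-independent proxy for decode
work; the paper-level figure of merit is ~20 % for systems under 10⁴
atoms).

Batch sizing:

* `natoms < 10⁴` (small): start at `natoms/(8·n_workers)` and halve
  until `D ≤ 0.20` or batch = 1.  If group granularity makes the bound
  infeasible the plan reports `target_met=False` — it never silently
  exceeds the bound.
* `natoms ≥ 10⁵` (large): fixed batch of 1000 atoms (granularity has
  little effect at this size).
* in between: adaptive with a floor of 250 atoms.

All thresholds are `PlanConfig` tunables, not truths.

Each worker then walks the control bits of the whole payload from bit
0 ("each worker reads the control bits independently"), skipping the
payload bits of foreign blocks and decoding its own groups into
disjoint rows of a shared integer array.  The plan is a pure function
of (scan, natoms, n_workers, config); workers touch disjoint output;
float conversion happens once, vectorized, after the merge — hence
bit-identity with the sequential decoder for any worker count and any
execution order.  Conformance tests exercise serial execution in random
permutations (correctness provable without real concurrency); a thread
pool is available as the execution vehicle since the kernels release
the GIL.  Each worker's instrumented decode count must equal its
planned atom total ("skip economy"); `decode_blocks` verifies this on
every call.  Group scans are recomputed per read; they are cheap
relative to decode and caching them across repeated reads is left out
deliberately.

## Frame skipping, indexing, time search

`skip_frame` advances using the declared compressed byte count — no
payload is read.  Index construction is one skip-walk; a truncated
trailing frame is dropped and flagged (MD runs are often killed
mid-write, so clean EOF at a frame boundary is normal end-of-trajectory
while EOF inside a frame is an error); mid-file corruption raises an
error carrying the last good offset and the partial index for salvage.
On any error the stream position is restored to the frame start.
Files with non-uniform atom counts across frames are rejected as a
format error.

Time search requires monotonically non-decreasing times (the format's
usual case and the search algorithm's stated scope); non-monotonic
files raise rather than degrade to a linear scan.  Comparisons use
exact float32 ordering with no epsilon — the stored times are
definitive, and callers wanting tolerance can pre-round the query.
Frame numbering is 0-based with half-open `[start, stop)` ranges
everywhere.  The sidecar index file (tab-separated text, one header
line) is this package's addition; it is always regenerable from the
xtc alone.

## Synthetic data

The generator replaces external MD data; it is deterministic (numpy
PCG64, named so byte-identical generation holds across platforms) and
is a pure function of its spec.  Models and what they exercise:

* `water_like` — triplets with ~0.1 nm internal spacing on a jittered
  lattice at ~100 atoms/nm³ (liquid-water-like density): run-length
  coding and the pair-swap heuristic fire constantly, as in real
  solvated systems.
* `random_walk` — uniformly spread atoms with small per-frame steps:
  absolute coding dominates; with a huge box (> ~16 800 nm at
  precision 1000) the per-axis wide path is reached.
* `adversarial_mix` — alternating tight clusters and wide scatters:
  drives the small index up and down within one frame.

Times are `frame·dt` (dt > 0 guarantees monotonicity), steps
`frame·1000`.  Default test sizes (300 / 8·10³ / 1.2·10⁵ atoms, 10–50
frames) mirror the small/medium/large regimes of real systems while
keeping the suite fast; the benchmark fixture uses the full protocol
(1000 frames × 20 passes).  What the models do **not** emulate:
physically meaningful dynamics, realistic box shapes (triclinic boxes
are carried but not generated), velocities/forces (xtc has none), or
inter-frame correlation — so passing tests demonstrate codec and
planner correctness on realistic *bit-stream structure*, not MD
physics.

## Benchmark protocol

`xtc bench` reads N frames per pass (default 1000) for P passes
(default 20) and reports the per-pass read rates, their mean and sample
standard deviation, and the decompression-only rates separately (frame
parsing and I/O excluded), since absolute rates are strongly
hardware-dependent.  A crc32 over the decoded coordinates of the first
pass is reported as a correctness side-channel: it is invariant under
the worker count.  No test asserts rate values.

## Known limitations

* Read parallelism is intra-frame only; no cross-frame pipeline.
* trr/tng/DCD containers, velocities and forces are out of scope.
* Lossy by construction: fidelity is bounded by the stored precision.
* `natoms ≤ 9` frames carry no precision field (stored uncompressed);
  readers report precision 0 for them.
* The approximate GROMACS-style offset bisection without reading
  headers is not implemented; seeking is index- or scan-based.
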