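"""Memory-bounded tune-and-split: z-axis chunking with halo overlap.

Filtering a volume needs two resident copies (input and output), so only
half the device capacity is usable for the input slab: ``K = M / 2`` with
``M`` the capacity in bytes.  When a volume does not fit, it is split along
the z axis into chunks.  Each chunk consists of a *core* slab — the slices
whose filtered values this chunk is responsible for — plus *halo* slices on
interior sides, of thickness ``search_radius + sim_radius``.  The halo is
the minimal overlap for which filtering a chunk reproduces the unsplit
filter on its core exactly: every core voxel's search box and all of its
members' similarity boxes lie inside the read slab.  After filtering, the
gather step drops halos and concatenates cores.

Cores partition ``[0, L3)``; chunks are greedily maximal (largest cores
first, last chunk possibly smaller), which minimises the chunk count N.
A multi-worker run may instead request N rounded up to a multiple of the
worker count so every worker receives equal work.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import BudgetTooSmallError, GatherError, PlanMismatchError
from .nlm_core import NLMParams
from .volumes import Volume, crop_volume

__all__ = ["MemoryBudget", "Chunk", "ChunkPlan", "plan_chunks", "split", "gather"]


@dataclass(frozen=True)
class MemoryBudget:
    """Device-memory stand-in: ``capacity_bytes`` total, half usable for the
    input slab (input and output copies coexist)."""

    capacity_bytes: int
    bytes_per_voxel: int = 4

    def __post_init__(self) -> None:
        if self.capacity_bytes < 1 or self.bytes_per_voxel < 1:
            raise BudgetTooSmallError(
                f"capacity and bytes/voxel must be positive, got "
                f"{self.capacity_bytes}, {self.bytes_per_voxel}"
            )

    @property
    def usable_bytes(self) -> int:
        return self.capacity_bytes // 2


@dataclass(frozen=True)
class Chunk:
    """One z chunk: half-open core ``[core0, core1)`` plus halo extents."""

    core0: int
    core1: int
    halo_lo: int
    halo_hi: int

    @property
    def read0(self) -> int:
        return self.core0 - self.halo_lo

    @property
    def read1(self) -> int:
        return self.core1 + self.halo_hi

    @property
    def read_extent(self) -> int:
        return self.read1 - self.read0


@dataclass(frozen=True)
class ChunkPlan:
    shape: tuple[int, int, int]
    chunks: tuple[Chunk, ...]
    halo_thickness: int
    budget: MemoryBudget | None = None
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if not self._validate:
            return
        L3 = self.shape[2]
        pos = 0
        for k, c in enumerate(self.chunks):
            if c.core0 != pos or c.core1 <= c.core0:
                raise PlanMismatchError(f"chunk {k} cores do not partition [0, {L3})")
            if c.read0 < 0 or c.read1 > L3:
                raise PlanMismatchError(f"chunk {k} read range exceeds [0, {L3})")
            pos = c.core1
        if pos != L3:
            raise PlanMismatchError(f"cores cover [0, {pos}) but L3 = {L3}")

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)

    def to_json(self) -> str:
        return json.dumps(
            {
                "shape": list(self.shape),
                "halo_thickness": self.halo_thickness,
                "n_chunks": self.n_chunks,
                "capacity_bytes": self.budget.capacity_bytes if self.budget else None,
                "chunks": [
                    {
                        "core": [c.core0, c.core1],
                        "halo": [c.halo_lo, c.halo_hi],
                        "read": [c.read0, c.read1],
                    }
                    for c in self.chunks
                ],
            },
            indent=2,
        )


def _max_read_extent(shape: tuple[int, int, int], budget: MemoryBudget) -> int:
    slice_bytes = shape[0] * shape[1] * budget.bytes_per_voxel
    return budget.usable_bytes // slice_bytes


def _greedy_chunks(L3: int, halo: int, max_read: int) -> list[Chunk]:
    chunks: list[Chunk] = []
    pos = 0
    while pos < L3:
        halo_lo = halo if pos > 0 else 0
        if (L3 - pos) + halo_lo <= max_read:
            chunks.append(Chunk(pos, L3, halo_lo, 0))
            break
        core_len = max_read - halo_lo - halo
        if core_len < 1:
            raise BudgetTooSmallError(
                f"budget admits reading only {max_read} slices but an interior "
                f"chunk needs >= {halo_lo + 1 + halo} (1 core slice + halos)"
            )
        chunks.append(Chunk(pos, pos + core_len, halo_lo, halo))
        pos += core_len
    return chunks


def _equal_chunks(L3: int, halo: int, n: int) -> list[Chunk]:
    """Split [0, L3) into n near-equal cores with full interior halos."""
    bounds = np.linspace(0, L3, n + 1).round().astype(int)
    chunks = []
    for k in range(n):
        c0, c1 = int(bounds[k]), int(bounds[k + 1])
        halo_lo = min(halo, c0)
        halo_hi = min(halo, L3 - c1)
        chunks.append(Chunk(c0, c1, halo_lo, halo_hi))
    return chunks


def plan_chunks(
    shape: tuple[int, int, int],
    budget: MemoryBudget | None,
    params: NLMParams,
    n_workers: int | None = None,
) -> ChunkPlan:
    """Size z chunks against the memory budget.

    With no budget (or one that holds the whole dataset twice) the plan is a
    single halo-free chunk.  When ``n_workers > 1`` the chunk count is
    rounded up to a multiple of the worker count so chunks can be dealt
    round-robin with equal loads; cores are then near-equal rather than
    greedy-maximal (both layouts satisfy the same read-extent bound).
    """
    L1, L2, L3 = shape
    if min(shape) < 1:
        raise PlanMismatchError(f"invalid shape {shape}")
    halo = params.pad_margin
    if budget is None:
        chunks = [Chunk(0, L3, 0, 0)]
        max_read = L3
    else:
        max_read = _max_read_extent(shape, budget)
        if max_read < 1:
            raise BudgetTooSmallError(
                f"usable budget {budget.usable_bytes} B cannot hold one "
                f"{L1}x{L2} slice of {budget.bytes_per_voxel} B/voxel"
            )
        chunks = _greedy_chunks(L3, halo, max_read)
    if n_workers is not None and n_workers > 1:
        n = len(chunks)
        target = -(-n // n_workers) * n_workers  # round up to multiple of G
        target = min(target, L3)  # cannot have more chunks than slices
        if target > n:
            candidate = _equal_chunks(L3, halo, target)
            if all(c.read_extent <= max_read for c in candidate):
                chunks = candidate
            # else: equalised chunks would break the budget (tiny max_read);
            # keep the greedy plan — correctness never depends on N % G.
    return ChunkPlan(shape=(L1, L2, L3), chunks=tuple(chunks), halo_thickness=halo, budget=budget)


def split(vol: Volume, plan: ChunkPlan) -> list[Volume]:
    """Cut the volume into the plan's read slabs (core + halos)."""
    if plan.shape != vol.shape:
        raise PlanMismatchError(f"plan built for {plan.shape}, volume is {vol.shape}")
    return [crop_volume(vol, c.read0, c.read1) for c in plan.chunks]


def gather(filtered_chunks: list[Volume], plan: ChunkPlan) -> Volume:
    """Reassemble filtered chunks: drop halo slices, concatenate cores."""
    if len(filtered_chunks) != plan.n_chunks:
        raise GatherError(
            f"expected {plan.n_chunks} filtered chunks, got {len(filtered_chunks)}"
        )
    cores = []
    for k, (chunk, vol) in enumerate(zip(plan.chunks, filtered_chunks)):
        expected = (plan.shape[0], plan.shape[1], chunk.read_extent)
        if vol.shape != expected:
            raise GatherError(f"chunk {k} has shape {vol.shape}, expected {expected}")
        cores.append(vol.data[:, :, chunk.halo_lo : chunk.halo_lo + (chunk.core1 - chunk.core0)])
    out = np.concatenate(cores, axis=2)
    if out.shape != plan.shape:
        raise GatherError(f"gathered shape {out.shape} != plan shape {plan.shape}")
    return Volume(out)
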