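"""Propagation-level analysis: walk counting and subunit signal tracing.

The propagation level *l* of a path is its number of intermediate
neurons, recurrent visits included, so the level-*l* matrix is the
exact integer power  M_l = A^(l+1)  of the adjacency matrix: entry
m(i,j)_l counts every walk of length l+1 from i to j.  High levels
expose strongly recurrent sub-circuits, whose walk counts grow much
faster than those of feed-forward pathways.

Signal tracing starts from a PB subunit: every type with a dendrite
there is seeded, activity propagates one synaptic level at a time
through the connection matrix, and each active type deposits a *hit*
in every subunit its axon innervates.  In ``multiplicity`` mode a
type's deposit is weighted by the number of walks that reach it
(recurrent amplification shows up as large hit counts); in
``reachability`` mode each reached type deposits once per level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectome import ConnectionMatrix
from .space import Network, SubunitSpace, CODE_AXON, CODE_DENDRITE, CODE_MIXED

_INT64_SAFE = 2**62


@dataclass(frozen=True)
class LevelMatrix:
    """Exact walk-count matrix at one propagation level."""

    level: int
    values: np.ndarray  # dtype int64 or object (arbitrary precision)

    def max_entry(self) -> int:
        return int(self.values.max())


def _safe_matmul(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Integer matmul that promotes to Python ints before int64 could
    overflow (walk counts grow geometrically with the level)."""
    if A.dtype == object or B.dtype == object:
        return A @ B
    bound = int(A.max()) * int(B.max()) * A.shape[1]
    if bound >= _INT64_SAFE:
        return A.astype(object) @ B.astype(object)
    return A @ B


def level_matrix(C: ConnectionMatrix, level: int) -> LevelMatrix:
    """M_l = A^(l+1), exact integers; level 0 is the adjacency itself."""
    if level < 0:
        raise ValueError("propagation level must be >= 0")
    M = C.A.astype(np.int64)
    out = M
    for _ in range(level):
        out = _safe_matmul(out, M)
    return LevelMatrix(level, out)


def level_matrices(C: ConnectionMatrix, max_level: int) -> list[LevelMatrix]:
    """M_0 .. M_max_level computed incrementally."""
    if max_level < 0:
        raise ValueError("propagation level must be >= 0")
    M = C.A.astype(np.int64)
    out = [LevelMatrix(0, M)]
    cur = M
    for l in range(1, max_level + 1):
        cur = _safe_matmul(cur, M)
        out.append(LevelMatrix(l, cur))
    return out


def hotspot_stats(block: pd.DataFrame) -> tuple[int, list[tuple[str, str]], dict[int, int]]:
    """Maximum path number of a sub-matrix, the (source, destination)
    pairs attaining it, and the full entry histogram."""
    values = block.to_numpy()
    if values.size == 0:
        return 0, [], {}
    vmax = int(values.max())
    pairs: list[tuple[str, str]] = []
    if vmax > 0:
        rr, cc = np.nonzero(values == vmax)
        pairs = [(str(block.index[r]), str(block.columns[c])) for r, c in zip(rr, cc)]
    flat = [int(v) for v in values.ravel()]
    hist: dict[int, int] = {}
    for v in flat:
        hist[v] = hist.get(v, 0) + 1
    return vmax, pairs, hist


@dataclass
class HitMap:
    """Per-subunit accumulated signal-arrival counts."""

    space: SubunitSpace
    hits: np.ndarray  # int64 or object, length = space.size
    start_subunits: tuple[str, ...]
    levels: int
    mode: str

    def by_label(self) -> dict[str, int]:
        return {l: int(h) for l, h in zip(self.space.labels, self.hits)}

    def block_hits(self, prefix: str) -> np.ndarray:
        return self.hits[self.space.block_indices(prefix)]

    def summary(self) -> pd.DataFrame:
        """Total hits per neuropil block."""
        rows = []
        for b in self.space.blocks:
            sl = self.space.block_slice(b.name)
            rows.append((b.name, int(np.sum(self.hits[sl]))))
        return pd.DataFrame(rows, columns=["block", "hits"]).set_index("block")


def trace_signal(
    net: Network,
    C: ConnectionMatrix,
    start_subunits: str | Sequence[str],
    levels: int = 2,
    mode: str = "multiplicity",
) -> HitMap:
    """Trace a signal injected into PB subunit(s) and count hits.

    Seeds are the connection-matrix types with a dendrite in any start
    subunit.  For ``levels`` rounds, every active type deposits one hit
    (times its walk multiplicity in ``multiplicity`` mode) into each
    subunit it innervates axonally, then activity advances one level
    through the adjacency matrix.  Hits accumulate over all rounds.
    """
    if isinstance(start_subunits, str):
        start_subunits = (start_subunits,)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if mode not in ("multiplicity", "reachability"):
        raise ValueError(f"unknown trace mode {mode!r}")
    start_idx = []
    for label in start_subunits:
        idx = net.space.index_of(label)
        if not label.startswith("PB "):
            raise ValueError(f"signal tracing starts from a PB subunit, got {label!r}")
        start_idx.append(idx)

    vecs = np.stack([net[name].vector for name in C.names])
    axo = ((vecs == CODE_AXON) | (vecs == CODE_MIXED)).astype(np.int64)
    den = (vecs == CODE_DENDRITE) | (vecs == CODE_MIXED)

    activity = den[:, start_idx].any(axis=1).astype(np.int64)
    A = C.A.astype(np.int64)
    hits = np.zeros(net.space.size, dtype=np.int64)
    for _ in range(levels):
        if mode == "reachability":
            activity = (activity > 0).astype(np.int64)
        deposit = axo.T @ activity
        if hits.dtype == object or deposit.dtype == object:
            hits = hits.astype(object) + deposit
        else:
            hits = hits + deposit
        if mode == "multiplicity":
            bound = int(activity.max(initial=0)) * int(A.max()) * A.shape[0]
            if bound >= _INT64_SAFE:
                activity = activity.astype(object)
            activity = A.T @ activity
        else:
            activity = (A.T @ activity > 0).astype(np.int64)
    return HitMap(
        space=net.space,
        hits=hits,
        start_subunits=tuple(start_subunits),
        levels=levels,
        mode=mode,
    )
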