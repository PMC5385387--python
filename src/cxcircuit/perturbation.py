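"""In-silico lesion, rescue, and axon-terminal relocation experiments.

All perturbations rebuild the connection matrix from the modified
network and re-measure the level-3 input–output path statistics, the
quantity in which the atypical EIP8/EIP17 pair dominates: removing the
pair from the observed network collapses the information hotspots,
adding it back to the generated network partially restores them, and
an exhaustive scan of alternative axonal terminal positions shows the
effect is specific to the pair's (atypical) medial PB terminals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectome import build_connection_matrix, input_output_block
from .generators import GeneratorSet
from .propagation import hotspot_stats, level_matrix
from .space import Network, NeuronType
from .synthesis import mirror_partner_map

DEFAULT_LEVEL = 3


@dataclass
class PerturbationResult:
    description: str
    removed: tuple[str, ...]
    added: tuple[str, ...]
    level: int
    max_path_number: int
    argmax_pairs: list[tuple[str, str]]
    histogram: dict[int, int]


def _io_stats(net: Network, level: int, weighted: bool = False):
    C = build_connection_matrix(net, weighted=weighted)
    M = level_matrix(C, level)
    block = input_output_block(C, M.values)
    return hotspot_stats(block)


def lesion(
    net: Network,
    types_to_remove: Iterable[str],
    level: int = DEFAULT_LEVEL,
    weighted: bool = False,
) -> PerturbationResult:
    """Remove neuron types and re-measure the input–output path counts."""
    removed = tuple(types_to_remove)
    lesioned = net.without(removed) if removed else net
    vmax, pairs, hist = _io_stats(lesioned, level, weighted)
    return PerturbationResult(
        description=f"lesion of {removed}" if removed else "no lesion",
        removed=removed,
        added=(),
        level=level,
        max_path_number=vmax,
        argmax_pairs=pairs,
        histogram=hist,
    )


def rescue(
    model_net: Network,
    types_to_add: Sequence[NeuronType],
    level: int = DEFAULT_LEVEL,
    weighted: bool = False,
) -> PerturbationResult:
    """Add (atypical) types to a generated network and re-measure.

    A type whose name already exists in the model network (the
    generator-predicted version of an atypical type) is replaced by
    the supplied one; genuinely new names are appended.
    """
    replacements = {t.name: t for t in types_to_add if t.name in model_net}
    additions = [t for t in types_to_add if t.name not in model_net]
    rescued = model_net.with_replaced(replacements)
    if additions:
        rescued = rescued.with_added(additions)
    vmax, pairs, hist = _io_stats(rescued, level, weighted)
    return PerturbationResult(
        description=f"rescue with {tuple(t.name for t in types_to_add)}",
        removed=(),
        added=tuple(t.name for t in types_to_add),
        level=level,
        max_path_number=vmax,
        argmax_pairs=pairs,
        histogram=hist,
    )


def lesion_scan(
    net: Network,
    gens: GeneratorSet,
    pair_with_mirror: bool = True,
    level: int = DEFAULT_LEVEL,
    include_local: bool = False,
) -> pd.DataFrame:
    """Remove every type (with its contralateral partner) in turn.

    Returns a table indexed by the removed type(s) with the post-lesion
    level-``level`` input–output maximum path number, sorted ascending
    so the most damaging removal comes first.
    """
    partners = mirror_partner_map(net, gens) if pair_with_mirror else {}
    scanned: set[frozenset[str]] = set()
    rows = []
    for t in net.types:
        if not include_local and t.role == "local":
            continue
        group = {t.name}
        if pair_with_mirror:
            partner = partners.get(t.name, t.name)
            if partner in net:
                group.add(partner)
        key = frozenset(group)
        if key in scanned:
            continue
        scanned.add(key)
        result = lesion(net, sorted(group), level=level)
        rows.append(
            {
                "removed": " & ".join(sorted(group)),
                "max_path_number": result.max_path_number,
            }
        )
    frame = pd.DataFrame(rows).set_index("removed")
    return frame.sort_values("max_path_number", kind="stable")


def relocation_scan(
    net: Network,
    gens: GeneratorSet,
    target_type: str = "EIP8",
    mirror_type: str = "EIP17",
    level: int = DEFAULT_LEVEL,
    pb_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Max path number for every placement of the target's PB axons.

    For each ordered PB subunit pair (p, q) the target type's axonal PB
    terminals are rewritten to {p, q} (the diagonal p == q encodes a
    single-terminal configuration), the mirror partner is kept as the
    exact mirror image of the modified target, the connectome is
    rebuilt and the level-``level`` input–output maximum path number is
    recorded.  Rows index p, columns q.
    """
    space = net.space
    if pb_labels is None:
        pb_labels = list(space.block("PB").labels)
    for label in pb_labels:
        if space.index_of(label) not in set(space.block_indices("PB")):
            raise ValueError(f"relocation target {label!r} is not a PB subunit")
    base = net[target_type]
    M = gens.mirror_global()
    pb_slice = space.block_slice("PB")
    out = np.zeros((len(pb_labels), len(pb_labels)), dtype=np.int64)
    for i, p in enumerate(pb_labels):
        for j, q in enumerate(pb_labels):
            vec = base.vector.copy()
            sub = vec[pb_slice]
            sub[sub == 2] = 0
            vec[pb_slice] = sub
            vec[space.index_of(p)] = 2
            vec[space.index_of(q)] = 2
            new_target = base.with_vector(vec, atypical=True)
            new_mirror = net[mirror_type].with_vector(M(vec), atypical=True)
            mutated = net.with_replaced(
                {target_type: new_target, mirror_type: new_mirror}
            )
            vmax, _, _ = _io_stats(mutated, level)
            out[i, j] = vmax
    return pd.DataFrame(out, index=list(pb_labels), columns=list(pb_labels))
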