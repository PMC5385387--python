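"""Subunit index space and innervation-vector data model.

The central complex of *Drosophila* and its associated neuropils are
modelled as a flat, ordered index space of glomerulus-level *subunits*.
Each neuron type is described by an integer code vector over that space:

    0  no innervation
    1  dendritic arbor
    2  axonal arbor
    3  axon/dendrite coexistence

The canonical space has 154 subunits partitioned into neuropil blocks:
PB (16), six FB layers of 8, four EB rings of 16, NO (8), IDFP (10),
CCP (2), CVLP (2) and VMP (4).  Bilateral blocks are ordered
right-lateral to left-lateral (PB = R8..R1, L1..L8); side-paired blocks
(NO, IDFP, CCP, CVLP, VMP) list the left half before the right half so
their mirror operator is a half-swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

CODE_NONE = 0
CODE_DENDRITE = 1
CODE_AXON = 2
CODE_MIXED = 3
VALID_CODES = (0, 1, 2, 3)

#: per-block structural kind -> (translation recipe, mirror recipe)
#: "bilateral": cyclic shift + full reversal (PB, FB layers, EB rings)
#: "paired":    identity translation + half-swap mirror (NO, IDFP, ...)
BLOCK_KINDS = ("bilateral", "paired")


@dataclass(frozen=True)
class Block:
    """One neuropil (or neuropil layer/ring) worth of subunits."""

    name: str
    labels: tuple[str, ...]
    kind: str  # "bilateral" or "paired"
    shift: int  # translation step for the block's T generator (0 = identity)

    def __post_init__(self) -> None:
        if self.kind not in BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.kind == "paired" and len(self.labels) % 2:
            raise ValueError(f"paired block {self.name!r} needs an even size")

    @property
    def size(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SubunitSpace:
    """Ordered, partitioned subunit index space.

    Subunits are addressed externally by label and internally by 0-based
    position in the concatenation of all blocks.
    """

    blocks: tuple[Block, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)
    _offsets: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index: dict[str, int] = {}
        offsets: dict[str, int] = {}
        pos = 0
        for block in self.blocks:
            offsets[block.name] = pos
            for label in block.labels:
                if label in index:
                    raise ValueError(f"duplicate subunit label {label!r}")
                index[label] = pos
                pos += 1
        object.__setattr__(self, "_index", index)
        object.__setattr__(self, "_offsets", offsets)

    @property
    def size(self) -> int:
        return sum(b.size for b in self.blocks)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(l for b in self.blocks for l in b.labels)

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown subunit label {label!r}") from None

    def block(self, name: str) -> Block:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"unknown block {name!r}")

    def block_offset(self, name: str) -> int:
        if name not in self._offsets:
            raise KeyError(f"unknown block {name!r}")
        return self._offsets[name]

    def block_slice(self, name: str) -> slice:
        off = self.block_offset(name)
        return slice(off, off + self.block(name).size)

    def block_indices(self, prefix: str) -> list[int]:
        """Indices of all subunits whose block name equals or starts with
        ``prefix`` (e.g. ``"FB"`` collects all six FB layers)."""
        out: list[int] = []
        for b in self.blocks:
            if b.name == prefix or b.name.startswith(prefix + "."):
                off = self._offsets[b.name]
                out.extend(range(off, off + b.size))
        if not out:
            raise KeyError(f"no block matches {prefix!r}")
        return out


# ---------------------------------------------------------------------------
# space builders


def _bilateral_labels(prefix: str, half: int) -> tuple[str, ...]:
    right = [f"{prefix} R{i}" for i in range(half, 0, -1)]
    left = [f"{prefix} L{i}" for i in range(1, half + 1)]
    return tuple(right + left)


def _paired_labels(prefix: str, half: int) -> tuple[str, ...]:
    return tuple(
        [f"{prefix} L{i}" for i in range(1, half + 1)]
        + [f"{prefix} R{i}" for i in range(1, half + 1)]
    )


IDFP_LABELS = (
    "IDFP HBm-L",
    "IDFP HBl-L",
    "IDFP DSB-L",
    "IDFP VSB-L",
    "IDFP RB-L",
    "IDFP HBm-R",
    "IDFP HBl-R",
    "IDFP DSB-R",
    "IDFP VSB-R",
    "IDFP RB-R",
)

VMP_LABELS = ("VMP d-L", "VMP v-L", "VMP d-R", "VMP v-R")


def build_space(
    pb: int = 16,
    fb_layers: Sequence[str] = ("a", "b", "c", "d", "e", "f"),
    fb_width: int = 8,
    eb_rings: Sequence[str] = ("A", "O", "C", "P"),
    eb_width: int = 16,
    eb_shift: int = 2,
    no: int = 8,
    idfp: int = 10,
    ccp: int = 2,
    cvlp: int = 2,
    vmp: int = 4,
) -> SubunitSpace:
    """Assemble a partitioned subunit space.

    Defaults produce the canonical 154-subunit layout; smaller arguments
    give structurally identical toy spaces for testing and simulation.
    """
    blocks: list[Block] = [Block("PB", _bilateral_labels("PB", pb // 2), "bilateral", 1)]
    for layer in fb_layers:
        blocks.append(
            Block(f"FB.{layer}", _bilateral_labels(f"FB.{layer}", fb_width // 2), "bilateral", 1)
        )
    for ring in eb_rings:
        blocks.append(
            Block(f"EB.{ring}", _bilateral_labels(f"EB.{ring}", eb_width // 2), "bilateral", eb_shift)
        )
    if no:
        blocks.append(Block("NO", _paired_labels("NO", no // 2), "paired", 0))
    if idfp:
        labels = IDFP_LABELS if idfp == 10 else _paired_labels("IDFP", idfp // 2)
        blocks.append(Block("IDFP", labels, "paired", 0))
    if ccp:
        blocks.append(Block("CCP", ("CCP L", "CCP R") if ccp == 2 else _paired_labels("CCP", ccp // 2), "paired", 0))
    if cvlp:
        blocks.append(Block("CVLP", ("CVLP L", "CVLP R") if cvlp == 2 else _paired_labels("CVLP", cvlp // 2), "paired", 0))
    if vmp:
        blocks.append(Block("VMP", VMP_LABELS if vmp == 4 else _paired_labels("VMP", vmp // 2), "paired", 0))
    return SubunitSpace(tuple(blocks))


def build_canonical_space() -> SubunitSpace:
    """The canonical 154-subunit space of the PB-innervating circuit."""
    space = build_space()
    # 154 = 16 + 6*8 + 4*16 + 8 + 10 + 2 + 2 + 4
    assert space.size == 154, "canonical space must have 154 subunits"
    return space


# ---------------------------------------------------------------------------
# innervation vectors


def make_vector(space: SubunitSpace, assignments: Mapping[str, int]) -> np.ndarray:
    """Build an innervation vector from ``{subunit label: code}``.

    Unlisted subunits are 0.  Unknown labels and codes outside {0,1,2,3}
    raise ``KeyError`` / ``ValueError``.
    """
    vec = np.zeros(space.size, dtype=np.int64)
    for label, code in assignments.items():
        if code not in VALID_CODES:
            raise ValueError(f"invalid innervation code {code!r} for {label!r}")
        vec[space.index_of(label)] = code
    return vec


def vector_assignments(space: SubunitSpace, vec: np.ndarray) -> dict[str, int]:
    """Inverse of :func:`make_vector`: nonzero entries as a label map."""
    labels = space.labels
    return {labels[i]: int(vec[i]) for i in np.flatnonzero(vec)}


def axon_subunits(vec: np.ndarray) -> frozenset[int]:
    """Indices innervated axonally (codes 2 and 3)."""
    return frozenset(np.flatnonzero((vec == CODE_AXON) | (vec == CODE_MIXED)).tolist())


def dendrite_subunits(vec: np.ndarray) -> frozenset[int]:
    """Indices innervated dendritically (codes 1 and 3)."""
    return frozenset(np.flatnonzero((vec == CODE_DENDRITE) | (vec == CODE_MIXED)).tolist())


# ---------------------------------------------------------------------------
# neuron types and networks

#: the 13 neuron classes of the PB-innervating circuit
CLASS_NAMES = (
    "PB LN",
    "CIVP",
    "CVP",
    "EIP",
    "PEI",
    "PEN",
    "PFN-FdN2",
    "PFN-FeN3",
    "PFN-FfN4",
    "PFI-IRB",
    "PFI-IHBl",
    "PFI-IHBm",
    "PFI-IL+R-HBm",
)

INPUT_CLASSES = frozenset({"EIP", "CIVP", "CVP"})
LOCAL_CLASSES = frozenset({"PB LN"})


def role_of_class(class_name: str) -> str:
    """Signal-flow role: PB inputs (EIP/CIVP/CVP), PB local (PB LN),
    PB outputs (everything else)."""
    if class_name in INPUT_CLASSES:
        return "input"
    if class_name in LOCAL_CLASSES:
        return "local"
    return "output"


@dataclass(frozen=True)
class NeuronType:
    """One neuron type: a named innervation vector with class metadata."""

    class_name: str
    type_index: int
    vector: np.ndarray
    atypical: bool = False

    def __post_init__(self) -> None:
        if self.type_index < 1:
            raise ValueError("type index must be positive")
        if not np.any(self.vector):
            raise ValueError(f"{self.name}: all-zero innervation vector")
        bad = set(np.unique(self.vector)) - set(VALID_CODES)
        if bad:
            raise ValueError(f"{self.name}: invalid codes {sorted(bad)}")

    @property
    def name(self) -> str:
        return f"{self.class_name}{self.type_index}"

    @property
    def role(self) -> str:
        return role_of_class(self.class_name)

    def with_vector(self, vector: np.ndarray, atypical: bool | None = None) -> "NeuronType":
        return NeuronType(
            self.class_name,
            self.type_index,
            vector,
            self.atypical if atypical is None else atypical,
        )


class Network:
    """An ordered collection of neuron types over one subunit space."""

    def __init__(self, space: SubunitSpace, types: Iterable[NeuronType]):
        self.space = space
        self.types: list[NeuronType] = list(types)
        self._by_name: dict[str, NeuronType] = {}
        for t in self.types:
            if len(t.vector) != space.size:
                raise ValueError(f"{t.name}: vector length {len(t.vector)} != space size {space.size}")
            if t.name in self._by_name:
                raise ValueError(f"duplicate neuron type name {t.name!r}")
            self._by_name[t.name] = t

    def __len__(self) -> int:
        return len(self.types)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> NeuronType:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown neuron type {name!r}") from None

    def names(self) -> list[str]:
        return [t.name for t in self.types]

    def of_class(self, class_name: str) -> list[NeuronType]:
        return [t for t in self.types if t.class_name == class_name]

    def class_names(self) -> list[str]:
        seen: list[str] = []
        for t in self.types:
            if t.class_name not in seen:
                seen.append(t.class_name)
        return seen

    def without(self, names: Iterable[str]) -> "Network":
        drop = set(names)
        missing = drop - set(self._by_name)
        if missing:
            raise KeyError(f"unknown neuron types {sorted(missing)}")
        return Network(self.space, [t for t in self.types if t.name not in drop])

    def with_added(self, new_types: Iterable[NeuronType]) -> "Network":
        return Network(self.space, self.types + list(new_types))

    def with_replaced(self, replacements: Mapping[str, NeuronType]) -> "Network":
        missing = set(replacements) - set(self._by_name)
        if missing:
            raise KeyError(f"unknown neuron types {sorted(missing)}")
        return Network(
            self.space,
            [replacements.get(t.name, t) for t in self.types],
        )

    def vectors(self) -> np.ndarray:
        return np.stack([t.vector for t in self.types])
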