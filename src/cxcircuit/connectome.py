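"""Type-level connection matrix from axon–dendrite co-innervation.

A directed edge i -> j is drawn when some subunit carries an axonal
arbor of type i and a dendritic arbor of type j: arbors sharing a
glomerulus-scale subunit are assumed to form synapses.  PB local
neurons are excluded — they innervate nearly every PB subunit and are
taken to provide global modulation rather than subunit-specific
routing.

Node order is class-sorted: the PB input classes first (CVP, EIP,
CIVP), then the output classes (PEI, PEN, the three PFN classes, the
four PFI classes), types by index within a class.  This is the layout
used by the input–output sub-matrix views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .space import (
    CODE_AXON,
    CODE_DENDRITE,
    CODE_MIXED,
    INPUT_CLASSES,
    LOCAL_CLASSES,
    Network,
)

#: row/column class order of the connection matrix
MATRIX_CLASS_ORDER = (
    "CVP",
    "EIP",
    "CIVP",
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


@dataclass
class ConnectionMatrix:
    """Directed type-level adjacency with input/output bookkeeping."""

    names: list[str]
    classes: list[str]
    A: np.ndarray  # square, non-negative integers
    weighted: bool

    def __post_init__(self) -> None:
        n = len(self.names)
        if self.A.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        self._pos = {name: i for i, name in enumerate(self.names)}

    @property
    def n(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self._pos[name]

    @property
    def input_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.classes) if c in INPUT_CLASSES]

    @property
    def output_indices(self) -> list[int]:
        return [
            i
            for i, c in enumerate(self.classes)
            if c not in INPUT_CLASSES and c not in LOCAL_CLASSES
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.names, columns=self.names)


def build_connection_matrix(
    net: Network, weighted: bool = False, allow_self: bool = False
) -> ConnectionMatrix:
    """Construct the directed connection matrix of a network.

    ``weighted=True`` stores the number of shared subunits per edge,
    otherwise edges are binary.  ``allow_self=True`` keeps diagonal
    entries (only types with axon/dendrite coexistence in a subunit can
    produce them).
    """
    kept = [t for t in net.types if t.class_name not in LOCAL_CLASSES]
    if not kept:
        raise ValueError("network has no non-local neuron types")

    order = {c: k for k, c in enumerate(MATRIX_CLASS_ORDER)}
    kept.sort(
        key=lambda t: (order.get(t.class_name, len(order)), t.class_name, t.type_index)
    )

    vecs = np.stack([t.vector for t in kept])
    axo = ((vecs == CODE_AXON) | (vecs == CODE_MIXED)).astype(np.int64)
    den = ((vecs == CODE_DENDRITE) | (vecs == CODE_MIXED)).astype(np.int64)
    A = axo @ den.T
    if not weighted:
        A = (A > 0).astype(np.int64)
    if not allow_self:
        np.fill_diagonal(A, 0)
    return ConnectionMatrix(
        names=[t.name for t in kept],
        classes=[t.class_name for t in kept],
        A=A,
        weighted=weighted,
    )


def input_output_block(C: ConnectionMatrix, level_matrix: np.ndarray) -> pd.DataFrame:
    """Restrict a (level) matrix to PB-input rows and PB-output columns.

    Rows keep the CVP/EIP/CIVP types, columns the PEI/PEN/PFN/PFI
    types, both in class-sorted order.  This view shows how signals
    entering PB travel to the output neurons.
    """
    if level_matrix.shape != C.A.shape:
        raise ValueError("level matrix shape does not match the connection matrix")
    rows = C.input_indices
    cols = C.output_indices
    return pd.DataFrame(
        level_matrix[np.ix_(rows, cols)],
        index=[C.names[i] for i in rows],
        columns=[C.names[j] for j in cols],
    )
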