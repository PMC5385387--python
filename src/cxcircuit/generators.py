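"""Permutation-matrix generator algebra for topographic circuits.

Five elementary block operators act on per-neuropil sub-vectors:

* translation ``T`` — cyclic shift of the innervated subunits,
* mirror ``M`` — reflection about the midline,
* identity ``I`` — "standing" (no movement between neighbouring types),
* split ``S = I + T`` — duplicates an innervated subunit into the
  adjacent one (row sums 1 or 2, so no longer a permutation),
* backward ``B = T⁻¹`` — undoes a translation, producing standing types.

Block operators combine by direct sum into global generators over the
whole subunit space, and the midline structure of side-paired neuropils
is expressed with a Kronecker product (``M⁽²⁾ ⊗ I⁽ᵏ⁾`` swaps the left
and right halves position-wise).

Innervation codes are categorical, not additive, so generators are
applied with a max-compose rule: output slot *i* receives the maximum
code among the input slots the matrix routes to it (2 + 2 -> 2).  For
permutation matrices this coincides with the ordinary matrix-vector
product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .space import Block, SubunitSpace

TRANSLATION_VARIANTS = ("input", "output", "inter")


def translation(shift: int, dim: int, cyclic: bool = True) -> np.ndarray:
    """T^(shift,dim): shifts every entry up by ``shift`` elements.

    With ``cyclic=True`` (the default and the convention used
    throughout) displaced entries wrap: T^(1,4) maps (0,1,2,3) to
    (1,2,3,0).
    """
    if not 0 < shift < dim:
        raise ValueError(f"translation shift must satisfy 0 < shift < dim, got {shift}, {dim}")
    T = np.zeros((dim, dim), dtype=np.int64)
    for i in range(dim):
        j = i + shift
        if j >= dim:
            if not cyclic:
                continue
            j -= dim
        T[i, j] = 1
    return T


def mirror(dim: int) -> np.ndarray:
    """M^(dim): reverses element order, e.g. (0,1,2,3) -> (3,2,1,0)."""
    if dim < 1:
        raise ValueError("mirror dimension must be >= 1")
    return np.eye(dim, dtype=np.int64)[::-1].copy()


def mirror_interleaved(halves: int, block: int) -> np.ndarray:
    """M^(halves) ⊗ I^(block): swaps the halves position-wise.

    With ``halves=2`` this is the midline mirror for side-paired
    neuropils whose subunits are listed left half then right half
    (IDFP, NO, CCP, CVLP, VMP): it maps HBm-L <-> HBm-R and so on.
    """
    if halves != 2:
        raise ValueError("only the two-sided (halves=2) mirror is defined")
    return np.kron(mirror(2), np.eye(block, dtype=np.int64))


def split(dim: int, shift: int = 1) -> np.ndarray:
    """S = I + T^(shift,dim): applied after T it duplicates the
    innervated subunit into the adjacent one (row sums in {1, 2})."""
    return np.eye(dim, dtype=np.int64) + translation(shift, dim)


def backward(dim: int, shift: int = 1) -> np.ndarray:
    """B = T⁻¹: the inverse (transpose) of the translation generator."""
    return translation(shift, dim).T.copy()


def apply_generator(matrix: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Apply a generator with the categorical max-compose rule.

    ``out[i] = max{ vec[j] : matrix[i, j] > 0 }`` (0 when the row is
    empty).  Equals the matrix-vector product for permutation matrices;
    for the split generator it keeps codes inside the {0,1,2,3}
    alphabet instead of summing them.
    """
    mask = matrix > 0
    contrib = mask * vec[np.newaxis, :]
    return contrib.max(axis=1, initial=0).astype(vec.dtype)


def is_permutation(matrix: np.ndarray) -> bool:
    return bool(
        np.all(matrix.sum(axis=0) == 1)
        and np.all(matrix.sum(axis=1) == 1)
        and np.all((matrix == 0) | (matrix == 1))
    )


def direct_sum(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """⊕: block-diagonal assembly of square matrices."""
    n = sum(m.shape[0] for m in matrices)
    out = np.zeros((n, n), dtype=np.int64)
    pos = 0
    for m in matrices:
        k = m.shape[0]
        out[pos : pos + k, pos : pos + k] = m
        pos += k
    return out


def _block_translation(block: Block) -> np.ndarray:
    if block.shift == 0:
        return np.eye(block.size, dtype=np.int64)
    return translation(block.shift, block.size)


def _block_mirror(block: Block) -> np.ndarray:
    if block.kind == "paired":
        return mirror_interleaved(2, block.size // 2)
    return mirror(block.size)


@dataclass(frozen=True)
class GlobalGenerator:
    """A 154x154 (or toy-sized) operator assembled block-by-block."""

    variant: str
    matrix: np.ndarray

    def __call__(self, vec: np.ndarray) -> np.ndarray:
        return apply_generator(self.matrix, vec)


class GeneratorSet:
    """The four global generators of a subunit space.

    Three translation variants share every block except PB and IDFP:

    * ``output`` — T in PB, FB and EB; identity elsewhere (PB-output
      classes: PEI, PEN, PFN*, PFI*),
    * ``input``  — like output but with a special IDFP permutation for
      the EIP class, which alternates between the DSB and VSB subunits,
    * ``inter``  — like output but with a special PB permutation for
      the PB local-neuron class,

    plus the single global mirror ``M``.  The two special permutations
    are data (they are not derivable from the translation rule) and are
    injected per space; by default they fall back to the identity.
    """

    def __init__(
        self,
        space: SubunitSpace,
        special_blocks: Mapping[tuple[str, str], np.ndarray] | None = None,
    ):
        self.space = space
        self._special = dict(special_blocks or {})
        for (variant, block_name), mat in self._special.items():
            if variant not in TRANSLATION_VARIANTS:
                raise ValueError(f"unknown translation variant {variant!r}")
            size = space.block(block_name).size
            if mat.shape != (size, size):
                raise ValueError(
                    f"special generator for {variant}/{block_name} has shape "
                    f"{mat.shape}, expected {(size, size)}"
                )
        self._cache: dict[str, GlobalGenerator] = {}

    def block_translation(self, block_name: str, variant: str = "output") -> np.ndarray:
        if (variant, block_name) in self._special:
            return self._special[(variant, block_name)]
        return _block_translation(self.space.block(block_name))

    def block_mirror(self, block_name: str) -> np.ndarray:
        return _block_mirror(self.space.block(block_name))

    def translation_global(self, variant: str = "output") -> GlobalGenerator:
        if variant not in TRANSLATION_VARIANTS:
            raise ValueError(
                f"unknown translation variant {variant!r}; expected one of {TRANSLATION_VARIANTS}"
            )
        key = f"T_{variant}"
        if key not in self._cache:
            mats = [self.block_translation(b.name, variant) for b in self.space.blocks]
            self._cache[key] = GlobalGenerator(key, direct_sum(mats))
        return self._cache[key]

    def mirror_global(self) -> GlobalGenerator:
        if "M" not in self._cache:
            mats = [self.block_mirror(b.name) for b in self.space.blocks]
            self._cache["M"] = GlobalGenerator("M", direct_sum(mats))
        return self._cache["M"]

    def backward_global(self, variant: str = "output") -> GlobalGenerator:
        """Bᵍˡᵒᵇᵃˡ = (Tᵍˡᵒᵇᵃˡ)⁻¹ = Tᵀ (all blocks are permutations)."""
        key = f"B_{variant}"
        if key not in self._cache:
            T = self.translation_global(variant).matrix
            self._cache[key] = GlobalGenerator(key, T.T.copy())
        return self._cache[key]


def serialize_triplets(matrix: np.ndarray) -> str:
    """Sparse (row, col, value) text serialization for fixture pinning."""
    lines = ["row\tcol\tvalue"]
    for i, j in zip(*np.nonzero(matrix)):
        lines.append(f"{i}\t{j}\t{int(matrix[i, j])}")
    return "\n".join(lines) + "\n"


def deserialize_triplets(text: str, dim: int) -> np.ndarray:
    out = np.zeros((dim, dim), dtype=np.int64)
    lines = [l for l in text.strip().splitlines() if l.strip()]
    for line in lines[1:]:
        i, j, v = line.split("\t")
        out[int(i), int(j)] = int(v)
    return out


def permutation_from_swaps(dim: int, swaps: Sequence[tuple[int, int]]) -> np.ndarray:
    """Permutation matrix exchanging the given index pairs."""
    perm = list(range(dim))
    for a, b in swaps:
        perm[a], perm[b] = perm[b], perm[a]
    P = np.zeros((dim, dim), dtype=np.int64)
    for i, j in enumerate(perm):
        P[i, j] = 1
    return P
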