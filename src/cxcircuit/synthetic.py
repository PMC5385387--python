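"""Random topographic networks with the structure of the real circuit.

The generator draws random class specifications on a (possibly
reduced) partitioned subunit space, synthesizes their typical orbits
with the same translation/mirror algebra used for the real circuit,
and then perturbs a configurable fraction of types with atypical
overrides (split, standing, or irregular mixed-polarity innervation),
returning the ground-truth atypical set.  This provides download-free
inputs for every analysis stage and a known answer for the
typical/atypical classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .generators import GeneratorSet, apply_generator, split
from .space import (
    CODE_MIXED,
    Network,
    NeuronType,
    SubunitSpace,
    build_space,
)
from .synthesis import (
    AtypicalOverlay,
    ClassSpec,
    apply_atypical_overrides,
    synthesize_network,
)

OVERRIDE_KINDS = ("split", "standing", "irregular")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a random topographic network.

    Defaults give a reduced space (8-subunit PB, two FB layers, one EB
    ring) that keeps the full partitioned/bilateral structure of the
    canonical one while staying small enough for property tests.
    """

    n_classes: int = 6
    orbit_length: int = 4
    atypical_fraction: float = 0.0
    override_kinds: tuple[str, ...] = OVERRIDE_KINDS
    seed: int = 0
    pb: int = 8
    fb_layers: tuple[str, ...] = ("a", "b")
    fb_width: int = 8
    eb_rings: tuple[str, ...] = ("A",)
    eb_width: int = 8
    no: int = 4
    idfp: int = 4
    vmp: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.atypical_fraction <= 1.0:
            raise ValueError("atypical fraction must be in [0, 1]")
        if self.orbit_length > self.pb // 2:
            raise ValueError("orbit length cannot exceed half the PB size")
        bad = set(self.override_kinds) - set(OVERRIDE_KINDS)
        if bad:
            raise ValueError(f"unknown override kinds {sorted(bad)}")

    def build_space(self) -> SubunitSpace:
        return build_space(
            pb=self.pb,
            fb_layers=self.fb_layers,
            fb_width=self.fb_width,
            eb_rings=self.eb_rings,
            eb_width=self.eb_width,
            eb_shift=2 if self.eb_width > 2 else 1,
            no=self.no,
            idfp=self.idfp,
            ccp=2,
            cvlp=2,
            vmp=self.vmp,
        )


def _random_class_spec(
    space: SubunitSpace, rng: np.random.Generator, class_name: str, orbit: int
) -> ClassSpec:
    """A random class: dendrite in PB, axons in 1–2 other blocks (the
    PB-output template), starting on the right side so the orbit stays
    ipsilateral like the real classes."""
    pb_block = space.block("PB")
    half = pb_block.size // 2
    start = int(rng.integers(0, half - orbit + 1)) if half > orbit else 0
    # right side runs from index half-1 (R1) down to 0 (R-lateral)
    pb_idx = space.block_offset("PB") + (half - 1 - start)
    assignments = {space.labels[pb_idx]: 1}
    other = [b for b in space.blocks if b.name != "PB"]
    n_axonal = int(rng.integers(1, 3))
    for b in rng.choice(len(other), size=min(n_axonal, len(other)), replace=False):
        block = other[int(b)]
        # innervate one subunit in the left/low half of the block
        slot = int(rng.integers(0, max(1, block.size // 2)))
        assignments[block.labels[slot]] = 2
    vec = np.zeros(space.size, dtype=np.int64)
    for label, code in assignments.items():
        vec[space.index_of(label)] = code
    return ClassSpec(
        class_name=class_name,
        initials=(vec,),
        orbit_lengths=(orbit,),
        t_variant="output",
    )


def _perturb(
    space: SubunitSpace,
    rng: np.random.Generator,
    net: Network,
    t: NeuronType,
    kinds: tuple[str, ...],
    forbidden: set[bytes],
) -> NeuronType | None:
    """One atypical override of type ``t``; None if no distinct vector
    could be produced."""
    for _ in range(8):
        kind = kinds[int(rng.integers(len(kinds)))]
        vec = t.vector.copy()
        nz = np.flatnonzero(vec)
        if kind == "irregular":
            vec[int(rng.choice(nz))] = CODE_MIXED
        elif kind == "split":
            idx = int(rng.choice(nz))
            for b in space.blocks:
                sl = space.block_slice(b.name)
                if sl.start <= idx < sl.stop:
                    vec[sl] = apply_generator(split(b.size, 1), vec[sl])
                    break
        else:  # standing: copy a block from the preceding type in the class
            siblings = [s for s in net.of_class(t.class_name) if s.type_index == t.type_index - 1]
            if not siblings:
                continue
            prev = siblings[0]
            blocks = [
                b for b in space.blocks
                if np.any(t.vector[space.block_slice(b.name)])
                and b.name != "PB"
            ]
            if not blocks:
                continue
            b = blocks[int(rng.integers(len(blocks)))]
            sl = space.block_slice(b.name)
            vec[sl] = prev.vector[sl]
        if np.any(vec) and vec.tobytes() not in forbidden:
            return t.with_vector(vec, atypical=True)
    return None


def generate_synthetic_network(
    spec: SyntheticSpec,
) -> tuple[Network, Network, set[str]]:
    """Returns (observed-like, model-like, ground-truth atypical names).

    With ``atypical_fraction == 0`` the two networks are identical and
    the truth set is empty.  Overrides are guaranteed to differ from
    every generated vector, so exact-vector classification recovers the
    truth set perfectly.
    """
    rng = np.random.default_rng(spec.seed)
    space = spec.build_space()
    gens = GeneratorSet(space)
    specs = [
        _random_class_spec(space, rng, f"SYN{k + 1}-", spec.orbit_length)
        for k in range(spec.n_classes)
    ]
    model = synthesize_network(space, gens, specs)

    n_override = int(round(spec.atypical_fraction * len(model)))
    truth: set[str] = set()
    replace: dict[str, NeuronType] = {}
    forbidden = {t.vector.tobytes() for t in model.types}
    order = rng.permutation(len(model.types))
    for i in order:
        if len(replace) >= n_override:
            break
        t = model.types[int(i)]
        new = _perturb(space, rng, model, t, spec.override_kinds, forbidden)
        if new is None:
            continue
        forbidden.add(new.vector.tobytes())
        replace[t.name] = new
        truth.add(t.name)
    observed = apply_atypical_overrides(model, AtypicalOverlay(replace=replace))
    return observed, model, truth
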