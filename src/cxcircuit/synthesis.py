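"""Network synthesis: recursive generator application to initial neurons.

A class specification carries one or more initial innervation vectors
and an orbit length per initial.  Generation emits, for every initial
``v``, the translation orbit ``T⁰v, T¹v, …`` and then the mirror image
of each emitted vector, deduplicating identical vectors while
preserving first-seen order.  Type indices follow generation order, so
for a one-initial class with orbit 8 the types 9–16 are the mirror
images of types 1–8 (the PEN layout).

The *model* network is the union of all class orbits.  The *observed*
network is obtained by overlaying atypical types: replacing some
generated types, appending extra ones, and dropping generated types
that were predicted but not observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .generators import GeneratorSet
from .space import Network, NeuronType, SubunitSpace, role_of_class


@dataclass(frozen=True)
class ClassSpec:
    """Recipe for one neuron class.

    ``orbit_lengths[i]`` is the number of translation applications
    (including T⁰) emitted for ``initials[i]``; mirror images of the
    whole emitted sequence follow.
    """

    class_name: str
    initials: tuple[np.ndarray, ...]
    orbit_lengths: tuple[int, ...]
    t_variant: str = "output"

    def __post_init__(self) -> None:
        if len(self.initials) != len(self.orbit_lengths):
            raise ValueError(f"{self.class_name}: one orbit length per initial required")
        if any(n < 1 for n in self.orbit_lengths):
            raise ValueError(f"{self.class_name}: orbit lengths must be >= 1")

    @property
    def role(self) -> str:
        return role_of_class(self.class_name)


def generate_class(space: SubunitSpace, gens: GeneratorSet, spec: ClassSpec) -> list[NeuronType]:
    """Emit the full typical orbit of one class.

    Raises ``ValueError`` if any generated vector is all-zero (a
    generator/space mismatch).
    """
    T = gens.translation_global(spec.t_variant)
    M = gens.mirror_global()
    emitted: list[np.ndarray] = []
    for v, length in zip(spec.initials, spec.orbit_lengths):
        cur = np.asarray(v, dtype=np.int64)
        for _ in range(length):
            emitted.append(cur)
            cur = T(cur)
    emitted.extend(M(v) for v in list(emitted))

    types: list[NeuronType] = []
    seen: set[bytes] = set()
    for vec in emitted:
        if not np.any(vec):
            raise ValueError(f"{spec.class_name}: orbit produced an all-zero vector")
        key = vec.tobytes()
        if key in seen:
            continue
        seen.add(key)
        types.append(NeuronType(spec.class_name, len(types) + 1, vec))
    return types


def synthesize_network(
    space: SubunitSpace, gens: GeneratorSet, specs: Sequence[ClassSpec]
) -> Network:
    """The model network: all class orbits, in spec order."""
    types: list[NeuronType] = []
    for spec in specs:
        types.extend(generate_class(space, gens, spec))
    return Network(space, types)


@dataclass(frozen=True)
class AtypicalOverlay:
    """Difference between the generated (model) and observed networks.

    * ``replace`` — generated types whose observed counterpart has a
      different (atypical) vector, keyed by type name;
    * ``append``  — observed atypical types with no generated
      counterpart;
    * ``unobserved`` — names of generated types that were predicted by
      the generators but never observed (dropped from the observed
      network).  Replaced names are implicitly unobserved and need not
      be listed here.
    """

    replace: Mapping[str, NeuronType] = field(default_factory=dict)
    append: tuple[NeuronType, ...] = ()
    unobserved: tuple[str, ...] = ()

    def atypical_count(self) -> int:
        return len(self.replace) + len(self.append)


def apply_atypical_overrides(model: Network, overlay: AtypicalOverlay) -> Network:
    """Overlay atypical types on a generated network.

    Replacement types are flagged atypical in place; appended types are
    inserted after their class, ordered by type index.  A replacement
    or appended vector identical to an existing generated vector is
    deduplicated with a warning (it would be indistinguishable from a
    typical type).
    """
    import warnings

    existing = {t.vector.tobytes() for t in model.types}
    replace: dict[str, NeuronType] = {}
    for name, new_type in overlay.replace.items():
        if name not in model:
            raise KeyError(f"override targets unknown type {name!r}")
        if new_type.vector.tobytes() in existing:
            warnings.warn(f"override for {name} duplicates a generated vector; dropped")
            continue
        replace[name] = new_type.with_vector(new_type.vector, atypical=True)

    appended: list[NeuronType] = []
    for t in overlay.append:
        if t.vector.tobytes() in existing:
            warnings.warn(f"appended type {t.name} duplicates a generated vector; dropped")
            continue
        appended.append(t.with_vector(t.vector, atypical=True))

    net = model.with_replaced(replace)
    if overlay.unobserved:
        net = net.without(overlay.unobserved)
    if appended:
        by_class: dict[str, list[NeuronType]] = {}
        for t in appended:
            by_class.setdefault(t.class_name, []).append(t)
        ordered: list[NeuronType] = []
        last_class = None
        for t in net.types:
            if last_class is not None and t.class_name != last_class:
                ordered.extend(sorted(by_class.pop(last_class, []), key=lambda x: x.type_index))
            ordered.append(t)
            last_class = t.class_name
        if last_class is not None:
            ordered.extend(sorted(by_class.pop(last_class, []), key=lambda x: x.type_index))
        for leftover in by_class.values():
            ordered.extend(sorted(leftover, key=lambda x: x.type_index))
        net = Network(net.space, ordered)
    return net


def classify_types(observed: Network, model: Network) -> tuple[set[str], set[str]]:
    """Split observed types into typical (vector generated by the
    model) and atypical (everything else)."""
    if observed.space is not model.space and observed.space != model.space:
        raise ValueError("networks must share a subunit space")
    generated = {t.vector.tobytes() for t in model.types}
    typical = {t.name for t in observed.types if t.vector.tobytes() in generated}
    atypical = {t.name for t in observed.types} - typical
    return typical, atypical


def mirror_partner_map(net: Network, gens: GeneratorSet) -> dict[str, str]:
    """Map each type to its contralateral (mirror-image) partner.

    A mirror-symmetric type maps to itself.  Types whose mirror image
    is absent from the network are omitted.
    """
    M = gens.mirror_global()
    by_vec = {t.vector.tobytes(): t.name for t in net.types}
    out: dict[str, str] = {}
    for t in net.types:
        partner = by_vec.get(M(t.vector).tobytes())
        if partner is not None:
            out[t.name] = partner
    return out
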