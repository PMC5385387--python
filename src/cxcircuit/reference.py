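"""Reference observed/model networks (synthetic reconstruction).

The published subunit-resolved innervation tables of the PB-innervating
circuit are not redistributable here, so this module ships a *synthetic
reconstruction*: a class-spec fixture built to satisfy every constraint
the study states in its main text — the 13 classes and their
per-neuropil translation/mirror generators, the 17 initial neuron types
(three for PB LN, two each for CVP and EIP, one for each remaining
class), the printed worked examples (the CVP1/CVP2 vectors, the
PEN1→PEN2 translation and PEN10→PEN2 mirroring, the PFN-FfN4
split/standing patterns), the type counts (172 generated, 194 observed,
148 shared typical, 46 atypical, 184 non-local), and the atypical
EIP8/EIP17 pair whose axons innervate the two medial PB subunits
instead of the lateral subunit predicted by the generators.

Where the study's supplementary material is the only source (exact
per-class orbits, the identity of every atypical type, the special
PB LN and EIP-IDFP permutations), the fixture makes one fixed,
documented choice consistent with the printed counts; it is a faithful
structural stand-in, not a transcription.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .generators import GeneratorSet, apply_generator, permutation_from_swaps, split
from .space import Network, NeuronType, SubunitSpace, build_canonical_space, make_vector
from .synthesis import (
    AtypicalOverlay,
    ClassSpec,
    apply_atypical_overrides,
    generate_class,
    synthesize_network,
)

FIXTURE_NAME = "class_specs_synthetic.json"

#: native axonal terminals of the atypical EIP8 type (EIP17 mirrors them)
EIP8_NATIVE_AXONS = ("PB L1", "PB L2")
HOTSPOT_PAIR = ("EIP8", "EIP17")


def load_class_fixture() -> dict:
    text = resources.files("cxcircuit.data").joinpath(FIXTURE_NAME).read_text()
    return json.loads(text)


def reference_generator_set(space: SubunitSpace | None = None) -> GeneratorSet:
    """Generator set with the two special block permutations: the
    EIP class's DSB/VSB alternation in IDFP (input variant) and the
    PB local-neuron permutation (inter variant)."""
    space = space or build_canonical_space()
    fixture = load_class_fixture()
    specials: dict[tuple[str, str], np.ndarray] = {}
    for key, rec in fixture["special_generators"].items():
        variant, block = key.split(":")
        dim = space.block(block).size
        specials[(variant, block)] = permutation_from_swaps(
            dim, [tuple(p) for p in rec["swaps"]]
        )
    return GeneratorSet(space, specials)


def reference_class_specs(space: SubunitSpace | None = None) -> list[ClassSpec]:
    space = space or build_canonical_space()
    fixture = load_class_fixture()
    specs = []
    for cls in fixture["classes"]:
        specs.append(
            ClassSpec(
                class_name=cls["name"],
                initials=tuple(make_vector(space, init) for init in cls["initials"]),
                orbit_lengths=tuple(cls["orbits"]),
                t_variant=cls["t_variant"],
            )
        )
    return specs


def _resolve_recipe(
    space: SubunitSpace,
    gens: GeneratorSet,
    typical: dict[int, NeuronType],
    produced: dict[int, np.ndarray],
    rec: dict,
) -> tuple[int, np.ndarray, bool]:
    """One atypical-override record -> (type index, vector, is_append)."""
    is_append = "new_index" in rec
    index = rec["new_index"] if is_append else rec["index"]
    kind = rec["recipe"]
    blocks = rec.get("blocks") or ([rec["block"]] if "block" in rec else [])

    if kind == "vector":
        vec = make_vector(space, rec["assignments"])
    elif kind == "mirror_of":
        src = rec["source"]
        if src not in produced:
            raise ValueError(f"mirror_of source {src} not yet produced")
        vec = gens.mirror_global()(produced[src])
    elif kind == "standing":
        # the type keeps the previous type's arbors in the given blocks
        # (the backward generator B = T^-1 cancels the translation)
        vec = typical[index].vector.copy()
        prev = typical[index - 1].vector
        for b in blocks:
            sl = space.block_slice(b)
            vec[sl] = prev[sl]
    elif kind in ("split", "split_of"):
        source = rec["source"] if kind == "split_of" else index
        vec = typical[source].vector.copy()
        for b in blocks:
            sl = space.block_slice(b)
            S = split(space.block(b).size, 1)
            vec[sl] = apply_generator(S, vec[sl])
    elif kind == "relocate_axons":
        vec = typical[index].vector.copy()
        for b in blocks:
            sl = space.block_slice(b)
            sub = vec[sl]
            sub[sub == 2] = 0
            vec[sl] = sub
        for label in rec["targets"]:
            vec[space.index_of(label)] = 2
    else:
        raise ValueError(f"unknown atypical recipe {kind!r}")
    produced[index] = vec
    return index, vec, is_append


def reference_overlay(
    space: SubunitSpace, gens: GeneratorSet, specs: list[ClassSpec]
) -> AtypicalOverlay:
    fixture = load_class_fixture()
    spec_by_name = {s.class_name: s for s in specs}
    replace: dict[str, NeuronType] = {}
    append: list[NeuronType] = []
    unobserved: list[str] = []
    for cls in fixture["classes"]:
        name = cls["name"]
        typical = {
            t.type_index: t for t in generate_class(space, gens, spec_by_name[name])
        }
        unobserved.extend(f"{name}{i}" for i in cls.get("unobserved", ()))
        produced: dict[int, np.ndarray] = {}
        for rec in cls.get("atypical", ()):
            index, vec, is_append = _resolve_recipe(space, gens, typical, produced, rec)
            ntype = NeuronType(name, index, vec, atypical=True)
            if is_append:
                append.append(ntype)
            else:
                replace[f"{name}{index}"] = ntype
    return AtypicalOverlay(
        replace=replace, append=tuple(append), unobserved=tuple(unobserved)
    )


def reference_networks() -> tuple[Network, Network]:
    """(observed, model) networks of the reconstruction.

    The model network is synthesized from the 17 initial neuron types
    with the global generators; the observed network overlays the 46
    atypical types and drops the generated-but-unobserved ones.
    """
    space = build_canonical_space()
    gens = reference_generator_set(space)
    specs = reference_class_specs(space)
    model = synthesize_network(space, gens, specs)
    overlay = reference_overlay(space, gens, specs)
    observed = apply_atypical_overrides(model, overlay)
    return observed, model
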