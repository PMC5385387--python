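import numpy as np
import pytest

from cxcircuit import (
    AtypicalOverlay,
    ClassSpec,
    GeneratorSet,
    apply_atypical_overrides,
    build_space,
    classify_types,
    generate_class,
    make_vector,
    mirror_partner_map,
    synthesize_network,
)
from cxcircuit.space import Network, NeuronType


@pytest.fixture(scope="module")
def toy():
    space = build_space(pb=8, fb_layers=("a",), fb_width=4, eb_rings=("A",),
                        eb_width=8, no=4, idfp=4, vmp=4)
    return space, GeneratorSet(space)


def test_pen_class_layout(gens, space, model):
    """One initial, orbit 8: sixteen types, 9-16 mirroring 1-8."""
    pens = model.of_class("PEN")
    assert len(pens) == 16
    M = gens.mirror_global()
    for k in range(1, 9):
        assert np.array_equal(M(model[f"PEN{k}"].vector), model[f"PEN{k + 8}"].vector)


def test_orbit_matches_brute_force_enumeration(toy):
    """Generation equals an independent oracle that builds the orbit
    from explicit matrix powers of the global generators."""
    space, gens = toy
    initial = make_vector(space, {"PB R2": 1, "FB.a L1": 2, "NO L1": 2})
    spec = ClassSpec("SYN-", (initial,), (3,))
    generated = {t.vector.tobytes() for t in generate_class(space, gens, spec)}

    T = gens.translation_global("output").matrix
    M = gens.mirror_global().matrix
    oracle = set()
    for k in range(3):
        v = np.linalg.matrix_power(T, k) @ initial
        oracle.add(v.tobytes())
        oracle.add((M @ v).tobytes())
    assert generated == oracle


def test_mirror_symmetric_initial_deduplicates(toy):
    space, gens = toy
    # symmetric under the global mirror: PB R1+L1, NO both sides
    initial = make_vector(space, {"PB R1": 1, "PB L1": 1, "NO L1": 2, "NO R1": 2})
    types = generate_class(space, gens, ClassSpec("SYN-", (initial,), (1,)))
    assert len(types) == 1  # the mirror image added nothing


def test_zero_initial_rejected(toy):
    space, gens = toy
    zero = np.zeros(space.size, dtype=np.int64)
    with pytest.raises(ValueError):
        generate_class(space, gens, ClassSpec("SYN-", (zero,), (2,)))


def test_generated_networks_are_mirror_closed(model, gens):
    M = gens.mirror_global()
    vectors = {t.vector.tobytes() for t in model.types}
    for t in model.types:
        assert M(t.vector).tobytes() in vectors


def test_isomorphism_invariant_per_block(model, space):
    """Types generated from one class share the per-neuropil multiset
    of innervation codes (same subunit count, same polarity)."""
    for class_name in ("PEN", "PEI", "PFN-FfN4", "PFI-IHBm", "EIP"):
        types = model.of_class(class_name)
        reference_multisets = None
        for t in types:
            multisets = tuple(
                tuple(sorted(t.vector[space.block_slice(b.name)].tolist()))
                for b in space.blocks
            )
            if reference_multisets is None:
                reference_multisets = multisets
            else:
                assert multisets == reference_multisets, f"{t.name} breaks isomorphism"


def test_synthesis_is_deterministic(space, gens):
    from cxcircuit import reference_class_specs

    specs = reference_class_specs(space)
    n1 = synthesize_network(space, gens, specs)
    n2 = synthesize_network(space, gens, specs)
    assert n1.names() == n2.names()
    assert np.array_equal(n1.vectors(), n2.vectors())


def test_classify_model_against_itself(model):
    typical, atypical = classify_types(model, model)
    assert len(typical) == len(model)
    assert not atypical


def test_classify_detects_single_perturbation(toy):
    space, gens = toy
    initial = make_vector(space, {"PB R3": 1, "EB.A L1": 2})
    net = synthesize_network(space, gens, [ClassSpec("SYN-", (initial,), (3,))])
    mutated = net.types[2]
    vec = mutated.vector.copy()
    vec[np.flatnonzero(vec)[0]] = 3  # flip one code slot
    observed = net.with_replaced({mutated.name: mutated.with_vector(vec, atypical=True)})
    typical, atypical = classify_types(observed, net)
    assert atypical == {mutated.name}
    assert len(typical) == len(net) - 1


def test_empty_overlay_is_identity(model):
    out = apply_atypical_overrides(model, AtypicalOverlay())
    assert out.names() == model.names()
    assert np.array_equal(out.vectors(), model.vectors())


def test_duplicate_override_is_dropped_with_warning(model):
    t = model.types[0]
    overlay = AtypicalOverlay(replace={t.name: t.with_vector(t.vector.copy())})
    with pytest.warns(UserWarning):
        out = apply_atypical_overrides(model, overlay)
    assert np.array_equal(out.vectors(), model.vectors())


def test_full_overlay_reproduces_observed(observed, model, space, gens):
    """Overlaying all atypical types (and dropping the unobserved
    predictions) on the generated network gives back the observed one."""
    from cxcircuit.reference import reference_class_specs, reference_overlay

    overlay = reference_overlay(space, gens, reference_class_specs(space))
    assert overlay.atypical_count() == 46
    rebuilt = apply_atypical_overrides(model, overlay)
    assert rebuilt.names() == observed.names()
    assert np.array_equal(rebuilt.vectors(), observed.vectors())


def test_standing_atypical_repeats_previous_type(observed, space):
    """The PFN-FfN4 type 2 neuron innervates the same FB subunit as
    type 1 instead of shifting."""
    sl = space.block_slice("FB.f")
    assert np.array_equal(observed["PFN-FfN42"].vector[sl], observed["PFN-FfN41"].vector[sl])
    assert not np.array_equal(
        observed["PFN-FfN42"].vector[sl], observed["PFN-FfN43"].vector[sl]
    )
    assert observed["PFN-FfN42"].atypical


def test_observed_network_is_mirror_closed(observed, gens):
    partners = mirror_partner_map(observed, gens)
    assert set(partners) == set(observed.names())
    for a, b in partners.items():
        assert partners[b] == a
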