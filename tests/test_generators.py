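import numpy as np
import pytest

from cxcircuit import (
    apply_generator,
    backward,
    make_vector,
    mirror,
    mirror_interleaved,
    split,
    translation,
)
from cxcircuit.generators import (
    deserialize_triplets,
    is_permutation,
    permutation_from_swaps,
    serialize_triplets,
)

RNG = np.random.default_rng(20170410)


# ---------------------------------------------------------------------------
# elementary block operators


def test_translation_worked_example():
    a = np.array([0, 1, 2, 3])
    assert (translation(1, 4) @ a).tolist() == [1, 2, 3, 0]


def test_translation_composition_and_order():
    T2 = translation(2, 16)
    assert np.array_equal(T2 @ T2, translation(4, 16))
    T = translation(1, 8)
    assert np.array_equal(np.linalg.matrix_power(T, 8), np.eye(8, dtype=int))


def test_translation_errors_and_noncyclic():
    with pytest.raises(ValueError):
        translation(4, 4)
    with pytest.raises(ValueError):
        translation(0, 4)
    Tnc = translation(1, 4, cyclic=False)
    assert (Tnc @ np.array([0, 1, 2, 3])).tolist() == [1, 2, 3, 0 * 3]
    assert Tnc.sum() == 3  # displaced entry dropped


def test_mirror_worked_example_and_involution():
    a = np.array([0, 1, 2, 3])
    assert (mirror(4) @ a).tolist() == [3, 2, 1, 0]
    for d in (1, 2, 7, 16):
        assert np.array_equal(mirror(d) @ mirror(d), np.eye(d, dtype=int))


def test_mirror_interleaved_swaps_sides(space):
    M = mirror_interleaved(2, 5)
    idfp = np.arange(10)
    assert (M @ idfp).tolist() == [5, 6, 7, 8, 9, 0, 1, 2, 3, 4]
    # on labels: HBm-L <-> HBm-R etc.
    v = make_vector(space, {"IDFP HBm-L": 1, "IDFP RB-L": 2})
    sub = v[space.block_slice("IDFP")]
    out = M @ sub
    assert out[space.index_of("IDFP HBm-R") - space.block_offset("IDFP")] == 1
    assert out[space.index_of("IDFP RB-R") - space.block_offset("IDFP")] == 2


def test_split_standing_worked_examples():
    """The PFN-FfN4 FB patterns: split after translation duplicates the
    slot, backward after translation stands still."""
    T = translation(1, 8)
    S = split(8, 1)
    B = backward(8, 1)
    type4 = np.array([0, 0, 0, 0, 0, 2, 0, 0])
    type5 = apply_generator(S, apply_generator(T, type4))
    assert type5.tolist() == [0, 0, 0, 2, 2, 0, 0, 0]
    type1 = np.array([0, 0, 0, 0, 0, 0, 2, 0])
    standing = apply_generator(B, apply_generator(T, type1))
    assert standing.tolist() == type1.tolist()


def test_backward_inverts_translation():
    for dim, shift in ((8, 1), (16, 2)):
        T = translation(shift, dim)
        B = backward(dim, shift)
        assert np.array_equal(B @ T, np.eye(dim, dtype=int))
        for _ in range(5):
            v = RNG.integers(0, 4, size=dim)
            assert np.array_equal(apply_generator(B, apply_generator(T, v)), v)


def test_split_row_sums():
    S = split(8)
    assert set(S.sum(axis=1).tolist()) <= {1, 2}
    assert not is_permutation(S)


def test_apply_generator_clamps_categorically():
    S = split(4)
    v = np.array([0, 2, 2, 0])
    # matrix-vector product would give a 4 where duplicated slots meet
    assert (S @ v).max() == 4
    assert apply_generator(S, v).tolist() == [2, 2, 2, 0]


# ---------------------------------------------------------------------------
# global generators


def test_global_generators_are_permutations(gens):
    for variant in ("input", "output", "inter"):
        assert is_permutation(gens.translation_global(variant).matrix)
        assert is_permutation(gens.backward_global(variant).matrix)
    assert is_permutation(gens.mirror_global().matrix)


def test_global_mirror_is_involution(gens, space):
    M = gens.mirror_global().matrix
    assert np.array_equal(M @ M, np.eye(space.size, dtype=int))


def test_pb_translation_worked_example(gens, space):
    """T shifts a PB R1 innervation to PB R2."""
    v = make_vector(space, {"PB R1": 1})
    out = gens.translation_global("output")(v)
    assert out[space.index_of("PB R2")] == 1
    assert out.sum() == 1


def test_pen_translation_and_mirror_worked_examples(gens, space, observed):
    """T x PEN1 = PEN2 and M x PEN10 = PEN2."""
    pen1, pen2, pen10 = (observed[n].vector for n in ("PEN1", "PEN2", "PEN10"))
    T = gens.translation_global("output")
    M = gens.mirror_global()
    assert np.array_equal(T(pen1), pen2)
    assert np.array_equal(M(pen10), pen2)
    # PEN1 innervates PB R1, EB R8+L8 and NO L1; PEN2 shifts PB by one
    # and EB by two subunits while NO stands
    assert pen2[space.index_of("PB R2")] == 1
    assert pen2[space.index_of("EB.P L6")] == 2
    assert pen2[space.index_of("EB.P L7")] == 2
    assert pen2[space.index_of("NO L1")] == 2


def test_mirror_translation_chain(gens, observed):
    """PEN10 = T^T x M x PEN1 (backward of the mirrored initial)."""
    pen1, pen10 = observed["PEN1"].vector, observed["PEN10"].vector
    B = gens.backward_global("output")
    M = gens.mirror_global()
    assert np.array_equal(B(M(pen1)), pen10)


def test_mirrored_translation_runs_backward(gens, space):
    """M T M = T^-1: translation in the mirrored frame reverses."""
    T = gens.translation_global("output").matrix
    M = gens.mirror_global().matrix
    assert np.array_equal(M @ T @ M, T.T)


def test_special_idfp_generator_alternates(gens, space):
    """The EIP-specific IDFP permutation exchanges DSB and VSB."""
    Tin = gens.translation_global("input")
    v = make_vector(space, {"IDFP DSB-R": 2})
    out = Tin(v)
    assert out[space.index_of("IDFP VSB-R")] == 2
    assert np.array_equal(Tin(out), v)  # period two


def test_unknown_variant_rejected(gens):
    with pytest.raises(ValueError):
        gens.translation_global("sideways")


def test_triplet_serialization_round_trip():
    S = split(6)
    text = serialize_triplets(S)
    assert np.array_equal(deserialize_triplets(text, 6), S)


def test_permutation_from_swaps():
    P = permutation_from_swaps(4, [(0, 1)])
    assert (P @ np.array([10, 20, 30, 40])).tolist() == [20, 10, 30, 40]
    assert is_permutation(P)
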