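import numpy as np
import pytest

from cxcircuit import (
    GeneratorSet,
    build_connection_matrix,
    build_space,
    input_output_block,
    lesion,
    lesion_scan,
    level_matrix,
    make_vector,
    relocation_scan,
    rescue,
)
from cxcircuit.propagation import hotspot_stats
from cxcircuit.space import Network, NeuronType


@pytest.fixture(scope="module")
def baseline_max(observed_matrix):
    M = level_matrix(observed_matrix, 3)
    vmax, _, _ = hotspot_stats(input_output_block(observed_matrix, M.values))
    return vmax


def test_empty_lesion_is_identity(observed, baseline_max):
    r = lesion(observed, [])
    assert r.max_path_number == baseline_max
    assert r.removed == ()


def test_lesion_unknown_type_rejected(observed):
    with pytest.raises(KeyError):
        lesion(observed, ["EIP999"])


def test_lesion_of_hotspot_pair_reduces_max(observed, baseline_max):
    r = lesion(observed, ["EIP8", "EIP17"])
    assert r.max_path_number < baseline_max
    assert sum(r.histogram.values()) > 0


def test_lesion_histogram_shortens_tail(observed):
    """Removing EIP8/EIP17 suppresses the long tail of the level-3
    path-number distribution."""
    base = lesion(observed, [])
    cut = lesion(observed, ["EIP8", "EIP17"])
    tail = lambda h, q: sum(n for v, n in h.items() if v >= q)
    threshold = max(cut.histogram) + 1
    assert tail(base.histogram, threshold) > 0
    assert tail(cut.histogram, threshold) == 0


def test_rescue_strictly_increases_model_max(observed, model, model_matrix):
    M = level_matrix(model_matrix, 3)
    model_max, _, _ = hotspot_stats(input_output_block(model_matrix, M.values))
    r = rescue(model, [observed["EIP8"], observed["EIP17"]])
    assert r.max_path_number > model_max


def test_lesion_scan_symmetric_toy():
    """On a mirror-symmetric network the scan result is identical for
    a pair and for its mirrored pair, and a self-mirrored type scans
    alone."""
    space = build_space(pb=4, fb_layers=(), eb_rings=("A",), eb_width=4,
                        no=0, idfp=0, ccp=0, cvlp=0, vmp=0)
    gens = GeneratorSet(space)
    # inputs (axon PB), outputs (dendrite PB), one self-mirrored input
    types = [
        NeuronType("EIP", 1, make_vector(space, {"PB R1": 2, "EB.A R1": 1})),
        NeuronType("EIP", 2, make_vector(space, {"PB L1": 2, "EB.A L1": 1})),
        NeuronType("EIP", 3, make_vector(space, {"PB R2": 2, "PB L2": 2, "EB.A R2": 1, "EB.A L2": 1})),
        NeuronType("PEN", 1, make_vector(space, {"PB R1": 1, "EB.A R1": 2})),
        NeuronType("PEN", 2, make_vector(space, {"PB L1": 1, "EB.A L1": 2})),
    ]
    net = Network(space, types)
    scan = lesion_scan(net, gens, pair_with_mirror=True, level=1)
    # the self-mirrored EIP3 appears alone and the mirror pairs jointly
    assert "EIP3" in scan.index
    assert "EIP1 & EIP2" in scan.index and "PEN1 & PEN2" in scan.index
    solo = lesion_scan(net, gens, pair_with_mirror=False, level=1)
    # single-type lesions of mirror partners are equivalent by symmetry
    assert solo.loc["EIP1", "max_path_number"] == solo.loc["EIP2", "max_path_number"]
    assert solo.loc["EIP3", "max_path_number"] == scan.loc["EIP3", "max_path_number"]


def test_lesion_scan_results_deterministic(observed, gens):
    s1 = lesion_scan(observed, gens, level=2)
    s2 = lesion_scan(observed, gens, level=2)
    assert s1.equals(s2)


def test_lesion_scan_mirror_pairs_once(observed, gens):
    scan = lesion_scan(observed, gens, level=2)
    # every non-local observed type appears in exactly one scan row
    names = [n for row in scan.index for n in row.split(" & ")]
    expected = [t.name for t in observed.types if t.role != "local"]
    assert sorted(names) == sorted(expected)


def test_relocation_native_cell_matches_unperturbed(observed, gens, baseline_max):
    """Writing EIP8's axons back to their native medial positions must
    reproduce the unperturbed observed maximum."""
    scan = relocation_scan(observed, gens, pb_labels=["PB L1", "PB L2", "PB L8"])
    assert scan.loc["PB L1", "PB L2"] == baseline_max
    assert scan.loc["PB L2", "PB L1"] == baseline_max  # order-independent
    # the generator-predicted lateral placement is weaker than native
    assert scan.loc["PB L8", "PB L8"] < baseline_max


def test_relocation_rejects_non_pb_positions(observed, gens):
    with pytest.raises((ValueError, KeyError)):
        relocation_scan(observed, gens, pb_labels=["EB.C R8"])


def test_relocation_edgeless_equals_lesion():
    """If the relocated terminals reach no dendrites, and the target
    has no other axons, the configuration is equivalent to a lesion."""
    space = build_space(pb=4, fb_layers=(), eb_rings=("A",), eb_width=4,
                        no=0, idfp=0, ccp=0, cvlp=0, vmp=0)
    gens = GeneratorSet(space)
    types = [
        NeuronType("EIP", 8, make_vector(space, {"PB R1": 2, "EB.A R1": 1})),
        NeuronType("EIP", 17, make_vector(space, {"PB L1": 2, "EB.A L1": 1})),
        NeuronType("PEN", 1, make_vector(space, {"PB R1": 1, "EB.A R1": 2})),
        NeuronType("PEN", 2, make_vector(space, {"PB L1": 1, "EB.A L1": 2})),
    ]
    net = Network(space, types)
    # nobody has dendrites in PB R2/L2: relocating there disconnects EIP8/17
    scan = relocation_scan(net, gens, target_type="EIP8", mirror_type="EIP17",
                           level=1, pb_labels=["PB R2"])
    lesioned = lesion(net, ["EIP8", "EIP17"], level=1)
    assert scan.loc["PB R2", "PB R2"] == lesioned.max_path_number
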