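# Methods

## The model

The package analyses the neural circuit formed by the neuron types that
innervate the protocerebral bridge (PB) of the *Drosophila* central
complex.  Anatomy enters only through a symbolic **subunit space**: the
five central-complex neuropils and four associated neuropil pairs are
partitioned into 154 glomerulus-level subunits — PB (16), six
fan-shaped-body (FB) layers of 8, four ellipsoid-body (EB) rings of 16,
the noduli (NO, 8), and the associated IDFP (10), CCP (2), CVLP (2) and
VMP (4).  A neuron **type** is a 154-slot integer vector with codes
0 (no innervation), 1 (dendrites), 2 (axons), 3 (axon/dendrite
coexistence).  Bilateral blocks are ordered right-lateral to
left-lateral (PB = R8…R1, L1…L8); side-paired blocks list left then
right halves, with IDFP in the order (HBm-L, HBl-L, DSB-L, VSB-L,
RB-L, then the right side).

### Generator algebra

The circuit's topographic regularity is captured by permutation-matrix
**generators** acting on per-neuropil sub-vectors:

* translation `T^(s,d)` — cyclic shift by `s` slots (PB and FB shift by
  one subunit per neighbouring type, EB by two);
* mirror `M` — full reversal for bilateral blocks, and the half-swap
  `M⁽²⁾ ⊗ I⁽ᵏ⁾` for side-paired blocks;
* identity `I` — "standing" (no movement);
* split `S = I + T` — duplicates an innervated slot into the adjacent
  one (row sums 1–2, no longer a permutation);
* backward `B = T⁻¹` — cancels a translation.

Block operators assemble by direct sum into four global generators:
three translation variants (PB-output; PB-input, which swaps DSB↔VSB in
IDFP each step for the EIP class; PB-interneuron, with a special PB
permutation for the local neurons) and one global mirror.  Generators
are applied with a categorical max-compose rule — an output slot takes
the maximum code among the slots routed to it — because innervation
codes are labels, not quantities (2 + 2 must remain 2 under a split).
For permutation matrices this equals the ordinary matrix–vector
product.

All translations are cyclic.  Orbit truncation is a property of the
class specification (orbit length), not of the matrices: a typical
PB-translating class uses orbit length 8 (types 1–8 on the right side)
followed by the mirror images (types 9–16), so wrap-around never
produces spurious contralateral types with wrong polarity.

### Synthesis and classification

A class specification holds one or more initial vectors, an orbit
length per initial, and the translation variant.  Generation emits the
translation orbit of every initial and then the mirror image of each
emitted vector, deduplicating identical vectors in first-seen order;
type indices follow generation order.  The **model network** is the
union of all class orbits; the **observed network** overlays atypical
types (replacements, additions, and removal of predicted-but-unobserved
types).  A type is **typical** when its vector equals some generated
vector exactly, **atypical** otherwise — exact-vector matching is
sufficient because any override changes at least one code slot.

### The reference networks are a synthetic reconstruction

The published subunit-resolved innervation tables are not
redistributable here, so the packaged fixture
(`data/class_specs_synthetic.json`) is a *synthetic reconstruction*
that satisfies every constraint printed in the study's main text: the
13 classes and their per-neuropil generators, the 17 initial types
(three PB LN, two CVP, two EIP, one for each remaining class), the
printed worked vectors (CVP1/CVP2, PEN1/PEN2/PEN10, the FfN4
split/standing patterns), the type counts (172 generated, 194
observed, 148 shared typical, 46 atypical, 184 non-local), and the
atypical EIP8/EIP17 pair whose axons sit on the two medial PB subunits
instead of the lateral subunit the generators predict.  Details that
only the original supplementary material fixes — the exact identity of
every atypical type, per-class orbit offsets, the PB local-neuron
permutation — are single documented choices.

Consequences for interpretation: structural results (counts, synthesis,
classification, mirror closure, the qualitative hotspot/lesion/rescue
and signal-rerouting phenomena) are genuine computations and transfer
to any fixture with the same structure.  *Numerical* path counts and
global graph statistics are properties of the particular innervation
tables: the reconstruction yields a level-3 input–output maximum of 32
(lesioned: 10), not the published 80 (26), and its graph statistics
differ from the published ones.  The package reports what it computes.

## Connectome construction

A directed edge i → j exists when some subunit carries an axonal arbor
(code 2 or 3) of type i and a dendritic arbor (code 1 or 3) of type j:
arbors sharing a glomerulus-scale subunit are assumed to synapse.  PB
local neurons are excluded (near-uniform PB coverage, presumed
modulatory).  The default adjacency is binary and self-loop-free;
weighted (shared-subunit count) and self-loop variants are flags.
Code-3 subunits contribute to both arbor sets, which lets the two
irregular EIP types both send and receive within their single EB
subunit.  Node order is class-sorted: inputs (CVP, EIP, CIVP) before
outputs (PEI, PEN, three PFN classes, four PFI classes).

## Propagation levels, hotspots, tracing

The propagation level *l* of a path is its number of intermediate
neurons, recurrent visits included, so the level-*l* matrix is the
exact integer power `M_l = A^(l+1)`.  Arithmetic promotes from int64 to
arbitrary-precision integers before any entry could overflow.  The
input–output sub-matrix (input rows × output columns) shows how PB
input signals reach the output classes; hotspot statistics report its
maximum entry, the attaining pairs, and the full histogram.

Signal tracing seeds every connectome type with a dendrite in the
chosen PB subunit(s) and runs a fixed number of synaptic levels
(default 2).  At each round every active type deposits a hit in each
subunit its axon innervates; in `multiplicity` mode deposits are
weighted by the walk count reaching the type, in `reachability` mode
each reached type deposits once.  Hits accumulate over all rounds
(accumulate-all; the final-level-only variant can be read off by
differencing two runs).

## Perturbations

Lesion removes named types, rescue adds (or, for generator-predicted
names, replaces with) supplied types; both rebuild the connectome and
re-measure the level-3 input–output statistics.  The pairwise lesion
scan removes every type together with its contralateral partner
(mirror partners are found by applying the global mirror to the
vectors) and tabulates the post-lesion maximum path number.  The
relocation scan rewrites the EIP8 PB axon terminals to every ordered
subunit pair (diagonal = single terminal), keeps EIP17 the exact mirror
image, and records the maximum path number; the native medial cell
reproduces the unperturbed value by construction.

## Graph statistics

Binary directed conventions: characteristic path length = mean
shortest-path distance over ordered reachable pairs; global
efficiency = mean inverse distance over all ordered pairs; clustering
= directed transitivity (Fagiolo; an undirected-projection variant is
also reported); modularity = mean ± sd over repeated Louvain runs
(default 100) with directed modularity; small-worldness
σ = (C/C_null)/(L/L_null) per null, mean ± sd over a degree-preserving
edge-swap ensemble (default 100 networks, 10 × |E| swaps).  All
stochastic parts derive from a single seed and are exactly
reproducible.  Standard algorithms come from networkx; the test suite
checks them against independent from-the-definition implementations
(BFS distances, Fagiolo's formula, closed forms).

## Synthetic data generator

`generate_synthetic_network` draws random class specifications on a
reduced subunit space (default: 8-subunit PB, two FB layers, one EB
ring — the full partitioned/bilateral structure at toy scale),
synthesizes their orbits with the same generator algebra, and perturbs
a chosen fraction of types with split, standing, or irregular (code-3)
overrides, returning the ground-truth atypical set.  Overrides are
guaranteed to differ from every generated vector, so classification
recovery is exact by design — what passing tests show is that the
machinery is consistent, not that real data are this clean.  The
generator emulates the partition structure, bilateral mirroring and
orbit regularity of the real circuit; it does not emulate biological
noise, multi-neuron types, or class-specific innervation richness.

## Numerical and design choices

* Orbit lengths, initial vectors and override recipes are data (the
  class-spec fixture), not code.
* Degenerate inputs raise labelled errors: all-zero vectors, unknown
  labels/types, codes outside {0–3}, edgeless graphs, non-PB trace
  starts, shifts ≥ dimension.
* Graphs too small to rewire (< 4 nodes or < 4 edges) are returned
  unchanged with a warning rather than failing.
* Problem sizes in tests and the acceptance script (level ≤ 5 oracles
  on ≤ 8 nodes, null ensembles of 5–20, 50–100 Louvain runs) were
  chosen to keep every run in the seconds-to-minutes range on one CPU.
* No CLI: this is a library driven from Python; the `examples/`
  scripts and `scripts/acceptance.py` are the runnable surface.

## Known limitations

* The reference networks are a reconstruction (above); published
  numerical path counts and Table-level statistics are not reproduced,
  and the relocation scan's global maximum need not coincide with the
  native terminal position as it does in the real data.
* Connectivity is subunit-overlap only — no synapse counts, weights,
  or dynamics; propagation is purely combinatorial.
* The generator approach presumes clear topographic organization; it
  is not a general pattern-inference tool.
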