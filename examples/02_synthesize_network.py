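"""Synthesize the circuit from its 17 initial neuron types.

Generates the model network by recursive application of the global
translation and mirror generators, overlays the 46 atypical types to
obtain the observed network, and classifies observed types as typical
(generator-predicted) or atypical.
"""

from cxcircuit import classify_types, reference_class_specs, reference_networks

observed, model = reference_networks()
specs = reference_class_specs(observed.space)

print("initial neuron types:", sum(len(s.initials) for s in specs))
print("model (generated) types:", len(model))
print("observed types:", len(observed))

typical, atypical = classify_types(observed, model)
print("typical (shared with the model):", len(typical))
print("atypical:", len(atypical))
print("example atypical types:", sorted(atypical)[:5])

# The model network is what the translation/mirror rules alone
# predict; every observed type outside it innervates some subunit in a
# way no generator orbit produces (split, standing, or irregular).
for name in ("PEN1", "PEN2", "EIP8", "EIP17"):
    t = observed[name]
    print(f"{t.name}: class {t.class_name}, role {t.role}, atypical {t.atypical}")
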