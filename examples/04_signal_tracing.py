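"""Subunit-resolved signal tracing.

Injects a signal into selected PB subunits, propagates it two synaptic
levels through the connectome, and counts hits (signal arrivals) per
subunit.  Starting centrally the observed and generated networks
behave identically; starting from the medial/lateral edge the atypical
EIP8/EIP17 pair reroutes signal into the medial PB subunits of the
observed network only.
"""

import numpy as np

from cxcircuit import build_connection_matrix, reference_networks, trace_signal

observed, model = reference_networks()
C_obs = build_connection_matrix(observed)
C_mod = build_connection_matrix(model)

for starts in (("PB L5", "PB R4"), ("PB R1", "PB L8")):
    h_obs = trace_signal(observed, C_obs, starts, levels=2)
    h_mod = trace_signal(model, C_mod, starts, levels=2)
    print(f"start {starts}: identical hit maps:",
          bool(np.array_equal(h_obs.hits, h_mod.hits)))
    sp = observed.space
    for label in ("PB R1", "PB L1", "PB R8", "PB L8"):
        i = sp.index_of(label)
        print(f"  {label}: observed {int(h_obs.hits[i])} hits, model {int(h_mod.hits[i])}")

# The medial PB subunits (R1, L1) collect more hits in the observed
# network only when the trace starts at the PB edge, where the
# atypical EIP pair picks the signal up in lateral EB and feeds it to
# the medial PB subunits.
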