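"""Simulate one sequencing library with ground truth.

Runs a one-step 35-cycle PCR of the even community, sequences 300 paired
reads, and summarises the truth labels: how many products are chimeric,
how many substitutions PCR and sequencing each contributed.
"""

import collections

import numpy as np

from ampmock.simulate import (make_contaminants, make_mock_strains,
                              method_params, simulate_library,
                              standard_communities)

strains = make_mock_strains(seed=0)
communities = standard_communities(strains)
contaminants = make_contaminants(8, seed=1, mock_strains=strains)

params = method_params("non_phasing", contaminant_rate=0.01)
lib = simulate_library(communities["Bm1"], params, 300, "Bm1.demo", contaminants,
                       seed=7)

origins = collections.Counter(t.origin for t in lib.truth)
print(f"read origins: {dict(origins)}")
print(f"chimera fraction: {100 * origins['chimera'] / len(lib.truth):.1f}%  "
      "(a one-step 35-cycle PCR accumulates incomplete-extension chimeras)")
pcr = np.mean([t.n_pcr_substitutions for t in lib.truth])
seq = np.mean([t.n_seq_substitutions for t in lib.truth])
print(f"mean substitutions per read pair: PCR {pcr:.2f}, sequencing {seq:.2f}")
print(f"first forward read: {lib.fwd[0][1][:60]}...")
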