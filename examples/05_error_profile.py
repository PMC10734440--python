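"""Per-position error profiling across the trimming grid.

Aligns forward/reverse/merged reads to their best-hit reference and pools
substitution counts. Reverse reads are noisier than forward (quality decays
faster), merging suppresses tail errors, and stringent trimming lowers the
rate further.
"""

from ampmock.errors import error_grid
from ampmock.qc import ReadRecord
from ampmock.simulate import (make_mock_strains, method_params,
                              simulate_library, standard_communities)

strains = make_mock_strains(seed=0)
communities = standard_communities(strains)
mock_refs = {s.strain_id: s.v4_seq for s in strains if s.v4_seq}

lib = simulate_library(communities["Bm1"], method_params("non_phasing"),
                       120, "demo", seed=9)
libraries = {"demo": {"fwd": [ReadRecord(i, s, q, "fwd") for i, s, q in lib.fwd],
                      "rev": [ReadRecord(i, s, q, "rev") for i, s, q in lib.rev]}}

table, profiles = error_grid(libraries, mock_refs,
                             trim_grid=("raw", "Q20-W5", "Q30-W2"))
sub = table[table.chimera_removal == "before"]
print(sub.pivot_table(index="trim", columns="read_type", values="rate_sub")
      .round(3).to_string())
print("\nSubstitution rate (%) per stratum: reverse > forward raw; trimming")
print("and merging both push the rate toward the PCR error floor.")
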