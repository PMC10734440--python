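"""Rarefy, cluster at 97%, flag unique OTUs, and classify artifacts.

Reproduces the spurious-sequence decomposition: singleton OTUs dominated
by chimeras, with contaminants and erroneous sequences making up the rest.
"""

from ampmock.otu import (build_otu_table, classify_artifacts, flag_unique_otus,
                         rarefy, spurious_summary)
from ampmock.pipeline import make_external_db
from ampmock.qc import ReadRecord, process_pairs
from ampmock.simulate import (make_contaminants, make_mock_strains,
                              method_params, simulate_library,
                              standard_communities)

strains = make_mock_strains(seed=0)
communities = standard_communities(strains)
mock_refs = {s.strain_id: s.v4_seq for s in strains if s.v4_seq}
external_db = make_external_db(strains, seed=2)
contaminants = make_contaminants(8, seed=1, mock_strains=strains)

libs = {}
for rep in (1, 2):
    lib = simulate_library(communities["Bm1"],
                           method_params("non_phasing", contaminant_rate=0.01),
                           300, f"rep{rep}", contaminants, seed=20 + rep)
    fwd = [ReadRecord(i, s, q, "fwd") for i, s, q in lib.fwd]
    rev = [ReadRecord(i, s, q, "rev") for i, s, q in lib.rev]
    merged, _ = process_pairs(fwd, rev, level="Q20-W5", min_len=200)
    libs[f"rep{rep}"] = [r.seq for r in merged]

depth = min(len(v) for v in libs.values())
libs = {k: rarefy(v, depth, seed=1) for k, v in libs.items()}
print(f"rarefied both replicates to {depth} sequences")

table = build_otu_table(libs)
flag_unique_otus(table, {k: k for k in libs})
classify_artifacts(table, mock_refs, external_db)

n_true = sum(1 for c in table.classification.values() if c.startswith("true_strain"))
print(f"{len(table.otu_ids)} OTUs; {n_true} map to mock strains")
print("\nunique-OTU (spurious) decomposition — rows are presence classes,")
print("columns the artifact classes:")
print(spurious_summary(table).to_string())
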