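#!/usr/bin/env python
"""Integrate regulator rankings across conditions.

Computes the pairwise top-100 overlap matrix, the regulator core common to
the three shared-core conditions, the interaction subnetwork induced by
that core, and its pathway enrichment. The expected picture: the trio
overlaps each other far more than it overlaps the unrelated condition
(block structure), and the shared core is recovered almost completely.
"""

import argparse
from pathlib import Path

import pandas as pd

from itrkit.integration_networks import (
    common_core,
    core_network,
    pathway_enrichment,
    topn_overlap_matrix,
    z_profiles,
)
from itrkit.knowledge_io import (
    read_gene_sets,
    read_interactions,
    read_prior_network,
    write_interactions,
)
from itrkit.regulator_activity import read_ranking

parser = argparse.ArgumentParser()
parser.add_argument("--inputs", type=Path, default=Path("results/inputs"))
parser.add_argument("--itrs", type=Path, default=Path("results/itrs"))
parser.add_argument("--out", type=Path, default=Path("results/integration"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

rankings = [read_ranking(p) for p in sorted(args.itrs.glob("itrs_*.tsv"))]
matrix = topn_overlap_matrix(rankings, n=100)
matrix.to_tsv(args.out / "overlap_matrix.tsv")
print("top-100 overlap matrix (%):")
print(matrix.values.to_string())

trio = [r for r in rankings if r.condition.startswith("trio")]
core = common_core(trio, n=100, min_conditions=3)
print(f"\ncore common to all {len(trio)} trio conditions: {len(core)} regulators")
pd.DataFrame(
    sorted((r, len(core.membership[r])) for r in core.regulators),
    columns=["regulator", "n_conditions"],
).to_csv(args.out / "core_set.tsv", sep="\t", index=False)

graph = read_interactions(args.inputs / "interactions.tsv")
subgraph, summary = core_network(core, graph)
write_interactions(subgraph, args.out / "core_network.tsv")
print(
    f"core network: {summary.n_nodes} nodes, {summary.n_edges} edges, "
    f"largest component {summary.largest_component}, "
    f"{summary.fraction_isolated:.0%} isolated"
)

pathways = read_gene_sets(args.inputs / "pathways.gmt")
# universe = the full regulator space (the edge-list file only keeps
# regulators with at least one interaction)
universe = read_prior_network(args.inputs / "prior_network.tsv").regulators
enrich = pathway_enrichment(subgraph.nodes, pathways, universe=universe)
enrich.to_csv(args.out / "core_enrichment.tsv", sep="\t", index=False)
print("\ntop pathway enrichments of the core:")
print(enrich.head(5).to_string(index=False))

profiles = z_profiles(rankings, set().union(*(r.top(10) for r in rankings)))
profiles.to_csv(args.out / "z_profiles.tsv", sep="\t", index=False, na_rep="NA")
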