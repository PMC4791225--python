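#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds the default scenario — a signed prior network of 200 regulators
over 5,000 genes, three conditions sharing a planted 60-regulator core
(emulating a block of related amplified cell lines), one unrelated
condition, plus an interaction graph and pathway sets over the regulator
space — and writes everything under results/inputs/.
"""

import argparse
import json
from pathlib import Path

from itrkit import synthetic_data as synth
from itrkit.knowledge_io import write_gene_sets, write_interactions, write_prior_network
from itrkit.omics_contrasts import write_contrast

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/inputs"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

config = synth.default_scenario(seed=args.seed)
network = synth.generate_prior_network(config)
write_prior_network(network, args.out / "prior_network.tsv")
print(f"prior network: {len(network)} edges, {len(network.regulators)} regulators")

tables, truth = synth.generate_contrasts(network, config)
for cond, table in tables.items():
    write_contrast(table, args.out / f"contrast_{cond}.tsv")
    n_de = int((table.records.fdr <= 0.05).sum())
    print(f"{cond}: {len(table)} genes, {n_de} significant at FDR <= 0.05")

write_interactions(synth.generate_interactions(config), args.out / "interactions.tsv")
write_gene_sets(synth.generate_pathway_sets(config), args.out / "pathways.gmt")
with open(args.out / "planted_truth.json", "w") as fh:
    json.dump(truth, fh, indent=2, sort_keys=True)
print(f"inputs written to {args.out}")
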