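#!/usr/bin/env python
"""Seed-anchored co-expression networks per stratum and their comparison.

Builds networks (Spearman > 0.9, edge limit 1 per co-expressed gene) within
recurrence +/- strata and within node x recurrence strata, exports them as
GraphML/JSON with full node annotation, and reports which co-expressed genes
are common or exclusive between recurrence strata.

Reads results/merged/, writes results/networks/.
"""

import json
from pathlib import Path

from gcna import CohortStudy, build_stratum_networks, compare_networks
from gcna.harmonize import read_clinical_table, read_expression_table
from gcna.pipeline import export_network
from gcna.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "networks"

expr = read_expression_table(ROOT / "merged" / "expression_merged.tsv", cohort="merged")
clin = read_clinical_table(ROOT / "merged" / "clinical_merged.tsv")
study = CohortStudy(expr, clin, ["merged"])
seeds = [s for s in SimulationConfig(rng_seed=0).seed_gene_ids if s in set(study.genes)]
print(f"{len(seeds)} seed genes present in the merged study")

OUT.mkdir(parents=True, exist_ok=True)
cox_cache = {}
networks = {}
for variables in (["recurrence"], ["node", "recurrence"]):
    networks.update(
        build_stratum_networks(study, seeds, variables, cox_cache=cox_cache)
    )

for label, net in networks.items():
    safe = label.replace("/", "_").replace("+", "pos").replace("-", "neg")
    export_network(net, OUT / f"network_{safe}.graphml", "graphml")
    export_network(net, OUT / f"network_{safe}.json", "json")
    print(f"{label}: {net.graph.number_of_nodes()} nodes, "
          f"{net.graph.number_of_edges()} edges, "
          f"co-expressed = {sorted(net.nonseed_nodes)}")

pairs = [("recurrence+", "recurrence-"),
         ("node+/recurrence+", "node+/recurrence-"),
         ("node-/recurrence+", "node-/recurrence-")]
comparisons = []
for a, b in pairs:
    if a in networks and b in networks:
        c = compare_networks(networks[a], networks[b])
        comparisons.append(c)
        print(f"\n{a} vs {b}:")
        print(f"  common:        {sorted(c.common_genes)}")
        print(f"  only {a}: {sorted(c.exclusive_to_a)}")
        print(f"  only {b}: {sorted(c.exclusive_to_b)}")

with open(OUT / "comparisons.json", "w") as fh:
    json.dump(
        [
            {"a": c.label_a, "b": c.label_b, "common": sorted(c.common_genes),
             "exclusive_to_a": sorted(c.exclusive_to_a),
             "exclusive_to_b": sorted(c.exclusive_to_b)}
            for c in comparisons
        ],
        fh, indent=2, sort_keys=True,
    )
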