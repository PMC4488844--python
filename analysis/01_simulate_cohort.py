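#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes a family cohort (per-family VCFs, a cohort PED, an annotation
table and the planted-mutation manifest), a case/control exome panel, a
PPI edge list with seed/hub/candidate designations, and a seven-species
protein alignment — everything the later analysis steps consume.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from lqtex.conservation import write_msa
from lqtex.ppi_enrichment import write_edge_list
from lqtex.synthetic_cohort import (
    SimulationConfig,
    simulate_case_control,
    simulate_cohort,
    simulate_msa,
    simulate_ppi,
)
from lqtex.variant_model import (
    write_annotations,
    write_candidate_report,
    write_ped,
    write_vcf,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("scratch/simulated"))
args = parser.parse_args()

out = args.out
(out / "families").mkdir(parents=True, exist_ok=True)

config = SimulationConfig(seed=args.seed, n_trio_families=21, n_multiplex_families=14,
                          n_background_sites=2000)
cohort = simulate_cohort(config)
annotations, peds = {}, []
for fam in cohort.families:
    write_vcf(fam.genotypes, out / "families" / f"{fam.pedigree.family_id}.vcf")
    annotations.update(fam.annotations)
    peds.append(fam.pedigree)
write_ped(peds, out / "cohort.ped")
write_annotations(annotations, out / "family_annotations.tsv")
write_candidate_report(cohort.manifest, out / "planted_manifest.tsv")
n_trio = sum(p.design == "trio" for p in peds)
print(f"families: {len(peds)} ({n_trio} trios, {len(peds) - n_trio} multiplex), "
      f"{len(cohort.manifest)} planted mutations")

cc = simulate_case_control(config)
write_vcf(cc.genotypes, out / "case_control.vcf")
write_annotations(cc.annotations, out / "case_control_annotations.tsv")
np.savetxt(out / "case_control_labels.txt", cc.labels, fmt="%d")
print(f"case/control panel: {int(cc.labels.sum())} cases, "
      f"{int((1 - cc.labels).sum())} controls, {cc.genotypes.n_sites} variants, "
      f"enriched gene {cc.enriched_gene}")

ig = simulate_ppi(config)
write_edge_list(ig.graph, out / "ppi_edges.tsv")
(out / "ppi_designations.json").write_text(json.dumps({
    "seeds": sorted(ig.seeds), "hub": ig.hub, "candidates": sorted(ig.candidates),
}, indent=2))
print(f"PPI graph: {ig.graph.number_of_nodes()} nodes, "
      f"{ig.graph.number_of_edges()} edges, hub {ig.hub}")

msa = simulate_msa(7, 120, conserved_positions=set(range(0, 120, 5)), seed=args.seed)
write_msa(msa, out / "alignment.fasta")
print("seven-species alignment: 120 columns, every fifth column conserved")
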