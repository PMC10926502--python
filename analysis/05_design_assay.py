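#!/usr/bin/env python
"""Design the diagnostic TaqMan assay on the main haplogroup, a control assay
on the conserved locus, and predict per-sample amplification in silico.

The main haplogroup is taken as the parsimony component of the modal
haplotype (the early-diverging outlier lineage joins only through a forced,
beyond-limit connection and is therefore excluded from the design targets,
while remaining on the specificity panel).

Writes results/assay_candidates.tsv, results/assay_control.tsv and
results/specificity.tsv.
"""

from pathlib import Path

from barcodedx.alignment import collapse_haplotypes, read_alignment, read_metadata
from barcodedx.design import (
    assay_report, design_assay, design_control_assay, in_silico_specificity,
)
from barcodedx.network import build_network, parsimony_component

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    aln = read_alignment(ROOT / "core_alignment.fasta")
    table = read_metadata(ROOT / "data" / "samples.tsv")
    haps = collapse_haplotypes(aln)
    net = build_network(haps)
    main_samples = {s for h in parsimony_component(net) for s in haps.members_of(h)}
    design_ids = [
        s for s in aln.sample_ids
        if table.group_of(s) != "target" or s in main_samples
    ]
    excluded = [s for s in aln.sample_ids if s not in design_ids]
    print(f"design targets: {len(main_samples)} main-haplogroup samples "
          f"({len(excluded)} divergent target samples excluded)")
    assays = design_assay(aln.subset(design_ids), table)
    if not assays:
        raise SystemExit("no feasible diagnostic assay")
    assay_report(assays[:10]).to_csv(ROOT / "assay_candidates.tsv", sep="\t", index=False)
    best = assays[0]
    for o in best.oligos():
        print(f"  {o.role:8s} {o.sequence}  Tm(NN) {o.tm_nn:.1f} C  "
              f"discriminative sites {o.disc_count}")
    print(f"  amplicon {best.amplicon[0] + 1}-{best.amplicon[1]} "
          f"({best.amplicon_length} nt), probe-primer Tm differential "
          f"{best.tm_differential:.2f} C")
    ctrl_aln = read_alignment(ROOT / "data" / "control_locus.fasta")
    control = design_control_assay(ctrl_aln, table, best)
    assay_report([control]).to_csv(ROOT / "assay_control.tsv", sep="\t", index=False)
    print("  control assay Tms:",
          " ".join(f"{o.role} {o.tm_nn:.1f}" for o in control.oligos()))
    spec = in_silico_specificity(best, aln, table)
    spec.to_csv(ROOT / "specificity.tsv", sep="\t", index=False)
    by_group = spec.groupby("group")["predicted_amplification"].agg(["sum", "count"])
    print("predicted amplification by group:")
    print(by_group.to_string())


if __name__ == "__main__":
    main()
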