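#!/usr/bin/env python
"""Generate the synthetic study data every later stage consumes.

Writes, under results/data/:
  barcode.fasta / samples.tsv  — planted-haplotype barcode alignment + labels
  control_locus.fasta          — conserved 18S-like alignment, same samples
  qpcr_wells.csv / qpcr_truth.csv — duplex qPCR run with ground-truth classes
  dilution_series.csv          — serial-dilution Cq table for the standard curve
"""

from pathlib import Path

import pandas as pd

from barcodedx.alignment import write_alignment, write_metadata
from barcodedx.simulate import (
    generate_barcode_dataset, generate_control_dataset, generate_dilution_series,
    generate_qpcr_run, wells_to_frame,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    aln, table, truth = generate_barcode_dataset(seed=SEED)
    write_alignment(aln, OUT / "barcode.fasta")
    write_metadata(table, OUT / "samples.tsv")
    pd.Series(truth["lineage"], name="lineage").rename_axis("sample_id").to_csv(
        OUT / "lineage_truth.csv"
    )
    ctrl = generate_control_dataset(table, seed=SEED + 1000)
    write_alignment(ctrl, OUT / "control_locus.fasta")
    wells, qtruth = generate_qpcr_run(seed=SEED)
    wells_to_frame(wells).to_csv(OUT / "qpcr_wells.csv", index=False)
    qtruth.to_csv(OUT / "qpcr_truth.csv", index=False)
    pts = generate_dilution_series(seed=SEED)
    pd.DataFrame(pts, columns=["concentration_ng_ul", "cq"]).to_csv(
        OUT / "dilution_series.csv", index=False
    )
    print(f"barcode alignment: {aln.n} samples x {aln.L} nt")
    print(f"qPCR wells: {len(wells)} ({len(qtruth)} samples)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
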