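#!/usr/bin/env python
"""Generate every synthetic input for the downstream analyses.

The study's raw data was never deposited, so all inputs are simulated
with known ground truth: dose-response series for three particle shapes
(viability and IL-1beta endpoints), an ELISA calibration plate, and an
Agilent-style feature-level expression table (8 conditions x 3
replicates) with spiked DEGs and two coherently shifted gene sets.
Truth files are written beside the data so later steps can check
recovery."""

import sys
from pathlib import Path

import pandas as pd

from goldpath import gsea, synth

SEED = 17
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    frames, truth_rows = [], []
    for name, truth in synth.default_endpoint_truths(seed=SEED).items():
        ds = synth.gen_dose_response(truth)
        df = ds.to_frame()
        df["series"] = name
        frames.append(df)
        s = truth.spec
        truth_rows.append((name, s.name, s.a, s.b, s.c, s.d, truth.log_sd))
    pd.concat(frames).to_csv(OUT / "dose_response.csv", index=False)
    pd.DataFrame(truth_rows, columns=["series", "model", "a", "b", "c", "d",
                                      "log_sd"]).to_csv(
        OUT / "dose_response_truth.csv", index=False)
    print(f"dose-response: {len(frames)} series "
          f"({sum(len(f) for f in frames)} observations)")

    elisa_truth = synth.ElisaTruth(seed=SEED + 100, od_sd=0.01)
    synth.gen_elisa_plate(elisa_truth).to_csv(OUT / "elisa_plate.csv",
                                              index=False)
    pd.DataFrame({"sample": [f"sample_{i+1}"
                             for i in range(len(elisa_truth.sample_conc))],
                  "true_conc": elisa_truth.sample_conc}).to_csv(
        OUT / "elisa_truth.csv", index=False)
    print(f"ELISA plate: 8-point standards + blank + "
          f"{len(elisa_truth.sample_conc)} samples")

    n_genes = int(sys.argv[1]) if len(sys.argv) > 1 else 2000
    etruth = synth.default_expression_truth(n_genes=n_genes, seed=SEED + 200)
    table, sheet, gene_truth = synth.gen_expression(etruth)
    table.to_csv(OUT / "features.tsv", sep="\t", index=False)
    sheet.to_csv(OUT / "sample_sheet.tsv", sep="\t")
    gene_truth.to_csv(OUT / "gene_truth.tsv", sep="\t")
    etruth.spikes.to_csv(OUT / "spiked_degs.tsv", sep="\t", index=False)
    gsea.GmtCollection(etruth.gene_sets,
                       {k: "synthetic" for k in etruth.gene_sets}).to_gmt(
        OUT / "gene_sets.gmt")
    print(f"expression: {len(table)} probes / {n_genes} genes x "
          f"{len(sheet)} samples, {len(etruth.spikes)} spiked DEGs, "
          f"{len(etruth.gene_sets)} shifted gene sets")


if __name__ == "__main__":
    main()
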