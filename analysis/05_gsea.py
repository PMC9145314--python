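#!/usr/bin/env python
"""Gene-set enrichment of every comparison against the synthetic gene
sets, with gene-label permutation significance.

The generator shifted two gene sets (cholesterol-synthesis-like and
oxidative-phosphorylation-like) downward in the rod-exposed wildtype
condition; this step should call them down there and nowhere else."""

from pathlib import Path

import pandas as pd

from goldpath import gsea

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "gsea"
SEED = 17
N_PERM = 1000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    collection = gsea.GmtCollection.from_gmt(
        ROOT / "synthetic" / "gene_sets.gmt")
    grids = {}
    for stats_file in sorted((ROOT / "microarray").glob("stats_*.tsv")):
        label = stats_file.stem.removeprefix("stats_")
        stats = pd.read_csv(stats_file, sep="\t", index_col=0)
        ranked = gsea.rank_genes(stats)
        res = gsea.permutation_significance(ranked, collection,
                                            n_perm=N_PERM, seed=SEED + 300)
        res.to_csv(OUT / f"enrichment_{label}.tsv", sep="\t")
        grids[label] = res
        calls = res[res["p"] < 0.05]
        desc = ", ".join(f"{s} {r.direction} (NES {r.nes:+.2f}, p={r.p:.3g})"
                         for s, r in calls.iterrows()) or "nothing called"
        print(f"{label:24s} {desc}")
    grid = gsea.significant_sets(grids, p_threshold=0.05, top_n=2)
    grid.to_csv(OUT / "summary_grid.tsv", sep="\t")


if __name__ == "__main__":
    main()
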