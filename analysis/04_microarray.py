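#!/usr/bin/env python
"""Microarray stage: reliability filter, log2 + quantile normalization,
symbol collapse, per-comparison t-tests, the union DEG selection with
its expected-false-positive FDR, PCA of the DEG matrix, and the
clustered log2FC heatmap."""

import json
from pathlib import Path

import pandas as pd

from goldpath import microarray as ma

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "microarray"
ALPHA = 0.001

COMPARISONS = [
    ("GNP-1_vs_C_WT", ("WT", "GNP-1"), ("WT", "control")),
    ("GNP-4_vs_C_WT", ("WT", "GNP-4"), ("WT", "control")),
    ("GNP-6_vs_C_WT", ("WT", "GNP-6"), ("WT", "control")),
    ("GNP-6_vs_C_ASC-def", ("ASC-def", "GNP-6"), ("ASC-def", "control")),
    ("GNP-6_vs_C_NLRP3-def", ("NLRP3-def", "GNP-6"), ("NLRP3-def", "control")),
    ("WT-C_vs_ASC-def-C", ("ASC-def", "control"), ("WT", "control")),
    ("WT-C_vs_NLRP3-def-C", ("NLRP3-def", "control"), ("WT", "control")),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(ROOT / "synthetic" / "features.tsv", sep="\t")
    sheet = pd.read_csv(ROOT / "synthetic" / "sample_sheet.tsv",
                        sep="\t").set_index("sample")

    reliable = ma.filter_reliable(table)
    norm = ma.log2_quantile_normalize(reliable)
    collapsed = ma.collapse_by_symbol(
        norm, reliable.set_index("feature_id")["symbol"])
    em = ma.ExpressionMatrix(collapsed, sheet)
    collapsed.to_csv(OUT / "normalized_matrix.tsv", sep="\t")
    print(f"{len(reliable)}/{len(table)} reliable probes -> "
          f"{collapsed.shape[0]} genes x {collapsed.shape[1]} samples")

    results = []
    for label, grp, ctl in COMPARISONS:
        r = ma.differential_expression(em, grp, ctl, label=label)
        r.stats.to_csv(OUT / f"stats_{label}.tsv", sep="\t")
        results.append(r)

    degs = ma.select_degs(results, alpha=ALPHA)
    fdr = ma.estimate_fdr(degs)
    pd.Series(degs.genes, name="gene").to_csv(OUT / "deg_union.tsv",
                                              sep="\t", index=False)
    (OUT / "deg_summary.json").write_text(json.dumps(
        {"per_comparison": degs.per_comparison, "union": len(degs.genes),
         "fdr": fdr}, indent=2))
    per = ", ".join(f"{k}={v}" for k, v in degs.per_comparison.items())
    print(f"DEGs per comparison: {per}")
    print(f"union = {len(degs.genes)} genes; expected-false-positive "
          f"FDR = {100 * fdr:.0f}%")

    spiked = set(pd.read_csv(ROOT / "synthetic" / "spiked_degs.tsv",
                             sep="\t")["gene"])
    hit = len(spiked & set(degs.genes))
    print(f"spiked-DEG recovery: {hit}/{len(spiked)} in the union")

    if len(degs.genes) >= 2:
        scores, frac = ma.pca_scores(collapsed.loc[degs.genes])
        scores.to_csv(OUT / "pca_scores.tsv", sep="\t")
        print(f"PCA on DEGs: PC1 {100 * frac[0]:.0f}%, "
              f"PC2 {100 * frac[1]:.1f}% of variance")
        hm = ma.log2fc_heatmap(em, COMPARISONS, degs.genes)
        hm.log2fc.to_csv(OUT / "heatmap_log2fc.tsv", sep="\t")
        ma.render_heatmap(hm, OUT / "heatmap.png")


if __name__ == "__main__":
    main()
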