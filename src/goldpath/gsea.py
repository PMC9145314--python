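"""Gene Set Enrichment Analysis: weighted Kolmogorov-Smirnov running sum.

Genes are ranked by a signed per-gene metric (the t-statistic of a
comparison).  For a gene set, a running sum walks the ranked list,
stepping up by |metric|^p (normalized) at set members ("hits") and down
by 1/(N - Nh) at non-members; the enrichment score ES is the running
sum's maximum signed deviation from zero.  Significance comes from a
gene-label permutation null (with three replicates per group a
phenotype permutation admits too few relabelings to be useful), with
NES = ES normalized by the mean |null ES| of matching sign and q-values
by Benjamini-Hochberg across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


class GseaError(ValueError):
    pass


def rank_genes(stats: pd.DataFrame, metric: str = "t") -> pd.Series:
    """Ranked list: genes sorted descending by the signed metric, ties
    broken by lexicographic gene order (deterministic)."""
    if metric not in stats.columns:
        raise GseaError(f"ranking metric {metric!r} missing from statistics")
    col = stats[metric]
    if col.isna().any():
        raise GseaError("ranking metric contains missing values")
    frame = col.rename("metric").rename_axis("gene").reset_index()
    frame = frame.sort_values(["metric", "gene"], ascending=[False, True],
                              kind="stable")
    return frame.set_index("gene")["metric"]


def enrichment_score(
    ranked: pd.Series, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES and the full running-sum profile for one gene set.

    A set covering the whole universe has a degenerate all-zero profile
    (no misses to step down on) and is reported as ES = 0.
    """
    genes = ranked.index
    hits = genes.isin(set(gene_set))
    n, nh = len(genes), int(hits.sum())
    if nh == 0:
        raise GseaError("gene set does not intersect the ranked universe")
    if nh == n:
        return 0.0, np.zeros(n)
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    if not np.all(np.isfinite(w)):  # infinite t from zero-variance genes
        finite = w[np.isfinite(w)]
        w = np.where(np.isfinite(w), w, finite.max() if len(finite) else 1.0)
    w_hit = np.where(hits, w, 0.0)
    norm = w_hit.sum()
    if norm == 0:  # all hit metrics are exactly zero: fall back to equal steps
        w_hit = hits.astype(float)
        norm = w_hit.sum()
    p_hit = np.cumsum(w_hit) / norm
    p_miss = np.cumsum(~hits) / (n - nh)
    running = p_hit - p_miss
    es_pos, es_neg = float(running.max()), float(running.min())
    # ties between equal-magnitude extrema resolve to the positive one
    es = es_pos if es_pos + es_neg >= -1e-12 else es_neg
    return es, running


@dataclass
class GmtCollection:
    """Named gene sets (GMT format: name, description, members)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str]

    @classmethod
    def from_gmt(cls, path) -> "GmtCollection":
        sets, desc = {}, {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                sets[parts[0]] = [g for g in parts[2:] if g]
                desc[parts[0]] = parts[1]
        return cls(sets, desc)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, self.descriptions.get(name, "")]
                                   + list(members)) + "\n")

    def restricted(self, universe, min_size: int = 2,
                   max_size: int | None = None) -> "GmtCollection":
        uni = set(universe)
        out, desc = {}, {}
        for name, members in self.sets.items():
            kept = [g for g in members if g in uni]
            if len(kept) >= min_size and (max_size is None or len(kept) <= max_size):
                out[name] = kept
                desc[name] = self.descriptions.get(name, "")
        return GmtCollection(out, desc)


def permutation_significance(
    ranked: pd.Series,
    collection: GmtCollection | dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Gene-label permutation test for every set in the collection.

    Null ES values come from random sets of matching size drawn from the
    universe; p = (1 + #{|null ES| >= |ES|}) / (1 + n_perm), NES = ES /
    mean |null ES| of matching sign, q = Benjamini-Hochberg across sets.
    """
    if n_perm < 100:
        raise GseaError("n_perm must be >= 100 for a usable significance floor")
    sets = collection.sets if isinstance(collection, GmtCollection) else collection
    rng = np.random.default_rng(seed)
    genes = ranked.index.to_numpy()
    n = len(genes)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        kept = [g for g in members if g in ranked.index]
        if not kept:
            continue
        es, _ = enrichment_score(ranked, kept, weight=weight)
        size = len(kept)
        if size not in null_cache:
            null = np.empty(n_perm)
            for i in range(n_perm):
                idx = rng.choice(n, size=size, replace=False)
                null[i], _ = enrichment_score(ranked, genes[idx], weight=weight)
            null_cache[size] = null
        null = null_cache[size]
        p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (1.0 + n_perm)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.mean(np.abs(same_sign)) if len(same_sign) else np.mean(np.abs(null))
        nes = es / denom if denom > 0 else 0.0
        rows.append((name, size, es, nes, p,
                     "up" if es > 0 else ("down" if es < 0 else "flat")))
    out = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p", "direction"])
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["q"] = []
    return out.set_index("set")


def significant_sets(
    results: dict[str, pd.DataFrame],
    p_threshold: float = 0.001,
    top_n: int = 20,
    min_occurrences: int = 2,
) -> pd.DataFrame:
    """Reporting filter across comparisons: sets significant multiple
    times, or repeatedly in a comparison's top ``top_n`` by |NES|.
    Returns a set x comparison grid of signed NES (NaN = not called)."""
    counts: dict[str, int] = {}
    for label, df in results.items():
        called = set(df.index[df["p"] < p_threshold])
        called |= set(df.reindex(df["nes"].abs().sort_values(ascending=False).index)
                      .head(top_n).index)
        for s in called:
            counts[s] = counts.get(s, 0) + 1
    keep = sorted(s for s, c in counts.items() if c >= min_occurrences)
    grid = pd.DataFrame(index=keep, columns=list(results), dtype=float)
    for label, df in results.items():
        for s in keep:
            if s in df.index and df.loc[s, "p"] < p_threshold:
                grid.loc[s, label] = df.loc[s, "nes"]
    return grid
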