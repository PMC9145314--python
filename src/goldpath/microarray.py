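"""Feature-level expression processing and differential expression.

Mirrors a one-colour Agilent-style workflow: scanner quality flags gate
which features are reliable, intensities are log2-transformed and
quantile normalized, features are collapsed to gene symbols (median),
and each exposure group is compared to its control with a per-gene
two-sample t-test.  Genes significant at p < alpha in at least one
comparison form the DEG set; the expected-false-positive FDR, PCA of
samples, and a clustered log2 fold-change heatmap complete the stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

FLAG_COLUMNS = (
    "above_noise",
    "below_saturation",
    "population_outlier",
    "uniform_spot",
    "is_control",
)
META_COLUMNS = ("feature_id", "symbol") + FLAG_COLUMNS


class SchemaError(ValueError):
    pass


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def filter_reliable(table: pd.DataFrame) -> pd.DataFrame:
    """Keep features that pass all five reliability criteria: above the
    noise floor, below saturation, not a population outlier, a uniform
    spot, and not a control feature."""
    for col in FLAG_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"feature table lacks flag column {col!r}")
    keep = (
        table["above_noise"].astype(bool)
        & table["below_saturation"].astype(bool)
        & ~table["population_outlier"].astype(bool)
        & table["uniform_spot"].astype(bool)
        & ~table["is_control"].astype(bool)
    )
    return table.loc[keep].copy()


def log2_quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """log2-transform the intensity columns and quantile normalize them
    so every sample shares the mean empirical distribution (within-sample
    ranks preserved).  Returns a feature x sample frame indexed by
    feature_id."""
    cols = sample_columns(table)
    vals = table[cols].to_numpy(dtype=float)
    bad = np.where(~(vals > 0).all(axis=1))[0]
    if len(bad):
        ids = table.iloc[bad]["feature_id"].tolist() if "feature_id" in table else list(bad)
        raise ValueError(f"non-positive intensities for features: {ids[:10]}")
    log_vals = np.log2(vals)
    order = np.argsort(log_vals, axis=0, kind="stable")
    ref = np.sort(log_vals, axis=0).mean(axis=1)
    out = np.empty_like(log_vals)
    for j in range(log_vals.shape[1]):
        out[order[:, j], j] = ref
    index = table["feature_id"] if "feature_id" in table else table.index
    return pd.DataFrame(out, index=pd.Index(index, name="feature_id"), columns=cols)


def collapse_by_symbol(matrix: pd.DataFrame, symbols: pd.Series) -> pd.DataFrame:
    """One row per gene symbol, aggregating a symbol's features by their
    median; features with an empty/missing symbol are dropped (count
    logged)."""
    symbols = symbols.reindex(matrix.index)
    empty = symbols.isna() | (symbols.astype(str).str.strip() == "")
    if empty.any():
        logger.info("dropping %d features without a gene symbol", int(empty.sum()))
    kept = matrix.loc[~empty]
    collapsed = kept.groupby(symbols.loc[~empty].astype(str)).median()
    collapsed.index.name = "symbol"
    return collapsed


@dataclass
class ExpressionMatrix:
    """Gene x sample log2 expression with per-sample metadata
    (cell_line, exposure, replicate)."""

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise SchemaError(f"samples missing from the sample sheet: {missing}")

    def group(self, cell_line: str, exposure: str) -> list[str]:
        m = (self.samples["cell_line"] == cell_line) & (
            self.samples["exposure"] == exposure
        )
        return list(self.samples.index[m])


@dataclass
class ComparisonResult:
    """Per-gene statistics of one group-vs-control comparison."""

    label: str
    stats: pd.DataFrame  # columns: log2fc, t, p

    @property
    def genes(self) -> pd.Index:
        return self.stats.index

    def significant(self, alpha: float) -> pd.Index:
        return self.stats.index[self.stats["p"] < alpha]


def differential_expression(
    matrix: ExpressionMatrix,
    group: list[str] | tuple[str, str],
    control: list[str] | tuple[str, str],
    label: str | None = None,
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-sample t-test per gene of an exposed group against its
    control; log2FC is the difference of group means.  Groups may be
    sample lists or (cell_line, exposure) pairs."""
    if isinstance(group, tuple):
        group = matrix.group(*group)
    if isinstance(control, tuple):
        control = matrix.group(*control)
    if len(group) < 2 or len(control) < 2:
        raise ValueError("need >= 2 replicates per group")
    a = matrix.values[group].to_numpy(dtype=float)
    b = matrix.values[control].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant genes (exact ties after quantile normalization)
        # trip scipy's precision-loss warning; they are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        zero_diff = degenerate & (log2fc == 0)
        t = np.where(zero_diff, 0.0, t)
        p = np.where(zero_diff, 1.0, p)
        nonzero = degenerate & (log2fc != 0)
        t = np.where(nonzero, np.copysign(np.inf, log2fc), t)
        p = np.where(nonzero, 0.0, p)
        logger.info("degenerate zero-variance genes: %d", int(degenerate.sum()))
    out = pd.DataFrame({"log2fc": log2fc, "t": t, "p": p}, index=matrix.values.index)
    return ComparisonResult(label or "comparison", out)


@dataclass
class DegSet:
    """Union DEG selection across comparisons with overlap accounting."""

    genes: list[str]
    per_comparison: dict[str, int]
    pairwise_overlaps: dict[tuple[str, str], int]
    alpha: float
    n_genes_universe: int

    @property
    def total_calls(self) -> int:
        """Significant calls summed over comparisons (a gene hit twice
        counts twice)."""
        return sum(self.per_comparison.values())


def select_degs(results: list[ComparisonResult], alpha: float = 0.001) -> DegSet:
    """Union of genes significant (p < alpha) in >= 1 comparison."""
    if not results:
        raise ValueError("need >= 1 comparison")
    universe = results[0].genes
    for r in results[1:]:
        if not universe.equals(r.genes):
            raise ValueError("inconsistent gene universes across comparisons")
    sig = {r.label: set(r.significant(alpha)) for r in results}
    union: set[str] = set().union(*sig.values())
    labels = [r.label for r in results]
    overlaps = {
        (la, lb): len(sig[la] & sig[lb])
        for i, la in enumerate(labels)
        for lb in labels[i + 1:]
    }
    return DegSet(
        genes=sorted(union),
        per_comparison={la: len(sig[la]) for la in labels},
        pairwise_overlaps=overlaps,
        alpha=alpha,
        n_genes_universe=len(universe),
    )


def estimate_fdr(
    deg_set_or_calls: DegSet | int,
    n_genes: int | None = None,
    n_comparisons: int | None = None,
    alpha: float | None = None,
) -> float:
    """Expected-false-positive FDR: (comparisons x genes x alpha) divided
    by the total significant calls across comparisons."""
    if isinstance(deg_set_or_calls, DegSet):
        ds = deg_set_or_calls
        calls = ds.total_calls
        n_genes = n_genes if n_genes is not None else ds.n_genes_universe
        n_comparisons = n_comparisons if n_comparisons is not None else len(ds.per_comparison)
        alpha = alpha if alpha is not None else ds.alpha
    else:
        calls = int(deg_set_or_calls)
        if None in (n_genes, n_comparisons, alpha):
            raise ValueError("n_genes, n_comparisons and alpha are required")
    if calls <= 0:
        raise ValueError("FDR undefined with zero significant calls")
    return min(1.0, n_comparisons * n_genes * alpha / calls)


def pca_scores(values: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores and variance fractions from the centered SVD of a
    gene x sample matrix (genes are variables, samples observations)."""
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need >= 2 genes and >= 2 samples")
    X = values.to_numpy(dtype=float).T  # samples x genes
    Xc = X - X.mean(axis=0)
    total = float(np.sum(Xc**2))
    if total == 0:
        raise ValueError("no variance in the matrix")
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U * S
    frac = S**2 / total
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=values.columns, columns=cols), frac


@dataclass
class HeatmapResult:
    log2fc: pd.DataFrame       # genes x comparisons, clustered row order
    linkage: np.ndarray | None
    leaf_order: list[str]
    missing_genes: list[str]


def log2fc_heatmap(
    matrix: ExpressionMatrix,
    comparisons: list[tuple[str, list[str] | tuple[str, str], list[str] | tuple[str, str]]],
    gene_list: list[str],
    metric: str = "euclidean",
    method: str = "average",
) -> HeatmapResult:
    """Per-gene mean log2FC per comparison for the listed genes, rows
    ordered by hierarchical clustering (Euclidean distance, average
    linkage by default).  Genes absent from the matrix are reported and
    skipped."""
    if not gene_list:
        raise ValueError("gene list is empty")
    present = [g for g in gene_list if g in matrix.values.index]
    missing = [g for g in gene_list if g not in matrix.values.index]
    if missing:
        logger.info("genes absent from the matrix: %s", missing)
    if not present:
        raise ValueError("no listed gene is present in the matrix")
    cols = {}
    for label, group, control in comparisons:
        g = matrix.group(*group) if isinstance(group, tuple) else group
        c = matrix.group(*control) if isinstance(control, tuple) else control
        sub = matrix.values.loc[present]
        cols[label] = sub[g].mean(axis=1) - sub[c].mean(axis=1)
    fc = pd.DataFrame(cols)
    if len(fc) == 1:
        return HeatmapResult(fc, None, list(fc.index), missing)
    Z = hierarchy.linkage(pdist(fc.to_numpy(), metric=metric), method=method)
    order = hierarchy.leaves_list(Z)
    fc = fc.iloc[order]
    return HeatmapResult(fc, Z, list(fc.index), missing)


def render_heatmap(result: HeatmapResult, path) -> None:
    """Write the clustered log2FC heatmap as a figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fc = result.log2fc
    fig, ax = plt.subplots(
        figsize=(1.2 + 0.6 * fc.shape[1], 1.5 + 0.22 * fc.shape[0])
    )
    vmax = float(np.abs(fc.to_numpy()).max()) or 1.0
    im = ax.imshow(fc.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(fc.shape[1]), fc.columns, rotation=45, ha="right")
    ax.set_yticks(range(fc.shape[0]), fc.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
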