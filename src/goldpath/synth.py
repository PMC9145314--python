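"""Synthetic raw data with known ground truth for every pipeline stage.

The generators emulate the study conditions: 2-fold dose series with
replicate viability/IL-1beta readouts following exponential/Hill curves
with multiplicative log-normal noise; 8-point 2-fold ELISA standard
plates; and an Agilent-style feature table of ~10,246 genes x 24 samples
(8 conditions x 3 replicates) with scanner-like quality flags, spiked
DEGs and pathway-coherent shifts.  Every generator is deterministic per
seed, and ground truth is carried alongside the generated data so
recovery tests never re-derive it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import StandardCurve5PL
from .fitting import DoseResponseDataset
from .models import ModelSpec, bmd_closed_form, eval_model

#: default 2-fold dose series (ug/mL): control + 6 points
DEFAULT_DOSES = (0.0, 3.125, 6.25, 12.5, 25.0, 50.0, 100.0)

#: the 8 study conditions: cell line x exposure
DEFAULT_CONDITIONS = (
    ("WT", "control"), ("WT", "GNP-1"), ("WT", "GNP-4"), ("WT", "GNP-6"),
    ("ASC-def", "control"), ("ASC-def", "GNP-6"),
    ("NLRP3-def", "control"), ("NLRP3-def", "GNP-6"),
)


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseTruth:
    """Generating model, design, and noise for one endpoint."""

    spec: ModelSpec
    doses: tuple[float, ...] = DEFAULT_DOSES
    n_replicates: int = 3
    log_sd: float = 0.10
    seed: int = 0
    endpoint_label: str = "viability"

    def true_bmd(self, bmr: float) -> float:
        return bmd_closed_form(self.spec, bmr)


def gen_dose_response(truth: DoseResponseTruth) -> DoseResponseDataset:
    """responses = curve(dose) x exp(N(0, log_sd)); replicate experiments
    are tagged and pooled, matching how replicate runs are analysed."""
    rng = np.random.default_rng(truth.seed)
    doses = np.repeat(truth.doses, truth.n_replicates)
    experiment = np.tile(np.arange(truth.n_replicates), len(truth.doses))
    mean = np.asarray(eval_model(truth.spec, doses), dtype=float)
    noise = rng.normal(0.0, truth.log_sd, size=len(doses)) if truth.log_sd > 0 else 0.0
    responses = mean * np.exp(noise)
    return DoseResponseDataset(
        doses=doses, responses=responses,
        endpoint_label=truth.endpoint_label, experiment=experiment,
    )


#: default generating curves for the three particle shapes, echoing the
#: qualitative pattern of the study: the rod-like condition loses
#: viability and gains IL-1beta with dose; star/sphere-like conditions
#: stay flat in viability with a mild IL-1beta decline.
def default_endpoint_truths(seed: int = 0) -> dict[str, DoseResponseTruth]:
    return {
        "rod_viability": DoseResponseTruth(
            ModelSpec("exponential", 3, a=100.0, b=-0.002, d=1.5),
            seed=seed, endpoint_label="viability"),
        "rod_il1b": DoseResponseTruth(
            ModelSpec("exponential", 5, a=40.0, b=0.05, c=6.0, d=1.0),
            log_sd=0.25, seed=seed + 1, endpoint_label="IL-1b"),
        "star_viability": DoseResponseTruth(
            ModelSpec("exponential", 1, a=100.0),
            seed=seed + 2, endpoint_label="viability"),
        "star_il1b": DoseResponseTruth(
            ModelSpec("exponential", 2, a=40.0, b=-0.014),
            log_sd=0.25, seed=seed + 3, endpoint_label="IL-1b"),
        "sphere_viability": DoseResponseTruth(
            ModelSpec("exponential", 1, a=100.0),
            seed=seed + 4, endpoint_label="viability"),
        "sphere_il1b": DoseResponseTruth(
            ModelSpec("exponential", 2, a=40.0, b=-0.014),
            log_sd=0.25, seed=seed + 5, endpoint_label="IL-1b"),
    }


# ---------------------------------------------------------------------------
# ELISA plates
# ---------------------------------------------------------------------------

@dataclass
class ElisaTruth:
    """True calibration and in-well sample concentrations for a plate."""

    curve: StandardCurve5PL = field(default_factory=lambda: StandardCurve5PL(
        lower=0.05, upper=2.4, c50=120.0, slope=-1.3, asymmetry=1.0))
    top_standard: float = 500.0   # pg/mL, 8-point 2-fold series below
    n_standard_points: int = 8
    sample_conc: tuple[float, ...] = (15.0, 60.0, 240.0)
    wells_per_condition: int = 4
    od_sd: float = 0.0
    dilution_factor: int = 20
    seed: int = 0

    def standard_series(self) -> np.ndarray:
        return self.top_standard / 2.0 ** np.arange(self.n_standard_points)


def gen_elisa_plate(truth: ElisaTruth) -> pd.DataFrame:
    """Plate table (well, role, concentration, OD): 8-point 2-fold
    standards + blank + replicate sample wells, ODs from the true 5PL
    plus additive noise."""
    rng = np.random.default_rng(truth.seed)
    rows = []
    well = itertools.count(1)
    for conc in truth.standard_series():
        for _ in range(2):
            rows.append((f"W{next(well):03d}", "standard", conc,
                         float(truth.curve.eval(conc))))
    for _ in range(2):
        rows.append((f"W{next(well):03d}", "blank", 0.0, truth.curve.lower))
    for i, conc in enumerate(truth.sample_conc):
        for _ in range(truth.wells_per_condition):
            rows.append((f"W{next(well):03d}", f"sample_{i + 1}", np.nan,
                         float(truth.curve.eval(conc))))
    plate = pd.DataFrame(rows, columns=["well", "role", "concentration", "OD"])
    if truth.od_sd > 0:
        plate["OD"] += rng.normal(0.0, truth.od_sd, size=len(plate))
    return plate


# ---------------------------------------------------------------------------
# expression matrix with feature-level flags
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTruth:
    """Design and effects for the synthetic feature-level expression data.

    Spiked DEGs are (gene index, cell_line, exposure, log2fc) rows;
    coherent set shifts move every member of a named synthetic gene set
    by a common mean in one condition (the pathway-level signal GSEA
    should recover).
    """

    n_genes: int = 10246
    conditions: tuple[tuple[str, str], ...] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    baseline_mean: tuple[float, float] = (8.0, 2.0)   # log2 mean ~ N(8, 2)
    within_sd: float = 0.25
    probes_per_gene: tuple[int, int] = (1, 3)
    flag_fail_rate: float = 0.0
    control_fraction: float = 0.0
    spikes: pd.DataFrame | None = None                # gene, cell_line, exposure, log2fc
    set_shifts: pd.DataFrame | None = None            # set_name, cell_line, exposure, shift
    gene_sets: dict[str, list[str]] | None = None
    seed: int = 0

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


def default_expression_truth(
    n_genes: int = 10246, seed: int = 0, n_spiked: int = 40,
    spike_log2fc: float = 2.0, set_size: int = 30, set_shift: float = -1.0,
) -> ExpressionTruth:
    """Study-shaped truth: DEGs spiked predominantly in the rod-exposed
    (GNP-6) conditions, plus coherent downward shifts of a
    cholesterol-synthesis-like and an oxidative-phosphorylation-like set
    in the rod-exposed wildtype condition."""
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    names = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    chosen = rng.choice(n_genes, size=n_spiked + 2 * set_size, replace=False)
    spiked = chosen[:n_spiked]
    sets = {
        "CHOLESTEROL_SYNTHESIS_LIKE": [names[i] for i in chosen[n_spiked:n_spiked + set_size]],
        "OXPHOS_LIKE": [names[i] for i in chosen[n_spiked + set_size:]],
    }
    rod_conditions = [("WT", "GNP-6"), ("ASC-def", "GNP-6"), ("NLRP3-def", "GNP-6")]
    rows = []
    for k, g in enumerate(spiked):
        cell, exp = rod_conditions[k % len(rod_conditions)]
        sign = 1.0 if k % 4 else -1.0
        rows.append((names[g], cell, exp, sign * spike_log2fc))
    shifts = pd.DataFrame(
        [("CHOLESTEROL_SYNTHESIS_LIKE", "WT", "GNP-6", set_shift),
         ("OXPHOS_LIKE", "WT", "GNP-6", set_shift)],
        columns=["set_name", "cell_line", "exposure", "shift"],
    )
    return ExpressionTruth(
        n_genes=n_genes,
        spikes=pd.DataFrame(rows, columns=["gene", "cell_line", "exposure", "log2fc"]),
        set_shifts=shifts, gene_sets=sets, seed=seed,
    )


def gen_expression(truth: ExpressionTruth) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (feature_table, sample_sheet, gene_truth).

    feature_table: one row per probe (1-3 probes/gene) with the five
    quality flags and one raw-intensity column per sample (intensities =
    2^log2signal).  sample_sheet: sample, cell_line, exposure, replicate.
    gene_truth: per-gene true mean log2 expression per condition.
    """
    rng = np.random.default_rng(truth.seed)
    genes = truth.gene_names()
    n = truth.n_genes
    conditions = list(truth.conditions)
    samples = []
    for cell, exp in conditions:
        for rep in range(1, truth.n_replicates + 1):
            samples.append((f"{cell}_{exp}_r{rep}", cell, exp, rep))
    sheet = pd.DataFrame(samples, columns=["sample", "cell_line", "exposure", "replicate"]
                         ).set_index("sample")

    base = rng.normal(*truth.baseline_mean, size=n)
    cond_mean = {cond: base.copy() for cond in conditions}
    if truth.spikes is not None:
        gene_pos = {g: i for i, g in enumerate(genes)}
        for _, row in truth.spikes.iterrows():
            cond_mean[(row["cell_line"], row["exposure"])][gene_pos[row["gene"]]] += row["log2fc"]
    if truth.set_shifts is not None and truth.gene_sets:
        gene_pos = {g: i for i, g in enumerate(genes)}
        for _, row in truth.set_shifts.iterrows():
            idx = [gene_pos[g] for g in truth.gene_sets[row["set_name"]]]
            cond_mean[(row["cell_line"], row["exposure"])][idx] += row["shift"]

    log2sig = np.empty((n, len(sheet)))
    for j, (_, meta) in enumerate(sheet.iterrows()):
        mu = cond_mean[(meta["cell_line"], meta["exposure"])]
        log2sig[:, j] = mu + rng.normal(0.0, truth.within_sd, size=n)

    # expand genes to probes with small probe offsets
    n_probes = rng.integers(truth.probes_per_gene[0],
                            truth.probes_per_gene[1] + 1, size=n)
    gene_idx = np.repeat(np.arange(n), n_probes)
    probe_offset = rng.normal(0.0, 0.15, size=len(gene_idx))
    probe_log2 = log2sig[gene_idx] + probe_offset[:, None]
    feature_ids = [f"P{k + 1:07d}" for k in range(len(gene_idx))]

    table = pd.DataFrame({"feature_id": feature_ids,
                          "symbol": [genes[i] for i in gene_idx]})
    m = len(table)
    fr = truth.flag_fail_rate
    table["above_noise"] = rng.random(m) >= fr
    table["below_saturation"] = rng.random(m) >= fr
    table["population_outlier"] = rng.random(m) < fr
    table["uniform_spot"] = rng.random(m) >= fr
    table["is_control"] = rng.random(m) < truth.control_fraction
    for j, s in enumerate(sheet.index):
        table[s] = 2.0 ** probe_log2[:, j]

    gene_truth = pd.DataFrame(
        {f"{cell}|{exp}": cond_mean[(cell, exp)] for cell, exp in conditions},
        index=pd.Index(genes, name="symbol"),
    )
    return table, sheet, gene_truth
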