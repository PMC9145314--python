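"""End-to-end orchestration: synth -> assay -> bmd -> microarray -> gsea.

A single validated config drives every stage; stages communicate only
through the files they declare, and a manifest (inputs, parameters,
seeds, outputs, checksums) makes a run reproducible: identical config
and seeds give identical checksums for all tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assays, gsea, microarray, synth
from .bmd import benchmark_dose_analysis
from .fitting import DoseResponseDataset

logger = logging.getLogger(__name__)

DEFAULTS = {
    "stages": {"synth": True, "assay": True, "bmd": True,
               "microarray": True, "gsea": True},
    "seed": 17,
    "alpha": 0.001,          # DEG significance per comparison
    "bmr": 0.10,             # benchmark response
    "ci_level": 0.90,
    "lrt_alpha": 0.05,
    "n_perm": 200,           # GSEA permutations
    "n_genes": 1500,         # synthetic expression size for the demo
    "out_dir": "pipeline_out",
    "inputs": {},            # used when the synth stage is disabled
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict | str | Path | None) -> dict:
    """Fill defaults, check ranges and referenced paths; aggregate all
    problems into a single error."""
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULTS))  # deep copy
    for key, val in config.items():
        if key == "stages":
            cfg["stages"].update(val)
        else:
            cfg[key] = val
    errors = []
    unknown = set(cfg) - set(DEFAULTS)
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    for name in ("alpha", "bmr", "lrt_alpha"):
        if not 0 < cfg[name] < 1:
            errors.append(f"{name} must be in (0, 1), got {cfg[name]}")
    if not 0 < cfg["ci_level"] < 1:
        errors.append(f"ci_level must be in (0, 1), got {cfg['ci_level']}")
    if cfg["n_perm"] < 100:
        errors.append("n_perm must be >= 100")
    if int(cfg["seed"]) < 0:
        errors.append("seed must be >= 0")
    if not cfg["stages"]["synth"]:
        for key in ("dose_response", "features", "sample_sheet"):
            path = cfg["inputs"].get(key)
            if path is None:
                errors.append(f"synth disabled but inputs.{key} not given")
            elif not Path(path).exists():
                errors.append(f"inputs.{key} does not exist: {path}")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path | None) -> dict:
    """Execute the enabled stages and return the manifest (also written
    to <out_dir>/manifest.json)."""
    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"config": cfg, "stages": {}}
    outputs: dict[str, list[str]] = {}

    def declare(stage: str, path: Path) -> Path:
        outputs.setdefault(stage, []).append(str(path))
        return path

    # ---- synth ------------------------------------------------------------
    if cfg["stages"]["synth"]:
        sdir = out / "synthetic"
        sdir.mkdir(exist_ok=True)
        truths = synth.default_endpoint_truths(seed=seed)
        dr_frames = []
        truth_rows = []
        for name, truth in truths.items():
            ds = synth.gen_dose_response(truth)
            df = ds.to_frame()
            df["series"] = name
            dr_frames.append(df)
            spec = truth.spec
            truth_rows.append((name, spec.name, spec.a, spec.b, spec.c, spec.d,
                               truth.log_sd))
        pd.concat(dr_frames).to_csv(declare("synth", sdir / "dose_response.csv"),
                                    index=False)
        pd.DataFrame(truth_rows, columns=["series", "model", "a", "b", "c", "d",
                                          "log_sd"]).to_csv(
            declare("synth", sdir / "dose_response_truth.csv"), index=False)

        elisa_truth = synth.ElisaTruth(seed=seed + 100, od_sd=0.01)
        plate = synth.gen_elisa_plate(elisa_truth)
        plate.to_csv(declare("synth", sdir / "elisa_plate.csv"), index=False)
        pd.DataFrame({"sample": [f"sample_{i+1}" for i in range(len(elisa_truth.sample_conc))],
                      "true_conc": elisa_truth.sample_conc}).to_csv(
            declare("synth", sdir / "elisa_truth.csv"), index=False)

        etruth = synth.default_expression_truth(n_genes=int(cfg["n_genes"]),
                                                seed=seed + 200)
        table, sheet, gene_truth = synth.gen_expression(etruth)
        table.to_csv(declare("synth", sdir / "features.tsv"), sep="\t", index=False)
        sheet.to_csv(declare("synth", sdir / "sample_sheet.tsv"), sep="\t")
        gene_truth.to_csv(declare("synth", sdir / "gene_truth.tsv"), sep="\t")
        gsea.GmtCollection(etruth.gene_sets,
                           {k: "synthetic" for k in etruth.gene_sets}).to_gmt(
            declare("synth", sdir / "gene_sets.gmt"))
        inputs = {"dose_response": sdir / "dose_response.csv",
                  "features": sdir / "features.tsv",
                  "sample_sheet": sdir / "sample_sheet.tsv",
                  "elisa_plate": sdir / "elisa_plate.csv",
                  "gene_sets": sdir / "gene_sets.gmt"}
    else:
        inputs = {k: Path(v) for k, v in cfg["inputs"].items()}

    # ---- assay ------------------------------------------------------------
    if cfg["stages"]["assay"] and "elisa_plate" in inputs:
        adir = out / "assay"
        adir.mkdir(exist_ok=True)
        plate = pd.read_csv(inputs["elisa_plate"])
        curve = assays.fit_5pl_from_plate(plate)
        with open(declare("assay", adir / "calibration_5pl.json"), "w") as fh:
            json.dump({"lower": curve.lower, "upper": curve.upper,
                       "c50": curve.c50, "slope": curve.slope,
                       "asymmetry": curve.asymmetry, "rss": curve.rss,
                       "monotone_standards": curve.monotone_standards},
                      fh, indent=2)
        rows = []
        for role, grp in plate[plate["role"].str.startswith("sample")].groupby("role"):
            od = float(grp["OD"].mean())
            try:
                conc = assays.invert_5pl(curve, od)
                flag = ""
            except assays.OutOfRangeError:
                conc, flag = float("nan"), "out_of_range"
            rows.append((role, od, conc, flag))
        pd.DataFrame(rows, columns=["sample", "mean_od", "conc_pg_ml", "flag"]).to_csv(
            declare("assay", adir / "elisa_samples.tsv"), sep="\t", index=False)

    # ---- bmd --------------------------------------------------------------
    if cfg["stages"]["bmd"]:
        bdir = out / "bmd"
        bdir.mkdir(exist_ok=True)
        dr = pd.read_csv(inputs["dose_response"])
        report = {}
        rows = []
        series = dr["series"].unique() if "series" in dr.columns else [None]
        for name in series:
            sub = dr[dr["series"] == name] if name is not None else dr
            ds = DoseResponseDataset.from_frame(sub)
            rep = benchmark_dose_analysis(
                ds, bmr=cfg["bmr"], alpha=cfg["lrt_alpha"],
                ci_level=cfg["ci_level"])
            key = name or "endpoint"
            report[key] = rep.to_dict()
            if rep.result:
                rows.append((key, rep.result.averaged_bmd,
                             rep.result.ci90[0], rep.result.ci90[1],
                             ";".join(rep.result.accepted_models)))
            else:
                rows.append((key, float("nan"), float("nan"), float("nan"),
                             "no dose-response"))
        with open(declare("bmd", bdir / "bmd_report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        pd.DataFrame(rows, columns=["series", "bmd", "bmdl", "bmdu",
                                    "accepted_models"]).to_csv(
            declare("bmd", bdir / "bmd_summary.tsv"), sep="\t", index=False)

    # ---- microarray -------------------------------------------------------
    comparisons = [
        ("GNP-1_vs_C_WT", ("WT", "GNP-1"), ("WT", "control")),
        ("GNP-4_vs_C_WT", ("WT", "GNP-4"), ("WT", "control")),
        ("GNP-6_vs_C_WT", ("WT", "GNP-6"), ("WT", "control")),
        ("GNP-6_vs_C_ASC-def", ("ASC-def", "GNP-6"), ("ASC-def", "control")),
        ("GNP-6_vs_C_NLRP3-def", ("NLRP3-def", "GNP-6"), ("NLRP3-def", "control")),
        ("WT-C_vs_ASC-def-C", ("ASC-def", "control"), ("WT", "control")),
        ("WT-C_vs_NLRP3-def-C", ("NLRP3-def", "control"), ("WT", "control")),
    ]
    results = None
    if cfg["stages"]["microarray"]:
        mdir = out / "microarray"
        mdir.mkdir(exist_ok=True)
        table = pd.read_csv(inputs["features"], sep="\t")
        sheet = pd.read_csv(inputs["sample_sheet"], sep="\t").set_index("sample")
        reliable = microarray.filter_reliable(table)
        norm = microarray.log2_quantile_normalize(reliable)
        collapsed = microarray.collapse_by_symbol(
            norm, reliable.set_index("feature_id")["symbol"])
        em = microarray.ExpressionMatrix(collapsed, sheet)
        collapsed.to_csv(declare("microarray", mdir / "normalized_matrix.tsv"),
                         sep="\t")
        results = [microarray.differential_expression(em, g, c, label=lbl)
                   for lbl, g, c in comparisons]
        for r in results:
            r.stats.to_csv(declare("microarray", mdir / f"stats_{r.label}.tsv"),
                           sep="\t")
        degs = microarray.select_degs(results, alpha=cfg["alpha"])
        fdr = microarray.estimate_fdr(degs)
        pd.Series(degs.genes, name="gene").to_csv(
            declare("microarray", mdir / "deg_union.tsv"), sep="\t", index=False)
        with open(declare("microarray", mdir / "deg_summary.json"), "w") as fh:
            json.dump({"per_comparison": degs.per_comparison,
                       "union_size": len(degs.genes),
                       "fdr": fdr, "alpha": degs.alpha},
                      fh, indent=2)
        if degs.genes:
            sub = collapsed.loc[degs.genes]
            if len(degs.genes) >= 2:
                scores, frac = microarray.pca_scores(sub)
                scores["explained_1"] = frac[0]
                scores.to_csv(declare("microarray", mdir / "pca_scores.tsv"),
                              sep="\t")
            hm = microarray.log2fc_heatmap(em, comparisons, degs.genes)
            hm.log2fc.to_csv(declare("microarray", mdir / "heatmap_log2fc.tsv"),
                             sep="\t")
            microarray.render_heatmap(hm, mdir / "heatmap.png")

    # ---- gsea -------------------------------------------------------------
    if cfg["stages"]["gsea"] and results is not None and "gene_sets" in inputs:
        gdir = out / "gsea"
        gdir.mkdir(exist_ok=True)
        collection = gsea.GmtCollection.from_gmt(inputs["gene_sets"])
        grids = {}
        for r in results:
            ranked = gsea.rank_genes(r.stats)
            res = gsea.permutation_significance(
                ranked, collection, n_perm=int(cfg["n_perm"]),
                seed=seed + 300)
            res.to_csv(declare("gsea", gdir / f"enrichment_{r.label}.tsv"),
                       sep="\t")
            grids[r.label] = res
        gsea.significant_sets(grids).to_csv(
            declare("gsea", gdir / "summary_grid.tsv"), sep="\t")

    # ---- manifest ---------------------------------------------------------
    for stage, paths in outputs.items():
        manifest["stages"][stage] = {
            "outputs": paths,
            "checksums": {p: _sha256(Path(p)) for p in paths
                          if not p.endswith(".png")},
        }
    manifest["seed"] = seed
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
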