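"""End-to-end benchmark pipeline: simulate -> pseudobulk -> references ->
deconvolve -> evaluate.

The run configuration is a plain mapping (usually loaded from YAML); every
stage draws its randomness from the global seed through named streams, so a
rerun with the same configuration is bit-identical. Artifacts and a
provenance record are written under the output directory when one is given.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import deconv, demux, evaluation, io, pseudobulk, reference, simulate
from .errors import RegistryError

__all__ = ["default_config", "run_pipeline"]


def default_config() -> dict:
    """Desk-scale defaults for a full benchmark run."""
    return {
        "seed": 0,
        "cohort": {},  # CohortConfig keyword overrides
        "bulk": {
            "depth": 5_000_000,
            "protocols": ["rRNA_chunk", "rRNA_dissociated", "polyA_dissociated"],
        },
        "pseudobulk": {
            "scenarios": ["realistic", "even", "sparse", "weighted"],
            "n_cells": 2000,
            "n_samples": 50,
            "noise_sd": 0.01,
        },
        "reference_ladder": [2000, 1000, 500, 200],
        "demux": {
            "thresholds": [0.90, 0.85, 0.80],
            "doublet_rate": 0.04,
            "hash_adhesion": 0.9,
        },
        "methods": ["nnls"],
        "anova_factors": list(evaluation.DEFAULT_ANOVA_FACTORS),
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None = None, out: Path | None = None) -> evaluation.EvaluationReport:
    """Execute the full benchmark and return its evaluation report."""
    cfg = _merge(default_config(), config or {})
    seed = int(cfg["seed"])

    # fail fast on unknown methods before any simulation
    for m in cfg["methods"]:
        if m not in deconv.available_methods():
            raise RegistryError(
                f"unknown method {m!r}; registered: {deconv.available_methods()}"
            )
    presets = simulate.protocol_presets()
    for p in cfg["bulk"]["protocols"]:
        if p not in presets:
            raise RegistryError(f"unknown protocol {p!r}; available: {sorted(presets)}")

    # --- stage 1: single-cell cohort -----------------------------------
    cohort = simulate.CohortConfig(rng_seed=seed, **cfg["cohort"])
    dataset = simulate.generate_reference(cohort, seed=seed)
    tumors = [str(t) for t in dataset.obs["sample_id"].cat.categories]

    # --- stage 2: demultiplexing ----------------------------------------
    half = len(tumors) // 2 or 1
    pools = [tumors[:half], tumors[half:]] if len(tumors) > 1 else [tumors]
    pairs = simulate.generate_assignment_tables(
        dataset, pools,
        hash_adhesion=cfg["demux"]["hash_adhesion"],
        doublet_rate=cfg["demux"]["doublet_rate"],
        seed=seed,
    )
    demux_rows = []
    hash_labels_parts = []
    for i, (hash_t, gen_t) in enumerate(pairs):
        for thr in cfg["demux"]["thresholds"]:
            for tbl in (hash_t, gen_t):
                summary = demux.summarize_assignments(demux.call_assignments(tbl, thr))
                demux_rows.append({
                    "pool": i, "modality": tbl.modality, "threshold": thr,
                    "n_total": summary.n_total, **summary.counts,
                    **{f"pct_{k}": v for k, v in summary.percents.items()},
                })
        hash_labels_parts.append(demux.call_assignments(hash_t, 0.90).labels)
    demux_table = pd.DataFrame(demux_rows)
    hash_labels = demux.DemuxLabels(labels=pd.concat(hash_labels_parts), threshold=0.90)

    # --- stage 3: references (size ladder + hash-assigned subset) -------
    references: dict[str, object] = {"full": dataset}
    for size in cfg["reference_ladder"]:
        if size < dataset.n_obs:
            references[str(size)] = reference.downsample_reference(dataset, size, seed=seed)
    try:
        references["hash_subset"] = reference.subset_by_labels(dataset, hash_labels)
    except Exception:
        pass  # a degenerate demux run just skips the subset reference
    signatures = {tag: deconv.build_signature(ref) for tag, ref in references.items()}

    # --- stage 4: matched bulk samples ----------------------------------
    bulks = [
        simulate.generate_bulk(dataset, tumor, presets[p],
                               depth=int(cfg["bulk"]["depth"]), seed=seed)
        for tumor in tumors
        for p in cfg["bulk"]["protocols"]
    ]

    # --- stage 5: deconvolution -----------------------------------------
    bulk_results = [
        deconv.deconvolve(signatures[tag], b, method=m, reference_tag=tag,
                          min_gene_overlap=min(200, dataset.n_vars // 2))
        for b in bulks
        for tag in signatures
        for m in cfg["methods"]
    ]
    bulk_df = evaluation.results_to_frame(bulk_results)

    # --- stage 6: pseudo-bulk scenarios ---------------------------------
    pb_est_rows, pb_truth_rows = [], []
    for scenario in cfg["pseudobulk"]["scenarios"]:
        sc_cfg = pseudobulk.ScenarioConfig(
            scenario=scenario,
            n_cells=int(cfg["pseudobulk"]["n_cells"]),
            n_samples=int(cfg["pseudobulk"]["n_samples"]),
            noise_sd=float(cfg["pseudobulk"]["noise_sd"]),
            seed=seed,
        )
        samples = pseudobulk.build_scenario_dataset(dataset, sc_cfg, seed=seed)
        for i, s in enumerate(samples):
            sid = f"{s.source_sample}:{scenario}:{i:03d}"
            for m in cfg["methods"]:
                res = deconv.deconvolve(
                    signatures["full"], s.counts.rename(sid), method=m,
                    reference_tag="full",
                    min_gene_overlap=min(200, dataset.n_vars // 2))
                for ct, frac in res.fractions.items():
                    pb_est_rows.append({"method": m, "sample": sid, "scenario": scenario,
                                        "cell_type": ct, "fraction": frac})
            for ct, frac in s.truth_rna_fraction.items():
                pb_truth_rows.append({"sample": sid, "scenario": scenario,
                                      "cell_type": ct, "fraction": frac})
    pb_est = pd.DataFrame(pb_est_rows)
    pb_truth = pd.DataFrame(pb_truth_rows)

    # --- stage 7: evaluation --------------------------------------------
    report = evaluation.EvaluationReport()
    report.rmse = evaluation.rmse(pb_est, pb_truth, group_cols=("method", "scenario"))
    report.differences = evaluation.proportion_differences(
        pb_est, pb_truth, group_cols=("method", "scenario"))

    full_bulk = bulk_df[bulk_df["reference_tag"] == "full"]
    report.variance_bulk = evaluation.robustness_variance(full_bulk, vary="protocol")

    ref_df = bulk_df.copy()
    ref_df["sample"] = ref_df["sample"] + ":" + ref_df["protocol"]
    report.variance_reference = evaluation.robustness_variance(ref_df, vary="reference_tag")

    rmse_per_method = report.rmse.groupby("method", as_index=False)["rmse"].mean()
    report.summary = evaluation.accuracy_robustness_summary(
        rmse_per_method, report.variance_bulk)

    epi = bulk_df[bulk_df["cell_type"] == "epithelial"].copy()
    size_tags = {str(s) for s in cfg["reference_ladder"]}
    epi = epi[epi["reference_tag"].isin(size_tags | {"full"})]
    epi["reference_size"] = epi["reference_tag"]
    epi["enrichment"] = np.where(epi["protocol"].str.startswith("polyA"),
                                 "polyA", "rRNA_depletion")
    epi["dissociated"] = epi["protocol"].str.endswith("dissociated")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report.anova = evaluation.anova_factors(
            epi, response="fraction", factors=tuple(cfg["anova_factors"]))

    report.extras["demux_summary"] = demux_table
    report.extras["bulk_results"] = bulk_df
    report.extras["pseudobulk_estimates"] = pb_est
    report.extras["pseudobulk_truth"] = pb_truth

    # --- artifacts -------------------------------------------------------
    if out is not None:
        out = Path(out)
        io.write_single_cell(dataset, out / "reference")
        io.write_bulk(bulks, out / "bulk")
        for name, df in [
            ("rmse", report.rmse), ("differences", report.differences),
            ("variance_bulk", report.variance_bulk),
            ("variance_reference", report.variance_reference),
            ("summary", report.summary), ("anova", report.anova),
            ("demux_summary", demux_table),
            ("bulk_results", bulk_df),
        ]:
            io.write_table(df, out / f"{name}.tsv")
        io.write_provenance(out / "provenance.json", {
            "seed": seed, "config": cfg,
            "n_cells": int(dataset.n_obs), "n_genes": int(dataset.n_vars),
            "references": {k: int(v.n_obs) for k, v in references.items()},
        })
    return report
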