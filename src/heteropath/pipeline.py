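"""End-to-end orchestration: simulate -> QC -> statistics -> scan -> coloc -> path.

A run is driven by a nested configuration dictionary (YAML on disk)
with one block per stage.  Every stochastic stage derives its seed from
the run seed, so a configuration reproduces identical numerical output.
Artifacts are flat CSV/BED/JSON files so each stage can be re-run and
inspected independently.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, coloc, genotype_core, io, pathsem, quantgen, simdata

DEFAULT_CONFIG = {
    "seed": 1,
    "stages": ["simulate", "qc", "herit", "hormone", "scan", "coloc", "path"],
    "map": {"n_chrom": 10, "chrom_length_bp": 270_000_000, "n_markers": 1000},
    "pedigree": {
        "n_families": 300,
        "target_generation": 6,
        "selection_mode": "truncation-pht",
        "candidates_per_cross": 20,
    },
    "phenotypes": {"n_env": 5, "n_rep": 2},
    "assay": {"n_seedlings": 12, "n_replicates": 3},
    "genes": {"n_genes": 120, "enrichment": 0.3},
    "qc": {"maf_threshold": 0.05, "max_missing": 0.05, "rp_het_limit": 3, "knn_k": 5, "knn_window": 30},
    "scan": {"trait": "PHT", "alpha": 0.05, "c_fraction": 0.995},
    "coloc": {"bin_mb": 1.0, "n_sim": 10_000, "pathway": None, "n_top_fallback": 10},
    "path": {"n_min": 30},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(overrides: dict | None) -> dict:
    config = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def validate_config(config: dict) -> list:
    """Schema and cross-field checks; returns a list of issue strings."""
    issues = []
    if "seed" not in config or config["seed"] is None:
        issues.append("seed: missing; a seed is required for a reproducible run")
    known = set(DEFAULT_CONFIG["stages"])
    for stage in config.get("stages", []):
        if stage not in known:
            issues.append(f"stages: unknown stage {stage!r}")
    if config.get("coloc", {}).get("bin_mb", 1.0) <= 0:
        issues.append("coloc.bin_mb: must be positive")
    c = config.get("scan", {}).get("c_fraction", 0.995)
    if not 0 < c <= 1:
        issues.append("scan.c_fraction: must be in (0, 1]")
    alpha = config.get("scan", {}).get("alpha", 0.05)
    if not 0 < alpha < 1:
        issues.append("scan.alpha: must be in (0, 1)")
    ped = config.get("pedigree", {})
    if ped.get("n_families", 1) < 1:
        issues.append("pedigree.n_families: must be >= 1")
    if config.get("genes", {}).get("enrichment", 0) not in (None,) and not (
        0 <= config["genes"]["enrichment"] <= 1
    ):
        issues.append("genes.enrichment: must be in [0, 1]")
    return issues


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def run_end_to_end(config: dict | None = None, out_dir=None) -> dict:
    """Execute the enabled stages in dependency order; return the report.

    The report collects per-stage numerical summaries plus provenance
    (config hash, seed).  If ``out_dir`` is given, all intermediate
    artifacts and the report are written there.
    """
    config = merge_config(config)
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid configuration: " + "; ".join(issues))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = list(config["stages"])
    report: dict = {
        "provenance": {
            "seed": seed,
            "config_sha256": hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest(),
        }
    }
    if "simulate" not in stages:
        raise ValueError("stage 'simulate' is required as the data source")

    params = simdata.default_structural_params()
    gmap = simdata.simulate_genome_map(seed=_stage_seed(seed, "map"), **config["map"])
    spec = simdata.PedigreeSpec(seed=_stage_seed(seed, "pedigree"), **config["pedigree"])
    matrix, latent = simdata.simulate_bc_population(gmap, spec, params)
    rp_calls = simdata.simulate_rp_controls(gmap, seed=_stage_seed(seed, "rp"))
    pheno = simdata.simulate_phenotypes(
        matrix, params, seed=_stage_seed(seed, "pheno"), latent=latent,
        **config["phenotypes"],
    )
    assay = simdata.simulate_hormone_assay(
        matrix, params, seed=_stage_seed(seed, "assay"), latent=latent,
        **config["assay"],
    )
    report["simulate"] = {
        "n_entries": matrix.n_entries,
        "n_markers": matrix.n_markers,
        "mean_heterozygosity_pct": float(latent["heterozygosity_pct"].mean()),
    }
    if out is not None:
        io.write_marker_matrix(matrix, out / "calls.tsv", out / "markers.tsv")
        io.write_phenotypes(pheno, out / "phenotypes.csv")
        io.write_hormone_assay(assay, out / "hormone_assay.csv")

    if "qc" in stages:
        qc_cfg = config["qc"]
        matrix, qc_report = genotype_core.qc_markers(
            matrix,
            rp_calls,
            maf_threshold=qc_cfg["maf_threshold"],
            max_missing=qc_cfg["max_missing"],
            rp_het_limit=qc_cfg["rp_het_limit"],
        )
        if (matrix.calls.to_numpy() == genotype_core.MISSING).any():
            matrix = genotype_core.impute_knn(
                matrix, k=qc_cfg["knn_k"], window=qc_cfg["knn_window"]
            )
        report["qc"] = qc_report.as_dict()
        if out is not None:
            io.write_json(qc_report.as_dict(), out / "qc_report.json")

    het = genotype_core.heterozygosity(matrix)
    dgp = genotype_core.donor_genome_proportion(het)
    report["genotype"] = {
        "mean_dgp_pct": float(dgp.mean()),
        "expected_dgp_pct": genotype_core.expected_dgp(spec.target_generation),
    }

    if "herit" in stages:
        vc = quantgen.variance_components(pheno, "PHT")
        report["herit"] = {
            "sigma2_g": vc.sigma2_g,
            "sigma2_ge": vc.sigma2_ge,
            "sigma2_e": vc.sigma2_e,
            "h2_PHT": quantgen.entry_mean_heritability(vc),
        }

    responses = quantgen.hormone_response(assay)
    entry_means = (
        pheno[pheno["trait"] == "PHT"].groupby("entry")["value"].mean().rename("PHT")
    )
    if "hormone" in stages:
        table = responses.join(entry_means).join(het)
        corr, _ = quantgen.correlation_table(table)
        pred = quantgen.predict_pht(responses, entry_means)
        report["hormone"] = {
            "correlations": corr.round(4).to_dict(),
            "prediction_r": pred["r"],
        }
        if out is not None:
            corr.to_csv(out / "correlations.csv")

    hits = None
    if "scan" in stages:
        q_frac = np.clip(het.to_numpy() / 100.0, 0.01, 0.99)
        Q = pd.DataFrame(
            {"anc_rp": 1.0 - q_frac, "anc_donor": q_frac}, index=het.index
        )
        results = assoc.glm_q_scan(matrix, entry_means, Q, trait="PHT")
        plan = assoc.MultipleTestingPlan.from_genotypes(
            matrix, alpha_family=config["scan"]["alpha"], C=config["scan"]["c_fraction"]
        )
        hits = assoc.declare_hits(results, plan.threshold)
        report["scan"] = {
            "n_tested": len(results),
            "m_eff": plan.m_eff,
            "threshold": plan.threshold,
            "n_hits": len(hits),
        }
        if out is not None:
            results.to_csv(out / "assoc_results.csv", index=False)
            hits.to_csv(out / "assoc_hits.csv", index=False)

    if "coloc" in stages:
        if hits is None:
            report["coloc"] = {"note": "scan stage disabled; test skipped"}
        else:
            note = None
            if hits.empty:
                # no genome-wide significant marker: use the top-ranked
                # markers so the enrichment machinery is still exercised
                n_top = int(config["coloc"].get("n_top_fallback", 10))
                hits = results.sort_values("p_value").head(n_top)
                note = f"no significant SNPs; top {n_top} markers used"
            causal = hits[["chrom", "bp"]]
            genes = simdata.simulate_candidate_genes(
                gmap,
                n_genes=config["genes"]["n_genes"],
                causal_snps=causal,
                enrichment=config["genes"]["enrichment"],
                seed=_stage_seed(seed, "genes"),
            )
            all_snps = matrix.markers.reset_index()
            result = coloc.coloc_test(
                hits[["marker", "chrom", "bp"]],
                all_snps,
                genes,
                bin_mb=config["coloc"]["bin_mb"],
                n_sim=config["coloc"]["n_sim"],
                seed=_stage_seed(seed, "coloc"),
                pathway=config["coloc"]["pathway"],
            )
            report["coloc"] = result.as_dict()
            if note:
                report["coloc"]["note"] = note
            if out is not None:
                io.write_genes_bed(genes, out / "candidate_genes.bed")
                result.capture_table.to_csv(out / "capture_table.csv", index=False)

    if "path" in stages:
        table = responses.join(entry_means).join(het)
        table = table.rename(
            columns={
                "heterozygosity_pct": "heterozygosity",
                "BR_response": "BR",
                "GA_response": "GA",
            }
        )[list(pathsem.DEFAULT_VARIABLES)].dropna()
        if len(table) < config["path"]["n_min"]:
            report["path"] = {"note": "too few complete entries for model search"}
        else:
            S = table.cov()
            search = pathsem.model_search(S, N=len(table))
            report["path"] = {
                "n_models": len(search.audit),
                "n_passing": len(search.passing_models),
                "best_edges": sorted(
                    f"{s}->{t}" for s, t in (search.best_edges() or [])
                ),
            }
            if out is not None:
                search.audit.to_csv(out / "path_audit.csv", index=False)

    if out is not None:
        io.write_json(report, out / "report.json")
    return report
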