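"""End-to-end orchestration: simulate → derive → score → stratify → sc-score.

A :class:`RunConfig` carries every stage parameter (defaults equal the
study-quoted values where one exists) plus a single global seed.  The seed
fans out to per-stage child seeds by a fixed derivation so any stage can be
re-run in isolation reproducibly.  ``run_all`` writes per-stage artifacts
and a versioned JSON report; identical (config, seed) yields byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bulk, io, sc, stratify
from .datamodel import METSIG_TFS, builtin_signature
from .simulate import BulkSimSpec, SCSimSpec, simulate_bulk_cohort, simulate_sc_dataset

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Parameters of one pipeline run (defaults are the study-quoted values)."""

    seed: int = 0
    out_dir: str = "metsig_run"
    anchor: str = "CDC42"
    tfs: tuple[str, ...] = METSIG_TFS
    alpha: float = 0.05
    rho_min: float = 0.4
    threshold: float = 1.0
    sc_k: int = 15
    n_pcs: int = 10
    qc_min_features: int = 500
    qc_max_features: int = 4500
    qc_max_mito: float = 0.20
    lfc_min: float = 0.25
    pct_min: float = 0.25
    use_builtin_signature: bool = False
    #: overrides for the coupled derivation cohort pair (tracked_fraction 1)
    derivation_bulk: dict = field(default_factory=dict)
    #: overrides for the mixed evaluation cohorts that are scored/stratified
    bulk_a: dict = field(default_factory=dict)
    bulk_b: dict = field(default_factory=dict)
    sc_spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.rho_min < 1.0:
            raise ValueError("rho_min must lie in (0, 1)")
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            obj = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "tfs" in obj:
            obj["tfs"] = tuple(obj["tfs"])
        return cls(**obj)


def child_seeds(seed: int, n: int) -> list[int]:
    """Fixed fan-out of the global seed into per-stage child seeds."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _log(stage: str, **payload) -> None:
    print(json.dumps({"stage": stage, **payload}, sort_keys=True), file=sys.stderr)


def _round(x: float, nd: int = 6) -> float:
    return float(round(float(x), nd))


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed, 6)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "parameters": {
            "alpha": config.alpha,
            "rho_min": config.rho_min,
            "threshold": config.threshold,
            "sc_k": config.sc_k,
        },
    }

    # --- simulate bulk cohorts ------------------------------------------
    # a coupled pair for derivation (the co-expression structure must hold
    # cohort-wide for the anchor-split DE chain) and a mixed pair, with
    # tracked and decoupled samples, for stratification
    stage = "simulate_bulk"
    try:
        deriv_kw = {"n_samples": 60, "tracked_fraction": 1.0, **config.derivation_bulk}
        spec_da = BulkSimSpec(**{"cohort": "DA", **deriv_kw, "seed": seeds[0]})
        spec_db = BulkSimSpec(**{"cohort": "DB", **deriv_kw, "seed": seeds[1]})
        mat_da, _, truth_da = simulate_bulk_cohort(spec_da)
        mat_db, _, _ = simulate_bulk_cohort(spec_db)
        spec_a = BulkSimSpec(**{"cohort": "A", **config.bulk_a, "seed": seeds[2]})
        spec_b = BulkSimSpec(**{"cohort": "B", **config.bulk_b, "seed": seeds[3]})
        (mat_a, ann_a, truth_a) = simulate_bulk_cohort(spec_a)
        (mat_b, ann_b, truth_b) = simulate_bulk_cohort(spec_b)
        io.write_counts_tsv(mat_a, out / "counts_A.tsv")
        io.write_counts_tsv(mat_b, out / "counts_B.tsv")
        io.write_annotation_csv(ann_a, out / "annotation_A.csv")
        io.write_annotation_csv(ann_b, out / "annotation_B.csv")
        _log(stage, cohorts=["DA", "DB", "A", "B"])
    except Exception as err:  # noqa: BLE001 - stage failures must name the stage
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    # --- derive ----------------------------------------------------------
    stage = "derive_signature"
    try:
        tfmap = {
            tf: set(truth_da.module_gene_ids) for tf in config.tfs
        }  # simulated TF map: the planted module is a target of every named TF
        decoys = [g for g in mat_da.gene_ids if g.startswith("G")][:200]
        tfmap[config.tfs[0]] = tfmap[config.tfs[0]] | set(decoys)
        io.write_gmt(tfmap, out / "tf_targets.gmt")
        if config.use_builtin_signature:
            signature = builtin_signature()
        else:
            signature = bulk.derive_signature(
                mat_da, mat_db, tfmap, set(config.tfs), config.anchor,
                alpha=config.alpha, rho_min=config.rho_min,
            )
        io.write_signature_json(signature, out / "signature.json")
        _log(stage, n_genes=len(signature))
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    stage = "score_stratify"
    try:
        per_cohort = {}
        for name, mat, ann, truth in (
            ("A", mat_a, ann_a, truth_a),
            ("B", mat_b, ann_b, truth_b),
        ):
            scores = bulk.metsig_score(mat, signature)
            model = stratify.fit_minmax_line(scores, threshold=config.threshold)
            strat = stratify.classify_inside(scores, model)
            assoc = stratify.associate_clinical(strat, scores, ann)
            table = scores.join(strat)
            table.reset_index().to_csv(out / f"stratification_{name}.csv", index=False)
            accuracy = float(np.mean(strat["inside"].to_numpy() == truth.tracked_mask))
            per_cohort[name] = {
                "inside_fraction": _round(assoc.inside_fraction),
                "clinical_rho": _round(assoc.corr.rho),
                "clinical_p": _round(assoc.corr.p_value, 10),
                "rank_test_p": _round(assoc.rank_test_p, 10),
                "accuracy_vs_truth": _round(accuracy),
                "planted_clinical_rho": _round(truth.true_clinical_link),
            }
        pooled_inside = np.mean(
            [per_cohort[c]["inside_fraction"] for c in per_cohort]
        )
        report["bulk"] = {
            "signature_genes": signature.genes,
            "anchor": signature.anchor_gene,
            "planted_module_recall": _round(
                len(set(signature.genes) & set(truth_da.module_gene_ids))
                / len(truth_da.module_gene_ids)
            ),
            "false_genes": len(set(signature.genes) - set(truth_da.module_gene_ids)),
            "per_cohort": per_cohort,
            "pooled_inside_fraction": _round(float(pooled_inside)),
        }
        _log(stage, **{k: v for k, v in report["bulk"].items() if k != "signature_genes"})
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    # --- single cell -----------------------------------------------------
    stage = "single_cell"
    try:
        sc_spec = SCSimSpec(**{**config.sc_spec, "seed": seeds[4]})
        adata = simulate_sc_dataset(sc_spec)
        io.write_sc_mtx(adata, out / "sc")
        filtered = sc.qc_filter(
            adata, config.qc_min_features, config.qc_max_features, config.qc_max_mito
        )
        norm = sc.lognormalize_cells(filtered)
        sc.cluster_cells(norm, k=config.sc_k, n_pcs=config.n_pcs, seed=seeds[5])
        # sc data carry the published gene symbols, so score with the
        # built-in six-gene signature regardless of the derived one
        cluster_scores = sc.cluster_metsig(norm, builtin_signature())
        hi = cluster_scores.index[cluster_scores["hi"]][0]
        markers = sc.find_markers(norm, hi, config.lfc_min, config.pct_min)
        cluster_scores.reset_index().to_csv(out / "cluster_scores.csv", index=False)
        markers.to_csv(out / "markers.csv", index=False)
        hi_truth = norm.obs.loc[norm.obs["cluster"] == hi, "true_cluster"]
        report["single_cell"] = {
            "cells_retained": int(filtered.n_obs),
            "qc_removed": filtered.uns["qc_removed"],
            "hi_cluster": int(hi),
            "hi_cluster_majority_truth": int(hi_truth.mode().iloc[0]),
            "planted_hi_cluster": sc_spec.hi_cluster_index,
            "n_markers": int(len(markers)),
            "cluster_metsig": {
                str(c): _round(v) for c, v in cluster_scores["metsig"].items()
            },
        }
        _log(stage, **{k: v for k, v in report["single_cell"].items()
                       if k not in ("cluster_metsig",)})
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    report_path = out / "report.json"
    with report_path.open("w", encoding="utf-8", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
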