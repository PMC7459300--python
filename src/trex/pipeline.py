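"""End-to-end orchestration: simulate -> qc -> demux -> repertoire -> score.

A single config dict (typically loaded from YAML) drives the stages; every
stage logs its decision counts into a machine-readable run summary that is
sufficient to reproduce the run (parameters, seeds, package version).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .demux import DemuxRules, demultiplex
from .overlap import direction_consistent_overlap, extract_degs
from .qc import lognormalize, qc_filter
from .repertoire import build_clonotype_table, repeat_spectrum, shannon_equitability
from .scoring import signature_score
from .synthetic import SyntheticConfig, generate_cohort, truth_cluster_labels, write_cohort
from .tcr import cell_chains, read_contigs, usable_contigs
from .tenx import read_cluster_labels, read_matrix_dir, write_matrix_dir, y_gene_totals

log = logging.getLogger("trex.pipeline")

DEFAULT_STAGES = ("simulate", "qc", "demux", "repertoire", "score", "overlap")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the failing stage."""


def _enabled(config: Mapping[str, Any], stage: str) -> bool:
    return bool(config.get("stages", {}).get(stage, stage != "overlap" and stage != "score"))


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path | None = None) -> dict:
    """Run the enabled stages in dependency order and write a run summary."""
    out = Path(out_dir or config.get("out_dir", "trex_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    summary: dict[str, Any] = {
        "schema_version": 1,
        "trex_version": __version__,
        "seed": seed,
        "stages": {},
    }
    adata = contig_records = truth = clusters = None
    stage = "simulate"
    try:
        if _enabled(config, "simulate"):
            sim_cfg = SyntheticConfig(**{**config.get("simulate", {}), "seed": seed})
            adata, contig_records, truth = generate_cohort(sim_cfg)
            write_cohort(adata, contig_records, truth, out / "cohort")
            clusters = truth_cluster_labels(truth)
            summary["stages"]["simulate"] = {
                "n_barcodes": int(adata.n_obs),
                "n_genes": int(adata.n_vars),
                "n_doublets": int(truth["is_doublet"].sum()),
                "params": {k: v for k, v in vars(sim_cfg).items() if k != "cluster_spec"},
            }
        else:
            paths = config.get("inputs", {})
            adata = read_matrix_dir(paths["matrix"])
            contig_records = read_contigs(paths["contigs"])
            clusters = read_cluster_labels(paths["clusters"]).to_dict()

        stage = "qc"
        raw = adata
        if _enabled(config, "qc"):
            qc_cfg = config.get("qc", {})
            kept, report = qc_filter(
                adata,
                min_umi=int(qc_cfg.get("min_umi", 1000)),
                max_mito=float(qc_cfg.get("max_mito", 0.10)),
            )
            report.to_csv(out / "qc_report.tsv", sep="\t")
            lognorm = lognormalize(kept)
            write_matrix_dir(lognorm, out / "lognorm")
            summary["stages"]["qc"] = {
                "n_input": int(len(report)),
                "n_kept": int(report["kept"].sum()),
                "removed_by_reason": report.loc[~report["kept"], "reason"]
                .value_counts()
                .to_dict(),
                "params": {"min_umi": int(qc_cfg.get("min_umi", 1000)),
                           "max_mito": float(qc_cfg.get("max_mito", 0.10))},
            }
            adata = kept

        stage = "demux"
        assignments = None
        if _enabled(config, "demux"):
            rules = DemuxRules(**config.get("demux", {}).get("rules", {}))
            cells = cell_chains(usable_contigs(contig_records))
            y_tot = y_gene_totals(raw).to_dict()
            kept_bcs = set(adata.obs_names)
            cells_kept = {bc: c for bc, c in cells.items() if bc in kept_bcs}
            y_kept = {bc: v for bc, v in y_tot.items() if bc in kept_bcs}
            clusters_kept = {bc: c for bc, c in clusters.items() if bc in kept_bcs}
            assignments, demux_summary = demultiplex(
                cells_kept, y_kept, clusters_kept, rules, barcodes=kept_bcs,
                drop_clusters=config.get("demux", {}).get("drop_clusters", ()),
            )
            assignments.to_csv(out / "assignments.tsv", sep="\t")
            summary["stages"]["demux"] = demux_summary

        stage = "repertoire"
        if _enabled(config, "repertoire") and assignments is not None:
            cells = cell_chains(usable_contigs(contig_records))
            rep_summary = {}
            for cell_type in ("iNKT", "MAIT", "gdT"):
                bcs = assignments.index[assignments["assigned_type"] == cell_type]
                keyed = [bc for bc in bcs if bc in cells]
                if not keyed:
                    continue
                table = build_clonotype_table(cells, clusters, barcodes=keyed)
                table.to_csv(out / f"clonotypes_{cell_type}.tsv", sep="\t")
                spec, spec_summary = repeat_spectrum(table)
                spec.to_csv(out / f"repeat_spectrum_{cell_type}.tsv", sep="\t")
                diversity = {}
                for cluster in table.attrs["cluster_columns"]:
                    counts = table.loc[table[cluster] > 0, cluster]
                    if len(counts):
                        diversity[cluster] = shannon_equitability(counts)
                pd.Series(diversity, name="shannon_equitability").to_csv(
                    out / f"diversity_{cell_type}.tsv", sep="\t"
                )
                rep_summary[cell_type] = {**spec_summary, "shannon_by_cluster": diversity}
            summary["stages"]["repertoire"] = rep_summary

        stage = "score"
        if _enabled(config, "score"):
            lognorm = lognormalize(adata)
            sigs = config.get("score", {}).get("signatures", {})
            scores = pd.DataFrame(
                {name: signature_score(lognorm, genes, name) for name, genes in sigs.items()}
            )
            scores.to_csv(out / "signature_scores.tsv", sep="\t")
            summary["stages"]["score"] = {"signatures": sorted(sigs)}

        stage = "overlap"
        if _enabled(config, "overlap"):
            ov_cfg = config["overlap"]
            deg_a = pd.read_csv(ov_cfg["deg_a"], sep="\t")
            deg_b = pd.read_csv(ov_cfg["deg_b"], sep="\t")
            up_a, down_a = extract_degs(deg_a)
            up_b, down_b = extract_degs(deg_b)
            universe = sorted(set(deg_a["gene"]) & set(deg_b["gene"]))
            result = direction_consistent_overlap(
                up_a, down_a, up_b, down_b, universe,
                r=int(ov_cfg.get("reps", 10_000)), seed=seed,
            )
            summary["stages"]["overlap"] = vars(result).copy()
    except Exception as exc:  # pragma: no cover - error path
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
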