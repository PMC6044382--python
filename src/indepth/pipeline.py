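"""One-command orchestration: load -> score -> cutoff -> network -> hubs.

``run_pipeline`` is the in-memory core (objects in, objects out);
``run_indepth`` wraps it with file I/O, stage logging, and run metadata so
a run is fully replayable from its config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from indepth.connectivity import score_reference
from indepth.cutoff import CutoffResult, resolve_cutoff, roc_report_frame
from indepth.errors import ValidationError
from indepth.hubs import HubScores, assign_weights, hub_scores
from indepth.network import (
    DEGNetwork,
    connect_downstream,
    select_upstream,
    simplify_graph,
    upstream_frame,
    write_graphml,
    write_sif,
)
from indepth.query_signature import (
    QuerySignature,
    load_query_expression,
    load_query_signature,
)
from indepth.reference_db import ReferenceDB, load_reference

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one run; defaults are the pipeline's standard constants."""

    reference_meta: str
    reference_zscore: str
    reference_expr: str | None = None
    query_expression: str | None = None   # (id, treated, control) TSV
    query_signature: str | None = None    # precomputed (gene, direction[, ratio]) TSV
    probe_map: str | None = None
    drug_name: str = ""
    out_dir: str = "indepth_out"
    cutoff_mode: str = "auto"             # "auto" | "fixed"
    cutoff_value: float = 0.2             # fixed value / auto fallback
    cell_filter: str | None = None        # scoring restriction
    roc_cell_filter: str | None = None    # ROC labelling restriction
    alpha_mode: str = "raw"               # "raw" | "symmetric"
    delta_numerator: str = "all"          # "all" | "landmark_only"
    scaling: str = "half"                 # "half" | "batch_max"
    downstream_combine: str = "union"     # "union" | "intersection"
    z_threshold: float = 2.0
    floor: float = 50.0
    up_threshold: float = 2.0
    down_threshold: float = 0.5


@dataclass
class RunResult:
    """Everything one run produced."""

    scores: pd.DataFrame
    cutoff: CutoffResult
    network: DEGNetwork
    hubs: HubScores
    hub_table: pd.DataFrame
    status: str                    # "ok" | "empty_network"
    paths: dict[str, Path] = field(default_factory=dict)


def run_pipeline(
    db: ReferenceDB,
    query: QuerySignature,
    config: RunConfig | None = None,
) -> RunResult:
    """Run scoring, cutoff resolution, network construction and hub scoring."""
    cfg = config or RunConfig(reference_meta="", reference_zscore="")
    scores = score_reference(query, db, cell_filter=cfg.cell_filter, scaling=cfg.scaling)
    cutoff = resolve_cutoff(
        query, db, scores=scores, mode=cfg.cutoff_mode,
        fixed_value=cfg.cutoff_value, roc_cell_filter=cfg.roc_cell_filter,
    )
    upstream = select_upstream(scores, cutoff.value, query, db)
    edges = connect_downstream(upstream, db, query, combine=cfg.downstream_combine)
    net = simplify_graph(edges, upstream, cutoff_used=cutoff.value)
    net = assign_weights(net, query, db, alpha_mode=cfg.alpha_mode,
                         delta_numerator=cfg.delta_numerator)
    if net.n_nodes == 0:
        hubs = HubScores(hub={}, authority={}, iterations=0, converged=True)
    else:
        hubs = hub_scores(net)
    status = "ok" if net.n_edges > 0 else "empty_network"
    if status == "empty_network":
        logger.info("no genetic perturbation was selected at cutoff %.4g; "
                    "network is empty (valid outcome)", cutoff.value)
    return RunResult(
        scores=scores, cutoff=cutoff, network=net, hubs=hubs,
        hub_table=hubs.frame(net, query), status=status,
    )


def _load_query(cfg: RunConfig) -> QuerySignature:
    if bool(cfg.query_expression) == bool(cfg.query_signature):
        raise ValidationError(
            "exactly one of query_expression / query_signature must be given"
        )
    if cfg.query_expression:
        sig = load_query_expression(
            cfg.query_expression, probe_map_path=cfg.probe_map, floor=cfg.floor,
            up_threshold=cfg.up_threshold, down_threshold=cfg.down_threshold,
        )
    else:
        sig = load_query_signature(cfg.query_signature)
    if cfg.drug_name:
        sig.meta["drug"] = cfg.drug_name
    return sig


def run_indepth(config: RunConfig) -> RunResult:
    """File-based end-to-end run: loads inputs, runs the pipeline, writes artifacts."""
    db = load_reference(
        config.reference_meta, config.reference_zscore, config.reference_expr,
        z_threshold=config.z_threshold,
    )
    query = _load_query(config)
    logger.info("query: %d UP DEGs, %d DOWN DEGs", len(query.up_degs), len(query.down_degs))
    result = run_pipeline(db, query, config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "scores": out / "scores.tsv",
        "roc_report": out / "roc_report.tsv",
        "upstream_candidates": out / "upstream_candidates.tsv",
        "sif": out / "network.sif",
        "graphml": out / "network.graphml",
        "hubs": out / "hubs.tsv",
        "run_metadata": out / "run_metadata.json",
    }
    result.scores.to_csv(paths["scores"], sep="\t", index=False, float_format="%.6g")
    roc_report_frame(config.drug_name, result.cutoff).to_csv(
        paths["roc_report"], sep="\t", index=False, float_format="%.6g"
    )
    upstream_frame(result.network.upstream).to_csv(
        paths["upstream_candidates"], sep="\t", index=False, float_format="%.6g"
    )
    write_sif(result.network, paths["sif"])
    write_graphml(result.network, paths["graphml"])
    result.hub_table.to_csv(paths["hubs"], sep="\t", index=False, float_format="%.10g")
    metadata = {
        "config": asdict(config),
        "n_records": len(db),
        "n_landmark_genes": db.n_landmark,
        "n_up_degs": len(query.up_degs),
        "n_down_degs": len(query.down_degs),
        "cutoff": result.cutoff.value,
        "cutoff_provenance": result.cutoff.provenance,
        "n_upstream_candidates": len(result.network.upstream),
        "n_nodes": result.network.n_nodes,
        "n_edges": result.network.n_edges,
        "hits_iterations": result.hubs.iterations,
        "hits_converged": result.hubs.converged,
        "status": result.status,
    }
    with open(paths["run_metadata"], "w") as fh:
        json.dump(metadata, fh, indent=2)
    result.paths = paths
    return result
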