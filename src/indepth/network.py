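"""Directed DEG network construction from selected perturbation records.

Four selection rules turn the connectivity-score table into a simple
directed graph over query DEGs:

1. keep genetic-perturbation records (knockdown / overexpression / ligand)
   scoring at or above the cutoff;
2. direction consistency — a knocked-down gene must be a DOWN DEG, an
   overexpressed or ligand-stimulated gene must be an UP DEG;
3. among records sharing the same (target gene, perturbagen id), keep only
   the highest-scoring one;
4. knockdown genes supported by fewer than two distinct perturbagen ids
   (independent shRNA clones) are discarded, guarding against off-target
   effects.

Edges then run from each surviving upstream gene to the query DEGs its
record significantly moved (|z| >= 2) in the same direction as the query.
Self-loops are removed and parallel edges merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from indepth.errors import ValidationError
from indepth.query_signature import QuerySignature
from indepth.reference_db import GENETIC_PERT_TYPES, ReferenceDB

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UpstreamCandidate:
    """A perturbation record retained as evidence for one upstream gene."""

    gene: str
    pert_type: str
    pert_id: str
    record_id: str
    score: float


@dataclass(frozen=True)
class Edge:
    """A directed upstream -> downstream regulation with record provenance."""

    source: str
    target: str
    direction: str  # the target's change: "up" or "down"
    supporting_records: tuple[str, ...]


@dataclass
class DEGNetwork:
    """Simple directed graph over query DEGs with record provenance.

    ``graph`` is a networkx DiGraph whose edges carry ``direction``,
    ``supporting_records`` and (after weighting) ``weight`` attributes.
    Isolated nodes are upstream genes that passed selection but drove no
    same-direction downstream DEG.
    """

    graph: nx.DiGraph
    cutoff_used: float
    upstream: list[UpstreamCandidate] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def select_upstream(
    scores: pd.DataFrame,
    cutoff: float,
    query: QuerySignature,
    db: ReferenceDB,
    audit: dict[str, int] | None = None,
) -> list[UpstreamCandidate]:
    """Apply rules 1-4 above to the score table; returns retained records.

    An empty result is valid: for some queries no genetic perturbation
    clears the cutoff. When ``audit`` is a dict it is filled with the record
    count surviving each rule, keyed n_genetic / n_cutoff / n_direction /
    n_dedup / n_final.
    """
    if not pd.notna(cutoff):
        raise ValidationError("cutoff must be finite")
    tab = scores[scores["scored"] & scores["pert_type"].isin(GENETIC_PERT_TYPES)]
    n_genetic = len(tab)
    tab = tab[tab["score"] >= cutoff]
    n_cutoff = len(tab)

    def _direction_ok(row) -> bool:
        if row.pert_type == "knockdown":
            return row.target_gene in query.down_degs
        return row.target_gene in query.up_degs  # overexpression / ligand

    mask = pd.Series([_direction_ok(r) for r in tab.itertuples()],
                     index=tab.index, dtype=bool)
    tab = tab[mask]
    n_direction = len(tab)

    # rule 3: best-scoring record per (target gene, perturbagen id);
    # record_id as final tie-break for determinism
    tab = (
        tab.sort_values(["score", "record_id"], ascending=[False, True])
        .drop_duplicates(subset=["target_gene", "pert_id"], keep="first")
    )
    n_dedup = len(tab)

    # rule 4: knockdown genes need >= 2 independent perturbagen ids
    kd = tab["pert_type"] == "knockdown"
    pert_counts = tab[kd].groupby("target_gene")["pert_id"].nunique()
    lonely = set(pert_counts.index[pert_counts < 2])
    tab = tab[~(kd & tab["target_gene"].isin(lonely))]
    n_final = len(tab)

    logger.info(
        "upstream selection: %d genetic records -> %d >= cutoff %.4g -> "
        "%d direction-consistent -> %d after pert_id dedup -> %d after >=2-shRNA rule",
        n_genetic, n_cutoff, cutoff, n_direction, n_dedup, n_final,
    )
    if audit is not None:
        audit.update(n_genetic=n_genetic, n_cutoff=n_cutoff, n_direction=n_direction,
                     n_dedup=n_dedup, n_final=n_final)
    tab = tab.sort_values(["target_gene", "pert_id"])
    return [
        UpstreamCandidate(
            gene=row.target_gene,
            pert_type=row.pert_type,
            pert_id=row.pert_id,
            record_id=row.record_id,
            score=float(row.score),
        )
        for row in tab.itertuples()
    ]


def connect_downstream(
    upstream: list[UpstreamCandidate],
    db: ReferenceDB,
    query: QuerySignature,
    combine: str = "union",
) -> list[Edge]:
    """Edges from upstream genes to same-direction significantly moved DEGs.

    For each retained record, downstream up-edges go to genes in the record's
    up-regulated set that are also query UP DEGs, and down-edges analogously.
    ``combine="union"`` (default) pools edges across a gene's records;
    ``combine="intersection"`` keeps only targets supported by every record
    of that gene.
    """
    if combine not in {"union", "intersection"}:
        raise ValidationError(f"unknown downstream combine mode {combine!r}")
    per_record: list[Edge] = []
    for cand in upstream:
        reg = db.regulated(cand.record_id)
        for gene in sorted(reg.up_set & query.up_degs):
            per_record.append(Edge(cand.gene, gene, "up", (cand.record_id,)))
        for gene in sorted(reg.down_set & query.down_degs):
            per_record.append(Edge(cand.gene, gene, "down", (cand.record_id,)))
    if combine == "union":
        return per_record
    # intersection: keep (source, target) pairs present in all of the source's records
    records_per_gene: dict[str, set[str]] = {}
    for cand in upstream:
        records_per_gene.setdefault(cand.gene, set()).add(cand.record_id)
    support: dict[tuple[str, str, str], set[str]] = {}
    for e in per_record:
        support.setdefault((e.source, e.target, e.direction), set()).update(e.supporting_records)
    return [
        Edge(src, tgt, direction, tuple(sorted(recs)))
        for (src, tgt, direction), recs in support.items()
        if recs == records_per_gene[src]
    ]


def simplify_graph(
    edges: list[Edge],
    upstream: list[UpstreamCandidate] | None = None,
    cutoff_used: float = float("nan"),
) -> DEGNetwork:
    """Remove self-loops, merge parallel edges, and assemble the network.

    Upstream genes whose every edge was removed (or that produced none) stay
    in the graph as isolated nodes: their perturbation cleared the cutoff but
    drove no same-direction downstream DEG.
    """
    upstream = upstream or []
    g = nx.DiGraph()
    merged: dict[tuple[str, str], dict] = {}
    for e in edges:
        if e.source == e.target:
            continue
        key = (e.source, e.target)
        if key in merged:
            merged[key]["supporting_records"].update(e.supporting_records)
            if merged[key]["direction"] != e.direction:
                # cannot happen when targets are DEGs (disjoint UP/DOWN sets)
                raise ValidationError(f"conflicting directions for edge {key}")
        else:
            merged[key] = {
                "direction": e.direction,
                "supporting_records": set(e.supporting_records),
            }
    for (src, tgt), attrs in merged.items():
        g.add_edge(
            src, tgt,
            direction=attrs["direction"],
            supporting_records=tuple(sorted(attrs["supporting_records"])),
        )
    for cand in upstream:
        g.add_node(cand.gene)
    logger.info("network: %d nodes, %d edges after simplification",
                g.number_of_nodes(), g.number_of_edges())
    return DEGNetwork(graph=g, cutoff_used=cutoff_used, upstream=list(upstream))


def upstream_frame(upstream: list[UpstreamCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": c.gene, "pert_type": c.pert_type, "pert_id": c.pert_id,
             "record_id": c.record_id, "score": c.score}
            for c in upstream
        ],
        columns=["gene", "pert_type", "pert_id", "record_id", "score"],
    )


def write_sif(net: DEGNetwork, path: str | Path) -> None:
    """Cytoscape SIF export: source, regulates_up/regulates_down, target."""
    with open(path, "w") as fh:
        for src, tgt, attrs in sorted(net.graph.edges(data=True)):
            fh.write(f"{src}\tregulates_{attrs['direction']}\t{tgt}\n")
        for node in sorted(net.graph.nodes):
            if net.graph.degree(node) == 0:
                fh.write(f"{node}\n")


def write_graphml(net: DEGNetwork, path: str | Path) -> None:
    """GraphML export with stringified provenance (GraphML has no list type)."""
    g = net.graph.copy()
    for _, _, attrs in g.edges(data=True):
        attrs["supporting_records"] = "|".join(attrs["supporting_records"])
    nx.write_graphml(g, path)
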