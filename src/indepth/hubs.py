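"""Edge weighting (alpha x delta) and Kleinberg hub/authority scoring.

Each edge u -> v carries weight alpha(u) * delta, where alpha is the
upstream gene's query signal-intensity ratio and delta is a per-record
penalty: (number of UP or DOWN query DEGs) / (number of landmark genes the
record up- or down-regulates), capped at 1 so sparse-signature records are
never rewarded. A record that moves many landmark genes (a promiscuous,
off-target-prone perturbation) is thereby down-weighted.

Hub and authority scores follow Kleinberg's HITS: the hub vector is the
principal eigenvector of W W^T and the authority vector of W^T W (W the
weighted adjacency matrix, rows = sources), computed by alternating power
iteration with sup-norm renormalisation. Final vectors are scaled so the
maximum entry is exactly 1; the gene with hub score 1 is the most highly
influential gene of the query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from indepth.errors import ValidationError
from indepth.network import DEGNetwork
from indepth.query_signature import QuerySignature
from indepth.reference_db import PerturbationRecord, ReferenceDB

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HubScores:
    """Normalised hub/authority scores for every network node."""

    hub: dict[str, float]
    authority: dict[str, float]
    iterations: int
    converged: bool

    def frame(self, net: DEGNetwork, query: QuerySignature) -> pd.DataFrame:
        """Per-gene report table sorted by hub score descending."""
        rows = []
        for node in net.graph.nodes:
            if node in query.up_degs:
                direction = "up"
            elif node in query.down_degs:
                direction = "down"
            else:
                direction = ""
            rows.append(
                {
                    "gene": node,
                    "direction": direction,
                    "ratio": query.gene_ratio.get(node, float("nan")),
                    "hub_score": self.hub[node],
                    "authority_score": self.authority[node],
                    "n_out_edges": net.graph.out_degree(node),
                    "n_in_edges": net.graph.in_degree(node),
                }
            )
        cols = ["gene", "direction", "ratio", "hub_score", "authority_score",
                "n_out_edges", "n_in_edges"]
        return (
            pd.DataFrame(rows, columns=cols)
            .sort_values(["hub_score", "gene"], ascending=[False, True])
            .reset_index(drop=True)
        )


def compute_delta(
    record: PerturbationRecord | str,
    query: QuerySignature,
    db: ReferenceDB,
    delta_numerator: str = "all",
) -> tuple[float, float]:
    """Per-record penalties (delta_up, delta_down), each capped at 1.

    delta_up = |query UP DEGs| / |record's up-regulated landmark genes|
    (0 when the record up-regulates nothing), and analogously for down.
    ``delta_numerator="landmark_only"`` counts only query DEGs that are
    landmark genes.
    """
    if delta_numerator not in {"all", "landmark_only"}:
        raise ValidationError(f"unknown delta_numerator {delta_numerator!r}")
    record_id = record.record_id if isinstance(record, PerturbationRecord) else record
    reg = db.regulated(record_id)
    if delta_numerator == "landmark_only":
        landmark = set(db.landmark_genes)
        n_up, n_down = len(query.up_degs & landmark), len(query.down_degs & landmark)
    else:
        n_up, n_down = len(query.up_degs), len(query.down_degs)
    d_up = min(1.0, n_up / len(reg.up_set)) if reg.up_set else 0.0
    d_down = min(1.0, n_down / len(reg.down_set)) if reg.down_set else 0.0
    return d_up, d_down


def assign_weights(
    net: DEGNetwork,
    query: QuerySignature,
    db: ReferenceDB,
    alpha_mode: str = "raw",
    delta_numerator: str = "all",
) -> DEGNetwork:
    """Set each edge's weight to alpha(source) x best supporting delta.

    ``alpha_mode="raw"`` uses the source gene's treatment/control ratio
    as-is; ``"symmetric"`` uses max(ratio, 1/ratio) so DOWN-DEG sources
    (ratio <= 0.5) are not systematically down-weighted. For merged parallel
    edges the largest delta over supporting records is used.
    """
    if alpha_mode not in {"raw", "symmetric"}:
        raise ValidationError(f"unknown alpha_mode {alpha_mode!r}")
    delta_cache: dict[str, tuple[float, float]] = {}
    for src, tgt, attrs in net.graph.edges(data=True):
        ratio = query.gene_ratio.get(src)
        if ratio is None:
            raise ValidationError(f"no query ratio (alpha) for upstream gene {src!r}")
        alpha = max(ratio, 1.0 / ratio) if alpha_mode == "symmetric" else ratio
        best_delta = 0.0
        for rid in attrs["supporting_records"]:
            if rid not in delta_cache:
                delta_cache[rid] = compute_delta(rid, query, db, delta_numerator)
            d_up, d_down = delta_cache[rid]
            best_delta = max(best_delta, d_up if attrs["direction"] == "up" else d_down)
        attrs["weight"] = alpha * best_delta
    return net


def hub_scores(
    net: DEGNetwork | nx.DiGraph,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> HubScores:
    """Weighted HITS by alternating power iteration, max-normalised.

    Deterministic: all-ones initialisation, sup-norm renormalisation each
    step, convergence when the hub vector moves by less than ``tol`` in
    sup-norm. An edge-free graph returns all-zero scores (converged). On
    hitting ``max_iter`` the best iterate is returned with converged=False.
    """
    g = net.graph if isinstance(net, DEGNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValidationError("hub scoring needs at least one node")
    nodes = list(g.nodes)
    if g.number_of_edges() == 0:
        zeros = {n: 0.0 for n in nodes}
        return HubScores(hub=dict(zeros), authority=dict(zeros),
                         iterations=0, converged=True)
    w = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    if np.any(w < 0):
        raise ValidationError("negative edge weights")
    h = np.ones(len(nodes))
    a = np.zeros(len(nodes))
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        a = w.T @ h
        if a.max() > 0:
            a /= a.max()
        h_new = w @ a
        if h_new.max() > 0:
            h_new /= h_new.max()
        delta = float(np.abs(h_new - h).max())
        h = h_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("HITS did not converge in %d iterations (last step %.3g)",
                       max_iter, delta)
    # sup-norm renormalisation already makes max(h) = 1; guard degenerate zeros
    if h.max() > 0:
        h = h / h.max()
    if a.max() > 0:
        a = a / a.max()
    return HubScores(
        hub={n: float(v) for n, v in zip(nodes, h)},
        authority={n: float(v) for n, v in zip(nodes, a)},
        iterations=iterations,
        converged=converged,
    )
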