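"""Similarity-score cutoff selection by ROC analysis against compound records.

Compound records sharing the query drug's name are treated as positives and
every other record as a negative; the area under the ROC curve (concordance
index, floored at 0.5 since values below chance mean the two databases are
not comparable) summarises separability and Youden's J picks the cutoff. If
no same-name compound records exist, or the ROC is degenerate, the cutoff
falls back to a fixed default of 0.2.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from indepth.errors import ValidationError
from indepth.query_signature import QuerySignature
from indepth.reference_db import ReferenceDB

logger = logging.getLogger(__name__)

DEFAULT_FALLBACK_CUTOFF = 0.2


@dataclass(frozen=True)
class RocAnalysis:
    """Result of one ROC cutoff analysis."""

    c_index: float
    best_cutoff: float
    youden_j: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CutoffResult:
    """Resolved cutoff plus the path (auto ROC vs fixed/fallback) that produced it."""

    value: float
    provenance: str  # "auto", "fixed", or "fallback"
    roc: RocAnalysis | None = None


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).casefold()


def label_records(query_name: str, db: ReferenceDB) -> pd.Series:
    """Binary labels over records: same-name compound records are positive.

    Name matching is case-insensitive with whitespace collapsed.
    """
    if not query_name or not query_name.strip():
        raise ValidationError("query_name must be non-empty")
    key = _normalize_name(query_name)
    labels = pd.Series(
        [
            rec.pert_type == "compound" and _normalize_name(rec.pert_name) == key
            for rec in db.records
        ],
        index=[rec.record_id for rec in db.records],
        dtype=bool,
    )
    if not labels.any():
        logger.warning("no compound records named %r in the reference", query_name)
    return labels


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValidationError("need at least one positive and one negative label")


def c_index(scores: np.ndarray, labels: np.ndarray) -> float:
    """Concordance index (ROC AUC, ties at 0.5), floored at 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels differ in length")
    _check_two_classes(labels)
    auc = float(roc_auc_score(labels, scores))
    return max(auc, 0.5)


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Cutoff maximising Youden's J = sensitivity + specificity - 1.

    Candidate cutoffs are the observed score values; a record is predicted
    positive when its score >= cutoff. Ties in J are broken toward the
    largest cutoff (the most stringent network). Returns (cutoff, J).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels differ in length")
    _check_two_classes(labels)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    candidates = np.unique(scores)  # ascending
    # vectorized: for each candidate c, sens = P(score>=c | pos), spec = P(score<c | neg)
    ge = scores[None, :] >= candidates[:, None]
    sens = (ge & labels[None, :]).sum(axis=1) / n_pos
    spec = ((~ge) & (~labels)[None, :]).sum(axis=1) / n_neg
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-15)[-1]  # largest cutoff among maxima
    return float(candidates[best]), float(j[best])


def resolve_cutoff(
    query: QuerySignature,
    db: ReferenceDB,
    scores: pd.DataFrame | None = None,
    mode: str = "auto",
    fixed_value: float = DEFAULT_FALLBACK_CUTOFF,
    roc_cell_filter: str | None = None,
) -> CutoffResult:
    """Resolve the similarity-score cutoff for upstream selection.

    ``mode="fixed"`` returns ``fixed_value`` directly. ``mode="auto"`` labels
    compound records by the query's drug name (``query.meta["drug"]``), runs
    the ROC analysis on the supplied connectivity-score table (optionally
    restricted to one cell line), and returns the Youden cutoff; when no
    positive records exist or the analysis is degenerate it falls back to
    ``fixed_value`` with provenance "fallback".
    """
    if mode == "fixed":
        if not (0 < fixed_value < 1):
            raise ValidationError(f"fixed cutoff must lie in (0, 1), got {fixed_value}")
        return CutoffResult(value=fixed_value, provenance="fixed")
    if mode != "auto":
        raise ValidationError(f"unknown cutoff mode {mode!r}")
    query_name = query.meta.get("drug", "")
    if scores is None or not query_name:
        logger.warning("auto cutoff needs a score table and a query drug name; "
                       "falling back to %.3g", fixed_value)
        return CutoffResult(value=fixed_value, provenance="fallback")
    labels = label_records(query_name, db)
    table = scores[scores["scored"]].copy()
    if roc_cell_filter is not None:
        table = table[table["cell_line"] == roc_cell_filter]
    lab = labels.reindex(table["record_id"]).to_numpy()
    vals = table["score"].to_numpy(dtype=float)
    if lab.sum() == 0 or lab.sum() == lab.size:
        logger.info("degenerate ROC labelling (%d positives of %d); falling back to %.3g",
                    int(lab.sum()), lab.size, fixed_value)
        return CutoffResult(value=fixed_value, provenance="fallback")
    ci = c_index(vals, lab)
    cut, j = youden_cutoff(vals, lab)
    roc = RocAnalysis(c_index=ci, best_cutoff=cut, youden_j=j,
                      n_pos=int(lab.sum()), n_neg=int(lab.size - lab.sum()))
    logger.info("auto cutoff %.4f (c-index %.3f, J %.3f, %d pos / %d neg)",
                cut, ci, j, roc.n_pos, roc.n_neg)
    return CutoffResult(value=cut, provenance="auto", roc=roc)


def roc_report_frame(query_name: str, result: CutoffResult) -> pd.DataFrame:
    """One-row report table for ``roc_report.tsv``."""
    roc = result.roc
    return pd.DataFrame(
        [{
            "query_name": query_name,
            "n_pos": roc.n_pos if roc else 0,
            "n_neg": roc.n_neg if roc else 0,
            "c_index": roc.c_index if roc else float("nan"),
            "best_cutoff": result.value,
            "youden_j": roc.youden_j if roc else float("nan"),
            "provenance": result.provenance,
        }]
    )
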