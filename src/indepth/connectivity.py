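"""CMap-style Kolmogorov-Smirnov connectivity scores against reference ranks.

The connectivity (similarity) score between a query signature and one
reference record asks whether the query's UP tags sit near the top of the
record's gene ranking and its DOWN tags near the bottom. Each tag set yields
a signed KS enrichment statistic; a record that moves the query's UP genes up
and DOWN genes down gets a score near +1, a record inducing the opposite
signature scores near -1, and discordant tag sets (both enrichment statistics
on the same side) score exactly 0.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from indepth.errors import EmptySelectionError, NoOverlapError, ValidationError
from indepth.query_signature import QuerySignature
from indepth.reference_db import ReferenceDB

logger = logging.getLogger(__name__)

SCORE_COLUMNS = [
    "record_id", "pert_id", "pert_type", "target_gene", "pert_name", "cell_line",
    "ks_up", "ks_down", "score", "scored",
]


def ks_enrichment(tag_positions: Iterable[int], n: int) -> float:
    """Signed KS enrichment of tag positions within a ranking of length n.

    With sorted positions V(1) < ... < V(t),

        a = max_j ( j/t - V(j)/n ),   b = max_j ( V(j)/n - (j-1)/t )

    and the statistic is ``a`` when a >= b, else ``-b``. Tags concentrated at
    the top of the ranking give a positive value, tags at the bottom a
    negative one; the result lies in (-1, 1].
    """
    v = np.sort(np.asarray(list(tag_positions), dtype=np.int64))
    t = v.size
    if t == 0:
        raise ValidationError("empty tag position list")
    if v[0] < 1 or v[-1] > n or np.any(np.diff(v) == 0):
        raise ValidationError("tag positions must be distinct integers in 1..n")
    j = np.arange(1, t + 1)
    a = np.max(j / t - v / n)
    b = np.max(v / n - (j - 1) / t)
    return float(a) if a >= b else float(-b)


def connectivity_score(
    up_tags: frozenset[str] | set[str],
    down_tags: frozenset[str] | set[str],
    rank: pd.Series,
) -> tuple[float, float, float]:
    """KS enrichment of both tag sets in one record's ranking -> (ks_up, ks_down, score).

    ``rank`` maps gene -> rank (1 = most up-regulated). Tags absent from the
    ranking are dropped. The combined score is (ks_up - ks_down)/2 when the
    two statistics disagree in sign (one side possibly 0), and 0 when they
    share a sign; an empty tag set contributes 0.
    """
    n = len(rank)
    up_in = [g for g in up_tags if g in rank.index]
    down_in = [g for g in down_tags if g in rank.index]
    n_dropped = (len(up_tags) - len(up_in)) + (len(down_tags) - len(down_in))
    if n_dropped:
        logger.debug("dropped %d query tags outside the rank universe", n_dropped)
    if not up_in and not down_in:
        raise NoOverlapError("neither tag set overlaps the ranked gene universe")
    ks_up = ks_enrichment(rank.loc[up_in].to_numpy(), n) if up_in else 0.0
    ks_down = ks_enrichment(rank.loc[down_in].to_numpy(), n) if down_in else 0.0
    score = 0.0 if ks_up * ks_down > 0 else (ks_up - ks_down) / 2.0
    return ks_up, ks_down, score


def _batch_rescale(raw: pd.Series) -> pd.Series:
    """CMap-build scaling: positive scores / batch max, negative / -batch min."""
    out = raw.copy()
    pos, neg = raw > 0, raw < 0
    if pos.any():
        out[pos] = raw[pos] / raw[pos].max()
    if neg.any():
        out[neg] = -raw[neg] / raw[neg].min()
    return out


def score_reference(
    query: QuerySignature,
    db: ReferenceDB,
    cell_filter: str | None = None,
    scaling: str = "half",
) -> pd.DataFrame:
    """Score every (optionally cell-filtered) reference record against a query.

    Only landmark genes participate: query tags outside the landmark list are
    dropped before scoring. Records where neither tag set overlaps are kept in
    the table with a null score and ``scored=False``.

    ``scaling="half"`` divides (ks_up - ks_down) by 2 (default, batch
    independent); ``scaling="batch_max"`` rescales by the batch extremes as in
    the original connectivity-map build.
    """
    if scaling not in {"half", "batch_max"}:
        raise ValidationError(f"unknown scaling mode {scaling!r}")
    records = db.records
    if cell_filter is not None:
        records = [r for r in records if r.cell_line == cell_filter]
        if not records:
            raise EmptySelectionError(f"cell_filter {cell_filter!r} matches no records")
    landmark = set(db.landmark_genes)
    up = frozenset(query.up_degs & landmark)
    down = frozenset(query.down_degs & landmark)
    n_dropped = len(query.up_degs) + len(query.down_degs) - len(up) - len(down)
    if n_dropped:
        logger.info("dropped %d non-landmark query DEGs before scoring", n_dropped)
    rows = []
    for rec in records:
        rank = db.rank_series(rec.record_id)
        try:
            ks_up, ks_down, raw = connectivity_score(up, down, rank)
            scored = True
        except NoOverlapError:
            ks_up = ks_down = raw = np.nan
            scored = False
        rows.append(
            {
                "record_id": rec.record_id,
                "pert_id": rec.pert_id,
                "pert_type": rec.pert_type,
                "target_gene": rec.target_gene or "",
                "pert_name": rec.pert_name,
                "cell_line": rec.cell_line,
                "ks_up": ks_up,
                "ks_down": ks_down,
                "score": raw,  # half-scaled; replaced below under batch_max
                "scored": scored,
            }
        )
    table = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    if scaling == "batch_max":
        raw_s = table["ks_up"] - table["ks_down"]
        raw_s[table["ks_up"] * table["ks_down"] > 0] = 0.0
        table["score"] = _batch_rescale(raw_s.where(table["scored"]))
    n_unscored = int((~table["scored"]).sum())
    if n_unscored:
        logger.info("%d of %d records had no tag overlap and were left unscored",
                    n_unscored, len(table))
    return table
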