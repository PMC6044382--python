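"""Signed log-FDR significance scores for enrichment-analysis output.

Takes any enrichment tool's per-gene-set FDR table, split by direction of
regulation (gene sets enriched among increased vs decreased genes), and
collapses it to one signed score per gene set:

* a gene set absent from a direction's table gets FDR 1 there (not enriched
  at all);
* FDR 0 is replaced by the smallest nonzero FDR within that direction's
  table, so the log transform is defined;
* the directional score is -log10(FDR) with a positive sign for the
  increased direction and negative for decreased;
* a gene set marginally enriched in both directions gets the sum of its two
  directional scores.

The module only transforms tables; it does not run the enrichment analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from indepth.errors import ValidationError

LOG_BASE = 10.0
DIRECTIONS = ("increased", "decreased")


def signed_fdr_scores(
    rows: pd.DataFrame,
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """Collapse a (gene_set, direction, fdr) table to signed scores.

    ``universe`` lists the gene sets to report; it defaults to those present
    in ``rows`` and must cover them. Returns a DataFrame with columns
    gene_set and score, one row per universe entry, in universe order.
    """
    for col in ("gene_set", "direction", "fdr"):
        if col not in rows.columns:
            raise ValidationError(f"enrichment table missing column {col!r}")
    bad_dir = set(rows["direction"]) - set(DIRECTIONS)
    if bad_dir:
        raise ValidationError(f"unknown direction values {sorted(bad_dir)}")
    fdr = rows["fdr"].to_numpy(dtype=float)
    if np.any(~np.isfinite(fdr)) or np.any(fdr < 0) or np.any(fdr > 1):
        raise ValidationError("FDR values must lie in [0, 1]")
    if universe is None:
        universe = list(dict.fromkeys(rows["gene_set"]))
    else:
        extra = set(rows["gene_set"]) - set(universe)
        if extra:
            raise ValidationError(f"gene sets outside the universe: {sorted(extra)}")
    if rows.duplicated(subset=["gene_set", "direction"]).any():
        raise ValidationError("a gene set appears more than once per direction")

    scores = pd.Series(0.0, index=pd.Index(universe, name="gene_set"))
    flagged: set[str] = set()
    for direction, sign in zip(DIRECTIONS, (+1.0, -1.0)):
        sub = rows[rows["direction"] == direction].set_index("gene_set")["fdr"]
        col = sub.reindex(universe).fillna(1.0)  # absent => not enriched at all
        nonzero = col[col > 0]
        if (col == 0).any():
            if nonzero.empty:
                # no substitute exists; flag these gene sets instead of -inf
                flagged.update(col.index[col == 0])
                col = col.replace(0.0, np.nan)
            else:
                col = col.replace(0.0, float(nonzero.min()))
        scores = scores + sign * (-np.log(col) / np.log(LOG_BASE))
    out = pd.DataFrame({"gene_set": universe, "score": scores.to_numpy()})
    out["flagged"] = out["gene_set"].isin(flagged)
    return out
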