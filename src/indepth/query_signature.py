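"""Query DEG signatures: treatment/control ratios and UP/DOWN DEG calling.

A query is a drug-treated vs control expression comparison summarised as
per-gene treatment-to-control intensity ratios. Intensities below a floor
(default 50) are raised to the floor before the ratio is taken, so very low
signals cannot produce extreme ratios. Genes with ratio >= 2 are UP DEGs and
ratio <= 0.5 are DOWN DEGs (both inclusive); the ratios themselves later
serve as the alpha edge-weight factor for upstream genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from indepth.errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 50.0
DEFAULT_UP_THRESHOLD = 2.0
DEFAULT_DOWN_THRESHOLD = 0.5


@dataclass
class RatioTable:
    """Per-identifier (probe or gene) treatment-to-control ratios."""

    ratio: pd.Series
    floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        self.ratio = pd.Series(self.ratio, dtype=float)
        vals = self.ratio.to_numpy()
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals <= 0)):
            raise ValidationError("ratios must be positive and finite")

    def __len__(self) -> int:
        return len(self.ratio)


@dataclass
class QuerySignature:
    """UP/DOWN DEG sets plus the per-gene ratio map they were called from."""

    up_degs: frozenset[str]
    down_degs: frozenset[str]
    gene_ratio: dict[str, float]
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.up_degs & self.down_degs:
            raise ValidationError("UP and DOWN DEG sets overlap")

    def alpha(self, gene: str) -> float:
        """Signal-intensity ratio of a gene, defaulting to 1 when unknown."""
        if gene not in self.gene_ratio:
            logger.warning("no ratio recorded for gene %s; alpha defaults to 1", gene)
            return 1.0
        return self.gene_ratio[gene]


def treatment_control_ratio(
    treated: pd.Series, control: pd.Series, floor: float = DEFAULT_FLOOR
) -> RatioTable:
    """Floored treatment-to-control ratios: max(t, floor) / max(c, floor)."""
    treated = pd.Series(treated, dtype=float)
    control = pd.Series(control, dtype=float)
    if not treated.index.equals(control.index):
        if set(treated.index) != set(control.index):
            raise ValidationError("treated and control identifiers do not match")
        control = control.reindex(treated.index)
    if (treated < 0).any() or (control < 0).any():
        raise ValidationError("negative intensity values")
    ratio = np.maximum(treated, floor) / np.maximum(control, floor)
    return RatioTable(ratio=ratio, floor=floor)


def aggregate_to_genes(
    probe_ratios: RatioTable,
    probe_map: pd.Series | pd.DataFrame,
    geometric: bool = False,
) -> RatioTable:
    """Collapse probe-level ratios to gene level by averaging.

    ``probe_map`` maps probe -> gene (a Series, or a two-column DataFrame
    ``probe``/``gene``). Probes without a mapping are dropped (count logged).
    The default is the arithmetic mean of ratios; ``geometric=True`` averages
    on the log scale instead.
    """
    if isinstance(probe_map, pd.DataFrame):
        if probe_map["probe"].duplicated().any():
            raise ValidationError("a probe maps to more than one gene")
        probe_map = probe_map.set_index("probe")["gene"]
    genes = probe_ratios.ratio.index.map(probe_map)
    unmapped = genes.isna()
    if unmapped.any():
        logger.info("dropping %d unmapped probes of %d", int(unmapped.sum()), len(genes))
    kept = probe_ratios.ratio[~unmapped]
    grouped = kept.groupby(genes[~unmapped].astype(str))
    if geometric:
        gene_ratio = grouped.agg(lambda x: float(np.exp(np.mean(np.log(x)))))
    else:
        gene_ratio = grouped.mean()
    gene_ratio.index.name = "gene"
    return RatioTable(ratio=gene_ratio, floor=probe_ratios.floor)


def call_degs(
    ratios: RatioTable,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
    meta: dict[str, str] | None = None,
) -> QuerySignature:
    """Call UP/DOWN DEGs from gene-level ratios at inclusive thresholds."""
    if not (0 < down_threshold < up_threshold):
        raise ValidationError(
            f"need 0 < down_threshold < up_threshold, got {down_threshold}, {up_threshold}"
        )
    if len(ratios) == 0:
        raise ValidationError("empty ratio table")
    r = ratios.ratio
    up = frozenset(r.index[r >= up_threshold].astype(str))
    down = frozenset(r.index[r <= down_threshold].astype(str))
    return QuerySignature(
        up_degs=up,
        down_degs=down,
        gene_ratio={str(g): float(v) for g, v in r.items()},
        meta=dict(meta or {}),
    )


def load_query_expression(
    path: str | Path,
    probe_map_path: str | Path | None = None,
    floor: float = DEFAULT_FLOOR,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
) -> QuerySignature:
    """Derive a signature from a TSV of (identifier, treated, control) columns.

    If a probe map is supplied, probe ratios are averaged to genes before DEG
    calling (gene-level calling; see methods note for the alternative order).
    """
    tab = pd.read_csv(path, sep="\t")
    id_col = tab.columns[0]
    tab = tab.set_index(id_col)
    for col in ("treated", "control"):
        if col not in tab.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    ratios = treatment_control_ratio(tab["treated"], tab["control"], floor=floor)
    if probe_map_path is not None:
        pmap = pd.read_csv(probe_map_path, sep="\t", dtype=str)
        ratios = aggregate_to_genes(ratios, pmap[["probe", "gene"]])
    return call_degs(ratios, up_threshold, down_threshold)


def load_query_signature(path: str | Path) -> QuerySignature:
    """Load a precomputed signature TSV: gene, direction in {UP, DOWN}[, ratio].

    When ratios are absent they default to 1 for every gene (with a warning);
    downstream edge weights then carry no alpha contribution.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"gene": str, "direction": str})
    for col in ("gene", "direction"):
        if col not in tab.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    bad = set(tab["direction"].str.upper()) - {"UP", "DOWN"}
    if bad:
        raise ValidationError(f"{path}: unknown direction values {sorted(bad)}")
    direction = tab["direction"].str.upper()
    up = frozenset(tab.loc[direction == "UP", "gene"])
    down = frozenset(tab.loc[direction == "DOWN", "gene"])
    if "ratio" in tab.columns:
        gene_ratio = {str(g): float(v) for g, v in zip(tab["gene"], tab["ratio"])}
    else:
        logger.warning("%s has no ratio column; alpha defaults to 1 for all genes", path)
        gene_ratio = {str(g): 1.0 for g in tab["gene"]}
    return QuerySignature(up_degs=up, down_degs=down, gene_ratio=gene_ratio)
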