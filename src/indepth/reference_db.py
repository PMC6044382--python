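"""Genetic-perturbation reference database: loading, rank vectors, regulated sets.

The reference emulates a LINCS L1000-style collection: a metadata table of
perturbation records (shRNA knockdown, ORF overexpression, ligand treatment,
or compound treatment) plus a landmark-gene x record matrix of differential-
expression z-scores, optionally accompanied by a same-shape expression matrix
used only to break ties when ranking genes.

Per record the database derives

* a rank vector — landmark genes ordered by z-score descending, rank 1 being
  the most strongly up-regulated gene (exact z ties broken by higher
  expression, residual ties by landmark-list order), and
* regulated sets — the genes the perturbation significantly moved,
  ``up_set = {g : z >= 2}`` and ``down_set = {g : z <= -2}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from indepth.errors import DimensionError, ValidationError

logger = logging.getLogger(__name__)

PERT_TYPES = frozenset({"knockdown", "overexpression", "ligand", "compound"})
#: perturbation types that name a perturbed gene and may act as upstream genes
GENETIC_PERT_TYPES = frozenset({"knockdown", "overexpression", "ligand"})

META_COLUMNS = ["record_id", "pert_id", "pert_type", "target_gene", "pert_name", "cell_line"]

DEFAULT_Z_THRESHOLD = 2.0


@dataclass(frozen=True)
class RegulatedSets:
    """Genes significantly moved by one perturbation record."""

    up_set: frozenset[str]
    down_set: frozenset[str]
    threshold: float = DEFAULT_Z_THRESHOLD


@dataclass
class PerturbationRecord:
    """One perturbation instance with its landmark z-score profile."""

    record_id: str
    pert_id: str
    pert_type: str
    target_gene: str | None
    pert_name: str
    cell_line: str
    z: np.ndarray
    expr: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pert_type not in PERT_TYPES:
            raise ValidationError(
                f"record {self.record_id!r}: unknown pert_type {self.pert_type!r} "
                f"(expected one of {sorted(PERT_TYPES)})"
            )
        if self.pert_type in GENETIC_PERT_TYPES and not self.target_gene:
            raise ValidationError(
                f"record {self.record_id!r}: pert_type {self.pert_type!r} requires a target_gene"
            )
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValidationError(f"record {self.record_id!r}: non-finite z-scores")
        if self.expr is not None:
            self.expr = np.asarray(self.expr, dtype=float)
            if self.expr.shape != self.z.shape:
                raise DimensionError(
                    f"record {self.record_id!r}: expr length {self.expr.size} != z length {self.z.size}"
                )


def build_rank_vector(z: np.ndarray, expr: np.ndarray | None = None) -> np.ndarray:
    """Rank landmark genes by z-score descending; rank 1 = most up-regulated.

    Exact z ties are broken by higher expression value (better rank); residual
    ties fall back to input (landmark-list) order, so the result is a
    deterministic permutation of ``1..n``.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 1:
        raise ValidationError("empty z vector")
    if not np.all(np.isfinite(z)):
        raise ValidationError("non-finite z-scores")
    n = z.size
    if expr is None:
        expr_key = np.zeros(n)
    else:
        expr_key = np.asarray(expr, dtype=float)
        if expr_key.shape != z.shape:
            raise DimensionError(f"expr length {expr_key.size} != z length {n}")
    # lexsort: last key is primary -> sort by -z, then -expr, then input order
    order = np.lexsort((np.arange(n), -expr_key, -z))
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def regulated_sets(
    z: np.ndarray, genes: list[str], threshold: float = DEFAULT_Z_THRESHOLD
) -> RegulatedSets:
    """Split genes into up/down regulated sets at an inclusive |z| threshold."""
    if threshold <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    z = np.asarray(z, dtype=float)
    if z.size != len(genes):
        raise DimensionError(f"z length {z.size} != gene list length {len(genes)}")
    genes_arr = np.asarray(genes, dtype=object)
    up = frozenset(genes_arr[z >= threshold])
    down = frozenset(genes_arr[z <= -threshold])
    return RegulatedSets(up_set=up, down_set=down, threshold=threshold)


@dataclass
class ReferenceDB:
    """Indexed perturbation reference: records over an ordered landmark-gene list.

    Rank vectors and regulated sets are derived lazily per record and cached.
    """

    landmark_genes: list[str]
    records: list[PerturbationRecord]
    z_threshold: float = DEFAULT_Z_THRESHOLD
    _by_id: dict[str, PerturbationRecord] = field(default_factory=dict, repr=False)
    _rank_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _regulated_cache: dict[str, RegulatedSets] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.landmark_genes)) != len(self.landmark_genes):
            raise ValidationError("duplicate landmark gene symbols")
        if any(not g for g in self.landmark_genes):
            raise ValidationError("empty landmark gene symbol")
        n = len(self.landmark_genes)
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ValidationError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)
            if rec.z.size != n:
                raise DimensionError(
                    f"record {rec.record_id!r}: z length {rec.z.size} != "
                    f"{n} landmark genes"
                )
        self._by_id = {rec.record_id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, record_id: str) -> PerturbationRecord:
        return self._by_id[record_id]

    @property
    def n_landmark(self) -> int:
        return len(self.landmark_genes)

    def rank_vector(self, record_id: str) -> np.ndarray:
        """Per-record rank permutation, aligned with ``landmark_genes``."""
        if record_id not in self._rank_cache:
            rec = self._by_id[record_id]
            self._rank_cache[record_id] = build_rank_vector(rec.z, rec.expr)
        return self._rank_cache[record_id]

    def rank_series(self, record_id: str) -> pd.Series:
        return pd.Series(self.rank_vector(record_id), index=self.landmark_genes)

    def regulated(self, record_id: str) -> RegulatedSets:
        if record_id not in self._regulated_cache:
            rec = self._by_id[record_id]
            self._regulated_cache[record_id] = regulated_sets(
                rec.z, self.landmark_genes, self.z_threshold
            )
        return self._regulated_cache[record_id]

    def meta_frame(self) -> pd.DataFrame:
        """Metadata of all records as a DataFrame (one row per record)."""
        rows = [
            {
                "record_id": r.record_id,
                "pert_id": r.pert_id,
                "pert_type": r.pert_type,
                "target_gene": r.target_gene if r.target_gene else "",
                "pert_name": r.pert_name,
                "cell_line": r.cell_line,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=META_COLUMNS)

    def z_frame(self) -> pd.DataFrame:
        """Landmark-gene x record z-score matrix."""
        data = np.column_stack([r.z for r in self.records]) if self.records else np.empty((self.n_landmark, 0))
        return pd.DataFrame(
            data, index=pd.Index(self.landmark_genes, name="gene"),
            columns=[r.record_id for r in self.records],
        )

    def expr_frame(self) -> pd.DataFrame | None:
        if not self.records or any(r.expr is None for r in self.records):
            return None
        data = np.column_stack([r.expr for r in self.records])
        return pd.DataFrame(
            data, index=pd.Index(self.landmark_genes, name="gene"),
            columns=[r.record_id for r in self.records],
        )


def _read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x record matrix from TSV or GCT text (dialect sniffed)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#1."):
        return read_gct(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return df


def read_gct(path: str | Path) -> pd.DataFrame:
    """Minimal reader for GCT v1.2/v1.3 text matrices.

    Returns a gene x sample DataFrame; row/column metadata beyond the gene
    identifier are discarded. Binary GCTX is not supported.
    """
    path = Path(path)
    with open(path) as fh:
        version_line = fh.readline().strip()
        dims = fh.readline().split()
        if version_line == "#1.2":
            if len(dims) < 2:
                raise ValidationError(f"{path}: malformed GCT 1.2 dimension line")
            nrow, ncol = int(dims[0]), int(dims[1])
            n_rowmeta = 1  # the Description column
        elif version_line == "#1.3":
            if len(dims) < 4:
                raise ValidationError(f"{path}: malformed GCT 1.3 dimension line")
            nrow, ncol, n_rowmeta, n_colmeta = (int(x) for x in dims[:4])
        else:
            raise ValidationError(f"{path}: unsupported GCT version line {version_line!r}")
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1 + n_rowmeta :]
        if len(sample_ids) != ncol:
            raise DimensionError(
                f"{path}: header names {len(sample_ids)} samples, dimension line says {ncol}"
            )
        if version_line == "#1.3":
            for _ in range(n_colmeta):
                fh.readline()
        body = pd.read_csv(fh, sep="\t", header=None, names=header)
    if len(body) != nrow:
        raise DimensionError(f"{path}: {len(body)} data rows, dimension line says {nrow}")
    out = body.set_index(header[0])[sample_ids].astype(float)
    out.index = out.index.astype(str)
    out.index.name = "gene"
    return out


def load_reference(
    meta_path: str | Path,
    zscore_path: str | Path,
    expr_path: str | Path | None = None,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> ReferenceDB:
    """Load and index a reference database from its metadata + matrix files.

    ``meta_path`` is a TSV with columns record_id, pert_id, pert_type,
    target_gene, pert_name, cell_line; matrices are TSV (first column the
    gene symbol) or GCT text, one column per record_id.
    """
    meta = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"{meta_path}: missing metadata columns {missing}")
    zmat = _read_matrix(zscore_path)
    if set(meta["record_id"]) != set(zmat.columns):
        only_meta = sorted(set(meta["record_id"]) - set(zmat.columns))[:5]
        only_z = sorted(set(zmat.columns) - set(meta["record_id"]))[:5]
        raise DimensionError(
            f"record_id mismatch between {meta_path} and {zscore_path} "
            f"(meta-only: {only_meta}, matrix-only: {only_z})"
        )
    emat = None
    if expr_path is not None:
        emat = _read_matrix(expr_path)
        if list(emat.index) != list(zmat.index):
            raise DimensionError(f"{expr_path}: gene rows differ from {zscore_path}")
        if set(emat.columns) != set(zmat.columns):
            raise DimensionError(f"{expr_path}: record columns differ from {zscore_path}")
    landmark = list(zmat.index)
    records = []
    for row in meta.itertuples(index=False):
        rid = row.record_id
        records.append(
            PerturbationRecord(
                record_id=rid,
                pert_id=row.pert_id,
                pert_type=row.pert_type,
                target_gene=row.target_gene or None,
                pert_name=row.pert_name,
                cell_line=row.cell_line,
                z=zmat[rid].to_numpy(),
                expr=emat[rid].to_numpy() if emat is not None else None,
            )
        )
    db = ReferenceDB(landmark_genes=landmark, records=records, z_threshold=z_threshold)
    logger.info("loaded reference: %d records, %d landmark genes", len(db), db.n_landmark)
    return db


def write_reference(db: ReferenceDB, out_dir: str | Path) -> dict[str, Path]:
    """Write the TSV triple (meta, z-scores, optional expression) for a database."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "meta": out_dir / "reference_meta.tsv",
        "zscore": out_dir / "reference_zscore.tsv",
    }
    db.meta_frame().to_csv(paths["meta"], sep="\t", index=False)
    db.z_frame().to_csv(paths["zscore"], sep="\t")
    expr = db.expr_frame()
    if expr is not None:
        paths["expr"] = out_dir / "reference_expr.tsv"
        expr.to_csv(paths["expr"], sep="\t")
    return paths
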