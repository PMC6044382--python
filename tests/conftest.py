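import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from indepth.reference_db import PerturbationRecord, ReferenceDB
from indepth.query_signature import QuerySignature

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


GENES6 = ["A", "B", "C", "D", "E", "F"]


def make_record(record_id, z, pert_type="knockdown", target_gene="A",
                pert_id=None, pert_name="", cell_line="HT29", expr=None):
    return PerturbationRecord(
        record_id=record_id,
        pert_id=pert_id or f"p_{record_id}",
        pert_type=pert_type,
        target_gene=target_gene if pert_type != "compound" else None,
        pert_name=pert_name or record_id,
        cell_line=cell_line,
        z=np.asarray(z, dtype=float),
        expr=expr,
    )


@pytest.fixture
def tiny_db():
    """Three records over six genes; values chosen for easy hand checks."""
    records = [
        make_record("r1", [3.0, 2.0, 0.0, -1.0, -2.5, 0.5], target_gene="D"),
        make_record("r2", [-2.0, 0.1, 2.0, 2.5, -3.0, 0.0], target_gene="C",
                    pert_type="overexpression"),
        make_record("r3", [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], pert_type="compound",
                    pert_name="etoposide"),
    ]
    return ReferenceDB(landmark_genes=list(GENES6), records=records)


def toy_cascade():
    """Hand-built 6-record reference exercising every upstream-selection rule.

    Query: UP = {A, C}, DOWN = {D, E}. With cutoff 0.5 the hand enumeration is
    6 genetic records -> 5 at/above cutoff -> 4 direction-consistent ->
    3 after per-(gene, pert_id) dedup -> 2 after the >=2-shRNA rule
    (both surviving records knock down D).
    """
    z = {
        # D knockdown, clone sh1, best score: downstream C up, E down (+ self D)
        "k1": [0.0, 2.2, 2.5, -4.0, -3.0, 0.0],
        # D knockdown, clone sh2: downstream A up, E down
        "k2": [2.0, 0.0, 0.0, -4.0, -2.5, 0.0],
        # D knockdown, clone sh1 again, lower score: removed by dedup
        "k3": [0.0, 0.0, 2.1, -4.0, -2.1, 0.0],
        # E knockdown, single clone: removed by the >=2-shRNA rule
        "k4": [0.0, 0.0, 0.0, 0.0, -4.0, 2.4],
        # A knockdown but A is an UP DEG: direction-inconsistent
        "k5": [-4.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        # D knockdown below the cutoff
        "k6": [0.0, 0.0, 0.0, -4.0, 0.0, 0.0],
    }
    meta = {
        "k1": ("D", "sh1", 0.9),
        "k2": ("D", "sh2", 0.8),
        "k3": ("D", "sh1", 0.7),
        "k4": ("E", "sh9", 0.85),
        "k5": ("A", "sh5", 0.95),
        "k6": ("D", "sh3", 0.3),
    }
    records = [
        make_record(rid, z[rid], target_gene=meta[rid][0], pert_id=meta[rid][1])
        for rid in sorted(z)
    ]
    db = ReferenceDB(landmark_genes=list(GENES6), records=records)
    query = QuerySignature(
        up_degs=frozenset({"A", "C"}),
        down_degs=frozenset({"D", "E"}),
        gene_ratio={"A": 4.0, "C": 2.5, "D": 0.25, "E": 0.4},
    )
    scores = pd.DataFrame(
        [
            {"record_id": rid, "pert_id": meta[rid][1], "pert_type": "knockdown",
             "target_gene": meta[rid][0], "pert_name": rid, "cell_line": "HT29",
             "ks_up": np.nan, "ks_down": np.nan, "score": meta[rid][2], "scored": True}
            for rid in sorted(z)
        ]
    )
    expected_audit = {"n_genetic": 6, "n_cutoff": 5, "n_direction": 4,
                      "n_dedup": 3, "n_final": 2}
    return db, query, scores, expected_audit


@pytest.fixture
def simple_query():
    return QuerySignature(
        up_degs=frozenset({"A", "C"}),
        down_degs=frozenset({"D", "E"}),
        gene_ratio={"A": 4.0, "C": 2.5, "D": 0.25, "E": 0.4, "B": 1.0, "F": 1.1},
        meta={"drug": "etoposide"},
    )
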