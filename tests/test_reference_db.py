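import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from indepth.errors import DimensionError, ValidationError
from indepth.reference_db import (
    ReferenceDB,
    build_rank_vector,
    load_reference,
    read_gct,
    regulated_sets,
    write_reference,
)
from conftest import GENES6, make_record
from oracles import rank_bruteforce


class TestBuildRankVector:
    def test_descending_order(self):
        assert build_rank_vector(np.array([-1.0, 0.0, 3.0])).tolist() == [3, 2, 1]

    def test_z_tie_broken_by_higher_expression(self):
        ranks = build_rank_vector(np.array([2.0, 2.0, -1.0]),
                                  expr=np.array([100.0, 200.0, 10.0]))
        assert ranks.tolist() == [2, 1, 3]

    def test_residual_tie_broken_by_input_order(self):
        assert build_rank_vector(np.zeros(4)).tolist() == [1, 2, 3, 4]

    def test_rejects_non_finite(self):
        with pytest.raises(ValidationError):
            build_rank_vector(np.array([1.0, np.nan]))

    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=20),
           st.booleans())
    def test_matches_stable_sort_oracle(self, zvals, with_expr):
        # integer z-scores force plenty of exact ties
        z = np.array(zvals, dtype=float)
        expr = (np.arange(len(z))[::-1] % 3).astype(float) if with_expr else None
        got = build_rank_vector(z, expr)
        assert got.tolist() == rank_bruteforce(zvals, expr)
        assert sorted(got) == list(range(1, len(z) + 1))

    def test_invariant_under_gene_reordering(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=15)
        perm = rng.permutation(15)
        assert build_rank_vector(z)[perm].tolist() == build_rank_vector(z[perm]).tolist()


class TestRegulatedSets:
    def test_inclusive_boundaries(self):
        rs = regulated_sets(np.array([2.0, 1.9, -2.0]), ["g1", "g2", "g3"])
        assert rs.up_set == {"g1"} and rs.down_set == {"g3"}

    def test_all_zero_gives_empty_sets(self):
        rs = regulated_sets(np.zeros(3), ["a", "b", "c"])
        assert not rs.up_set and not rs.down_set

    def test_rejects_nonpositive_threshold(self):
        with pytest.raises(ValidationError):
            regulated_sets(np.zeros(2), ["a", "b"], threshold=0)

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=30))
    def test_matches_bruteforce_filter_and_disjoint(self, zvals):
        genes = [f"g{i}" for i in range(len(zvals))]
        rs = regulated_sets(np.array(zvals), genes)
        assert rs.up_set == {g for g, z in zip(genes, zvals) if z >= 2}
        assert rs.down_set == {g for g, z in zip(genes, zvals) if z <= -2}
        assert not (rs.up_set & rs.down_set)


class TestReferenceDB:
    def test_construction_and_indexes(self, tiny_db):
        assert len(tiny_db) == 3 and tiny_db.n_landmark == 6
        for rec in tiny_db.records:
            assert sorted(tiny_db.rank_vector(rec.record_id)) == list(range(1, 7))
        assert tiny_db.regulated("r1").up_set == {"A", "B"}
        assert tiny_db.regulated("r1").down_set == {"E"}

    def test_duplicate_record_id_rejected(self):
        recs = [make_record("r1", np.zeros(6)), make_record("r1", np.zeros(6))]
        with pytest.raises(ValidationError, match="duplicate record_id"):
            ReferenceDB(landmark_genes=list(GENES6), records=recs)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            ReferenceDB(landmark_genes=list(GENES6),
                        records=[make_record("r1", np.zeros(5))])

    def test_unknown_pert_type_rejected(self):
        with pytest.raises(ValidationError, match="pert_type"):
            make_record("r1", np.zeros(6), pert_type="crispr")

    def test_genetic_perturbation_requires_target(self):
        with pytest.raises(ValidationError, match="target_gene"):
            make_record("r1", np.zeros(6), target_gene=None)


class TestLoadWriteRoundTrip:
    def test_round_trip_reproduces_tables(self, tiny_db, tmp_path):
        paths = write_reference(tiny_db, tmp_path / "ref")
        db2 = load_reference(paths["meta"], paths["zscore"])
        paths2 = write_reference(db2, tmp_path / "ref2")
        for key in paths:
            assert paths[key].read_bytes() == paths2[key].read_bytes()

    def test_missing_record_in_meta_is_dimension_error(self, tiny_db, tmp_path):
        paths = write_reference(tiny_db, tmp_path / "ref")
        meta = pd.read_csv(paths["meta"], sep="\t")
        meta.iloc[:-1].to_csv(paths["meta"], sep="\t", index=False)
        with pytest.raises(DimensionError):
            load_reference(paths["meta"], paths["zscore"])


class TestGct:
    @pytest.mark.parametrize("version,extra", [
        ("#1.2", "2\t3"),
        ("#1.3", "2\t3\t1\t0"),
    ])
    def test_reads_both_text_dialects(self, tmp_path, version, extra):
        text = (f"{version}\n{extra}\n"
                "NAME\tDescription\ts1\ts2\ts3\n"
                "gA\tna\t1.0\t2.0\t3.0\n"
                "gB\tna\t-1.0\t0.0\t0.5\n")
        p = tmp_path / "m.gct"
        p.write_text(text)
        df = read_gct(p)
        assert df.shape == (2, 3)
        assert df.loc["gB", "s3"] == 0.5

    def test_malformed_dimensions_rejected(self, tmp_path):
        p = tmp_path / "bad.gct"
        p.write_text("#1.2\n5\t3\nNAME\tDescription\ts1\ts2\ts3\ngA\tx\t1\t2\t3\n")
        with pytest.raises(DimensionError):
            read_gct(p)
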