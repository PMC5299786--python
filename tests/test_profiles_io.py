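import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import funcvar as fv
from funcvar.profiles_io import FuncvarError


def _write(path, text):
    path.write_text(text)
    return str(path)


class TestReadProfile:
    def test_parses_small_table(self, tmp_path):
        p = _write(tmp_path / "t.tsv", "gene\tsA\tsB\nKO1\t1\t2\nKO2\t3\t4\n")
        prof = fv.read_profile(p)
        assert prof.sample_ids == ["sA", "sB"]
        assert prof.gene_ids == ["KO1", "KO2"]
        assert prof.data.loc["sB", "KO2"] == 4.0
        assert prof.normalization_state == "raw"

    def test_csv_delimiter_from_extension(self, tmp_path):
        p = _write(tmp_path / "t.csv", "gene,sA,sB\nKO1,1,2\nKO2,3,4\n")
        assert fv.read_profile(p).data.loc["sA", "KO2"] == 3.0

    def test_negative_value_names_cell(self, tmp_path):
        p = _write(tmp_path / "t.tsv", "gene\tsA\tsB\nKO1\t1\t-1\n")
        with pytest.raises(FuncvarError, match="KO1.*sB|sB.*KO1"):
            fv.read_profile(p)

    def test_orientation_flag_transposes(self, tmp_path):
        p1 = _write(tmp_path / "a.tsv", "gene\tsA\tsB\nKO1\t1\t2\nKO2\t3\t4\n")
        p2 = _write(tmp_path / "b.tsv", "sample\tKO1\tKO2\nsA\t1\t3\nsB\t2\t4\n")
        a = fv.read_profile(p1, orientation="genes_in_rows")
        b = fv.read_profile(p2, orientation="genes_in_columns")
        assert a.equals(b)

    def test_empty_cell_is_error(self, tmp_path):
        p = _write(tmp_path / "t.tsv", "gene\tsA\tsB\nKO1\t1\t\n")
        with pytest.raises(FuncvarError, match="empty cell"):
            fv.read_profile(p)

    def test_ragged_row_is_error(self, tmp_path):
        p = _write(tmp_path / "t.tsv", "gene\tsA\tsB\nKO1\t1\t2\t3\n")
        with pytest.raises(FuncvarError, match="ragged"):
            fv.read_profile(p)

    def test_duplicate_gene_id_is_error(self, tmp_path):
        p = _write(tmp_path / "t.tsv", "gene\tsA\nKO1\t1\nKO1\t2\n")
        with pytest.raises(FuncvarError, match="duplicate"):
            fv.read_profile(p)


class TestRoundTrip:
    def test_write_read_identity(self, toy_profile, tmp_path):
        path = tmp_path / "out.tsv"
        fv.write_profile(toy_profile, path)
        again = fv.read_profile(path)
        assert again.equals(toy_profile, rtol=1e-12)

    def test_many_digit_values_preserved(self, tmp_path):
        vals = np.array([[1.2345678901234567e-3, 9.87654321098765e8]])
        prof = fv.GeneProfile(pd.DataFrame(vals, index=["s1"],
                                           columns=["KO1", "KO2"]))
        path = tmp_path / "out.tsv"
        fv.write_profile(prof, path)
        assert np.allclose(fv.read_profile(path).values, vals, rtol=1e-12, atol=0)

    def test_empty_profile_rejected(self, toy_profile, tmp_path):
        empty = fv.GeneProfile(toy_profile.data.iloc[:0])
        with pytest.raises(FuncvarError):
            fv.write_profile(empty, tmp_path / "x.tsv")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 2 ** 31 - 1))
    def test_roundtrip_random_profiles(self, tmp_path_factory, n_s, n_g, seed):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(rng.gamma(1.0, 5.0, (n_s, n_g)),
                            index=[f"s{i}" for i in range(n_s)],
                            columns=[f"g{i}" for i in range(n_g)])
        prof = fv.GeneProfile(data)
        path = tmp_path_factory.mktemp("rt") / "p.tsv"
        fv.write_profile(prof, path)
        assert fv.read_profile(path).equals(prof, rtol=1e-12)


class TestPathwayMap:
    def test_shared_nonshared_classification(self, tmp_path):
        p = _write(tmp_path / "m.tsv", "KO1\tP1\nKO1\tP2\nKO2\tP1\n")
        pmap = fv.read_pathway_map(p)
        assert pmap.shared_genes == {"KO1"}
        assert pmap.nonshared_genes == {"KO2"}

    def test_duplicate_pair_warns_and_dedupes(self, tmp_path):
        p = _write(tmp_path / "m.tsv", "KO1\tP1\nKO1\tP1\n")
        with pytest.warns(UserWarning, match="duplicate"):
            pmap = fv.read_pathway_map(p)
        assert len(pmap) == 1

    def test_wrong_field_count_reports_line(self, tmp_path):
        p = _write(tmp_path / "m.tsv", "KO1\tP1\nKO2\tP1\textra\n")
        with pytest.raises(FuncvarError, match="line 2"):
            fv.read_pathway_map(p)

    def test_empty_map_rejected_downstream(self, tmp_path):
        p = _write(tmp_path / "m.tsv", "\n")
        pmap = fv.read_pathway_map(p)
        with pytest.raises(FuncvarError):
            fv.classify_genes(pmap)


class TestOtherTables:
    def test_genome_content_requires_integers(self):
        with pytest.raises(FuncvarError, match="non-integer"):
            fv.GenomeContent(pd.DataFrame([[1.5]], index=["g1"], columns=["KO1"]))

    def test_metadata_rejects_duplicate_individual_visit(self):
        frame = pd.DataFrame(
            {"individual_id": ["A", "A"], "visit": [1, 1]},
            index=pd.Index(["s1", "s2"], name="sample_id"))
        with pytest.raises(FuncvarError, match="unique"):
            fv.SampleMetadata(frame)

    def test_metadata_roundtrip(self, tmp_path):
        frame = pd.DataFrame(
            {"individual_id": ["A", "B"], "visit": [1, 1],
             "group": ["case", "control"]},
            index=pd.Index(["s1", "s2"], name="sample_id"))
        meta = fv.SampleMetadata(frame)
        path = tmp_path / "meta.tsv"
        from funcvar.profiles_io import write_metadata
        write_metadata(meta, path)
        again = fv.read_metadata(path)
        assert list(again.data["individual_id"]) == ["A", "B"]
        assert list(again.data["group"]) == ["case", "control"]

    def test_marker_list_roundtrip(self, tmp_path):
        from funcvar.profiles_io import write_marker_set
        markers = fv.MarkerSet.from_ids(["M1", "M2"])
        path = tmp_path / "m.txt"
        write_marker_set(markers, path)
        assert fv.read_marker_set(path).gene_ids == markers.gene_ids

    def test_distance_matrix_validation(self):
        bad = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]],
                           index=["a", "b"], columns=["a", "b"])
        with pytest.raises(FuncvarError, match="symmetric"):
            fv.DistanceMatrix(bad)
        with pytest.raises(FuncvarError, match="diagonal"):
            fv.DistanceMatrix(pd.DataFrame([[1.0]], index=["a"], columns=["a"]))
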