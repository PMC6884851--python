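import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import spatqreg as sq
from spatqreg.data_model import MISSING_LEVEL


def _tiny_csv(rows):
    header = "birth_weight,bmi_class,smoking,birth_order,education,wealth,height_class,weight_class,mother_age,antenatal_visits,district"
    return io.StringIO("\n".join([header] + rows))


ROW = "3.1,18.5-25,no,1,none,poorest,<150,<45,25,4,D01"


class TestReadDataset:
    def test_missing_response_rows_dropped_and_counted(self):
        rows = [ROW, ROW.replace("3.1", "NA"), ROW, ROW, ROW]
        data = sq.read_dataset(_tiny_csv(rows))
        assert data.n == 4
        assert data.n_dropped_response == 1

    def test_all_rows_with_response_retained(self):
        data = sq.read_dataset(_tiny_csv([ROW] * 5))
        assert data.n == 5
        assert data.n_dropped_response == 0

    def test_unknown_category_value_names_column(self):
        bad = ROW.replace("poorest", "plutocrat")
        with pytest.raises(sq.SchemaError, match="wealth"):
            sq.read_dataset(_tiny_csv([ROW, bad]))

    def test_missing_categorical_becomes_extra_level(self):
        rows = [ROW, ROW.replace("no,1", "NA,1")]
        data = sq.read_dataset(_tiny_csv(rows))
        assert MISSING_LEVEL in data.category_levels["smoking"]
        assert data.df.loc[1, "smoking"] == MISSING_LEVEL
        # the missing level is never a reference level
        assert data.schema.references["smoking"] != MISSING_LEVEL

    def test_missing_metrical_becomes_nan(self):
        rows = [ROW, ROW.replace(",25,", ",NA,")]
        data = sq.read_dataset(_tiny_csv(rows))
        assert np.isnan(data.df.loc[1, "mother_age"])

    def test_nonpositive_weight_dropped(self):
        rows = [ROW, ROW.replace("3.1", "-1.0")]
        data = sq.read_dataset(_tiny_csv(rows))
        assert data.n == 1 and data.n_dropped_response == 1


def test_dataset_roundtrip(tmp_path, grid28):
    data, _ = sq.simulate_dataset(150, grid28, seed=3, missing_rate=0.05)
    path = tmp_path / "records.csv"
    sq.write_dataset(data, path)
    back = sq.read_dataset(path, data.schema)
    assert back == data


class TestAdjacency:
    def _read(self, text, tmp_path):
        p = tmp_path / "graph.txt"
        p.write_text(text)
        return sq.read_adjacency(p)

    def test_two_node_edge(self, tmp_path):
        g = self._read("A: B\nB: A\n", tmp_path)
        assert g.n == 2 and g.n_edges() == 1
        assert g.n_i() == {"A": 1, "B": 1}

    def test_asymmetric_symmetrized_with_warning(self, tmp_path):
        with pytest.warns(UserWarning, match="symmetrized"):
            g = self._read("A: B\nB:\n", tmp_path)
        assert g.n_edges() == 1

    def test_three_node_path_degrees(self, tmp_path):
        g = self._read("A: B\nB: A C\nC: B\n", tmp_path)
        assert [g.n_i()[x] for x in "ABC"] == [1, 2, 1]

    def test_self_loop_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="self-loop"):
            self._read("A: A B\nB: A\n", tmp_path)

    def test_unknown_label_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown neighbour"):
            self._read("A: B Z\nB: A\n", tmp_path)

    def test_gal_format(self, tmp_path):
        text = "3\nA 1\nB\nB 2\nA C\nC 1\nB\n"
        g = self._read(text, tmp_path)
        assert g.nodes == ["A", "B", "C"]
        assert g.n_i() == {"A": 1, "B": 2, "C": 1}

    def test_roundtrip(self, tmp_path, grid28):
        p = tmp_path / "g.txt"
        sq.write_adjacency(grid28, p)
        assert sq.read_adjacency(p) == grid28


class TestBuildDesign:
    def _data(self, values, levels=("x", "y", "z")):
        schema = sq.DataSchema(categoricals={"g": list(levels)},
                               references={"g": levels[0]}, metricals=("m",),
                               response="bw", district="d")
        df = pd.DataFrame({"bw": np.full(len(values), 3.0), "g": values,
                           "m": [2.0, 5.0, 5.0, 9.0][: len(values)],
                           "d": "D01"})
        return sq.Dataset(df=df, schema=schema,
                          category_levels={"g": list(levels)})

    def _spec(self):
        return sq.ModelSpec(tau=0.05, fixed_terms=[sq.FixedTerm("g", "x")],
                            smooth_terms=[sq.SmoothTerm("m")],
                            spatial_term=None)

    def test_column_count_and_order(self):
        des = sq.build_design(self._data(["x", "y", "z", "y"]), self._spec())
        assert des.colnames == ["intercept", "g=y", "g=z"]
        assert des.W.shape == (4, 3)

    def test_reference_row_is_intercept_only(self):
        des = sq.build_design(self._data(["x", "y", "z", "x"]), self._spec())
        assert np.array_equal(des.W[0], [1.0, 0.0, 0.0])
        # dotted with any coefficient vector whose dummies are zero
        beta = np.array([2.7, 0.0, 0.0])
        assert des.W[0] @ beta == 2.7

    def test_smooth_index_over_sorted_uniques(self):
        des = sq.build_design(self._data(["x", "y", "z", "y"]), self._spec())
        assert np.array_equal(des.smooth_grids["m"], [2.0, 5.0, 9.0])
        assert np.array_equal(des.smooth_index["m"], [0, 1, 1, 2])

    def test_single_observed_level_rejected(self):
        with pytest.raises(sq.DesignError, match="single observed level"):
            sq.build_design(self._data(["x", "x", "x", "x"]), self._spec())

    @given(st.permutations(list(range(4))))
    def test_row_permutation_equivariance(self, perm):
        data = self._data(["x", "y", "z", "y"])
        des = sq.build_design(data, self._spec())
        shuffled = sq.Dataset(df=data.df.iloc[perm].reset_index(drop=True),
                              schema=data.schema,
                              category_levels=data.category_levels)
        des2 = sq.build_design(shuffled, self._spec())
        assert np.array_equal(des2.W, des.W[perm])
        assert np.array_equal(des2.smooth_index["m"],
                              des.smooth_index["m"][perm])
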