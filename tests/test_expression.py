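"""Expression layer: loading, replicate averaging, filter/floor, LFCs,
regulated-set selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erp import expression


def _write(tmp_path, tpm: pd.DataFrame, meta: pd.DataFrame):
    tpm_path = tmp_path / "tpm.tsv"
    meta_path = tmp_path / "meta.tsv"
    tpm.to_csv(tpm_path, sep="\t", index_label="gene_id")
    meta.to_csv(meta_path, sep="\t", index=False)
    return tpm_path, meta_path


def _meta(rows):
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "timepoint_h", "assay", "replicate"])


class TestLoad:
    def test_identity_load(self, tmp_path):
        tpm = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]}, index=["g1", "g2", "g3"]
        )
        meta = _meta([["s1", "WT", 0, "ribo", 1], ["s2", "WT", 1, "ribo", 1]])
        m = expression.load_expression(*_write(tmp_path, tpm, meta))
        assert m.values.shape == (3, 2)
        assert list(m.gene_ids) == ["g1", "g2", "g3"]

    def test_replicates_averaged(self, tmp_path):
        tpm = pd.DataFrame({"r1": [10.0], "r2": [14.0], "c": [4.0]}, index=["g1"])
        meta = _meta(
            [["r1", "WT", 1, "ribo", 1], ["r2", "WT", 1, "ribo", 2], ["c", "WT", 0, "ribo", 1]]
        )
        m = expression.load_expression(*_write(tmp_path, tpm, meta))
        assert m.values.loc["g1", "WT_ribo_1h"] == 12.0

    def test_na_cell_names_offender(self, tmp_path):
        tpm = pd.DataFrame({"s1": ["NA"], "s2": [2.0]}, index=["g1"])
        meta = _meta([["s1", "WT", 0, "ribo", 1], ["s2", "WT", 1, "ribo", 1]])
        with pytest.raises(ValueError, match="g1.*s1"):
            expression.load_expression(*_write(tmp_path, tpm, meta))

    def test_missing_metadata_column(self, tmp_path):
        tpm = pd.DataFrame({"s1": [1.0], "sX": [2.0]}, index=["g1"])
        meta = _meta([["s1", "WT", 0, "ribo", 1]])
        with pytest.raises(ValueError, match="sX"):
            expression.load_expression(*_write(tmp_path, tpm, meta))

    def test_duplicate_gene_id(self):
        values = pd.DataFrame({"c0": [1.0, 2.0]}, index=["g1", "g1"])
        with pytest.raises(ValueError, match="duplicate gene id"):
            expression.ExpressionMatrix(
                values, [expression.SampleMeta("c0", "WT", 0.0, "ribo")]
            )

    def test_missing_control_rejected(self):
        values = pd.DataFrame({"c1": [1.0]}, index=["g1"])
        metas = [expression.SampleMeta("c1", "WT", 1.0, "ribo")]
        with pytest.raises(ValueError, match="control"):
            expression.build_matrix(values, metas)


class TestFilterAndFloor:
    @pytest.mark.parametrize(
        "row,kept,expected",
        [
            ([1, 1, 3, 1, 2], False, None),            # mean 1.6 < 2 -> removed
            ([4, 4, 4, 4, 4], True, [4, 4, 4, 4, 4]),  # untouched
            ([2, 3, 5, 8, 2], True, [4, 4, 5, 8, 4]),  # mean 4.0: kept, floored
        ],
    )
    def test_rule(self, row, kept, expected):
        values = pd.DataFrame(
            [row, [10] * 5], index=["g", "keepalive"],
            columns=[f"c{t}" for t in range(5)],
        )
        metas = [
            expression.SampleMeta(f"c{t}", "WT", float(t), "ribo") for t in range(5)
        ]
        m = expression.ExpressionMatrix(values.astype(float), metas)
        out = expression.filter_and_floor(m)
        assert ("g" in out.gene_ids) == kept
        if kept:
            assert list(out.values.loc["g"]) == expected

    def test_all_filtered_is_error(self, small_matrix):
        with pytest.raises(ValueError, match="filtered"):
            expression.filter_and_floor(small_matrix, min_avg_tpm=1e9)

    def test_idempotent(self, default_dataset):
        m, _ = default_dataset
        once = expression.filter_and_floor(m)
        twice = expression.filter_and_floor(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestComputeLfc:
    def test_hand_values(self, small_matrix):
        floored = expression.filter_and_floor(small_matrix)
        lfc = expression.compute_lfc(floored, "ribo")
        col = lfc.lfc[("WT", 1.0)]
        assert col["g1"] == pytest.approx(1.0)   # 8 / 4
        assert col["g2"] == pytest.approx(-2.0)  # floored 4 / 16
        assert col["g3"] == pytest.approx(0.0)

    def test_matrix_vs_itself_is_zero(self, default_dataset):
        m, _ = default_dataset
        floored = expression.filter_and_floor(m)
        # control columns against themselves: every 0 h condition excluded,
        # so build a matrix whose stress columns equal the control
        sub = floored.subset(assay="ribo", genotype="WT")
        ctrl = sub.values["WT_ribo_0h"]
        values = pd.DataFrame({s.sample_id: ctrl for s in sub.samples}, index=sub.values.index)
        clone = expression.ExpressionMatrix(values, sub.samples)
        lfc = expression.compute_lfc(clone, "ribo")
        assert np.allclose(lfc.lfc.to_numpy(), 0.0)

    def test_missing_control_raises(self, small_matrix):
        no_ctrl = small_matrix.subset(assay="ribo")
        no_ctrl.values = no_ctrl.values[["c1"]]
        no_ctrl.samples = [s for s in no_ctrl.samples if s.timepoint_h > 0]
        with pytest.raises(ValueError, match="control"):
            expression.compute_lfc(no_ctrl, "ribo")


class TestSelectRegulated:
    def _table(self, lfcs):
        frame = pd.DataFrame(
            {("WT", t): [v] for t, v in zip([1.0, 2.0, 5.0, 8.0], lfcs)}, index=["g"]
        )
        frame.columns = pd.MultiIndex.from_tuples(frame.columns)
        return expression.LfcTable(frame, "ribo")

    def test_single_timepoint_hit(self):
        assert expression.select_regulated(self._table([0.2, 1.1, 0.5, 0.3]), "WT") == {"g"}

    def test_all_below_cutoff(self):
        assert expression.select_regulated(self._table([0.9, -0.9, 0.5, 0.0]), "WT") == set()

    def test_boundary_inclusive(self):
        assert expression.select_regulated(self._table([1.0, 0, 0, 0]), "WT") == {"g"}

    def test_unknown_genotype(self):
        with pytest.raises(KeyError):
            expression.select_regulated(self._table([1, 0, 0, 0]), "XX")

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        lfcs=st.lists(
            st.floats(-4, 4, allow_nan=False), min_size=4, max_size=4
        ),
        cut_lo=st.floats(1.1, 2.0),
        cut_hi=st.floats(2.0, 4.0),
    )
    def test_monotone_in_cutoff(self, lfcs, cut_lo, cut_hi):
        table = self._table(lfcs)
        high = expression.select_regulated(table, "WT", cut_hi)
        low = expression.select_regulated(table, "WT", cut_lo)
        assert high <= low
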