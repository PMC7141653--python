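"""Label-file and IOI-table I/O, onset/IOI conversions and their round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rhythmkit import (
    Dataset,
    ElementSequence,
    InsufficientDataError,
    IOISequence,
    ParseError,
    SchemaError,
    ValidationError,
    compute_iois,
    onsets_from_iois,
    read_ioi_table,
    read_label_file,
    write_ioi_table,
)

positive_iois = st.lists(
    st.floats(min_value=1e-4, max_value=10.0, allow_nan=False), min_size=1, max_size=40
)


class TestElementSequence:
    def test_rejects_non_monotone_onsets(self):
        with pytest.raises(ValidationError):
            ElementSequence(onsets=[0.0, 0.2, 0.1])

    def test_rejects_offset_before_onset(self):
        with pytest.raises(ValidationError):
            ElementSequence(onsets=[0.0, 0.2], offsets=[0.1, 0.15])

    def test_duration_spans_first_to_last_onset(self):
        assert ElementSequence(onsets=[0.5, 0.7, 1.5]).duration == 1.0


class TestLabelFile:
    def test_parses_three_row_file(self, label_file):
        p = label_file([(0.0, 0.05), (0.1, 0.15), (0.2, 0.25)])
        seq = read_label_file(p)
        assert len(seq) == 3
        assert np.allclose(seq.onsets, [0.0, 0.1, 0.2])
        assert seq.sequence_id == "seq01"

    def test_header_and_labels_are_accepted(self, label_file):
        p = label_file(
            [(0.0, 0.05, "A"), (0.1, 0.15, "B")], header="onset\toffset\tlabel"
        )
        seq = read_label_file(p)
        assert seq.labels == ("A", "B")

    def test_offset_before_onset_names_the_row(self, label_file):
        p = label_file([(0.0, 0.05), (0.1, 0.08), (0.2, 0.25)])
        with pytest.raises(ParseError, match="row 2"):
            read_label_file(p)

    def test_shuffled_rows_sorted_with_warning_by_default(self, label_file, caplog):
        p = label_file([(0.2, 0.25), (0.0, 0.05), (0.1, 0.15)])
        with caplog.at_level("WARNING", logger="rhythmkit"):
            seq = read_label_file(p)
        assert np.allclose(seq.onsets, [0.0, 0.1, 0.2])
        assert any("out of time order" in r.message for r in caplog.records)

    def test_shuffled_rows_raise_in_strict_mode(self, label_file):
        p = label_file([(0.2, 0.25), (0.0, 0.05)])
        with pytest.raises(ParseError):
            read_label_file(p, strict=True)

    def test_non_numeric_field_reports_line(self, label_file):
        p = label_file([(0.0, 0.05), ("x", 0.2)])
        with pytest.raises(ParseError, match="row 2"):
            read_label_file(p)

    def test_millisecond_unit_converts_to_seconds(self, label_file):
        p = label_file([(0, 50), (100, 150)])
        seq = read_label_file(p, unit="ms")
        assert np.allclose(seq.onsets, [0.0, 0.1])

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(IOError):
            read_label_file(tmp_path / "nope.txt")


class TestIOITable:
    def _toy(self, tmp_path):
        df = pd.DataFrame(
            dict(
                species=["sp"] * 4,
                individual=["a", "a", "b", "b"],
                sequence_id=["s1", "s1", "s2", "s2"],
                ioi_s=[0.1, 0.2, 0.3, 0.4],
            )
        )
        p = tmp_path / "toy.csv"
        df.to_csv(p, index=False)
        return p

    def test_toy_table_yields_two_sequences(self, tmp_path):
        ds = read_ioi_table(self._toy(tmp_path))
        assert len(ds) == 2
        assert [len(s) for s in ds.sequences] == [2, 2]
        assert ds.sequences[1].individual_id == "b"

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame(dict(species=["x"], ioi_s=[0.1])).to_csv(p, index=False)
        with pytest.raises(SchemaError, match="sequence_id"):
            read_ioi_table(p)

    def test_non_positive_ioi_lists_rows(self, tmp_path):
        p = tmp_path / "neg.csv"
        pd.DataFrame(
            dict(
                species=["x"] * 2, individual=["a"] * 2,
                sequence_id=["s"] * 2, ioi_s=[0.1, -0.2],
            )
        ).to_csv(p, index=False)
        with pytest.raises(ValidationError, match=r"\[1\]"):
            read_ioi_table(p)

    def test_custom_column_mapping_and_ms_unit(self, tmp_path):
        p = tmp_path / "alt.tsv"
        pd.DataFrame(
            dict(Sp=["x"], Ind=["a"], Seq=["s"], IOI_ms=[100.0])
        ).to_csv(p, sep="\t", index=False)
        ds = read_ioi_table(
            p,
            columns=dict(species="Sp", individual="Ind", sequence="Seq", ioi="IOI_ms"),
            unit="ms",
        )
        assert np.allclose(ds.sequences[0].iois, [0.1])

    def test_write_read_round_trip_preserves_full_precision(self, tmp_path):
        iois = np.array([0.1234567890123456, 1 / 3, 0.05])
        ds = Dataset(
            name="rt",
            sequences=[IOISequence(iois=iois, sequence_id="s1", species="x",
                                   individual_id="a")],
        )
        p = tmp_path / "rt.csv"
        write_ioi_table(ds, p)
        back = read_ioi_table(p)
        assert np.array_equal(back.sequences[0].iois, iois)

    def test_xlsx_round_trip(self, tmp_path):
        df = pd.DataFrame(
            dict(species=["x"] * 2, individual=["a"] * 2,
                 sequence_id=["s"] * 2, ioi_s=[0.25, 0.5])
        )
        p = tmp_path / "t.xlsx"
        df.to_excel(p, index=False)
        ds = read_ioi_table(p)
        assert np.allclose(ds.pooled_iois(), [0.25, 0.5])


class TestConversions:
    def test_iois_are_first_differences(self):
        seq = ElementSequence(onsets=[0.0, 0.1, 0.3])
        assert np.allclose(compute_iois(seq).iois, [0.1, 0.2])

    def test_single_onset_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            compute_iois(ElementSequence(onsets=[0.0]))

    def test_onsets_from_iois_anchors_at_zero(self):
        seq = onsets_from_iois([0.1, 0.2])
        assert np.allclose(seq.onsets, [0.0, 0.1, 0.3])

    def test_empty_ioi_list_degenerates_with_warning(self):
        with pytest.warns(UserWarning):
            seq = onsets_from_iois([])
        assert np.array_equal(seq.onsets, [0.0])

    @given(positive_iois)
    def test_round_trip_identity(self, iois):
        # differencing the cumulative sums reintroduces rounding at the
        # scale of the accumulated total, not of the individual IOI
        back = compute_iois(onsets_from_iois(iois))
        atol = 1e-12 * max(1.0, float(np.sum(iois)))
        assert np.allclose(back.iois, iois, rtol=0, atol=atol)

    def test_dataset_rejects_duplicate_sequence_ids(self):
        with pytest.raises(ValidationError):
            Dataset(
                sequences=[
                    IOISequence(iois=[0.1], sequence_id="s"),
                    IOISequence(iois=[0.2], sequence_id="s"),
                ]
            )

    def test_grouping_by_individual(self, standins):
        ds = standins["C_perspicillata"]
        groups = ds.by_individual()
        assert len(groups) == 5
        assert sum(len(v) for v in groups.values()) == len(ds)
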