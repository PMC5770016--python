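"""Domain-type invariants and table/image round trips."""

import numpy as np
import pandas as pd
import pytest

from dentinchron.chronology import estimate_days, prediction_pair, summarize_spacings
from dentinchron.io import (
    load_image,
    read_measurement_table,
    read_metadata_table,
    read_summary_table,
    save_image,
    write_measurement_table,
    write_metadata_table,
    write_summary_table,
)
from dentinchron.model import (
    DayEstimate,
    GLGRecord,
    GrowthPath,
    ImageWithScale,
    PredictionPair,
    Profile,
    SchemaError,
    SpacingMeasurement,
    ValidationError,
)


class TestDomainInvariants:
    def test_record_rejects_bad_values(self):
        with pytest.raises(ValidationError):
            GLGRecord("s", "a", thickness_um=-1.0)
        with pytest.raises(ValidationError):
            GLGRecord("s", "a", thickness_um=1.0, sex="X")
        with pytest.raises(ValidationError):
            GLGRecord("s", "a", thickness_um=1.0, preparation="frozen")

    def test_spacing_must_be_positive(self):
        with pytest.raises(ValidationError):
            SpacingMeasurement(("s", "a"), position_um=1.0, spacing_um=0.0)

    def test_day_estimate_convexity_enforced(self):
        with pytest.raises(ValidationError):
            DayEstimate(days=300.0, err_minus=20.0, err_plus=10.0)

    def test_prediction_pair_doubling_enforced(self):
        with pytest.raises(ValidationError):
            PredictionPair(pred_1glg_um=1.5, pred_2glg_um=3.2)

    def test_profile_requires_increasing_arclength(self):
        with pytest.raises(ValidationError):
            Profile(s_um=[0.0, 0.5, 0.5], intensity=[1, 2, 3])

    def test_growth_path_rejects_repeated_vertices(self):
        with pytest.raises(ValidationError):
            GrowthPath([[0, 0], [0, 0], [1, 1]])


class TestMeasurementTables:
    def _write_dataset(self, tmp_path):
        records = [
            GLGRecord("W1", "a", 500.0, sex="F", tooth_position=2, whale_length_cm=350.0),
            GLGRecord("W1", "b", 410.5),
        ]
        measurements = [
            SpacingMeasurement(("W1", "a"), 10.0, 1.5),
            SpacingMeasurement(("W1", "a"), 11.6, 1.7),
            SpacingMeasurement(("W1", "b"), 5.0, 2.1),
        ]
        mpath = write_measurement_table(measurements, tmp_path / "m.csv")
        rpath = write_metadata_table(records, tmp_path / "r.csv")
        return records, measurements, mpath, rpath

    def test_round_trip_identity(self, tmp_path):
        records, measurements, mpath, rpath = self._write_dataset(tmp_path)
        recs2, ms2 = read_measurement_table(mpath, metadata=rpath)
        assert recs2 == records
        assert ms2 == measurements

    def test_header_only_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("specimen_id,glg_label,position_um,spacing_um\n")
        recs, ms = read_measurement_table(p)
        assert recs == [] and ms == []

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("specimen_id,glg_label,position_um\nW1,a,3.0\n")
        with pytest.raises(SchemaError, match="spacing_um"):
            read_measurement_table(p)

    def test_nonpositive_spacing_reports_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "specimen_id,glg_label,position_um,spacing_um\n"
            "W1,a,3.0,1.5\nW1,a,4.5,-1.0\n"
        )
        with pytest.raises(ValidationError, match="row 3"):
            read_measurement_table(p)

    def test_position_beyond_thickness_rejected(self, tmp_path):
        records, _, mpath, rpath = self._write_dataset(tmp_path)
        bad = tmp_path / "far.csv"
        bad.write_text(
            "specimen_id,glg_label,position_um,spacing_um\nW1,b,999.0,1.5\n"
        )
        with pytest.raises(ValidationError, match="exceeds"):
            read_measurement_table(bad, metadata=records)

    def test_duplicate_glg_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "specimen_id,glg_label,thickness_um\nW1,a,500.0\nW1,a,410.0\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_metadata_table(p)


class TestSummaryTable:
    def _build(self, records, summaries):
        summ = [summaries[r.key] for r in records]
        est = [estimate_days(r.thickness_um, s) for r, s in zip(records, summ)]
        pred = [prediction_pair(r.thickness_um) for r in records]
        return summ, est, pred

    def test_reference_dataset_average_spacing(self, tmp_path, beluga_records, beluga_summaries):
        summ, est, pred = self._build(beluga_records, beluga_summaries)
        path = write_summary_table(beluga_records, summ, est, pred, tmp_path / "t.csv")
        df = read_summary_table(path)
        avg = df[df["specimen_id"] == "Average"].iloc[0]
        assert avg["mean_um"] == pytest.approx(1.65, abs=0.005)
        assert avg["thickness_um"] == pytest.approx(587.86, abs=0.005)

    def test_single_glg_average_equals_row(self, tmp_path, beluga_records, beluga_summaries):
        recs = beluga_records[:1]
        summ, est, pred = self._build(recs, beluga_summaries)
        df = read_summary_table(
            write_summary_table(recs, summ, est, pred, tmp_path / "one.csv")
        )
        row, avg = df.iloc[0], df.iloc[1]
        for col in ("mean_um", "days", "pred_1glg_um"):
            assert row[col] == avg[col]

    def test_empty_input_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_summary_table([], [], [], [], tmp_path / "x.csv")

    def test_misaligned_lists_rejected(self, tmp_path, beluga_records, beluga_summaries):
        summ, est, pred = self._build(beluga_records, beluga_summaries)
        with pytest.raises(ValidationError, match="misaligned"):
            write_summary_table(beluga_records, summ[:-1], est, pred, tmp_path / "x.csv")

    def test_written_values_round_trip_at_printed_precision(
        self, tmp_path, beluga_records, beluga_summaries
    ):
        summ, est, pred = self._build(beluga_records, beluga_summaries)
        p1 = write_summary_table(beluga_records, summ, est, pred, tmp_path / "a.csv")
        df1 = read_summary_table(p1)
        p2 = tmp_path / "b.csv"
        df1.to_csv(p2, index=False)
        pd.testing.assert_frame_equal(df1, read_summary_table(p2))


class TestImages:
    def test_single_page_round_trip(self, tmp_path, rng):
        img = ImageWithScale(rng.random((64, 128)).astype(np.float32), um_per_px=0.1)
        path = save_image(img, tmp_path / "a.tif")
        back = load_image(path, 0.1)
        assert back.pixels.ndim == 2
        np.testing.assert_allclose(back.pixels, img.pixels)

    def test_multipage_stack_round_trip(self, tmp_path, rng):
        img = ImageWithScale(rng.random((20, 32, 48)).astype(np.float32), um_per_px=0.1)
        back = load_image(save_image(img, tmp_path / "z.tif"), 0.1)
        assert back.is_stack and back.pixels.shape[0] == 20

    def test_zero_scale_rejected(self, tmp_path, rng):
        img = ImageWithScale(rng.random((8, 8)), um_per_px=0.1)
        path = save_image(img, tmp_path / "s.tif")
        with pytest.raises(ValidationError):
            load_image(path, 0.0)
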