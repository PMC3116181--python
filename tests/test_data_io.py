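import io
import json

import numpy as np
import pandas as pd
import pytest

import hydrosar as h
from hydrosar.data_io import (
    AA_LABELS,
    RowSumWarning,
    TableFormatError,
    TableValidationError,
    load_sd1_activities,
    pool_zscales,
    read_report,
    validate_zscale_orderings,
)
from hydrosar.validation import ValidationReport


def _csv_row(values, sample="1"):
    header = "sample," + ",".join(AA_LABELS)
    row = sample + "," + ",".join(str(v) for v in values)
    return io.StringIO(header + "\n" + row + "\n")


class TestCompositionLoading:
    def test_single_panel_row_parses_and_sums_to_100(self, panel):
        row = panel.composition.loc["1"]
        src = _csv_row(row.to_numpy())
        comp = h.load_composition_table(src)
        assert comp.shape == (1, 18)
        assert comp.sum(axis=1).iloc[0] == pytest.approx(100.00, abs=0.01)

    def test_missing_column_names_the_column(self):
        header = "sample," + ",".join(a for a in AA_LABELS if a != "TRP")
        src = io.StringIO(header + "\n1," + ",".join(["5"] * 17) + "\n")
        with pytest.raises(TableFormatError, match="TRP"):
            h.load_composition_table(src)

    def test_row_sum_violation_warns_and_names_sample(self, panel):
        src = _csv_row((panel.composition.loc["1"] / 2).to_numpy(), sample="s1")
        with pytest.warns(RowSumWarning, match="s1"):
            h.load_composition_table(src)
        src = _csv_row((panel.composition.loc["1"] / 2).to_numpy(), sample="s1")
        with pytest.raises(TableValidationError, match="s1"):
            h.load_composition_table(src, strict_row_sum=True)

    def test_non_numeric_cell_reports_location(self):
        vals = ["5.0"] * 18
        vals[3] = "oops"
        with pytest.raises(TableFormatError, match="GLX"):
            h.load_composition_table(_csv_row(vals))

    def test_negative_value_rejected(self):
        vals = [100 / 17.0] * 18
        vals[0] = -1.0
        with pytest.raises(TableValidationError, match="negative"):
            h.load_composition_table(_csv_row(vals))


class TestZScales:
    def test_pooled_asx_is_mean_of_asn_and_asp(self, zscales):
        # ASN z3 = 0.84, ASP z3 = 2.36 -> ASX z3 = 1.60
        assert zscales.loc["ASX", "z3"] == pytest.approx(1.60)
        assert zscales.loc["ASX", "z1"] == pytest.approx((3.22 + 3.64) / 2)
        assert zscales.loc["GLX", "z2"] == pytest.approx((0.53 + 0.39) / 2)

    def test_all_pooled_labels_present(self, zscales):
        assert list(zscales.index) == list(AA_LABELS)
        assert not zscales.isna().any().any()

    def test_electronic_ordering_violation_is_detected(self, zscales):
        broken = zscales.copy()
        broken.loc["CYS", "z3"] = broken.loc["PRO", "z3"] - 1.0
        with pytest.raises(TableValidationError, match="Cys > Pro > Asx"):
            validate_zscale_orderings(broken)

    def test_duplicate_residue_rows_rejected(self):
        raw = pd.DataFrame(
            {"z1": 0.0, "z2": 0.0, "z3": 0.0},
            index=pd.Index(list(h.data_io.STANDARD_AA) + ["GLY"], name="aa"),
        )
        with pytest.raises(TableValidationError, match="GLY"):
            pool_zscales(raw)

    def test_missing_residue_rejected(self):
        raw = pd.DataFrame(
            {"z1": 0.0, "z2": 0.0, "z3": 0.0},
            index=pd.Index([a for a in h.data_io.STANDARD_AA if a != "TRP"]),
        )
        with pytest.raises(TableFormatError, match="TRP"):
            pool_zscales(raw)


class TestBundledDataset:
    def test_spot_values_match_publication(self, panel):
        assert panel.composition.loc["16", "ARG"] == 30.18
        assert panel.reference_groups.loc["9", "AAA"] == 16.62
        assert panel.composition.loc["1", "ASX"] == 11.39
        assert panel.composition.loc["1", "TRP"] == 1.23

    def test_group_sums_consistent_with_reference_block(self, panel):
        recomputed = h.group_sums(panel.composition)
        dev = (recomputed - panel.reference_groups).abs()
        assert dev.to_numpy().max() <= 0.02 + 1e-12

    def test_activities_empty_but_attachable(self, panel):
        assert panel.activities == {}
        y = pd.Series(
            np.linspace(10, 60, 16), index=panel.composition.index, name="dpph"
        )
        ds = panel.with_activities({"dpph": y})
        assert "dpph" in ds.activities
        assert panel.activities == {}  # original untouched

    def test_foreign_sample_ids_rejected(self, panel):
        y = pd.Series([1.0, 2.0, 3.0], index=["1", "2", "nope"], name="x")
        with pytest.raises(TableValidationError, match="nope"):
            panel.with_activities({"x": y})


class TestActivityIO:
    def test_sd1_shaped_synthetic_file_loads(self, tmp_path, panel):
        # synthetic stand-in shaped like the supplementary activity table
        ids = panel.composition.index
        df = pd.DataFrame(
            {
                "dpph": np.linspace(20, 70, 16),
                "frap": np.linspace(0.2, 1.4, 16),
                "h2o2": [np.nan] * 5 + list(np.linspace(10, 50, 11)),
                "superoxide": np.linspace(5, 60, 16),
            },
            index=ids,
        )
        p = tmp_path / "activities_synthetic.csv"
        df.to_csv(p, index_label="sample")
        acts = load_sd1_activities(p)
        assert set(acts) == {"dpph", "frap", "h2o2", "superoxide"}
        assert len(acts["h2o2"]) == 11  # subset assay
        assert acts["frap"].attrs["units"] == "absorbance at 700 nm"

    def test_unrecognised_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample,abts\n1,5\n")
        with pytest.raises(TableFormatError, match="(?i)abts"):
            load_sd1_activities(p)


class TestReports:
    def test_roundtrip_is_bit_exact(self, tmp_path):
        rep = ValidationReport(
            n=16, x_set="AA", a=1, r2=0.7281234567891234, q2cv=0.6681234567899999,
            perm_r2_intercept=0.223, perm_q2_intercept=-0.219, valid=True,
            activity="frap",
        )
        p = h.write_report(rep, tmp_path / "rep.json")
        back = read_report(p)
        assert back["r2"] == rep.r2 and back["q2cv"] == rep.q2cv
        assert set(back) >= {"n", "x_set", "a", "r2", "q2cv",
                             "perm_r2_intercept", "perm_q2_intercept", "valid"}

    def test_csv_rendering(self, tmp_path):
        rep = ValidationReport(n=16, x_set="gAA", a=1, r2=0.5, q2cv=0.4,
                               perm_r2_intercept=0.1, perm_q2_intercept=-0.1,
                               valid=True)
        p = h.write_report(rep, tmp_path / "rep.csv", fmt="csv")
        frame = pd.read_csv(p)
        assert frame.loc[0, "x_set"] == "gAA"

    def test_empty_report_refused(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            h.write_report({}, tmp_path / "empty.json")
        assert not (tmp_path / "empty.json").exists()
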