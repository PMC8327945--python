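"""DNA→nucleus calibration: recovery, prediction, augmentation."""

import numpy as np
import pandas as pd
import pytest

from karyoscale import (
    augment_with_inferred_nuclei,
    fit_calibration,
    predict_nucleus_volume,
    test_isometry_of_calibration,
)
from karyoscale.calibration import CalibrationModel
from karyoscale.io import SPECIES_COLUMNS


def make_table(slope, intercepts, n_per_clade=10, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for clade, intercept in intercepts.items():
        dna = 10 ** rng.uniform(-0.5, 1.5, n_per_clade)
        nuc = 10 ** (intercept + slope * np.log10(dna) + rng.normal(0, noise, n_per_clade))
        for i, (d, v) in enumerate(zip(dna, nuc)):
            rows.append(
                {
                    "species": f"{clade}_{i}",
                    "clade": clade,
                    "cell_volume_um3": v * 20,
                    "nucleus_volume_um3": v,
                    "dna_content_pg": d,
                    "nucleus_source": "measured",
                }
            )
    return pd.DataFrame(rows)[SPECIES_COLUMNS]


class TestFit:
    def test_noiseless_recovery(self):
        table = make_table(1.03, {"fish": 0.8, "birds": 1.1})
        model = fit_calibration(table)
        assert model.slope == pytest.approx(1.03, abs=1e-10)
        assert model.intercepts["fish"] == pytest.approx(0.8, abs=1e-10)
        assert model.intercepts["birds"] == pytest.approx(1.1, abs=1e-10)
        assert model.r_squared == pytest.approx(1.0)
        assert model.homogeneous_slopes

    def test_single_clade_exact_line(self):
        table = make_table(1.0, {"fish": 1.0})
        model = fit_calibration(table)
        assert model.slope == pytest.approx(1.0, abs=1e-10)
        assert model.homogeneous_slopes

    def test_round_trip_on_own_predictions(self):
        """Refitting on the model's own noiseless predictions returns it."""
        table = make_table(0.9, {"frogs": 0.5, "mammals": 1.2}, noise=0.15, seed=1)
        model = fit_calibration(table)
        pred = table.copy()
        for clade in ("frogs", "mammals"):
            m = pred["clade"] == clade
            point, _ = predict_nucleus_volume(
                model, clade, pred.loc[m, "dna_content_pg"].to_numpy()
            )
            pred.loc[m, "nucleus_volume_um3"] = point
        refit = fit_calibration(pred)
        assert refit.slope == pytest.approx(model.slope, abs=1e-8)
        for clade in ("frogs", "mammals"):
            assert refit.intercepts[clade] == pytest.approx(
                model.intercepts[clade], abs=1e-8
            )

    def test_small_clades_excluded(self):
        table = pd.concat(
            [make_table(1.0, {"fish": 1.0}), make_table(1.0, {"birds": 1.0}, n_per_clade=2)]
        )
        model = fit_calibration(table)
        assert "birds" not in model.intercepts
        assert model.n_species == 10

    def test_no_usable_rows_error(self):
        table = make_table(1.0, {"fish": 1.0})
        table["dna_content_pg"] = np.nan
        with pytest.raises(ValueError, match="no usable"):
            fit_calibration(table)

    def test_heterogeneous_slopes_flagged(self):
        t1 = make_table(0.4, {"fish": 1.0}, n_per_clade=30, noise=0.02, seed=2)
        t2 = make_table(1.6, {"birds": 1.0}, n_per_clade=30, noise=0.02, seed=3)
        model = fit_calibration(pd.concat([t1, t2], ignore_index=True))
        assert not model.homogeneous_slopes
        assert model.per_clade_slopes["fish"] == pytest.approx(0.4, abs=0.05)
        assert model.per_clade_slopes["birds"] == pytest.approx(1.6, abs=0.05)

    def test_r_squared_matches_two_pass_computation(self):
        table = make_table(1.03, {"fish": 0.8, "birds": 1.1}, noise=0.2, seed=5)
        model = fit_calibration(table)
        y = np.log10(table["nucleus_volume_um3"])
        x = np.log10(table["dna_content_pg"])
        fitted = table["clade"].map(model.intercepts) + model.slope * x
        ss_res = ((y - fitted) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert model.r_squared == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)


class TestIsometry:
    @pytest.mark.parametrize(
        "ci, expected",
        [((0.98, 1.08), True), ((1.05, 1.20), False), ((0.90, 1.00), True)],
    )
    def test_decision(self, ci, expected):
        model = CalibrationModel(
            slope=np.mean(ci), intercepts={"fish": 1.0}, residual_sd=0.1,
            r_squared=0.9, slope_ci=ci, homogeneous_slopes=True, n_species=10,
            df_resid=8,
        )
        assert test_isometry_of_calibration(model) is expected


class TestPredict:
    def model(self, slope, intercept):
        return CalibrationModel(
            slope=slope, intercepts={"X": intercept}, residual_sd=0.05,
            r_squared=0.95, slope_ci=(slope - 0.1, slope + 0.1),
            homogeneous_slopes=True, n_species=20, df_resid=18, slope_se=0.05,
            clade_stats={"X": (20, 0.5, 5.0)},
        )

    def test_unit_case(self):
        point, (lo, hi) = predict_nucleus_volume(self.model(1.0, 1.0), "X", 1.0)
        assert point == pytest.approx(10.0)
        assert lo < 10.0 < hi

    def test_direct_evaluation(self):
        point, _ = predict_nucleus_volume(self.model(1.03, 0.5), "X", 10.0)
        assert point == pytest.approx(10**1.53, rel=1e-9)

    def test_domain_and_clade_errors(self):
        with pytest.raises(ValueError):
            predict_nucleus_volume(self.model(1.0, 1.0), "X", 0.0)
        with pytest.raises(KeyError, match="available"):
            predict_nucleus_volume(self.model(1.0, 1.0), "Y", 1.0)

    def test_strictly_increasing_in_dna(self):
        m = self.model(1.03, 0.5)
        dna = np.linspace(0.1, 20, 50)
        points, _ = predict_nucleus_volume(m, "X", dna)
        assert (np.diff(points) > 0).all()


class TestAugment:
    def test_mixed_table(self):
        measured = make_table(1.0, {"fish": 1.0})
        dna_only = make_table(1.0, {"fish": 1.0}, seed=1)
        dna_only["nucleus_volume_um3"] = np.nan
        dna_only["nucleus_source"] = np.nan
        dna_only["species"] = dna_only["species"] + "_dna"
        table = pd.concat([measured, dna_only], ignore_index=True)
        model = fit_calibration(table)
        out = augment_with_inferred_nuclei(table, model)
        assert out["nucleus_volume_um3"].notna().all()
        assert (out["nucleus_source"] == "inferred").sum() == 10
        # measured rows untouched
        pd.testing.assert_frame_equal(out.iloc[:10], table.iloc[:10])

    def test_unknown_clade_passed_through(self):
        table = make_table(1.0, {"fish": 1.0})
        extra = make_table(1.0, {"salamanders": 1.0}, n_per_clade=1)
        extra["nucleus_volume_um3"] = np.nan
        model = fit_calibration(table)
        out = augment_with_inferred_nuclei(
            pd.concat([table, extra], ignore_index=True), model
        )
        assert out["nucleus_volume_um3"].isna().sum() == 1
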