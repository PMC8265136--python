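"""SCFA standard-curve calibration, quantification, group tests and
species-acid correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mgmwas import synthdata
from mgmwas.exceptions import CalibrationError
from mgmwas.scfa import (
    ACIDS,
    STANDARD_LEVELS,
    SCFAPanel,
    compare_groups,
    fit_standard_curve,
    quantify,
    species_scfa_correlation,
)

from conftest import make_metadata, make_table


class TestStandardCurve:
    def test_exact_line(self):
        curve = fit_standard_curve(concentrations=[1, 2, 5, 10], areas=[2, 4, 10, 20], acid="butyric")
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_duplicates_match_ols_oracle(self):
        conc = np.array([1.0, 1.0, 5.0, 5.0, 10.0, 10.0])
        area = np.array([2.1, 1.9, 10.4, 9.6, 20.5, 19.5])
        curve = fit_standard_curve(concentrations=conc, areas=area)
        # closed-form OLS
        b = ((conc - conc.mean()) * (area - area.mean())).sum() / ((conc - conc.mean()) ** 2).sum()
        a = area.mean() - b * conc.mean()
        assert curve.slope == pytest.approx(b, abs=1e-12)
        assert curve.intercept == pytest.approx(a, abs=1e-12)

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(CalibrationError):
            fit_standard_curve(concentrations=[5.0, 5.0], areas=[1.0, 2.0])


class TestQuantify:
    def test_seven_level_round_trip_noiseless(self):
        levels = np.array(STANDARD_LEVELS)
        curves = {}
        rng = np.random.default_rng(0)
        for acid in ACIDS:
            slope, intercept = rng.uniform(0.5, 3.0), rng.uniform(-5, 5)
            curves[acid] = fit_standard_curve(
                concentrations=levels, areas=slope * levels + intercept, acid=acid
            )
        areas = pd.DataFrame(
            {acid: curves[acid].slope * levels + curves[acid].intercept for acid in ACIDS},
            index=[f"std{i}" for i in range(len(levels))],
        )
        panel = quantify(areas, curves)
        for acid in ACIDS:
            np.testing.assert_allclose(panel.data[acid].to_numpy(), levels, atol=1e-9)

    def test_inverse_identities_and_clipping(self):
        curve = fit_standard_curve(concentrations=[1, 2, 5, 10], areas=[7, 9, 15, 25], acid="acetic")
        areas = pd.DataFrame({"acetic": [curve.intercept, curve.slope * 50 + curve.intercept, 0.0]},
                             index=["a", "b", "c"])
        panel = quantify(areas, {"acetic": curve})
        assert panel.data.loc["a", "acetic"] == pytest.approx(0.0, abs=1e-12)
        assert panel.data.loc["b", "acetic"] == pytest.approx(50.0)
        assert panel.data.loc["c", "acetic"] == 0.0 and bool(panel.clipped.loc["c", "acetic"])
        assert bool(panel.below_loq.loc["a", "acetic"])

    def test_noisy_recovery_within_five_percent(self):
        rng = np.random.default_rng(5)
        levels = np.array(STANDARD_LEVELS)
        curve = fit_standard_curve(concentrations=levels, areas=3.0 * levels + 2.0, acid="butyric")
        recovered = []
        for _ in range(200):
            noisy = (3.0 * levels + 2.0) * (1 + rng.normal(0, 0.02, len(levels)))
            recovered.append(curve.back_calculate(noisy))
        rel_err = np.abs(np.array(recovered) / levels - 1)
        assert np.quantile(rel_err, 0.95) < 0.05


class TestCompareGroups:
    @staticmethod
    def _panel_meta(x, y):
        samples = [f"MG{i}" for i in range(len(x))] + [f"HC{i}" for i in range(len(y))]
        panel = SCFAPanel(pd.DataFrame({"butyric": np.r_[x, y]}, index=samples))
        meta = make_metadata({s: ("case" if s.startswith("MG") else "control") for s in samples})
        return panel, meta

    def test_identical_groups_p_near_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        panel, meta = self._panel_meta(x, x)
        res = compare_groups(panel, meta)
        assert res.loc["butyric", "p"] > 0.99

    def test_welch_matches_closed_form(self):
        rng = np.random.default_rng(8)
        x = rng.normal(10, 1, 12)
        y = rng.normal(11, 3, 20)
        panel, meta = self._panel_meta(x, y)
        res = compare_groups(panel, meta)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert res.loc["butyric", "t"] == pytest.approx(t, abs=1e-12)
        assert res.loc["butyric", "p"] == pytest.approx(p, abs=1e-12)

    def test_label_swap_negates_t(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(10, 1, 10), rng.normal(10.5, 1, 10)
        panel, meta = self._panel_meta(x, y)
        swapped = make_metadata(
            {s: ("control" if s.startswith("MG") else "case") for s in panel.samples}
        )
        a = compare_groups(panel, meta)
        b = compare_groups(panel, swapped)
        assert a.loc["butyric", "t"] == pytest.approx(-b.loc["butyric", "t"])
        assert a.loc["butyric", "p"] == pytest.approx(b.loc["butyric", "p"])


class TestCorrelation:
    def test_proportional_and_antiproportional(self):
        taxa = make_table({"s__A": [0.1, 0.2, 0.3, 0.4], "s__B": [0.4, 0.3, 0.2, 0.1]})
        panel = SCFAPanel(pd.DataFrame({"butyric": [1.0, 2.0, 3.0, 4.0]}, index=taxa.samples))
        r, p = species_scfa_correlation(taxa, panel)
        assert r.loc["s__A", "butyric"] == pytest.approx(1.0)
        assert r.loc["s__B", "butyric"] == pytest.approx(-1.0)

    def test_matches_pearson_t_transform_oracle(self):
        rng = np.random.default_rng(10)
        a = rng.random(15)
        b = 0.5 * a + rng.normal(size=15)
        taxa = make_table({"s__X": a.tolist()})
        panel = SCFAPanel(pd.DataFrame({"acetic": b - b.min()}, index=taxa.samples))
        r, p = species_scfa_correlation(taxa, panel)
        rr = np.corrcoef(a, b - b.min())[0, 1]
        t = rr * np.sqrt(13 / (1 - rr**2))
        assert r.loc["s__X", "acetic"] == pytest.approx(rr, abs=1e-12)
        assert p.loc["s__X", "acetic"] == pytest.approx(2 * stats.t.sf(abs(t), 13), abs=1e-12)

    def test_zero_variance_flagged_missing(self):
        taxa = make_table({"s__flat": [0.5, 0.5, 0.5, 0.5]})
        panel = SCFAPanel(pd.DataFrame({"acetic": [1.0, 2.0, 3.0, 4.0]}, index=taxa.samples))
        r, p = species_scfa_correlation(taxa, panel)
        assert np.isnan(r.loc["s__flat", "acetic"])

    def test_null_p_uniform(self):
        rng = np.random.default_rng(30)
        ps = []
        for _ in range(50):
            taxa = make_table({"s__X": rng.random(20).tolist()})
            panel = SCFAPanel(pd.DataFrame({"acetic": rng.random(20)}, index=taxa.samples))
            _, p = species_scfa_correlation(taxa, panel)
            ps.append(p.iloc[0, 0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestGeneratorCoupling:
    def test_planted_coupling_gives_positive_correlation(self):
        hits = 0
        for seed in range(10):
            cfg = synthdata.SynthConfig(
                n_case=30, n_control=30, n_features=10, n_differential=0,
                effect_size=0.0, scfa_group_shift=0.0,
                scfa_species_coupling=2.0, seed=seed,
            )
            taxa, meta, _ = synthdata.generate_taxonomic_profiles(cfg)
            panel, truth = synthdata.generate_scfa_panel(cfg, taxa, meta)
            coupled = truth.scfa_true_params["coupling"]["butyric"]["species"]
            r, _ = species_scfa_correlation(taxa.subset_features([coupled]), panel)
            hits += r.loc[coupled, "butyric"] > 0
        assert hits >= 9
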