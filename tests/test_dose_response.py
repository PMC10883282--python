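import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from proteoscreen import dose_response as dr
from proteoscreen.io_formats import ScreenWellRecord

DOSES = np.array([476.19 / 3**i for i in range(10)])


def make_plate(signals_by_dose, neg=100000.0, pos=2000.0, n_controls=4):
    wells = []
    for i in range(n_controls):
        wells.append(ScreenWellRecord("DMSO", "L1", 0.0, i + 1, neg,
                                      "negative_control"))
        wells.append(ScreenWellRecord("PC", "L1", 5.0, i + 1, pos,
                                      "positive_control"))
    for dose, signal in signals_by_dose:
        wells.append(ScreenWellRecord("D1", "L1", dose, 1, signal))
    return wells


class TestNormalizeViability:
    @pytest.mark.parametrize("signal,expected", [
        (100000.0, 1.0), (2000.0, 0.0), (51000.0, 0.5),
    ])
    def test_anchors_and_linearity(self, signal, expected):
        out = dr.normalize_viability(make_plate([(1.0, signal)]))
        assert out["viability"].iloc[0] == pytest.approx(expected)

    def test_plate_failure_when_controls_inverted(self):
        wells = make_plate([(1.0, 5000.0)], neg=100.0, pos=200.0)
        with pytest.raises(ValueError, match="plate failure"):
            dr.normalize_viability(wells)

    def test_replicates_averaged_with_sd(self):
        wells = make_plate([(1.0, 60000.0), (1.0, 80000.0)])
        out = dr.normalize_viability(wells)
        assert len(out) == 1
        assert out["n"].iloc[0] == 2
        assert out["viability_mean"].iloc[0] == pytest.approx(
            ((60000 - 2000) + (80000 - 2000)) / 2 / 98000
        )


class TestFit4PL:
    def test_noiseless_parameter_recovery(self):
        v = dr.four_pl(DOSES, 1.0, 0.0, 1.0, 1.0)
        fit = dr.fit_4pl(DOSES, v)
        assert fit.converged
        assert fit.e == pytest.approx(1.0, rel=0.01)
        assert fit.b == pytest.approx(1.0, rel=1e-3)

    @pytest.mark.parametrize("b", [0.3, 1.0, 5.0])
    def test_recovery_across_slopes(self, b):
        v = dr.four_pl(DOSES, b, 0.1, 1.0, 3.0)
        fit = dr.fit_4pl(DOSES, v)
        assert fit.e == pytest.approx(3.0, rel=1e-3)
        assert fit.b == pytest.approx(b, rel=1e-3)

    def test_curve_midpoint_at_ed50(self):
        v = dr.four_pl(DOSES, 1.3, 0.05, 0.98, 2.0)
        fit = dr.fit_4pl(DOSES, v)
        assert fit(fit.e) == pytest.approx((fit.c + fit.d) / 2)

    def test_needs_four_distinct_doses(self):
        with pytest.raises(ValueError, match="4 distinct"):
            dr.fit_4pl([1.0, 1.0, 2.0, 3.0], [1, 1, 0.5, 0.2])

    def test_noisy_ed50_recovery(self):
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            e = float(10 ** rng.uniform(np.log10(0.5), np.log10(50)))
            v = dr.four_pl(DOSES, 1.2, 0.05, 1.0, e)
            fit = dr.fit_4pl(DOSES, v + rng.normal(0, 0.02, size=len(DOSES)))
            errs.append(abs(fit.e - e) / e)
        assert float(np.median(errs)) < 0.20


class TestStandardizedAUC:
    def test_constant_viability_limits(self):
        flat = dr.fit_4pl(DOSES, np.ones_like(DOSES))
        assert dr.standardized_auc(flat, (DOSES.min(), DOSES.max())) == 1.0
        dead = dr.fit_4pl(DOSES, np.zeros_like(DOSES))
        assert dr.standardized_auc(dead, (DOSES.min(), DOSES.max())) == 0.0

    def test_steep_symmetric_curve_gives_half(self):
        lo, hi = 0.01, 100.0
        fit = dr.CurveFit(b=40.0, c=0.0, d=1.0, e=math.sqrt(lo * hi),
                          converged=True, rmse=0.0)
        assert dr.standardized_auc(fit, (lo, hi)) == pytest.approx(0.5,
                                                                   abs=1e-6)

    def test_unit_invariance(self):
        fit_um = dr.CurveFit(b=1.0, c=0.0, d=1.0, e=2.0, converged=True,
                             rmse=0.0)
        fit_nm = dr.CurveFit(b=1.0, c=0.0, d=1.0, e=2000.0, converged=True,
                             rmse=0.0)
        a_um = dr.standardized_auc(fit_um, (0.01, 100.0))
        a_nm = dr.standardized_auc(fit_nm, (10.0, 100000.0))
        assert a_um == pytest.approx(a_nm, abs=1e-9)

    def test_empty_range_rejected(self):
        fit = dr.CurveFit(b=1, c=0, d=1, e=1, converged=True, rmse=0)
        with pytest.raises(ValueError, match="dose range"):
            dr.standardized_auc(fit, (10.0, 1.0))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        e=st.floats(min_value=0.05, max_value=400),
        b=st.floats(min_value=0.3, max_value=5),
        c=st.floats(min_value=0.0, max_value=0.3),
    )
    def test_pointwise_lower_curve_never_higher_auc(self, e, b, c):
        hi = dr.CurveFit(b=b, c=c + 0.1, d=1.0, e=e, converged=True, rmse=0)
        lo = dr.CurveFit(b=b, c=c, d=0.9, e=e, converged=True, rmse=0)
        rng_ = (DOSES.min(), DOSES.max())
        assert dr.standardized_auc(lo, rng_) <= dr.standardized_auc(hi, rng_) + 1e-12


class TestPotencyFilter:
    def _response(self, ec50, auc, maxinh):
        frame = lambda v: pd.DataFrame({"L1": [v]}, index=["D1"])
        return dr.DrugResponseMatrix(frame(auc), frame(ec50), frame(maxinh))

    def test_all_filters_pass(self):
        resp = self._response(0.05, 0.8, 0.9)
        assert dr.potency_filter(resp, {"D1"})["L1"] == 1

    @pytest.mark.parametrize("ec50,auc,maxinh", [
        (0.05, 0.95, 0.9),  # AUC too high
        (0.2, 0.8, 0.9),    # EC50 too high
        (0.05, 0.8, 0.4),   # inhibition too weak
    ])
    def test_single_filter_rejection(self, ec50, auc, maxinh):
        resp = self._response(ec50, auc, maxinh)
        assert dr.potency_filter(resp, {"D1"})["L1"] == 0

    def test_non_ki_drugs_not_counted(self):
        resp = self._response(0.05, 0.8, 0.9)
        assert dr.potency_filter(resp, set())["L1"] == 0


class TestZPrime:
    def test_noiseless_limit(self):
        assert dr.zprime([0.0, 0.0], [10.0, 10.0]) == 1.0

    def test_hand_computed_value(self):
        # sample SDs of {-0.5, 0, 0.5} and {9.5, 10, 10.5} are exactly 0.5
        assert dr.zprime([-0.5, 0.0, 0.5], [9.5, 10.0, 10.5]) == pytest.approx(0.7)

    def test_overlapping_controls_negative(self, rng):
        pos = rng.normal(0, 5, 50)
        neg = rng.normal(10, 5, 50)
        assert dr.zprime(pos, neg) < 0

    def test_identical_means_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            dr.zprime([1.0, 1.0], [1.0, 1.0])


class TestScreenPipeline:
    def test_planted_effective_count_recovered_noiseless(self):
        from proteoscreen import synthetic_data as sd

        cfg = sd.PanelConfig(
            seed=9, viability_noise_frac=0.0, n_cell_lines=6, n_proteins=100,
            n_psites=250, n_kinases=10, n_drugs=8, n_kinase_inhibitors=6,
            n_periodic_proteins=25, n_marker_links=0,
        )
        *_, screen, truth = sd.generate_panel(cfg)
        plates = {}
        for w in screen:
            plates.setdefault(w.cell_line, []).append(w)
        viability = pd.concat(
            [dr.normalize_viability(p) for p in plates.values()],
            ignore_index=True,
        )
        fitted, _ = dr.fit_screen(viability)
        expected = dr.potency_filter(
            truth.response_matrix((min(cfg.doses), max(cfg.doses))),
            truth.kinase_inhibitors,
        )
        got = dr.potency_filter(fitted, truth.kinase_inhibitors)
        assert got.equals(expected)
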