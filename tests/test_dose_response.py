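"""Four-parameter logistic inhibition fitting: Ki, floors, classification."""

import warnings

import numpy as np
import pytest

from allostery_screen.dose_response import (
    DoseResponseCurve,
    IdentifiabilityWarning,
    classify_inhibition,
    competitive_shift_analysis,
    estimate_ki,
    fit_four_pl,
    four_pl,
)
from allostery_screen.simulate import CurveSimConfig, gen_dose_response

CONC = np.concatenate([[0.0], np.geomspace(5e-8, 1e-4, 10)])


def _noiseless(top=100.0, bottom=0.0, ic50=5.8e-6, hill=1.0, conc=CONC, name="inh"):
    return DoseResponseCurve(name, conc, four_pl(conc, top, bottom, ic50, hill))


class TestModelIdentities:
    def test_midpoint(self):
        assert four_pl(np.array([5.8e-6]), 100, 0, 5.8e-6, 1.0)[0] == pytest.approx(50.0)

    def test_zero_dose_is_top(self):
        assert four_pl(np.array([0.0]), 87.0, 12.0, 1e-6, 1.3)[0] == 87.0

    def test_monotone_nonincreasing_for_positive_hill(self):
        x = np.geomspace(1e-9, 1e-3, 200)
        y = four_pl(x, 100, 20, 1e-6, 2.0)
        assert np.all(np.diff(y) <= 0)


class TestFitting:
    def test_noiseless_full_inhibition_recovery(self):
        fit = fit_four_pl(_noiseless())
        assert fit.converged
        assert fit.ic50 == pytest.approx(5.8e-6, rel=1e-6)
        assert fit.top == pytest.approx(100.0, rel=1e-6)
        assert abs(fit.bottom) < 1e-4
        assert fit.hill == pytest.approx(1.0, rel=1e-6)

    def test_noiseless_partial_inhibition_recovery(self):
        fit = fit_four_pl(_noiseless(bottom=30.0, ic50=0.78e-6))
        assert fit.ic50 == pytest.approx(0.78e-6, rel=1e-6)
        assert fit.bottom == pytest.approx(30.0, rel=1e-6)
        assert fit.residual_fraction == pytest.approx(0.30, rel=1e-6)

    def test_log_and_linear_space_agree_on_noiseless_data(self):
        conc = np.geomspace(5e-8, 1e-4, 10)  # no zero anchor
        curve = _noiseless(conc=conc, bottom=10.0)
        lin = fit_four_pl(curve, log_space=False)
        log = fit_four_pl(curve, log_space=True)
        assert log.ic50 == pytest.approx(lin.ic50, rel=1e-8)

    def test_fixed_top_variant(self):
        fit = fit_four_pl(_noiseless(), fix_top=100.0)
        assert fit.top == 100.0
        assert fit.ic50 == pytest.approx(5.8e-6, rel=1e-5)

    def test_flat_curve_rejected(self):
        """A sub-30-point activity span carries no dose information
        (e.g. a co-ligand inert below its own inhibitory range)."""
        y = np.full(CONC.size, 98.0) + np.linspace(0, -5, CONC.size)
        with pytest.raises(ValueError, match="span"):
            fit_four_pl(DoseResponseCurve("flat", CONC, y))

    def test_too_few_concentrations_rejected(self):
        c = np.array([0.0, 1e-7, 1e-6, 1e-5, 1e-4])
        with pytest.raises(ValueError, match="6 distinct"):
            fit_four_pl(DoseResponseCurve("x", c, four_pl(c, 100, 0, 1e-6, 1)))

    def test_identifiability_warning_when_range_ends_early(self):
        conc = np.concatenate([[0.0], np.geomspace(1e-8, 2e-6, 9)])  # max = 2 x ic50
        curve = _noiseless(ic50=1e-6, conc=conc)
        with pytest.warns(IdentifiabilityWarning):
            fit_four_pl(curve)

    def test_well_saturated_design_no_warning(self):
        with warnings.catch_warnings():
            warnings.simplefilter("error", IdentifiabilityWarning)
            fit_four_pl(_noiseless(ic50=1e-6))


class TestKi:
    def test_definitional_passthrough(self):
        fit = fit_four_pl(_noiseless())
        ki, se = estimate_ki(fit)
        assert ki == fit.ic50
        assert se >= 0

    def test_floor_does_not_bias_inflection(self):
        """Full and partial inhibitors with the same midpoint give the
        same Ki: the floor moves the plateau, not the inflection."""
        rng_seeds = range(15)
        kis_full, kis_part = [], []
        for s in rng_seeds:
            for store, bottom in ((kis_full, 0.0), (kis_part, 30.0)):
                cfg = CurveSimConfig("four_pl", {"top": 100.0, "bottom": bottom,
                                                 "ic50": 2e-6, "hill": 1.0},
                                     noise_sd=2.0, seed=s)
                (curve,), _ = gen_dose_response(cfg)
                store.append(fit_four_pl(curve).ic50)
        assert np.median(kis_full) == pytest.approx(np.median(kis_part), rel=0.15)
        assert np.median(kis_full) == pytest.approx(2e-6, rel=0.15)

    def test_unconverged_fit_rejected(self):
        fit = fit_four_pl(_noiseless())
        bad = type(fit)(**{**fit.__dict__, "converged": False})
        with pytest.raises(ValueError, match="unconverged"):
            estimate_ki(bad)


class TestClassification:
    def test_zero_floor_is_complete(self):
        assert classify_inhibition(fit_four_pl(_noiseless())) == "complete"

    @pytest.mark.parametrize("floor_pct", [30.0, 50.0])
    def test_partial_floor_recovered(self, floor_pct):
        cfg = CurveSimConfig("four_pl", {"top": 100.0, "bottom": floor_pct,
                                         "ic50": 1e-6, "hill": 1.0},
                             noise_sd=2.0, seed=3)
        (curve,), _ = gen_dose_response(cfg)
        fit = fit_four_pl(curve)
        assert classify_inhibition(fit) == "partial"
        assert 100 * fit.residual_fraction == pytest.approx(floor_pct, abs=5.0)


class TestCompetitiveShift:
    def test_null_case_ratio_near_one(self):
        a = _noiseless(ic50=5.8e-6)
        b = _noiseless(ic50=5.8e-6)
        out = competitive_shift_analysis(a, b)
        assert out["ki_ratio"] == pytest.approx(1.0, abs=1e-6)
        assert abs(out["delta_ki"]) <= 2 * max(out["delta_ki_se"], 1e-12)

    def test_coligand_potentiation_recovered(self):
        """Co-ligand shifting Ki 5.8 -> 4.2 uM: ratio recovered at 2% noise
        with the assay's triplicate design (replicates pooled per fit)."""
        def pooled(ic50, seed):
            cfg = CurveSimConfig("four_pl", {"top": 100.0, "bottom": 0.0,
                                             "ic50": ic50, "hill": 1.0},
                                 noise_sd=2.0, n_replicates=3, seed=seed)
            curves, _ = gen_dose_response(cfg)
            return DoseResponseCurve(
                curves[0].inhibitor_id,
                np.concatenate([c.concentrations for c in curves]),
                np.concatenate([c.activities for c in curves]),
            )
        out = competitive_shift_analysis(pooled(5.8e-6, 21), pooled(4.2e-6, 22))
        assert out["ki_ratio"] == pytest.approx(4.2 / 5.8, rel=0.15)

    def test_unpaired_designs_rejected(self):
        a = _noiseless()
        b = _noiseless(conc=CONC * 2.0)
        with pytest.raises(ValueError, match="share the concentration design"):
            competitive_shift_analysis(a, b)
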