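"""Titration models: occurrence curve, pKa construction, step model, mixture."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fosubstep.models import (
    PHCurveModel,
    SynthaseStepModel,
    eval_td_occurrence,
    eval_tn,
    eval_ts,
    extract_pkas,
    fit_synthase_model,
    fit_td_occurrence,
    fit_three_gaussians,
    protonated_fraction,
    unprotonated_fraction,
)
from fosubstep.presets import get_preset


# ---------------------------------------------------------------------------
# occurrence curve (Dixon-style log-log inhibition)
# ---------------------------------------------------------------------------

class TestTDOccurrence:
    def test_wt_high_ph_plateau(self, wt_td_model):
        # the WT curve levels off just above tmin at alkaline pH
        assert eval_td_occurrence(wt_td_model, 9.0) == pytest.approx(22.07, abs=0.01)

    def test_low_ph_saturation_equals_plateau_ratio(self):
        model = get_preset("aN214L").td_model
        assert model.t_saturating == pytest.approx(60.40, abs=0.01)
        assert eval_td_occurrence(model, -10.0) == pytest.approx(model.t_saturating, rel=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(
        tmin=st.floats(1.0, 50.0),
        k1=st.floats(4.0, 9.0),
        delta=st.floats(0.05, 2.0),
    )
    def test_monotone_and_plateau_ratio(self, tmin, k1, delta):
        model = PHCurveModel(tmin=tmin, k1=k1, k2=k1 + delta)
        ph = np.linspace(0.0, 14.0, 200)
        t = eval_td_occurrence(model, ph)
        assert (np.diff(t) <= 1e-9).all(), "occurrence must not increase with pH"
        ratio = eval_td_occurrence(model, -20.0) / eval_td_occurrence(model, 30.0)
        assert ratio == pytest.approx(10.0 ** delta, rel=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PHCurveModel(tmin=-1.0, k1=6.0, k2=6.5)
        with pytest.raises(ValueError):
            PHCurveModel(tmin=10.0, k1=7.0, k2=6.5)


class TestPkaExtraction:
    @pytest.mark.parametrize(
        "genotype, expected",
        [("WT", (5.69, 7.46)), ("aN214L", (6.36, 8.14))],
    )
    def test_tangent_intercepts(self, genotype, expected):
        # independent oracle: tangent at the inflection of log10 T(pH)
        # intersected with the two plateaus (values frozen from the closed
        # form, cross-checked numerically below)
        pka1, pka2 = extract_pkas(get_preset(genotype).td_model)
        assert pka1 == pytest.approx(expected[0], abs=0.01)
        assert pka2 == pytest.approx(expected[1], abs=0.01)

    def test_matches_numerical_tangent_construction(self, wt_td_model):
        m = wt_td_model
        ph = np.linspace(4.0, 10.0, 200001)
        logt = np.log10(eval_td_occurrence(m, ph))
        slope = np.gradient(logt, ph)
        i = np.argmin(slope)  # steepest descent = inflection
        y_hi = np.log10(m.tmin)
        y_lo = np.log10(m.t_saturating)
        pka2_num = ph[i] + (y_hi - logt[i]) / slope[i]
        pka1_num = ph[i] + (y_lo - logt[i]) / slope[i]
        pka1, pka2 = extract_pkas(m)
        assert pka1 == pytest.approx(pka1_num, abs=1e-3)
        assert pka2 == pytest.approx(pka2_num, abs=1e-3)

    @settings(derandomize=True, max_examples=50)
    @given(k1=st.floats(4.0, 9.0), delta=st.floats(0.05, 2.0), tmin=st.floats(1.0, 50.0))
    def test_symmetry_about_inflection(self, k1, delta, tmin):
        model = PHCurveModel(tmin=tmin, k1=k1, k2=k1 + delta)
        pka1, pka2 = extract_pkas(model)
        # the construction is symmetric about the inflection (k1+k2)/2
        assert (pka1 + pka2) / 2.0 == pytest.approx((model.k1 + model.k2) / 2.0, abs=1e-9)
        assert pka1 < pka2

    def test_degenerate_curve_flagged(self):
        with pytest.raises(ValueError):
            extract_pkas(PHCurveModel(tmin=20.0, k1=6.5, k2=6.5))


class TestOccurrenceFit:
    def test_noise_free_recovery(self, wt_td_model):
        ph = np.arange(4.5, 9.01, 0.25)
        fit = fit_td_occurrence(ph, eval_td_occurrence(wt_td_model, ph))
        assert not fit.flagged
        assert fit.params.tmin == pytest.approx(wt_td_model.tmin, abs=1e-3)
        assert fit.params.k1 == pytest.approx(wt_td_model.k1, abs=1e-3)
        assert fit.params.k2 == pytest.approx(wt_td_model.k2, abs=1e-3)

    def test_monte_carlo_k1_recovery(self, wt_td_model, rng):
        ph = np.arange(4.5, 9.01, 0.25)
        clean = eval_td_occurrence(wt_td_model, ph)
        k1s = []
        for _ in range(50):
            fit = fit_td_occurrence(ph, clean + rng.normal(0, 2.0, ph.size))
            if not fit.flagged:
                k1s.append(fit.params.k1)
        assert len(k1s) >= 45
        assert np.mean(k1s) == pytest.approx(wt_td_model.k1, abs=0.1)

    def test_constant_data_flagged(self):
        ph = np.arange(5.0, 8.01, 0.5)
        fit = fit_td_occurrence(ph, np.full(ph.size, 30.0))
        assert fit.flagged

    def test_requires_enough_points(self):
        with pytest.raises(ValueError):
            fit_td_occurrence([5.0, 6.0, 7.0], [40.0, 30.0, 25.0])


# ---------------------------------------------------------------------------
# Henderson-Hasselbalch occupancies and the synthase-step model
# ---------------------------------------------------------------------------

class TestOccupancies:
    def test_half_protonation_at_pka(self):
        assert protonated_fraction(7.0, 7.0) == pytest.approx(0.5)
        assert protonated_fraction(7.0, 5.0) == pytest.approx(0.990, abs=5e-4)

    @settings(derandomize=True, max_examples=50)
    @given(pka=st.floats(3.0, 11.0), ph=st.floats(0.0, 14.0))
    def test_fractions_sum_to_one(self, pka, ph):
        assert protonated_fraction(pka, ph) + unprotonated_fraction(pka, ph) == pytest.approx(1.0, abs=1e-12)


class TestSynthaseStepModel:
    def test_wt_tn_near_neutral(self, wt_synthase_model):
        assert eval_tn(wt_synthase_model, 7.1) == pytest.approx(14.25, abs=0.01)

    def test_limits(self, wt_synthase_model):
        assert eval_tn(wt_synthase_model, -5.0) == pytest.approx(wt_synthase_model.p1, abs=1e-6)
        assert eval_tn(wt_synthase_model, 20.0) == pytest.approx(wt_synthase_model.p2, abs=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(
        pka1=st.floats(4.0, 7.5),
        gap=st.floats(0.1, 3.0),
        p1=st.floats(1.0, 50.0),
        p2=st.floats(1.0, 50.0),
        ph=st.floats(3.0, 11.0),
    )
    def test_ts_tn_conservation_and_interior_minimum(self, pka1, gap, p1, p2, ph):
        model = SynthaseStepModel(pka1=pka1, p1=p1, pka2=pka1 + gap, p2=p2)
        assert eval_ts(model, ph) + eval_tn(model, ph) == pytest.approx(100.0, abs=1e-10)
        # TN has its minimum strictly inside (pKa1, pKa2) provided neither
        # route dominates: TN'(pKa1) < 0 < TN'(pKa2) requires the weight
        # ratio to stay below (1 + 10^gap)^2 / (4 * 10^gap)
        ratio_bound = (1.0 + 10.0**gap) ** 2 / (4.0 * 10.0**gap)
        if max(p1 / p2, p2 / p1) < 0.95 * ratio_bound:
            grid = np.linspace(model.pka1 - 4, model.pka2 + 4, 2001)
            ph_min = grid[np.argmin(eval_tn(model, grid))]
            assert model.pka1 < ph_min < model.pka2

    def test_wt_tn_minimum_position(self, wt_synthase_model):
        grid = np.linspace(5.0, 9.0, 40001)
        ph_min = grid[np.argmin(eval_tn(wt_synthase_model, grid))]
        assert ph_min == pytest.approx(7.15, abs=0.02)

    def test_noise_free_fit_recovery(self, wt_synthase_model):
        ph = np.arange(5.0, 9.01, 0.25)
        fit = fit_synthase_model(ph, eval_tn(wt_synthase_model, ph))
        assert not fit.flagged
        assert fit.params.pka1 == pytest.approx(wt_synthase_model.pka1, abs=1e-3)
        assert fit.params.pka2 == pytest.approx(wt_synthase_model.pka2, abs=1e-3)
        assert fit.params.p1 == pytest.approx(wt_synthase_model.p1, abs=1e-2)
        assert fit.params.p2 == pytest.approx(wt_synthase_model.p2, abs=1e-2)

    def test_monte_carlo_pka1_recovery(self, wt_synthase_model, rng):
        ph = np.arange(5.0, 9.01, 0.25)
        clean = eval_tn(wt_synthase_model, ph)
        pkas = []
        for _ in range(50):
            fit = fit_synthase_model(ph, clean + rng.normal(0, 2.0, ph.size))
            if not fit.flagged:
                pkas.append(fit.params.pka1)
        assert len(pkas) >= 45
        assert np.mean(pkas) == pytest.approx(wt_synthase_model.pka1, abs=0.15)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SynthaseStepModel(pka1=7.0, p1=38.0, pka2=6.5, p2=33.0)
        with pytest.raises(ValueError):
            SynthaseStepModel(pka1=6.5, p1=80.0, pka2=7.7, p2=30.0)


# ---------------------------------------------------------------------------
# efficiency-class mixture
# ---------------------------------------------------------------------------

class TestThreeGaussianFit:
    @staticmethod
    def _histogram(values):
        edges = np.arange(0.0, 105.0, 10.0)
        counts, _ = np.histogram(values, bins=edges)
        return counts, edges

    def test_single_population_dominates(self, rng):
        counts, edges = self._histogram(rng.normal(45.0, 8.0, size=600))
        fit = fit_three_gaussians(counts, edges)
        weights = sorted(fit.params.weights)
        assert weights[-1] >= 0.90
        assert weights[0] <= 0.05

    def test_exact_recovery_on_separated_components(self):
        # noise-free counts generated from the model itself at bin centers
        edges = np.arange(0.0, 105.0, 10.0)
        centers = (edges[:-1] + edges[1:]) / 2.0
        truth = [(120.0, 20.0, 6.0), (80.0, 50.0, 7.0), (50.0, 80.0, 6.0)]
        counts = sum(a * np.exp(-0.5 * ((centers - mu) / sd) ** 2) for a, mu, sd in truth)
        fit = fit_three_gaussians(counts, edges)
        for got, (_, mu, sd) in zip(range(3), truth):
            assert fit.params.means[got] == pytest.approx(mu, abs=0.05)
            assert fit.params.sds[got] == pytest.approx(sd, abs=0.1)

    def test_three_class_ratio_recovery(self, rng):
        # low/medium/high class means in the generating ratio 1 : 1.5 : 2.2,
        # with the within-class spread a ~300-stroke data set produces
        comps = [25.0, 37.5, 55.0]
        values = np.concatenate([rng.normal(m, 3.0, size=170) for m in comps])
        counts, edges = self._histogram(values)
        fit = fit_three_gaussians(counts, edges)
        means = fit.params.means
        for got, want in zip(means, comps):
            assert got == pytest.approx(want, abs=3.0)
        assert means[1] / means[0] == pytest.approx(1.5, rel=0.15)
        assert means[2] / means[0] == pytest.approx(2.2, rel=0.15)
        assert sum(fit.params.weights) == pytest.approx(1.0, abs=1e-9)

    def test_needs_enough_occupied_bins(self):
        counts = np.zeros(10)
        counts[3] = 50
        with pytest.raises(ValueError):
            fit_three_gaussians(counts)
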