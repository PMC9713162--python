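"""Delphi aggregation and the two-panel validation statistics."""

import numpy as np
import pytest

from surgdelay import synthetic_data as syn
from surgdelay.delphi_qol import (DelphiRating, PanelEstimate, bland_altman,
                                  combine_panels, estimates_dict,
                                  mixed_model_difference, panel_estimate,
                                  round_feedback, validate_panels,
                                  vas_to_utility)
from surgdelay.errors import DomainError
from surgdelay.psa_engine import PSAConfig


def rating(rater, vas, panel="A", sid="s1", state="pre", rnd=2):
    return DelphiRating(rater_id=rater, panel=panel, surgery_id=sid,
                        state=state, round=rnd, vas=vas)


class TestVasToUtility:
    @pytest.mark.parametrize("vas,expected", [(0, 0.0), (100, 1.0), (73, 0.73)])
    def test_linear_map(self, vas, expected):
        assert vas_to_utility(vas) == expected

    def test_strictly_monotone(self):
        grid = np.linspace(0, 100, 51)
        u = [vas_to_utility(v) for v in grid]
        assert all(a < b for a, b in zip(u, u[1:]))

    @pytest.mark.parametrize("bad", [-1, 100.5])
    def test_out_of_range(self, bad):
        with pytest.raises(DomainError):
            vas_to_utility(bad)


class TestRoundFeedback:
    def test_interpolated_percentiles(self):
        ratings = [rating(f"r{i}", v, rnd=1) for i, v in enumerate([40, 50, 60])]
        fb = round_feedback(ratings)[("s1", "pre")]
        assert fb["median"] == 50
        assert fb["iqr"] == (45, 55)

    def test_single_rating(self):
        fb = round_feedback([rating("r1", 70, rnd=1)])[("s1", "pre")]
        assert fb["median"] == 70 and fb["iqr"] == (70, 70)

    def test_all_identical(self):
        ratings = [rating(f"r{i}", 55, rnd=1) for i in range(5)]
        fb = round_feedback(ratings)[("s1", "pre")]
        assert fb["median"] == 55 and fb["iqr"] == (55, 55)

    def test_missing_round_is_error(self):
        with pytest.raises(DomainError):
            round_feedback([rating("r1", 70, rnd=2)], round=1)


class TestPanelEstimate:
    def test_single_rater(self):
        est = panel_estimate([rating("r1", 80)], "A")
        assert est[0].utility == 0.8 and est[0].n_raters == 1

    def test_mean_of_round2(self):
        est = panel_estimate([rating("r1", 60), rating("r2", 80)], "A")
        assert est[0].utility == pytest.approx(0.7)

    def test_round1_fallback(self):
        ratings = [rating("r1", 50, rnd=1),  # r1 skipped round 2
                   rating("r2", 30, rnd=1), rating("r2", 70, rnd=2)]
        est = panel_estimate(ratings, "A")
        assert est[0].utility == pytest.approx(0.6)

    def test_unknown_panel(self):
        with pytest.raises(DomainError):
            panel_estimate([rating("r1", 80)], "nope")

    def test_median_aggregate_switch(self):
        ratings = [rating("r1", 10), rating("r2", 20), rating("r3", 90)]
        est = panel_estimate(ratings, "A", aggregate="median")
        assert est[0].utility == pytest.approx(0.2)


class TestCombinePanels:
    def test_balanced_pooling(self):
        ratings = [rating("a1", 60, panel="A"), rating("b1", 80, panel="B")]
        assert combine_panels(ratings)[0].utility == pytest.approx(0.7)

    def test_rater_weighted_pooling(self):
        ratings = [rating("a1", 60, panel="A"), rating("a2", 60, panel="A"),
                   rating("b1", 90, panel="B")]
        assert combine_panels(ratings)[0].utility == pytest.approx(0.7)

    def test_single_panel_equals_panel_estimate(self):
        ratings = [rating("r1", 60), rating("r2", 80)]
        assert combine_panels(ratings) == panel_estimate(ratings, "A")

    def test_convexity(self):
        params = syn.gen_surgery_params(syn.TruthSpec(n_surgeries=4, seed=3))
        ratings = syn.gen_delphi_ratings(syn.truth_utilities(params),
                                         syn.DelphiDesign(seed=4))
        a = estimates_dict(panel_estimate(ratings, "maasstad"))
        b = estimates_dict(panel_estimate(ratings, "other"))
        for item, c in estimates_dict(combine_panels(ratings)).items():
            lo = min(a[item].utility, b[item].utility)
            hi = max(a[item].utility, b[item].utility)
            assert lo - 1e-12 <= c.utility <= hi + 1e-12


def estimates(values, state="pre"):
    return [PanelEstimate(surgery_id=f"s{i}", state=state, utility=v,
                          median=v, iqr=(v, v), n_raters=1)
            for i, v in enumerate(values)]


class TestBlandAltman:
    def test_identical_vectors(self):
        a = estimates([0.5, 0.6, 0.7])
        ba = bland_altman(a, a, "pre")
        assert ba.bias == 0 and ba.loa_low == 0 and ba.loa_high == 0

    def test_constant_offset(self):
        a = estimates([0.55, 0.65, 0.75])
        b = estimates([0.50, 0.60, 0.70])
        ba = bland_altman(a, b, "pre")
        assert ba.bias == pytest.approx(0.05)
        assert ba.loa_low == pytest.approx(0.05, abs=1e-12)
        assert ba.loa_high == pytest.approx(0.05, abs=1e-12)

    def test_worked_limits(self):
        # differences {+0.1, -0.1}: sd = 0.1414, limits +/- 0.277
        a = estimates([0.6, 0.5])
        b = estimates([0.5, 0.6])
        ba = bland_altman(a, b, "pre")
        assert ba.bias == pytest.approx(0.0, abs=1e-12)
        assert ba.loa_high == pytest.approx(0.277, abs=1e-3)
        assert ba.loa_low == pytest.approx(-0.277, abs=1e-3)

    def test_antisymmetry(self):
        a = estimates([0.52, 0.66, 0.78, 0.41])
        b = estimates([0.50, 0.70, 0.71, 0.45])
        fwd, rev = bland_altman(a, b, "pre"), bland_altman(b, a, "pre")
        assert fwd.bias == pytest.approx(-rev.bias)
        assert fwd.loa_low == pytest.approx(-rev.loa_high)
        assert fwd.loa_high == pytest.approx(-rev.loa_low)

    def test_unmatched_items_listed(self):
        a, b = estimates([0.5, 0.6]), estimates([0.5, 0.6, 0.7])
        with pytest.raises(DomainError, match="s2"):
            bland_altman(a, b, "pre")


def two_panel_ratings(shift_vas=0.0, sd=0.0, n_surgeries=6, seed=0,
                      n_raters=(5, 4)):
    # utilities bounded away from 1 so small panel shifts are never clipped
    params = syn.gen_surgery_params(syn.TruthSpec(
        n_surgeries=n_surgeries, qol_pre_range=(0.30, 0.70),
        qol_post_gain_range=(0.05, 0.20), seed=seed))
    design = syn.DelphiDesign(n_raters_per_panel=n_raters,
                              panel_labels=("A", "B"), rater_sd=sd,
                              panel_shift=shift_vas, seed=seed + 1)
    return syn.gen_delphi_ratings(syn.truth_utilities(params), design), params


class TestMixedModel:
    def test_zero_noise_zero_shift(self):
        ratings, _ = two_panel_ratings()
        md = mixed_model_difference(ratings)
        assert md.estimate == pytest.approx(0.0, abs=1e-8)

    def test_deterministic_shift_recovered_exactly(self):
        # +5 VAS on panel B, no noise: reference minus comparison = -0.05
        ratings, _ = two_panel_ratings(shift_vas=5.0)
        md = mixed_model_difference(ratings)
        assert md.estimate == pytest.approx(-0.05, abs=1e-6)

    def test_balanced_no_item_variance_collapses_to_means(self):
        # identical truth for all items -> zero between-item variance;
        # estimate equals the difference of panel grand means
        truth = {(f"s{i}", st): 0.6 for i in range(4) for st in ("pre", "post")}
        design = syn.DelphiDesign(n_raters_per_panel=(6, 6),
                                  panel_labels=("A", "B"), rater_sd=3.0,
                                  panel_shift=0.0, round2_shrinkage=0.0, seed=9)
        ratings = syn.gen_delphi_ratings(truth, design)
        final = {}
        for r in ratings:
            if r.round == 2:
                final.setdefault(r.panel, []).append(r.vas / 100)
        simple = np.mean(final["A"]) - np.mean(final["B"])
        md = mixed_model_difference(ratings)
        assert md.estimate == pytest.approx(simple, abs=1e-6)

    def test_ci_brackets_estimate(self):
        ratings, _ = two_panel_ratings(shift_vas=2.0, sd=4.0)
        md = mixed_model_difference(ratings)
        assert md.ci[0] <= md.estimate <= md.ci[1]

    def test_single_panel_rejected(self):
        with pytest.raises(DomainError):
            mixed_model_difference([rating("r1", 50), rating("r2", 60, sid="s2")])


class TestValidatePanels:
    def test_duplicated_panel_identity(self):
        params = syn.gen_surgery_params(syn.TruthSpec(n_surgeries=5, seed=2))
        design = syn.DelphiDesign(n_raters_per_panel=(4,), panel_labels=("A",),
                                  rater_sd=4.0, seed=3)
        one = syn.gen_delphi_ratings(syn.truth_utilities(params), design)
        mirrored = one + [DelphiRating(rater_id="B" + r.rater_id, panel="B",
                                       surgery_id=r.surgery_id, state=r.state,
                                       round=r.round, vas=r.vas) for r in one]
        cmp = validate_panels(mirrored, params, PSAConfig(n_draws=40, seed=5))
        assert cmp.spearman_rho == pytest.approx(1.0)
        assert cmp.bland_altman["pre"].bias == pytest.approx(0.0, abs=1e-12)
        assert cmp.bland_altman["post"].bias == pytest.approx(0.0, abs=1e-12)
        assert cmp.mixed.estimate == pytest.approx(0.0, abs=1e-10)

    def test_uniform_shift_preserves_order(self):
        ratings, params = two_panel_ratings(shift_vas=5.0)
        cmp = validate_panels(ratings, params, PSAConfig(n_draws=40, seed=6))
        assert cmp.spearman_rho == pytest.approx(1.0)
        assert cmp.bland_altman["pre"].bias == pytest.approx(-0.05, abs=1e-9)
        assert cmp.bland_altman["post"].bias == pytest.approx(-0.05, abs=1e-9)

    def test_large_noise_degrades_rho(self):
        ratings, params = two_panel_ratings(sd=25.0, n_surgeries=10, seed=4)
        cmp = validate_panels(ratings, params, PSAConfig(n_draws=40, seed=7))
        assert cmp.spearman_rho < 1.0

    def test_missing_estimate_is_domain_error(self):
        ratings, params = two_panel_ratings()
        extra = syn.gen_surgery_params(syn.TruthSpec(n_surgeries=7, seed=0))
        with pytest.raises(DomainError):
            validate_panels(ratings, extra, PSAConfig(n_draws=5, seed=1))
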