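"""Curve features, the rule set, IV/LV classifiers and pair selection."""

import random

import numpy as np
import pytest
from sklearn.metrics import balanced_accuracy_score

from ctperf.curves import BolusParams, IntensityCurve, corrupt_curve, make_bolus_curve
from ctperf.phantom import default_spec
from ctperf.pipeline import make_training_curves
from ctperf.validity import (
    IVClassifier,
    PairWarning,
    RuleConfig,
    featurize,
    iv_predict,
    lv_predict,
    rule_check,
    select_pair,
    train_iv,
    train_lv,
)


def _clean(kind="AIF", n=30, dt=1.5):
    spec = default_spec()
    params = spec.aif_params if kind == "AIF" else spec.vof_params()
    return make_bolus_curve(params, n, dt)


class TestFeaturize:
    def test_flat_curve(self):
        f = featurize(IntensityCurve(np.full(30, 40.0), dt=1.5))
        assert f.peak_enhancement == 0
        assert f.n_peaks == 0

    def test_triangular_hand_example(self):
        c = IntensityCurve(np.array([0, 0, 50, 100, 50, 0, 0.0]), dt=1.0, baseline_frames=2)
        f = featurize(c)
        assert f.time_to_peak == pytest.approx(3.0)
        assert f.fwhm == pytest.approx(2.0)
        assert f.n_peaks == 1

    def test_gamma_time_to_peak_at_analytic_mode(self):
        p = BolusParams(t0=6.0, alpha=2.0, beta=1.5)
        f = featurize(make_bolus_curve(p, 30, 1.5))
        assert f.time_to_peak == pytest.approx(1.5 * round(p.time_to_peak / 1.5))

    def test_decay_fraction_bounds(self, rng):
        for _ in range(10):
            c = IntensityCurve(rng.random(30) * 100, dt=1.5)
            assert 0.0 <= featurize(c).decay_fraction <= 1.0


class TestRuleCheck:
    def test_clean_aif_passes_all_rules(self):
        res = rule_check(_clean("AIF"), "AIF")
        assert res.valid and res.failed_rules == ()

    def test_weak_enhancement_fails_peak_rule(self):
        c = make_bolus_curve(BolusParams(amplitude=50.0), 30, 1.5)
        res = rule_check(c, "AIF")
        assert not res.valid
        assert "peak" in res.failed_rules

    def test_multi_peak_fails_single_peak_rule(self):
        c = corrupt_curve(_clean("AIF"), "multi_peak", 1.0, 0)
        assert "single_peak" in rule_check(c, "AIF").failed_rules

    def test_truncated_bolus_fails_decay_rule(self):
        c = corrupt_curve(_clean("AIF"), "truncated_bolus", 1.0, 0)
        assert "decay" in rule_check(c, "AIF").failed_rules

    def test_all_failures_reported_not_just_first(self):
        flat = corrupt_curve(_clean("AIF"), "flat", 1.0, 0)
        res = rule_check(flat, "AIF")
        assert len(res.failed_rules) >= 2

    def test_disabled_rules_accept_any_enhancing_curve(self, rng):
        cfg = RuleConfig(enabled=())
        for _ in range(5):
            c = IntensityCurve(rng.random(30) * 120, dt=1.5)
            assert rule_check(c, "AIF", cfg).valid

    def test_valid_iff_no_failed_rules(self):
        for c in (_clean("AIF"), corrupt_curve(_clean("AIF"), "jagged", 20, 1)):
            res = rule_check(c, "AIF")
            assert res.valid == (len(res.failed_rules) == 0)


class TestIVClassifier:
    def test_held_out_balanced_accuracy(self, rng):
        tr_c, tr_l = make_training_curves("AIF", 200, 200, seed=0)
        te_c, te_l = make_training_curves("AIF", 50, 50, seed=77)
        clf = train_iv(tr_c, tr_l, "AIF", seed=0)
        pred = [clf.predict_curve(c) for c in te_c]
        assert balanced_accuracy_score(te_l, pred) >= 0.9

    def test_training_set_consistency_and_probability_bounds(self):
        tr_c, tr_l = make_training_curves("AIF", 60, 60, seed=0)
        clf = train_iv(tr_c, tr_l, "AIF", seed=0)
        p, call = iv_predict(clf, _clean("AIF"))
        assert 0.0 <= p <= 1.0 and call
        flat = corrupt_curve(_clean("AIF"), "flat", 1.0, 0)
        assert not iv_predict(clf, flat)[1]

    def test_single_class_labels_raise(self):
        curves = [_clean("AIF") for _ in range(4)]
        with pytest.raises(ValueError):
            train_iv(curves, [True] * 4, "AIF", seed=0)

    def test_deterministic_given_seed(self):
        tr_c, tr_l = make_training_curves("AIF", 40, 40, seed=0)
        probe, _ = make_training_curves("AIF", 10, 10, seed=9)
        p1 = [train_iv(tr_c, tr_l, "AIF", seed=5).predict_proba_curve(c) for c in probe]
        p2 = [train_iv(tr_c, tr_l, "AIF", seed=5).predict_proba_curve(c) for c in probe]
        assert p1 == p2

    def test_training_invariant_to_curve_order(self):
        tr_c, tr_l = make_training_curves("AIF", 40, 40, seed=0)
        probe, _ = make_training_curves("AIF", 10, 10, seed=9)
        idx = list(range(len(tr_c)))
        random.Random(3).shuffle(idx)
        a = train_iv(tr_c, tr_l, "AIF", seed=5)
        b = train_iv([tr_c[i] for i in idx], [tr_l[i] for i in idx], "AIF", seed=5)
        assert [a.predict_proba_curve(c) for c in probe] == [
            b.predict_proba_curve(c) for c in probe
        ]

    def test_role_mismatch_raises(self):
        tr_c, tr_l = make_training_curves("AIF", 30, 30, seed=0)
        clf = train_iv(tr_c, tr_l, "AIF", seed=0)
        with pytest.raises(ValueError, match="role"):
            iv_predict(clf, _clean("VOF"), kind="VOF")


@pytest.fixture(scope="module")
def lv():
    a, _ = make_training_curves("AIF", 150, 0, seed=0)
    v, _ = make_training_curves("VOF", 150, 0, seed=1)
    return train_lv(a + v, [False] * 150 + [True] * 150, seed=0)


class TestLVClassifier:

    def test_separates_arterial_from_venous(self, lv):
        assert lv_predict(lv, _clean("VOF"))[1]
        assert not lv_predict(lv, _clean("AIF"))[1]

    def test_held_out_balanced_accuracy(self, lv):
        ta, _ = make_training_curves("AIF", 40, 0, seed=5)
        tv, _ = make_training_curves("VOF", 40, 0, seed=6)
        pred = [lv_predict(lv, c)[1] for c in ta + tv]
        assert balanced_accuracy_score([False] * 40 + [True] * 40, pred) >= 0.9

    def test_same_curve_same_probability(self, lv):
        c = _clean("VOF")
        assert lv_predict(lv, c)[0] == lv_predict(lv, c)[0]


class TestSelectPair:
    def _cands(self):
        aifs = [_clean("AIF")] + [
            corrupt_curve(_clean("AIF"), m, 1.0, i) for i, m in enumerate(
                ("flat", "jagged", "multi_peak", "flat"))
        ]
        vofs = [_clean("VOF")] + [corrupt_curve(_clean("VOF"), "flat", 1.0, i) for i in (1, 2)]
        return aifs, vofs

    def test_picks_the_valid_pair(self, validity_models):
        iv_aif, iv_vof, lv = validity_models
        aifs, vofs = self._cands()
        pair = select_pair(aifs, vofs, iv_aif, iv_vof, lv)
        assert pair == (0, 0)

    def test_all_flat_returns_warning(self):
        flat = [corrupt_curve(_clean("AIF"), "flat", 1.0, i) for i in range(5)]
        flatv = [corrupt_curve(_clean("VOF"), "flat", 1.0, i) for i in range(3)]
        assert isinstance(select_pair(flat, flatv), PairWarning)

    def test_zero_delay_pair_rejected(self):
        # venous slot holds an arterial-shaped curve: peaks coincide
        aifs = [_clean("AIF")] * 5
        vofs = [make_bolus_curve(BolusParams(amplitude=200.0), 30, 1.5)] * 3
        out = select_pair(aifs, vofs)
        assert isinstance(out, PairWarning)

    def test_rules_alone_suffice_without_models(self):
        aifs, vofs = self._cands()
        assert select_pair(aifs, vofs) == (0, 0)

    def test_selected_pair_respects_delay_window(self, validity_models, rng):
        iv_aif, iv_vof, lv = validity_models
        cfg = RuleConfig()
        for seed in range(5):
            aifs, _ = make_training_curves("AIF", 3, 2, seed=seed)
            vofs, _ = make_training_curves("VOF", 2, 1, seed=seed + 50)
            out = select_pair(aifs[:5], vofs[:3], iv_aif, iv_vof, lv)
            if isinstance(out, PairWarning):
                continue
            i, j = out
            d = featurize(vofs[j]).time_to_peak - featurize(aifs[i]).time_to_peak
            assert cfg.delay_window[0] <= d <= cfg.delay_window[1]
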