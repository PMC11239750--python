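"""Paired study orchestration, class aggregates, and diagnostic statistics."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

import coroflow as cf
from coroflow.study import LesionResult, aggregates_frame, diagnostics_table


def concordance_auc(pred, invasive, cutoff=0.8):
    """Exhaustive pairwise-concordance oracle: probability that a random
    positive lesion (invasive FFR <= cutoff) has a lower predicted FFR than
    a random negative one, ties counting one half."""
    pos = [p for p, v in zip(pred, invasive) if v <= cutoff]
    neg = [p for p, v in zip(pred, invasive) if v > cutoff]
    total = 0.0
    for a, b in itertools.product(pos, neg):
        if a < b:
            total += 1.0
        elif a == b:
            total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_indices(pred, invasive, cutoff=0.8):
    tp = tn = fp = fn = 0
    for p, v in zip(pred, invasive):
        if v <= cutoff:
            if p <= cutoff:
                tp += 1
            else:
                fn += 1
        else:
            if p <= cutoff:
                fp += 1
            else:
                tn += 1
    return tp, tn, fp, fn


class TestBlandAltman:
    def test_identical_vectors(self):
        assert cf.bland_altman([0.7, 0.8, 0.9], [0.7, 0.8, 0.9]) == (0.0, 0.0)

    def test_constant_offset(self):
        bias, sd = cf.bland_altman([0.7, 0.9], [0.8, 1.0])
        assert bias == pytest.approx(0.1)
        assert sd == pytest.approx(0.0, abs=1e-15)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        pred = rng.uniform(0.4, 1.0, 30)
        inv = np.clip(pred + rng.normal(0, 0.05, 30), 0.3, 1.0)
        bias, sd = cf.bland_altman(pred, inv)
        d = inv - pred
        assert bias == pytest.approx(d.mean(), rel=1e-12)
        assert sd == pytest.approx(math.sqrt(((d - d.mean()) ** 2).sum() / (len(d) - 1)), rel=1e-12)

    def test_direction_flip(self):
        b1, _ = cf.bland_altman([0.7], [0.8] , direction="invasive_minus_pred") if False else cf.bland_altman([0.7, 0.9], [0.8, 1.0])
        b2, _ = cf.bland_altman([0.7, 0.9], [0.8, 1.0], direction="pred_minus_invasive")
        assert b2 == pytest.approx(-b1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cf.bland_altman([0.7], [0.8, 0.9])


class TestDiagnosticIndices:
    def test_perfect_agreement(self):
        idx = cf.diagnostic_indices([0.7, 0.9, 0.6], [0.7, 0.9, 0.6])
        assert (idx.sensitivity, idx.specificity, idx.accuracy) == (1.0, 1.0, 1.0)

    def test_worked_two_by_two(self):
        idx = cf.diagnostic_indices([0.7, 0.85, 0.6, 0.9], [0.75, 0.7, 0.6, 0.9])
        assert (idx.tp, idx.fn, idx.tn, idx.fp) == (2, 1, 1, 0)
        assert idx.sensitivity == pytest.approx(2 / 3)
        assert idx.specificity == 1.0
        assert idx.accuracy == pytest.approx(3 / 4)

    def test_inverted_predictions(self):
        idx = cf.diagnostic_indices([0.9, 0.7], [0.7, 0.9])
        assert (idx.sensitivity, idx.specificity, idx.accuracy) == (0.0, 0.0, 0.0)

    def test_undefined_reported_as_none(self):
        idx = cf.diagnostic_indices([0.7, 0.6], [0.7, 0.6])  # no negatives
        assert idx.specificity is None
        assert idx.sensitivity == 1.0

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = rng.integers(3, 40)
            pred = rng.uniform(0.3, 1.0, n)
            inv = rng.uniform(0.3, 1.0, n)
            idx = cf.diagnostic_indices(pred, inv)
            tp, tn, fp, fn = brute_force_indices(pred, inv)
            assert (idx.tp, idx.tn, idx.fp, idx.fn) == (tp, tn, fp, fn)

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        pred = rng.uniform(0.3, 1.0, 20)
        inv = rng.uniform(0.3, 1.0, 20)
        idx1 = cf.diagnostic_indices(pred, inv)
        perm = rng.permutation(20)
        idx2 = cf.diagnostic_indices(pred[perm], inv[perm])
        assert (idx1.sensitivity, idx1.specificity, idx1.accuracy) == (
            idx2.sensitivity,
            idx2.specificity,
            idx2.accuracy,
        )


class TestRocAuc:
    def test_perfect_separation(self):
        pred = [0.5, 0.6, 0.9, 0.95]
        inv = [0.7, 0.75, 0.9, 0.95]
        assert cf.roc_auc(pred, inv) == 1.0

    def test_all_tied_is_half(self):
        assert cf.roc_auc([0.8, 0.8, 0.8, 0.8], [0.7, 0.6, 0.9, 0.95]) == 0.5

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            cf.roc_auc([0.5, 0.6], [0.7, 0.75])

    def test_equals_pairwise_concordance(self):
        """Trapezoidal ROC sweep equals exhaustive concordance enumeration on
        random paired sets up to n = 50, including ties."""
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(4, 51))
            pred = np.round(rng.uniform(0.3, 1.0, n), 2)  # rounding forces ties
            inv = rng.uniform(0.3, 1.0, n)
            if (inv <= 0.8).all() or (inv > 0.8).all():
                continue
            assert cf.roc_auc(pred, inv) == pytest.approx(concordance_auc(pred, inv), abs=1e-12)

    def test_six_point_toy(self):
        pred = [0.5, 0.75, 0.78, 0.82, 0.9, 0.78]
        inv = [0.6, 0.7, 0.85, 0.75, 0.9, 0.95]
        assert cf.roc_auc(pred, inv) == pytest.approx(concordance_auc(pred, inv))


def _result(**kw):
    defaults = dict(
        lesion_id=1,
        ffr_id=1,
        flow_setup="murray",
        ffr_pred=0.8,
        gffr_pred=0.72,
        delta_p_abs_mmHg=10.0,
        delta_p_wire_mmHg=14.0,
        inflow_abs_ml_s=10.0,
        inflow_wire_ml_s=9.5,
        ffr_class=3,
        ffr_invasive=0.78,
    )
    defaults.update(kw)
    return LesionResult(**defaults)


class TestClassAggregates:
    def test_single_lesion_percentages(self):
        aggs = cf.class_aggregates([_result()])
        a3 = [a for a in aggs if a.ffr_class == 3][0]
        assert a3.mean_ffr_drop_pct == pytest.approx(10.0)
        assert a3.mean_delta_p_rise_pct == pytest.approx(40.0)
        assert a3.mean_inflow_drop_pct == pytest.approx(5.0)

    def test_identical_wire_states_zero(self):
        r = _result(gffr_pred=0.8, delta_p_wire_mmHg=10.0, inflow_wire_ml_s=10.0)
        a3 = [a for a in cf.class_aggregates([r]) if a.ffr_class == 3][0]
        assert a3.mean_ffr_drop_pct == 0.0
        assert a3.mean_delta_p_rise_pct == 0.0
        assert a3.mean_inflow_drop_pct == 0.0

    def test_duplication_idempotent(self):
        rs = [_result(), _result(lesion_id=2, ffr_pred=0.76, gffr_pred=0.7)]
        once = cf.class_aggregates(rs)
        twice = cf.class_aggregates(rs + rs)
        for a, b in zip(once, twice):
            if a.n:
                assert b.mean_ffr_drop_pct == pytest.approx(a.mean_ffr_drop_pct)

    def test_empty_class_flagged_missing(self):
        aggs = cf.class_aggregates([_result()])
        a1 = [a for a in aggs if a.ffr_class == 1][0]
        assert a1.missing
        assert a1.mean_ffr_drop_pct is None

    def test_class_from_prediction_when_unpaired(self):
        r = _result(ffr_class=None, ffr_invasive=None, ffr_pred=0.45, gffr_pred=0.4)
        a1 = [a for a in cf.class_aggregates([r]) if a.ffr_class == 1][0]
        assert a1.n == 1

    def test_frame_shape(self):
        df = aggregates_frame(cf.class_aggregates([_result()]))
        assert list(df.ffr_class) == [1, 2, 3, 4]


@pytest.fixture(scope="module")
def mini_results(config):
    cohort = cf.generate_cohort(1, seed=3, config=config)
    return cohort, cf.paired_wire_study(cohort, config=config, mode="steady")


class TestPairedStudy:
    def test_bookkeeping(self, mini_results):
        cohort, results = mini_results
        assert len(cohort) == 4
        assert len(results) == 8  # 4 lesions x 2 flow setups
        assert not any(r.failed for r in results)
        keys = {(r.lesion_id, r.flow_setup) for r in results}
        assert len(keys) == 8

    def test_wire_invariants_per_lesion(self, mini_results):
        _, results = mini_results
        for r in results:
            assert r.gffr_pred <= r.ffr_pred
            assert r.delta_p_wire_mmHg >= r.delta_p_abs_mmHg
            assert r.inflow_wire_ml_s <= r.inflow_abs_ml_s

    def test_diagnostics_table_structure(self, mini_results):
        _, results = mini_results
        df = diagnostics_table(results)
        assert set(df.model) == {"wire_absent", "wire_included"}
        assert set(df.flow_setup) == {"murray", "length_based"}
        assert (df.n == 4).all()

    def test_failure_recorded_not_raised(self, config):
        cohort = cf.generate_cohort(1, seed=3, config=config)
        # sabotage one tree so its simulation fails: throat too tight for wire
        bad = cohort[0].tree.copy()
        sid = bad.measurement.lesion_segment_id
        bad.segments[sid].stenosis = cf.StenosisSpec(0.988, bad.segments[sid].stenosis.stenosis_length_cm)
        cohort[0].tree = bad
        results = cf.paired_wire_study(cohort, flow_setups=("murray",), config=config, mode="steady")
        assert len(results) == 4
        failed = [r for r in results if r.failed]
        assert len(failed) == 1
        assert "fit" in failed[0].failure_reason or "venous" in failed[0].failure_reason
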