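"""Metric suite vs textbook oracles; reduction-protocol invariants."""

import numpy as np
import pytest

from labreduce.encounters import CohortTensors
from labreduce.evaluation import (compute_metrics, no_reduction_evaluate,
                                  reduction_evaluate, threshold_sweep,
                                  value_consistency, _binary_block)
from labreduce.network import ModelConfig, PredictionBundle, SelectiveNet, select
from labreduce.losses import LossConfig
from labreduce.training import Checkpoint, TrainConfig
from labreduce.encounters import Standardizer


# ----------------------------------------------------- textbook metric oracles

def auc_pairwise(labels, scores):
    """Pairwise-concordance AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for a in pos:
        for b in neg:
            wins += a > b
            ties += a == b
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def average_precision(labels, scores):
    """Textbook AP: sum over descending unique thresholds of
    (R_k - R_{k-1}) * P_k, with tied scores entering together."""
    n_pos = labels.sum()
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    for s in sorted(set(scores), reverse=True):
        at = scores == s
        tp += int(labels[at].sum())
        fp += int((1 - labels[at]).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def test_metric_block_matches_oracles_on_small_fixtures():
    rng = np.random.default_rng(8)
    for _ in range(30):
        n = rng.integers(4, 21)
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # ties likely
        blk = _binary_block(scores, labels)
        assert blk["auc"] / 100 == pytest.approx(auc_pairwise(labels, scores), abs=1e-9)
        assert blk["auprc"] / 100 == pytest.approx(average_precision(labels, scores),
                                                   abs=1e-9)
        pred = scores >= 0.5
        assert blk["accuracy"] / 100 == pytest.approx((pred == labels).mean(), abs=1e-12)
        assert blk["prevalence"] / 100 == pytest.approx(labels.mean(), abs=1e-12)
        if pred.sum():
            assert blk["precision"] / 100 == pytest.approx(labels[pred].mean(), abs=1e-12)


def test_single_class_selection_reports_undefined_auc():
    blk = _binary_block(np.array([0.2, 0.9]), np.array([1, 1]))
    assert np.isnan(blk["auc"]) and np.isnan(blk["auprc"])
    assert blk["prevalence"] == 100.0


def test_perfect_scores_reach_100():
    blk = _binary_block(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
    assert blk["auc"] == 100.0 and blk["auprc"] == 100.0 and blk["accuracy"] == 100.0


# ------------------------------------------------------------ fixture helpers

def _toy_checkpoint(tensors, p_bias=0.0, epochs=0, seed=4):
    """Untrained (or barely trained) checkpoint for protocol tests."""
    model = SelectiveNet(ModelConfig(hidden_size=8, mlp_hidden=5, seed=seed))
    model.head_p.b2.data[:] = p_bias
    std = Standardizer().fit(tensors)
    return Checkpoint(model=model, loss_config=LossConfig(target_coverage=0.85),
                      train_config=TrainConfig(epochs=epochs), standardizer=std)


def test_never_selecting_model_reduces_nothing(small_tensors):
    sub = small_tensors.subset(np.arange(40))
    ck = _toy_checkpoint(sub, p_bias=-30.0)
    row, dec = reduction_evaluate(ck, sub, tau=0.5)
    assert row["reduction_rate"] == 0.0
    assert row["model_coverage"] == 0.0
    assert dec["reduced"].sum() == 0


def test_reduction_subset_of_selection_subset_of_observed(small_tensors):
    sub = small_tensors.subset(np.arange(60))
    ck = _toy_checkpoint(sub, p_bias=0.3)
    for tau in (0.05, 0.5, 0.95):
        row, dec = reduction_evaluate(ck, sub, tau=tau)
        sel, red = dec["selected"], dec["reduced"]
        assert np.all(red <= sel)
        assert np.all(sel <= (sub.o > 0))
        assert not sel[:, 0].any()  # first draws are never candidates
        assert row["reduction_rate"] <= row["model_coverage"] + 1e-12


def test_no_reduction_invariant_to_encounter_order(small_tensors):
    sub = small_tensors.subset(np.arange(30))
    ck = _toy_checkpoint(sub)
    r1, _ = no_reduction_evaluate(ck, sub)
    perm = np.random.default_rng(1).permutation(30)
    r2, _ = no_reduction_evaluate(ck, sub.subset(perm))
    for k in ("model_coverage", "normality_auc", "stability_auc", "normality_accuracy"):
        assert r1[k] == pytest.approx(r2[k], abs=1e-9)


def test_protocols_agree_when_nothing_is_reduced(small_tensors):
    sub = small_tensors.subset(np.arange(30))
    ck = _toy_checkpoint(sub, p_bias=-30.0)
    red, _ = reduction_evaluate(ck, sub)
    nored, _ = no_reduction_evaluate(ck, sub)
    # zero selections on both sides: coverage matches, metrics undefined alike
    assert red["model_coverage"] == nored["model_coverage"] == 0.0
    assert np.isnan(red["normality_auc"]) and np.isnan(nored["normality_auc"])


def test_sweep_deterministic_and_bounded(small_tensors):
    sub = small_tensors.subset(np.arange(25))
    ck = _toy_checkpoint(sub, p_bias=0.2)
    taus = (0.05, 0.5, 0.95)
    df1 = threshold_sweep(ck, sub, taus)
    df2 = threshold_sweep(ck, sub, taus)
    assert df1.equals(df2)
    assert len(df1) == 3
    assert df1.model_coverage.iloc[0] >= df1.model_coverage.iloc[-1]
    with pytest.raises(ValueError):
        threshold_sweep(ck, sub, ())
    with pytest.raises(ValueError):
        threshold_sweep(ck, sub, (0.01,))


def test_value_consistency_arithmetic():
    # one encounter, LBNR 12.0; predicted normal with value 11.7
    data = CohortTensors(ids=["e"], X=np.zeros((1, 4, 39)), y=np.ones((1, 4)),
                         z=np.ones((1, 4)), v=np.full((1, 4), 12.5),
                         o=np.ones((1, 4)), lbnr=np.array([12.0]),
                         seq_len=np.array([4]))
    bundle = PredictionBundle(p=np.ones((1, 4)),
                              normality=np.array([[0.9, 0.9, 0.9, 0.2]]),
                              stability=np.ones((1, 4)),
                              value=np.array([[11.7, 12.1, 13.0, 5.0]]))
    # predicted-normal timesteps are t=1,2 (t=0 unpredictable, t=3 predicted abnormal)
    assert value_consistency(bundle, data, m_percent=0) == pytest.approx(100 * 2 / 2)
    bundle.value[0, 1] = 11.7
    assert value_consistency(bundle, data, m_percent=0) == pytest.approx(50.0)
    assert value_consistency(bundle, data, m_percent=3) == pytest.approx(100.0)  # 11.64
    none_normal = PredictionBundle(p=bundle.p, normality=np.zeros((1, 4)),
                                   stability=bundle.stability, value=bundle.value)
    assert np.isnan(value_consistency(none_normal, data))


def test_compute_metrics_coverage_accounting(small_tensors):
    sub = small_tensors.subset(np.arange(20))
    ck = _toy_checkpoint(sub, p_bias=30.0)  # selects everything predictable
    row, dec = reduction_evaluate(ck, sub, tau=0.5)
    assert row["model_coverage"] == pytest.approx(100.0)
    n_predictable = sub.predictable.sum()
    assert dec["selected"].sum() == n_predictable
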