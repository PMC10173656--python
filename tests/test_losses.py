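"""Selective-loss components against an independent loop-based oracle."""

import math

import numpy as np
import pytest

from labreduce.autodiff import Tensor
from labreduce.losses import (EmptySelectionError, LossConfig, auxiliary_value_loss,
                              bce, coverage_penalty, empirical_coverage, psi,
                              selective_risk, total_loss)


# ------------------------------------------------------------------- oracle
# Straight-line reimplementation of the objective with explicit Python loops,
# written independently of the vectorized module code.

def oracle_components(y_score, z_score, v_pred, p, y, z, v, valid, c, lam, alpha):
    eps = 1e-7
    idx = [(i, t) for i in range(valid.shape[0]) for t in range(valid.shape[1])
           if valid[i, t] > 0]
    n = len(idx)

    def xent(s, label):
        s = min(max(s, eps), 1 - eps)
        return -(label * math.log(s) + (1 - label) * math.log(1 - s))

    phi = sum(p[i, t] for i, t in idx) / n
    r_y = sum(xent(y_score[i, t], y[i, t]) * p[i, t] for i, t in idx) / n / phi
    r_z = sum(xent(z_score[i, t], z[i, t]) * p[i, t] for i, t in idx) / n / phi
    pen = lam * max(0.0, c - phi) ** 2
    l_aux = sum((v_pred[i, t] - v[i, t]) ** 2 for i, t in idx) / n
    lf = r_y + r_z + pen
    return {"phi": phi, "r_Y": r_y, "r_Z": r_z, "penalty": pen, "L_aux": l_aux,
            "L_f": lf, "L": alpha * lf + (1 - alpha) * l_aux}


def random_fixture(rng):
    n_enc = rng.integers(1, 5)
    T = rng.integers(2, 9)
    shape = (n_enc, T)
    valid = (rng.random(shape) < 0.7).astype(float)
    if valid.sum() == 0:
        valid[0, -1] = 1.0
    return {
        "y_score": rng.uniform(0.01, 0.99, shape), "z_score": rng.uniform(0.01, 0.99, shape),
        "v_pred": rng.uniform(0, 16, shape), "p": rng.uniform(0.05, 1.0, shape),
        "y": (rng.random(shape) < 0.3).astype(float),
        "z": (rng.random(shape) < 0.9).astype(float),
        "v": rng.uniform(5, 16, shape), "valid": valid,
    }


def module_components(fx, c, lam, alpha):
    outputs = {"y": Tensor(fx["y_score"]), "z": Tensor(fx["z_score"]),
               "v": Tensor(fx["v_pred"]), "p": Tensor(fx["p"])}
    labels = {"y": fx["y"], "z": fx["z"], "v": fx["v"]}
    cfg = LossConfig(target_coverage=c, lam=lam, alpha=alpha)
    _, parts = total_loss(outputs, labels, fx["valid"], cfg)
    return parts


def test_total_loss_matches_oracle_on_random_fixtures():
    rng = np.random.default_rng(42)
    for trial in range(100):
        fx = random_fixture(rng)
        c = float(rng.choice([0.75, 0.85, 0.95, 1.0]))
        lam, alpha = 32.0, 0.5
        got = module_components(fx, c, lam, alpha)
        want = oracle_components(fx["y_score"], fx["z_score"], fx["v_pred"], fx["p"],
                                 fx["y"], fx["z"], fx["v"], fx["valid"], c, lam, alpha)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, rel=1e-6, abs=1e-9), f"{k} trial {trial}"


# ------------------------------------------------------------ hand examples

def test_empirical_coverage_hand_values():
    assert empirical_coverage([1, 0, 1, 0], [1, 1, 1, 1]).item() == pytest.approx(0.5)
    assert empirical_coverage([1, 1, 1], [1, 1, 1]).item() == pytest.approx(1.0)
    assert empirical_coverage([0.2, 0.4, 0.9], [1, 1, 1]).item() == pytest.approx(0.5)
    with pytest.raises(EmptySelectionError):
        empirical_coverage([0.5], [0.0])


def test_coverage_penalty_hand_values():
    assert coverage_penalty(0.85, 0.9, 32.0).item() == 0.0
    assert coverage_penalty(0.85, 0.80, 32.0).item() == pytest.approx(0.08)
    assert psi(0.5).item() == pytest.approx(0.25)
    assert psi(-1.3).item() == 0.0


def test_bce_hand_values():
    assert bce(1 - 1e-9, 1.0).item() == pytest.approx(0.0, abs=1e-6)
    assert bce(0.5, 1.0).item() == pytest.approx(math.log(2), rel=1e-9)
    assert bce(0.9, 0.0).item() == pytest.approx(-math.log(0.1), rel=1e-7)


def test_selective_risk_hand_values():
    assert selective_risk([1.0, 2.0], [0.5, 1.0], [1, 1]).item() == pytest.approx(5 / 3)
    # all selected: plain mean
    assert selective_risk([1.0, 3.0], [1.0, 1.0], [1, 1]).item() == pytest.approx(2.0)
    # single-timestep indicator selection picks out that loss
    assert selective_risk([1.0, 3.0], [0.0, 1.0], [1, 1]).item() == pytest.approx(3.0)
    with pytest.raises(EmptySelectionError):
        selective_risk([1.0], [0.0], [1.0])


def test_auxiliary_value_loss_ignores_selection():
    v_pred, v, m = [10.0, 12.0], [11.0, 12.0], [1, 1]
    assert auxiliary_value_loss(v_pred, v, m).item() == pytest.approx(0.5)
    assert auxiliary_value_loss(v, v, m).item() == 0.0


@pytest.mark.parametrize("alpha,key", [(1.0, "L_f"), (0.0, "L_aux")])
def test_alpha_boundaries_collapse_to_single_term(alpha, key):
    rng = np.random.default_rng(3)
    fx = random_fixture(rng)
    parts = module_components(fx, 0.85, 32.0, alpha)
    assert parts["L"] == pytest.approx(parts[key], rel=1e-12)


# -------------------------------------------------------------- properties

def test_padding_and_permutation_invariance():
    rng = np.random.default_rng(5)
    fx = random_fixture(rng)
    base = module_components(fx, 0.85, 32.0, 0.5)
    # append an all-invalid encounter: nothing changes
    fx_pad = {k: np.concatenate([v, np.zeros((1, v.shape[1]))]) for k, v in fx.items()}
    padded = module_components(fx_pad, 0.85, 32.0, 0.5)
    # permute encounters: nothing changes
    perm = np.random.default_rng(6).permutation(fx["p"].shape[0])
    fx_perm = {k: v[perm] for k, v in fx.items()}
    permuted = module_components(fx_perm, 0.85, 32.0, 0.5)
    for k in base:
        assert padded[k] == pytest.approx(base[k], rel=1e-9)
        assert permuted[k] == pytest.approx(base[k], rel=1e-9)


def test_coverage_penalty_gradient_direction():
    """Under-coverage pushes every p_t up; at/over coverage exerts no force."""
    m = np.ones((1, 4))
    for c, expect_negative in [(0.9, True), (0.3, False)]:
        p = Tensor(np.full((1, 4), 0.5), requires_grad=True)
        pen = coverage_penalty(c, empirical_coverage(p, m), 32.0)
        pen.backward()
        if expect_negative:
            assert np.all(p.grad < 0)  # decreasing loss direction raises p
        else:
            assert np.all(p.grad == 0)


def test_total_loss_differentiable_wrt_outputs():
    rng = np.random.default_rng(9)
    fx = random_fixture(rng)
    outputs = {k2: Tensor(fx[k1], requires_grad=True)
               for k1, k2 in [("y_score", "y"), ("z_score", "z"), ("v_pred", "v"), ("p", "p")]}
    L, _ = total_loss(outputs, {"y": fx["y"], "z": fx["z"], "v": fx["v"]},
                      fx["valid"], LossConfig(target_coverage=0.95))
    L.backward()
    for t in outputs.values():
        assert t.grad is not None and np.all(np.isfinite(t.grad))


def test_encounter_level_mode_on_uniform_batch_matches_pooled():
    # with identical encounters the two averaging modes coincide
    rng = np.random.default_rng(11)
    row_p = rng.uniform(0.1, 1.0, (1, 6))
    row_l = rng.uniform(0, 2, (1, 6))
    p, L = np.repeat(row_p, 3, 0), np.repeat(row_l, 3, 0)
    m = np.ones_like(p)
    pooled = selective_risk(L, p, m, encounter_level=False).item()
    per_enc = selective_risk(L, p, m, encounter_level=True).item()
    assert per_enc == pytest.approx(pooled, rel=1e-12)
    assert empirical_coverage(p, m, True).item() == pytest.approx(
        empirical_coverage(p, m, False).item(), rel=1e-12)
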