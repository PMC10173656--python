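"""Coverage-constrained multi-task selective loss.

The selective part averages the normality and stability cross-entropies with
selection-probability weights and normalizes by the empirical coverage
``phi(P)``, then adds a one-sided quadratic penalty ``lambda * max(0, c -
phi)^2`` that pushes coverage up towards the target ``c`` (over-coverage is
never penalized).  An auxiliary mean-squared Hgb-value loss over *all*
observed timesteps — selected or not — anchors the shared representation:

    L = alpha * [ r(f_Y) + r(f_Z) + lambda * psi(c - phi(P)) ] + (1 - alpha) * L_aux

All terms pool valid timesteps (observed Hgb with at least one prior draw)
across the encounters of a mini-batch by default; a per-encounter averaging
mode is available behind ``encounter_level``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

COVERAGE_GRID = (0.75, 0.8, 0.85, 0.9, 0.95, 1.0)


class EmptySelectionError(ZeroDivisionError):
    """No valid timesteps, or zero empirical coverage."""


@dataclass
class LossConfig:
    target_coverage: float = 0.85  # c, conventionally from COVERAGE_GRID
    lam: float = 32.0              # penalty weight lambda
    alpha: float = 0.5             # selective vs auxiliary mix
    tau_train: float = 0.5         # training-time selection threshold
    encounter_level: bool = False  # average per encounter instead of per batch

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LossConfig":
        return cls(**d)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def empirical_coverage(p, valid_mask, encounter_level: bool = False) -> Tensor:
    """phi(P): mean selection probability over valid timesteps."""
    p = _as_tensor(p)
    m = np.asarray(valid_mask, dtype=np.float64)
    if m.sum() == 0:
        raise EmptySelectionError("no valid timesteps for coverage")
    if encounter_level:
        rows = m.sum(axis=-1)
        keep = rows > 0
        per_enc = (p * Tensor(m)).sum(axis=-1)[keep] / Tensor(rows[keep])
        return per_enc.mean()
    return (p * Tensor(m)).sum() / m.sum()


def psi(a) -> Tensor:
    """One-sided quadratic penalty psi(a) = max(0, a)^2."""
    return ad.square(ad.relu(_as_tensor(a)))


def coverage_penalty(c: float, phi, lam: float) -> Tensor:
    """lambda * psi(c - phi): zero whenever coverage meets the target."""
    return lam * psi(c - _as_tensor(phi))


def bce(score, label) -> Tensor:
    """Elementwise negative binary cross-entropy of probabilities vs {0,1} labels."""
    s = ad.clip_probs(_as_tensor(score))
    y = Tensor(np.asarray(label, dtype=np.float64))
    return -(y * ad.log(s) + (1.0 - y) * ad.log(1.0 - s))


def selective_risk(losses, p, valid_mask, encounter_level: bool = False) -> Tensor:
    """p-weighted mean loss over valid timesteps, normalized by coverage."""
    losses, p = _as_tensor(losses), _as_tensor(p)
    m = np.asarray(valid_mask, dtype=np.float64)
    if m.sum() == 0:
        raise EmptySelectionError("no valid timesteps")
    if encounter_level:
        rows = m.sum(axis=-1)
        keep = rows > 0
        num = (losses * p * Tensor(m)).sum(axis=-1)[keep] / Tensor(rows[keep])
        den = (p * Tensor(m)).sum(axis=-1)[keep] / Tensor(rows[keep])
        if np.any(den.data <= 0):
            raise EmptySelectionError("zero coverage in an encounter")
        return (num / den).mean()
    phi = empirical_coverage(p, m)
    if phi.data <= 0:
        raise EmptySelectionError("zero empirical coverage")
    return (losses * p * Tensor(m)).sum() / m.sum() / phi


def auxiliary_value_loss(value_preds, v, valid_mask) -> Tensor:
    """Unweighted MSE over all valid timesteps, independent of selection."""
    f = _as_tensor(value_preds)
    v = np.asarray(v, dtype=np.float64)
    m = np.asarray(valid_mask, dtype=np.float64)
    if m.sum() == 0:
        raise EmptySelectionError("no valid timesteps")
    d = f - Tensor(v)
    return (d * d * Tensor(m)).sum() / m.sum()


def total_loss(outputs: dict, labels: dict, valid_mask, cfg: LossConfig
               ) -> tuple[Tensor, dict]:
    """Combined objective plus a per-component breakdown for logging.

    `outputs` holds Tensors 'y', 'z', 'v' and 'p' (None disables selection:
    the risks collapse to plain means and the penalty vanishes); `labels`
    holds arrays 'y', 'z', 'v'.  `valid_mask` flags observed-Hgb timesteps
    with a prior draw.
    """
    m = np.asarray(valid_mask, dtype=np.float64)
    ly = bce(outputs["y"], labels["y"])
    lz = bce(outputs["z"], labels["z"])
    p = outputs.get("p")
    enc = cfg.encounter_level
    if p is None:
        ones = Tensor(np.ones_like(m))
        r_y = selective_risk(ly, ones, m, enc)
        r_z = selective_risk(lz, ones, m, enc)
        phi_val, pen = 1.0, Tensor(0.0)
    else:
        r_y = selective_risk(ly, p, m, enc)
        r_z = selective_risk(lz, p, m, enc)
        phi = empirical_coverage(p, m, enc)
        phi_val = float(phi.data)
        pen = coverage_penalty(cfg.target_coverage, phi, cfg.lam)
    l_aux = auxiliary_value_loss(outputs["v"], labels["v"], m)
    lf = r_y + r_z + pen
    total = cfg.alpha * lf + (1.0 - cfg.alpha) * l_aux
    parts = {"L": float(total.data), "L_f": float(lf.data), "r_Y": float(r_y.data),
             "r_Z": float(r_z.data), "phi": phi_val, "penalty": float(pen.data),
             "L_aux": float(l_aux.data)}
    return total, parts
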