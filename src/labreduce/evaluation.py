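"""Evaluation protocols, metric suite, value-consistency and threshold sweep.

Two protocols: *reduction* simulates deployment — whenever the model
recommends omitting the next Hgb (predicted normal and stable among
selected candidates), that value is zeroed in all subsequent inputs;
*no-reduction* always feeds full observations.  The gap between the two is
the robustness statistic.

Classification metrics (prevalence, AUC, AUPRC, accuracy, precision) are
computed over *selected* timesteps; model coverage is the selected fraction
of predictable timesteps (observed Hgb with at least one prior draw) and the
reduction rate is the omitted fraction of all observed Hgb tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .encounters import HGB_COL, HGB_IND_COL, HGBCHG_COL, CohortTensors
from .network import PredictionBundle, select
from .training import Checkpoint

TAU_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))
CLASS_CUTOFF = 0.5  # score cutoff for predicted normal / predicted stable


def _binary_block(scores: np.ndarray, labels: np.ndarray) -> dict:
    """Prevalence/AUC/AUPRC/accuracy/precision of one task, in percent."""
    labels = labels.astype(int)
    pred = scores >= CLASS_CUTOFF
    out = {"prevalence": 100.0 * labels.mean() if labels.size else np.nan,
           "accuracy": 100.0 * (pred == labels).mean() if labels.size else np.nan}
    pp = pred.sum()
    out["precision"] = 100.0 * labels[pred].mean() if pp > 0 else np.nan
    if labels.size and 0 < labels.sum() < labels.size:
        out["auc"] = 100.0 * roc_auc_score(labels, scores)
        out["auprc"] = 100.0 * average_precision_score(labels, scores)
    else:  # single-class selection: AUC/AUPRC undefined
        out["auc"] = np.nan
        out["auprc"] = np.nan
    return out


def compute_metrics(bundle: PredictionBundle, data: CohortTensors,
                    selection_mask: np.ndarray, reduced_mask: np.ndarray | None = None
                    ) -> dict:
    """Metric block over the selected timesteps of a cohort."""
    sel = np.asarray(selection_mask, dtype=bool)
    predictable = data.predictable
    n_pred = predictable.sum()
    row = {"model_coverage": 100.0 * sel.sum() / n_pred if n_pred else np.nan,
           "n_selected": int(sel.sum())}
    if reduced_mask is not None:
        n_obs = (data.o > 0).sum()
        row["reduction_rate"] = 100.0 * reduced_mask.sum() / n_obs if n_obs else np.nan
        row["n_reduced"] = int(reduced_mask.sum())
    for task, scores, labels in (("normality", bundle.normality, data.y),
                                 ("stability", bundle.stability, data.z)):
        blk = _binary_block(scores[sel], labels[sel])
        row.update({f"{task}_{k}": v for k, v in blk.items()})
    return row


def _zero_hgb_input(X: np.ndarray, o: np.ndarray, rows: np.ndarray, t: int) -> None:
    """Hide the Hgb at timestep t of `rows` from all later inputs."""
    X[rows, t, HGB_COL] = 0.0
    X[rows, t, HGB_IND_COL] = 0.0
    X[rows, t, HGBCHG_COL] = 0.0
    for i in rows:
        nxt = np.nonzero(o[i, t + 1:])[0]
        if nxt.size:
            X[i, t + 1 + nxt[0], HGBCHG_COL] = 0.0


def reduction_evaluate(checkpoint: Checkpoint, data: CohortTensors, tau: float = 0.5
                       ) -> tuple[dict, dict]:
    """Stepwise reduction simulation over a test cohort.

    From t=1 on, the model is run on the current (possibly already-reduced)
    inputs; where it recommends omission — selected (p > tau), predicted
    normal and predicted stable — the true Hgb at t is zeroed out of every
    later input.  Gold labels always come from the true values.  Returns the
    metric row and the per-timestep decision arrays.
    """
    model = checkpoint.model
    X = checkpoint.standardizer.transform(data)
    o = data.o
    N, T = o.shape
    p_rec = np.zeros((N, T))
    y_rec = np.zeros((N, T))
    z_rec = np.zeros((N, T))
    v_rec = np.zeros((N, T))
    reduced = np.zeros((N, T), dtype=bool)
    for t in range(1, int(data.seq_len.max())):
        obs_t = o[:, t] > 0
        if not obs_t.any():
            continue
        bundle = model.predict(X, data.seq_len)
        p_rec[:, t] = bundle.p[:, t]
        y_rec[:, t] = bundle.normality[:, t]
        z_rec[:, t] = bundle.stability[:, t]
        v_rec[:, t] = bundle.value[:, t]
        omit = (obs_t & (bundle.p[:, t] > tau)
                & (bundle.normality[:, t] >= CLASS_CUTOFF)
                & (bundle.stability[:, t] >= CLASS_CUTOFF))
        if omit.any():
            reduced[omit, t] = True
            _zero_hgb_input(X, o, np.nonzero(omit)[0], t)
    bundle = PredictionBundle(p=p_rec, normality=y_rec, stability=z_rec, value=v_rec)
    sel = select(p_rec, tau, data.predictable)
    row = compute_metrics(bundle, data, sel, reduced_mask=reduced)
    row.update({"tau": tau, "protocol": "reduction",
                "target_coverage": checkpoint.loss_config.target_coverage})
    decisions = {"bundle": bundle, "selected": sel, "reduced": reduced}
    return row, decisions


def no_reduction_evaluate(checkpoint: Checkpoint, data: CohortTensors, tau: float = 0.5
                          ) -> tuple[dict, dict]:
    """Idealized protocol: a single forward pass on full observations."""
    X = checkpoint.standardizer.transform(data)
    bundle = checkpoint.model.predict(X, data.seq_len)
    sel = select(bundle.p, tau, data.predictable)
    row = compute_metrics(bundle, data, sel)
    row.update({"tau": tau, "protocol": "no_reduction",
                "target_coverage": checkpoint.loss_config.target_coverage})
    return row, {"bundle": bundle, "selected": sel}


def robustness_gap(reduction_row: dict, no_reduction_row: dict) -> dict:
    """Signed per-metric difference (reduction minus no-reduction)."""
    keys = [k for k, v in reduction_row.items()
            if isinstance(v, (int, float)) and k in no_reduction_row]
    return {k: reduction_row[k] - no_reduction_row[k] for k in keys}


def model_coverage(checkpoint: Checkpoint, data: CohortTensors, tau: float = 0.5) -> float:
    """Fraction (0-1) of predictable timesteps selected at threshold tau."""
    X = checkpoint.standardizer.transform(data)
    bundle = checkpoint.model.predict(X, data.seq_len)
    m = data.predictable
    return float(select(bundle.p, tau, m).sum() / m.sum())


def value_consistency(bundle: PredictionBundle, data: CohortTensors,
                      mask: np.ndarray | None = None, m_percent: float = 0.0) -> float:
    """Percent of predicted-normal timesteps whose predicted value clears
    (1 - m/100) * LBNR; NaN when nothing is predicted normal."""
    mask = data.predictable if mask is None else np.asarray(mask, dtype=bool)
    pred_normal = mask & (bundle.normality >= CLASS_CUTOFF)
    if not pred_normal.any():
        return float("nan")
    thresh = (1.0 - m_percent / 100.0) * data.lbnr[:, None]
    ok = bundle.value >= thresh
    return 100.0 * float(ok[pred_normal].mean())


def threshold_sweep(checkpoint: Checkpoint, data: CohortTensors,
                    taus=TAU_GRID) -> pd.DataFrame:
    """Reduction-protocol metric rows over a grid of selection thresholds."""
    taus = list(taus)
    if not taus:
        raise ValueError("tau grid is empty")
    if min(taus) < 0.05 or max(taus) > 0.95:
        raise ValueError("tau grid must lie within [0.05, 0.95]")
    rows = []
    for tau in taus:
        row, _ = reduction_evaluate(checkpoint, data, tau=float(tau))
        rows.append(row)
    return pd.DataFrame(rows)


def evaluation_report(checkpoints: dict[float, Checkpoint], data: CohortTensors,
                      tau: float = 0.5, m_grid=(0, 3, 5, 10)) -> pd.DataFrame:
    """Tidy per-coverage report under both protocols, with value consistency."""
    rows = []
    for c in sorted(checkpoints):
        ck = checkpoints[c]
        red, dec = reduction_evaluate(ck, data, tau)
        nored, _ = no_reduction_evaluate(ck, data, tau)
        for m in m_grid:
            red[f"value_consistency_m{m}"] = value_consistency(
                dec["bundle"], data, dec["selected"], m_percent=m)
        rows.extend([red, nored])
    return pd.DataFrame(rows)
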