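"""High-level modelling interface: build a model from data, fit, inspect results.

`HgbReductionModel` bundles a training cohort, the network/loss/training
configuration and a held-out test cohort; `fit()` trains one network per
target coverage and returns an `HgbReductionResults` carrying the trained
checkpoints, evaluation tables and a text `summary()`.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd

from .encounters import (CohortTensors, apply_cohort_filters, encounters_to_tensors,
                         load_cohort_csv, split_cohort)
from .evaluation import (evaluation_report, model_coverage, reduction_evaluate, threshold_sweep, value_consistency)
from .losses import LossConfig
from .network import ModelConfig
from .synthetic import SimConfig, calibrate_prevalence, generate_cohort
from .training import Checkpoint, TrainConfig, train


class HgbReductionModel:
    """Selective Hgb-test-reduction model over a fixed train/test cohort split."""

    def __init__(self, train_data: CohortTensors, test_data: CohortTensors | None = None,
                 model_config: ModelConfig | None = None,
                 loss_config: LossConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.train_data = train_data
        self.test_data = test_data
        self.model_config = model_config or ModelConfig()
        self.loss_config = loss_config or LossConfig()
        self.train_config = train_config or TrainConfig()

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_encounters(cls, encounters, train_frac: float = 0.8, seed: int = 0,
                        filter_cohort: bool = True, **kw) -> "HgbReductionModel":
        if filter_cohort:
            encounters = apply_cohort_filters(encounters)
        tr, te = split_cohort(encounters, train_frac, seed)
        return cls(encounters_to_tensors(tr), encounters_to_tensors(te), **kw)

    @classmethod
    def from_csv(cls, long_path, demo_path, **kw) -> "HgbReductionModel":
        return cls.from_encounters(load_cohort_csv(long_path, demo_path), **kw)

    @classmethod
    def from_synthetic(cls, sim_config: SimConfig | None = None, calibrate: bool = True,
                       train_frac: float = 0.8, seed: int | None = None,
                       **kw) -> "HgbReductionModel":
        cfg = sim_config or SimConfig()
        if seed is not None:
            cfg = cfg.replace(seed=seed)
        if calibrate:
            cfg = calibrate_prevalence(cfg)
        return cls.from_encounters(generate_cohort(cfg), train_frac=train_frac,
                                   seed=cfg.seed, **kw)

    # ------------------------------------------------------------------- fit
    def fit(self, coverage=None) -> "HgbReductionResults":
        """Train one checkpoint per target coverage (scalar or iterable)."""
        if coverage is None:
            grid = self.train_config.coverage_grid
        elif np.isscalar(coverage):
            grid = (float(coverage),)
        else:
            grid = tuple(float(c) for c in coverage)
        checkpoints = train(self.train_data, self.model_config, self.loss_config,
                            self.train_config, coverage_grid=grid)
        return HgbReductionResults(self, checkpoints)


class HgbReductionResults:
    """Fitted selective models and their held-out evaluation."""

    def __init__(self, model: HgbReductionModel, checkpoints: dict[float, Checkpoint]):
        self.model = model
        self.checkpoints = checkpoints

    @property
    def coverages(self) -> list[float]:
        return sorted(self.checkpoints)

    def _data(self, data=None) -> CohortTensors:
        data = data if data is not None else self.model.test_data
        if data is None:
            raise ValueError("no held-out data attached; pass a cohort explicitly")
        return data

    def coverage_table(self, data=None, tau: float = 0.5) -> pd.DataFrame:
        """Held-out model coverage vs target coverage per fitted model."""
        data = self._data(data)
        rows = []
        for c in self.coverages:
            cov = model_coverage(self.checkpoints[c], data, tau)
            rows.append({"target_coverage": c, "model_coverage": cov,
                         "abs_diff_pp": 100.0 * abs(cov - c)})
        return pd.DataFrame(rows)

    def evaluate(self, data=None, tau: float = 0.5) -> pd.DataFrame:
        """Full per-coverage report under both protocols."""
        return evaluation_report(self.checkpoints, self._data(data), tau=tau)

    def threshold_sweep(self, coverage: float | None = None, data=None,
                        taus=None) -> pd.DataFrame:
        c = coverage if coverage is not None else self.coverages[0]
        kw = {} if taus is None else {"taus": taus}
        return threshold_sweep(self.checkpoints[float(c)], self._data(data), **kw)

    def value_consistency(self, coverage: float | None = None, data=None,
                          m_percent: float = 0.0, tau: float = 0.5) -> float:
        c = coverage if coverage is not None else self.coverages[0]
        data = self._data(data)
        _, dec = reduction_evaluate(self.checkpoints[float(c)], data, tau)
        return value_consistency(dec["bundle"], data, dec["selected"], m_percent)

    def summary(self, data=None, tau: float = 0.5) -> str:
        """Text table of the held-out evaluation, one row per target coverage."""
        data = self._data(data)
        lines = ["Selective Hgb test reduction — held-out evaluation",
                 "=" * 66,
                 f"encounters: train={len(self.model.train_data)}, "
                 f"test={len(data)};  selection threshold tau={tau}",
                 "-" * 66,
                 f"{'c':>5} {'cover%':>7} {'reduc%':>7} {'normAUC':>8} "
                 f"{'normAUPRC':>9} {'stabAUC':>8} {'stabAcc':>8}"]
        for c in self.coverages:
            row, _ = reduction_evaluate(self.checkpoints[c], data, tau)
            lines.append(
                f"{c:>5.2f} {row['model_coverage']:>7.2f} {row['reduction_rate']:>7.2f} "
                f"{row['normality_auc']:>8.2f} {row['normality_auprc']:>9.2f} "
                f"{row['stability_auc']:>8.2f} {row['stability_accuracy']:>8.2f}")
        lines.append("-" * 66)
        lines.append("cover% = selected share of predictable Hgb draws; "
                     "reduc% = omitted share of all observed Hgb draws")
        return "\n".join(lines)

    # ------------------------------------------------------------ persistence
    def save(self, outdir) -> None:
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        index = []
        for c, ck in self.checkpoints.items():
            name = f"checkpoint_c{int(round(c * 100)):03d}.npz"
            ck.save(outdir / name)
            index.append({"coverage": c, "file": name})
        (outdir / "checkpoints.json").write_text(json.dumps(index, indent=2))

    @staticmethod
    def load_checkpoints(outdir) -> dict[float, Checkpoint]:
        outdir = pathlib.Path(outdir)
        index = json.loads((outdir / "checkpoints.json").read_text())
        return {e["coverage"]: Checkpoint.load(outdir / e["file"]) for e in index}
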