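"""Synthetic inpatient cohort generator.

Emulates the statistical structure the selective-prediction method assumes:
irregular hourly draws of 12 labs + 5 vitals with structured missingness,
age/sex-dependent Hgb normal ranges, and Hgb trajectories mixing long stable
runs with abrupt normal-to-abnormal drops.

Generative story (an abstraction of inpatient anemia dynamics, with no claim
of physiologic fidelity): encounters fall into four acuity classes — stably
normal (routine monitoring of recovered patients: the reducible tests),
chronically abnormal (stable anemia), acute (admitted near-normal, suffers
discrete drop events with partial recovery: the source of transitions), and
a small erratic-outlier class (near coin-flip on both label tasks: the
low-confidence minority the selective mechanism learns to reject).  A
per-class baseline moves by drift, drop events and reversion toward its
admission level; AR(1) measurement noise rides on top, and a
currently-normal value is clamped at the lower normal bound unless a drop
occurred that step, so noise alone never produces a normal-to-abnormal
transition and the zero-drop, zero-drift configuration is exactly
transition-free.

:func:`calibrate_prevalence` pins the cohort to target label prevalences by
coordinate bisection: the transition/prevalence ratio is monotone in the
global drop-hazard scale, the prevalence in the global level offset; both
are measured through the real preprocessing and labeling pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .encounters import (CBC_PANEL, DEFAULT_RANGES, LABS, VITALS,
                         DrawRecord, EncounterSequence, apply_cohort_filters,
                         encounters_to_tensors)

# physiologic means and spreads for the auxiliary labs and vitals
LAB_DISTS = {
    "Na": (140.0, 3.0), "K": (4.1, 0.4), "Cl": (102.0, 4.0), "HCO3": (24.0, 3.0),
    "Ca": (9.3, 0.5), "Mg": (2.0, 0.25), "PO4": (3.5, 0.6), "BUN": (18.0, 8.0),
    "Cr": (1.0, 0.4), "Plt": (250.0, 80.0), "WBC": (8.0, 3.0),
}
VITAL_DISTS = {
    "pulse": (80.0, 12.0), "dbp": (72.0, 10.0), "sbp": (120.0, 15.0),
    "resp_rate": (17.0, 3.0), "spo2": (97.0, 1.5),
}

HGB_FLOOR = 2.0  # g/dL physiologic floor


class CalibrationError(RuntimeError):
    """Targets unreachable within the generator's parameter bounds."""


@dataclass
class SimConfig:
    """Tunable knobs of the synthetic cohort.

    Defaults approximate an anemic inpatient population whose label
    prevalences sit near the study conditions (normality ~19.5%, transition
    rate ~9.2% of observed Hgb draws); exact matching is the job of
    :func:`calibrate_prevalence`.
    """
    n_encounters: int = 2000
    seed: int = 0
    mean_draws: float = 10.0          # truncated-geometric mean, in [2, 30]
    gap_mean_hours: float = 6.0       # mean hours between consecutive draws
    # Hgb process, all in g/dL.  Encounters fall into three acuity classes —
    # stably normal (routine monitoring of a recovered patient), chronically
    # abnormal (stable anemia), and acute (admitted near-normal, then drops).
    # The printed class shares/hazards jointly set the label prevalences and
    # the supply of confidently-predictable vs unpredictable draws.
    class_mix: tuple = (0.07, 0.12, 0.76, 0.05)     # stable-normal, chronic,
                                                    # acute, erratic outlier
    class_offsets: tuple = (1.2, -1.8, 0.7, 0.0)    # start level rel. LBNR
    class_vol: tuple = (0.5, 0.7, 1.6, 4.0)         # volatility multiplier
    class_hazard: tuple = (0.0, 0.03, 0.90, 0.50)   # per-draw drop hazard
    class_drop_mean: tuple = (2.0, 2.0, 2.0, 1.0)   # mean drop size; erratic
                                                    # drops are shallow so the
                                                    # level churns both ways
    hgb_start_offset: float = 0.0     # global additive shift of all class offsets
    hgb_between_sd: float = 0.40      # encounter-level baseline spread
    hgb_sigma_step: float = 0.45      # AR measurement-noise innovation sd
    hgb_vol_log_sd: float = 0.40      # extra log-normal volatility spread (acute)
    hgb_vol_cap: float = 8.0          # cap on the realized multiplier
    hgb_rho: float = 0.5              # AR(1) coefficient of the noise
    hgb_drift: float = 0.0            # per-draw baseline drift
    baseline_reversion: float = 0.30  # per-draw relaxation of the baseline back
                                      # towards its admission level (marrow
                                      # response / transfusion abstraction)
    drop_event_prob: float = 1.4      # global hazard scale; realized per-encounter
                                      # hazard is capped at 0.95
    drop_magnitude_mean: float = 2.0
    drop_magnitude_sd: float = 0.5
    lab_correlation: float = 0.3      # corr of auxiliary labs with Hgb
    missing_rates: dict = field(default_factory=lambda: {
        **{k: 0.35 for k in LABS if k not in CBC_PANEL},
        **{k: 0.30 for k in CBC_PANEL},      # CBC shares one mask
        **{k: 0.10 for k in VITALS},
    })
    pediatric_frac: float = 0.02
    target_normal_prev: float = 0.195
    target_transition_rate: float = 0.092
    inject_exclusions: bool = False   # add SBP<90 and single-Hgb test cases

    def validate(self) -> None:
        probs = [self.pediatric_frac, self.target_normal_prev,
                 self.target_transition_rate, *self.missing_rates.values(),
                 *self.class_hazard, *self.class_mix]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if not 0.0 <= self.drop_event_prob <= 3.0:
            raise ValueError("drop_event_prob (hazard scale) must lie in [0, 3]")
        if self.n_encounters < 1:
            raise ValueError("n_encounters must be >= 1")
        if self.mean_draws < 2:
            raise ValueError("mean_draws must be >= 2")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


def _sample_demographics(rng: np.random.Generator, cfg: SimConfig):
    sex = int(rng.integers(0, 2))
    if rng.random() < cfg.pediatric_frac:
        age = float(rng.uniform(0.6, 17.0))
    else:
        age = float(rng.uniform(18.0, 90.0))
    race = int(rng.choice(5, p=[0.5, 0.2, 0.15, 0.1, 0.05]))
    return sex, race, age


def _hgb_trajectory(rng: np.random.Generator, cfg: SimConfig, lbnr: float, n: int,
                    allow_drops: bool = True) -> np.ndarray:
    """True Hgb values at every draw of one encounter.

    An acuity class is drawn first (stable-normal / chronic-abnormal / acute)
    fixing the start level, volatility and drop hazard.  The baseline then
    starts at lbnr + class offset + global offset + encounter effect; per
    draw it adds drift and, with the class hazard (scaled by the global
    hazard scale, capped at 0.95), subtracts a discrete drop.  AR(1) noise
    rides on the baseline; a currently-normal value is clamped at the LBNR
    unless a drop occurred this step (or drift is negative), so noise alone
    never produces a normal-to-abnormal transition.
    """
    k = int(rng.choice(len(cfg.class_mix), p=cfg.class_mix))
    mult = cfg.class_vol[k]
    if k == 2:  # acute class: graded severity
        mult = min(mult * float(np.exp(rng.normal(0.0, cfg.hgb_vol_log_sd))),
                   cfg.hgb_vol_cap)
    b = (lbnr + cfg.class_offsets[k] + cfg.hgb_start_offset
         + rng.normal(0.0, cfg.hgb_between_sd))
    sigma = cfg.hgb_sigma_step * mult
    drop_p = min(cfg.drop_event_prob * cfg.class_hazard[k]
                 * (mult / cfg.class_vol[k] if k == 2 else 1.0), 0.95)
    e = rng.normal(0.0, sigma)
    b0 = b
    vals = np.empty(n)
    prev_val = None
    for t in range(n):
        dropped = False
        if t > 0:
            b += cfg.hgb_drift + cfg.baseline_reversion * (b0 - b)
            if allow_drops and rng.random() < drop_p:
                b -= max(rng.normal(cfg.class_drop_mean[k], cfg.drop_magnitude_sd), 0.3)
                dropped = True
            e = cfg.hgb_rho * e + rng.normal(0.0, sigma)
        val = b + e
        if (prev_val is not None and prev_val >= lbnr and not dropped
                and cfg.hgb_drift >= 0.0):
            val = max(val, lbnr)  # sticky-normal: no spurious downward crossing
        val = max(val, HGB_FLOOR)
        vals[t] = val
        prev_val = val
    return vals


def generate_cohort(config: SimConfig) -> list[EncounterSequence]:
    """Generate a cohort of raw (untrimmed) encounter sequences.

    Deterministic under ``config.seed``.  All encounters pass the standard
    cohort filters unless ``inject_exclusions`` is set, in which case a small
    fraction carry SBP readings below 90 mmHg or only a single observed Hgb.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chem = [k for k in LABS if k not in CBC_PANEL]
    p_geom = 1.0 / max(config.mean_draws - 1.0, 1.0)
    encounters = []
    for i in range(config.n_encounters):
        sex, race, age = _sample_demographics(rng, config)
        lbnr = DEFAULT_RANGES.lbnr(age, sex)
        n = int(min(1 + rng.geometric(p_geom), 30))
        n = max(n, 2)
        gaps = rng.geometric(1.0 / config.gap_mean_hours, size=n - 1)
        hours = np.concatenate([[0], np.cumsum(gaps)]).astype(int)

        single_hgb = config.inject_exclusions and rng.random() < 0.05
        low_sbp = config.inject_exclusions and rng.random() < 0.05

        hgb = _hgb_trajectory(rng, config, lbnr, n)
        hgb_z = (hgb - lbnr + 1.0) / 1.5  # rough population z-score of Hgb
        r = config.lab_correlation

        cbc_obs = rng.random(n) >= config.missing_rates["Hgb"]
        cbc_obs[0] = True
        cbc_obs[-1] = True
        if single_hgb:
            cbc_obs[:] = False
            cbc_obs[0] = True

        draws = []
        for t in range(n):
            values = {}
            if cbc_obs[t]:
                values["Hgb"] = round(float(hgb[t]), 2)
                for name in ("Plt", "WBC"):
                    mu, sd = LAB_DISTS[name]
                    val = mu + r * sd * hgb_z[t] + np.sqrt(1 - r * r) * sd * rng.normal()
                    values[name] = round(float(max(val, 0.1)), 2)
            for name in chem:
                if rng.random() >= config.missing_rates[name]:
                    mu, sd = LAB_DISTS[name]
                    val = mu + r * sd * hgb_z[t] + np.sqrt(1 - r * r) * sd * rng.normal()
                    values[name] = round(float(max(val, 0.05)), 2)
            for name in VITALS:
                if rng.random() >= config.missing_rates[name]:
                    mu, sd = VITAL_DISTS[name]
                    val = rng.normal(mu, sd)
                    if name == "sbp":
                        val = val - 40.0 if (low_sbp and t == n // 2) else max(val, 90.0)
                    if name == "spo2":
                        val = min(val, 100.0)
                    values[name] = round(float(max(val, 1.0)), 1)
            draws.append(DrawRecord(hour_index=int(hours[t]), values=values))
        encounters.append(EncounterSequence(
            encounter_id=f"E{i:05d}", sex=sex, race=race, age=age, draws=draws))
    return encounters


def measure_prevalences(config: SimConfig, n: int | None = None,
                        seed: int | None = None) -> tuple[float, float]:
    """Empirical (normality prevalence, transition rate) over observed Hgb draws,
    computed through the real preprocessing and labeling pipeline."""
    cfg = config.replace(n_encounters=n or config.n_encounters,
                         seed=config.seed if seed is None else seed,
                         inject_exclusions=False)
    cohort = apply_cohort_filters(generate_cohort(cfg))
    tens = encounters_to_tensors(cohort)
    obs = tens.o > 0
    prev = float(tens.y[obs].mean())
    trans = float((tens.z[obs] == 0).mean())
    return prev, trans


def _bisect(measure, lo, hi, target, iters=11):
    """Bisection for a monotone-increasing scalar map; returns (x, f(x))."""
    f_lo, f_hi = measure(lo), measure(hi)
    if not f_lo <= target <= f_hi:
        x = lo if abs(f_lo - target) < abs(f_hi - target) else hi
        return x, (f_lo if x == lo else f_hi), False
    x, fx = lo, f_lo
    for _ in range(iters):
        x = 0.5 * (lo + hi)
        fx = measure(x)
        if fx < target:
            lo = x
        else:
            hi = x
        if abs(fx - target) < 0.004:
            break
    return x, fx, True


def calibrate_prevalence(config: SimConfig, target_normal_prev: float | None = None,
                         target_transition_rate: float | None = None,
                         n_pilot: int = 800, rounds: int = 3,
                         tol: float = 0.01) -> SimConfig:
    """Tune the start offset and drop probability so pilot-cohort label
    prevalences hit the targets within `tol` (1 percentage point by default).

    Coordinate bisection: the start offset is monotone in normality
    prevalence, the drop probability in the transition rate; each round
    re-solves both to absorb their interaction.  Raises
    :class:`CalibrationError` (reporting achieved values) when a target is
    outside what the parameter bounds can reach.
    """
    tp = config.target_normal_prev if target_normal_prev is None else target_normal_prev
    tt = config.target_transition_rate if target_transition_rate is None else target_transition_rate
    if not (0.0 < tp < 1.0) or not (0.0 <= tt < 1.0):
        raise ValueError("targets must lie in (0,1)")
    cfg = config.replace(target_normal_prev=tp, target_transition_rate=tt)
    pilot_seed = (config.seed * 7919 + 13) % (2 ** 31)

    # The two knobs are coupled: raising the drop probability also lowers the
    # time spent normal.  The transition/prevalence *ratio* (the per-draw
    # hazard of leaving the normal range) is monotone in the drop probability
    # and nearly independent of the offset, so bisect the ratio on the drop
    # probability and the prevalence on the offset.
    ratio_target = tt / tp

    def ratio_of(dp: float) -> float:
        p, t = measure_prevalences(cfg.replace(drop_event_prob=dp),
                                   n=n_pilot, seed=pilot_seed)
        return t / max(p, 1e-9)

    for _ in range(rounds):
        if tt == 0.0:
            cfg = cfg.replace(drop_event_prob=0.0)
        else:
            dp, ratio, ok = _bisect(ratio_of, 0.0, 2.5, ratio_target)
            cfg = cfg.replace(drop_event_prob=dp)
            if not ok and abs(ratio - ratio_target) > tol / max(tp, 1e-9):
                raise CalibrationError(
                    f"transition/prevalence ratio {ratio_target:.3f} unreachable; "
                    f"achieved {ratio:.3f}")
        off, prev, ok = _bisect(
            lambda x: measure_prevalences(cfg.replace(hgb_start_offset=x),
                                          n=n_pilot, seed=pilot_seed)[0],
            -2.5, 2.5, tp)
        cfg = cfg.replace(hgb_start_offset=off)
        if not ok and abs(prev - tp) > tol:
            raise CalibrationError(
                f"normality prevalence target {tp:.3f} unreachable; achieved {prev:.3f}")

    prev, trans = measure_prevalences(cfg, n=n_pilot, seed=pilot_seed)
    if abs(prev - tp) > tol or abs(trans - tt) > tol:
        raise CalibrationError(
            f"calibration did not converge: achieved prevalence {prev:.3f} "
            f"(target {tp:.3f}), transition {trans:.3f} (target {tt:.3f})")
    return cfg
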