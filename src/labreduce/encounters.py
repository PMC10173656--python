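"""Inpatient encounter data model: hourly draws, feature tensors, gold labels.

One *encounter* is an ordered sequence of hourly laboratory draws.  Raw
long-format events (``encounter_id, timestamp, variable, value``) are
aggregated to hourly :class:`DrawRecord` objects, trimmed to the window
bounded by the first and last observed hemoglobin (Hgb) result, capped at
``MAX_TIMESTEPS`` draws and encoded as a fixed ``30 x 39`` feature matrix:
12 lab values, 5 vital values, 3 demographic columns, the time difference
since the previous draw, the Hgb change since the previous observed Hgb, and
17 missing-value indicators.  Missing analytes are zero-imputed with their
indicator set to 0.

Gold labels per timestep: normality ``y`` (Hgb at/above the age- and
sex-specific lower bound of the normal range), stability ``z`` (no
normal-to-abnormal drop relative to the previous observed Hgb), the Hgb value
``v`` and the observation flag ``o``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# ----------------------------------------------------------------- constants

LABS = ["Na", "K", "Cl", "HCO3", "Ca", "Mg", "PO4", "BUN", "Cr", "Plt", "WBC", "Hgb"]
VITALS = ["pulse", "dbp", "sbp", "resp_rate", "spo2"]
ANALYTES = LABS + VITALS          # 17 measured channels
CBC_PANEL = ["Plt", "WBC", "Hgb"]  # ordered together, share one observation mask

N_FEATURES = 39
MAX_TIMESTEPS = 30

HGB_COL = LABS.index("Hgb")            # 11
SBP_COL = len(LABS) + VITALS.index("sbp")  # 14
SEX_COL, RACE_COL, AGE_COL = 17, 18, 19
TDIFF_COL, HGBCHG_COL = 20, 21
IND_OFFSET = 22                        # indicator for channel k lives at 22 + k
HGB_IND_COL = IND_OFFSET + HGB_COL     # 33

SEX_CODES = {"F": 0, "f": 0, "female": 0, "M": 1, "m": 1, "male": 1, 0: 0, 1: 1}
RACE_CODES = {"white": 0, "black": 1, "hispanic": 2, "asian": 3, "other": 4}

FEATURE_NAMES = (ANALYTES + ["sex", "race", "age"] + ["time_diff", "hgb_change"]
                 + [f"{a}_obs" for a in ANALYTES])

# Stability branch feature subset: Hgb value changes, demographics, time
# differences and observation indicators.
STABILITY_SUBSET_COLS = np.array(
    [SEX_COL, RACE_COL, AGE_COL, TDIFF_COL, HGBCHG_COL]
    + list(range(IND_OFFSET, IND_OFFSET + len(ANALYTES))), dtype=int)


class UnknownAnalyteError(ValueError):
    """An event names a variable outside the 17 known labs/vitals."""


class NoObservedHgbError(ValueError):
    """A sequence contains no observed Hgb result; the encounter is undefined."""


# --------------------------------------------------------------- normal range

@dataclass(frozen=True)
class NormalRangeRow:
    age_lo: float   # inclusive, years
    age_hi: float   # exclusive, years (inf for open-ended)
    sex: str        # 'female', 'male' or 'any'
    lbnr: float     # g/dL
    ubnr: float     # g/dL


class NormalRangeTable:
    """Age/sex-stratified Hgb normal ranges.

    Band convention: [0.5, 7) years uses the youngest band, [7, 13) the
    school-age band, >= 13 the adult rows.  Only the lower bound (LBNR) is
    used for labeling; values above the upper bound are out of scope.
    """

    def __init__(self, rows: list[NormalRangeRow] | None = None):
        self.rows = rows if rows is not None else [
            NormalRangeRow(0.5, 7.0, "any", 10.5, 14.5),
            NormalRangeRow(7.0, 13.0, "any", 11.0, 16.0),
            NormalRangeRow(13.0, float("inf"), "female", 12.0, 16.0),
            NormalRangeRow(13.0, float("inf"), "male", 14.0, 18.0),
        ]
        for r in self.rows:
            if not r.lbnr < r.ubnr:
                raise ValueError(f"LBNR must be below UBNR in row {r}")

    def lbnr(self, age: float, sex) -> float:
        if age < 0.5:
            raise ValueError(f"age {age} below 0.5 years: outside the range table")
        sex_name = "female" if SEX_CODES.get(sex, sex) == 0 else "male"
        for r in self.rows:
            if r.age_lo <= age < r.age_hi and r.sex in ("any", sex_name):
                return r.lbnr
        raise ValueError(f"no normal-range row for age={age}, sex={sex}")

    def to_dict(self) -> list[dict]:
        return [vars(r).copy() for r in self.rows]


DEFAULT_RANGES = NormalRangeTable()


def normality_label(hgb: float, age: float, sex, ranges: NormalRangeTable = DEFAULT_RANGES,
                    boundary_normal: bool = True) -> int:
    """1 iff `hgb` is at/above the LBNR for this age band and sex.

    `boundary_normal` controls whether a value exactly equal to the LBNR
    counts as normal (default) or abnormal.
    """
    if hgb <= 0:
        raise ValueError("Hgb must be positive")
    b = ranges.lbnr(age, sex)
    return int(hgb >= b) if boundary_normal else int(hgb > b)


def stability_label(prev_hgb_normality, curr_normality: int) -> int:
    """0 iff the previous observed Hgb was normal and the current is abnormal.

    Any other combination — abnormal→abnormal, abnormal→normal, normal→normal,
    or a first observation with no predecessor (`prev_hgb_normality` None) —
    is stable.
    """
    return 0 if (prev_hgb_normality == 1 and curr_normality == 0) else 1


# --------------------------------------------------------------------- types

@dataclass
class DrawRecord:
    """All analytes measured within one hour of one encounter."""
    hour_index: int
    values: dict[str, float] = field(default_factory=dict)  # observed analytes only

    def observed(self, name: str) -> bool:
        return name in self.values


@dataclass
class EncounterSequence:
    encounter_id: str
    sex: int          # 0 female, 1 male
    race: int
    age: float        # years
    draws: list[DrawRecord] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.draws)

    def n_observed_hgb(self) -> int:
        return sum(1 for d in self.draws if d.observed("Hgb"))

    def hgb_series(self) -> list[tuple[int, float]]:
        return [(t, d.values["Hgb"]) for t, d in enumerate(self.draws) if d.observed("Hgb")]


@dataclass
class LabelSet:
    """Per-timestep gold labels, zero-padded to the feature-tensor length."""
    y: np.ndarray   # normality, {0,1}; meaningful only where o == 1
    z: np.ndarray   # stability, {0,1}; meaningful only where o == 1
    v: np.ndarray   # Hgb value g/dL; 0 where unobserved
    o: np.ndarray   # observation indicator


@dataclass
class CohortTensors:
    """Stacked model-ready arrays for a list of encounters."""
    ids: list[str]
    X: np.ndarray        # (N, 30, 39)
    y: np.ndarray        # (N, 30)
    z: np.ndarray
    v: np.ndarray
    o: np.ndarray
    lbnr: np.ndarray     # (N,) per-encounter lower normal bound
    seq_len: np.ndarray  # (N,) number of non-padded rows

    def __len__(self):
        return len(self.ids)

    @property
    def predictable(self) -> np.ndarray:
        """Mask of observed-Hgb timesteps that have at least one prior draw.

        Predictions are causal, so the first draw of an encounter (which by
        construction carries the first Hgb) can never be predicted; coverage
        and selection metrics are computed over this mask.
        """
        m = self.o.astype(bool).copy()
        m[:, 0] = False
        return m

    def subset(self, idx) -> "CohortTensors":
        idx = np.asarray(idx)
        return CohortTensors([self.ids[i] for i in idx], self.X[idx], self.y[idx],
                             self.z[idx], self.v[idx], self.o[idx],
                             self.lbnr[idx], self.seq_len[idx])


# ---------------------------------------------------------------- operations

def aggregate_hourly(raw_events) -> dict[str, list[DrawRecord]]:
    """Collapse raw events to one DrawRecord per (encounter, hour).

    `raw_events` is a DataFrame (or convertible) with columns
    ``encounter_id, timestamp, variable, value``; duplicate measurements of
    one analyte within one hour are arithmetically averaged.  Hour indices
    count whole hours since each encounter's first event.
    """
    df = pd.DataFrame(raw_events, columns=["encounter_id", "timestamp", "variable", "value"]) \
        if not isinstance(raw_events, pd.DataFrame) else raw_events.copy()
    unknown = set(df["variable"]) - set(ANALYTES)
    if unknown:
        raise UnknownAnalyteError(f"unknown analyte name(s): {sorted(unknown)}")
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    t0 = df.groupby("encounter_id")["timestamp"].transform("min")
    df["hour_index"] = ((df["timestamp"] - t0) // pd.Timedelta(hours=1)).astype(int)

    agg = df.groupby(["encounter_id", "hour_index", "variable"], sort=True)["value"].mean()
    out: dict[str, list[DrawRecord]] = {}
    for (enc, hour), grp in agg.groupby(level=[0, 1], sort=True):
        rec = DrawRecord(hour_index=int(hour),
                         values={name: float(val) for (_, _, name), val in grp.items()})
        out.setdefault(enc, []).append(rec)
    return out


def apply_cohort_filters(encounters: list[EncounterSequence], min_sbp: float = 90.0
                         ) -> list[EncounterSequence]:
    """Drop encounters with any systolic BP below `min_sbp` or < 2 observed Hgb."""
    kept, n_sbp, n_hgb = [], 0, 0
    for enc in encounters:
        sbps = [d.values["sbp"] for d in enc.draws if d.observed("sbp")]
        if any(s < min_sbp for s in sbps):
            n_sbp += 1
            continue
        if enc.n_observed_hgb() < 2:
            n_hgb += 1
            continue
        kept.append(enc)
    logger.info("cohort filters: removed %d (SBP < %g mmHg), %d (< 2 Hgb); kept %d",
                n_sbp, min_sbp, n_hgb, len(kept))
    return kept


def build_sequence(draws: list[DrawRecord], demographics: dict, max_len: int = MAX_TIMESTEPS,
                   ranges: NormalRangeTable = DEFAULT_RANGES, boundary_normal: bool = True
                   ) -> tuple[EncounterSequence, np.ndarray, LabelSet]:
    """Trim, cap and encode one encounter.

    Trims to the window [first observed Hgb … last observed Hgb], keeps the
    first `max_len` draws, and returns the trimmed :class:`EncounterSequence`
    together with its zero-padded ``max_len x 39`` feature matrix and gold
    labels.
    """
    hgb_idx = [i for i, d in enumerate(draws) if d.observed("Hgb")]
    if not hgb_idx:
        raise NoObservedHgbError("no observed Hgb in sequence")
    draws = draws[hgb_idx[0]: hgb_idx[-1] + 1]
    draws = draws[:max_len]
    # after truncation the tail may end on a non-Hgb draw; re-trim to keep the
    # last-draw-has-Hgb invariant
    last = max(i for i, d in enumerate(draws) if d.observed("Hgb"))
    draws = draws[: last + 1]

    sex = SEX_CODES.get(demographics["sex"], demographics["sex"])
    race = RACE_CODES.get(demographics.get("race", 0), demographics.get("race", 0))
    age = float(demographics["age"])
    enc = EncounterSequence(encounter_id=str(demographics.get("encounter_id", "")),
                            sex=int(sex), race=int(race), age=age, draws=draws)

    T = len(draws)
    X = np.zeros((max_len, N_FEATURES))
    y = np.zeros(max_len)
    z = np.ones(max_len)
    v = np.zeros(max_len)
    o = np.zeros(max_len)

    prev_hgb, prev_norm = None, None
    for t, d in enumerate(draws):
        for k, name in enumerate(ANALYTES):
            if d.observed(name):
                X[t, k] = d.values[name]
                X[t, IND_OFFSET + k] = 1.0
        X[t, SEX_COL], X[t, RACE_COL], X[t, AGE_COL] = sex, race, age
        X[t, TDIFF_COL] = 0.0 if t == 0 else d.hour_index - draws[t - 1].hour_index
        if d.observed("Hgb"):
            hgb = d.values["Hgb"]
            X[t, HGBCHG_COL] = 0.0 if prev_hgb is None else hgb - prev_hgb
            o[t] = 1.0
            v[t] = hgb
            y[t] = normality_label(hgb, age, sex, ranges, boundary_normal)
            z[t] = stability_label(prev_norm, int(y[t]))
            prev_hgb, prev_norm = hgb, int(y[t])
    # padded rows keep z at its init value; zero it so padding is all-neutral
    z[T:] = 0.0
    z[o == 0] = 0.0
    return enc, X, LabelSet(y=y, z=z, v=v, o=o)


def split_cohort(encounters: list, train_frac: float = 0.8, seed: int = 0):
    """Deterministic encounter-level train/test partition."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must lie strictly in (0,1), got {train_frac}")
    if len(encounters) < 2:
        raise ValueError("need at least 2 encounters to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(encounters))
    n_train = int(round(train_frac * len(encounters)))
    n_train = min(max(n_train, 1), len(encounters) - 1)
    train = [encounters[i] for i in order[:n_train]]
    test = [encounters[i] for i in order[n_train:]]
    return train, test


def encounters_to_tensors(encounters: list[EncounterSequence], max_len: int = MAX_TIMESTEPS,
                          ranges: NormalRangeTable = DEFAULT_RANGES,
                          boundary_normal: bool = True) -> CohortTensors:
    """Stack per-encounter feature matrices and labels into batch arrays."""
    ids, Xs, ys, zs, vs, os_, lb, ln = [], [], [], [], [], [], [], []
    for enc in encounters:
        demo = {"encounter_id": enc.encounter_id, "sex": enc.sex, "race": enc.race,
                "age": enc.age}
        trimmed, X, lab = build_sequence(enc.draws, demo, max_len, ranges, boundary_normal)
        ids.append(enc.encounter_id)
        Xs.append(X)
        ys.append(lab.y)
        zs.append(lab.z)
        vs.append(lab.v)
        os_.append(lab.o)
        lb.append(ranges.lbnr(enc.age, enc.sex))
        ln.append(trimmed.length)
    return CohortTensors(ids, np.stack(Xs), np.stack(ys), np.stack(zs), np.stack(vs),
                         np.stack(os_), np.array(lb), np.array(ln, dtype=int))


# ----------------------------------------------------------- standardization

CONTINUOUS_COLS = np.arange(0, 17)  # labs + vitals: z-scored on observed entries
SCALE_ONLY_COLS = np.array([TDIFF_COL, HGBCHG_COL])  # scaled, not centered: 0 stays 0


class Standardizer:
    """Z-scoring of continuous feature columns using training-set statistics.

    Lab/vital columns are centered and scaled over *observed* entries only so
    zero-imputed missing values keep their sentinel meaning after masking;
    age is z-scored over non-padded rows; time-difference and Hgb-change are
    scaled by their standard deviation without centering so 0 ("no elapsed
    time" / "no predecessor") is preserved.  Padding rows stay all-zero.
    """

    def __init__(self):
        self.mean_ = None
        self.std_ = None

    def fit(self, cohort: CohortTensors) -> "Standardizer":
        X = cohort.X
        T = np.arange(X.shape[1])
        padded = T[None, :] >= cohort.seq_len[:, None]
        self.mean_ = np.zeros(N_FEATURES)
        self.std_ = np.ones(N_FEATURES)
        for k in CONTINUOUS_COLS:
            obs = X[:, :, IND_OFFSET + k] > 0
            vals = X[:, :, k][obs]
            if vals.size:
                self.mean_[k] = vals.mean()
                self.std_[k] = max(vals.std(), 1e-8)
        rows = ~padded
        self.mean_[AGE_COL] = X[:, :, AGE_COL][rows].mean()
        self.std_[AGE_COL] = max(X[:, :, AGE_COL][rows].std(), 1e-8)
        for k in SCALE_ONLY_COLS:
            self.std_[k] = max(X[:, :, k][rows].std(), 1e-8)
        return self

    def transform(self, cohort: CohortTensors) -> np.ndarray:
        X = cohort.X.copy()
        T = np.arange(X.shape[1])
        nonpad = (T[None, :] < cohort.seq_len[:, None])
        for k in CONTINUOUS_COLS:
            obs = (X[:, :, IND_OFFSET + k] > 0) & nonpad
            X[:, :, k] = np.where(obs, (X[:, :, k] - self.mean_[k]) / self.std_[k], 0.0)
        X[:, :, AGE_COL] = np.where(nonpad, (X[:, :, AGE_COL] - self.mean_[AGE_COL])
                                    / self.std_[AGE_COL], 0.0)
        for k in SCALE_ONLY_COLS:
            X[:, :, k] = np.where(nonpad, X[:, :, k] / self.std_[k], 0.0)
        return X

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "std": self.std_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        s = cls()
        s.mean_ = np.asarray(d["mean"], dtype=float)
        s.std_ = np.asarray(d["std"], dtype=float)
        return s


# ----------------------------------------------------------------- file I/O

EPOCH = pd.Timestamp("2020-01-01T00:00:00")


def write_cohort_csv(encounters: list[EncounterSequence], long_path, demo_path) -> None:
    """Serialize encounters to the long-format event CSV + demographics CSV."""
    rows = []
    for enc in encounters:
        for d in enc.draws:
            ts = (EPOCH + pd.Timedelta(hours=d.hour_index)).isoformat()
            for name, val in sorted(d.values.items()):
                rows.append((enc.encounter_id, ts, name, val))
    pd.DataFrame(rows, columns=["encounter_id", "timestamp", "variable", "value"]) \
        .to_csv(long_path, index=False)
    demo = [(e.encounter_id, e.sex, e.race, e.age) for e in encounters]
    pd.DataFrame(demo, columns=["encounter_id", "sex", "race", "age_years"]) \
        .to_csv(demo_path, index=False)


def load_cohort_csv(long_path, demo_path) -> list[EncounterSequence]:
    """Read the long-format event CSV + demographics CSV back into encounters.

    Encounters without a single observed Hgb cannot be aligned to the Hgb
    window and are skipped with a warning.
    """
    events = pd.read_csv(long_path)
    demo = pd.read_csv(demo_path).set_index("encounter_id")
    per_enc = aggregate_hourly(events)
    out = []
    for enc_id, draws in per_enc.items():
        if not any(d.observed("Hgb") for d in draws):
            logger.warning("encounter %s has no observed Hgb; skipped", enc_id)
            continue
        row = demo.loc[enc_id]
        out.append(EncounterSequence(
            encounter_id=str(enc_id), sex=int(SEX_CODES.get(row["sex"], row["sex"])),
            race=int(RACE_CODES.get(row["race"], row["race"])),
            age=float(row["age_years"]), draws=draws))
    return out
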