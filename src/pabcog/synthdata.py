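"""Synthetic cohorts, posture-event streams, and cognitive-test sessions.

The generators emulate the structure of a cross-sectional study of
vocational-education students: four educational tracks (Hairdresser, Admin,
Sports, Nursing) whose members wear a thigh-worn posture sensor for a week
and sit two executive-function tests (a color-shape task-switching test and
a letter-memory updating test).  Every generator takes an explicit seed and
exposes its ground-truth parameters, so downstream processing can be tested
by parameter recovery.

Daily activity is modelled as a composition of four posture classes —
sitting, standing, stepping, time in bed — that sums to exactly 24 h.
Participant- and day-level variation is added as zero-sum Gaussian noise on
the hour vector, which keeps expectations exactly on the profile targets.
Within a day, waking time is tiled with alternating activity episodes whose
durations are exponential draws rescaled to hit the day's class totals, and
one nightly in-bed episode spans the midnight boundary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ACTIVITY_CLASSES = ("sitting", "standing", "stepping", "time_in_bed")
WAKING_CLASSES = ("sitting", "standing", "stepping")

#: Consonant alphabet for the letter-memory test (vowels and Y excluded).
CONSONANTS = tuple("BCDFGHJKLMNPQRSTVWXZ")

#: Default stream origin: a Monday, so a 7-day stream holds 5 weekdays and
#: both weekend days and passes the 2-weekday/2-weekend-day validity rule.
DEFAULT_START = pd.Timestamp("2019-09-02 00:00:00")


class ConfigurationError(ValueError):
    """Raised for infeasible or inconsistent generator settings."""


@dataclass(frozen=True)
class CovariateParams:
    """Track-level covariate distribution (means/SDs emulate a study table)."""

    female_proportion: float
    age_mean: float
    age_sd: float
    fat_pct_mean: float
    fat_pct_sd: float
    muscle_pct_mean: float
    muscle_pct_sd: float
    bmi_mean: float
    bmi_sd: float
    #: correlation between fat % and muscle % (strongly negative in practice,
    #: which is what makes the VIF screen drop one of the two).
    fat_muscle_corr: float = -0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.female_proportion <= 1.0:
            raise ConfigurationError("female_proportion must lie in [0, 1]")
        for name in ("age_sd", "fat_pct_sd", "muscle_pct_sd", "bmi_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not -1.0 < self.fat_muscle_corr < 1.0:
            raise ConfigurationError("fat_muscle_corr must lie in (-1, 1)")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ConfigurationError(f"{f.name} must be finite")


@dataclass(frozen=True)
class TrackProfile:
    """Ground-truth daily behaviour of one educational track.

    ``target_daily_hours`` must cover the four activity classes and sum to
    24 h; ``mean_bout_minutes`` controls episode (bout) granularity, and
    ``mvpa_fraction_of_stepping`` the share of stepping time at a cadence of
    at least 100 steps/min.
    """

    track_name: str
    target_daily_hours: Mapping[str, float]
    mean_bout_minutes: Mapping[str, float]
    mvpa_fraction_of_stepping: float
    covariate_params: CovariateParams
    #: between-participant SD of each class's daily hours
    between_sd_hours: Mapping[str, float] = field(
        default_factory=lambda: {
            "sitting": 1.5, "standing": 1.1, "stepping": 0.6, "time_in_bed": 0.95,
        }
    )
    #: day-to-day SD within a participant
    day_sd_hours: Mapping[str, float] = field(
        default_factory=lambda: {
            "sitting": 1.4, "standing": 1.0, "stepping": 0.6, "time_in_bed": 0.8,
        }
    )

    def __post_init__(self) -> None:
        missing = set(ACTIVITY_CLASSES) - set(self.target_daily_hours)
        if missing:
            raise ConfigurationError(f"target_daily_hours missing {sorted(missing)}")
        total = sum(self.target_daily_hours[c] for c in ACTIVITY_CLASSES)
        if abs(total - 24.0) > 1e-9:
            raise ConfigurationError(
                f"target_daily_hours must sum to 24.0, got {total!r}"
            )
        if any(self.target_daily_hours[c] < 0 for c in ACTIVITY_CLASSES):
            raise ConfigurationError("daily hours must be non-negative")
        if self.target_daily_hours["time_in_bed"] >= 24.0:
            raise ConfigurationError("time_in_bed must leave waking time")
        if not 0.0 <= self.mvpa_fraction_of_stepping <= 1.0:
            raise ConfigurationError("mvpa_fraction_of_stepping must lie in [0, 1]")
        for c in WAKING_CLASSES:
            if self.mean_bout_minutes.get(c, 0.0) <= 0:
                raise ConfigurationError(f"mean_bout_minutes[{c}] must be > 0")
        for m in (self.between_sd_hours, self.day_sd_hours):
            if any(m[c] < 0 or not np.isfinite(m[c]) for c in ACTIVITY_CLASSES):
                raise ConfigurationError("hour SDs must be finite and >= 0")


def _scaled_hours(raw: Mapping[str, float]) -> dict[str, float]:
    """Rescale an hour map proportionally so it sums to exactly 24."""
    total = sum(raw[c] for c in ACTIVITY_CLASSES)
    return {c: raw[c] * 24.0 / total for c in ACTIVITY_CLASSES}


def default_profiles() -> dict[str, TrackProfile]:
    """The four built-in track profiles.

    Daily-hour targets are the study-condition group levels (hours/day of
    sitting, standing, stepping and time in bed per track), proportionally
    rescaled to close the 24-h composition.  Mean sitting-bout lengths are
    chosen so the expected SB-ratio (share of sedentary time in bouts under
    30 min) differs by track; covariate parameters emulate the cohort's
    demographics and body composition.
    """
    cov = {
        "Hairdresser": CovariateParams(1.0, 19.5, 2.3, 30.9, 7.2, 28.3, 2.4, 21.8, 3.7),
        "Admin": CovariateParams(16 / 24, 18.6, 2.5, 29.0, 9.9, 31.1, 7.0, 23.8, 4.0),
        "Sports": CovariateParams(13 / 34, 17.6, 0.6, 22.5, 7.3, 36.4, 6.0, 22.7, 2.3),
        "Nursing": CovariateParams(16 / 19, 22.6, 4.9, 30.7, 9.7, 30.1, 6.0, 23.4, 4.0),
    }
    hours = {
        "Hairdresser": {"sitting": 7.65, "standing": 5.14, "stepping": 1.72, "time_in_bed": 9.50},
        "Admin": {"sitting": 9.76, "standing": 3.12, "stepping": 1.78, "time_in_bed": 9.34},
        "Sports": {"sitting": 7.86, "standing": 3.94, "stepping": 2.61, "time_in_bed": 9.59},
        "Nursing": {"sitting": 9.23, "standing": 4.23, "stepping": 2.16, "time_in_bed": 8.37},
    }
    # mean sitting-bout length tunes the expected SB-ratio per track
    # (exponential bouts: share of time in bouts < 30 min = 1-e^-c(1+c), c=30/m)
    sit_bout = {"Hairdresser": 18.0, "Admin": 19.0, "Sports": 15.0, "Nursing": 18.0}
    mvpa = {"Hairdresser": 0.42, "Admin": 0.38, "Sports": 0.48, "Nursing": 0.42}
    return {
        name: TrackProfile(
            track_name=name,
            target_daily_hours=_scaled_hours(hours[name]),
            mean_bout_minutes={
                "sitting": sit_bout[name], "standing": 10.0, "stepping": 6.0,
            },
            mvpa_fraction_of_stepping=mvpa[name],
            covariate_params=cov[name],
        )
        for name in hours
    }


@dataclass(frozen=True)
class CognitiveProfile:
    """Ground truth for a simulated test-taker.

    RTs are lognormal with mean ``base_rt_ms`` (plus the shift or inhibition
    cost on the trials that demand it) and coefficient of variation
    ``rt_cv``.  Contaminant responses — anticipations under 170 ms and
    lapses over 5000 ms — are injected at the stated rates so the RT-window
    filter has something to remove.
    """

    base_rt_ms: float = 600.0
    shift_cost_ms: float = 250.0
    inhibition_cost_ms: float = 120.0
    rt_cv: float = 0.2
    error_rate: float = 0.06
    lapse_rate: float = 0.01
    guess_rate: float = 0.01
    updating_recall_prob: float = 0.75

    def __post_init__(self) -> None:
        for name in ("error_rate", "lapse_rate", "guess_rate", "updating_recall_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.lapse_rate + self.guess_rate > 1.0:
            raise ConfigurationError("lapse_rate + guess_rate must be <= 1")
        if not self.base_rt_ms > 170.0:
            raise ConfigurationError("base_rt_ms must exceed 170 ms")
        if not 0.0 < self.rt_cv < 1.0:
            raise ConfigurationError("rt_cv must lie in (0, 1)")


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(
    n_per_track: Mapping[str, int],
    profiles: Mapping[str, TrackProfile] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a participant table with track, sex, and body-composition covariates.

    Age, BMI, fat % and muscle % come from truncated normals with the track's
    parameters; fat % and muscle % are drawn jointly with a strong negative
    correlation, the realistic multicollinearity the covariate screen must
    detect.  Sex is 1 = female with the track's female proportion.
    """
    profiles = profiles if profiles is not None else default_profiles()
    for track, n in n_per_track.items():
        if track not in profiles:
            raise ConfigurationError(f"unknown track {track!r}")
        if n < 1:
            raise ConfigurationError(f"count for track {track!r} must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for track in n_per_track:  # insertion order: reproducible
        cp = profiles[track].covariate_params
        for _ in range(n_per_track[track]):
            pid += 1
            female = int(rng.random() < cp.female_proportion)
            age = _trunc_normal(rng, cp.age_mean, cp.age_sd, 16.0, 65.0)
            fat, muscle = _fat_muscle_pair(rng, cp)
            bmi = _trunc_normal(rng, cp.bmi_mean, cp.bmi_sd, 14.0, 45.0)
            rows.append(
                {
                    "participant_id": f"P{pid:04d}",
                    "track": track,
                    "female": female,
                    "age": age,
                    "fat_pct": fat,
                    "muscle_pct": muscle,
                    "bmi": bmi,
                }
            )
    return pd.DataFrame(rows)


def _trunc_normal(rng, mean, sd, lo, hi) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def _fat_muscle_pair(rng, cp: CovariateParams) -> tuple[float, float]:
    r = cp.fat_muscle_corr
    for _ in range(1000):
        z1, z2 = rng.standard_normal(2)
        fat = cp.fat_pct_mean + cp.fat_pct_sd * z1
        muscle = cp.muscle_pct_mean + cp.muscle_pct_sd * (r * z1 + np.sqrt(1 - r * r) * z2)
        if 3.0 <= fat <= 60.0 and 10.0 <= muscle <= 65.0:
            return float(fat), float(muscle)
    return cp.fat_pct_mean, cp.muscle_pct_mean


# ---------------------------------------------------------------------------
# posture-event streams


def _zero_sum_noise(rng, sds: np.ndarray) -> np.ndarray:
    """Gaussian perturbation constrained to sum to zero (keeps 24-h closure
    and leaves each class's expectation unchanged)."""
    eps = rng.standard_normal(sds.size) * sds
    var = sds**2
    tot = var.sum()
    if tot == 0:
        return np.zeros_like(sds)
    return eps - eps.sum() * var / tot


def sample_daily_hours(
    profile: TrackProfile, n_days: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw an ``(n_days, 4)`` matrix of daily hours per activity class.

    Rows sum to exactly 24.  A participant-level offset (between-participant
    SD) is shared by all days; independent day-level offsets are added on
    top.  Both offsets are zero-sum across classes, so class means stay on
    the profile targets.  Negative candidates are redrawn.
    """
    target = np.array([profile.target_daily_hours[c] for c in ACTIVITY_CLASSES])
    bsd = np.array([profile.between_sd_hours[c] for c in ACTIVITY_CLASSES])
    dsd = np.array([profile.day_sd_hours[c] for c in ACTIVITY_CLASSES])

    def ok(v: np.ndarray) -> bool:
        # positivity required only where the profile puts mass; in-bed must
        # leave waking time
        return bool(np.all(v >= 0.0) and np.all(v[target > 0] > 0.05) and v[3] < 23.0)

    person = target
    for _ in range(200):
        cand = target + _zero_sum_noise(rng, bsd)
        if ok(cand):
            person = cand
            break
    days = np.empty((n_days, 4))
    for d in range(n_days):
        day = person
        for _ in range(200):
            cand = person + _zero_sum_noise(rng, dsd)
            if ok(cand):
                day = cand
                break
        days[d] = day
    return days


def generate_event_stream(
    profile: TrackProfile,
    n_days: int,
    seed: int | np.random.Generator = 0,
    participant_id: str = "P0001",
    start: pd.Timestamp = DEFAULT_START,
) -> pd.DataFrame:
    """Simulate a gapless ``n_days``-long posture-event stream.

    Returns a DataFrame with columns ``participant_id, start, duration_s,
    activity, steps`` whose events are sorted, contiguous, and span exactly
    ``n_days`` x 24 h from ``start`` (midnight).  Each day holds one nightly
    in-bed episode straddling midnight (the stream opens and closes with the
    partial halves); waking time is tiled with alternating sitting /
    standing / stepping episodes whose durations are exponential draws
    rescaled so class totals match the day's sampled hour vector.  Stepping
    episodes carry step counts: a share ``mvpa_fraction_of_stepping`` of
    them at cadence >= 100 steps/min, the rest below.
    """
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    hours = sample_daily_hours(profile, n_days, rng)
    # split each day's in-bed total into a morning part (tail of the previous
    # night) and an evening part (head of tonight's episode)
    phi = np.clip(rng.normal(0.88, 0.04, n_days), 0.7, 0.97)
    morning_h = phi * hours[:, 3]
    evening_h = hours[:, 3] - morning_h

    starts: list[float] = []   # seconds from stream origin
    durs: list[float] = []
    acts: list[str] = []
    steps: list[int] = []

    def emit(t0: float, dur_s: float, activity: str, n_steps: int = 0) -> None:
        # drop sub-microsecond residuals from float arithmetic; the stream
        # contiguity tolerance absorbs them
        if dur_s < 1e-6:
            return
        starts.append(t0)
        durs.append(dur_s)
        acts.append(activity)
        steps.append(n_steps)

    mean_bout_s = {c: profile.mean_bout_minutes[c] * 60.0 for c in WAKING_CLASSES}
    t = 0.0
    for d in range(n_days):
        day_start = d * 86400.0
        emit(t, day_start + morning_h[d] * 3600.0 - t, "time_in_bed")
        t = day_start + morning_h[d] * 3600.0
        waking_s = (24.0 - hours[d, 3]) * 3600.0
        cls_tot = {c: hours[d, i] * 3600.0 for i, c in enumerate(WAKING_CLASSES)}
        episodes = _tile_waking(rng, cls_tot, mean_bout_s)
        for activity, dur_s in episodes:
            n_steps = 0
            if activity == "stepping":
                if rng.random() < profile.mvpa_fraction_of_stepping:
                    cadence = rng.uniform(105.0, 125.0)
                else:
                    cadence = rng.uniform(70.0, 95.0)
                n_steps = max(1, int(round(cadence * dur_s / 60.0)))
            emit(t, dur_s, activity, n_steps)
            t += dur_s
        # tonight's in-bed: evening part plus next day's morning part
        next_morning = morning_h[d + 1] * 3600.0 if d + 1 < n_days else 0.0
        night = evening_h[d] * 3600.0 + next_morning
        end = n_days * 86400.0
        emit(t, min(night, end - t), "time_in_bed")
        t = min(t + night, end)

    df = pd.DataFrame(
        {
            "participant_id": participant_id,
            "start": start + pd.to_timedelta(np.array(starts), unit="s"),
            "duration_s": np.array(durs),
            "activity": acts,
            "steps": np.array(steps, dtype=np.int64),
        }
    )
    # exact closure: nudge the final event so the span is n_days * 24 h
    total = df["duration_s"].sum()
    df.loc[df.index[-1], "duration_s"] += n_days * 86400.0 - total
    return df


def _tile_waking(
    rng: np.random.Generator,
    class_totals_s: Mapping[str, float],
    mean_bout_s: Mapping[str, float],
) -> list[tuple[str, float]]:
    """Fill a waking period with alternating episodes hitting exact totals."""
    per_class: dict[str, np.ndarray] = {}
    for c in WAKING_CLASSES:
        total = class_totals_s[c]
        if total <= 0:
            continue
        k = max(1, int(round(total / mean_bout_s[c])))
        raw = rng.exponential(mean_bout_s[c], size=k)
        raw = np.maximum(raw, 1.0)
        per_class[c] = raw * (total / raw.sum())
    order: list[str] = []
    remaining = {c: len(v) for c, v in per_class.items()}
    n_left = sum(remaining.values())
    uniforms = iter(rng.random(2 * n_left + 8))
    prev = None
    while n_left:
        choices = [c for c, r in remaining.items() if r > 0 and c != prev]
        if not choices:  # only the previous class left: allow a repeat
            choices = [c for c, r in remaining.items() if r > 0]
        # draw proportional to remaining episode counts, without numpy overhead
        total_w = sum(remaining[c] for c in choices)
        try:
            u = next(uniforms) * total_w
        except StopIteration:
            uniforms = iter(rng.random(2 * n_left + 8))
            u = next(uniforms) * total_w
        acc = 0.0
        c = choices[-1]
        for cand in choices:
            acc += remaining[cand]
            if u < acc:
                c = cand
                break
        order.append(c)
        remaining[c] -= 1
        n_left -= 1
        prev = c
    idx = {c: 0 for c in per_class}
    out = []
    for c in order:
        out.append((c, float(per_class[c][idx[c]])))
        idx[c] += 1
    return out


def generate_cohort_streams(
    cohort: pd.DataFrame,
    profiles: Mapping[str, TrackProfile] | None = None,
    n_days: int = 7,
    seed: int = 0,
    start: pd.Timestamp = DEFAULT_START,
) -> pd.DataFrame:
    """Event streams for every cohort row, concatenated into one table."""
    profiles = profiles if profiles is not None else default_profiles()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cohort))
    frames = []
    for (_, row), child in zip(cohort.iterrows(), children):
        rng = np.random.default_rng(child)
        frames.append(
            generate_event_stream(
                profiles[row["track"]], n_days, rng,
                participant_id=row["participant_id"], start=start,
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# color-shape test sessions

CST_ROUND_TASKS = {1: "shape", 2: "color", 3: None, 4: "shape", 5: "color"}
CST_PRACTICE_PER_ROUND = 16
CST_TEST_PER_ROUND = 64


def generate_cst_session(
    profile: CognitiveProfile,
    seed: int | np.random.Generator = 0,
    participant_id: str = "P0001",
) -> pd.DataFrame:
    """Simulate one color-shape session: 5 rounds x (16 practice + 64 test).

    Round 3 mixes the shape and color tasks at random; a test trial is a
    shift trial iff its task differs from the previous test trial's (the
    round's first test trial has no predecessor and counts as non-shift).
    Rounds 4-5 present bivalent stimuli, congruent with probability 0.5.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma2 = np.log1p(profile.rt_cv**2)
    sigma = np.sqrt(sigma2)
    frames = []
    for rnd in range(1, 6):
        for phase, n in (("practice", CST_PRACTICE_PER_ROUND), ("test", CST_TEST_PER_ROUND)):
            fixed = CST_ROUND_TASKS[rnd]
            if fixed is None:
                is_shape = rng.random(n) < 0.5
                task = np.where(is_shape, "shape", "color")
            else:
                task = np.full(n, fixed)
            is_shift = np.zeros(n, dtype=bool)
            if rnd == 3:
                is_shift[1:] = task[1:] != task[:-1]
            is_congruent = np.zeros(n, dtype=bool)
            if rnd in (4, 5):
                is_congruent = rng.random(n) < 0.5
            mean_rt = np.full(n, profile.base_rt_ms)
            if rnd == 3:
                mean_rt[is_shift] += profile.shift_cost_ms
            if rnd in (4, 5):
                mean_rt[~is_congruent] += profile.inhibition_cost_ms
            mu = np.log(mean_rt) - sigma2 / 2.0
            rt = np.exp(mu + sigma * rng.standard_normal(n))
            u = rng.random(n)
            guess = u < profile.guess_rate
            lapse = (~guess) & (u < profile.guess_rate + profile.lapse_rate)
            rt[guess] = rng.uniform(50.0, 169.9, int(guess.sum()))
            rt[lapse] = rng.uniform(5000.1, 9000.0, int(lapse.sum()))
            correct = rng.random(n) >= profile.error_rate
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": participant_id,
                        "round": rnd,
                        "phase": phase,
                        "index": np.arange(n),
                        "task": task,
                        "is_shift": is_shift,
                        "is_congruent": is_congruent,
                        "rt_ms": rt,
                        "correct": correct,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# letter-memory test sessions

LMT_SERIES_LENGTHS = (5, 7, 9)
LMT_TRIALS_PER_LENGTH = 4


def generate_lmt_session(
    profile: CognitiveProfile,
    seed: int | np.random.Generator = 0,
    participant_id: str = "P0001",
) -> pd.DataFrame:
    """Simulate one letter-memory session: 12 test trials, lengths 5/7/9 x4.

    Each of the three target letters (the last three presented) is recalled
    correctly with probability ``updating_recall_prob``; otherwise the
    response is "Blank" or a consonant outside the target multiset, so a
    miss can never score.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = np.repeat(LMT_SERIES_LENGTHS, LMT_TRIALS_PER_LENGTH)
    rng.shuffle(lengths)
    rows = []
    for i, length in enumerate(lengths):
        presented = [CONSONANTS[j] for j in rng.integers(0, len(CONSONANTS), int(length))]
        target = presented[-3:]
        recalled = []
        for letter in target:
            if rng.random() < profile.updating_recall_prob:
                recalled.append(letter)
            elif rng.random() < 0.5:
                recalled.append("Blank")
            else:
                wrong = [c for c in CONSONANTS if c not in target]
                recalled.append(wrong[rng.integers(0, len(wrong))])
        rows.append(
            {
                "participant_id": participant_id,
                "index": i,
                "series_length": int(length),
                "presented": "".join(presented),
                "recalled_1": recalled[0],
                "recalled_2": recalled[1],
                "recalled_3": recalled[2],
            }
        )
    return pd.DataFrame(rows)


def generate_cohort_sessions(
    cohort: pd.DataFrame,
    profile: CognitiveProfile | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CST and LMT sessions for every cohort row (one shared profile)."""
    profile = profile if profile is not None else CognitiveProfile()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cohort))
    cst_frames, lmt_frames = [], []
    for (_, row), child in zip(cohort.iterrows(), children):
        rng = np.random.default_rng(child)
        pid = row["participant_id"]
        cst_frames.append(generate_cst_session(profile, rng, participant_id=pid))
        lmt_frames.append(generate_lmt_session(profile, rng, participant_id=pid))
    return pd.concat(cst_frames, ignore_index=True), pd.concat(lmt_frames, ignore_index=True)


# ---------------------------------------------------------------------------
# serialization

EVENT_CSV_COLUMNS = ["participant_id", "start", "duration_s", "activity", "steps"]


def write_events_csv(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["start"] = pd.to_datetime(out["start"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    out[EVENT_CSV_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "activity": str})
    df["start"] = pd.to_datetime(df["start"])
    df["steps"] = df["steps"].astype(np.int64)
    return df


def profiles_from_config(path) -> dict[str, TrackProfile]:
    """Load track profiles from a JSON/YAML config file.

    Schema: a mapping ``track name -> {target_daily_hours, mean_bout_minutes,
    mvpa_fraction_of_stepping, covariate_params, [between_sd_hours],
    [day_sd_hours]}`` mirroring the dataclass fields.
    """
    text = open(path).read()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    out = {}
    for name, cfg in raw.items():
        kwargs = dict(cfg)
        kwargs["covariate_params"] = CovariateParams(**kwargs["covariate_params"])
        out[name] = TrackProfile(track_name=name, **kwargs)
    return out
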