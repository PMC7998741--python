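"""Executive-function scoring: letter-memory updating and color-shape costs.

Two tasks are scored.  The letter-memory test (LMT) probes working-memory
updating: each trial presents 5, 7 or 9 consonants one at a time and asks
for the last three, in any order; the score is the total number of correctly
recalled letters over 12 trials (0-36).

The color-shape test (CST) has five rounds of 64 test trials each: two pure
single-task rounds (shape, color), a mixed round in which the task switches
unpredictably (shifting), and two rounds with bivalent stimuli where the
irrelevant dimension may conflict (inhibition).  Shifting cost is the mean
correct RT on switch trials of round 3 minus the pooled mean correct RT of
rounds 1-2; inhibition cost is the same baseline subtracted from the pooled
mean on incongruent trials of rounds 4-5.

RTs pass a fixed filter chain before averaging, applied in this order:

1. chance filter — a participant with any round at ≤32/64 correct test
   trials is excluded entirely;
2. round-3 trials that demand no switch (two consecutive same-task trials,
   and the round's first trial) are dropped;
3. congruent trials of rounds 4-5 are dropped;
4. RTs below 170 ms or above 5000 ms are dropped (strict inequalities:
   exactly 170 or 5000 ms is retained);
5. incorrect trials are dropped (costs use correct RTs only);
6. intrapersonal outliers — per round, trials outside the mean ± 3 SD of
   that round's remaining trials — are dropped in a single pass.

Every removal is tallied in an exclusion log so that
``|input| = |survivors| + Σ removals`` per rule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthdata import CONSONANTS, CST_TEST_PER_ROUND

RT_LOW_MS = 170.0
RT_HIGH_MS = 5000.0
SD_MULTIPLIER = 3.0
CHANCE_MAX_CORRECT = 32  # ≤ this many correct of 64 → excluded by chance filter
LMT_MAX_SCORE = 36

FILTER_RULES = (
    "chance_excluded",
    "nonshift_excluded",
    "congruent_excluded",
    "rt_window_excluded",
    "incorrect_excluded",
    "sd_outlier_excluded",
)


class SessionValidationError(ValueError):
    pass


@dataclass
class CognitiveScores:
    participant_id: str
    updating_accuracy: float  # 0-36, NaN when missing
    shifting_cost_ms: float  # NaN when missing
    inhibition_cost_ms: float
    exclusion_log: dict[str, int] = field(default_factory=dict)
    missing_reasons: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# letter-memory test


def score_lmt(trials: pd.DataFrame | Sequence[Mapping]) -> float:
    """Total correctly recalled letters over the session, order-free.

    Per trial the score is the multiset intersection between the recalled
    entries and the target (the last three presented letters), so a repeated
    target letter must be recalled twice to count twice.  "Blank" and
    missing entries score 0; a trial with no response contributes 0.
    """
    df = trials if isinstance(trials, pd.DataFrame) else pd.DataFrame(list(trials))
    if len(df) > 12:
        raise SessionValidationError(f"expected at most 12 test trials, got {len(df)}")
    total = 0
    for _, row in df.iterrows():
        presented = str(row["presented"])
        target = Counter(presented[-3:])
        recalled = []
        for col in ("recalled_1", "recalled_2", "recalled_3"):
            v = row.get(col)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            v = str(v)
            if v == "Blank" or v == "":
                continue
            if len(v) != 1 or v.upper() not in CONSONANTS + tuple("AEIOUY"):
                raise SessionValidationError(f"recalled entry {v!r} is not a letter or Blank")
            recalled.append(v.upper())
        total += sum((Counter(recalled) & target).values())
    return float(total)


# ---------------------------------------------------------------------------
# color-shape test filter chain


def filter_cst(
    trials: pd.DataFrame,
    rt_low_ms: float = RT_LOW_MS,
    rt_high_ms: float = RT_HIGH_MS,
    sd_multiplier: float = SD_MULTIPLIER,
    sd_pooled_rounds: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the filter chain to one participant's session.

    Returns the surviving test trials and a per-rule exclusion log.  When
    the chance filter trips, the survivors are empty and the log charges all
    test trials to ``chance_excluded``.  ``sd_pooled_rounds=True`` computes
    the ±3 SD window from all remaining trials pooled instead of per round.
    """
    test = trials[trials["phase"] == "test"].copy()
    counts = test.groupby("round").size()
    if set(counts.index) != {1, 2, 3, 4, 5} or (counts != CST_TEST_PER_ROUND).any():
        raise SessionValidationError(
            f"expected 64 test trials in each of rounds 1-5, got {counts.to_dict()}"
        )
    log = {rule: 0 for rule in FILTER_RULES}

    correct_per_round = test.groupby("round")["correct"].sum()
    if (correct_per_round <= CHANCE_MAX_CORRECT).any():
        log["chance_excluded"] = len(test)
        return test.iloc[0:0], log

    keep = np.ones(len(test), dtype=bool)
    rnd = test["round"].to_numpy()
    rt = test["rt_ms"].to_numpy(dtype=float)
    correct = test["correct"].to_numpy(dtype=bool)

    m = keep & (rnd == 3) & ~test["is_shift"].to_numpy(dtype=bool)
    log["nonshift_excluded"] = int(m.sum())
    keep &= ~m

    m = keep & np.isin(rnd, (4, 5)) & test["is_congruent"].to_numpy(dtype=bool)
    log["congruent_excluded"] = int(m.sum())
    keep &= ~m

    m = keep & ((rt < rt_low_ms) | (rt > rt_high_ms))
    log["rt_window_excluded"] = int(m.sum())
    keep &= ~m

    m = keep & ~correct
    log["incorrect_excluded"] = int(m.sum())
    keep &= ~m

    # single-pass intrapersonal outlier filter on the remaining trials
    out = np.zeros(len(test), dtype=bool)
    if sd_pooled_rounds:
        groups: Iterable[np.ndarray] = [keep]
    else:
        groups = [keep & (rnd == r) for r in (1, 2, 3, 4, 5)]
    for g in groups:
        if g.sum() == 0:
            continue
        mu = rt[g].mean()
        sd = rt[g].std(ddof=1) if g.sum() > 1 else 0.0
        out |= g & ((rt < mu - sd_multiplier * sd) | (rt > mu + sd_multiplier * sd))
    log["sd_outlier_excluded"] = int(out.sum())
    keep &= ~out

    return test[keep], log


def shifting_cost(filtered: pd.DataFrame) -> float:
    """Mean RT on surviving round-3 switch trials minus the pooled mean RT
    of surviving rounds 1-2.  NaN when either set is empty."""
    baseline = filtered[filtered["round"].isin((1, 2))]["rt_ms"]
    shift = filtered[(filtered["round"] == 3) & filtered["is_shift"]]["rt_ms"]
    if baseline.empty or shift.empty:
        return float("nan")
    return float(shift.mean() - baseline.mean())


def inhibition_cost(filtered: pd.DataFrame) -> float:
    """Mean RT on surviving incongruent trials of rounds 4-5 minus the
    pooled mean RT of surviving rounds 1-2.  NaN when either set is empty."""
    baseline = filtered[filtered["round"].isin((1, 2))]["rt_ms"]
    incong = filtered[filtered["round"].isin((4, 5)) & ~filtered["is_congruent"]]["rt_ms"]
    if baseline.empty or incong.empty:
        return float("nan")
    return float(incong.mean() - baseline.mean())


def baseline_cost_components(
    filtered: pd.DataFrame, baseline_mean_of_rounds: bool = False
) -> float:
    """Rounds-1-2 baseline: pooled mean by default; optionally the mean of
    the two round means (configuration alternative)."""
    baseline = filtered[filtered["round"].isin((1, 2))]
    if baseline.empty:
        return float("nan")
    if baseline_mean_of_rounds:
        return float(baseline.groupby("round")["rt_ms"].mean().mean())
    return float(baseline["rt_ms"].mean())


def score_cst(
    trials: pd.DataFrame,
    participant_id: str = "",
    **filter_kwargs,
) -> CognitiveScores:
    """Filter one session and compute both costs with missing-value reasons."""
    if not participant_id and "participant_id" in trials.columns and len(trials):
        participant_id = str(trials["participant_id"].iat[0])
    filtered, log = filter_cst(trials, **filter_kwargs)
    reasons: dict[str, str] = {}
    if log["chance_excluded"]:
        reasons["shifting_cost_ms"] = reasons["inhibition_cost_ms"] = (
            "participant excluded: a round at or below 32/64 correct"
        )
        return CognitiveScores(participant_id, float("nan"), float("nan"), float("nan"), log, reasons)
    s = shifting_cost(filtered)
    i = inhibition_cost(filtered)
    if np.isnan(s):
        reasons["shifting_cost_ms"] = "no surviving baseline or shift trials"
    if np.isnan(i):
        reasons["inhibition_cost_ms"] = "no surviving baseline or incongruent trials"
    return CognitiveScores(participant_id, float("nan"), s, i, log, reasons)


def score_sessions(
    cst: pd.DataFrame,
    lmt: pd.DataFrame,
    **filter_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every participant's CST and LMT; return (scores, exclusion log).

    The scores table has one row per participant with ``updating_accuracy``,
    ``shifting_cost_ms``, ``inhibition_cost_ms``; the log table one row per
    participant with per-rule removal counts.
    """
    rows, logs = [], []
    lmt_by_pid = dict(tuple(lmt.groupby("participant_id"))) if len(lmt) else {}
    for pid, g in cst.groupby("participant_id", sort=True):
        sc = score_cst(g.reset_index(drop=True), str(pid), **filter_kwargs)
        # the chance filter is a CST rule; the letter-memory score stands on
        # its own session
        if str(pid) in lmt_by_pid:
            sc.updating_accuracy = score_lmt(lmt_by_pid[str(pid)])
        rows.append(
            {
                "participant_id": sc.participant_id,
                "updating_accuracy": sc.updating_accuracy,
                "shifting_cost_ms": sc.shifting_cost_ms,
                "inhibition_cost_ms": sc.inhibition_cost_ms,
            }
        )
        logs.append({"participant_id": sc.participant_id, **sc.exclusion_log})
    return pd.DataFrame(rows), pd.DataFrame(logs)
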