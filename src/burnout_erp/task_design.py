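"""Executive reaction-time (Go/NoGo) task: trial sequences and error taxonomy.

The task presents, per trial, a triangle (up/down), a fixation cross, and a
traffic light (green/red) carrying a task-irrelevant distractor (emotional
spider / neutral flower drawing).  A block-level rule maps one light colour to
"Go"; on Go trials the subject presses the button matching the triangle
orientation, on NoGo trials any press is an error.  The rule colour reverses
between consecutive blocks.

A session is four practice blocks followed by four test blocks; practice
blocks are excluded from analysis.  Each 64-trial block fully crosses
condition (Go/NoGo) with distractor valence, 16 trials per cell.

Trial-level timing convention: time 0 is trial onset (triangle onset); the
traffic light -- the Go/NoGo signal -- appears at ``LIGHT_ONSET_MS``.
Reaction times are measured from light onset (the earliest moment the
Go/NoGo decision is possible); raw onset timestamps are retained so the
convention can be switched.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: traffic-light (Go/NoGo signal) onset relative to trial onset, ms
#: (150 ms triangle + 150 ms fixation cross).
LIGHT_ONSET_MS = 300.0

TRIALS_PER_BLOCK = 64
_CELLS_PER_COMBO = 16  # condition x distractor cell size


class Condition(str, enum.Enum):
    GO = "Go"
    NOGO = "NoGo"


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the Executive RT test."""

    block_index: int                # 1-based over the whole session
    is_practice: bool
    trial_index_in_block: int       # 1..64
    triangle: str                   # "up" | "down"
    light: str                      # "green" | "red"
    go_rule_color: str              # the block's Go colour
    distractor: str                 # "emotional" | "neutral"
    stimulator: str                 # "ON" | "OFF" (metadata only)

    @property
    def condition(self) -> str:
        return Condition.GO.value if self.light == self.go_rule_color else Condition.NOGO.value

    @property
    def is_go(self) -> bool:
        return self.condition == Condition.GO.value


@dataclass(frozen=True)
class ResponseRecord:
    """Behavioural response to one trial.

    ``rt_ms`` is measured from traffic-light onset and is present iff a
    button was pressed.
    """

    pressed: bool
    button: str = "none"            # "up" | "down" | "none"
    rt_ms: float | None = None

    def __post_init__(self):
        if self.pressed and (self.button == "none" or self.rt_ms is None):
            raise ValueError("pressed response requires a button and an RT")
        if not self.pressed and (self.button != "none" or self.rt_ms is not None):
            raise ValueError("non-response must have button='none' and no RT")


@dataclass(frozen=True)
class TrialOutcome:
    """The four dichotomisations of one trial used by the error models.

    ``class_total``      : correct | error
    ``class_incorrect``  : incorrect | other        (wrong button on a Go trial)
    ``class_miss``       : miss | other             (no press on a Go trial)
    ``class_commission`` : commission_error | correct | not_applicable
                           (any press on a NoGo trial; n/a on Go trials)
    """

    trial: TrialSpec
    response: ResponseRecord
    class_total: str
    class_incorrect: str
    class_miss: str
    class_commission: str

    @property
    def primary_class(self) -> str:
        """The single class describing the trial: correct/incorrect/miss/commission."""
        if self.class_commission == "commission_error":
            return "commission"
        if self.class_incorrect == "incorrect":
            return "incorrect"
        if self.class_miss == "miss":
            return "miss"
        return "correct"


@dataclass
class BehaviorSummary:
    """Across-trial behavioural summary (medians/IQRs, error percentages)."""

    n_trials: int
    n_go: int
    n_nogo: int
    median_rt_ms: float
    iqr_rt_ms: float
    pct_total_errors: float       # % of all trials
    pct_incorrect: float          # % of Go trials
    pct_missing: float            # % of Go trials
    pct_commission: float         # % of NoGo trials


def generate_block(rng: np.random.Generator, block_index: int, is_practice: bool,
                   go_rule_color: str, stimulator: str) -> list[TrialSpec]:
    """One 64-trial block: full condition x distractor crossing, shuffled."""
    nogo_color = "red" if go_rule_color == "green" else "green"
    cells: list[tuple[str, str]] = []
    for light in (go_rule_color, nogo_color):
        for distractor in ("emotional", "neutral"):
            cells.extend([(light, distractor)] * _CELLS_PER_COMBO)
    order = rng.permutation(len(cells))
    triangles = rng.choice(["up", "down"], size=len(cells))
    trials = []
    for pos, idx in enumerate(order, start=1):
        light, distractor = cells[idx]
        trials.append(TrialSpec(
            block_index=block_index,
            is_practice=is_practice,
            trial_index_in_block=pos,
            triangle=str(triangles[pos - 1]),
            light=light,
            go_rule_color=go_rule_color,
            distractor=distractor,
            stimulator=stimulator,
        ))
    return trials


def generate_session(seed: int | np.random.Generator, n_practice: int = 4,
                     n_test: int = 4) -> list[TrialSpec]:
    """Full session: ``n_practice`` practice blocks then ``n_test`` test blocks.

    The Go-rule colour alternates between consecutive blocks, starting from a
    seeded random choice.  The stimulator flag (metadata only; ON/OFF are
    averaged in every analysis) alternates ON/OFF by block half.
    """
    if n_practice < 0 or n_test < 0:
        raise ValueError("block counts must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    first_color = str(rng.choice(["green", "red"]))
    n_blocks = n_practice + n_test
    trials: list[TrialSpec] = []
    for b in range(n_blocks):
        color = first_color if b % 2 == 0 else ("red" if first_color == "green" else "green")
        stim = "ON" if (b % n_blocks) < n_blocks / 2 else "OFF"
        if n_blocks == 1:
            stim = "ON"
        trials.extend(generate_block(rng, block_index=b + 1,
                                     is_practice=b < n_practice,
                                     go_rule_color=color, stimulator=stim))
    return trials


def classify_response(trial: TrialSpec, response: ResponseRecord) -> TrialOutcome:
    """Classify one (trial, response) pair into the four error dichotomies."""
    if trial.is_go:
        correct_button = trial.triangle  # "up" triangle -> "up" button
        if not response.pressed:
            total, inc, miss = "error", "other", "miss"
        elif response.button == correct_button:
            total, inc, miss = "correct", "other", "other"
        else:
            total, inc, miss = "error", "incorrect", "other"
        commission = "not_applicable"
    else:
        if response.pressed:
            total, commission = "error", "commission_error"
        else:
            total, commission = "correct", "correct"
        inc, miss = "other", "other"
    return TrialOutcome(trial=trial, response=response, class_total=total,
                        class_incorrect=inc, class_miss=miss,
                        class_commission=commission)


def summarize_behavior(outcomes: Sequence[TrialOutcome],
                       practice_excluded: bool = True) -> BehaviorSummary:
    """Summarise a subject's outcomes: median/IQR RT over correct Go trials and
    error percentages.

    Denominators: incorrect and missing are % of Go trials, commission is % of
    NoGo trials, total is % of all trials.
    """
    if practice_excluded:
        outcomes = [o for o in outcomes if not o.trial.is_practice]
    if not outcomes:
        raise ValueError("no outcomes left after practice exclusion")
    go = [o for o in outcomes if o.trial.is_go]
    nogo = [o for o in outcomes if not o.trial.is_go]
    rts = np.array([o.response.rt_ms for o in go
                    if o.class_total == "correct" and o.response.pressed], float)
    if rts.size:
        q25, med, q75 = np.percentile(rts, [25, 50, 75])
    else:
        med = q25 = q75 = np.nan
    n, n_go, n_nogo = len(outcomes), len(go), len(nogo)
    n_err = sum(o.class_total == "error" for o in outcomes)
    n_inc = sum(o.class_incorrect == "incorrect" for o in go)
    n_miss = sum(o.class_miss == "miss" for o in go)
    n_comm = sum(o.class_commission == "commission_error" for o in nogo)
    pct = lambda k, d: 100.0 * k / d if d else np.nan
    return BehaviorSummary(
        n_trials=n, n_go=n_go, n_nogo=n_nogo,
        median_rt_ms=float(med), iqr_rt_ms=float(q75 - q25),
        pct_total_errors=pct(n_err, n),
        pct_incorrect=pct(n_inc, n_go),
        pct_missing=pct(n_miss, n_go),
        pct_commission=pct(n_comm, n_nogo),
    )


def trials_to_frame(trials: Iterable[TrialSpec]) -> pd.DataFrame:
    """Tabulate trials, one row per trial."""
    rows = [{
        "block_index": t.block_index, "is_practice": t.is_practice,
        "trial_index_in_block": t.trial_index_in_block, "triangle": t.triangle,
        "light": t.light, "go_rule_color": t.go_rule_color,
        "condition": t.condition, "distractor": t.distractor,
        "stimulator": t.stimulator,
    } for t in trials]
    return pd.DataFrame(rows)


def outcomes_to_frame(outcomes: Iterable[TrialOutcome]) -> pd.DataFrame:
    """Tabulate outcomes with their trial context and dichotomisations."""
    rows = []
    for o in outcomes:
        t = o.trial
        rows.append({
            "block_index": t.block_index, "is_practice": t.is_practice,
            "trial_index_in_block": t.trial_index_in_block,
            "condition": t.condition, "distractor": t.distractor,
            "stimulator": t.stimulator, "pressed": o.response.pressed,
            "button": o.response.button, "rt_ms": o.response.rt_ms,
            "class_total": o.class_total, "class_incorrect": o.class_incorrect,
            "class_miss": o.class_miss, "class_commission": o.class_commission,
            "primary_class": o.primary_class,
        })
    return pd.DataFrame(rows)
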