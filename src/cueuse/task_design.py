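"""Trial schedules and reward rule for the cueing task.

The main task crosses spatial certainty (directional cue valid p = .8,
invalid p = .2, bidirectional/neutral p = .5) with four incentive-value
configurations. Each of 2 blocks holds 360 trials: 200 directional
(160 valid / 40 invalid) and 160 bidirectional, every cue-validity
condition equally divided over the four value configurations and target
side counterbalanced. Reward on correct trials is a base amount plus a
bonus proportional to how early in a 350-850 ms window the response lands.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Literal

import numpy as np
import pandas as pd

from .encoding_models import VALUE_LABELS

__all__ = [
    "SCHEDULE_COLUMNS",
    "RewardRule",
    "build_learning_schedules",
    "build_main_schedule",
    "compute_reward",
]

#: Column order of every schedule table the package emits.
SCHEDULE_COLUMNS = [
    "subject",
    "phase",
    "block",
    "sub_block",
    "trial",
    "spatial_cue",
    "cue_valid",
    "p_tgt",
    "value_config",
    "target_side",
    "target_tilt",
    "distractor_orientation",
]

# Cue-validity cells per 360-trial main block: label, p(target|cue), count.
_MAIN_CELLS = [("valid", 0.8, 160), ("invalid", 0.2, 40), ("neutral", 0.5, 160)]


@dataclass(frozen=True)
class RewardRule:
    """RT-proportional reward: base plus a bonus scaled within an RT window.

    High-value trials pay 50 base + up to 50 bonus points, low-value trials
    5 + 5; responses at or before 350 ms earn the full bonus, at or after
    850 ms none, linear in between. Reward is attainable on a p = .8
    lottery of trials.
    """

    base_high: float = 50.0
    base_low: float = 5.0
    bonus_high: float = 50.0
    bonus_low: float = 5.0
    rt_window: tuple[float, float] = (350.0, 850.0)
    availability_p: float = 0.8

    def __post_init__(self) -> None:
        if not self.rt_window[0] < self.rt_window[1]:
            raise ValueError("rt_window lower bound must be below upper bound")
        if not 0.0 <= self.availability_p <= 1.0:
            raise ValueError("availability_p must be in [0, 1]")


def compute_reward(
    rt_ms: float,
    correct: bool,
    value_level: Literal["high", "low"],
    available: bool,
    rule: RewardRule = RewardRule(),
) -> float:
    """Points earned on one trial under the RT-proportional reward rule."""
    if rt_ms <= 0:
        raise ValueError(f"rt_ms must be positive, got {rt_ms}")
    if value_level not in ("high", "low"):
        raise ValueError(f"unknown value level {value_level!r}")
    if not correct or not available:
        return 0.0
    lo, hi = rule.rt_window
    frac = float(np.clip((hi - rt_ms) / (hi - lo), 0.0, 1.0))
    if value_level == "high":
        return rule.base_high + rule.bonus_high * frac
    return rule.base_low + rule.bonus_low * frac


def _counterbalanced_cell(
    n: int, validity: str, p_tgt: float, value_config: str
) -> list[dict]:
    """One cue-validity x value cell with target side and gabor attributes
    counterbalanced (n must be divisible by 4 for a full crossing, which
    every cell of the fixed design is)."""
    specs = []
    # interleave sides so any even n splits target side equally
    attrs = [
        (side, tilt, ori)
        for tilt, ori in product(("cw", "ccw"), ("vertical", "horizontal"))
        for side in ("left", "right")
    ]
    reps, rem = divmod(n, len(attrs))
    seq = attrs * reps + attrs[:rem]
    for target_side, tilt, dst_ori in seq:
        if validity == "neutral":
            spatial_cue = "bidirectional"
        elif validity == "valid":
            spatial_cue = target_side
        else:  # invalid: cue points away from the target
            spatial_cue = "right" if target_side == "left" else "left"
        specs.append(
            dict(
                spatial_cue=spatial_cue,
                cue_valid=(validity == "valid") if validity != "neutral" else pd.NA,
                p_tgt=p_tgt,
                value_config=value_config,
                target_side=target_side,
                target_tilt=tilt,
                distractor_orientation=dst_ori,
            )
        )
    return specs


def build_main_schedule(
    seed: int | np.random.Generator,
    subject: int = 0,
    n_blocks: int = 2,
    trials_per_sub_block: int = 20,
) -> pd.DataFrame:
    """Pseudorandomised main-task schedule: 720 trials over 2 blocks.

    Per block, each cue-validity condition's trials are split equally over
    the four value configurations (valid 160 -> 40 each, invalid 40 -> 10
    each, neutral 160 -> 40 each), and the order is a seeded uniform
    permutation within block.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows: list[dict] = []
    for block in range(n_blocks):
        block_rows: list[dict] = []
        for validity, p_tgt, count in _MAIN_CELLS:
            per_config, rem = divmod(count, len(VALUE_LABELS))
            if rem:
                raise ValueError("cue-condition count not divisible by value configs")
            for label in VALUE_LABELS:
                block_rows.extend(
                    _counterbalanced_cell(per_config, validity, p_tgt, label)
                )
        for row in (block_rows[i] for i in rng.permutation(len(block_rows))):
            row.update(subject=subject, phase="main", block=block, trial=0)
            rows.append(row)
    df = pd.DataFrame(rows)
    overall = np.arange(len(df))
    df["sub_block"] = overall // trials_per_sub_block
    df["trial"] = overall
    return df[SCHEDULE_COLUMNS]


def build_learning_schedules(
    seed: int | np.random.Generator, subject: int = 0
) -> pd.DataFrame:
    """Spatial- and value-learning schedules.

    Spatial phase: one 32-trial bidirectional block (16 target-left) and
    two 40-trial directional blocks (32 valid / 8 invalid; one left-cue,
    one right-cue block). Value phase: 16 trials per value cue with the
    target always at the cued (coloured) location.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows: list[dict] = []

    def add_block(phase: str, block: int, specs: list[dict]) -> None:
        order = rng.permutation(len(specs))
        for i, idx in enumerate(order):
            row = dict(specs[idx])
            row.update(subject=subject, phase=phase, block=block, trial=i, sub_block=block)
            rows.append(row)

    specs = _counterbalanced_cell(32, "neutral", 0.5, "hT/hD")
    add_block("spatial_learning", 0, specs)
    for block, cue_side in ((1, "left"), (2, "right")):
        specs = []
        for target_side_matches, n in ((True, 32), (False, 8)):
            target = cue_side if target_side_matches else ("right" if cue_side == "left" else "left")
            sub = _counterbalanced_cell(n, "valid" if target_side_matches else "invalid", 0.8, "hT/hD")
            for s in sub:
                s["spatial_cue"] = cue_side
                s["target_side"] = target
                s["p_tgt"] = 0.8 if target_side_matches else 0.2
            specs.extend(sub)
        add_block("spatial_learning", block, specs)

    for block, config in ((0, "hT/lD"), (1, "lT/hD")):
        # one coloured (cued) ring; target always appears there
        specs = _counterbalanced_cell(16, "neutral", 0.5, config)
        add_block("value_learning", block, specs)

    df = pd.DataFrame(rows)
    return df[SCHEDULE_COLUMNS]
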