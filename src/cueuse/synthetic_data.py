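"""Synthetic trial-level cohorts for the cueing task.

Generates reaction times and accuracy with the statistical structure the
analysis assumes: a linear condition model on top of the Hick-Hyman
regressors, subject-level random effects, heavy-tailed (shifted-lognormal)
residual noise — RT distributions in this task deviate from normality,
which is what motivates the median-based pipeline — and two participant
subtypes: *trackers*, who use both the spatial and the incentive-value
cues, and *followers*, who use only the spatial cue (beta_val = 0).

The mean RT for a trial in spatial condition ``s`` and value configuration
``v`` is::

    E[RT] = beta0 + u_subject + u_cell(s, v)
            + beta_sh * r_sh(s) + beta_val * r_model(v)

where ``r_sh`` and ``r_model`` are the regressor tables from
:mod:`cueuse.encoding_models`. Accuracy is Bernoulli with a logit-linear
condition effect of opposite sign to the RT effect, so slower conditions
are also less accurate (no speed-accuracy trade-off).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding_models import (
    SPATIAL_PROBS,
    VALUE_LABELS,
    RegressorTable,
    build_regressor_table,
)
from .task_design import SCHEDULE_COLUMNS, build_main_schedule

__all__ = [
    "TRIAL_COLUMNS",
    "CohortSpec",
    "SubjectParams",
    "draw_subject_params",
    "inject_artifacts",
    "simulate_cohort",
    "simulate_trial",
]

#: Trial-table schema: the schedule columns plus the simulated responses.
TRIAL_COLUMNS = SCHEDULE_COLUMNS + ["rt_ms", "correct"]

_VALUE_MODELS = ("rv", "mot", "cf", "none")


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters for one simulated participant.

    RT-scale parameters are in ms. ``value_model`` selects which encoding
    model shapes the value-configuration effect; ``none`` (a *follower*)
    forces ``beta_val`` to be irrelevant. ``noise_shift``/``noise_sigma``
    parameterise the shifted-lognormal residual. ``acc_effect`` is the
    logit-accuracy cost per ms of predicted slowing.
    """

    subject: int
    beta0: float = 500.0
    beta_sh: float = 40.0
    beta_val: float = 145.0
    value_model: str = "cf"
    subject_re: float = 0.0
    cell_re_sd: float = 15.0
    noise_shift: float = 150.0
    noise_sigma: float = 0.28
    acc_base: float = 0.75
    acc_effect: float = 0.005
    subtype: str = "tracker"

    def __post_init__(self) -> None:
        if self.value_model not in _VALUE_MODELS:
            raise ValueError(f"unknown value_model {self.value_model!r}")
        if self.subtype not in ("tracker", "follower"):
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.beta_sh <= 0:
            raise ValueError("beta_sh must be positive: every subject uses the spatial cue")
        if (self.subtype == "follower") != (self.value_model == "none"):
            raise ValueError("followers must have value_model='none' and vice versa")


@dataclass(frozen=True)
class CohortSpec:
    """Population-level description of a simulated cohort.

    Subject parameters are drawn as ``N(mean, sd)`` (``beta_sh`` truncated
    below at ``beta_sh_floor`` so the spatial effect never vanishes or
    flips sign). Defaults emulate the published task: 720 trials per
    subject, a ~500 ms baseline, a spatial effect of roughly 40 ms between
    the most and least certain cue, and a counterfactual value effect
    sized so the expected lT/hD - hT/hD slowing is about 59 ms
    (145 ms/unit x ln 1.5).
    """

    n_trackers: int = 131
    n_followers: int = 15
    seed: int = 0
    tracker_value_model: str = "cf"
    beta0_mean: float = 500.0
    beta0_sd: float = 40.0
    beta_sh_mean: float = 40.0
    beta_sh_sd: float = 6.0
    beta_sh_floor: float = 5.0
    beta_val_mean: float = 145.0
    beta_val_sd: float = 12.0
    follower_beta_sh_mean: float = 70.0
    follower_beta_sh_sd: float = 15.0
    subject_re_sd: float = 0.0
    cell_re_sd: float = 15.0
    noise_shift: float = 150.0
    noise_sigma: float = 0.28
    acc_base: float = 0.75
    acc_effect: float = 0.005
    high_points: float = 100.0
    low_points: float = 10.0

    def __post_init__(self) -> None:
        if self.n_trackers < 0 or self.n_followers < 0:
            raise ValueError("subject counts must be non-negative")
        for name in ("beta0_sd", "beta_sh_sd", "beta_val_sd", "subject_re_sd", "cell_re_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def subtype_separated(cls, seed: int = 0, **overrides) -> "CohortSpec":
        """Well-separated tracker/follower cohort for subtype-recovery checks.

        Tightens within-subtype heterogeneity and residual noise so the
        between-subtype separation in feature space is far beyond 2 pooled
        within-subtype sds. With a 131/15 imbalance, the k-means
        sum-of-squares objective prefers halving the majority cloud unless
        the minority sits several within-sds away on more than one
        feature, so validating label recovery requires this regime rather
        than marginal (~2 sd) separation.
        """
        defaults = dict(
            n_trackers=131,
            n_followers=15,
            seed=seed,
            beta_sh_sd=6.0,
            cell_re_sd=6.0,
            beta_val_sd=12.0,
            noise_sigma=0.12,
            follower_beta_sh_mean=100.0,
            follower_beta_sh_sd=8.0,
        )
        defaults.update(overrides)
        return cls(**defaults)


def _regressors(spec_or_params, value_model: str) -> tuple[RegressorTable, RegressorTable | None]:
    high = getattr(spec_or_params, "high_points", 100.0)
    low = getattr(spec_or_params, "low_points", 10.0)
    sh = build_regressor_table("sh")
    val = None
    if value_model != "none":
        val = build_regressor_table(value_model, high_points=high, low_points=low)
    return sh, val


def draw_subject_params(spec: CohortSpec, rng: np.random.Generator) -> list[SubjectParams]:
    """Draw per-subject generative parameters for a mixed cohort.

    Trackers come first (subject ids 0..n_trackers-1), then followers.
    """
    out: list[SubjectParams] = []
    n_total = spec.n_trackers + spec.n_followers
    for i in range(n_total):
        is_follower = i >= spec.n_trackers
        sh_mean = spec.follower_beta_sh_mean if is_follower else spec.beta_sh_mean
        sh_sd = spec.follower_beta_sh_sd if is_follower else spec.beta_sh_sd
        beta_sh = max(rng.normal(sh_mean, sh_sd), spec.beta_sh_floor)
        beta_val = 0.0 if is_follower else max(rng.normal(spec.beta_val_mean, spec.beta_val_sd), 0.0)
        out.append(
            SubjectParams(
                subject=i,
                beta0=rng.normal(spec.beta0_mean, spec.beta0_sd),
                beta_sh=beta_sh,
                beta_val=beta_val,
                value_model="none" if is_follower else spec.tracker_value_model,
                subject_re=rng.normal(0.0, spec.subject_re_sd) if spec.subject_re_sd else 0.0,
                cell_re_sd=spec.cell_re_sd,
                noise_shift=spec.noise_shift,
                noise_sigma=spec.noise_sigma,
                acc_base=spec.acc_base,
                acc_effect=spec.acc_effect,
                subtype="follower" if is_follower else "tracker",
            )
        )
    return out


def _linear_predictor(
    params: SubjectParams,
    p_tgt: np.ndarray,
    value_config: np.ndarray,
    sh: RegressorTable,
    val: RegressorTable | None,
) -> np.ndarray:
    sh_map = {p: sh[p] for p in SPATIAL_PROBS}
    mu = params.beta0 + params.subject_re + params.beta_sh * np.vectorize(sh_map.get)(p_tgt)
    if val is not None:
        val_map = {lbl: val[lbl] for lbl in VALUE_LABELS}
        mu = mu + params.beta_val * np.vectorize(val_map.get)(value_config)
    return mu


def _cell_effects(params: SubjectParams, rng: np.random.Generator) -> dict[tuple[float, str], float]:
    return {
        (p, lbl): rng.normal(0.0, params.cell_re_sd) if params.cell_re_sd else 0.0
        for p in SPATIAL_PROBS
        for lbl in VALUE_LABELS
    }


def _simulate_responses(
    params: SubjectParams,
    schedule: pd.DataFrame,
    rng: np.random.Generator,
    cell_re: dict[tuple[float, str], float] | None = None,
) -> pd.DataFrame:
    sh, val = _regressors(params, params.value_model)
    p_tgt = schedule["p_tgt"].to_numpy(dtype=float)
    config = schedule["value_config"].to_numpy()
    mu = _linear_predictor(params, p_tgt, config, sh, val)
    if cell_re is None:
        cell_re = _cell_effects(params, rng)
    mu = mu + np.array([cell_re[(p, c)] for p, c in zip(p_tgt, config)])

    body = mu - params.noise_shift
    if np.any(body <= 0):
        raise ValueError("mean RT fell at or below the lognormal shift; "
                         "lower noise_shift or raise beta0")
    # The linear predictor locates the conditional *median* RT (the
    # pipeline's summary statistic), so condition effects propagate to
    # cell medians without lognormal attenuation; the conditional mean
    # lies a factor exp(sigma^2/2) above on the shifted part.
    sigma = params.noise_sigma
    if sigma > 0:
        rt = params.noise_shift + rng.lognormal(mean=np.log(body), sigma=sigma)
    else:
        rt = mu.copy()

    # accuracy: inverse of the condition RT pattern on the logit scale
    cond_effect = mu - params.beta0 - params.subject_re
    centred = cond_effect - cond_effect.mean()
    logit = np.log(params.acc_base / (1.0 - params.acc_base)) - params.acc_effect * centred
    p_correct = 1.0 / (1.0 + np.exp(-logit))
    correct = rng.random(len(schedule)) < p_correct

    out = schedule.copy()
    out["rt_ms"] = rt
    out["correct"] = correct.astype(bool)
    return out


def simulate_trial(
    params: SubjectParams,
    trial: pd.Series | dict,
    rng: np.random.Generator,
    cell_re: dict[tuple[float, str], float] | None = None,
) -> tuple[float, bool]:
    """Simulate one (rt_ms, correct) response for a single trial spec."""
    row = pd.DataFrame([dict(trial)])
    sim = _simulate_responses(params, row, rng, cell_re=cell_re)
    return float(sim["rt_ms"].iloc[0]), bool(sim["correct"].iloc[0])


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a full main-task cohort: one 720-trial schedule per subject.

    Deterministic given ``spec.seed``; all randomness flows through one
    generator.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = draw_subject_params(spec, rng)
    tables = []
    for params in subjects:
        schedule = build_main_schedule(rng, subject=params.subject)
        tables.append(_simulate_responses(params, schedule, rng))
    if not tables:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(tables, ignore_index=True)[TRIAL_COLUMNS]


def inject_artifacts(
    table: pd.DataFrame,
    rate_fast: float,
    rate_slow: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Replace a seeded fraction of correct-trial RTs with outliers.

    Fast artifacts are anticipations drawn uniformly in [100, 250) ms;
    slow artifacts sit 12 cell standard deviations above the cell median
    (at least 500 ms above), far beyond the 2.5-sd removal cut even after
    the injected values inflate the cell sd. Injected rows are flagged in
    a ``_artifact`` column for test assertions.
    """
    if not 0.0 <= rate_fast <= 1.0 or not 0.0 <= rate_slow <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    out = table.copy()
    out["_artifact"] = ""
    if rate_fast == 0.0 and rate_slow == 0.0:
        return out

    correct_idx = out.index[out["correct"]].to_numpy()
    n = len(out)
    n_fast = int(round(rate_fast * n))
    n_slow = int(round(rate_slow * n))
    fast_idx = rng.choice(correct_idx, size=min(n_fast, len(correct_idx)), replace=False)

    # Slow artifacts: at most 10% of any cell's correct trials receive one,
    # so the injected values (12 pre-injection cell sds above the median)
    # stay beyond the post-injection 2.5-sd cut: inflating the sd with a
    # fraction f of points at offset D raises the cut to at most
    # 2.5 * sqrt(f) * D ~ 0.79 D.
    cell_keys = ["subject", "p_tgt", "value_config"]
    pre = out[out["correct"]].groupby(cell_keys)["rt_ms"]
    med, sd = pre.median(), pre.std().fillna(0.0)
    cap = np.maximum((pre.size() * 0.10).astype(int), 1)
    taken: dict[tuple, int] = {}
    slow_idx = []
    candidates = rng.permutation(np.setdiff1d(correct_idx, fast_idx))
    for idx in candidates:
        if len(slow_idx) == n_slow:
            break
        key = tuple(out.loc[idx, cell_keys])
        if taken.get(key, 0) < cap[key]:
            taken[key] = taken.get(key, 0) + 1
            slow_idx.append(idx)

    out.loc[fast_idx, "rt_ms"] = rng.uniform(100.0, 249.0, size=len(fast_idx))
    out.loc[fast_idx, "_artifact"] = "fast"
    for idx in slow_idx:
        key = tuple(out.loc[idx, cell_keys])
        out.at[idx, "rt_ms"] = med[key] + max(12.0 * sd[key], 500.0)
    out.loc[slow_idx, "_artifact"] = "slow"
    return out
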