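"""Encoding models of attentional cue use.

Four hypotheses about how symbolic cues modify visual priorities are each
expressed as a deterministic, condition-level parametric regressor built on
the Hick-Hyman law of decision time, RT = beta * log(1/p + 1), where ``p``
is the probability (or probability-like quantity) of the event the encoding
mechanism tracks and the ``+ 1`` inside the log represents the fixed option
not to respond:

* ``sh`` (selection history): anticipatory; ``p`` is the experienced
  reliability of the spatial cue (.8 / .5 / .2).
* ``rv`` (relative value): anticipatory; ``p`` is the value at the target
  location normalised by the summed values on display.
* ``mot`` (motivational): anticipatory; ``p`` is the expected value summed
  across the display, so more reward on offer speeds responding everywhere.
* ``cf`` (counterfactual): reactive; ``p`` is a counterfactual loss
  L(x, x', y') = (x' - y')^2 + d(x, x') comparing the experienced outcome
  ``x`` with the counterfactual outcome ``x'`` and the best outcome on
  offer ``y'``; ``d`` is the MAD-scaled absolute distance, zero when
  x = x'.
* ``sh_cf_null``: a counterfactual encoding of the *spatial* factor,
  used only as a null model against which to compare ``sh``.

All regressors exclude the fitted coefficient beta: they are the unitless
quantities log(1/p + 1) that a linear mixed-effects model later scales.
The log is natural; any base change is absorbed by beta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MODEL_IDS",
    "SPATIAL_PROBS",
    "VALUE_LABELS",
    "LossInputs",
    "RegressorTable",
    "ValueConfig",
    "build_regressor_table",
    "counterfactual_loss",
    "hick_hyman",
    "median_abs_dev",
    "motivational_p",
    "relative_value_p",
]

#: Spatial-certainty levels: p(target at cued location | cue).
SPATIAL_PROBS: tuple[float, ...] = (0.8, 0.5, 0.2)

#: The four target/distractor value configurations (h = high, l = low).
VALUE_LABELS: tuple[str, ...] = ("hT/hD", "hT/lD", "lT/hD", "lT/lD")

#: Known encoding models; ``sh``/``sh_cf_null`` vary over the spatial
#: factor, the rest over the value factor.
MODEL_IDS: tuple[str, ...] = ("sh", "sh_cf_null", "rv", "mot", "cf")

_SPATIAL_MODELS = frozenset({"sh", "sh_cf_null"})
_VALUE_MODELS = frozenset({"rv", "mot", "cf"})


@dataclass(frozen=True)
class ValueConfig:
    """Incentive values (points) signalled at target and distractor locations."""

    v_tgt: float
    v_dst: float
    label: str

    def __post_init__(self) -> None:
        if self.v_tgt <= 0 or self.v_dst <= 0:
            raise ValueError("incentive values must be positive")
        if self.label not in VALUE_LABELS:
            raise ValueError(f"unknown value configuration label {self.label!r}")
        tgt_high, dst_high = self.label[0] == "h", self.label[3] == "h"
        if (self.v_tgt >= self.v_dst) != (tgt_high or not dst_high):
            raise ValueError(f"values ({self.v_tgt}, {self.v_dst}) inconsistent "
                             f"with label {self.label!r}")

    @classmethod
    def from_label(cls, label: str, high: float = 100.0, low: float = 10.0) -> "ValueConfig":
        if high <= low or low <= 0:
            raise ValueError("need high > low > 0 point values")
        if label not in VALUE_LABELS:
            raise ValueError(f"unknown value configuration label {label!r}")
        v_tgt = high if label[0] == "h" else low
        v_dst = high if label[3] == "h" else low
        return cls(v_tgt=v_tgt, v_dst=v_dst, label=label)


@dataclass(frozen=True)
class LossInputs:
    """Arguments of the counterfactual loss.

    ``x`` is the experienced outcome, ``x_cf`` the counterfactual outcome
    (what the other location offered), ``y_des`` the desired outcome (the
    maximum on offer), and ``mad`` the median absolute deviation of the
    feature, which scales the distance term. All in points.
    """

    x: float
    x_cf: float
    y_des: float
    mad: float

    def __post_init__(self) -> None:
        if self.mad < 0:
            raise ValueError("mad must be non-negative")


@dataclass(frozen=True)
class RegressorTable:
    """Condition-level parametric predictions from one encoding model.

    ``entries`` maps a condition key (a spatial probability for ``sh`` /
    ``sh_cf_null``, a value-configuration label for ``rv``/``mot``/``cf``)
    to the unitless regressor value that multiplies the fitted beta.
    """

    model_id: str
    entries: Mapping[float | str, float]
    factor: str = field(default="")

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if not self.entries:
            raise ValueError("empty regressor table")
        for key, value in self.entries.items():
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"regressor entry for {key!r} is {value}")
        if not self.factor:
            object.__setattr__(
                self, "factor", "spatial" if self.model_id in _SPATIAL_MODELS else "value"
            )

    def __getitem__(self, key: float | str) -> float:
        return self.entries[key]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns model_id, condition, value."""
        return pd.DataFrame(
            {
                "model_id": self.model_id,
                "condition": list(self.entries.keys()),
                "value": list(self.entries.values()),
            }
        )


def hick_hyman(p: float) -> float:
    """Hick-Hyman information regressor log(1/p + 1), natural log.

    Piecewise at zero: ``p = 0`` carries no event to respond to, the
    information term drops and the regressor is exactly 0.
    """
    p = float(p)
    if not math.isfinite(p) or p < 0:
        raise ValueError(f"p must be finite and non-negative, got {p}")
    if p == 0.0:
        return 0.0
    return math.log(1.0 / p + 1.0)


def median_abs_dev(values: Sequence[float]) -> float:
    """Median absolute deviation from the median, no consistency constant."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median_abs_dev of an empty set")
    return float(np.median(np.abs(arr - np.median(arr))))


def counterfactual_loss(inp: LossInputs) -> float:
    """Loss L = (x' - y')^2 + d(x, x') with MAD-scaled distance d.

    ``d`` is 0 when the experienced and counterfactual outcomes coincide,
    else |x - x'| / MAD (a single feature, so the sum over features is one
    term). Requires ``mad > 0`` whenever x differs from x'.
    """
    squared = (inp.x_cf - inp.y_des) ** 2
    if inp.x == inp.x_cf:
        d = 0.0
    else:
        if inp.mad == 0:
            raise ZeroDivisionError("mad = 0 with x != x_cf: distance undefined")
        d = abs(inp.x - inp.x_cf) / inp.mad
    return float(squared + d)


def relative_value_p(v_tgt: float, values: Iterable[float]) -> float:
    """Target value as a proportion of the summed values on display."""
    vals = [float(v) for v in values]
    if any(v <= 0 for v in vals):
        raise ValueError("all displayed values must be positive")
    if not any(math.isclose(v_tgt, v) for v in vals):
        raise ValueError("v_tgt must be one of the displayed values")
    return float(v_tgt) / sum(vals)


def motivational_p(loc_probs: Sequence[float], values: Sequence[float]) -> float:
    """Expected value summed over locations: sum_x p_x * v_x."""
    probs = np.asarray(loc_probs, dtype=float)
    vals = np.asarray(values, dtype=float)
    if probs.shape != vals.shape:
        raise ValueError("loc_probs and values must have equal length")
    if not math.isclose(probs.sum(), 1.0):
        raise ValueError("location probabilities must sum to 1")
    return float(probs @ vals)


def _value_configs(high: float, low: float) -> list[ValueConfig]:
    return [ValueConfig.from_label(lbl, high=high, low=low) for lbl in VALUE_LABELS]


def build_regressor_table(
    model_id: str,
    conditions: Sequence[float | str] | None = None,
    *,
    high_points: float = 100.0,
    low_points: float = 10.0,
    loc_probs: Sequence[float] = (0.5, 0.5),
) -> RegressorTable:
    """Build the condition -> regressor mapping for one encoding model.

    ``conditions`` defaults to the full relevant factor (the three spatial
    probabilities, or the four value-configuration labels) and must cover
    it when given. ``loc_probs`` are the location probabilities entering
    the motivational model; value cues are non-predictive of target side
    in this design, hence 0.5 each.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")

    if model_id in _SPATIAL_MODELS:
        probs = tuple(float(c) for c in conditions) if conditions is not None else SPATIAL_PROBS
        if conditions is not None and set(np.round(probs, 10)) != set(np.round(SPATIAL_PROBS, 10)):
            raise ValueError(f"spatial conditions {probs} do not cover {SPATIAL_PROBS}")
        if model_id == "sh":
            entries = {p: hick_hyman(p) for p in probs}
        else:
            # Null model: counterfactual encoding of whether attention, as
            # directed by the cue, matched the target side. Match indicator
            # x in {0, 1}, counterfactual its complement, desired outcome 1,
            # MAD over {0, 1} = 0.5. The neutral cue directs attention
            # nowhere, so x = x' and the loss vanishes.
            mad = median_abs_dev([0.0, 1.0])
            entries = {}
            for p in probs:
                if math.isclose(p, 0.5):
                    loss = 0.0
                else:
                    match = 1.0 if p > 0.5 else 0.0
                    loss = counterfactual_loss(
                        LossInputs(x=match, x_cf=1.0 - match, y_des=1.0, mad=mad)
                    )
                entries[p] = hick_hyman(loss)
        return RegressorTable(model_id=model_id, entries=entries)

    labels = tuple(str(c) for c in conditions) if conditions is not None else VALUE_LABELS
    if set(labels) != set(VALUE_LABELS):
        raise ValueError(f"value conditions {labels} do not cover {VALUE_LABELS}")
    configs = {vc.label: vc for vc in _value_configs(high_points, low_points)}

    entries = {}
    for label in labels:
        vc = configs[label]
        if model_id == "rv":
            p = relative_value_p(vc.v_tgt, [vc.v_tgt, vc.v_dst])
        elif model_id == "mot":
            p = motivational_p(loc_probs, [vc.v_tgt, vc.v_dst])
        else:  # cf
            mad = median_abs_dev([high_points, low_points])
            p = counterfactual_loss(
                LossInputs(
                    x=vc.v_tgt,
                    x_cf=vc.v_dst,
                    y_des=max(vc.v_tgt, vc.v_dst),
                    mad=mad,
                )
            )
        entries[label] = hick_hyman(p)
    return RegressorTable(model_id=model_id, entries=entries)
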