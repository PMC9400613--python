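"""Exclusion rules, outlier filtering, condition summaries and features.

Pipeline order is fixed: subject exclusion (< 60 % accuracy overall) ->
RT outlier filtering on correct trials (< 250 ms, then > 2.5 sd above the
cell median per subject x spatial certainty x value configuration) ->
per-cell summaries (median correct RT, accuracy, inverse efficiency) ->
clustering features (one spatial-certainty effect and three incentive-
value effects per subject).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .encoding_models import SPATIAL_PROBS, VALUE_LABELS

__all__ = [
    "FEATURE_NAMES",
    "cluster_features",
    "exclude_low_accuracy",
    "filter_correct_rt",
    "preprocess",
    "split_half_reliability",
    "summarize",
]

CELL_KEYS = ["subject", "p_tgt", "value_config"]

#: Per-subject clustering features: the spatial cueing effect and the three
#: incentive-value effects relative to the hT/hD baseline.
FEATURE_NAMES = ["SC", "IVi", "IVii", "IViii"]


def exclude_low_accuracy(
    table: pd.DataFrame, threshold: float = 0.60
) -> tuple[pd.DataFrame, list]:
    """Drop all trials of subjects whose overall accuracy is below threshold.

    The cut is strict: a subject at exactly the threshold is retained.
    """
    if table.empty:
        raise ValueError("empty trial table")
    acc = table.groupby("subject")["correct"].mean()
    excluded = sorted(acc.index[acc < threshold].tolist())
    kept = table[~table["subject"].isin(excluded)].reset_index(drop=True)
    return kept, excluded


def filter_correct_rt(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove RT outliers among correct trials; incorrect trials pass through.

    Two sequential rules on correct trials: (1) RT < 250 ms (strict);
    (2) RT > cell median + 2.5 x cell sd, with median and sd computed from
    the correct trials of each subject x spatial x value cell *after* the
    fast cut. Returns the filtered table and the removed rows (with a
    ``removed_by`` column).
    """
    missing = [c for c in CELL_KEYS + ["rt_ms", "correct"] if c not in table.columns]
    if missing:
        raise KeyError(f"trial table missing required columns: {missing}")

    correct = table[table["correct"]].copy()
    incorrect = table[~table["correct"]]

    fast = correct[correct["rt_ms"] < 250.0].copy()
    fast["removed_by"] = "fast"
    correct = correct[correct["rt_ms"] >= 250.0]

    grp = correct.groupby(CELL_KEYS)["rt_ms"]
    med = grp.transform("median")
    sd = grp.transform("std").fillna(0.0)
    slow_mask = correct["rt_ms"] > med + 2.5 * sd
    slow = correct[slow_mask].copy()
    slow["removed_by"] = "slow"
    correct = correct[~slow_mask]

    kept = (
        pd.concat([correct, incorrect])
        .sort_index()
        .reset_index(drop=True)
    )
    removed = pd.concat([fast, slow]).sort_index().reset_index(drop=True)
    return kept, removed


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per subject x condition cell: median correct RT, accuracy, inverse
    efficiency (ie = median RT / accuracy).

    Returns one row per subject for each of the 12 design cells; cells
    with no correct trials carry NaN (flagged missing, never zero).
    """
    subjects = sorted(table["subject"].unique())
    grid = pd.MultiIndex.from_product(
        [subjects, SPATIAL_PROBS, VALUE_LABELS], names=CELL_KEYS
    )
    correct = table[table["correct"]]
    med = correct.groupby(CELL_KEYS)["rt_ms"].median().reindex(grid)
    acc = table.groupby(CELL_KEYS)["correct"].mean().reindex(grid)
    out = pd.DataFrame({"median_rt": med, "accuracy": acc}).reset_index()
    out["inverse_efficiency"] = out["median_rt"] / out["accuracy"]
    return out


def marginal_summaries(table: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Per-subject summaries of one factor, pooling trials over the other.

    For ``factor='spatial'`` the correct trials of all four value
    configurations contribute to each spatial level's median (and
    conversely for ``factor='value'``). Pooling, rather than averaging the
    twelve cell medians, keeps the sparse invalid-cue cells from
    dominating the small-sample bias of the median.
    """
    col = {"spatial": "p_tgt", "value": "value_config"}[factor]
    correct = table[table["correct"]]
    med = correct.groupby(["subject", col])["rt_ms"].median()
    acc = table.groupby(["subject", col])["correct"].mean()
    out = pd.DataFrame({"median_rt": med, "accuracy": acc}).reset_index()
    out["inverse_efficiency"] = out["median_rt"] / out["accuracy"]
    return out


def cluster_features(summaries: pd.DataFrame, dv: str = "median_rt") -> pd.DataFrame:
    """The four per-subject effects entering the clustering analysis.

    SC    = RT(p = .2) - RT(p = .8), each averaged over value configs;
    IVi   = RT(hT/hD) - RT(lT/lD);
    IVii  = RT(hT/hD) - RT(lT/hD);
    IViii = RT(hT/hD) - RT(hT/lD), value cells averaged over spatial
    certainty (unweighted mean of cell medians).
    """
    missing = summaries[summaries[dv].isna()]
    if len(missing):
        cells = [tuple(r) for r in missing[CELL_KEYS].itertuples(index=False)]
        raise ValueError(f"missing summary cells: {cells}")

    by_spatial = summaries.pivot_table(index="subject", columns="p_tgt", values=dv, aggfunc="mean")
    by_value = summaries.pivot_table(index="subject", columns="value_config", values=dv, aggfunc="mean")
    out = pd.DataFrame(index=by_spatial.index)
    out["SC"] = by_spatial[0.2] - by_spatial[0.8]
    out["IVi"] = by_value["hT/hD"] - by_value["lT/lD"]
    out["IVii"] = by_value["hT/hD"] - by_value["lT/hD"]
    out["IViii"] = by_value["hT/hD"] - by_value["hT/lD"]
    return out.reset_index()


def split_half_reliability(table: pd.DataFrame) -> pd.DataFrame:
    """Split-half reliability of the clustering features.

    Features are computed separately on odd and even trials (1st, 3rd, ...
    vs 2nd, 4th, ... in presentation order within subject) and correlated
    across subjects (Pearson r, df = n - 2, two-sided p). A feature that
    is constant in either half has undefined r, reported as NaN.
    """
    n_subjects = table["subject"].nunique()
    if n_subjects < 3:
        raise ValueError("split-half reliability needs at least 3 subjects")

    order = table.groupby("subject").cumcount()
    halves = {}
    for name, mask in (("odd", order % 2 == 0), ("even", order % 2 == 1)):
        halves[name] = cluster_features(summarize(table[mask])).set_index("subject")

    rows = []
    for feat in FEATURE_NAMES:
        joined = pd.concat(
            [halves["odd"][feat], halves["even"][feat]], axis=1, keys=["odd", "even"]
        ).dropna()
        n = len(joined)
        if n < 3 or joined["odd"].std() == 0 or joined["even"].std() == 0:
            rows.append(dict(feature=feat, r=np.nan, df=n - 2, p=np.nan))
            continue
        r, p = stats.pearsonr(joined["odd"], joined["even"])
        rows.append(dict(feature=feat, r=float(r), df=n - 2, p=float(p)))
    return pd.DataFrame(rows)


def preprocess(
    table: pd.DataFrame, accuracy_threshold: float = 0.60
) -> dict:
    """Run the fixed pipeline and return all stage outputs plus a log."""
    kept, excluded = exclude_low_accuracy(table, threshold=accuracy_threshold)
    filtered, removed = filter_correct_rt(kept)
    summaries = summarize(filtered)
    features = cluster_features(summaries)
    log = {
        "n_subjects_in": int(table["subject"].nunique()),
        "excluded_subjects": excluded,
        "accuracy_threshold": accuracy_threshold,
        "n_trials_removed_fast": int((removed["removed_by"] == "fast").sum()),
        "n_trials_removed_slow": int((removed["removed_by"] == "slow").sum()),
        "order": ["exclude_low_accuracy", "filter_correct_rt", "summarize", "cluster_features"],
    }
    return {
        "trials": filtered,
        "removed": removed,
        "summaries": summaries,
        "features": features,
        "log": log,
    }
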