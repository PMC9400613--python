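"""Orchestration, configuration and delimited-text IO for the pipeline.

One flat CSV dialect (UTF-8, header row, '.' decimal) carries every table;
synthetic and deposited trial data share the same schema so either can be
fed to the pipeline. ``run_pipeline`` sequences the full analysis —
simulate (optional) -> preprocess -> regressors -> LME comparison -> NHST
battery -> clustering -> per-group LME comparison — and is deterministic
given the top-level seed, from which each stochastic stage derives its own
child seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, encoding_models, inference, preprocessing, synthetic_data

__all__ = [
    "RunConfig",
    "read_trials",
    "run_pipeline",
    "stage_seeds",
    "write_trials",
]

REQUIRED_TRIAL_COLUMNS = {
    "subject": "integer subject id",
    "p_tgt": "p(target | cue), one of 0.8 / 0.5 / 0.2",
    "value_config": "one of hT/hD, hT/lD, lT/hD, lT/lD",
    "rt_ms": "reaction time in ms",
    "correct": "boolean response accuracy",
}

#: Contrasts whose difference each value model predicts (or predicts null);
#: every unordered pair of value configurations.
VALUE_CONTRASTS = [
    ("lT/hD", "hT/hD"),
    ("lT/hD", "lT/lD"),
    ("lT/hD", "hT/lD"),
    ("hT/hD", "lT/lD"),
    ("hT/hD", "hT/lD"),
    ("lT/lD", "hT/lD"),
]

#: Contrasts the counterfactual model predicts to be null (tested with a
#: JZS Bayesian t-test when the NHST follow-up fails to reject).
CF_NULL_CONTRASTS = [("hT/hD", "lT/lD"), ("hT/hD", "hT/lD"), ("lT/lD", "hT/lD")]


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; serialisable to YAML."""

    seed: int = 0
    out_dir: str | None = None
    trials_path: str | None = None  # read instead of simulating when set
    column_aliases: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    accuracy_threshold: float = 0.60
    high_points: float = 100.0
    low_points: float = 10.0
    spatial_models: tuple = ("sh", "sh_cf_null")
    value_models: tuple = ("rv", "mot", "cf")
    dv: str = "median_rt"
    k_range: tuple = (1, 10)
    n_init: int = 1000
    min_samples: int | None = None
    mahalanobis_alpha: float = 0.01
    run_group_analysis: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic child seeds (< 2**31) for each stochastic stage."""
    ss = np.random.SeedSequence(seed)
    names = ["simulate", "kmeans", "optics"]
    children = ss.generate_state(len(names)) % (2**31 - 1)
    return dict(zip(names, (int(c) for c in children)))


def read_trials(path: str | Path, column_aliases: dict | None = None) -> pd.DataFrame:
    """Read and validate a trial-level CSV.

    ``column_aliases`` maps file column names to the canonical schema
    (e.g. ``{"RT": "rt_ms"}``), so deposited data with different headers
    can be loaded without rewriting the file.
    """
    df = pd.read_csv(path)
    if column_aliases:
        df = df.rename(columns=column_aliases)
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; "
            f"expected schema: {REQUIRED_TRIAL_COLUMNS}"
        )
    if not pd.api.types.is_numeric_dtype(df["rt_ms"]):
        bad = df.index[pd.to_numeric(df["rt_ms"], errors="coerce").isna()].tolist()[:10]
        raise ValueError(f"{path}: non-numeric rt_ms values at rows {bad}")
    unknown = set(df["value_config"]) - set(encoding_models.VALUE_LABELS)
    if unknown:
        raise ValueError(f"{path}: unknown value_config labels {sorted(unknown)}")
    bad_p = set(np.round(df["p_tgt"].unique(), 10)) - set(encoding_models.SPATIAL_PROBS)
    if bad_p:
        raise ValueError(f"{path}: unknown p_tgt levels {sorted(bad_p)}")
    df["correct"] = df["correct"].astype(bool)
    return df


def write_trials(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def _model_comparison(trials, models, factor, dv, high, low):
    marginal = preprocessing.marginal_summaries(trials, factor)
    fits = []
    for model_id in models:
        reg = encoding_models.build_regressor_table(model_id, high_points=high, low_points=low)
        fits.append(inference.fit_lme(marginal, reg, dv=dv))
    ranking = inference.compare_models(fits)
    wald = pd.DataFrame([inference.wald_test(f) for f in fits])
    table = ranking.merge(wald[["model_id", "statistic", "p"]], on="model_id")
    table = table.rename(columns={"statistic": "wald_W", "p": "wald_p"})
    table.insert(0, "factor", factor)
    return table


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns all tables plus a summary dict.

    Any stage failure is re-raised with the stage name attached. When
    ``config.out_dir`` is set, every table plus a JSON summary and a
    manifest are written there.
    """
    seeds = stage_seeds(config.seed)
    result: dict = {"config": asdict(config), "seeds": seeds}
    stage = "simulate"
    try:
        if config.trials_path:
            trials = read_trials(config.trials_path, config.column_aliases)
        else:
            spec = synthetic_data.CohortSpec(
                seed=seeds["simulate"],
                high_points=config.high_points,
                low_points=config.low_points,
                **config.cohort,
            )
            trials = synthetic_data.simulate_cohort(spec)
        result["trials"] = trials

        stage = "preprocess"
        prep = preprocessing.preprocess(trials, accuracy_threshold=config.accuracy_threshold)
        result.update(prep)
        summaries = prep["summaries"]

        stage = "regressors"
        all_models = list(config.spatial_models) + list(config.value_models)
        result["regressors"] = pd.concat(
            [
                encoding_models.build_regressor_table(
                    m, high_points=config.high_points, low_points=config.low_points
                ).to_frame()
                for m in all_models
            ],
            ignore_index=True,
        )

        stage = "fit"
        comparison = pd.concat(
            [
                _model_comparison(prep["trials"], config.spatial_models, "spatial",
                                  config.dv, config.high_points, config.low_points),
                _model_comparison(prep["trials"], config.value_models, "value",
                                  config.dv, config.high_points, config.low_points),
            ],
            ignore_index=True,
        )
        result["model_comparison"] = comparison

        stage = "nhst"
        anova = inference.rm_anova(
            summaries, dv=config.dv, within=["p_tgt", "value_config"], subject="subject"
        )
        value_means = inference.condition_means(summaries, "value", dv=config.dv)
        ttests = inference.pairwise_tests(value_means, VALUE_CONTRASTS)
        wide = value_means.pivot_table(index="subject", columns="condition", values="response")
        bayes = []
        for a, b in CF_NULL_CONTRASTS:
            diffs = (wide[a] - wide[b]).dropna().to_numpy()
            if diffs.std(ddof=1) > 0:
                bayes.append(dict(contrast=f"{a} - {b}", bf10=inference.jzs_bayes_t(diffs)))
        result["anova"] = anova
        result["pairwise"] = ttests
        result["bayes_null_contrasts"] = pd.DataFrame(bayes)

        stage = "cluster"
        features = prep["features"]
        flags, d2 = clustering.mahalanobis_screen(features, alpha=config.mahalanobis_alpha)
        screened = features[~flags].reset_index(drop=True)
        scaled = clustering.scale_features(screened)
        sweep = clustering.kmeans_sweep(
            scaled, k_range=range(config.k_range[0], config.k_range[1] + 1),
            n_init=config.n_init, seed=seeds["kmeans"],
        )
        selection = clustering.select_solution(sweep)
        optics = clustering.optics_cluster(scaled, min_samples=config.min_samples)
        labels = pd.DataFrame(
            {
                "subject": screened["subject"],
                "kmeans": selection["labels"],
                "optics": optics.labels,
                "mahalanobis_d2": d2[~flags],
            }
        )
        result["cluster_labels"] = labels
        result["kmeans_diagnostics"] = sweep.diagnostics_frame()
        result["kmeans_selection"] = selection
        result["optics"] = optics
        result["mahalanobis_excluded"] = features.loc[flags, "subject"].tolist()

        stage = "group_fit"
        group_tables = []
        if config.run_group_analysis:
            # main OPTICS cluster vs outliers, mirroring the subtype split
            labels["group"] = np.where(labels["optics"] == -1, "minor", "major")
            for name, subjects in labels.groupby("group")["subject"]:
                sub = prep["trials"][prep["trials"]["subject"].isin(subjects)]
                if sub["subject"].nunique() < 3:
                    continue
                tbl = pd.concat(
                    [
                        _model_comparison(sub, config.spatial_models, "spatial",
                                          config.dv, config.high_points, config.low_points),
                        _model_comparison(sub, config.value_models, "value",
                                          config.dv, config.high_points, config.low_points),
                    ],
                    ignore_index=True,
                )
                tbl.insert(0, "group", name)
                group_tables.append(tbl)
        result["group_model_comparison"] = (
            pd.concat(group_tables, ignore_index=True) if group_tables else pd.DataFrame()
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result["summary"] = _summarise(result)
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _summarise(result: dict) -> dict:
    comp = result["model_comparison"]
    best = {
        factor: sub.sort_values("aic").iloc[0]["model_id"]
        for factor, sub in comp.groupby("factor")
    }
    labels = result["cluster_labels"]
    summary = {
        "seed": result["config"]["seed"],
        "n_subjects": int(result["summaries"]["subject"].nunique()),
        "excluded_subjects": result["log"]["excluded_subjects"],
        "winning_model": best,
        "kmeans_k": result["kmeans_selection"]["k"],
        "kmeans_cluster_sizes": labels["kmeans"].value_counts().sort_index().tolist(),
        "optics_n_outliers": int((labels["optics"] == -1).sum()),
        "optics_n_clusters": int(labels.loc[labels["optics"] >= 0, "optics"].nunique()),
        "mahalanobis_excluded": result["mahalanobis_excluded"],
    }
    grp = result["group_model_comparison"]
    if len(grp):
        summary["group_winning_model"] = {
            f"{g}/{f}": sub.sort_values("aic").iloc[0]["model_id"]
            for (g, f), sub in grp.groupby(["group", "factor"])
        }
    return summary


def _write_outputs(result: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    tables = [
        "trials", "removed", "summaries", "features", "regressors",
        "model_comparison", "anova", "pairwise", "bayes_null_contrasts",
        "cluster_labels", "kmeans_diagnostics", "group_model_comparison",
    ]
    for name in tables:
        obj = result.get(name)
        if isinstance(obj, pd.DataFrame) and len(obj):
            path = out_dir / f"{name}.csv"
            obj.to_csv(path, index=False)
            manifest.append(path.name)
    optics = result["optics"]
    reach = pd.DataFrame(
        {"order": optics.ordering, "reachability": optics.reachability[optics.ordering]}
    )
    reach.to_csv(out_dir / "optics_reachability.csv", index=False)
    manifest.append("optics_reachability.csv")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(result["summary"], fh, indent=2, default=str)
    manifest.append("summary.json")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({"files": manifest, "log": result["log"]}, fh, indent=2, default=str)
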