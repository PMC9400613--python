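"""Simulation-based validation studies of the analysis pipeline.

Each study regenerates synthetic cohorts under known conditions and
measures how faithfully the pipeline recovers them: the generating
encoding model (by AIC), its coefficients (CI coverage), the calibration
of the Wald and FDR machinery under the null, and the tracker/follower
subtype structure. These studies back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import collections

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import clustering, encoding_models, inference, preprocessing, synthetic_data

__all__ = [
    "bh_null_calibration",
    "model_recovery_study",
    "subtype_recovery_study",
    "wald_null_calibration",
]

_VALUE_MODELS = ("rv", "mot", "cf")
_SPATIAL_MODELS = ("sh", "sh_cf_null")


def _fit_all(trials: pd.DataFrame) -> dict[str, inference.FitResult]:
    fits = {}
    value = preprocessing.marginal_summaries(trials, "value")
    spatial = preprocessing.marginal_summaries(trials, "spatial")
    for m in _VALUE_MODELS:
        fits[m] = inference.fit_lme(value, encoding_models.build_regressor_table(m))
    for m in _SPATIAL_MODELS:
        fits[m] = inference.fit_lme(spatial, encoding_models.build_regressor_table(m))
    return fits


def model_recovery_study(
    generating_model: str,
    n_seeds: int = 20,
    n_subjects: int = 40,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Simulate cohorts under one encoding model and refit all models.

    Returns one row per seed with the AIC-winning value and spatial
    models, the effect estimates for the generating model and the
    spatial model, and whether each 95% CI covers the generating
    population coefficient.
    """
    rows = []
    for i in range(n_seeds):
        spec = synthetic_data.CohortSpec(
            n_trackers=n_subjects, n_followers=0,
            seed=base_seed + i, tracker_value_model=generating_model,
        )
        trials = preprocessing.preprocess(synthetic_data.simulate_cohort(spec))["trials"]
        fits = _fit_all(trials)
        best_value = min(_VALUE_MODELS, key=lambda m: fits[m].aic)
        best_spatial = min(_SPATIAL_MODELS, key=lambda m: fits[m].aic)
        fv, fs = fits[generating_model], fits["sh"]
        rows.append(
            dict(
                seed=base_seed + i,
                generating_model=generating_model,
                best_value=best_value,
                best_spatial=best_spatial,
                beta_val_hat=fv.beta_hat,
                beta_val_se=fv.se,
                beta_val_covered=abs(fv.beta_hat - spec.beta_val_mean) <= 1.96 * fv.se,
                beta_sh_hat=fs.beta_hat,
                beta_sh_se=fs.se,
                beta_sh_covered=abs(fs.beta_hat - spec.beta_sh_mean) <= 1.96 * fs.se,
                delta_aic_runner_up=sorted(fits[m].aic for m in _VALUE_MODELS)[1]
                - fits[best_value].aic,
                lthd_minus_hthd_ms=_lthd_effect(trials),
            )
        )
    return pd.DataFrame(rows)


def _lthd_effect(trials: pd.DataFrame) -> float:
    """Mean over subjects of median RT(lT/hD) - median RT(hT/hD)."""
    marg = preprocessing.marginal_summaries(trials, "value")
    wide = marg.pivot_table(index="subject", columns="value_config", values="median_rt")
    return float((wide["lT/hD"] - wide["hT/hD"]).mean())


def wald_null_calibration(
    n_reps: int = 1000,
    n_subjects: int = 40,
    seed: int = 0,
    subject_sd: float = 30.0,
    noise_sd: float = 15.0,
) -> np.ndarray:
    """Wald p-values for the spatial slope under a null generator.

    Summary-level responses contain a subject random intercept and iid
    cell noise but no condition effect; returns the p-value per replicate.
    """
    rng = np.random.default_rng(seed)
    reg = encoding_models.build_regressor_table("sh")
    probs = list(encoding_models.SPATIAL_PROBS)
    ps = np.empty(n_reps)
    for rep in range(n_reps):
        u = rng.normal(0.0, subject_sd, n_subjects)
        rows = [
            dict(subject=s, p_tgt=p, median_rt=500.0 + u[s] + rng.normal(0.0, noise_sd))
            for s in range(n_subjects)
            for p in probs
        ]
        fit = inference.fit_lme(pd.DataFrame(rows), reg)
        ps[rep] = inference.wald_test(fit)["p"]
    return ps


def bh_null_calibration(
    n_reps: int = 1000,
    n_tests: int = 20,
    n_subjects: int = 20,
    seed: int = 0,
    q: float = 0.05,
) -> np.ndarray:
    """Per-replicate count of BH discoveries in an all-null test family."""
    rng = np.random.default_rng(seed)
    discoveries = np.empty(n_reps, dtype=int)
    contrasts = [(f"c{2 * i}", f"c{2 * i + 1}") for i in range(n_tests)]
    conditions = [c for pair in contrasts for c in pair]
    for rep in range(n_reps):
        values = rng.normal(size=(n_subjects, len(conditions)))
        data = pd.DataFrame(
            dict(
                subject=np.repeat(np.arange(n_subjects), len(conditions)),
                condition=np.tile(conditions, n_subjects),
                response=values.ravel(),
            )
        )
        res = inference.pairwise_tests(data, contrasts, q=q)
        discoveries[rep] = int(res["significant"].sum())
    return discoveries


def subtype_recovery_study(seeds=(0, 1, 2), n_init: int = 1000) -> pd.DataFrame:
    """Recover tracker/follower subtypes from well-separated cohorts.

    Follows the full published pipeline: preprocess, Mahalanobis screen,
    z-score, k-means sweep with majority selection, OPTICS with
    reachability extraction, then the per-group follow-ups (value effect
    on accuracy per group, spatial-certainty Wald per group, group x
    value interaction).
    """
    rows = []
    for seed in seeds:
        spec = synthetic_data.CohortSpec.subtype_separated(seed=seed)
        trials = synthetic_data.simulate_cohort(spec)
        prep = preprocessing.preprocess(trials)
        feats = prep["features"]
        flags, _ = clustering.mahalanobis_screen(feats)
        kept = feats[~flags].reset_index(drop=True)
        truth = (kept["subject"] >= spec.n_trackers).astype(int).to_numpy()
        scaled = clustering.scale_features(kept)
        mat = scaled[preprocessing.FEATURE_NAMES].to_numpy()

        # between-subtype separation along the discriminant direction,
        # in pooled within-subtype sd units
        gap = mat[truth == 1].mean(0) - mat[truth == 0].mean(0)
        direction = gap / np.linalg.norm(gap)
        proj = mat @ direction
        n0, n1 = (truth == 0).sum(), (truth == 1).sum()
        pooled_sd = np.sqrt(
            ((n0 - 1) * proj[truth == 0].var(ddof=1) + (n1 - 1) * proj[truth == 1].var(ddof=1))
            / (n0 + n1 - 2)
        )
        separation = float((proj[truth == 1].mean() - proj[truth == 0].mean()) / pooled_sd)

        sweep = clustering.kmeans_sweep(mat, n_init=n_init, seed=seed)
        sel = clustering.select_solution(sweep)
        ari = adjusted_rand_score(truth, sweep.labels_by_k[2])

        optics = clustering.optics_cluster(mat)
        lab = optics.labels
        counts = collections.Counter(lab[lab >= 0])
        main = counts.most_common(1)[0][0] if counts else None
        followers_outside = float(np.mean(lab[truth == 1] != main)) if main is not None else np.nan
        trackers_inside = float(np.mean(lab[truth == 0] == main)) if main is not None else np.nan

        # per-group follow-up on the OPTICS grouping, as in the published analysis
        group = np.where(lab == main, "tracker", "follower")
        subj_group = dict(zip(kept["subject"], group))
        trials_k = prep["trials"][prep["trials"]["subject"].isin(kept["subject"])].copy()
        trials_k["group"] = trials_k["subject"].map(subj_group)

        stats: dict[str, float] = {}
        acc = (
            trials_k.groupby(["subject", "group", "value_config"])["correct"]
            .mean()
            .reset_index()
            .rename(columns={"correct": "accuracy"})
        )
        mixed = inference.rm_anova(acc, dv="accuracy", within="value_config",
                                   subject="subject", between="group")
        stats["interaction_p"] = float(
            mixed.loc[mixed["effect"] == "Interaction", "p_unc"].iloc[0]
        )
        for name, sub in acc.groupby("group"):
            res = inference.rm_anova(sub, dv="accuracy", within="value_config",
                                     subject="subject")
            stats[f"value_effect_p_{name}"] = float(res["p"].iloc[0])
        for name, sub in trials_k.groupby("group"):
            marg = preprocessing.marginal_summaries(sub, "spatial")
            fit = inference.fit_lme(marg, encoding_models.build_regressor_table("sh"))
            stats[f"spatial_wald_p_{name}"] = inference.wald_test(fit)["p"]

        rows.append(
            dict(
                seed=seed,
                n_screened=int(flags.sum()),
                separation_sd=separation,
                kmeans_k=sel["k"],
                kmeans_ari=ari,
                optics_n_outliers=int((lab == -1).sum()),
                optics_n_clusters=len(counts),
                followers_outside_main=followers_outside,
                trackers_in_main=trackers_inside,
                **stats,
            )
        )
    return pd.DataFrame(rows)
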