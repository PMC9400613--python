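"""Group-level analysis: preprocessing, NHST battery, LME model comparison.

Reads scratch/trials.csv (from 02_simulate_cohort.py; simulates it if
absent), applies the exclusion and RT-outlier rules, runs the 3 x 4
repeated-measures ANOVA with FDR-corrected follow-ups and Bayesian null
checks, compares the encoding models by AIC/BIC with Wald tests, and
writes the tables under results/.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from cueuse import inference, preprocessing
from cueuse.encoding_models import build_regressor_table
from cueuse.pipeline import CF_NULL_CONTRASTS, VALUE_CONTRASTS, read_trials
from cueuse.preprocessing import split_half_reliability
from cueuse.synthetic_data import CohortSpec, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    trials_path = ROOT / "scratch" / "trials.csv"
    if trials_path.exists():
        trials = read_trials(trials_path)
        print(f"Loaded {trials_path}")
    else:
        trials = simulate_cohort(CohortSpec(seed=args.seed))
        print("scratch/trials.csv absent; simulated the default cohort instead")

    prep = preprocessing.preprocess(trials)
    log = prep["log"]
    print(f"Excluded {len(log['excluded_subjects'])} subjects below 60% accuracy; "
          f"removed {log['n_trials_removed_fast']} fast and "
          f"{log['n_trials_removed_slow']} slow RT outliers.")

    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    anova = inference.rm_anova(prep["summaries"], dv="median_rt",
                               within=["p_tgt", "value_config"])
    anova.to_csv(out / "rm_anova.csv", index=False)
    print("\n3 (spatial certainty) x 4 (value configuration) RM-ANOVA on median RT:")
    print(anova.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

    value_means = inference.condition_means(prep["summaries"], "value")
    ttests = inference.pairwise_tests(value_means, VALUE_CONTRASTS)
    ttests.to_csv(out / "pairwise_value.csv", index=False)
    print("\nFDR-corrected paired t-tests over value configurations:")
    print(ttests.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

    wide = value_means.pivot_table(index="subject", columns="condition", values="response")
    bayes = pd.DataFrame(
        [dict(contrast=f"{a} - {b}",
              bf10=inference.jzs_bayes_t((wide[a] - wide[b]).dropna().to_numpy()))
         for a, b in CF_NULL_CONTRASTS]
    )
    bayes.to_csv(out / "bayes_null_contrasts.csv", index=False)
    print("\nJZS Bayes factors for the contrasts the counterfactual model "
          "predicts null (BF10 < 1 favours the null):")
    print(bayes.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    comparisons = []
    for factor, models in (("spatial", ("sh", "sh_cf_null")), ("value", ("rv", "mot", "cf"))):
        marg = preprocessing.marginal_summaries(prep["trials"], factor)
        fits = [inference.fit_lme(marg, build_regressor_table(m)) for m in models]
        ranking = inference.compare_models(fits)
        wald = pd.DataFrame([inference.wald_test(f) for f in fits])
        tbl = ranking.merge(wald[["model_id", "statistic", "p"]], on="model_id")
        tbl.insert(0, "factor", factor)
        comparisons.append(tbl)
    comparison = pd.concat(comparisons, ignore_index=True)
    comparison.to_csv(out / "model_comparison.csv", index=False)
    print("\nLME model comparison (AIC ranks within each factor):")
    print(comparison.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    winners = {f: t.sort_values('aic').iloc[0]['model_id']
               for f, t in comparison.groupby('factor')}
    print(f"\nWinning models: spatial -> {winners['spatial']}, value -> {winners['value']}")

    rel = split_half_reliability(prep["trials"])
    rel.to_csv(out / "reliability.csv", index=False)
    print("\nSplit-half (odd/even trial) reliability of the clustering features:")
    print(rel.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    return 0


if __name__ == "__main__":
    sys.exit(main())
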