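"""Build the encoding-model regressor tables.

Writes the condition-level parametric predictions of all five encoding
models (selection history, its counterfactual null, relative value,
motivational, counterfactual) to results/regressors.csv and prints them
with the predicted qualitative orderings.
"""

import sys
from pathlib import Path

import pandas as pd

from cueuse.encoding_models import MODEL_IDS, build_regressor_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tables = {m: build_regressor_table(m) for m in MODEL_IDS}
    frame = pd.concat([t.to_frame() for t in tables.values()], ignore_index=True)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "regressors.csv", index=False)

    print("Regressor tables (unitless; an LME slope beta scales them to ms):\n")
    print(frame.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    cf = tables["cf"]
    print(
        "\nCounterfactual model: hT/hD and lT/lD sit at exactly 0, hT/lD at "
        f"{cf['hT/lD']:.2e} (negligible), and lT/hD at {cf['lT/hD']:.4f} = ln 1.5 "
        "- the selective slowing when a low-value target appears beside a "
        "high-value distractor."
    )
    print(f"\nWrote {OUT / 'regressors.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
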