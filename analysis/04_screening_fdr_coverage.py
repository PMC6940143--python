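"""Operating characteristics of the decision pipeline at metabolome scale.

Three studies on replicated synthetic data:
  1. the p < 0.5 pre-screen keeps ~50% of pure-noise features and >99% of
     strong signals;
  2. the realized false discovery proportion of the screen + univariate fit +
     Bayesian-FDR pipeline (level 0.05) on 180 null + 20 signal features —
     this is expected to be poorly controlled (~0.6) because tail-probability
     p-values from independently fitted features are uniform under the null
     rather than posterior null probabilities, and the running-mean rule's
     rejection prefix then admits many nulls (see docs/methods.md);
  3. frequentist coverage of the corrected model's 95% credible interval,
     which should sit near 95%.
"""

import sys
from pathlib import Path

import pandas as pd

from trapme import experiments as ex

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    scr = ex.screening_experiment(seed=seed)
    fdr = ex.fdr_experiment(seed=seed, n_replicates=50)
    cov = ex.coverage_experiment(seed=seed, n_replicates=100)
    tab = pd.DataFrame([
        {"quantity": "screen null retention", "value": scr["null_retention"],
         "expected": 0.5},
        {"quantity": "screen signal retention", "value": scr["signal_retention"],
         "expected": 1.0},
        {"quantity": "realized FDR (level 0.05)", "value": fdr["realized_fdr"],
         "expected": float("nan")},
        {"quantity": "power", "value": fdr["power"], "expected": float("nan")},
        {"quantity": "95% CrI coverage (corrected)", "value": cov["coverage"],
         "expected": 0.95},
    ])
    tab.to_csv(OUT / "04_decision_pipeline.csv", index=False)
    print(tab.round(3).to_string(index=False))
    print(f"\nmean rejections per replicate: {fdr['mean_rejections']:.1f} "
          f"(20 true signals): the Bayesian-FDR rule over-rejects when fed "
          f"uniform null tail probabilities — a limitation of the decision "
          f"rule, not of the samplers (coverage is calibrated).")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
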