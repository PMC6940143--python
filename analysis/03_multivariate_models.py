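"""Multivariate variants: correlated exposures and correlated omic responses.

Part A — two-pollutant attenuation. With Sigma_Z = Sigma_U = I and
beta = (1, 0), the naive fit centres on Lambda' beta = (0.5, 0) and the
corrected fit recovers (1, 0). With correlated exposures (rho = 0.8)
classical error contaminates the null pollutant's naive coefficient
(Lambda' beta ≈ (0.41, 0.24)) — bias away from zero, not attenuation. The
corrected model then still identifies the total exposure effect (the
coefficient sum), but the individual attribution is weakly identified: the
latent exposures are nearly collinear and the posterior has a long flat
ridge along beta_1 + beta_2 = const, which is reported here via the sum.

Part B — three correlated omic features. The multiomics model's Wishart-prior
residual covariance recovers a generating correlation of 0.7.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from trapme import experiments as ex

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for rho in (0.0, 0.8):
        r = ex.multivariate_attenuation_experiment(seed=seed, rho_z=rho)
        rows.append({
            "rho_z": rho,
            "naive_expected_active": r["naive_expected"][0],
            "naive_expected_null": r["naive_expected"][1],
            "naive_mean_active": r["naive_mean"][0],
            "naive_mean_null": r["naive_mean"][1],
            "corrected_mean_active": r["corrected_mean"][0],
            "corrected_mean_null": r["corrected_mean"][1],
            "corrected_mean_sum": r["corrected_mean"][0] + r["corrected_mean"][1],
            "true_sum": r["beta_true"].sum(),
        })
    tab = pd.DataFrame(rows)
    tab.to_csv(OUT / "03_multiexposure_attenuation.csv", index=False)
    print("two-pollutant fits, beta = (1, 0):")
    print(tab.round(3).to_string(index=False))
    print("with rho=0.8 the naive null coefficient is biased upward, as the "
          "matrix attenuation law predicts; the corrected model identifies "
          "the coefficient sum, while splitting it between two nearly "
          "collinear latent exposures remains weakly identified.\n")

    c = ex.covariance_recovery_experiment(seed=seed, rho=0.7)
    corr = pd.DataFrame(np.round(c["posterior_corr"], 3))
    corr.to_csv(OUT / "03_residual_correlation.csv", index=False)
    print("posterior mean residual correlation (truth: 0.7 between features 1-2):")
    print(corr.to_string(index=False))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
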