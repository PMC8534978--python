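"""Monte-Carlo parameter recovery for the Arrhenius fitting chain.

Generates 200 noisy Rancimat datasets (multiplicative lognormal IP noise,
sigma = 0.05, four temperatures) from a known activation energy and refits
each, summarizing bias and spread. Writes results/mc_recovery.tsv.

Finding: the estimator is unbiased within Monte-Carlo error; with only
four temperatures the per-dataset spread is a few kJ/mol, which is why
reported activation energies from induction-period data carry ~5%
uncertainty even at modest noise.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from oxikin.rancimat import arrhenius_fit, rate_constants
from oxikin.simulate import generate_rancimat

OUT = Path(__file__).resolve().parent.parent / "results"

TRUTH_EA = 66.29
TRUTH_LN_A = 20.55
SIGMA = 0.05
N_SEEDS = 200


def main() -> None:
    eas = []
    for seed in range(N_SEEDS):
        ip = generate_rancimat(TRUTH_EA, TRUTH_LN_A, noise_sigma=SIGMA, seed=seed)
        eas.append(arrhenius_fit(rate_constants(ip), "synthetic").ea_kj_mol)
    eas = np.asarray(eas)
    mc_se = eas.std(ddof=1) / np.sqrt(N_SEEDS)
    summary = pd.DataFrame([{
        "true_ea_kj_mol": TRUTH_EA,
        "mean_recovered": eas.mean(),
        "sd_recovered": eas.std(ddof=1),
        "mc_se": mc_se,
        "bias": eas.mean() - TRUTH_EA,
        "n_seeds": N_SEEDS,
        "noise_sigma": SIGMA,
    }])
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "mc_recovery.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    verdict = "within" if abs(eas.mean() - TRUTH_EA) < 2 * mc_se else "OUTSIDE"
    print(f"bias is {verdict} 2 Monte-Carlo standard errors")


if __name__ == "__main__":
    main()
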