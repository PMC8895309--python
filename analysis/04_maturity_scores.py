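#!/usr/bin/env python
"""Diffusion x age PLSC per tract: tract maturity scores.

Tracts whose age latent variable fails permutation testing get no scores.
Writes results/maturity_scores.tsv.
"""

from pathlib import Path

import pandas as pd

from tractpls import build_analysis_matrix, load_cohort, load_metrics, maturity_scores
from tractpls.cohort import TRACTS

OUT = Path(__file__).resolve().parents[1] / "results"
SEED, N_PERM, N_BOOT = 1, 2000, 2000


def main() -> None:
    cohort = load_cohort(OUT / "cohort.csv")
    metrics = load_metrics(OUT / "metrics.csv")
    rows = []
    for tract in TRACTS:
        mat = build_analysis_matrix(cohort, metrics, tract, "age")
        ms = maturity_scores(mat, tract=tract, n_perm=N_PERM, n_boot=N_BOOT,
                             seed=SEED, allow_insignificant=True)
        status = "" if ms.significant else "  [NOT significant: no maturity scores]"
        print(f"{tract} (n={mat.n}): age-LV p={ms.lv_p_value:.4f}{status}")
        if not ms.significant:
            continue
        flip = " (sign-flipped to align with age)" if ms.sign_flipped else ""
        print(f"   corr(maturity score, age) = {ms.age_correlation:.2f}{flip}")
        top = sorted(zip(ms.x_names, ms.bootstrap.bootstrap_ratio),
                     key=lambda kv: -abs(kv[1]))[:2]
        print(f"   most reliable contributors: "
              + ", ".join(f"{k} (BR={v:.1f})" for k, v in top))
        for sid, val in zip(ms.subject_ids, ms.score):
            rows.append({"tract": tract, "subject_id": sid, "maturity_score": val})
    pd.DataFrame(rows).to_csv(OUT / "maturity_scores.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
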