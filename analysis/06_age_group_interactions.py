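#!/usr/bin/env python
"""Does the maturity-memory slope differ between younger (< 7 y) and older
(>= 7 y) children?  OLS with a maturity x age-group interaction term per
significant tract and recall score.

Writes results/interactions.tsv.
"""

from pathlib import Path

import pandas as pd

from tractpls import (
    age_group_interaction,
    build_analysis_matrix,
    load_cohort,
    load_metrics,
    maturity_scores,
)
from tractpls.cohort import EM_SCORES, TRACTS

OUT = Path(__file__).resolve().parents[1] / "results"
SEED, N_PERM, N_BOOT = 1, 2000, 2000


def main() -> None:
    cohort = load_cohort(OUT / "cohort.csv")
    metrics = load_metrics(OUT / "metrics.csv")
    beh = cohort.data.set_index("subject_id")
    rows = []
    for tract in TRACTS:
        mat = build_analysis_matrix(cohort, metrics, tract, "age")
        ms = maturity_scores(mat, tract=tract, n_perm=N_PERM, n_boot=N_BOOT,
                             seed=SEED, allow_insignificant=True)
        if not ms.significant:
            continue
        age = beh.loc[ms.subject_ids, "age"].to_numpy(float)
        for score in EM_SCORES:
            em = beh.loc[ms.subject_ids, score].to_numpy(float)
            res = age_group_interaction(ms, em, age, behavior=score)
            mark = "*" if res.interaction_p < 0.05 else " "
            print(f"{mark} {tract} x {score}: slopes "
                  f"young={res.slope_young:.2f} old={res.slope_old:.2f}, "
                  f"interaction p={res.interaction_p:.3f} "
                  f"(n={res.n_young}/{res.n_old})")
            rows.append({
                "tract": tract, "behavior": score,
                "slope_young": res.slope_young, "slope_old": res.slope_old,
                "interaction_coefficient": res.interaction_coefficient,
                "interaction_p": res.interaction_p,
            })
    pd.DataFrame(rows).to_csv(OUT / "interactions.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
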