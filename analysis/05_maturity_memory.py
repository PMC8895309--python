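#!/usr/bin/env python
"""Maturity-memory associations: Pearson correlations of each significant
tract's maturity score with the three recall scores (one FDR family),
Bayes factors for the survivors, and the discrimination specificity panel.

Writes results/associations.tsv.
"""

from pathlib import Path

import pandas as pd

from tractpls import (
    build_analysis_matrix,
    load_cohort,
    load_metrics,
    maturity_em_association,
    maturity_scores,
)
from tractpls.cohort import TRACTS

OUT = Path(__file__).resolve().parents[1] / "results"
SEED, N_PERM, N_BOOT = 1, 2000, 2000


def main() -> None:
    cohort = load_cohort(OUT / "cohort.csv")
    metrics = load_metrics(OUT / "metrics.csv")
    scores = {}
    for tract in TRACTS:
        mat = build_analysis_matrix(cohort, metrics, tract, "age")
        ms = maturity_scores(mat, tract=tract, n_perm=N_PERM, n_boot=N_BOOT,
                             seed=SEED, allow_insignificant=True)
        if ms.significant:
            scores[tract] = ms
        else:
            print(f"{tract}: excluded (age-LV p={ms.lv_p_value:.3f})")

    assoc = maturity_em_association(scores, cohort)
    rows = []
    for a in assoc:
        mark = "*" if a.panel == "em" and a.p_fdr < 0.05 else " "
        bf = f", BF10={a.bf10:.2f}" if a.bf10 is not None else ""
        print(f"{mark} {a.tract} x {a.behavior}: r={a.r:.2f}, "
              f"q={a.p_fdr:.3f}{bf} (n={a.n})")
        rows.append({"tract": a.tract, "behavior": a.behavior, "panel": a.panel,
                     "r": a.r, "p_raw": a.p_raw, "p_fdr": a.p_fdr,
                     "bf10": a.bf10, "n": a.n})
    pd.DataFrame(rows).to_csv(OUT / "associations.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
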