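#!/usr/bin/env python
"""Memory x diffusion PLSC per tract: LV1 permutation significance,
bootstrap ratios of the diffusion parameters, recall-score weights.

Writes results/plsc_<tract>.tsv.
"""

from pathlib import Path

import pandas as pd

from tractpls import (
    behavior_weights,
    bootstrap_ratios,
    build_analysis_matrix,
    load_cohort,
    load_metrics,
    permutation_test,
    plsc_decompose,
)
from tractpls.cohort import TRACTS

OUT = Path(__file__).resolve().parents[1] / "results"
SEED, N_PERM, N_BOOT = 1, 2000, 2000


def main() -> None:
    cohort = load_cohort(OUT / "cohort.csv")
    metrics = load_metrics(OUT / "metrics.csv")
    for tract in TRACTS:
        mat = build_analysis_matrix(cohort, metrics, tract, "em_scores")
        model = plsc_decompose(mat.X, mat.Y, x_names=mat.x_names,
                               y_names=mat.y_names)
        perm = permutation_test(mat.X, mat.Y, 0, n_perm=N_PERM, seed=SEED)
        boot = bootstrap_ratios(mat.X, mat.Y, 0, n_boot=N_BOOT, seed=SEED + 1,
                                model=model)
        weights = behavior_weights(mat.Y, model.Lx[:, 0], y_names=mat.y_names)
        print(f"{tract} (n={mat.n}): LV1 p={perm.p_value:.4f}")
        for name, br, ok in zip(mat.x_names, boot.bootstrap_ratio, boot.reliable):
            flag = "*" if ok else " "
            print(f"   {name:32s} BR={br:7.2f}{flag}")
        for name, w, p in zip(weights.y_names, weights.weight, weights.p_value):
            print(f"   weight {name}: r={w:.2f} (p={p:.4f})")
        pd.DataFrame(
            {"x_name": mat.x_names, "bootstrap_ratio": boot.bootstrap_ratio,
             "reliable": boot.reliable}
        ).to_csv(OUT / f"plsc_{tract}.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
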