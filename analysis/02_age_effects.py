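#!/usr/bin/env python
"""Univariate age effects: each recall score regressed on age, and the
24-cell panel of metric-age Pearson correlations with one BH-FDR family.

Reads results/cohort.csv + metrics.csv; writes results/table2_analog.tsv.
"""

from pathlib import Path

from tractpls import correlate_with_age, load_cohort, load_metrics, regress_on_age
from tractpls.cohort import EM_SCORES

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = load_cohort(OUT / "cohort.csv")
    metrics = load_metrics(OUT / "metrics.csv")
    ages = cohort.ages()

    print("recall ~ age (OLS):")
    for score in EM_SCORES:
        res = regress_on_age(
            cohort.em_scores()[score].to_numpy(), ages.to_numpy(), outcome=score
        )
        print(f"  {score}: F={res.F:.2f}, R^2={res.r_squared:.3f}, "
              f"beta={res.beta_std:.2f}, p={res.p:.4f}")

    table = correlate_with_age(metrics, ages)
    table.to_csv(OUT / "table2_analog.tsv", sep="\t", index=False)
    sig = table[table["p_fdr"] < 0.05]
    print(f"\nmetric-age panel: {len(table)} cells, "
          f"{len(sig)} significant after FDR")
    for _, row in sig.iterrows():
        print(f"  {row['tract']} {row['hemisphere']} {row['metric'].upper()}: "
              f"r={row['r']:.2f} (q={row['p_fdr']:.3f})")


if __name__ == "__main__":
    main()
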