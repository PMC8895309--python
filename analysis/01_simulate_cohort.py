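#!/usr/bin/env python
"""Draw the study cohort: 37 children aged 4-12 with recall scores rising
with age, RD-dominated tract maturation, and planted maturity-memory
coupling (uncinate x delayed recall, dorsal cingulum x short-delay recall).
One subject loses the uncinate and fornix reconstructions.

Writes results/cohort.csv and results/metrics.csv.
"""

from pathlib import Path

from tractpls import SimConfig, generate_cohort, write_cohort, write_metrics

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    cfg = SimConfig(seed=SEED)
    cohort, metrics, truth = generate_cohort(cfg)
    OUT.mkdir(exist_ok=True)
    write_cohort(cohort, OUT / "cohort.csv")
    write_metrics(metrics, OUT / "metrics.csv")
    print(f"cohort: n={cohort.n}, ages {cohort.data['age'].min():.1f}-"
          f"{cohort.data['age'].max():.1f} "
          f"(mean {cohort.data['age'].mean():.2f}, SD {cohort.data['age'].std():.2f})")
    print(f"metric rows: {len(metrics.data)} "
          f"({len(metrics.subjects_with_tract('uncinate_fasciculus'))} subjects "
          "with a complete uncinate)")
    rd = truth.realized_metric_age_corr[("uncinate_fasciculus", "right", "rd")]
    print(f"realized corr(right uncinate RD, age) = {rd:.2f} (target -0.61)")
    print(f"realized age R^2 of recall scores: "
          f"{ {k: round(v, 2) for k, v in truth.realized_em_age_r2.items()} }")


if __name__ == "__main__":
    main()
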