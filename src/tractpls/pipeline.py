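"""End-to-end pipeline: config -> staged analyses -> serialized report.

Stage order mirrors the study design: univariate age effects, memory x
diffusion PLSC per tract, diffusion x age PLSC yielding maturity scores
(tracts whose age latent variable fails permutation testing are reported
but excluded from the maturity-memory stage), maturity-memory correlations
with FDR and Bayes factors plus the discrimination specificity panel, and
age-group interaction models.

Outputs: ``report.json`` (nested, schema-validated), ``associations.tsv``,
``table2_analog.tsv``, ``maturity_scores.tsv``, ``plsc_<tract>.tsv``, and a
log on standard error.  Every number in the report is recomputable from
config + inputs + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    age_group_interaction,
    correlate_with_age,
    maturity_em_association,
    regress_on_age,
)
from .cohort import (
    EM_SCORES,
    TRACTS,
    Cohort,
    InsufficientDataError,
    TractMetricTable,
    build_analysis_matrix,
    load_cohort,
    load_metrics,
    write_cohort,
    write_metrics,
)
from .inference import behavior_weights, bootstrap_ratios, permutation_test
from .maturity import maturity_scores
from .plsc import plsc_decompose
from .simulate import SimConfig, generate_cohort

log = logging.getLogger("tractpls")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    cohort_path: str | None = None
    metrics_path: str | None = None
    simulate: bool = False
    sim: SimConfig = field(default_factory=SimConfig)
    tracts: tuple[str, ...] = TRACTS
    n_perm: int = 5000
    n_boot: int = 5000
    alpha: float = 0.05
    fdr_joint_family: bool = True
    bf_method: str = "jzs"
    bf_kappa: float = 1.0
    age_cutoff: float = 7.0
    seed: int = 0
    out_dir: str = "results"
    tab: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if sim_raw:
            cfg.sim = SimConfig(
                **{k: v for k, v in sim_raw.items() if k in SimConfig.__dataclass_fields__}
            )
        if "tracts" in raw:
            cfg.tracts = tuple(raw["tracts"])
        return cfg

    def digest(self) -> str:
        payload = json.dumps(
            {k: repr(v) for k, v in self.__dict__.items() if k != "out_dir"},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate(config: RunConfig, out_dir: Path) -> tuple[Cohort, TractMetricTable]:
    """Draw a synthetic cohort and write the cohort/metric CSVs."""
    sim = config.sim.replace(seed=config.sim.seed or config.seed)
    cohort, metrics, _truth = generate_cohort(sim)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, out_dir / "cohort.csv", tab=config.tab)
    write_metrics(metrics, out_dir / "metrics.csv", tab=config.tab)
    log.info("simulated cohort: n=%d subjects (seed %d)", cohort.n, sim.seed)
    return cohort, metrics


def _stage(name):
    def wrap(fn):
        def inner(*a, **kw):
            log.info("stage: %s", name)
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - re-raised with stage tag
                raise PipelineStageError(name, e) from e
        return inner
    return wrap


@_stage("univariate-age")
def _univariate_stage(cohort: Cohort, metrics: TractMetricTable) -> dict:
    ages = cohort.ages()
    em = cohort.em_scores()
    em_reg = {}
    for score in EM_SCORES:
        res = regress_on_age(em[score].to_numpy(), ages.to_numpy(), outcome=score)
        em_reg[score] = {
            "F": res.F, "r_squared": res.r_squared,
            "beta_std": res.beta_std, "p": res.p, "n": res.n,
        }
    table2 = correlate_with_age(metrics, ages)
    return {"em_age_regressions": em_reg, "metric_age_table": table2}


@_stage("em-plsc")
def _em_plsc_stage(cohort, metrics, config: RunConfig, rng_seed: int) -> dict:
    out = {}
    for tract in config.tracts:
        try:
            mat = build_analysis_matrix(cohort, metrics, tract, "em_scores")
        except InsufficientDataError as e:
            log.warning("%s: %s", tract, e)
            out[tract] = {"error": str(e)}
            continue
        model = plsc_decompose(mat.X, mat.Y, x_names=mat.x_names, y_names=mat.y_names)
        perm = permutation_test(
            mat.X, mat.Y, 0, n_perm=config.n_perm, seed=rng_seed
        )
        boot = bootstrap_ratios(
            mat.X, mat.Y, 0, n_boot=config.n_boot, seed=rng_seed + 1, model=model
        )
        weights = behavior_weights(mat.Y, model.Lx[:, 0], y_names=mat.y_names,
                                   alpha=config.alpha)
        log.info("%s EM-PLSC: LV1 p=%.4f (n=%d)", tract, perm.p_value, mat.n)
        out[tract] = {
            "n": mat.n,
            "dropped": mat.dropped,
            "singular_values": model.S.tolist(),
            "lv1_p": perm.p_value,
            "bootstrap_ratios": dict(zip(mat.x_names, boot.bootstrap_ratio.tolist())),
            "reliable": dict(zip(mat.x_names, boot.reliable.tolist())),
            "behavior_weights": {
                name: {"r": float(w), "p": float(p)}
                for name, w, p in zip(weights.y_names, weights.weight, weights.p_value)
            },
        }
    return out


@_stage("age-plsc-maturity")
def _maturity_stage(cohort, metrics, config: RunConfig, rng_seed: int) -> tuple[dict, dict]:
    scores = {}
    report = {}
    for tract in config.tracts:
        try:
            mat = build_analysis_matrix(cohort, metrics, tract, "age")
        except InsufficientDataError as e:
            log.warning("%s: %s", tract, e)
            report[tract] = {"error": str(e)}
            continue
        ms = maturity_scores(
            mat, tract=tract, n_perm=config.n_perm, n_boot=config.n_boot,
            seed=rng_seed, alpha=config.alpha, allow_insignificant=True,
        )
        report[tract] = {
            "n": mat.n,
            "lv_p_value": ms.lv_p_value,
            "significant": ms.significant,
            "age_correlation": ms.age_correlation,
            "sign_flipped": ms.sign_flipped,
            "bootstrap_ratios": dict(
                zip(ms.x_names, ms.bootstrap.bootstrap_ratio.tolist())
            ),
        }
        if ms.significant:
            scores[tract] = ms
            log.info("%s maturity: LV p=%.4f, corr(score, age)=%.3f",
                     tract, ms.lv_p_value, ms.age_correlation)
        else:
            log.info("%s maturity: LV p=%.4f — excluded from maturity-memory "
                     "stage", tract, ms.lv_p_value)
    return scores, report


@_stage("maturity-em")
def _association_stage(scores, cohort, config: RunConfig) -> list:
    if not scores:
        log.warning("no tract passed the age-PLSC stage; association skipped")
        return []
    return maturity_em_association(
        scores, cohort, alpha=config.alpha, bf_method=config.bf_method,
        bf_kappa=config.bf_kappa, joint_family=config.fdr_joint_family,
    )


@_stage("age-group-interaction")
def _interaction_stage(scores, cohort, config: RunConfig) -> list:
    beh = cohort.data.set_index("subject_id")
    out = []
    for tract, ms in scores.items():
        age = beh.loc[ms.subject_ids, "age"].to_numpy(float)
        for score in EM_SCORES:
            em = beh.loc[ms.subject_ids, score].to_numpy(float)
            out.append(
                age_group_interaction(ms, em, age, cutoff=config.age_cutoff,
                                      behavior=score)
            )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report files; returns the report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        cohort, metrics = simulate(config, out_dir)
    else:
        if not (config.cohort_path and config.metrics_path):
            raise ValueError("cohort_path and metrics_path required unless simulating")
        cohort = load_cohort(config.cohort_path, tab=config.tab)
        metrics = load_metrics(config.metrics_path, tab=config.tab)
        if cohort.rejected:
            log.warning("rejected cohort rows: %s", cohort.rejected)

    uni = _univariate_stage(cohort, metrics)
    em_plsc = _em_plsc_stage(cohort, metrics, config, config.seed)
    scores, maturity_report = _maturity_stage(cohort, metrics, config, config.seed + 1000)
    assoc = _association_stage(scores, cohort, config)
    interactions = _interaction_stage(scores, cohort, config)

    report = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "n_perm": config.n_perm,
            "n_boot": config.n_boot,
            "alpha": config.alpha,
            "bf_method": config.bf_method,
            "age_cutoff": config.age_cutoff,
            "config_hash": config.digest(),
        },
        "univariate": {
            "em_age_regressions": uni["em_age_regressions"],
        },
        "em_plsc": em_plsc,
        "maturity": maturity_report,
        "associations": [
            {
                "tract": a.tract, "behavior": a.behavior, "panel": a.panel,
                "r": a.r, "p_raw": a.p_raw, "p_fdr": a.p_fdr,
                "bf10": a.bf10, "n": a.n,
            }
            for a in assoc
        ],
        "interactions": [
            {
                "tract": it.tract, "behavior": it.behavior, "cutoff": it.cutoff,
                "slope_young": it.slope_young, "slope_old": it.slope_old,
                "interaction_coefficient": it.interaction_coefficient,
                "interaction_p": it.interaction_p,
                "n_young": it.n_young, "n_old": it.n_old,
            }
            for it in interactions
        ],
    }
    validate_report(report)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default, sort_keys=True)
        fh.write("\n")
    uni["metric_age_table"].to_csv(out_dir / "table2_analog.tsv", sep="\t", index=False)
    pd.DataFrame(report["associations"]).to_csv(
        out_dir / "associations.tsv", sep="\t", index=False
    )
    _write_maturity_tsv(scores, out_dir / "maturity_scores.tsv")
    for tract, entry in em_plsc.items():
        if "error" in entry:
            continue
        pd.DataFrame(
            {
                "x_name": list(entry["bootstrap_ratios"]),
                "bootstrap_ratio": list(entry["bootstrap_ratios"].values()),
                "reliable": list(entry["reliable"].values()),
            }
        ).to_csv(out_dir / f"plsc_{tract}.tsv", sep="\t", index=False)
    log.info("report written to %s", out_dir / "report.json")
    return report


def _write_maturity_tsv(scores, path) -> None:
    rows = []
    for tract, ms in scores.items():
        for sid, val in zip(ms.subject_ids, ms.score):
            rows.append({"tract": tract, "subject_id": sid, "maturity_score": val})
    pd.DataFrame(rows, columns=["tract", "subject_id", "maturity_score"]).to_csv(
        path, sep="\t", index=False
    )


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


# ---------------------------------------------------------------------------
# Report schema

def _schema_path() -> Path:
    return Path(__file__).with_name("report_schema.json")


def validate_report(report: dict) -> None:
    """Structural validation against the shipped JSON schema.

    A minimal checker (required keys and primitive types, one level of
    nesting) — the schema document itself is the published contract.
    """
    with open(_schema_path()) as fh:
        schema = json.load(fh)
    _check_object(report, schema, "report")


_TYPES = {
    "object": dict,
    "array": list,
    "number": (int, float, np.floating, np.integer),
    "string": str,
    "boolean": (bool, np.bool_),
    "integer": (int, np.integer),
}


def _check_object(obj, schema, where: str) -> None:
    typ = schema.get("type")
    if typ and not isinstance(obj, _TYPES[typ]):
        raise ValueError(f"{where}: expected {typ}, got {type(obj).__name__}")
    for key in schema.get("required", []):
        if key not in obj:
            raise ValueError(f"{where}: missing required key '{key}'")
    for key, sub in schema.get("properties", {}).items():
        if key in obj:
            _check_object(obj[key], sub, f"{where}.{key}")
    if typ == "array" and "items" in schema:
        for i, item in enumerate(obj):
            _check_object(item, schema["items"], f"{where}[{i}]")
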