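"""Run configuration and report-bundle assembly.

A run is described by a :class:`RunConfig` (YAML or JSON): pathway
thresholds, exactly one cohort source (the deterministic fixture or
generator parameters with a mandatory seed), the cost scenarios to
tabulate, and the confidence level.  A run writes a fixed bundle of CSV
reports plus a machine-readable manifest sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alvarado import RiskThresholds
from .cohort import CohortParams, build_fixture_cohort, generate_cohort, write_cohort
from .costs import PAPER_SCENARIOS, CostScenario, proportions_from_traces, scenario_saving, total_cost
from .diagnostics import (
    KNOWN_DISCREPANCIES,
    clopper_pearson,
    cohort_rates,
    confusion_from_traces,
    performance,
    round_half_up,
)
from .pathway import (
    Disposition,
    PathwayConfig,
    PatientRecord,
    TestResult,
    classify_cost_group,
    run_cohort,
)

__all__ = ["RunConfig", "write_report_bundle"]

log = logging.getLogger("dialapp")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    pathway: PathwayConfig = field(default_factory=PathwayConfig)
    use_fixture: bool = True
    cohort_params: CohortParams | None = None
    ci_level: float = 0.95
    alvarado_classifier_cutoff: int = 7  # standalone-classifier convention, score > cutoff

    def __post_init__(self) -> None:
        if self.use_fixture == (self.cohort_params is not None):
            raise ValueError(
                "exactly one cohort source: set use_fixture or cohort_params, not both"
            )
        if not 0 < self.ci_level < 1:
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        thresholds = RiskThresholds(**data.get("thresholds", {}))
        pathway = PathwayConfig(
            thresholds=thresholds,
            **{
                k: v
                for k, v in data.get("pathway", {}).items()
                if k != "thresholds"
            },
        )
        cohort = data.get("cohort", {"fixture": True})
        if cohort.get("fixture", False):
            use_fixture, params = True, None
        else:
            gen = dict(cohort.get("generator", {}))
            if "seed" not in gen:
                raise ValueError("generator cohort source requires an explicit seed")
            for key in ("component_probs_diseased", "component_probs_healthy"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            use_fixture, params = False, CohortParams(**gen)
        return cls(
            pathway=pathway,
            use_fixture=use_fixture,
            cohort_params=params,
            ci_level=data.get("ci_level", 0.95),
            alvarado_classifier_cutoff=data.get("alvarado_classifier_cutoff", 7),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML parser also accepts JSON
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return {
            "thresholds": dataclasses.asdict(self.pathway.thresholds),
            "pathway": {
                "require_gyn_consult_for_childbearing_females": self.pathway.require_gyn_consult_for_childbearing_females,
                "max_observation_hours": self.pathway.max_observation_hours,
            },
            "cohort": (
                {"fixture": True}
                if self.use_fixture
                else {
                    "generator": {
                        k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in dataclasses.asdict(self.cohort_params).items()
                    }
                }
            ),
            "ci_level": self.ci_level,
            "alvarado_classifier_cutoff": self.alvarado_classifier_cutoff,
        }

    def build_cohort(self) -> list[PatientRecord]:
        if self.use_fixture:
            return build_fixture_cohort()
        return generate_cohort(self.cohort_params)


def _metric_rows(name: str, report) -> list[dict]:
    rows = []
    for metric, m in report.metrics().items():
        rows.append(
            {
                "instrument": name,
                "metric": metric,
                "estimate_pct": m.rounded(1),
                "ci_low_pct": None if m.ci_low_pct is None else round_half_up(m.ci_low_pct, 1),
                "ci_high_pct": None if m.ci_high_pct is None else round_half_up(m.ci_high_pct, 1),
                "numerator": m.k,
                "denominator": m.n,
            }
        )
    return rows


def write_report_bundle(config: RunConfig, out_dir) -> dict:
    """Run the pathway on the configured cohort and write the bundle.

    Writes cohort.csv, traces.csv, traces.json, performance.csv,
    rates.csv, costs.csv, flow.csv, manifest.json (and recovery.csv for
    generated cohorts).  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for note in KNOWN_DISCREPANCIES:
        log.warning("known source discrepancy: %s", note)

    records = config.build_cohort()
    write_cohort(records, out / "cohort.csv")
    traces, summary = run_cohort(records, config.pathway)

    trace_rows = []
    for t in traces:
        group, setting = classify_cost_group(t)
        trace_rows.append(
            {
                "patient_id": t.patient_id,
                "score": t.score,
                "disposition": t.disposition.value,
                "surgery_trigger": t.surgery_trigger.value,
                "observed": t.observed,
                "tests": "+".join(sorted(t.tests_performed)),
                "imaging_label": t.imaging_label or "",
                "cost_group": group.value,
                "care_setting": setting.value,
            }
        )
    pd.DataFrame(trace_rows).to_csv(out / "traces.csv", index=False)
    with open(out / "traces.json", "w") as fh:
        json.dump(
            [
                {
                    "patient_id": t.patient_id,
                    "events": [dataclasses.asdict(e) for e in t.events],
                    "disposition": t.disposition.value,
                    "surgery_trigger": t.surgery_trigger.value,
                    "observed": t.observed,
                }
                for t in traces
            ],
            fh,
            indent=1,
        )

    pd.DataFrame([dataclasses.asdict(summary)]).to_csv(out / "flow.csv", index=False)

    perf_rows = []
    for name, rule in [
        ("diagnostic_algorithm", "pathway_surgery"),
        ("ultrasound", "us_positive"),
        ("ct", "ct_positive"),
        (
            f"alvarado_gt{config.alvarado_classifier_cutoff}",
            ("score_gt", config.alvarado_classifier_cutoff),
        ),
    ]:
        cm = confusion_from_traces(traces, records, rule)
        if cm.n == 0:
            continue
        perf_rows += _metric_rows(name, performance(cm, config.ci_level))
    pd.DataFrame(perf_rows).to_csv(out / "performance.csv", index=False)

    rates = cohort_rates(traces, records)
    rate_rows = [
        {"rate": "negative_appendectomy", "pct": rates.nar_pct,
         "numerator": rates.counts["negative_appendectomies"], "denominator": rates.counts["operated"]},
        {"rate": "perforation", "pct": rates.perforation_pct,
         "numerator": rates.counts["perforated"], "denominator": rates.counts["operated"]},
        {"rate": "ct", "pct": rates.ct_rate_pct,
         "numerator": rates.counts["ct_performed"], "denominator": rates.counts["n"]},
        {"rate": "appendectomy", "pct": rates.appendectomy_rate_pct,
         "numerator": rates.counts["operated"], "denominator": rates.counts["n"]},
        {"rate": "discharge", "pct": rates.discharge_rate_pct,
         "numerator": rates.counts["discharged"], "denominator": rates.counts["n"]},
        {"rate": "negative_appendectomy_female", "pct": rates.nar_female_pct,
         "numerator": rates.counts["nar_female"], "denominator": rates.counts["female_surgeries"]},
        {"rate": "negative_appendectomy_male", "pct": rates.nar_male_pct,
         "numerator": rates.counts["nar_male"], "denominator": rates.counts["male_surgeries"]},
    ]
    pd.DataFrame(rate_rows).to_csv(out / "rates.csv", index=False)

    cost_rows = []
    scenarios = dict(PAPER_SCENARIOS)
    for mode in ("ALL_PATIENTS", "CT_OR_SURGERY_ONLY"):
        props = proportions_from_traces(traces, mode)
        name = f"cohort_{mode.lower()}"
        scenarios[name] = CostScenario(name=name, proportions=props)
    for name, sc in scenarios.items():
        total = total_cost(sc)
        for key, p in sc.proportions.items():
            cost_rows.append(
                {
                    "scenario": name,
                    "group": key,
                    "proportion": round(p, 6),
                    "unit_cost_eur": sc.unit_costs[key],
                    "subtotal_eur": round(p * sc.unit_costs[key] * sc.n_cases, 2),
                    "total_eur": round(total, 2),
                }
            )
    pd.DataFrame(cost_rows).to_csv(out / "costs.csv", index=False)
    savings = {
        "three_group_pre_minus_pathway_eur": scenario_saving(
            scenarios["three_group_pre_pathway"], scenarios["three_group_pathway"]
        ),
        "four_group_pre_minus_pathway_eur": scenario_saving(
            scenarios["four_group_pre_pathway"], scenarios["four_group_pathway"]
        ),
    }
    pd.DataFrame([savings]).to_csv(out / "savings.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": None if config.use_fixture else config.cohort_params.seed,
        "n_patients": len(records),
        "known_discrepancies": list(KNOWN_DISCREPANCIES),
        "savings_eur": savings,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()

    if not config.use_fixture:
        manifest["parameter_recovery"] = _parameter_recovery(
            records, traces, config
        )
        pd.DataFrame(manifest["parameter_recovery"]).to_csv(
            out / "recovery.csv", index=False
        )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _parameter_recovery(records, traces, config: RunConfig) -> list[dict]:
    """Estimated vs configured test characteristics on a generated cohort.

    Estimates use the full latent results (every patient carries one),
    so they check the generator, not the selective-imaging pathway.
    """
    p = config.cohort_params
    diseased = [r for r in records if r.true_appendicitis]
    healthy = [r for r in records if not r.true_appendicitis]
    rows = []
    for name, configured, k, n in [
        ("prevalence", (p.prevalence if p.disease_given_female is None
                        else p.p_female * p.disease_given_female
                        + (1 - p.p_female) * p.disease_given_male),
         len(diseased), len(records)),
        ("us_sens", p.us_sens,
         sum(r.us_latent is TestResult.POSITIVE for r in diseased), len(diseased)),
        ("us_spec", p.us_spec,
         sum(r.us_latent is not TestResult.POSITIVE for r in healthy), len(healthy)),
        ("ct_sens", p.ct_sens,
         sum(r.ct_latent is TestResult.POSITIVE for r in diseased), len(diseased)),
        ("ct_spec", p.ct_spec,
         sum(r.ct_latent is not TestResult.POSITIVE for r in healthy), len(healthy)),
    ]:
        if n == 0:
            continue
        low, high = clopper_pearson(k, n, config.ci_level)
        rows.append(
            {
                "parameter": name,
                "configured": round(configured, 6),
                "estimate": round(k / n, 6),
                "ci_low": round(low / 100.0, 6),
                "ci_high": round(high / 100.0, 6),
                "numerator": k,
                "denominator": n,
            }
        )
    return rows
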