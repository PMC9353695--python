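"""End-to-end orchestration: simulate -> ingest -> reconcile -> score -> evaluate."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import custody, evaluation, features, ingestion, risk, synthetic_hospital
from .risk import RiskParams
from .synthetic_hospital import GroundTruth, SimConfig


@dataclass
class PipelineResult:
    truth: GroundTruth
    ledger: pd.DataFrame
    rejects: pd.DataFrame
    unmapped: pd.DataFrame
    pain_scores: pd.DataFrame
    custody: custody.CustodyResult
    discrepancies: pd.DataFrame
    offclock: pd.DataFrame
    offclock_skipped: pd.DataFrame
    features: pd.DataFrame
    model: risk.RiskModel
    report: risk.EvalReport
    assessments: pd.DataFrame
    roster: pd.DataFrame
    comparisons: pd.DataFrame
    aggregates: evaluation.AggregateReport


def run_pipeline(
    config: SimConfig,
    workdir: str | Path,
    params: RiskParams | None = None,
    grace_minutes: float = custody.DEFAULT_GRACE_MINUTES,
    roster_lag_days: tuple[float, float] = (10, 30),
) -> PipelineResult:
    """Run the whole analytic chain on a fresh synthetic hospital.

    Writes the extracts under ``workdir`` and returns every intermediate
    artifact.  Deterministic given ``config.seed`` (which also seeds the
    roster lag and, via ``params.seed`` when params is None, the training
    split)."""
    workdir = Path(workdir)
    params = params or RiskParams(seed=config.seed)

    paths, truth = synthetic_hospital.simulate(config, workdir)
    ledger, norm, rejects = ingestion.ingest_directory(workdir)

    cust = custody.link_episodes(ledger)
    disc = custody.reconcile_supply(ledger)
    off, off_skipped = custody.off_clock_events(ledger, grace_minutes)

    formulary = ingestion.FormularyMap.from_csv(workdir / "formulary_map.csv")
    feats = features.from_custody(
        cust, disc, off, ledger,
        pain_scores=norm.pain_scores,
        prn_medications=formulary.prn_analgesic,
    )

    model, report, assessments = risk.run_risk_pipeline(feats, params)

    end_date = config.date_range[1]
    roster = synthetic_hospital.write_known_incident_roster(
        truth, workdir / "roster.csv", lag_days=roster_lag_days,
        seed=config.seed, end_date=end_date)
    comparisons = evaluation.compare_incidents(assessments, roster)
    aggregates = evaluation.aggregate(comparisons)

    return PipelineResult(
        truth=truth, ledger=ledger, rejects=rejects, unmapped=norm.unmapped,
        pain_scores=norm.pain_scores, custody=cust, discrepancies=disc,
        offclock=off, offclock_skipped=off_skipped, features=feats,
        model=model, report=report, assessments=assessments, roster=roster,
        comparisons=comparisons, aggregates=aggregates,
    )
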