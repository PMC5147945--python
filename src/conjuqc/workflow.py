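"""End-to-end orchestration of a stability study.

Glue that runs the whole pipeline on a set of monthly acquisitions:
gate each tube, enforce the minimum-event rule, measure the concurrent
standards tube, refit the MESF calibration at every timepoint, assign
MESF to each conjugate, monitor the standards for instrument drift, and
emit the stability series, rankings and attribution verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fcs_io import EventTable
from .gating import check_min_events, gate_singlets
from .histogram_stats import ChannelStats, population_stats
from .mesf import (
    DriftReport,
    MESFValue,
    fit_calibration,
    measure_standards,
    monitor_standards,
)
from .qc_pipeline import (
    QCConfig,
    QCVerdict,
    StabilitySeries,
    attribute_decline,
    build_stability_series,
    rank_stability,
)
from .synthetic import StudyData


@dataclass
class StabilityAnalysis:
    """Everything the stability pipeline computed for one study."""

    series: dict[str, StabilitySeries]
    drift_report: DriftReport
    calibrations: dict            # month -> MESFCalibrationResult
    stats: dict                   # month -> conjugate id -> ChannelStats
    mesf: dict                    # month -> conjugate id -> MESFValue
    ranking: QCVerdict
    attributions: dict[str, QCVerdict]
    low_event_acquisitions: list = field(default_factory=list)

    def fi_table(self) -> pd.DataFrame:
        """Tidy FI table: one row per (month, conjugate)."""
        rows = [
            {"month": m, "conjugate": cid, "fi": s.geo_mean,
             "cv_percent": s.cv_percent, "n": s.n}
            for m, per in self.stats.items() for cid, s in per.items()
        ]
        return pd.DataFrame(rows)


def analyze_stability_study(
    study: StudyData,
    config: QCConfig | None = None,
    gate_k: float = 4.0,
) -> StabilityAnalysis:
    """Run the full QC pipeline on a (simulated or loaded) stability study."""
    config = config or QCConfig()
    months = study.months
    conjugate_ids = sorted(study.conjugate_tubes[months[0]])
    assigned = {k: v["assigned_mesf"] for k, v in study.ground_truth["standards"].items()}
    reference_gms = {k: v["true_gm"] for k, v in study.ground_truth["standards"].items()}
    blank = study.config.blank_label

    stats: dict = {}
    mesf_by_month: dict = {}
    calibrations: dict = {}
    standards_series = []
    low_events: list = []

    for month in months:
        per_stats: dict[str, ChannelStats] = {}
        for cid in conjugate_ids:
            tube = study.conjugate_tubes[month][cid]
            gate = gate_singlets(tube, k=gate_k)
            if not check_min_events(gate, config.min_events):
                low_events.append((month, cid, gate.n_kept))
            per_stats[cid] = population_stats(tube, gate, "FL2")
        stats[month] = per_stats

        tube, _labels = study.standard_tubes[month]
        measured = measure_standards(tube, assigned, reference_gms, blank)
        standards_series.append((month, measured))
        cal = fit_calibration(measured, fit_date=month)
        calibrations[month] = cal
        mesf_by_month[month] = {
            cid: cal.assign(per_stats[cid].geo_mean, sample_id=cid)
            for cid in conjugate_ids
        }

    drift = monitor_standards(standards_series, tolerance=config.drift_tolerance)

    series: dict[str, StabilitySeries] = {}
    for cid in conjugate_ids:
        series[cid] = build_stability_series(
            cid,
            months,
            [stats[m][cid] for m in months],
            [mesf_by_month[m][cid] for m in months],
            drift_report=drift,
        )
    ranking = rank_stability(list(series.values()))
    attributions = {
        cid: attribute_decline(series[cid], drift, config) for cid in conjugate_ids
    }
    return StabilityAnalysis(
        series=series, drift_report=drift, calibrations=calibrations,
        stats=stats, mesf=mesf_by_month, ranking=ranking,
        attributions=attributions, low_event_acquisitions=low_events,
    )


def single_tube_stats(
    table: EventTable,
    channel: str = "FL2",
    config: QCConfig | None = None,
    gate_k: float = 4.0,
    control: EventTable | None = None,
):
    """Gate one tube and compute its histogram statistics.

    Returns ``(GateResult, ChannelStats, min_events_ok)``.
    """
    config = config or QCConfig()
    gate = gate_singlets(table, k=gate_k)
    ok = check_min_events(gate, config.min_events)
    control_gate = gate_singlets(control, k=gate_k) if control is not None else None
    st = population_stats(
        table, gate, channel, control=control, control_gate=control_gate,
        percentile=config.positivity_percentile,
    )
    return gate, st, ok
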