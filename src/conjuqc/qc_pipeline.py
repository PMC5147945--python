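"""QC decision layer for conjugate-coupled beads.

Implements the decision rules of the bead-conjugate QC protocol:

* concentration/dilution optimization — pick the coupling level that
  maximizes brightness (FI) while coupling homogeneously (minimal CV),
  with a one-way ANOVA across levels attached;
* coupling-homogeneity comparison of the lowest vs. highest level by
  Welch's t-test on replicate CVs;
* long-term stability — time series of FI (and MESF where in range),
  ΔFI = initial - final FI and the percent decrease, with
  instrument-drift-flagged months excluded from trend statements;
* attribution of a fluorescence decline to the instrument (all MESF
  standards moved together) or to the conjugate itself;
* secondary-stain integrity check separating fluorochrome fading (PE
  lost, FITC secondary stain retained) from uncoupling/degradation
  (both lost);
* plain group comparisons (Welch t-test / one-way ANOVA) at α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, SeriesError
from .histogram_stats import ChannelStats
from .mesf import ABOVE_RANGE, DriftReport, MESFValue


@dataclass
class QCConfig:
    """Tunable thresholds of the QC decision rules."""

    alpha: float = 0.05                   # per-comparison significance level
    min_events: int = 2000                # acquisition floor (gated events)
    drift_tolerance: float = 0.10         # relative GM deviation for drift flags
    positivity_percentile: float = 99.0   # control percentile for percent-positive
    pe_fade_threshold: float = 0.50       # PE retention below this = faded
    fitc_retention_threshold: float = 0.75  # FITC retention at/above this = antibody present
    cv_conflict_slack: float = 0.15       # relative CV excess tolerated before flagging
    pooled_ttest: bool = False            # pooled-variance t instead of Welch
    holm_correction: bool = False         # off by default: per-comparison alpha
    channel_map: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.min_events < 1:
            raise ConfigurationError("min_events must be >= 1")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a group-comparison test."""

    method: str
    statistic: float
    p_value: float
    significant: bool
    flags: tuple[str, ...] = ()


@dataclass
class QCVerdict:
    """Categorical outcome of one decision rule with its supporting numbers."""

    subject: str
    rule: str           # concentration_choice | homogeneity | stability_rank |
                        # decline_attribution | stain_integrity
    verdict: str
    evidence: dict
    p_values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ConfigurationError("a QC verdict must carry evidence")
        for name, p in self.p_values.items():
            if not (0 < p <= 1 or np.isnan(p)):
                raise ConfigurationError(f"invalid p-value for {name!r}: {p}")


@dataclass
class StabilitySeries:
    """Time course of one conjugate's fluorescence with stability metrics.

    ``delta_fi`` and ``pct_decrease`` are computed from the first and last
    NON-excluded timepoints; ``delta_fi_raw`` keeps the full-span value for
    reference.  ``excluded_timepoints`` lists drift-flagged months omitted
    from trend statements.
    """

    conjugate_id: str
    timepoints: list
    fi: list[float]
    mesf: list[MESFValue | None]
    delta_fi: float
    pct_decrease: float
    excluded_timepoints: list
    delta_fi_raw: float
    pct_decrease_raw: float
    fi_only: bool              # True when MESF was never evaluable (too bright)

    @property
    def initial_fi(self) -> float:
        return self.fi[0]

    def mesf_series(self) -> list[tuple[object, float]]:
        """(timepoint, MESF) pairs restricted to in-range assignments."""
        return [
            (t, m.mesf) for t, m in zip(self.timepoints, self.mesf)
            if m is not None and m.evaluable
        ]


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def compare_groups(
    groups: Sequence[Sequence[float]],
    method: str = "t_test",
    config: QCConfig | None = None,
) -> TestResult:
    """Welch t-test (2 groups) or one-way ANOVA (>= 2 groups) with p-value."""
    config = config or QCConfig()
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ConfigurationError("each group needs n >= 2")
    flags: list[str] = []
    if method == "t_test":
        if len(arrays) != 2:
            raise ConfigurationError("t_test requires exactly 2 groups")
        a, b = arrays
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                return TestResult("t_test", float("nan"), float("nan"), False,
                                  ("undefined_zero_variance",))
            flags.append("zero_variance")
        stat, p = sps.ttest_ind(a, b, equal_var=config.pooled_ttest)
    elif method == "anova":
        if len(arrays) < 2:
            raise ConfigurationError("anova requires >= 2 groups")
        if all(a.std(ddof=1) == 0 for a in arrays):
            means = {float(a.mean()) for a in arrays}
            if len(means) == 1:
                return TestResult("anova", float("nan"), float("nan"), False,
                                  ("undefined_zero_variance",))
            flags.append("zero_variance")
        stat, p = sps.f_oneway(*arrays)
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    stat, p = float(stat), float(p)
    if np.isnan(p):
        flags.append("undefined_test")
        return TestResult(method, stat, p, False, tuple(flags))
    return TestResult(method, stat, p, p <= config.alpha, tuple(flags))


# ---------------------------------------------------------------------------
# concentration / dilution optimization
# ---------------------------------------------------------------------------

def optimize_concentration(
    panel: dict[object, Sequence[ChannelStats]],
    config: QCConfig | None = None,
    subject: str = "",
) -> QCVerdict:
    """Choose the coupling concentration/dilution level.

    ``panel`` maps each level (ascending concentration order, e.g.
    ``{0.5: [...], 1: [...], 2.5: [...], 5: [...]}`` or ordinal dilution
    strings) to its replicate :class:`ChannelStats`.  The chosen level
    maximizes mean FI while its mean CV is compatible with the panel
    minimum; FI ties break toward the lower level.  When FI and CV point
    to clearly different levels the verdict flags the conflict instead of
    silently choosing; when the ANOVA across levels is not significant no
    level is preferred and the lowest is the default.
    """
    config = config or QCConfig()
    levels = list(panel.keys())
    if len(levels) < 2:
        raise ConfigurationError("concentration optimization needs >= 2 levels")
    if any(len(panel[lv]) < 2 for lv in levels):
        raise ConfigurationError("each level needs >= 2 replicates")

    fi = {lv: [s.geo_mean for s in panel[lv]] for lv in levels}
    cv = {lv: [s.cv_percent for s in panel[lv]] for lv in levels}
    mean_fi = {lv: float(np.mean(fi[lv])) for lv in levels}
    mean_cv = {lv: float(np.nanmean(cv[lv])) for lv in levels}

    anova = compare_groups([fi[lv] for lv in levels], "anova", config)
    evidence = {
        "mean_fi": mean_fi,
        "mean_cv": mean_cv,
        "fi_order": sorted(levels, key=lambda lv: mean_fi[lv]),
        "cv_order": sorted(levels, key=lambda lv: mean_cv[lv]),
    }
    p_values = {"anova_fi": anova.p_value} if not np.isnan(anova.p_value) else {}

    if not anova.significant:
        return QCVerdict(subject, "concentration_choice", "no level preferred",
                         {**evidence, "choice": levels[0]}, p_values)

    best_fi = max(mean_fi.values())
    # FI ties (within float fuzz) break toward the lower concentration.
    choice = next(lv for lv in levels if mean_fi[lv] >= best_fi * (1 - 1e-12))
    min_cv = min(mean_cv.values())
    if mean_cv[choice] > min_cv * (1.0 + config.cv_conflict_slack):
        return QCVerdict(
            subject, "concentration_choice", "fi_cv_conflict",
            {**evidence, "fi_choice": choice,
             "cv_choice": evidence["cv_order"][0]},
            p_values,
        )
    return QCVerdict(subject, "concentration_choice", "optimal",
                     {**evidence, "choice": choice}, p_values)


def compare_cv(
    cv_low: Sequence[float],
    cv_high: Sequence[float],
    config: QCConfig | None = None,
    subject: str = "",
) -> QCVerdict:
    """Homogeneity comparison of the lowest vs. highest coupling level.

    Welch's t-test on replicate CVs; the high level is "more homogeneous"
    iff its mean CV is lower and the difference is significant.
    """
    config = config or QCConfig()
    test = compare_groups([cv_low, cv_high], "t_test", config)
    mlo, mhi = float(np.mean(cv_low)), float(np.mean(cv_high))
    evidence = {"mean_cv_low": mlo, "mean_cv_high": mhi,
                "direction": "high_lower" if mhi < mlo else "high_not_lower"}
    if "undefined_zero_variance" in test.flags:
        return QCVerdict(subject, "homogeneity", "indistinguishable", evidence)
    p_values = {"t_test_cv": test.p_value}
    if mhi < mlo and test.significant:
        verdict = "more homogeneous at high concentration"
    elif test.significant:
        verdict = "more homogeneous at low concentration"
    else:
        verdict = "not significantly different"
    return QCVerdict(subject, "homogeneity", verdict, evidence, p_values)


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

def build_stability_series(
    conjugate_id: str,
    timepoints: Sequence,
    stats: Sequence[ChannelStats],
    mesf_values: Sequence[MESFValue | None] | None = None,
    drift_report: DriftReport | None = None,
    exclude_drift: bool = True,
) -> StabilitySeries:
    """Assemble one conjugate's stability time course.

    ΔFI and the percent decrease use the first and last non-excluded
    timepoints (months flagged as instrument drift are excluded when
    ``exclude_drift``); the raw full-span values are kept alongside.
    """
    timepoints = list(timepoints)
    if len(timepoints) < 2:
        raise SeriesError("stability series needs >= 2 timepoints")
    if len(stats) != len(timepoints):
        raise SeriesError("one ChannelStats required per timepoint")
    fi = [s.geo_mean for s in stats]
    mesf = list(mesf_values) if mesf_values is not None else [None] * len(timepoints)
    if len(mesf) != len(timepoints):
        raise SeriesError("one MESF value (or None) required per timepoint")

    excluded = []
    if exclude_drift and drift_report is not None:
        excluded = [t for t in timepoints if drift_report.is_flagged(t)]
    usable = [i for i, t in enumerate(timepoints) if t not in excluded]
    if len(usable) < 2:
        raise SeriesError(
            f"{conjugate_id}: fewer than 2 non-excluded timepoints remain"
        )
    first, last = usable[0], usable[-1]
    delta = fi[first] - fi[last]
    pct = 100.0 * delta / fi[first]
    delta_raw = fi[0] - fi[-1]
    pct_raw = 100.0 * delta_raw / fi[0]
    fi_only = all(m is None or m.range_flag == ABOVE_RANGE for m in mesf)
    return StabilitySeries(
        conjugate_id=conjugate_id, timepoints=timepoints, fi=fi, mesf=mesf,
        delta_fi=delta, pct_decrease=pct, excluded_timepoints=excluded,
        delta_fi_raw=delta_raw, pct_decrease_raw=pct_raw, fi_only=fi_only,
    )


def rank_stability(series_set: Sequence[StabilitySeries],
                   subject: str = "panel") -> QCVerdict:
    """Rank conjugates by stability (ascending ΔFI) and brightness (initial FI).

    Stability and brightness are distinct rankings — the brightest
    conjugate need not be the most stable — so both are reported.
    Conjugates whose MESF was never evaluable carry an "FI-only"
    provenance tag.  Mismatched time spans yield a comparability warning
    but the ranking is still produced.
    """
    if len(series_set) < 2:
        raise ConfigurationError("stability ranking needs >= 2 series")
    spans = {(s.timepoints[0], s.timepoints[-1]) for s in series_set}
    warnings = [] if len(spans) == 1 else [
        "comparability warning: series cover different timepoint spans"
    ]
    by_stability = sorted(series_set, key=lambda s: s.delta_fi)
    by_brightness = sorted(series_set, key=lambda s: -s.initial_fi)
    deltas = {s.conjugate_id: s.delta_fi for s in series_set}
    ties = len(set(deltas.values())) < len(deltas)
    evidence = {
        "delta_fi": deltas,
        "pct_decrease": {s.conjugate_id: s.pct_decrease for s in series_set},
        "initial_fi": {s.conjugate_id: s.initial_fi for s in series_set},
        "stability_order": [s.conjugate_id for s in by_stability],
        "brightness_order": [s.conjugate_id for s in by_brightness],
        "fi_only": [s.conjugate_id for s in series_set if s.fi_only],
        "warnings": warnings,
    }
    verdict = "tie" if ties else f"most stable: {by_stability[0].conjugate_id}"
    return QCVerdict(subject, "stability_rank", verdict, evidence)


def attribute_decline(
    series: StabilitySeries,
    drift_report: DriftReport,
    config: QCConfig | None = None,
) -> QCVerdict:
    """Attribute each timepoint's fluorescence change and the overall trend.

    A timepoint where the conjugate deviates from baseline beyond the
    drift tolerance is labelled "instrument" only when the standards drift
    flag is set for that month (all standards moved together); otherwise
    "conjugate".  The overall verdict is a "true conjugate decrease" iff
    the first-vs-last decline persists using only non-flagged timepoints.
    """
    config = config or QCConfig()
    overlap = [t for t in series.timepoints if t in drift_report.deviations.index]
    if not overlap:
        raise SeriesError("no overlapping timepoints between conjugate and standards")
    tol = config.drift_tolerance
    base = series.fi[0]
    labels = {}
    for t, value in zip(series.timepoints, series.fi):
        dev = (value - base) / base
        if abs(dev) <= tol:
            labels[t] = "stable"
        elif drift_report.is_flagged(t):
            labels[t] = "instrument"
        else:
            labels[t] = "conjugate"

    usable = [
        (t, v) for t, v in zip(series.timepoints, series.fi)
        if not drift_report.is_flagged(t)
    ]
    if len(usable) < 2:
        raise SeriesError("fewer than 2 non-flagged timepoints for attribution")
    (t0, v0), (t1, v1) = usable[0], usable[-1]
    decline = (v0 - v1) / v0
    overall = "true conjugate decrease" if decline > tol else "no true decrease"
    return QCVerdict(
        series.conjugate_id, "decline_attribution", overall,
        {
            "per_timepoint": labels,
            "first_last": {"t0": t0, "t1": t1, "fi0": v0, "fi1": v1},
            "decline_fraction": decline,
            "flagged_months": list(drift_report.flagged),
        },
    )


# ---------------------------------------------------------------------------
# secondary-stain integrity
# ---------------------------------------------------------------------------

def stain_integrity_check(
    pe: tuple[float, float],
    fitc: tuple[float, float],
    config: QCConfig | None = None,
    subject: str = "",
) -> QCVerdict:
    """Separate fluorochrome fading from uncoupling after light/RT exposure.

    ``pe`` and ``fitc`` are (protected FI, exposed FI) pairs: the PE
    reporter read directly, and a FITC secondary stain against the coupled
    antibody.  Lost PE with retained FITC means the fluorochrome faded but
    the antibody is still on the bead; losing the FITC signal means the
    antibody itself is gone (uncoupling/degradation) regardless of PE.
    """
    config = config or QCConfig()
    for name, (prot, exposed) in (("PE", pe), ("FITC", fitc)):
        if prot <= 0 or exposed <= 0:
            raise ValueError(f"{name} intensities must be > 0")
    pe_ret = pe[1] / pe[0]
    fitc_ret = fitc[1] / fitc[0]
    if fitc_ret < config.fitc_retention_threshold:
        verdict = "uncoupling/degradation"
    elif pe_ret < config.pe_fade_threshold:
        verdict = "fluorochrome fading"
    else:
        verdict = "stable"
    return QCVerdict(
        subject, "stain_integrity", verdict,
        {
            "pe_retention": pe_ret, "fitc_retention": fitc_ret,
            "pe_protected": pe[0], "pe_exposed": pe[1],
            "fitc_protected": fitc[0], "fitc_exposed": fitc[1],
            "pe_fade_threshold": config.pe_fade_threshold,
            "fitc_retention_threshold": config.fitc_retention_threshold,
        },
    )
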