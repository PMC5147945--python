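"""Quantitative fluorescence cytometry (QFCM) via MESF calibration.

An MESF standard set — four fluorescent bead populations with certified
MESF assignments (molecules of equivalent soluble fluorochrome) plus a
certified blank — is acquired alongside every sample tube.  The
calibration model is ordinary least squares on the log-log scale,

    log10(MESF) = slope * log10(GM) + intercept,

fitted over the non-blank standards; the blank is excluded from the fit
and defines the lower detection limit, while the brightest standard's
geometric mean defines the upper limit.  Samples brighter than the top
standard receive an extrapolated MESF but are hard-flagged non-evaluable:
downstream stability statements must fall back to raw fluorescence
intensity for them.

Because the standards travel through every acquisition, their geometric
means over time also monitor the *instrument*: a sensitivity change moves
all standards together, which is the attribution criterion used by
:func:`monitor_standards`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CalibrationError, SeriesError
from .fcs_io import EventTable
from .gating import code_bounds_from_references
from .histogram_stats import geometric_mean

IN_RANGE = "in_range"
BELOW_BLANK = "below_blank"
ABOVE_RANGE = "above_range"


@dataclass(frozen=True)
class Standard:
    """One calibration bead population: certified MESF + measured GM."""

    label: str
    assigned_mesf: float
    geo_mean: float


@dataclass
class MESFStandardSet:
    """Ordered MESF standard populations including the certified blank."""

    populations: list[Standard]
    blank_label: str

    def __post_init__(self) -> None:
        labels = [p.label for p in self.populations]
        if labels.count(self.blank_label) != 1:
            raise CalibrationError(
                f"exactly one blank population required (blank_label={self.blank_label!r})"
            )
        blank = self.blank
        others = self.non_blank
        if others and blank.assigned_mesf >= min(p.assigned_mesf for p in others):
            raise CalibrationError("blank must carry the smallest assigned MESF")
        mesf = [p.assigned_mesf for p in others]
        gms = [p.geo_mean for p in others]
        if any(b <= a for a, b in zip(mesf, mesf[1:])) or \
                any(b <= a for a, b in zip(gms, gms[1:])):
            raise CalibrationError(
                "non-blank standards must be strictly increasing in both "
                "assigned MESF and measured geometric mean"
            )

    @property
    def blank(self) -> Standard:
        return next(p for p in self.populations if p.label == self.blank_label)

    @property
    def non_blank(self) -> list[Standard]:
        return [p for p in self.populations if p.label != self.blank_label]


@dataclass(frozen=True)
class MESFValue:
    """MESF assignment for one sample with its calibration-range flag."""

    sample_id: str
    mesf: float
    range_flag: str  # IN_RANGE | BELOW_BLANK | ABOVE_RANGE

    @property
    def evaluable(self) -> bool:
        """Usable in MESF-based statements (above-range samples are not)."""
        return self.range_flag == IN_RANGE


class MESFCalibration:
    """Calibration model: log10(MESF) ~ log10(GM) over non-blank standards.

    Usage follows the model/results idiom::

        result = MESFCalibration(standards).fit()
        value = result.assign(sample_gm, sample_id="A1")

    At least two non-blank standards with distinct geometric means are
    required; the fit is a deterministic ordinary least squares.
    """

    def __init__(self, standards: MESFStandardSet):
        self.standards = standards
        usable = standards.non_blank
        if len(usable) < 2 or len({p.geo_mean for p in usable}) < 2:
            raise CalibrationError(
                "calibration requires >= 2 non-blank standards with distinct GMs"
            )

    def fit(self, fit_date=None) -> "MESFCalibrationResult":
        pops = self.standards.non_blank
        x = np.log10([p.geo_mean for p in pops])
        y = np.log10([p.assigned_mesf for p in pops])
        if len(pops) == 2:
            slope = (y[1] - y[0]) / (x[1] - x[0])
            intercept = y[0] - slope * x[0]
            r_squared = 1.0
            stderr = float("nan")
        else:
            fit = sps.linregress(x, y)
            slope, intercept = float(fit.slope), float(fit.intercept)
            r_squared = float(fit.rvalue) ** 2
            stderr = float(fit.stderr)
        if slope <= 0:
            raise CalibrationError(f"non-positive calibration slope ({slope:.4g})")
        blank_gm = self.standards.blank.geo_mean
        lower = 10 ** (slope * np.log10(blank_gm) + intercept) if blank_gm > 0 else 0.0
        return MESFCalibrationResult(
            model=self,
            slope=slope,
            intercept=intercept,
            r_squared=r_squared,
            slope_stderr=stderr,
            lower_limit_mesf=float(lower),
            upper_limit_gm=float(pops[-1].geo_mean),
            fit_date=fit_date,
        )


@dataclass
class MESFCalibrationResult:
    """Fitted calibration line with detection limits."""

    model: MESFCalibration
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    lower_limit_mesf: float
    upper_limit_gm: float
    fit_date: object = None

    def predict(self, sample_gm) -> np.ndarray:
        """MESF for geometric mean(s) on the fitted line (no range logic)."""
        gm = np.asarray(sample_gm, dtype=float)
        return 10 ** (self.slope * np.log10(gm) + self.intercept)

    def assign(self, sample_gm: float, sample_id: str = "") -> MESFValue:
        """Assign an MESF value with its range flag.

        Above-range samples (GM brighter than the top standard) are still
        reported numerically but flagged non-evaluable; below-blank samples
        are flagged analogously against the blank-derived lower limit.
        """
        if sample_gm <= 0:
            raise ValueError("sample geometric mean must be > 0")
        mesf = float(self.predict(sample_gm))
        if sample_gm > self.upper_limit_gm:
            flag = ABOVE_RANGE
        elif mesf < self.lower_limit_mesf:
            flag = BELOW_BLANK
        else:
            flag = IN_RANGE
        return MESFValue(sample_id=sample_id, mesf=mesf, range_flag=flag)

    def summary(self) -> str:
        lines = [
            "MESF calibration (OLS, log10 MESF ~ log10 GM, blank excluded)",
            "-" * 62,
            f"standards (non-blank): {len(self.model.standards.non_blank)}",
            f"slope:                 {self.slope:.6g}",
            f"intercept:             {self.intercept:.6g}",
            f"R-squared:             {self.r_squared:.6g}",
            f"lower limit (MESF):    {self.lower_limit_mesf:.6g}",
            f"upper limit (GM):      {self.upper_limit_gm:.6g}",
        ]
        if self.fit_date is not None:
            lines.append(f"fit date:              {self.fit_date}")
        return "\n".join(lines)


def fit_calibration(standards: MESFStandardSet, fit_date=None) -> MESFCalibrationResult:
    """Functional wrapper: fit the log-log calibration for one standard set."""
    return MESFCalibration(standards).fit(fit_date=fit_date)


def assign_mesf(result: MESFCalibrationResult, sample_gm: float,
                sample_id: str = "") -> MESFValue:
    """Functional wrapper around :meth:`MESFCalibrationResult.assign`."""
    return result.assign(sample_gm, sample_id=sample_id)


def measure_standards(
    tube: EventTable,
    assigned: dict[str, float],
    reference_gms: dict[str, float],
    blank_label: str,
    channel: str = "FL2",
) -> MESFStandardSet:
    """Measure an acquired standards tube into an :class:`MESFStandardSet`.

    The five populations are mixed in one tube; they are separated on the
    reporter channel by disjoint intervals at the log-space midpoints of
    the per-population reference geometric means, then each population's
    GM is measured from its events.
    """
    bounds = code_bounds_from_references(reference_gms)
    values = tube.channel(channel)
    pops = []
    for label in sorted(assigned, key=lambda k: assigned[k]):
        lo, hi = bounds[label]
        sel = values[(values >= lo) & (values < hi)]
        if sel.size == 0:
            raise CalibrationError(f"standards tube: no events for population {label!r}")
        pops.append(Standard(label, assigned[label], geometric_mean(sel)))
    return MESFStandardSet(populations=pops, blank_label=blank_label)


# ---------------------------------------------------------------------------
# instrument monitoring from the standards time series
# ---------------------------------------------------------------------------

@dataclass
class DriftReport:
    """Per-timepoint instrument-drift assessment from the standards series.

    ``deviations`` holds the relative deviation ``(GM_t - GM_0)/GM_0`` of
    each standard at each timepoint; a timepoint is flagged as instrument
    drift only when every non-blank standard moves in the same direction
    beyond the tolerance — a coherent shift of all standards is the
    signature of a sensitivity change in the instrument, not of any one
    bead lot.
    """

    deviations: pd.DataFrame          # index = timepoint, columns = standards
    flagged: list                     # timepoints attributed to the instrument
    warnings: dict                    # timepoint -> message (inconsistent standards)
    first_last_diff: dict             # standard label -> GM_first - GM_last
    tolerance: float

    def is_flagged(self, timepoint) -> bool:
        return timepoint in self.flagged


def monitor_standards(
    series: Sequence[tuple[object, MESFStandardSet]],
    tolerance: float = 0.10,
) -> DriftReport:
    """Assess instrument drift from time-ordered standards measurements.

    ``series`` is ``[(timepoint, MESFStandardSet), ...]`` with identical
    standard labels throughout; the first entry is the baseline.  A
    timepoint is flagged "instrument drift" when the relative deviation of
    ALL non-blank standards from baseline exceeds ``tolerance`` in the same
    direction; a lone deviating standard raises a warning instead.
    """
    if len(series) < 2:
        raise SeriesError("standards monitoring needs >= 2 timepoints")
    base_t, base = series[0]
    labels = [p.label for p in base.non_blank]
    rows, flagged, warnings = {}, [], {}
    for t, s in series:
        if [p.label for p in s.non_blank] != labels:
            raise SeriesError(
                f"standards label mismatch at timepoint {t!r} (expected {labels})"
            )
        dev = {
            p.label: (p.geo_mean - b.geo_mean) / b.geo_mean
            for p, b in zip(s.non_blank, base.non_blank)
        }
        rows[t] = dev
        d = np.array([dev[label] for label in labels])
        beyond = np.abs(d) > tolerance
        if beyond.all() and (np.all(d > 0) or np.all(d < 0)):
            flagged.append(t)
        elif beyond.any():
            off = [label for label, b in zip(labels, beyond) if b]
            warnings[t] = (
                f"inconsistent standards: {off} beyond {tolerance:.0%} "
                "while others are stable (not attributed to the instrument)"
            )
    last = series[-1][1]
    diffs = {
        p.label: b.geo_mean - p.geo_mean
        for p, b in zip(last.non_blank, base.non_blank)
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")[labels]
    return DriftReport(
        deviations=frame, flagged=flagged, warnings=warnings,
        first_last_diff=diffs, tolerance=tolerance,
    )
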