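"""Traditional flow-cytometry statistics for a gated population.

Three parameters summarise a fluorescence histogram in bead-based QC:

* the geometric mean (FI) of the linear intensities — the brightness of
  the reporter;
* the coefficient of variation, ``CV% = 100 * SD / mean`` on the linear
  scale — the homogeneity of the coupling (narrow peak = low CV);
* the percent positive — the fraction of events above a positivity
  threshold, by default the 99th percentile of an uncoupled-bead control.

All statistics are computed on linear relative fluorescence, matching the
convention of the instrument-vendor analysis software the protocol's CV
and FI values correspond to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedStatisticError
from .fcs_io import EventTable
from .gating import GateResult

#: Fraction of non-positive events above which the GM is flagged as suspect.
NONPOSITIVE_FLAG_FRACTION = 0.01


@dataclass
class ChannelStats:
    """Summary statistics for one gated population on one channel."""

    channel: str
    n: int
    geo_mean: float
    arith_mean: float
    sd: float
    cv_percent: float          # NaN when undefined (n < 2); see flags
    pct_positive: float        # NaN when no threshold was supplied
    threshold: float | None = None
    n_nonpositive: int = 0     # events excluded from the geometric mean
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "channel", "n", "geo_mean", "arith_mean", "sd",
            "cv_percent", "pct_positive", "threshold", "n_nonpositive",
        )}
        d["flags"] = ";".join(self.flags)
        return d


def geometric_mean(values, policy: str = "exclude") -> float:
    """Geometric mean ``exp(mean(ln v))`` of positive linear intensities.

    ``policy`` controls non-positive values: ``"exclude"`` drops them
    (the count is reported via :func:`population_stats`), ``"error"``
    raises.  Undefined when no positive values remain.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise UndefinedStatisticError("geometric mean of an empty sample")
    pos = v > 0
    if not pos.all():
        if policy == "error":
            raise UndefinedStatisticError(
                f"geometric mean undefined: {int((~pos).sum())} non-positive values"
            )
        v = v[pos]
    if v.size == 0:
        raise UndefinedStatisticError(
            "geometric mean undefined: all values non-positive"
        )
    return float(np.exp(np.mean(np.log(v))))


def cv_percent(values) -> float:
    """Coefficient of variation, ``100 * SD / mean`` (SD with n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise UndefinedStatisticError("CV requires at least 2 events")
    mean = float(np.mean(v))
    if mean <= 0:
        raise UndefinedStatisticError("CV undefined: non-positive mean")
    return 100.0 * float(np.std(v, ddof=1)) / mean


def robust_cv_percent(values) -> float:
    """Robust CV alternative: ``100 * 0.7413 * IQR / median``."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise UndefinedStatisticError("robust CV requires at least 2 events")
    med = float(np.median(v))
    if med <= 0:
        raise UndefinedStatisticError("robust CV undefined: non-positive median")
    q1, q3 = np.percentile(v, [25, 75])
    return 100.0 * 0.7413 * float(q3 - q1) / med


def percent_positive(values, threshold: float) -> float:
    """Percent of events strictly above ``threshold`` (linear units)."""
    if threshold <= 0:
        raise ValueError("positivity threshold must be > 0")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise UndefinedStatisticError("percent positive of an empty sample")
    return 100.0 * float(np.count_nonzero(v > threshold)) / v.size


def positivity_threshold(control: EventTable, channel: str = "FL2",
                         percentile: float = 99.0,
                         gate: GateResult | None = None) -> float:
    """Positivity threshold from an uncoupled-bead control population.

    The threshold is the given percentile (default 99th) of the control's
    gated intensities on ``channel``.
    """
    v = control.channel(channel)
    if gate is not None:
        v = v[gate.kept]
    return float(np.percentile(v, percentile))


def population_stats(
    table: EventTable,
    gate: GateResult,
    channel: str = "FL2",
    threshold: float | None = None,
    control: EventTable | None = None,
    control_gate: GateResult | None = None,
    percentile: float = 99.0,
) -> ChannelStats:
    """All three histogram statistics for the gated events of ``channel``.

    The positivity threshold is, in order of precedence: the explicit
    ``threshold``; the ``percentile``-th percentile of the gated control
    (``control``/``control_gate``); otherwise absent and ``pct_positive``
    is NaN.
    """
    if gate.n_kept == 0:
        raise UndefinedStatisticError("population statistics of an empty gate")
    v = table.channel(channel)[gate.kept]
    flags: list[str] = []

    n_nonpos = int(np.count_nonzero(v <= 0))
    gm = geometric_mean(v)
    if n_nonpos > NONPOSITIVE_FLAG_FRACTION * v.size:
        flags.append("gm_excluded_gt_1pct")

    arith = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else float("nan")
    try:
        cv = cv_percent(v)
    except UndefinedStatisticError:
        cv = float("nan")
        flags.append("cv_undefined")

    if threshold is None and control is not None:
        threshold = positivity_threshold(control, channel, percentile, control_gate)
    pct = percent_positive(v, threshold) if threshold is not None else float("nan")

    return ChannelStats(
        channel=channel, n=int(v.size), geo_mean=gm, arith_mean=arith, sd=sd,
        cv_percent=cv, pct_positive=pct, threshold=threshold,
        n_nonpositive=n_nonpos, flags=flags,
    )
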