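"""Singlet bead gating and bead-code classification.

The bead population is selected on the FSC x SSC dot plot with a
deterministic, reproducible stand-in for the usual manual gate: an
axis-aligned box centred on the robust mode of the scatter cloud with
half-widths ``k`` robust standard deviations (scaled MAD) per axis.
The mode seed is the densest bin of a coarse 2D histogram (ties broken
toward the bin closest to the joint median), after which the box is
iterated — centre = per-axis median of the kept events, half-width =
k x 1.4826 x MAD of the kept events — to a fixed point.  The fixed-point
construction makes the gate idempotent and lets it lock onto a single
cluster even when the scatter distribution is multimodal; doublets at
roughly twice the singlet scatter fall far outside the box and are
excluded.

Bead codes are classified by disjoint FL4 intervals; events whose FL4
falls between intervals are labelled ``"unassigned"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GateError
from .fcs_io import EventTable

_MAD_SCALE = 1.4826  # normal-consistency factor for the MAD

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GateResult:
    """Outcome of the singlet scatter gate."""

    kept: np.ndarray                      # sorted event indices inside the gate
    center: tuple[float, float]           # (FSC, SSC) box centre
    halfwidth: tuple[float, float]        # per-axis half-widths, > 0
    method: str = "robust-box"
    k: float = 4.0

    @property
    def n_kept(self) -> int:
        return int(len(self.kept))


@dataclass
class BeadCodeAssignment:
    """Per-event bead-code labels plus the FL4 intervals used."""

    labels: np.ndarray                    # one label per event (or UNASSIGNED)
    code_bounds: dict[str, tuple[float, float]]
    counts: dict[str, int] = field(default_factory=dict)

    def indices(self, code: str) -> np.ndarray:
        return np.flatnonzero(self.labels == code)


def _mad(x: np.ndarray, center: float) -> float:
    return float(np.median(np.abs(x - center)))


def _box_halfwidth(x: np.ndarray, center: float, k: float) -> float:
    h = k * _MAD_SCALE * _mad(x, center)
    # Degenerate clouds (all-identical scatter) still need a positive box.
    floor = 1e-9 * max(1.0, abs(center))
    return max(h, floor)


def _mode_seed(fsc: np.ndarray, ssc: np.ndarray) -> np.ndarray:
    """Indices of events in the densest 2D histogram bin (plus neighbours).

    Ties between equally dense bins are broken toward the bin whose centre is
    closest to the joint median, so a balanced bimodal cloud resolves to the
    cluster containing (or nearest to) the coordinate-wise median.
    """
    n = len(fsc)
    bins = max(8, min(48, int(np.sqrt(n / 8.0)) or 8))
    hist, fedges, sedges = np.histogram2d(fsc, ssc, bins=bins)
    best = hist.max()
    cand = np.argwhere(hist >= best)
    med = np.array([np.median(fsc), np.median(ssc)])
    fcent = 0.5 * (fedges[:-1] + fedges[1:])
    scent = 0.5 * (sedges[:-1] + sedges[1:])
    fscale = max(fedges[-1] - fedges[0], 1e-12)
    sscale = max(sedges[-1] - sedges[0], 1e-12)
    dist = [
        ((fcent[i] - med[0]) / fscale) ** 2 + ((scent[j] - med[1]) / sscale) ** 2
        for i, j in cand
    ]
    bi, bj = cand[int(np.argmin(dist))]
    fi = np.clip([bi - 1, bi + 2], 0, bins)
    sj = np.clip([bj - 1, bj + 2], 0, bins)
    lo_f, hi_f = fedges[fi[0]], fedges[fi[1]]
    lo_s, hi_s = sedges[sj[0]], sedges[sj[1]]
    seed = np.flatnonzero(
        (fsc >= lo_f) & (fsc <= hi_f) & (ssc >= lo_s) & (ssc <= hi_s)
    )
    return seed if seed.size else np.arange(n)


def gate_singlets(table: EventTable, k: float = 4.0) -> GateResult:
    """Select the singlet bead population on FSC x SSC.

    ``k`` scales the box half-width in robust standard deviations; the
    default of 4 keeps essentially all of a well-behaved singlet cloud
    while excluding doublets at ~2x scatter.  Deterministic for a fixed
    input, and idempotent: gating the gated subset returns the same set.
    """
    if k <= 0:
        raise ValueError("spread multiplier k must be > 0")
    fsc = table.channel("FSC")
    ssc = table.channel("SSC")

    kept = _mode_seed(fsc, ssc)
    for _ in range(100):
        cf, cs = float(np.median(fsc[kept])), float(np.median(ssc[kept]))
        hf = _box_halfwidth(fsc[kept], cf, k)
        hs = _box_halfwidth(ssc[kept], cs, k)
        new = np.flatnonzero(
            (np.abs(fsc - cf) <= hf) & (np.abs(ssc - cs) <= hs)
        )
        if new.size == kept.size and np.array_equal(new, kept):
            break
        kept = new
        if kept.size == 0:
            raise GateError("empty gate: no events inside the scatter box")
    if kept.size == 0:
        raise GateError("empty gate: no events inside the scatter box")
    return GateResult(
        kept=kept, center=(cf, cs), halfwidth=(hf, hs), method="robust-box", k=k
    )


def check_min_events(gate: GateResult, minimum: int = 2000) -> bool:
    """Minimum-event acquisition rule: pass iff the gate holds >= ``minimum``.

    The default of 2000 gated bead events is the acquisition floor used
    throughout the QC protocol.  Failing acquisitions are flagged by the
    caller, never silently dropped.
    """
    if minimum < 1:
        raise ValueError("minimum must be >= 1")
    return gate.n_kept >= minimum


def _validate_disjoint(code_bounds: dict[str, tuple[float, float]]) -> None:
    items = sorted(code_bounds.items(), key=lambda kv: kv[1][0])
    for (name, (lo, hi)) in items:
        if not (0 <= lo < hi):
            raise ConfigurationError(f"bead code {name!r}: invalid interval [{lo}, {hi})")
    for (a, (_, hi_a)), (b, (lo_b, _)) in zip(items, items[1:]):
        if hi_a > lo_b:
            raise ConfigurationError(
                f"bead code intervals overlap: {a!r} and {b!r}"
            )


def classify_bead_codes(
    table: EventTable, code_bounds: dict[str, tuple[float, float]]
) -> BeadCodeAssignment:
    """Label each event by the disjoint FL4 interval containing its value.

    Intervals are half-open ``[lo, hi)`` in linear units.  Every event gets
    exactly one label; values in no interval are ``"unassigned"``.
    """
    _validate_disjoint(code_bounds)
    fl4 = table.channel("FL4")
    labels = np.full(len(fl4), UNASSIGNED, dtype=object)
    for code, (lo, hi) in code_bounds.items():
        labels[(fl4 >= lo) & (fl4 < hi)] = code
    counts = {code: int((labels == code).sum()) for code in code_bounds}
    counts[UNASSIGNED] = int((labels == UNASSIGNED).sum())
    return BeadCodeAssignment(labels=labels, code_bounds=dict(code_bounds), counts=counts)


def code_bounds_from_references(code_gms: dict[str, float]) -> dict[str, tuple[float, float]]:
    """Derive disjoint FL4 intervals from per-code reference geometric means.

    Boundaries are placed at the log-space midpoints between adjacent code
    GMs (bead populations are approximately lognormal, so the geometric
    midpoint is the natural separator); the outermost bounds mirror the
    nearest interior boundary in log space.
    """
    if not code_gms:
        raise ConfigurationError("no bead codes supplied")
    items = sorted(code_gms.items(), key=lambda kv: kv[1])
    logs = np.log10([gm for _, gm in items])
    if len(items) == 1:
        code, gm = items[0]
        return {code: (gm / 10.0, gm * 10.0)}
    mids = 0.5 * (logs[:-1] + logs[1:])
    lo_edge = 2 * logs[0] - mids[0]
    hi_edge = 2 * logs[-1] - mids[-1]
    edges = np.concatenate([[lo_edge], mids, [hi_edge]])
    return {
        code: (float(10 ** edges[i]), float(10 ** edges[i + 1]))
        for i, (code, _) in enumerate(items)
    }
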