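"""Synthetic bead-acquisition generator with known ground truth.

Every input the QC pipeline consumes can be generated here: single-bead
tubes, mixed MESF standard tubes, concentration panels, 18-month stability
studies with an instrument-sensitivity dip, and protected/exposed pairs
for the secondary-stain check.

Generative model
----------------
Single-bead fluorescence is lognormal: a population with geometric mean
``gm`` and log-shape ``sigma_log`` draws ``FL ~ exp(N(ln gm, sigma_log))``,
which reproduces the unimodal peaks bead populations show on a log-scale
histogram and keeps closed-form checks available (sample GM -> gm,
CV% -> 100*sqrt(exp(sigma^2)-1)).  Scatter is normal per axis; a
``doublet_frac`` of events is replaced by exact 2x aggregates (twice the
scatter and twice the fluorescence).  Conjugate brightness decays
geometrically per month, and an instrument drift window multiplies every
population — standards and conjugates alike — by a common factor.

All randomness flows through a single integer seed; identical
configuration + seed gives bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .fcs_io import ChannelSpec, EventTable

#: Default FL4 geometric means of the configured bead codes (10-fold apart).
DEFAULT_BEAD_CODES = {"012": 50.0, "035": 500.0, "070": 5000.0}

#: Synthetic MESF standard set: label -> (assigned MESF, true geometric mean).
#: GM levels sit in the regime of a PE MESF kit on a 4-decade axis (blank
#: near the origin, top standard ~1.4e3); the assigned MESF values are
#: SYNTHETIC stand-ins on the line log10(MESF) = log10(GM) + 2 — the real
#: kit's certified values are lot-specific and must be user-supplied.
DEFAULT_STANDARDS = {
    "blank": (200.0, 2.0),
    "bead1": (3_000.0, 30.0),
    "bead2": (6_500.0, 65.0),
    "bead3": (27_800.0, 278.0),
    "bead4": (144_300.0, 1443.0),
}


@dataclass
class ScatterParams:
    """Normal scatter cloud of the singlet bead population."""

    fsc_mean: float = 500.0
    fsc_cv: float = 0.08
    ssc_mean: float = 300.0
    ssc_cv: float = 0.10


@dataclass
class ConjugateSpec:
    """Ground truth for one simulated conjugate."""

    conjugate_id: str
    initial_gm: float              # FL2 geometric mean at month 0, 5 ug/mL
    sigma_log: float = 0.30        # lognormal shape at the working concentration
    monthly_decay: float = 0.0     # geometric decay rate per month, in [0, 1)
    bead_code: str = "012"

    def gm_at(self, month: float, drift: float = 1.0) -> float:
        return self.initial_gm * (1.0 - self.monthly_decay) ** month * drift


@dataclass
class SimulationConfig:
    """Full parameterization of a simulated QC study."""

    seed: int = 0
    n_events: int = 5000
    bead_codes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BEAD_CODES))
    fl4_sigma_log: float = 0.15
    scatter: ScatterParams = field(default_factory=ScatterParams)
    doublet_frac: float = 0.02
    conjugates: list[ConjugateSpec] = field(default_factory=list)
    standards: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STANDARDS))
    blank_label: str = "blank"
    standards_sigma_log: float = 0.10
    n_events_per_standard: int = 2000
    drift_window: tuple[int, int] | None = None   # inclusive month range
    drift_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.doublet_frac < 1):
            raise ConfigurationError("doublet fraction must be in [0, 1)")
        if self.drift_factor <= 0:
            raise ConfigurationError("drift factor must be > 0")
        for gm in self.bead_codes.values():
            if gm <= 0:
                raise ConfigurationError("bead-code FL4 geometric means must be > 0")
        for c in self.conjugates:
            if not (0 <= c.monthly_decay < 1):
                raise ConfigurationError(
                    f"{c.conjugate_id}: monthly decay must be in [0, 1)")
            if c.initial_gm <= 0:
                raise ConfigurationError(f"{c.conjugate_id}: initial GM must be > 0")

    def drift_at(self, month: float) -> float:
        if self.drift_window is not None:
            lo, hi = self.drift_window
            if lo <= month <= hi:
                return self.drift_factor
        return 1.0


_LINEAR_SPEC = {c: ChannelSpec(linear=True) for c in ("FSC", "SSC", "FL1", "FL2", "FL4")}


def _lognormal(rng: np.random.Generator, gm: float, sigma: float, n: int) -> np.ndarray:
    return np.exp(rng.normal(np.log(gm), sigma, size=n))


def simulate_population(
    n: int,
    gm: float,
    sigma_log: float = 0.30,
    code_fl4: float = 50.0,
    fl4_sigma_log: float = 0.15,
    fl1_gm: float = 2.0,
    fl1_sigma_log: float = 0.30,
    scatter: ScatterParams | None = None,
    doublet_frac: float = 0.0,
    seed: int | np.random.Generator = 0,
    meta: dict | None = None,
) -> EventTable:
    """Simulate one tube of a single bead population.

    FL2 is lognormal around ``gm``, FL4 lognormal around the bead code's
    GM, FL1 a dim background unless a FITC stain GM is given, scatter
    normal per axis (clipped at 0).  A ``doublet_frac`` of events is
    replaced by 2x aggregates in both scatter and fluorescence.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if gm <= 0 or code_fl4 <= 0:
        raise ConfigurationError("geometric means must be > 0")
    if not (0 <= doublet_frac < 1):
        raise ConfigurationError("doublet fraction must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scatter = scatter or ScatterParams()

    fl2 = _lognormal(rng, gm, sigma_log, n)
    fl4 = _lognormal(rng, code_fl4, fl4_sigma_log, n)
    fl1 = _lognormal(rng, fl1_gm, fl1_sigma_log, n)
    fsc = rng.normal(scatter.fsc_mean, scatter.fsc_cv * scatter.fsc_mean, n)
    ssc = rng.normal(scatter.ssc_mean, scatter.ssc_cv * scatter.ssc_mean, n)

    if doublet_frac > 0:
        doublet = rng.random(n) < doublet_frac
        for arr in (fsc, ssc, fl1, fl2, fl4):
            arr[doublet] *= 2.0

    frame = pd.DataFrame({
        "FSC": np.clip(fsc, 0, None),
        "SSC": np.clip(ssc, 0, None),
        "FL1": fl1, "FL2": fl2, "FL4": fl4,
    })
    return EventTable(events=frame, meta=dict(meta or {}), channel_spec=dict(_LINEAR_SPEC))


def simulate_standard_tube(
    standards: dict[str, tuple[float, float]] | None = None,
    n_per_population: int = 2000,
    sigma_log: float = 0.10,
    scatter: ScatterParams | None = None,
    seed: int | np.random.Generator = 0,
    meta: dict | None = None,
) -> tuple[EventTable, np.ndarray]:
    """Simulate the mixed MESF standards tube (all populations in one tube).

    ``standards`` maps label -> (assigned MESF, true FL2 geometric mean)
    and must include a blank plus >= 2 brighter populations.  Returns the
    event table and the per-event ground-truth population labels (kept
    out of the table itself so the pipeline cannot see them).
    """
    standards = standards or dict(DEFAULT_STANDARDS)
    if len(standards) < 3:
        raise ConfigurationError(
            "a standards tube needs a blank plus >= 2 non-blank populations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tables, labels = [], []
    for label, (_, gm) in sorted(standards.items(), key=lambda kv: kv[1][1]):
        pop = simulate_population(
            n_per_population, gm, sigma_log, code_fl4=5.0, scatter=scatter,
            doublet_frac=0.0, seed=rng,
        )
        tables.append(pop.events)
        labels.extend([label] * n_per_population)
    frame = pd.concat(tables, ignore_index=True)
    table = EventTable(events=frame, meta=dict(meta or {}),
                       channel_spec=dict(_LINEAR_SPEC))
    return table, np.array(labels, dtype=object)


@dataclass
class StudyData:
    """A simulated stability study plus its generative ground truth."""

    config: SimulationConfig
    months: list[int]
    # month -> conjugate id -> EventTable
    conjugate_tubes: dict[int, dict[str, EventTable]]
    # month -> (EventTable, population labels)
    standard_tubes: dict[int, tuple[EventTable, np.ndarray]]
    ground_truth: dict

    def truth_as_json(self) -> dict:
        return self.ground_truth


def simulate_stability_study(
    config: SimulationConfig, months: list[int]
) -> StudyData:
    """Simulate a long-term stability study month by month.

    Each month yields one tube per conjugate plus a concurrent standards
    tube acquired under the same instrument state: conjugate GM at month t
    is ``initial_gm * (1 - decay)^t * drift(t)`` and every standard's GM is
    ``true_gm * drift(t)``, with ``drift(t)`` equal to the configured
    factor inside the drift window and 1 elsewhere.
    """
    if not months or sorted(months) != list(months):
        raise ConfigurationError("months must be a non-empty ascending list")
    if not config.conjugates:
        raise ConfigurationError("no conjugates configured")
    rng = np.random.default_rng(config.seed)
    conj_tubes: dict[int, dict[str, EventTable]] = {}
    std_tubes: dict[int, tuple[EventTable, np.ndarray]] = {}
    for month in months:
        drift = config.drift_at(month)
        per_conj = {}
        for spec in config.conjugates:
            gm = spec.gm_at(month, drift)
            per_conj[spec.conjugate_id] = simulate_population(
                config.n_events, gm, spec.sigma_log,
                code_fl4=config.bead_codes[spec.bead_code],
                fl4_sigma_log=config.fl4_sigma_log,
                scatter=config.scatter, doublet_frac=config.doublet_frac,
                seed=rng,
                meta={"conjugate_id": spec.conjugate_id, "timepoint_months": month},
            )
        conj_tubes[month] = per_conj
        drifted = {
            label: (mesf, gm * drift)
            for label, (mesf, gm) in config.standards.items()
        }
        std_tubes[month] = simulate_standard_tube(
            drifted, config.n_events_per_standard, config.standards_sigma_log,
            scatter=config.scatter, seed=rng,
            meta={"sample_id": "standards", "timepoint_months": month},
        )
    truth = {
        "months": list(months),
        "drift_window": list(config.drift_window) if config.drift_window else None,
        "drift_factor": config.drift_factor,
        "conjugates": {
            c.conjugate_id: {
                "initial_gm": c.initial_gm,
                "monthly_decay": c.monthly_decay,
                "sigma_log": c.sigma_log,
                "bead_code": c.bead_code,
                "gm_by_month": {m: c.gm_at(m, config.drift_at(m)) for m in months},
            }
            for c in config.conjugates
        },
        "standards": {k: {"assigned_mesf": v[0], "true_gm": v[1]}
                      for k, v in config.standards.items()},
        "seed": config.seed,
    }
    return StudyData(config=config, months=list(months),
                     conjugate_tubes=conj_tubes, standard_tubes=std_tubes,
                     ground_truth=truth)


def simulate_concentration_panel(
    levels: dict[object, tuple[float, float]],
    n_replicates: int = 3,
    n_events: int = 3000,
    scatter: ScatterParams | None = None,
    doublet_frac: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> dict[object, list[EventTable]]:
    """Simulate a concentration/dilution panel with replicate tubes.

    ``levels`` maps each level (ascending) to its (FL2 GM, sigma_log):
    brightness typically rises and the lognormal shape narrows with
    concentration, mirroring a concentration-dependent coupling.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    panel: dict[object, list[EventTable]] = {}
    for level, (gm, sigma) in levels.items():
        panel[level] = [
            simulate_population(
                n_events, gm, sigma, scatter=scatter, doublet_frac=doublet_frac,
                seed=rng, meta={"level": level, "replicate": r},
            )
            for r in range(n_replicates)
        ]
    return panel


def simulate_secondary_stain(
    pe_gm_protected: float = 731.0,
    fitc_gm_protected: float = 80.0,
    pe_fade: float = 0.077,
    fitc_retention: float = 0.89,
    n: int = 5000,
    sigma_log: float = 0.30,
    scatter: ScatterParams | None = None,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Simulate the protected vs. light/RT-exposed secondary-stain pair.

    The exposed tube multiplies the PE (FL2) GM by ``pe_fade`` and the
    FITC (FL1) secondary-stain GM by ``fitc_retention``; the protected
    tube keeps both.  Returns ``{"protected": EventTable, "exposed":
    EventTable, "truth": {...}}``.
    """
    if pe_fade <= 0 or fitc_retention <= 0:
        raise ConfigurationError("fade and retention factors must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _tube(pe_gm: float, fitc_gm: float, condition: str) -> EventTable:
        return simulate_population(
            n, pe_gm, sigma_log, fl1_gm=fitc_gm, fl1_sigma_log=sigma_log,
            scatter=scatter, doublet_frac=0.0, seed=rng,
            meta={"condition": condition},
        )

    protected = _tube(pe_gm_protected, fitc_gm_protected, "protected")
    exposed = _tube(pe_gm_protected * pe_fade,
                    fitc_gm_protected * fitc_retention, "exposed")
    return {
        "protected": protected,
        "exposed": exposed,
        "truth": {
            "pe_fade": pe_fade, "fitc_retention": fitc_retention,
            "pe_gm_protected": pe_gm_protected,
            "fitc_gm_protected": fitc_gm_protected,
        },
    }


def a_series_study(seed: int = 0, n_events: int = 3000) -> SimulationConfig:
    """Default 18-month study configuration.

    Three conjugates spanning the observed stability range — total
    decreases of ~30%, ~77% and ~79% over 18 months — plus the default
    standards, a 20% instrument dip over months 4-7, and modest doublets.
    """
    def rate(total_decrease: float, span: int = 18) -> float:
        return 1.0 - (1.0 - total_decrease) ** (1.0 / span)

    return SimulationConfig(
        seed=seed,
        n_events=n_events,
        conjugates=[
            ConjugateSpec("A1", initial_gm=1633.3, sigma_log=0.30,
                          monthly_decay=rate(0.30), bead_code="012"),
            ConjugateSpec("A2", initial_gm=1200.0, sigma_log=0.30,
                          monthly_decay=rate(0.79), bead_code="035"),
            ConjugateSpec("A3", initial_gm=950.0, sigma_log=0.30,
                          monthly_decay=rate(0.77), bead_code="070"),
        ],
        drift_window=(4, 7),
        drift_factor=0.80,
    )
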