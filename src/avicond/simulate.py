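"""Synthetic monthly condemnation series generator.

The generator emulates the statistical structure of slaughterhouse
inspection records: per-species head counts following a schedule with a
species-composition breakpoint (turkey phase-out, griller-to-heavy-chicken
switch), cause- and species-specific per-head condemnation probabilities,
calendar-month multiplicative seasonal effects, a slow multiplicative
trend, and Poisson (optionally negative-binomial) count noise.

For month index ``t`` (0-based from the series start) with calendar month
``m`` and drawn head counts ``N_s``, the count of cause ``c`` is drawn
with mean::

    mu = sum_s N_s * p[c][s] * season_c[m] * trend**t

Seasonal 12-vectors are renormalized to arithmetic mean 1 on construction,
so the injected multiplier and the seasonal-index estimand coincide up to
trend-induced bias (a strong trend inflates late-calendar ratios; the
generator exposes ``trend`` so that bias can be quantified rather than
hidden).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import CauseDefinition, Dataset, DEFAULT_CAUSES, MonthKey, MonthlyRecord, Species
from .errors import ConfigError


def month_range(start: MonthKey, n_months: int) -> list[MonthKey]:
    """The ``n_months`` consecutive calendar months starting at ``start``."""
    out = []
    y, m = start.year, start.month
    for _ in range(n_months):
        out.append(MonthKey(y, m))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


@dataclass(frozen=True)
class SchedulePhase:
    """Mean monthly head counts per species over an inclusive month range."""

    start: MonthKey
    end: MonthKey
    head: dict[Species, float]

    def covers(self, key: MonthKey) -> bool:
        return self.start <= key <= self.end


@dataclass
class SimulationConfig:
    """Fully specifies one synthetic series; deterministic given ``seed``."""

    start: MonthKey
    n_months: int
    schedule: list[SchedulePhase]
    cause_baselines: dict[str, dict[Species, float]]  # per-head probability
    seasonal: dict[str, np.ndarray] = field(default_factory=dict)  # 12-vectors
    trend: float = 1.0
    noise: str = "poisson"  # "poisson" | "negative_binomial"
    dispersion: float | None = None  # NB size parameter k (var = mu + mu^2/k)
    seed: int = 0
    causes: tuple[CauseDefinition, ...] = DEFAULT_CAUSES

    def __post_init__(self):
        if self.n_months < 12:
            raise ConfigError("n_months must be at least 12")
        if self.trend <= 0:
            raise ConfigError("trend must be positive")
        if self.noise not in ("poisson", "negative_binomial"):
            raise ConfigError(f"unknown noise model {self.noise!r}")
        if self.noise == "negative_binomial" and (
            self.dispersion is None or self.dispersion <= 0
        ):
            raise ConfigError("negative_binomial noise needs dispersion > 0")
        codes = {c.code for c in self.causes}
        for cause, per_species in self.cause_baselines.items():
            if cause not in codes:
                raise ConfigError(f"baseline for unregistered cause {cause!r}")
            for sp, p in per_species.items():
                if not 0 < p < 1:
                    raise ConfigError(
                        f"probability for ({cause}, {sp.value}) must be in (0,1), got {p}"
                    )
        for key in month_range(self.start, self.n_months):
            if not any(ph.covers(key) for ph in self.schedule):
                raise ConfigError(f"schedule does not cover {key}")
        # Renormalize seasonal vectors to mean 1 so the injected multiplier
        # is the seasonal-index estimand.
        normalized = {}
        for cause, vec in self.seasonal.items():
            if cause not in codes:
                raise ConfigError(f"seasonal vector for unregistered cause {cause!r}")
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (12,) or np.any(arr <= 0):
                raise ConfigError(f"seasonal vector for {cause!r} must be 12 positive reals")
            normalized[cause] = arr / arr.mean()
        self.seasonal = normalized

    def months(self) -> list[MonthKey]:
        return month_range(self.start, self.n_months)

    def head_means(self, key: MonthKey) -> dict[Species, float]:
        for ph in self.schedule:
            if ph.covers(key):
                return ph.head
        raise ConfigError(f"schedule does not cover {key}")

    def expected_count(self, cause: str, t: int, head: dict[Species, float] | None = None) -> float:
        """Expected count of ``cause`` at month index ``t`` given head
        counts (defaults to the schedule means)."""
        key = self.months()[t]
        head = head if head is not None else self.head_means(key)
        season = self.seasonal.get(cause)
        s = 1.0 if season is None else float(season[key.month - 1])
        p = self.cause_baselines.get(cause, {})
        return sum(head.get(sp, 0.0) * p.get(sp, 0.0) for sp in Species) * s * self.trend**t


def _draw_counts(rng: np.random.Generator, mu: float, noise: str, dispersion: float | None) -> int:
    if mu <= 0:
        return 0
    if noise == "poisson":
        return int(rng.poisson(mu))
    k = float(dispersion)  # NB as gamma-mixed Poisson
    return int(rng.poisson(rng.gamma(shape=k, scale=mu / k)))


def simulate_dataset(cfg: SimulationConfig) -> Dataset:
    """Draw one synthetic :class:`~avicond.data.Dataset` from ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    records = []
    for t, key in enumerate(cfg.months()):
        head_means = cfg.head_means(key)
        slaughtered = {
            sp: int(rng.poisson(mean)) if mean > 0 else 0
            for sp, mean in head_means.items()
        }
        condemned = {}
        for cause in (c.code for c in cfg.causes):
            if cause not in cfg.cause_baselines:
                condemned[cause] = 0
                continue
            mu = cfg.expected_count(cause, t, {sp: float(n) for sp, n in slaughtered.items()})
            condemned[cause] = _draw_counts(rng, mu, cfg.noise, cfg.dispersion)
        records.append(MonthlyRecord(key, slaughtered, condemned))
    return Dataset(records, cfg.causes, provenance=f"simulated(seed={cfg.seed})")


#: Cause-specific per-head condemnation probabilities for the reference
#: series. Back-solved from published group summaries of an 11-year
#: Brazilian export-slaughterhouse series: group-A months (turkey +
#: chicken) condemn ~7.0% of head overall, heavy-chicken-only months
#: ~10.1%; aerosacculitis is concentrated in turkeys.
_REFERENCE_BASELINES: dict[str, dict[Species, float]] = {
    "contamination":      {Species.TURKEY: 0.020,  Species.GRILLER: 0.0225, Species.HEAVY: 0.0448},
    "contusion":          {Species.TURKEY: 0.015,  Species.GRILLER: 0.0160, Species.HEAVY: 0.0325},
    "dermatosis":         {Species.TURKEY: 0.008,  Species.GRILLER: 0.0078, Species.HEAVY: 0.0107},
    "aerosacculitis":     {Species.TURKEY: 0.125,  Species.GRILLER: 0.0010, Species.HEAVY: 0.00002},
    "arthritis":          {Species.TURKEY: 0.010,  Species.GRILLER: 0.0027, Species.HEAVY: 0.0035},
    "septicemia":         {Species.TURKEY: 0.006,  Species.GRILLER: 0.0022, Species.HEAVY: 0.0028},
    "disgusting_aspects": {Species.TURKEY: 0.006,  Species.GRILLER: 0.0021, Species.HEAVY: 0.0027},
    "excessive_scalding": {Species.TURKEY: 0.002,  Species.GRILLER: 0.0015, Species.HEAVY: 0.0018},
    "cellulitis":         {Species.TURKEY: 0.003,  Species.GRILLER: 0.0011, Species.HEAVY: 0.0014},
    "ascitic_syndrome":   {Species.TURKEY: 0.0004, Species.GRILLER: 0.0004, Species.HEAVY: 0.0005},
    "cachexia":           {Species.TURKEY: 0.0003, Species.GRILLER: 0.0002, Species.HEAVY: 0.0002},
    "others":             {Species.TURKEY: 0.0006, Species.GRILLER: 0.0004, Species.HEAVY: 0.0005},
}

# Cold-season peak for ascitic syndrome (southern-hemisphere winter,
# July-led) and a May-September trough for aerosacculitis; other causes
# are left seasonally flat.
_REFERENCE_SEASONAL = {
    "ascitic_syndrome": np.array(
        [0.65, 0.70, 0.80, 0.65, 0.68, 0.90, 1.55, 1.45, 1.35, 1.25, 1.00, 1.00]
    ),
    "aerosacculitis": np.array(
        [1.20, 1.20, 1.15, 1.10, 0.72, 0.65, 0.60, 0.62, 0.70, 1.05, 1.10, 1.12]
    ),
}


def reference_config(seed: int = 1) -> SimulationConfig:
    """The default study conditions: 131 months (January 2009 – November
    2019), ~5.9M head/month with turkeys ≈5% of head until their phase-out,
    a griller-to-heavy-chicken switch in July 2017, overall condemnation
    ≈7% of slaughter in the turkey era, and a 0.1%/month upward trend."""
    schedule = [
        SchedulePhase(MonthKey(2009, 1), MonthKey(2016, 12),
                      {Species.TURKEY: 295_000, Species.GRILLER: 5_600_000}),
        SchedulePhase(MonthKey(2017, 1), MonthKey(2017, 6),
                      {Species.TURKEY: 149_000, Species.GRILLER: 5_600_000}),
        SchedulePhase(MonthKey(2017, 7), MonthKey(2017, 12),
                      {Species.TURKEY: 149_000, Species.HEAVY: 5_600_000}),
        SchedulePhase(MonthKey(2018, 1), MonthKey(2018, 2),
                      {Species.TURKEY: 129_000, Species.HEAVY: 5_600_000}),
        SchedulePhase(MonthKey(2018, 3), MonthKey(2019, 11),
                      {Species.HEAVY: 5_600_000}),
    ]
    return SimulationConfig(
        start=MonthKey(2009, 1),
        n_months=131,
        schedule=schedule,
        cause_baselines=dict(_REFERENCE_BASELINES),
        seasonal={k: v.copy() for k, v in _REFERENCE_SEASONAL.items()},
        trend=1.001,
        seed=seed,
    )


def single_cause_config(
    cause: str = "ascitic_syndrome",
    p: float = 0.005,
    head: float = 1_000_000,
    n_months: int = 132,
    start: MonthKey = MonthKey(2009, 1),
    multipliers=None,
    trend: float = 1.0,
    noise: str = "poisson",
    dispersion: float | None = None,
    seed: int = 0,
) -> SimulationConfig:
    """A minimal one-cause configuration for calibration experiments
    (seasonal-multiplier recovery, null rejection rates, power curves)."""
    defn = CauseDefinition(cause, cause.replace("_", " ").title(), asi_eligible=True)
    seasonal = {} if multipliers is None else {cause: np.asarray(multipliers, dtype=float)}
    end = month_range(start, n_months)[-1]
    return SimulationConfig(
        start=start,
        n_months=n_months,
        schedule=[SchedulePhase(start, end, {Species.HEAVY: float(head)})],
        cause_baselines={cause: {Species.HEAVY: p}},
        seasonal=seasonal,
        trend=trend,
        noise=noise,
        dispersion=dispersion,
        seed=seed,
        causes=(defn,),
    )
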