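"""Synthetic Sahelian climate and hospital-admission generator.

The station and hospital records the analysis is designed for are not
publicly deposited, so this module generates data with the same
statistical structure, with all ground truth exposed for recovery
tests:

* **Climate** — a semi-arid seasonal TMAX cycle with two warm maxima
  (spring, the main one, and autumn), an AR(1) day-to-day anomaly, and
  injectable heatwave episodes with known dates and excess profiles.
  RHMIN follows an anti-phased seasonal curve (moist August, dry
  February) and is anti-correlated with the TMAX anomaly day-to-day.
* **Admissions** — daily counts drawn Poisson with log-rate
  ``baseline + sum_k beta_k * lag_k(Icum) + sum_s gamma_s * c_s`` where
  the lag weights beta_k concentrate the heat effect at lags 3-5 and
  ``c_s`` are exogenous daily consultation counts for the vulnerable
  strata (women, infants 0-4, seniors 65-79, seniors 80+), drawn
  multinomially from the stratum mix.

Identifiability convention for injected episodes: within an injected
window the AR(1) anomaly is rectified to be non-negative, and on the
single margin day before and after it is rectified to be non-positive.
The additive structure ``TMAX = seasonal + anomaly + excess`` is
otherwise unchanged.  This guarantees that an injected episode with
excess comfortably above the climatological 90th-percentile margin is
detected with exactly its injected start and end dates, so the injected
windows are usable as exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .climatology import build_climatology, detect_heatwaves
from .events import characterize_runs, daily_icum
from .features import build_feature_table, DEMOGRAPHIC_COLUMNS

__all__ = [
    "InjectedEvent",
    "ClimateScenario",
    "HealthScenario",
    "generate_climate",
    "generate_admissions",
    "generate_dataset",
    "ground_truth",
    "default_climate_scenario",
    "default_health_scenario",
]


class InvalidScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class InjectedEvent:
    """One injected heatwave episode: start date and per-day excess (°C)."""

    start: str  # ISO date
    excesses: tuple

    @property
    def duration(self) -> int:
        return len(self.excesses)

    @property
    def start_date(self) -> pd.Timestamp:
        return pd.Timestamp(self.start)

    @property
    def end_date(self) -> pd.Timestamp:
        return self.start_date + pd.Timedelta(days=self.duration - 1)


@dataclass
class ClimateScenario:
    """Parameters of the synthetic station climate.

    The seasonal TMAX curve is a sum of an annual and a semi-annual
    harmonic producing a dominant spring maximum (~41 °C around early
    May) and a secondary autumn maximum, on a 37 °C mean — a
    qualitative match to a semi-arid Sahelian station where extremes
    reach the mid-40s °C in the March-June window.
    """

    start: str = "2017-01-01"
    end: str = "2021-12-31"
    seasonal_mean: float = 37.0
    amp_annual: float = 2.5
    phase_annual_doy: float = 125.0
    amp_semiannual: float = 2.0
    phase_semiannual_doy: float = 115.0
    ar1_coefficient: float = 0.7
    daily_sd: float = 1.0          # marginal SD of the AR(1) anomaly, °C
    rh_mean: float = 30.0
    rh_amp: float = 20.0
    rh_phase_doy: float = 235.0
    rh_temp_slope: float = -1.5    # % per °C of TMAX anomaly
    rh_noise_sd: float = 4.0
    injected_events: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.ar1_coefficient < 1.0):
            raise InvalidScenarioError("ar1_coefficient must be in [0, 1)")
        events = sorted(self.injected_events, key=lambda e: e.start_date)
        for a, b in zip(events, events[1:]):
            # margin days must not touch either: require a clear day between
            if b.start_date <= a.end_date + pd.Timedelta(days=2):
                raise InvalidScenarioError(
                    f"injected events overlap or touch: {a.start} and {b.start}"
                )
        self.injected_events = events

    def seasonal_curve(self, doy: np.ndarray) -> np.ndarray:
        year = 365.25
        return (
            self.seasonal_mean
            + self.amp_annual * np.cos(2 * np.pi * (doy - self.phase_annual_doy) / year)
            + self.amp_semiannual
            * np.cos(4 * np.pi * (doy - self.phase_semiannual_doy) / year)
        )

    def rh_curve(self, doy: np.ndarray) -> np.ndarray:
        return self.rh_mean + self.rh_amp * np.cos(
            2 * np.pi * (doy - self.rh_phase_doy) / 365.25
        )


@dataclass
class HealthScenario:
    """Parameters of the synthetic admissions process.

    ``lag_weights[k]`` is the log-rate increment per °C of the daily
    cumulative heatwave excess lagged ``k`` days; the defaults
    concentrate the effect at lags 3-5 (peak on day 3, dip on day 4,
    rebound on day 5) as delayed heat-health responses typically show.
    """

    baseline_log_rate: float = float(np.log(6.0))
    lag_weights: tuple = (0.0, 0.005, 0.01, 0.06, 0.035, 0.05, 0.02, 0.005)
    demographic_fractions: tuple = (0.52, 0.13, 0.10, 0.05)  # women, 0-4, 65-79, 80+
    demographic_log_effects: tuple = (0.03, 0.05, 0.06, 0.08)
    consult_daily_total: float = 8.0   # mean daily consultations split by stratum
    overdispersion: float | None = None  # negative-binomial size; None = Poisson
    seed: int = 0

    def __post_init__(self):
        if len(self.lag_weights) != 8:
            raise InvalidScenarioError("lag_weights must cover lags 0..7")
        if any(f < 0 for f in self.demographic_fractions) or sum(
            self.demographic_fractions
        ) > 1.0 + 1e-12:
            raise InvalidScenarioError("demographic fractions must be >= 0 and sum <= 1")


def generate_climate(scenario: ClimateScenario) -> pd.DataFrame:
    """Daily ``date, tmax_c, rhmin_pct`` table; seeded and reproducible."""
    dates = pd.date_range(scenario.start, scenario.end, freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = scenario.seasonal_curve(doy)

    rng = np.random.default_rng([int(scenario.seed), 101])
    phi = scenario.ar1_coefficient
    innov_sd = scenario.daily_sd * np.sqrt(1.0 - phi**2)
    noise = np.empty(n)
    noise[0] = rng.normal(0.0, scenario.daily_sd)
    eps = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        noise[t] = phi * noise[t - 1] + eps[t]

    excess = np.zeros(n)
    pos = {d: i for i, d in enumerate(dates)}
    for ev in scenario.injected_events:
        if ev.duration < 3:
            raise InvalidScenarioError("injected events must last >= 3 days")
        if min(ev.excesses) <= 0:
            raise InvalidScenarioError("injected excesses must be > 0")
        for off, exc in enumerate(ev.excesses):
            day = ev.start_date + pd.Timedelta(days=off)
            i = pos.get(day)
            if i is None:
                raise InvalidScenarioError(f"injected day {day.date()} outside series")
            excess[i] = exc
            noise[i] = max(noise[i], 0.0)  # keep the window identifiable
        for margin in (ev.start_date - pd.Timedelta(days=1), ev.end_date + pd.Timedelta(days=1)):
            i = pos.get(margin)
            if i is not None:
                noise[i] = min(noise[i], 0.0)

    tmax = seasonal + noise + excess
    tmax = np.clip(tmax, 10.0, 55.0)

    rh_noise = rng.normal(0.0, scenario.rh_noise_sd, size=n)
    rhmin = scenario.rh_curve(doy) + scenario.rh_temp_slope * (tmax - seasonal) + rh_noise
    rhmin = np.clip(rhmin, 2.0, 100.0)
    return pd.DataFrame({"date": dates, "tmax_c": tmax, "rhmin_pct": rhmin})


STRATUM_NAMES = DEMOGRAPHIC_COLUMNS  # women_count, infants_0_4, seniors_65_79, seniors_80p


def generate_admissions(
    exposure_lags: pd.DataFrame,
    scenario: HealthScenario,
) -> tuple[pd.DataFrame, dict]:
    """Daily admissions with demographic splits from a lagged exposure table.

    ``exposure_lags`` must contain ``date``, ``icum_daily`` and
    ``lag_1`` .. ``lag_7`` with no missing lag values (rows with
    undefined lags are the caller's to drop).

    Returns the admissions table and the ground-truth parameter record.
    """
    lag_cols = ["icum_daily"] + [f"lag_{k}" for k in range(1, 8)]
    missing = [c for c in lag_cols if c not in exposure_lags.columns]
    if missing:
        raise ValueError(f"exposure table missing lag columns: {missing}")
    sub = exposure_lags.dropna(subset=lag_cols).reset_index(drop=True)
    n = len(sub)
    rng = np.random.default_rng([int(scenario.seed), 202])

    # exogenous daily consultation counts per vulnerable stratum
    totals = rng.poisson(scenario.consult_daily_total, size=n)
    fracs = list(scenario.demographic_fractions)
    probs = fracs + [max(0.0, 1.0 - sum(fracs))]
    strata = rng.multinomial(totals, probs)  # (n, 5); last column = other
    counts = {name: strata[:, j] for j, name in enumerate(STRATUM_NAMES)}

    X = sub[lag_cols].to_numpy(dtype=float)
    beta = np.asarray(scenario.lag_weights, dtype=float)
    gamma = np.asarray(scenario.demographic_log_effects, dtype=float)
    C = np.column_stack([counts[name] for name in STRATUM_NAMES]).astype(float)
    log_rate = scenario.baseline_log_rate + X @ beta + C @ gamma
    if np.any(log_rate > 20.0):
        raise InvalidScenarioError("mis-scaled scenario: log-rate exceeds 20")
    mu = np.exp(log_rate)
    if scenario.overdispersion is None:
        admissions = rng.poisson(mu)
    else:
        size = scenario.overdispersion
        admissions = rng.negative_binomial(size, size / (size + mu))

    out = pd.DataFrame({"date": sub["date"].to_numpy(), "admissions": admissions})
    for name in STRATUM_NAMES:
        out[name] = counts[name]
    truth = {
        "baseline_log_rate": scenario.baseline_log_rate,
        "lag_weights": list(scenario.lag_weights),
        "demographic_log_effects": list(scenario.demographic_log_effects),
        "demographic_fractions": list(scenario.demographic_fractions),
        "overdispersion": scenario.overdispersion,
    }
    return out, truth


def default_injected_events() -> list[InjectedEvent]:
    """Ten injected episodes over 2017-2021, clustered in the spring and
    autumn warm seasons, peak excesses 3-5 °C, durations 3-7 days."""
    profiles = [
        ("2017-04-10", (3.2, 4.5, 3.6)),
        ("2017-10-20", (3.0, 3.8, 4.6, 3.4)),
        ("2018-03-05", (3.1, 3.9, 4.8, 4.2, 3.3)),
        ("2018-05-18", (3.4, 4.2, 3.5)),
        ("2019-04-02", (3.0, 3.7, 4.4, 5.0, 4.1, 3.2)),
        ("2019-11-08", (3.3, 4.1, 3.6)),
        ("2020-03-14", (3.2, 4.0, 5.2, 4.4, 3.5)),
        ("2020-10-05", (3.1, 3.8, 3.4)),
        ("2021-04-22", (3.0, 3.9, 4.7, 5.3, 4.5, 3.6, 3.1)),
        ("2021-11-15", (3.2, 4.3, 3.7)),
    ]
    return [InjectedEvent(start=s, excesses=e) for s, e in profiles]


def default_climate_scenario(seed: int = 0) -> ClimateScenario:
    return ClimateScenario(injected_events=default_injected_events(), seed=seed)


def default_health_scenario(seed: int = 0) -> HealthScenario:
    return HealthScenario(seed=seed)


def ground_truth(
    climate: ClimateScenario, health: HealthScenario | None = None
) -> dict:
    """Serializable ground-truth record for recovery tests."""
    truth = {
        "injected_events": [
            {
                "start": ev.start_date.date().isoformat(),
                "end": ev.end_date.date().isoformat(),
                "duration": ev.duration,
                "excesses": list(ev.excesses),
            }
            for ev in climate.injected_events
        ],
        "climate_seed": climate.seed,
    }
    if health is not None:
        truth.update(
            {
                "baseline_log_rate": health.baseline_log_rate,
                "lag_weights": list(health.lag_weights),
                "demographic_log_effects": list(health.demographic_log_effects),
                "demographic_fractions": list(health.demographic_fractions),
            }
        )
    return json.loads(json.dumps(truth))  # plain-JSON types only


def generate_dataset(
    climate_scenario: ClimateScenario | None = None,
    health_scenario: HealthScenario | None = None,
    reference_start: str = "1991-01-01",
    reference_end: str = "2020-12-31",
    percentile: float = 0.90,
    window_days: int = 7,
    min_duration: int = 3,
    seed: int = 0,
) -> dict:
    """End-to-end synthetic study dataset.

    Generates a 30-year reference climate (same scenario parameters, no
    injections) and the injected analysis-period climate, builds the
    TMAX climatology, detects and characterises events, derives the
    daily cumulative-excess exposure and its lags, and draws admissions
    from the lagged exposure.  The health signal is thus defined on
    exactly the exposure scale the analysis pipeline reconstructs.
    """
    climate_scenario = climate_scenario or default_climate_scenario(seed=seed)
    health_scenario = health_scenario or default_health_scenario(seed=seed)

    reference_scenario = ClimateScenario(
        **{
            **asdict(climate_scenario),
            "start": reference_start,
            "end": reference_end,
            "injected_events": [],
            "seed": climate_scenario.seed + 1_000_000,
        }
    )
    reference = generate_climate(reference_scenario)
    climate = generate_climate(climate_scenario)

    climatology = build_climatology(
        reference, index_kind="TMAX", percentile=percentile, window_days=window_days
    )
    runs = detect_heatwaves(climate, climatology, min_duration=min_duration)
    events = characterize_runs(runs, index_kind="TMAX")
    exposure = daily_icum(climate["date"], events)
    admissions, health_truth = generate_admissions(
        _with_lags(exposure), health_scenario
    )
    table = build_feature_table(exposure, admissions)
    table["day_index"] = np.arange(len(table), dtype=float)
    truth = ground_truth(climate_scenario, health_scenario)
    return {
        "reference": reference,
        "climate": climate,
        "climatology": climatology,
        "events": events,
        "exposure": exposure,
        "admissions": admissions,
        "table": table,
        "truth": truth,
    }


def _with_lags(exposure: pd.DataFrame) -> pd.DataFrame:
    from .features import build_lags

    return build_lags(exposure, max_lag=7)
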