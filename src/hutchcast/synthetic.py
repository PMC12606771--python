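"""Synthetic rabbit-house microclimate generator.

Emulates the statistical structure of summer sensor records from enclosed
rabbit houses in three Chinese regions (Nanping/Fujian, Qingyang/Gansu,
Jiyuan/Henan): diurnal sinusoidal cycles whose seven-day-mean outdoor
extremes match the published regional statistics, AR(1) sensor noise,
first-order-lag indoor response to outdoor drivers, linear cross-channel
coupling, an occupancy/ventilation-driven CO2 cycle, and the two artifact
kinds real loggers produce (spike outliers and missing spans).

Channel order everywhere: Tin, RHin, CO2, WS, Tout, RHout
(indoor temperature degC, indoor relative humidity %, indoor CO2 ppm,
indoor wind speed m/s, outdoor temperature degC, outdoor RH %).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ["Tin", "RHin", "CO2", "WS", "Tout", "RHout"]

# index aliases into CHANNELS
TIN, RHIN, CO2, WS, TOUT, RHOUT = range(6)

#: solar-driven daily temperature peak at 15:00 -> sine phase zero at 09:00
_PHASE_OFFSET_MIN = 540.0


@dataclass
class RegionPreset:
    """Climate/housing preset for one region.

    Outdoor temperature and humidity extremes are the seven-day-mean daily
    max/min the generator reproduces exactly in the noise-free limit.
    ``coupling`` is a 6x6 matrix C: channel j receives C[j, i] times the
    anomaly of channel i (applied in generation order).
    """

    name: str
    outdoor_temp_max: float
    outdoor_temp_min: float
    outdoor_rh_max: float
    outdoor_rh_min: float
    indoor_offset_temp: float
    indoor_rh_level: float
    co2_base: float
    co2_amplitude: float
    wind_mean: float
    coupling: np.ndarray
    noise_sd: np.ndarray
    ar_coefficient: float = 0.9
    lag_minutes: float = 60.0

    def __post_init__(self):
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if not self.outdoor_temp_max > self.outdoor_temp_min:
            raise ValueError("outdoor temperature max must exceed min")
        if not self.outdoor_rh_max > self.outdoor_rh_min:
            raise ValueError("outdoor RH max must exceed min")
        if not (0.0 <= self.outdoor_rh_min and self.outdoor_rh_max <= 100.0):
            raise ValueError("RH bounds must lie in [0, 100]")
        if self.co2_base <= 0:
            raise ValueError("co2_base must be positive")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.coupling.shape != (6, 6):
            raise ValueError("coupling must be 6x6")
        if self.noise_sd.shape != (6,):
            raise ValueError("noise_sd must have 6 entries")


@dataclass
class SimulationConfig:
    """Length, resolution, seed and artifact plan for one simulated run."""

    n_days: int = 14
    step_minutes: int = 1
    seed: int = 0
    outlier_rate: float = 0.0
    gap_spec: list[tuple[int, int]] = field(default_factory=list)  # (start row, minutes)

    def __post_init__(self):
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if 60 % self.step_minutes != 0:
            raise ValueError("step_minutes must divide 60")
        if not 0.0 <= self.outlier_rate <= 0.05:
            raise ValueError("outlier_rate must lie in [0, 0.05]")


@dataclass
class RawSeriesTable:
    """Regular-step multichannel sensor table; NaN marks missing entries."""

    frame: pd.DataFrame  # DatetimeIndex, columns == CHANNELS
    step_minutes: int

    def __post_init__(self):
        if list(self.frame.columns) != CHANNELS:
            raise ValueError(f"columns must be {CHANNELS}")
        dt = np.diff(self.frame.index.asi8)
        if len(dt) and (dt <= 0).any():
            raise ValueError("timestamps must be strictly increasing")
        if len(dt) and not (dt == dt[0]).all():
            raise ValueError("timestamps must have a constant step")

    def __len__(self):
        return len(self.frame)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def mask(self) -> np.ndarray:
        """True where the entry is missing."""
        return self.frame.isna().to_numpy()

    def copy(self) -> "RawSeriesTable":
        return RawSeriesTable(self.frame.copy(), self.step_minutes)


@dataclass
class ArtifactLog:
    """Exact record of injected artifacts, for detector validation."""

    spikes: list[tuple[int, int, float, float]]  # (row, channel, original, injected)
    gap_rows: list[tuple[int, int]]  # (start row, n rows), all channels masked


def _coupling_matrix(strong: float, aux: float) -> np.ndarray:
    """Qualitative coupling pattern: indoor T drives RHin (negative) and CO2
    (negative, ventilation-mediated); wind speed mildly cools and dilutes."""
    c = np.zeros((6, 6))
    c[RHIN, TIN] = -1.6 * strong     # warmer air, lower indoor RH
    c[CO2, TIN] = -28.0 * strong     # daytime ventilation flushes CO2
    c[TIN, WS] = -0.35 * aux         # fan airflow cools
    c[CO2, WS] = -40.0 * aux         # airflow dilutes CO2
    c[RHIN, RHOUT] = 0.25 * aux      # outdoor moisture ingress
    return c


_PRESETS: dict[str, dict] = {
    # Published seven-day-mean outdoor extremes for the week of 20-26 Aug 2023.
    # Indoor levels are free parameters set to respect the qualitative regional
    # ordering: Fujian hottest/most humid with the tightest coupling, Gansu
    # coolest with the largest swings, high CO2 and the weakest coupling,
    # Henan intermediate.
    "fujian": dict(
        outdoor_temp_max=30.15, outdoor_temp_min=23.51,
        outdoor_rh_max=98.09, outdoor_rh_min=74.25,
        indoor_offset_temp=1.5, indoor_rh_level=82.0,
        co2_base=900.0, co2_amplitude=220.0, wind_mean=1.6,
        coupling=_coupling_matrix(strong=1.0, aux=1.0),
        noise_sd=np.array([0.12, 0.7, 22.0, 0.15, 0.25, 1.2]),
        ar_coefficient=0.9,
    ),
    "gansu": dict(
        outdoor_temp_max=23.15, outdoor_temp_min=15.73,
        outdoor_rh_max=95.03, outdoor_rh_min=59.93,
        indoor_offset_temp=2.5, indoor_rh_level=65.0,
        co2_base=1500.0, co2_amplitude=420.0, wind_mean=0.8,
        coupling=_coupling_matrix(strong=0.4, aux=0.4),
        noise_sd=np.array([0.18, 1.0, 45.0, 0.12, 0.35, 1.8]),
        ar_coefficient=0.9,
    ),
    "henan": dict(
        outdoor_temp_max=29.97, outdoor_temp_min=20.45,
        outdoor_rh_max=97.15, outdoor_rh_min=67.26,
        indoor_offset_temp=2.0, indoor_rh_level=74.0,
        co2_base=1100.0, co2_amplitude=300.0, wind_mean=1.2,
        coupling=_coupling_matrix(strong=0.7, aux=0.7),
        noise_sd=np.array([0.15, 0.85, 30.0, 0.13, 0.30, 1.5]),
        ar_coefficient=0.9,
    ),
}


def make_region_preset(name: str) -> RegionPreset:
    """Return the preset for one of the three study regions."""
    key = name.lower()
    if key not in _PRESETS:
        raise ValueError(
            f"unknown region {name!r}; valid regions: {sorted(_PRESETS)}"
        )
    return RegionPreset(name=key, **_PRESETS[key])


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation `sd`."""
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi * phi) if phi > 0 else sd
    e = rng.normal(0.0, innov_sd, size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x


def _lowpass(x: np.ndarray, step_minutes: float, tau_minutes: float) -> np.ndarray:
    """First-order lag filter y' = (x - y)/tau, initialised at x[0]."""
    a = step_minutes / (tau_minutes + step_minutes)
    y = np.empty_like(x)
    y[0] = x[0]
    for i in range(1, len(x)):
        y[i] = y[i - 1] + a * (x[i] - y[i - 1])
    return y


def simulate_house(preset: RegionPreset, config: SimulationConfig) -> RawSeriesTable:
    """Generate an artifact-free multichannel series for one house.

    Outdoor temperature is mesor + amplitude*sin(diurnal phase) + AR(1)
    noise, peaking at 15:00 so the noise-free seven-day pointwise mean
    attains the preset extremes exactly on any step grid dividing 60 min.
    Outdoor RH runs in anti-phase. Indoor channels are first-order-lag
    responses to the outdoor drivers plus the preset's linear coupling
    terms; CO2 adds a ventilation-driven cycle peaking at night.
    """
    rng = np.random.default_rng(config.seed)
    step = config.step_minutes
    n = config.n_days * 24 * 60 // step
    minute = (np.arange(n) * step) % 1440.0
    phase = 2.0 * np.pi * (minute - _PHASE_OFFSET_MIN) / 1440.0
    s = np.sin(phase)

    C, sd, phi = preset.coupling, preset.noise_sd, preset.ar_coefficient

    t_mesor = 0.5 * (preset.outdoor_temp_max + preset.outdoor_temp_min)
    t_amp = 0.5 * (preset.outdoor_temp_max - preset.outdoor_temp_min)
    tout = t_mesor + t_amp * s + _ar1(rng, n, sd[TOUT], phi)

    rh_mesor = 0.5 * (preset.outdoor_rh_max + preset.outdoor_rh_min)
    rh_amp = 0.5 * (preset.outdoor_rh_max - preset.outdoor_rh_min)
    rhout = rh_mesor - rh_amp * s + _ar1(rng, n, sd[RHOUT], phi)
    if sd[RHOUT] > 0:
        rhout = np.clip(rhout, 0.0, 100.0)

    # fans ramp with daytime heat
    ws = preset.wind_mean * (1.0 + 0.4 * s) + _ar1(rng, n, sd[WS], phi)
    if sd[WS] > 0:
        ws = np.clip(ws, 0.0, None)
    ws_anom = ws - preset.wind_mean

    tin = (
        preset.indoor_offset_temp
        + _lowpass(tout, step, preset.lag_minutes)
        + C[TIN, WS] * ws_anom
        + _ar1(rng, n, sd[TIN], phi)
    )
    tin_anom = tin - tin.mean()

    rhin = (
        preset.indoor_rh_level
        + C[RHIN, TIN] * tin_anom
        + C[RHIN, RHOUT] * _lowpass(rhout - rh_mesor, step, preset.lag_minutes)
        + _ar1(rng, n, sd[RHIN], phi)
    )
    if sd[RHIN] > 0:
        rhin = np.clip(rhin, 0.0, 100.0)

    # CO2 builds overnight (low ventilation), flushed during the day
    co2 = (
        preset.co2_base
        - preset.co2_amplitude * np.sin(2.0 * np.pi * (minute - _PHASE_OFFSET_MIN + 120.0) / 1440.0)
        + C[CO2, TIN] * tin_anom
        + C[CO2, WS] * ws_anom
        + _ar1(rng, n, sd[CO2], phi)
    )
    if sd[CO2] > 0:
        co2 = np.clip(co2, 350.0, None)

    idx = pd.date_range("2023-08-20", periods=n, freq=f"{step}min", name="timestamp")
    frame = pd.DataFrame(
        np.column_stack([tin, rhin, co2, ws, tout, rhout]), index=idx, columns=CHANNELS
    )
    return RawSeriesTable(frame, step)


def inject_artifacts(
    table: RawSeriesTable, config: SimulationConfig
) -> tuple[RawSeriesTable, ArtifactLog]:
    """Inject spike outliers and missing spans into a clean table.

    Spikes displace floor(outlier_rate * n_rows) points (spread over all
    channels) by 6-8 local robust standard deviations, mimicking transient
    sensor faults; each is logged. Gap spans from ``gap_spec`` mask every
    channel, mimicking logger power/network loss.
    """
    if table.mask.any():
        raise ValueError("table already contains missing values")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA27]))
    frame = table.frame.copy()
    n = len(frame)
    step = table.step_minutes

    gap_rows: list[tuple[int, int]] = []
    gap_mask = np.zeros(n, dtype=bool)
    for start, minutes in config.gap_spec:
        n_pts = minutes // step
        if start < 0 or start + n_pts > n:
            raise ValueError(
                f"gap ({start}, {minutes} min) extends beyond the table end"
            )
        gap_mask[start:start + n_pts] = True
        gap_rows.append((start, n_pts))

    half = 30  # robust-stat window half-width, in rows
    spikes: list[tuple[int, int, float, float]] = []
    n_spikes = int(config.outlier_rate * n)
    if n_spikes:
        eligible = np.flatnonzero(~gap_mask)
        eligible = eligible[(eligible >= half) & (eligible < n - half)]
        cells = rng.choice(eligible.size * 6, size=n_spikes, replace=False)
        values = frame.to_numpy()
        for cell in np.sort(cells):
            row = int(eligible[cell // 6])
            ch = int(cell % 6)
            window = values[row - half:row + half + 1, ch]
            med = float(np.median(window))
            scale = 1.4826 * float(np.median(np.abs(window - med)))
            scale = max(scale, 0.01 * max(abs(med), 1.0))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            magnitude = rng.uniform(6.0, 8.0)
            original = float(values[row, ch])
            injected = med + sign * magnitude * scale
            frame.iloc[row, ch] = injected
            spikes.append((row, ch, original, injected))

    frame.iloc[gap_mask, :] = np.nan
    return RawSeriesTable(frame, step), ArtifactLog(spikes=spikes, gap_rows=gap_rows)


def pearson_matrix(table: RawSeriesTable) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of the six channels.

    Constant channels yield NaN entries (undefined correlation), flagged
    with a warning rather than silently reported as zero.
    """
    notna = table.frame.notna()
    pair_counts = notna.T.astype(int) @ notna.astype(int)
    if (pair_counts.to_numpy() < 3).any():
        raise ValueError("every channel pair needs >= 3 complete observations")
    corr = table.frame.corr(method="pearson", min_periods=3)
    off = ~np.eye(6, dtype=bool)
    if np.isnan(corr.to_numpy()[off]).any():
        warnings.warn("constant channel: undefined correlation entries left as NaN")
    return corr
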