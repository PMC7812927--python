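"""Climate series: reading, validation, PET fallback and a synthetic generator.

The model consumes daily precipitation (mm) and evapotranspiration (mm); if a
file provides only temperature, potential evapotranspiration is derived with
a Hamon-type formula (daylength times saturation vapour density).  The
synthetic generator produces a sinusoidal annual temperature cycle and
Bernoulli-exponential rainfall, seeded and reproducible, for fully offline
runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_state import ValidationError

__all__ = ["ClimateSeries", "hamon_pet", "read_climate", "synthetic_climate"]


@dataclass
class ClimateSeries:
    """Daily climate: ISO dates, precipitation (mm), ET (mm), temperature (C)."""

    dates: np.ndarray  # datetime64[D]
    p: np.ndarray
    e: np.ndarray
    t: np.ndarray
    pet_derived: bool = False

    def __post_init__(self):
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.p = np.asarray(self.p, dtype=float)
        self.e = np.asarray(self.e, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        n = len(self.dates)
        if not (len(self.p) == len(self.e) == len(self.t) == n):
            raise ValidationError("climate columns have unequal lengths")
        gaps = np.diff(self.dates).astype(int)
        bad = np.nonzero(gaps != 1)[0]
        if bad.size:
            rows = ", ".join(str(self.dates[i + 1]) for i in bad[:10])
            raise ValidationError(f"climate dates must be consecutive days; offending rows at: {rows}")
        if (self.p < 0).any():
            rows = ", ".join(str(self.dates[i]) for i in np.nonzero(self.p < 0)[0][:10])
            raise ValidationError(f"negative precipitation at: {rows}")
        if (self.e < 0).any():
            raise ValidationError("negative evapotranspiration")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def doy(self) -> np.ndarray:
        years = self.dates.astype("datetime64[Y]")
        return (self.dates - years.astype("datetime64[D]")).astype(int) + 1

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates.astype(str),
                "precipitation_mm": self.p,
                "et_mm": self.e,
                "temperature_c": self.t,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def hamon_pet(t: np.ndarray, doy: np.ndarray, latitude: float = 51.3) -> np.ndarray:
    """Hamon-type daily potential evapotranspiration (mm day^-1).

    PET = 29.8 * daylength_h * e_sat / (T + 273.2), with e_sat in kPa from
    the Magnus formula and daylength from solar declination at ``latitude``.
    A simple stand-in for site-calibrated PET, used only when the climate
    file lacks an ET column.
    """
    t = np.asarray(t, dtype=float)
    phi = np.deg2rad(latitude)
    decl = 0.4093 * np.sin(2.0 * np.pi * (284.0 + np.asarray(doy)) / 365.0)
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    daylength = 24.0 * np.arccos(cos_omega) / np.pi
    e_sat = 0.611 * np.exp(17.27 * t / (t + 237.3))
    pet = 29.8 * daylength * e_sat / (t + 273.2)
    return np.maximum(pet, 0.0)


def read_climate(path, latitude: float = 51.3) -> ClimateSeries:
    """Read a delimited climate file (columns: date, precipitation_mm, and
    et_mm and/or temperature_c).

    Missing or duplicated days raise with the offending rows listed; if only
    temperature is present, PET is derived via :func:`hamon_pet` and the
    series is flagged ``pet_derived``.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "date" not in df.columns or "precipitation_mm" not in df.columns:
        raise ValidationError("climate file needs 'date' and 'precipitation_mm' columns")
    dates = np.asarray(df["date"], dtype="datetime64[D]")
    dup = pd.Index(dates).duplicated()
    if dup.any():
        rows = ", ".join(str(d) for d in dates[dup][:10])
        raise ValidationError(f"duplicate climate dates: {rows}")
    p = df["precipitation_mm"].to_numpy(dtype=float)
    t = df["temperature_c"].to_numpy(dtype=float) if "temperature_c" in df.columns else np.full(len(p), np.nan)
    if "et_mm" in df.columns:
        e = df["et_mm"].to_numpy(dtype=float)
        derived = False
    else:
        if np.isnan(t).any():
            raise ValidationError("need either 'et_mm' or a complete 'temperature_c' column")
        years = dates.astype("datetime64[Y]")
        doy = (dates - years.astype("datetime64[D]")).astype(int) + 1
        e = hamon_pet(t, doy, latitude)
        derived = True
    if np.isnan(t).all():
        t = np.full(len(p), 10.0)
    return ClimateSeries(dates, p, e, t, pet_derived=derived)


def synthetic_climate(
    n_days: int,
    mean_t: float = 10.5,
    t_amplitude: float = 7.5,
    annual_p: float = 850.0,
    wet_day_prob: float = 0.45,
    seed: int = 0,
    start: str = "1999-01-01",
    latitude: float = 51.3,
    t_noise_sd: float = 2.0,
) -> ClimateSeries:
    """Synthetic temperate-maritime daily climate, seeded and reproducible.

    Temperature is a sinusoid peaking in late July plus Gaussian noise;
    rain falls on Bernoulli(``wet_day_prob``) days with exponential depths
    whose mean is tuned so the expected annual total equals ``annual_p``;
    ET is Hamon PET from the generated temperature.  Defaults emulate a
    Belgian Campine pine-forest climate.
    """
    if n_days <= 0:
        raise ValidationError("n_days must be positive")
    if not 0.0 <= wet_day_prob <= 1.0:
        raise ValidationError("wet_day_prob must be in [0,1]")
    rng = np.random.default_rng(seed)
    dates = np.datetime64(start, "D") + np.arange(n_days)
    years = dates.astype("datetime64[Y]")
    doy = (dates - years.astype("datetime64[D]")).astype(int) + 1
    t = (
        mean_t
        + t_amplitude * np.sin(2.0 * np.pi * (doy - 105.0) / 365.25)
        + rng.normal(0.0, t_noise_sd, n_days)
    )
    if wet_day_prob > 0.0:
        wet = rng.random(n_days) < wet_day_prob
        mean_depth = annual_p / (365.25 * wet_day_prob)
        p = np.where(wet, rng.exponential(mean_depth, n_days), 0.0)
    else:
        p = np.zeros(n_days)
    e = hamon_pet(t, doy, latitude)
    return ClimateSeries(dates, p, e, t, pet_derived=True)
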