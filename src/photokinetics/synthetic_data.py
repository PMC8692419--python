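"""Seeded generators emulating the illumination experiments.

Everything the analysis pipeline consumes can be generated here at desk
scale with known ground truth: photoconversion traces (10 min of 400 nm
light, 1 Hz sampling), on-to-off switching cycle series (10 min of
470 nm light per cycle, instantaneous 400 nm regeneration between
cycles, pH 9.2 buffer), thermal-relaxation absorbance recoveries,
Gaussian emission bands with optional per-cycle blue-shifts, and
Henderson–Hasselbalch titration curves — each with additive Gaussian
noise under a fixed seed, so identical seeds give identical data.

Variant presets transcribe the measured rate constants, amplitude
ratios, pK_a and brightness parameters of the mSAASoti cysteine-mutant
panel (see ``presets.yaml``); per-cycle fatigue and spectral-shift
magnitudes are reconstructed defaults flagged in that file.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .cycle_analysis import CycleSeries, RegenerationPulse
from .errors import InvalidParameterError
from .fitting import Illumination, TimeTrace
from .kinetic_models import (
    BiexpParams,
    ConversionParams,
    MonoexpParams,
    eval_biexp,
    eval_photoconversion,
    eval_relaxation,
)
from .spectra_titration import Spectrum, TitrationSeries

__all__ = [
    "NoiseModel",
    "VariantPreset",
    "available_presets",
    "load_preset",
    "gen_conversion_trace",
    "gen_relaxation_trace",
    "gen_cycle_series",
    "gen_titration",
    "gen_spectrum_pair",
]

#: default conditions: 1 Hz sampling over the 10 min illumination window
DEFAULT_N_POINTS = 600
DEFAULT_T_END = 600.0

CONVERSION_LIGHT = Illumination(wavelength_nm=400.0, irradiance_mw_cm2=146.0)
SWITCHING_LIGHT = Illumination(wavelength_nm=470.0, irradiance_mw_cm2=167.0)

EMISSION_GRID_NM = (480.0, 650.0, 1.0)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise of scale ``sigma`` (a.u.) under a fixed
    seed.  The default sigma is 1% of the unit peak amplitude — the
    recorded traces are low-noise, and 1% keeps recovery tolerances
    meaningful."""

    kind: str = "gaussian_additive"
    sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind != "gaussian_additive":
            raise InvalidParameterError(f"unsupported noise kind {self.kind!r}")
        if not np.isfinite(self.sigma) or self.sigma < 0:
            raise InvalidParameterError(f"sigma must be >= 0, got {self.sigma}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class VariantPreset:
    """Ground-truth parameter set for one protein variant."""

    name: str
    conversion: ConversionParams
    switch_cycle1: BiexpParams
    switch_cycle2: BiexpParams
    relaxation: MonoexpParams
    fatigue: float
    blue_shift_per_cycle_nm: float
    pka_green: float
    epsilon_1e3: float
    phi: float
    reconstructed: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.fatigue <= 1.0:
            raise InvalidParameterError(f"fatigue must lie in (0, 1], got {self.fatigue}")


@lru_cache(maxsize=1)
def _preset_table() -> dict:
    text = resources.files("photokinetics").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> tuple[str, ...]:
    return tuple(_preset_table()["variants"])


def _switch_params(entry: dict) -> BiexpParams:
    ratio = float(entry["ratio"])
    k1 = float(entry["k1"]) * 1e-3
    k2 = float(entry["k2"]) * 1e-3 if entry["k2"] is not None else k1
    return BiexpParams(I1=1.0, k1=k1, I2=ratio, k2=k2, c=0.0,
                       opposed=bool(entry["opposed"]))


def load_preset(name: str) -> VariantPreset:
    table = _preset_table()["variants"]
    if name not in table:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(table)}")
    v = table[name]
    return VariantPreset(
        name=name,
        conversion=ConversionParams(
            amplitude_I=1.0,
            k1=float(v["conversion"]["k1"]) * 1e-3,
            k2=float(v["conversion"]["k2"]) * 1e-3,
            c=0.0,
        ),
        switch_cycle1=_switch_params(v["switch_cycle1"]),
        switch_cycle2=_switch_params(v["switch_cycle2"]),
        relaxation=MonoexpParams(A0=1.0, k=float(v["recovery"]["k"]) * 1e-3, c=0.0),
        fatigue=float(v["fatigue"]),
        blue_shift_per_cycle_nm=float(v["blue_shift_per_cycle_nm"]),
        pka_green=float(v["pka_green"]),
        epsilon_1e3=float(v["epsilon_1e3"]),
        phi=float(v["phi"]),
        reconstructed=tuple(v.get("reconstructed", ())),
    )


def _sample_grid(n_points: int, t_end: float) -> np.ndarray:
    if n_points < 8:
        raise InvalidParameterError(f"n_points must be >= 8, got {n_points}")
    return np.arange(n_points) * (t_end / n_points)


def _add_noise(y: np.ndarray, rng: np.random.Generator, sigma: float) -> np.ndarray:
    return y if sigma == 0 else y + rng.normal(0.0, sigma, size=y.shape)


def gen_conversion_trace(
    preset: VariantPreset,
    n_points: int = DEFAULT_N_POINTS,
    t_end: float = DEFAULT_T_END,
    noise: NoiseModel | None = None,
) -> TimeTrace:
    """Green-to-red photoconversion trace under 400 nm illumination."""
    noise = noise or NoiseModel()
    t = _sample_grid(n_points, t_end)
    y = eval_photoconversion(preset.conversion, t)
    y = _add_noise(y, noise.rng(), noise.sigma)
    illum = Illumination(CONVERSION_LIGHT.wavelength_nm,
                         CONVERSION_LIGHT.irradiance_mw_cm2, t_end)
    return TimeTrace(t=t, y=y, kind="photoconversion", illumination=illum)


def gen_relaxation_trace(
    preset: VariantPreset,
    n_points: int = DEFAULT_N_POINTS,
    t_end: float = DEFAULT_T_END,
    noise: NoiseModel | None = None,
) -> TimeTrace:
    """Thermal off-to-on recovery, recorded as anionic-form absorbance."""
    noise = noise or NoiseModel()
    t = _sample_grid(n_points, t_end)
    y = eval_relaxation(preset.relaxation, t)
    y = _add_noise(y, noise.rng(), noise.sigma)
    return TimeTrace(t=t, y=y, kind="relaxation", illumination=None)


def _initial_value(p: BiexpParams) -> float:
    return p.I1 - p.I2 + p.c if p.opposed else p.I1 + p.I2 + p.c


def _gaussian_band(center: float, width: float, rng: np.random.Generator,
                   sigma: float) -> Spectrum:
    lo, hi, step = EMISSION_GRID_NM
    wl = np.arange(lo, hi + step / 2, step)
    inten = np.exp(-0.5 * ((wl - center) / width) ** 2)
    inten = _add_noise(inten, rng, sigma)
    return Spectrum(wavelength=wl, intensity=inten)


def gen_cycle_series(
    preset: VariantPreset,
    n_cycles: int = 3,
    noise: NoiseModel | None = None,
    *,
    n_points: int = DEFAULT_N_POINTS,
    t_cycle: float = DEFAULT_T_END,
    with_spectra: bool = True,
) -> CycleSeries:
    """Repeated on-to-off switching cycles with photofatigue.

    Cycle 1 follows the preset's first-cycle kinetics (opposed for
    wt-like variants, same-sign/mono for C175A-like); later cycles follow
    the second-cycle kinetics with the t=0 intensity scaled to
    ``fatigue^(cycle-1)`` of the first cycle's — the 400 nm regeneration
    pulse is treated as instantaneous and complete.  For variants with a
    nonzero ``blue_shift_per_cycle_nm`` the attached emission spectra
    (index 0 = before illumination) shift accordingly.
    """
    if n_cycles < 1:
        raise InvalidParameterError(f"n_cycles must be >= 1, got {n_cycles}")
    noise = noise or NoiseModel()
    rng = noise.rng()
    t = _sample_grid(n_points, t_cycle)
    y0_ref = _initial_value(preset.switch_cycle1)
    illum = Illumination(SWITCHING_LIGHT.wavelength_nm,
                         SWITCHING_LIGHT.irradiance_mw_cm2, t_cycle)
    traces = []
    for i in range(n_cycles):
        base = preset.switch_cycle1 if i == 0 else preset.switch_cycle2
        scale = 1.0 if i == 0 else preset.fatigue ** i * y0_ref / _initial_value(base)
        p = BiexpParams(I1=base.I1 * scale, k1=base.k1, I2=base.I2 * scale,
                        k2=base.k2, c=base.c * scale, opposed=base.opposed)
        y = _add_noise(eval_biexp(p, t), rng, noise.sigma)
        traces.append(TimeTrace(t=t, y=y, kind="switch_on_off", illumination=illum))

    spectra = None
    if with_spectra:
        defaults = _preset_table()["defaults"]
        center = float(defaults["emission_center_nm"])
        width = float(defaults["emission_width_nm"])
        spectra = tuple(
            _gaussian_band(center + preset.blue_shift_per_cycle_nm * i, width,
                           rng, noise.sigma)
            for i in range(n_cycles + 1)
        )
    return CycleSeries(cycles=tuple(traces), regeneration=RegenerationPulse(),
                       buffer_ph=9.2, spectra=spectra)


def gen_titration(
    pka: float,
    n_points: int = 12,
    ph_range: tuple[float, float] = (4.0, 9.0),
    noise: NoiseModel | None = None,
    *,
    s_min: float = 0.0,
    s_max: float = 1.0,
    hill: float = 1.0,
) -> TitrationSeries:
    """Henderson–Hasselbalch titration of the chromophore around ``pka``."""
    lo, hi = ph_range
    if not lo < pka < hi:
        raise InvalidParameterError(f"ph_range {ph_range} must span pKa {pka}")
    noise = noise or NoiseModel()
    ph = np.linspace(lo, hi, n_points)
    signal = s_min + (s_max - s_min) / (1.0 + 10.0 ** (hill * (pka - ph)))
    signal = _add_noise(signal, noise.rng(), noise.sigma)
    return TitrationSeries(ph=ph, signal=signal)


def gen_spectrum_pair(
    center: float = 519.0,
    shift: float = -3.0,
    width: float = 15.0,
    noise: NoiseModel | None = None,
) -> tuple[Spectrum, Spectrum]:
    """Before/after emission bands: Gaussian at ``center`` and at
    ``center + shift`` on a 1 nm grid (negative shift = blue-shift)."""
    if width <= 0:
        raise InvalidParameterError(f"width must be > 0, got {width}")
    noise = noise or NoiseModel()
    rng = noise.rng()
    before = _gaussian_band(center, width, rng, noise.sigma)
    after = _gaussian_band(center + shift, width, rng, noise.sigma)
    return before, after
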