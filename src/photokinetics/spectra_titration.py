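"""Emission spectra and steady-state photophysics.

Peak localisation with sub-grid precision (needed to quantify the small
cycle-to-cycle emission blue-shifts that accompany cysteine
photo-oxidation), Henderson–Hasselbalch pK_a fitting of pH titrations of
the chromophore (only the anionic form absorbs/emits at ~509/519 nm),
and molecular brightness epsilon * phi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    InvalidParameterError,
    NoPeakError,
    PartialCoverageWarning,
    UnidentifiableError,
)

__all__ = [
    "Spectrum",
    "TitrationSeries",
    "PhotophysicsRecord",
    "PkaFit",
    "emission_max",
    "blue_shift",
    "fit_pka",
    "brightness",
]


@dataclass(frozen=True)
class Spectrum:
    """An emission band: wavelength (nm, strictly increasing, within the
    visible/near-UV window) versus intensity (a.u.)."""

    wavelength: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "intensity", inten)
        if wl.ndim != 1 or wl.shape != inten.shape:
            raise InvalidParameterError("wavelength and intensity must match 1-D shapes")
        if wl.size < 16:
            raise InvalidParameterError(f"spectrum needs >= 16 points, got {wl.size}")
        if np.any(np.diff(wl) <= 0):
            raise InvalidParameterError("wavelengths must be strictly increasing")
        if wl[0] < 300 or wl[-1] > 800:
            raise InvalidParameterError("wavelengths must lie within [300, 800] nm")
        if not np.all(np.isfinite(inten)):
            raise InvalidParameterError("intensity contains non-finite values")


@dataclass(frozen=True)
class TitrationSeries:
    """Signal (anionic-form absorbance or fluorescence) versus pH."""

    ph: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "signal", sig)
        if ph.ndim != 1 or ph.shape != sig.shape:
            raise InvalidParameterError("ph and signal must match 1-D shapes")
        if ph.size < 6:
            raise InvalidParameterError(f"titration needs >= 6 points, got {ph.size}")
        if np.any(np.diff(ph) <= 0):
            raise InvalidParameterError("pH values must be strictly increasing")
        if ph[0] < 3 or ph[-1] > 12:
            raise InvalidParameterError("pH values must lie within [3, 12]")
        if not np.all(np.isfinite(sig)):
            raise InvalidParameterError("signal contains non-finite values")


@dataclass(frozen=True)
class PhotophysicsRecord:
    """Molar extinction (10^3 M^-1 cm^-1), fluorescence quantum yield and
    their product, the molecular brightness."""

    epsilon: float
    phi: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.epsilon) or self.epsilon <= 0:
            raise InvalidParameterError(f"epsilon must be > 0, got {self.epsilon}")
        if not np.isfinite(self.phi) or not 0.0 <= self.phi <= 1.0:
            raise InvalidParameterError(f"phi must lie in [0, 1], got {self.phi}")

    @property
    def brightness(self) -> float:
        return brightness(self.epsilon, self.phi)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with reflected edges; window forced odd."""
    if window <= 1:
        return y
    if window % 2 == 0:
        window += 1
    pad = window // 2
    padded = np.pad(y, pad, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def emission_max(
    s: Spectrum,
    *,
    smooth_window: int = 5,
    log_parabolic: bool = False,
    method: str = "quadratic",
) -> float:
    """Peak wavelength with sub-grid precision.

    ``method="quadratic"``: the band is lightly smoothed, the discrete
    maximum located, and a 3-point quadratic (optionally log-parabolic,
    exact for a Gaussian band) interpolation refines the peak position
    below the sampling step.  This is model-free but uses only the
    curvature right at the maximum, where the position information is
    weakest, so its noise floor is a few tenths of a nm on a realistic
    band.

    ``method="gaussian"``: a least-squares Gaussian-plus-baseline fit of
    the whole band, seeded by the quadratic estimate.  Because the
    position information of a band sits in its flanks, this reaches
    roughly tenfold better precision and is what `blue_shift` uses.

    A spectrum whose maximum sits on the grid edge has no interior peak
    and raises :class:`NoPeakError`.
    """
    wl, y = s.wavelength, _smooth(s.intensity, smooth_window)
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        raise NoPeakError("spectrum is monotone over the sampled range; no interior peak")
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    if log_parabolic:
        if min(y0, y1, y2) <= 0:
            raise NoPeakError("log-parabolic interpolation needs positive intensities")
        y0, y1, y2 = np.log(y0), np.log(y1), np.log(y2)
    denom = y0 - 2.0 * y1 + y2
    delta = 0.0 if denom == 0 else float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))
    step = 0.5 * (wl[i + 1] - wl[i - 1])
    peak = float(wl[i] + delta * step)
    if method == "quadratic":
        return peak
    if method != "gaussian":
        raise ValueError(f"unknown peak method {method!r}")

    amp0 = float(y[i])
    base0 = float(np.min(y))
    width0 = max(_fwhm_estimate(wl, y, i) / 2.3548, 2.0 * (wl[1] - wl[0]))
    x0 = np.array([peak, amp0 - base0, width0, base0])

    def resid(x: np.ndarray) -> np.ndarray:
        mu, amp, width, base = x
        return amp * np.exp(-0.5 * ((s.wavelength - mu) / width) ** 2) + base - s.intensity

    res = least_squares(resid, x0, method="lm")
    mu = float(res.x[0])
    if not res.success or not wl[0] <= mu <= wl[-1]:
        raise NoPeakError("Gaussian band fit did not locate a peak in range")
    return mu


def _fwhm_estimate(wl: np.ndarray, y: np.ndarray, i_peak: int) -> float:
    half = 0.5 * (y[i_peak] + np.min(y))
    above = y >= half
    return float(wl[above][-1] - wl[above][0]) if above.any() else 10.0


def blue_shift(before: Spectrum, after: Spectrum, *, method: str = "gaussian",
               **peak_kwargs) -> float:
    """Signed peak displacement after illumination, in nm; negative
    values are blue-shifts.  Uses the Gaussian band fit by default —
    cycle-to-cycle shifts are fractions of the sampling step, below the
    noise floor of the local quadratic estimator."""
    return (emission_max(after, method=method, **peak_kwargs)
            - emission_max(before, method=method, **peak_kwargs))


@dataclass(frozen=True)
class PkaFit:
    """Henderson–Hasselbalch fit: pK_a with its standard error, the
    asymptotic signal levels and the Hill exponent used."""

    pka: float
    stderr: float
    s_min: float
    s_max: float
    hill: float
    rss: float
    converged: bool


def _hh_model(x: np.ndarray, ph: np.ndarray, hill: float | None) -> np.ndarray:
    pka, amp, s_min = x[:3]
    h = x[3] if hill is None else hill
    return s_min + amp / (1.0 + 10.0 ** (h * (pka - ph)))


def fit_pka(
    ts: TitrationSeries, *, hill: float = 1.0, fit_hill: bool = False
) -> PkaFit:
    """Least-squares Henderson–Hasselbalch fit of a titration.

    The model is ``S(pH) = S_min + (S_max - S_min)/(1 + 10^{n(pKa - pH)})``
    with a single protonatable group (Hill exponent ``n = 1``) by
    default.  Emits :class:`PartialCoverageWarning` when the series does
    not span a full pH unit on each side of the inflection, and raises
    :class:`UnidentifiableError` for flat series or when the fitted pK_a
    falls outside the sampled pH range.
    """
    ph, sig = ts.ph, ts.signal
    span = float(np.ptp(sig))
    noise = float(np.median(np.abs(np.diff(sig) - np.median(np.diff(sig)))) / 0.6745 / np.sqrt(2))
    if span <= 0 or span < 10.0 * noise:
        raise UnidentifiableError("titration signal is flat; no inflection in range")

    s_min0 = float(np.min(sig))
    amp0 = span
    half = s_min0 + 0.5 * amp0
    pka0 = float(ph[int(np.argmin(np.abs(sig - half)))])
    if pka0 - ph[0] < 1.0 or ph[-1] - pka0 < 1.0:
        warnings.warn(
            f"titration spans < 1 pH unit on one side of the inflection (~{pka0:.2f})",
            PartialCoverageWarning,
            stacklevel=2,
        )

    x0 = [pka0, amp0, s_min0]
    lower = [ph[0] - 1.0, 0.0, -np.inf]
    upper = [ph[-1] + 1.0, np.inf, np.inf]
    if fit_hill:
        x0.append(hill)
        lower.append(0.1)
        upper.append(4.0)
    fixed_hill = None if fit_hill else hill

    res = least_squares(
        lambda x: _hh_model(x, ph, fixed_hill) - sig,
        np.asarray(x0, dtype=float),
        bounds=(lower, upper),
        method="trf",
    )
    pka_hat = float(res.x[0])
    if not res.success or not ph[0] <= pka_hat <= ph[-1]:
        raise UnidentifiableError(
            f"fitted pKa {pka_hat:.2f} outside sampled range [{ph[0]}, {ph[-1]}]"
        )
    rss = float(2.0 * res.cost)
    dof = ph.size - res.x.size
    if dof > 0 and rss > 0:
        cov = (rss / dof) * np.linalg.pinv(res.jac.T @ res.jac)
        se = float(np.sqrt(max(cov[0, 0], 0.0)))
    else:
        se = 0.0
    return PkaFit(
        pka=pka_hat,
        stderr=se,
        s_min=float(res.x[2]),
        s_max=float(res.x[2] + res.x[1]),
        hill=float(res.x[3]) if fit_hill else hill,
        rss=rss,
        converged=bool(res.success),
    )


def brightness(epsilon: float, phi: float) -> float:
    """Molecular brightness epsilon * phi, rounded half-up to one decimal
    (the convention of the published tables, in 10^3 M^-1 cm^-1 when
    epsilon is given in those units)."""
    if not np.isfinite(epsilon) or epsilon <= 0:
        raise InvalidParameterError(f"epsilon must be > 0, got {epsilon}")
    if not np.isfinite(phi) or not 0.0 <= phi <= 1.0:
        raise InvalidParameterError(f"phi must lie in [0, 1], got {phi}")
    product = Decimal(str(epsilon)) * Decimal(str(phi))
    return float(product.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
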