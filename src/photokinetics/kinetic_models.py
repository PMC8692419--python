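"""Closed-form kinetics of fluorescent-protein chromophore phototransformations.

Biphotochromic fluorescent proteins undergo two light-driven reactions:
an irreversible green-to-red photoconversion (violet, ~400 nm) and a
reversible on/off photoswitching (blue, ~470 nm) of the green form, whose
dark state recovers either thermally or under a short 400 nm pulse.  At
fixed irradiance both behave as first-order processes with effective rate
constants, which gives four closed-form signal models:

* photoconversion — a consecutive monomolecular process
  Green -> Red -> Bleached; the red-channel fluorescence follows
  ``I(t) = I * k1/(k2 - k1) * (exp(-k1 t) - exp(-k2 t)) + c``
  where ``k1`` is red-form formation, ``k2`` its photodestruction and
  ``c`` a background/residual offset;
* on-to-off switching, first illumination cycle — opposed bi-exponential
  ``I(t) = I1 exp(-k1 t) - I2 exp(-k2 t) + c`` (the negative component
  reflects a transient green-intensity increase);
* on-to-off switching, later cycles — same-sign bi-exponential
  ``I(t) = I1 exp(-k1 t) + I2 exp(-k2 t) + c``;
* thermal relaxation (dark -> fluorescent recovery) — mono-exponential
  rise ``A(t) = A0 * (1 - exp(-k t)) + c``.

A generic first-order reaction-network integrator (`integrate_scheme`)
serves both as a brute-force numerical oracle for the closed forms and as
the simulator for multi-population schemes such as cysteine
photo-oxidation, where a second, photo-oxidised population switches with
its own rate constants.

All times are seconds and all rates s^-1 unless a trace declares
otherwise; signals are in arbitrary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    DegenerateParametersError,
    InvalidParameterError,
    InvalidSchemeError,
    NormalizationUndefinedError,
)

__all__ = [
    "ConversionParams",
    "BiexpParams",
    "LinExpParams",
    "MonoexpParams",
    "eval_linexp",
    "KineticScheme",
    "SchemeResult",
    "eval_photoconversion",
    "eval_biexp",
    "eval_relaxation",
    "integrate_scheme",
    "normalized_trace",
    "halflife",
    "LN2",
]

LN2 = math.log(2.0)

#: relative rate separation below which the photoconversion closed form
#: is treated as degenerate
_RATE_EQUAL_RTOL = 1e-9


def _check_finite(**values: float) -> None:
    for name, value in values.items():
        if not np.isfinite(value):
            raise InvalidParameterError(f"{name} must be finite, got {value!r}")


def _time_grid(t) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError("time grid contains non-finite values")
    if np.any(arr < 0):
        raise InvalidParameterError("time values must be >= 0")
    return arr


@dataclass(frozen=True)
class ConversionParams:
    """Parameters of the green-to-red photoconversion model.

    ``amplitude_I`` is the pre-exponential factor (the red-form signal
    that would be reached without photodestruction scales with it),
    ``k1`` the red-form formation rate, ``k2`` its photodestruction rate
    and ``c`` the background plus residual signal.
    """

    amplitude_I: float
    k1: float
    k2: float
    c: float = 0.0

    def __post_init__(self) -> None:
        _check_finite(amplitude_I=self.amplitude_I, k1=self.k1, k2=self.k2, c=self.c)
        if self.k1 <= 0:
            raise InvalidParameterError(f"k1 must be > 0, got {self.k1}")
        if self.k2 < 0:
            raise InvalidParameterError(f"k2 must be >= 0, got {self.k2}")
        if self.amplitude_I < 0:
            raise InvalidParameterError(f"amplitude_I must be >= 0, got {self.amplitude_I}")


@dataclass(frozen=True)
class BiexpParams:
    """Parameters of the bi-exponential photoswitching model.

    ``opposed=True`` selects the first-cycle sign convention
    ``I1 exp(-k1 t) - I2 exp(-k2 t) + c``; ``opposed=False`` the same-sign
    later-cycle form.  The sign of the second component is carried
    exclusively by ``opposed`` — amplitudes stay non-negative.
    """

    I1: float
    k1: float
    I2: float
    k2: float
    c: float = 0.0
    opposed: bool = True

    def __post_init__(self) -> None:
        _check_finite(I1=self.I1, k1=self.k1, I2=self.I2, k2=self.k2, c=self.c)
        if self.I1 < 0 or self.I2 < 0:
            raise InvalidParameterError("amplitudes I1, I2 must be >= 0")
        if self.k1 <= 0 or self.k2 <= 0:
            raise InvalidParameterError("rates k1, k2 must be > 0")


@dataclass(frozen=True)
class LinExpParams:
    """Coincident-rate limit of the opposed bi-exponential,
    ``(A + B t) exp(-k t) + c``.

    As k2 -> k1 with the opposed amplitudes growing as I2 = B/(k2 - k1),
    ``I1 exp(-k1 t) - I2 exp(-k2 t)`` tends to this linear-times-
    exponential form; noise can push the least-squares optimum of a
    first switching cycle onto that boundary, where the separate rates
    are no longer identifiable but the opposed (transient-rise)
    component clearly is.
    """

    A: float
    B: float
    k: float
    c: float = 0.0

    def __post_init__(self) -> None:
        _check_finite(A=self.A, B=self.B, k=self.k, c=self.c)
        if self.A < 0 or self.B < 0:
            raise InvalidParameterError("amplitudes A, B must be >= 0")
        if self.k <= 0:
            raise InvalidParameterError(f"rate k must be > 0, got {self.k}")


def eval_linexp(p: LinExpParams, t) -> np.ndarray:
    """Linear-times-exponential signal ``(A + B t) exp(-k t) + c``."""
    t = _time_grid(t)
    return (p.A + p.B * t) * np.exp(-p.k * t) + p.c


@dataclass(frozen=True)
class MonoexpParams:
    """Parameters of the mono-exponential thermal-relaxation model:
    recovery amplitude ``A0``, rate ``k`` and offset ``c``."""

    A0: float
    k: float
    c: float = 0.0

    def __post_init__(self) -> None:
        _check_finite(A0=self.A0, k=self.k, c=self.c)
        if self.A0 < 0:
            raise InvalidParameterError(f"A0 must be >= 0, got {self.A0}")
        if self.k <= 0:
            raise InvalidParameterError(f"k must be > 0, got {self.k}")


def _bateman_shape(k1: float, k2: float, t: np.ndarray) -> np.ndarray:
    """k1/(k2-k1) * (exp(-k1 t) - exp(-k2 t)), evaluated stably.

    Rewritten as ``k1 * exp(-min(k1,k2) t) * (1 - exp(-|k2-k1| t))/|k2-k1|``
    (an identity for either rate ordering) so the difference of
    exponentials never cancels catastrophically nor overflows; the
    fraction tends to ``t`` as k2 -> k1.
    """
    ad = abs(k2 - k1)
    klo = min(k1, k2)
    x = ad * t
    frac = np.where(x < 1e-12, t, -np.expm1(-x) / (ad if ad != 0 else 1.0))
    return k1 * np.exp(-klo * t) * frac


def eval_photoconversion(
    p: ConversionParams, t, *, allow_equal_rates: bool = False
) -> np.ndarray:
    """Red-channel intensity of the consecutive Green->Red->Bleached process.

    Raises :class:`DegenerateParametersError` when ``k1 == k2`` (to within
    1e-9 relative) unless ``allow_equal_rates`` is set, in which case the
    L'Hopital limit ``I * k1 * t * exp(-k1 t) + c`` is returned.  The
    degenerate default is deliberate: coincident rates are not
    identifiable from a single trace and should surface, not be hidden.
    """
    t = _time_grid(t)
    if abs(p.k2 - p.k1) <= _RATE_EQUAL_RTOL * max(p.k1, p.k2):
        if not allow_equal_rates:
            raise DegenerateParametersError(
                f"k1 == k2 == {p.k1}; pass allow_equal_rates=True for the "
                "I*k1*t*exp(-k1*t) limit"
            )
        return p.amplitude_I * p.k1 * t * np.exp(-p.k1 * t) + p.c
    return p.amplitude_I * _bateman_shape(p.k1, p.k2, t) + p.c


def eval_biexp(p: BiexpParams, t) -> np.ndarray:
    """Bi-exponential switching signal; sign of the second term set by
    ``p.opposed``."""
    t = _time_grid(t)
    sign = -1.0 if p.opposed else 1.0
    return p.I1 * np.exp(-p.k1 * t) + sign * p.I2 * np.exp(-p.k2 * t) + p.c


def eval_relaxation(p: MonoexpParams, t) -> np.ndarray:
    """Mono-exponential absorbance recovery ``A0 * (1 - exp(-k t)) + c``."""
    t = _time_grid(t)
    return p.A0 * (-np.expm1(-p.k * t)) + p.c


@dataclass(frozen=True)
class KineticScheme:
    """A first-order reaction network: labelled states, rate-labelled
    transitions, initial populations and a linear fluorescence observable.

    The observable is a per-state weight vector; the signal is
    ``sum_s weight[s] * population[s](t)``, matching the monomolecular
    assumption under which the closed-form models are derived.
    """

    states: tuple[str, ...]
    transitions: tuple[tuple[str, str, float], ...]
    initial_populations: Mapping[str, float]
    observable: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        states = tuple(self.states)
        if len(set(states)) != len(states) or not states:
            raise InvalidSchemeError("states must be a non-empty set of unique labels")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "transitions", tuple(tuple(tr) for tr in self.transitions))
        for src, dst, rate in self.transitions:
            if src not in states or dst not in states:
                raise InvalidSchemeError(f"transition {src}->{dst} references unknown state")
            if not np.isfinite(rate) or rate < 0:
                raise InvalidSchemeError(f"rate for {src}->{dst} must be >= 0, got {rate}")
        for s, v in self.initial_populations.items():
            if s not in states:
                raise InvalidSchemeError(f"initial population for unknown state {s!r}")
            if not np.isfinite(v) or v < 0:
                raise InvalidSchemeError(f"initial population of {s!r} must be >= 0")
        for s, w in self.observable.items():
            if s not in states:
                raise InvalidSchemeError(f"observable weight for unknown state {s!r}")
            if not np.isfinite(w):
                raise InvalidSchemeError(f"observable weight of {s!r} must be finite")

    def rate_matrix(self) -> np.ndarray:
        """Generator matrix M such that dy/dt = M @ y."""
        idx = {s: i for i, s in enumerate(self.states)}
        m = np.zeros((len(self.states), len(self.states)))
        for src, dst, rate in self.transitions:
            m[idx[dst], idx[src]] += rate
            m[idx[src], idx[src]] -= rate
        return m

    def initial_vector(self) -> np.ndarray:
        return np.array([float(self.initial_populations.get(s, 0.0)) for s in self.states])

    def observable_vector(self) -> np.ndarray:
        return np.array([float(self.observable.get(s, 0.0)) for s in self.states])


@dataclass(frozen=True)
class SchemeResult:
    """Integrated populations (state x time) and the observable series."""

    t: np.ndarray
    states: tuple[str, ...]
    populations: np.ndarray
    observable: np.ndarray

    def population(self, state: str) -> np.ndarray:
        return self.populations[self.states.index(state)]


def integrate_scheme(
    scheme: KineticScheme, t, *, rtol: float = 1e-8, atol: float = 1e-10
) -> SchemeResult:
    """Integrate the scheme's linear ODE system on a strictly increasing
    time grid starting at 0.

    Uses an adaptive stiff-capable solver (LSODA) with tight tolerances;
    the systems are tiny, so stiff-safe accuracy is cheap.  Total
    population is conserved (to integrator tolerance) for closed schemes.
    """
    t = _time_grid(t)
    if t.size < 2 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise InvalidParameterError("t must be strictly increasing from 0 with >= 2 points")
    m = scheme.rate_matrix()
    y0 = scheme.initial_vector()
    sol = solve_ivp(
        lambda _s, y: m @ y,
        (t[0], t[-1]),
        y0,
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=atol,
        jac=lambda _s, _y: m,
    )
    if not sol.success:  # pragma: no cover - solver failure on linear systems
        raise InvalidSchemeError(f"integration failed: {sol.message}")
    pops = np.clip(sol.y, 0.0, None)
    obs = scheme.observable_vector() @ pops
    return SchemeResult(t=t, states=scheme.states, populations=pops, observable=obs)


def normalized_trace(p: ConversionParams, trace, *, mode: str = "reported") -> np.ndarray:
    """Normalise a photoconversion trace to its Imax convention.

    ``mode="reported"`` divides by ``Imax = I * (k1 - k2)/k1``, the
    convention under which 1 marks the red-form intensity that would be
    reached with no photodestruction.  Note this divisor equals neither
    the analytic maximum of the curve nor the k2=0 plateau (which is
    ``I``); ``mode="plateau"`` divides by the plateau ``I`` instead.
    """
    arr = np.asarray(trace, dtype=float)
    if mode == "reported":
        divisor = p.amplitude_I * (p.k1 - p.k2) / p.k1
    elif mode == "plateau":
        divisor = p.amplitude_I
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    if not divisor > 0:
        raise NormalizationUndefinedError(
            f"normalisation divisor {divisor} is not positive (k1 ={p.k1}, k2 ={p.k2})"
        )
    return arr / divisor


def halflife(k: float) -> float:
    """Half-life ln2/k of a first-order process, in the reciprocal of
    k's unit (τ_1/2 of thermal relaxation when k is the recovery rate)."""
    if not np.isfinite(k) or k <= 0:
        raise InvalidParameterError(f"rate must be > 0 and finite, got {k!r}")
    return LN2 / k
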