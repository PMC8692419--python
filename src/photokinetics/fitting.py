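"""Nonlinear least-squares estimation of the kinetic models from traces.

Implements model-aware initialisation heuristics, bounded trust-region
least squares with multistart restarts, parameter standard errors from
the linearised problem at the optimum, and small-sample-corrected AICc
model selection between nested exponential models.

Model identifiers:

========  =====================================================  ==========
model_id  signal model                                           parameters
========  =====================================================  ==========
eq1       I*k1/(k2-k1)*(exp(-k1 t) - exp(-k2 t)) + c             amplitude_I, k1, k2, c
eq2       I1*exp(-k1 t) - I2*exp(-k2 t) + c  (opposed)           I1, k1, I2, k2, c
eq3       I1*exp(-k1 t) + I2*exp(-k2 t) + c                      I1, k1, I2, k2, c
eq4       A0*(1 - exp(-k t)) + c  (relaxation rise)              A0, k, c
mono      I1*exp(-k1 t) + c  (single-exponential decay)          I1, k1, c
eq2lim    (A + B t)*exp(-k t) + c  (opposed, coincident rates)   A, B, k, c
========  =====================================================  ==========

The eq2lim form is the boundary of the opposed family: as k2 -> k1
with I2 = B/(k2 - k1), eq2 tends to it.  Noise can place the
least-squares optimum of a genuinely opposed cycle exactly on that
boundary, where eq2 itself cannot converge; offering the limit as its
own candidate keeps the opposed component detectable there.

Reported-parameter conventions follow the field's tables: for eq3 the
slower component is labelled 1 (k1 <= k2); for eq2 the components are
identified by sign, not magnitude; for eq1, whose curve is invariant
under (I, k1, k2) -> (I*k1/k2, k2, k1), fits are canonicalised to
k1 >= k2 (formation faster than destruction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    InvalidParameterError,
    NoModelError,
    UninformativeTraceError,
)
from .kinetic_models import BiexpParams, ConversionParams, LinExpParams, MonoexpParams

__all__ = [
    "Illumination",
    "TimeTrace",
    "FitResult",
    "ModelRanking",
    "MODEL_IDS",
    "init_guess",
    "fit_trace",
    "select_model",
    "amplitude_ratio",
]

TRACE_KINDS = ("photoconversion", "switch_on_off", "relaxation")

#: optimiser bounds shared by every model
RATE_BOUNDS = (1e-6, 10.0)


@dataclass(frozen=True)
class Illumination:
    """Illumination metadata attached to a trace (all optional)."""

    wavelength_nm: float | None = None
    irradiance_mw_cm2: float | None = None
    duration_s: float | None = None


@dataclass(frozen=True)
class TimeTrace:
    """A sampled signal-versus-time record, the universal fitting input.

    ``sigma`` is an optional per-point standard deviation used for
    weighted least squares; the default is unweighted.
    """

    t: np.ndarray
    y: np.ndarray
    kind: str = "photoconversion"
    illumination: Illumination | None = None
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise InvalidParameterError("t and y must be 1-D arrays of equal length")
        if t.size < 8:
            raise InvalidParameterError(f"trace needs >= 8 points, got {t.size}")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise InvalidParameterError("trace contains non-finite values")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise InvalidParameterError("t must be strictly increasing with t[0] >= 0")
        if self.kind not in TRACE_KINDS:
            raise InvalidParameterError(
                f"kind must be one of {TRACE_KINDS}, got {self.kind!r}"
            )
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != t.shape or np.any(~np.isfinite(s)) or np.any(s <= 0):
                raise InvalidParameterError("sigma must be positive, finite, same length")
            object.__setattr__(self, "sigma", s)

    def __len__(self) -> int:
        return int(self.t.size)


# ---------------------------------------------------------------------------
# model registry — vectorised predictors bypass the parameter dataclasses so
# the optimiser and finite-difference Jacobian can probe slightly
# out-of-bound points without tripping validation

def _predict_eq1(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    amp, k1, k2, c = x
    ad = abs(k2 - k1)
    if ad <= 1e-12 * max(abs(k1), abs(k2), 1e-300):
        return amp * k1 * t * np.exp(-k1 * t) + c
    klo = min(k1, k2)
    frac = np.where(ad * t < 1e-12, t, -np.expm1(-ad * t) / ad)
    return amp * k1 * np.exp(-klo * t) * frac + c


def _predict_eq2(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    i1, k1, i2, k2, c = x
    return i1 * np.exp(-k1 * t) - i2 * np.exp(-k2 * t) + c


def _predict_eq3(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    i1, k1, i2, k2, c = x
    return i1 * np.exp(-k1 * t) + i2 * np.exp(-k2 * t) + c


def _predict_eq4(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    a0, k, c = x
    return a0 * (-np.expm1(-k * t)) + c


def _predict_mono(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    i1, k1, c = x
    return i1 * np.exp(-k1 * t) + c


def _predict_eq2lim(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    a, b, k, c = x
    return (a + b * t) * np.exp(-k * t) + c


# analytic Jacobians (columns in parameter order); eq1 falls back to finite
# differences because its derivatives degenerate as k1 -> k2

def _jac_biexp(sign: float):
    def jac(x: np.ndarray, t: np.ndarray) -> np.ndarray:
        i1, k1, i2, k2, _c = x
        e1, e2 = np.exp(-k1 * t), np.exp(-k2 * t)
        return np.column_stack([e1, -i1 * t * e1, sign * e2,
                                -sign * i2 * t * e2, np.ones_like(t)])
    return jac


def _jac_eq4(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    a0, k, _c = x
    e = np.exp(-k * t)
    return np.column_stack([1.0 - e, a0 * t * e, np.ones_like(t)])


def _jac_mono(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    i1, k1, _c = x
    e = np.exp(-k1 * t)
    return np.column_stack([e, -i1 * t * e, np.ones_like(t)])


def _jac_eq2lim(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    a, b, k, _c = x
    e = np.exp(-k * t)
    return np.column_stack([e, t * e, -(a + b * t) * t * e, np.ones_like(t)])


class _ModelDef(NamedTuple):
    param_names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    predict: Callable[[np.ndarray, np.ndarray], np.ndarray]
    make_params: Callable[[np.ndarray], object]
    to_vector: Callable[[object], np.ndarray]
    jac: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None


_INF = np.inf
_KLO, _KHI = RATE_BOUNDS

_MODELS: dict[str, _ModelDef] = {
    "eq1": _ModelDef(
        ("amplitude_I", "k1", "k2", "c"),
        np.array([0.0, _KLO, _KLO, 0.0]),
        np.array([_INF, _KHI, _KHI, _INF]),
        _predict_eq1,
        lambda x: ConversionParams(float(x[0]), float(x[1]), float(x[2]), float(x[3])),
        lambda p: np.array([p.amplitude_I, p.k1, p.k2, p.c]),
    ),
    "eq2": _ModelDef(
        ("I1", "k1", "I2", "k2", "c"),
        np.array([0.0, _KLO, 0.0, _KLO, 0.0]),
        np.array([_INF, _KHI, _INF, _KHI, _INF]),
        _predict_eq2,
        lambda x: BiexpParams(float(x[0]), float(x[1]), float(x[2]), float(x[3]),
                              float(x[4]), opposed=True),
        lambda p: np.array([p.I1, p.k1, p.I2, p.k2, p.c]),
        _jac_biexp(-1.0),
    ),
    "eq3": _ModelDef(
        ("I1", "k1", "I2", "k2", "c"),
        np.array([0.0, _KLO, 0.0, _KLO, 0.0]),
        np.array([_INF, _KHI, _INF, _KHI, _INF]),
        _predict_eq3,
        lambda x: BiexpParams(float(x[0]), float(x[1]), float(x[2]), float(x[3]),
                              float(x[4]), opposed=False),
        lambda p: np.array([p.I1, p.k1, p.I2, p.k2, p.c]),
        _jac_biexp(1.0),
    ),
    "eq4": _ModelDef(
        ("A0", "k", "c"),
        np.array([0.0, _KLO, 0.0]),
        np.array([_INF, _KHI, _INF]),
        _predict_eq4,
        lambda x: MonoexpParams(float(x[0]), float(x[1]), float(x[2])),
        lambda p: np.array([p.A0, p.k, p.c]),
        _jac_eq4,
    ),
    "mono": _ModelDef(
        ("I1", "k1", "c"),
        np.array([0.0, _KLO, 0.0]),
        np.array([_INF, _KHI, _INF]),
        _predict_mono,
        lambda x: BiexpParams(float(x[0]), float(x[1]), 0.0, float(x[1]),
                              float(x[2]), opposed=False),
        lambda p: np.array([p.I1, p.k1, p.c]),
        _jac_mono,
    ),
    # coincident-rate limit of the opposed bi-exponential: (A + B t) e^(-kt) + c
    "eq2lim": _ModelDef(
        ("A", "B", "k", "c"),
        np.array([0.0, 0.0, _KLO, 0.0]),
        np.array([_INF, _INF, _KHI, _INF]),
        _predict_eq2lim,
        lambda x: LinExpParams(float(x[0]), float(x[1]), float(x[2]), float(x[3])),
        lambda p: np.array([p.A, p.B, p.k, p.c]),
        _jac_eq2lim,
    ),
}

MODEL_IDS = tuple(_MODELS)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single-trace fit: estimated parameters, their
    standard errors (from the covariance of the linearised problem at
    the optimum), the residual sum of squares and the AICc score."""

    model_id: str
    params: object
    stderr: dict[str, float]
    rss: float
    n_points: int
    aicc: float
    converged: bool
    n_restarts: int = 0
    message: str = ""

    @property
    def params_dict(self) -> dict[str, float]:
        names = _MODELS[self.model_id].param_names
        vec = _MODELS[self.model_id].to_vector(self.params)
        return {n: float(v) for n, v in zip(names, vec)}


# ---------------------------------------------------------------------------
# initialisation heuristics

def _noise_floor(y: np.ndarray) -> float:
    """Robust noise scale from first differences (MAD-based); first
    differences of a smooth curve contribute little, so this tracks the
    additive noise sigma up to a factor close to 1."""
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad / 0.6745 / np.sqrt(2.0))


def _loglinear_rate(t: np.ndarray, z: np.ndarray, floor: float) -> tuple[float, float]:
    """Fit ln z = ln A - k t on points with z above the floor; returns
    (k, A).  Raises ValueError when too few usable points remain."""
    mask = z > max(floor, 1e-300)
    if int(mask.sum()) < 3:
        raise ValueError("too few points above floor for log-linear fit")
    slope, intercept = np.polyfit(t[mask], np.log(z[mask]), 1)
    return max(-float(slope), _KLO), float(np.exp(intercept))


def _clip_to_bounds(x: np.ndarray, md: _ModelDef) -> np.ndarray:
    return np.clip(x, md.lower, np.where(np.isfinite(md.upper), md.upper, x))


def init_guess(trace: TimeTrace, model_id: str):
    """Starting values for `fit_trace`, derived from trace geometry.

    eq4: offset from the first sample, amplitude from the total rise and
    the rate from a log-linear fit of ``ln(1 - (y-c)/A0)`` over the first
    half-rise.  eq1: destruction rate from the tail log-slope, formation
    rate by inverting the peak-time relation
    ``t_peak = ln(k1/k2)/(k1 - k2)``.  eq2/eq3/mono: classic peeling —
    slow component from the tail, fast component from the early residual.

    Raises :class:`UninformativeTraceError` when the trace dynamic range
    is below ten times the estimated noise floor.
    """
    if model_id not in _MODELS:
        raise ValueError(f"unknown model_id {model_id!r}")
    t, y = trace.t, trace.y
    n = t.size
    nf = _noise_floor(y)
    span = float(np.ptp(y))
    if span <= 0 or span < 10.0 * nf:
        raise UninformativeTraceError(
            f"trace range {span:.3g} is below 10x the noise floor {nf:.3g}"
        )
    md = _MODELS[model_id]

    if model_id == "eq4":
        c0 = float(y[0])
        a0 = max(float(y[-1] - y[0]), 0.5 * span)
        half_idx = int(np.argmax(y >= c0 + 0.5 * a0))
        half_idx = max(half_idx, 3)
        z = 1.0 - (y[:half_idx + 1] - c0) / a0
        try:
            k, _ = _loglinear_rate(t[:half_idx + 1], z, 1e-6)
        except ValueError:
            k = LN_HALF_RISE / max(t[half_idx], t[1])
        x = np.array([a0, k, max(c0, 0.0)])

    elif model_id == "mono":
        c0 = max(float(y[-1]), 0.0)
        try:
            k, a = _loglinear_rate(t, y - c0, 3.0 * nf)
        except ValueError:
            k, a = 2.0 / max(t[-1], 1.0), span
        x = np.array([a, k, c0])

    elif model_id == "eq2lim":
        c0 = max(float(y[-1]), 0.0)
        try:
            k, a = _loglinear_rate(t, y - c0, 3.0 * nf)
        except ValueError:
            k, a = 2.0 / max(t[-1], 1.0), span
        a0 = max(float(y[0]) - c0, 1e-6)
        x = np.array([a0, 0.1 * a0 * k, k, c0])

    elif model_id == "eq1":
        c0 = max(float(np.min(y)), 0.0)
        ipk = int(np.argmax(y))
        tail_start = min(max(ipk + 1, int(0.6 * n)), n - 4)
        try:
            k2g, _ = _loglinear_rate(t[tail_start:], y[tail_start:] - c0, 3.0 * nf)
        except ValueError:
            k2g = 1e-3
        k1g = _invert_peak_time(t[ipk], k2g) if 0 < ipk < n - 1 else max(5.0 * k2g, 1e-3)
        shape_pk = k1g / (k2g - k1g) * (np.exp(-k1g * t[ipk]) - np.exp(-k2g * t[ipk])) \
            if abs(k2g - k1g) > 1e-15 else k1g * t[ipk] * np.exp(-k1g * t[ipk])
        amp = (float(y[ipk]) - c0) / shape_pk if shape_pk > 0 else span
        x = np.array([max(amp, 1e-12), k1g, k2g, c0])

    elif model_id in ("eq2", "eq3"):
        c0 = max(float(y[-1]), 0.0)
        half = n // 2
        try:
            k_slow, i_slow = _loglinear_rate(t[half:], y[half:] - c0, 3.0 * nf)
        except ValueError:
            k_slow, i_slow = 3.0 / max(t[-1], 1.0), span
        if model_id == "eq2":
            resid = i_slow * np.exp(-k_slow * t) + c0 - y
        else:
            resid = y - c0 - i_slow * np.exp(-k_slow * t)
        early = max(4, int(0.3 * n))
        try:
            k_fast, i_fast = _loglinear_rate(t[:early], resid[:early], 3.0 * nf)
        except ValueError:
            k_fast, i_fast = 2.5 * k_slow, 0.3 * i_slow
        if k_fast <= 1.2 * k_slow:
            k_fast = 2.0 * k_slow
        x = np.array([i_slow, k_slow, max(i_fast, 1e-12), k_fast, c0])

    else:  # pragma: no cover - registry and branches are in sync
        raise ValueError(model_id)

    x = _clip_to_bounds(x, md)
    return md.make_params(x)


#: half-rise of (1 - exp(-kt)) occurs at ln 2 / k
LN_HALF_RISE = np.log(2.0)


def _invert_peak_time(tpk: float, k2: float) -> float:
    """Solve t_peak = ln(k1/k2)/(k1-k2) for k1 > k2 by bisection."""
    from scipy.optimize import brentq

    def f(k1: float) -> float:
        return np.log(k1 / k2) - tpk * (k1 - k2)

    lo, hi = k2 * 1.01, _KHI
    try:
        if f(lo) > 0 > f(hi):
            return float(brentq(f, lo, hi))
    except ValueError:
        pass
    return max(3.0 / tpk, 2.0 * k2)


# ---------------------------------------------------------------------------
# fitting

def _jitter(x: np.ndarray, md: _ModelDef, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative log-normal jitter — rates are scale parameters, so
    restarts should explore factors, not offsets."""
    factors = np.exp(rng.normal(0.0, 0.5, size=x.size))
    return _clip_to_bounds(x * factors, md)


def _fallback_starts(model_id: str, trace: TimeTrace) -> list[np.ndarray]:
    """Deterministic coarse starts from trace geometry, used when the
    heuristic initialisation leads the optimiser astray (e.g. onto the
    k1 ~ k2 ridge of a bi-exponential)."""
    span = float(np.ptp(trace.y))
    base = max(float(np.min(trace.y)), 0.0)
    t_end = float(trace.t[-1] - trace.t[0]) or 1.0
    r = 1.0 / t_end
    if model_id == "eq1":
        return [np.array([span, 10.0 * r, 2.0 * r, base]),
                np.array([2.0 * span, 4.0 * r, 0.5 * r, base])]
    if model_id in ("eq2", "eq3"):
        return [np.array([1.2 * span, 2.0 * r, 0.3 * span, 8.0 * r, base]),
                np.array([span, 3.5 * r, 0.5 * span, 15.0 * r, base])]
    if model_id == "eq4":
        return [np.array([span, 2.0 * r, float(trace.y[0])]),
                np.array([span, 6.0 * r, float(trace.y[0])])]
    if model_id == "eq2lim":
        return [np.array([span, span * r, 2.0 * r, base]),
                np.array([span, 0.0, 5.0 * r, base])]
    return [np.array([span, 2.0 * r, base]),
            np.array([span, 6.0 * r, base])]


def _numeric_jacobian(resid, x: np.ndarray) -> np.ndarray:
    """Central-difference Jacobian of the residual vector at x."""
    eps = np.finfo(float).eps ** (1.0 / 3.0)
    cols = []
    for i in range(x.size):
        h = eps * max(abs(x[i]), 1e-4)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        cols.append((resid(xp) - resid(xm)) / (2.0 * h))
    return np.column_stack(cols)


def _canonical_order(model_id: str, x: np.ndarray) -> np.ndarray:
    if model_id == "eq1" and x[1] < x[2]:
        # (I,k1,k2) and (I*k1/k2, k2, k1) trace the same curve
        return np.array([x[0] * x[1] / x[2], x[2], x[1], x[3]])
    if model_id == "eq3" and x[1] > x[3]:
        return np.array([x[2], x[3], x[0], x[1], x[4]])
    return x


def _aicc(rss: float, n: int, n_params: int, scale: float) -> float:
    """Small-sample-corrected AIC for a Gaussian residual model.

    The RSS is floored at numerical precision relative to the trace
    scale: on noise-free data every adequate model fits to rounding
    error, and comparing logs of rounding errors would reward whichever
    model chased numerical noise hardest.  At the floor, models are
    ranked purely by their parameter-count penalty (parsimony).
    """
    k = n_params + 1  # +1 for the residual variance
    floor = n * (1e-10 * max(scale, 1e-300)) ** 2
    rss = max(rss, floor)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 <= 0:
        return float("inf")
    return float(aic + 2.0 * k * (k + 1) / (n - k - 1))


def fit_trace(
    trace: TimeTrace,
    model_id: str,
    init=None,
    *,
    multistart: int = 5,
    fix_c: float | None = None,
) -> FitResult:
    """Bounded least-squares fit of ``model_id`` to a trace.

    Rates are constrained to [1e-6, 10] s^-1 and amplitudes/offsets to be
    non-negative.  If the first attempt (from ``init`` or `init_guess`)
    fails to converge, up to ``multistart`` log-normally jittered restarts
    are tried before reporting ``converged=False`` with the best attempt.
    Standard errors come from ``s^2 (J^T J)^-1`` at the optimum.

    ``fix_c`` pins the offset instead of floating it.  For
    background-subtracted traces this is more than a convenience: with
    nearly coincident rates the floated offset opens a flat likelihood
    valley that visibly biases the rate and amplitude estimates, so a
    known baseline should be fixed, not estimated.
    """
    if model_id not in _MODELS:
        raise ValueError(f"unknown model_id {model_id!r}")
    md = _MODELS[model_id]
    if init is None:
        init = init_guess(trace, model_id)
    x0 = _clip_to_bounds(np.asarray(md.to_vector(init), dtype=float), md)
    c_idx = md.param_names.index("c")
    if fix_c is not None:
        x0[c_idx] = fix_c
    free = np.array([fix_c is None or i != c_idx for i in range(x0.size)])

    t, y = trace.t, trace.y
    w = None if trace.sigma is None else 1.0 / trace.sigma

    def assemble(xf: np.ndarray) -> np.ndarray:
        x = x0.copy()
        x[free] = xf
        return x

    def resid_full(x: np.ndarray) -> np.ndarray:
        r = md.predict(x, t) - y
        return r if w is None else r * w

    def resid(xf: np.ndarray) -> np.ndarray:
        return resid_full(assemble(xf))

    if md.jac is not None:
        def jac_free(xf: np.ndarray) -> np.ndarray:
            j = md.jac(assemble(xf), t)[:, free]
            return j if w is None else j * w[:, None]
    else:
        jac_free = "2-point"

    rng = np.random.default_rng(0)  # fixed: refits must be reproducible
    starts = [x0]
    for fb in _fallback_starts(model_id, trace):
        fb = _clip_to_bounds(fb, md)
        if fix_c is not None:
            fb[c_idx] = fix_c
        starts.append(fb)
    while len(starts) < multistart + 1:
        starts.append(_jitter(x0, md, rng))
    best = None
    best_converged = None
    n_restarts = 0
    for attempt in range(multistart + 1):
        start = starts[attempt]
        res = least_squares(
            resid, start[free], jac=jac_free,
            bounds=(md.lower[free], md.upper[free]),
            method="trf", x_scale="jac", max_nfev=150 * x0.size,
            ftol=1e-12, xtol=1e-12, gtol=1e-14,
        )
        if best is None or res.cost < best.cost:
            best = res
        if res.success and np.all(np.isfinite(res.x)) and (
            best_converged is None or res.cost < best_converged.cost
        ):
            best_converged = res
        # stop restarting once a converged solution (near-)matches the best
        # cost seen; further starts only re-polish degenerate alternatives
        if best_converged is not None and best_converged.cost <= best.cost * 1.01:
            break
        n_restarts = attempt
    # A failed attempt can show a marginally lower cost by crawling along a
    # degenerate ridge (e.g. k1 -> k2 with diverging opposed amplitudes)
    # until the evaluation budget runs out; a converged solution with an
    # indistinguishable cost is the meaningful one.
    if best_converged is not None and best_converged.cost <= best.cost * 1.01:
        best = best_converged
    converged = bool(best.success and np.all(np.isfinite(best.x)))

    x = _canonical_order(model_id, assemble(best.x))
    r = resid_full(x)
    rss = float(r @ r)
    n, p = t.size, int(free.sum())
    jac = jac_free(x[free]) if callable(jac_free) else _numeric_jacobian(resid, x[free])
    dof = n - p
    if dof > 0 and rss > 0:
        cov = (rss / dof) * np.linalg.pinv(jac.T @ jac)
        se_free = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    else:
        se_free = np.zeros(p)
    se = np.zeros(x.size)
    se[free] = se_free
    stderr = {name: float(s) for name, s in zip(md.param_names, se)}

    message = ""
    second_rate = 3 if x.size == 5 else 2
    if model_id in ("eq1", "eq2", "eq3") and abs(x[1] - x[second_rate]) < 1e-3 * x[1]:
        message = "rates nearly coincident; parameters weakly identifiable"

    return FitResult(
        model_id=model_id,
        params=md.make_params(x),
        stderr=stderr,
        rss=rss,
        n_points=n,
        aicc=_aicc(rss, n, p, float(np.ptp(y))) if converged else float("inf"),
        converged=converged,
        n_restarts=n_restarts,
        message=message,
    )


@dataclass(frozen=True)
class ModelRanking:
    """Candidate fits ranked by AICc (ascending).  Models whose AICc lies
    within 2 of the best are statistically indistinguishable on this
    trace and are listed in ``indistinguishable``."""

    results: tuple[FitResult, ...]
    indistinguishable: tuple[str, ...]

    @property
    def best(self) -> FitResult:
        return self.results[0]

    @property
    def is_ambiguous(self) -> bool:
        return len(self.indistinguishable) > 1


def select_model(trace: TimeTrace, candidates: Sequence[str]) -> ModelRanking:
    """Fit every candidate model and rank them by AICc."""
    if not candidates:
        raise ValueError("need at least one candidate model")
    fits: list[FitResult] = []
    for mid in candidates:
        fits.append(fit_trace(trace, mid))
    if not any(f.converged for f in fits):
        raise NoModelError(f"no candidate converged on this trace: {list(candidates)}")
    ranked = sorted(fits, key=lambda f: (not f.converged, f.aicc))
    best_aicc = ranked[0].aicc
    ties = tuple(f.model_id for f in ranked if f.converged and f.aicc - best_aicc < 2.0)
    return ModelRanking(results=tuple(ranked), indistinguishable=ties)


def amplitude_ratio(fit: FitResult) -> float:
    """I2/I1 of a bi-exponential switching fit (Table-style column)."""
    if fit.model_id not in ("eq2", "eq3"):
        raise InvalidParameterError(
            f"amplitude ratio is defined for eq2/eq3 fits, not {fit.model_id!r}"
        )
    p = fit.params
    if p.I1 == 0:
        raise InvalidParameterError("I1 is zero; amplitude ratio undefined")
    return float(p.I2 / p.I1)
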