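"""Relaxation-parameter estimation from magnetization decay curves.

Three estimators, in increasing order of model complexity:

* :func:`fit_monoexponential` — apparent single rate per curve; this is
  what NMRD dispersion profiles are built from.
* :func:`fit_biexponential` — apparent two-component fit (rates R1S >= R1L
  with amplitude fraction a_s of the fast component).
* :func:`fit_2sx_multifield` — the constrained simultaneous inversion of
  the two-site exchange model over all evolution fields of one specimen:
  a single intracellular lifetime tau_in and extracellular fraction v_ex
  shared across fields, one free intrinsic intracellular rate per field,
  and the extracellular rate fixed per field to the Matrigel reference.
  Volume closure and mass balance are enforced by parameterization.

All fits use Levenberg–Marquardt (lmfit's ``leastsq``, which handles box
constraints by internal parameter transformation) started from
deterministic multi-start grids, never random restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

from .exchange import BiExpFit, ExchangeParams, apparent_from_physio
from .io import AcquisitionScheme, DecayCurve, NMRDProfile, default_scheme

__all__ = [
    "MonoExpFit",
    "ExchangeFitResult",
    "ModelChoice",
    "IdentifiabilityError",
    "fit_monoexponential",
    "fit_biexponential",
    "fit_2sx_multifield",
    "select_model",
]

# convergence tolerances shared by all fits
XTOL = 1e-12
FTOL = 1e-14
MAX_NFEV = 20000


class IdentifiabilityError(ValueError):
    """The data cannot constrain the requested parameters."""


@dataclass
class MonoExpFit:
    """Result of a mono-exponential fit ``amp * exp(-r1 t) + offset``."""

    r1: float
    amplitude: float
    offset: float
    r1_stderr: float | None = None
    redchi: float = float("nan")
    aic: float = float("nan")
    n_points: int = 0
    success: bool = True
    message: str = ""


@dataclass
class ExchangeFitResult:
    """Constrained multi-field 2SX inversion for one specimen."""

    tau_in: float
    v_ex: float
    tau_in_stderr: float | None
    v_ex_stderr: float | None
    r1_in_per_field: dict[float, float]
    r1_ex_per_field: dict[float, float]
    redchi: float
    nfev: int
    success: bool
    v_ex_at_bound: bool = False
    message: str = ""


@dataclass
class ModelChoice:
    """Mono-vs-bi model comparison by corrected AIC."""

    decision: str  # "mono" | "bi"
    delta_aicc: float  # AICc(mono) - AICc(bi); positive favors bi
    mono: MonoExpFit = None
    bi: BiExpFit = None


def _aicc(aic: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return float("inf")
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def _curve_sigma(curve: DecayCurve) -> float:
    if curve.noise_sigma is not None and curve.noise_sigma > 0:
        return curve.noise_sigma
    return 1.0


def _mono_residual(params, t, y, sigma):
    model = params["amp"] * np.exp(-t * params["r1"]) + params["offset"]
    return (model - y) / sigma


def fit_monoexponential(curve: DecayCurve) -> MonoExpFit:
    """Fit ``amp * exp(-r1 t) + offset`` to one decay curve.

    The offset absorbs the evolution-field equilibrium magnetization, so
    the same model fits pre-polarized decays (amp > 0) and non-polarized
    recoveries (amp < 0).  A deterministic three-point multi-start on the
    initial rate guards against the rate/offset trade-off; a flat curve is
    returned as a flagged failure, never a number.
    """
    t, y = curve.times, curve.magnetization
    span = float(np.ptp(y))
    scale = max(abs(y).max(), 1.0)
    if span <= 1e-12 * scale:
        return MonoExpFit(
            r1=float("nan"), amplitude=0.0, offset=float(y.mean()),
            success=False, n_points=t.size,
            message="flat curve: relaxation rate unidentifiable",
        )
    sigma = _curve_sigma(curve)
    offset0 = float(y[-1])
    amp0 = float(y[0] - y[-1])
    # crude rate guess: time at which the normalized decay crosses 1/e
    frac = (y - offset0) / amp0
    below = np.flatnonzero(frac < np.exp(-1.0))
    r1_guess = 1.0 / t[below[0]] if below.size and t[below[0]] > 0 else 1.0 / t[-1]

    best = None
    for factor in (0.3, 1.0, 3.0):
        params = lmfit.Parameters()
        params.add("amp", value=amp0)
        params.add("offset", value=offset0)
        params.add("r1", value=r1_guess * factor, min=1e-8, max=1e8)
        try:
            res = lmfit.minimize(
                _mono_residual, params, args=(t, y, sigma),
                method="leastsq", xtol=XTOL, ftol=FTOL, max_nfev=MAX_NFEV,
            )
        except Exception:  # singular Jacobian etc.
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        return MonoExpFit(
            r1=float("nan"), amplitude=float("nan"), offset=float("nan"),
            success=False, n_points=t.size, message="all starts failed",
        )
    p = best.params
    return MonoExpFit(
        r1=float(p["r1"].value),
        amplitude=float(p["amp"].value),
        offset=float(p["offset"].value),
        r1_stderr=float(p["r1"].stderr) if p["r1"].stderr is not None else None,
        redchi=float(best.redchi),
        aic=float(best.aic),
        n_points=t.size,
        success=bool(best.success),
    )


def _bi_residual(params, t, y, sigma):
    a_s = params["a_s"]
    model = (
        params["amp"]
        * ((1.0 - a_s) * np.exp(-t * params["r1_long"])
           + a_s * np.exp(-t * params["r1_short"]))
        + params["offset"]
    )
    return (model - y) / sigma


#: deterministic multi-start grid for the bi-exponential fit
BI_START_RATIOS = (2.0, 5.0, 10.0, 20.0)
BI_START_FRACTIONS = (0.1, 0.2, 0.3, 0.5)


def fit_biexponential(curve: DecayCurve, init: BiExpFit | None = None) -> BiExpFit:
    """Fit the apparent bi-exponential model to one decay curve.

    The model is ``amp * [(1 - a_s) exp(-t R1L) + a_s exp(-t R1S)] +
    offset`` with R1S >= R1L enforced structurally (R1S = R1L + delta,
    delta >= 0).  Starts span rate ratios {2, 5, 10, 20} around the
    mono-exponential rate and a_s in {0.1, 0.2, 0.3, 0.5}; an explicit
    ``init`` is tried first.  The best-residual solution wins.
    """
    t, y = curve.times, curve.magnetization
    if t.size < 8:
        raise ValueError("bi-exponential fit needs at least 8 points")
    mono = fit_monoexponential(curve)
    if not mono.success:
        return BiExpFit(
            r1_long=0.0, r1_short=0.0, a_short=0.0, success=False,
            message="underlying mono-exponential fit failed: " + mono.message,
        )
    sigma = _curve_sigma(curve)

    starts: list[tuple[float, float, float, float, float]] = []
    if init is not None:
        starts.append((init.r1_long, init.r1_short, init.a_short,
                       init.amplitude, y[-1]))
    for ratio in BI_START_RATIOS:
        for a0 in BI_START_FRACTIONS:
            r_long = mono.r1 / np.sqrt(ratio)
            starts.append((r_long, r_long * ratio, a0,
                           mono.amplitude, mono.offset))

    best = None
    for r_long0, r_short0, a0, amp0, off0 in starts:
        params = lmfit.Parameters()
        params.add("amp", value=amp0)
        params.add("offset", value=off0)
        params.add("r1_long", value=max(r_long0, 1e-8), min=1e-8, max=1e8)
        params.add("delta", value=max(r_short0 - r_long0, 1e-8), min=0.0, max=1e8)
        params.add("r1_short", expr="r1_long + delta")
        params.add("a_s", value=a0, min=0.0, max=1.0)
        try:
            res = lmfit.minimize(
                _bi_residual, params, args=(t, y, sigma),
                method="leastsq", xtol=XTOL, ftol=FTOL, max_nfev=MAX_NFEV,
            )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        return BiExpFit(r1_long=0.0, r1_short=0.0, a_short=0.0,
                        success=False, message="all starts failed")
    p = best.params
    stderr = {
        name: (float(p[name].stderr) if p[name].stderr is not None else None)
        for name in ("r1_long", "r1_short", "a_s", "amp")
    }
    return BiExpFit(
        r1_long=float(p["r1_long"].value),
        r1_short=float(p["r1_short"].value),
        a_short=float(p["a_s"].value),
        amplitude=float(p["amp"].value),
        stderr=stderr,
        redchi=float(best.redchi),
        aic=float(best.aic),
        n_points=t.size,
        success=bool(best.success),
    )


def select_model(curve: DecayCurve) -> ModelChoice:
    """Mono-vs-bi decision by corrected AIC; ties go to the simpler model.

    A difference AICc(mono) - AICc(bi) below 2 is treated as a tie and
    resolved in favor of the mono-exponential model (parsimony).
    """
    mono = fit_monoexponential(curve)
    bi = fit_biexponential(curve)
    n = curve.n_points
    # a mono fit already at machine precision cannot be improved upon in
    # any meaningful way; the AIC of near-zero residuals is numerically
    # unstable, so short-circuit to the simpler model
    scale = float(np.ptp(curve.magnetization)) or 1.0
    mono_rms = np.sqrt(max(mono.redchi, 0.0) * (n - 3) / n) * _curve_sigma(curve)
    if mono.success and mono_rms < 1e-9 * scale:
        return ModelChoice(decision="mono", delta_aicc=0.0, mono=mono, bi=bi)
    delta = _aicc(mono.aic, n, 3) - _aicc(bi.aic, n, 5)
    decision = "bi" if (bi.success and delta >= 2.0) else "mono"
    return ModelChoice(decision=decision, delta_aicc=float(delta), mono=mono, bi=bi)


# ---------------------------------------------------------------------------
# constrained simultaneous multi-field inversion

#: deterministic tau_in multi-start grid (s)
TAU_STARTS = (0.2, 0.5, 1.0, 2.0)


def _lookup_rate(table, nu: float) -> float:
    if isinstance(table, NMRDProfile):
        idx = np.flatnonzero(np.isclose(table.frequencies, nu, rtol=1e-6))
        if idx.size == 0:
            raise ValueError(f"no fixed extracellular rate supplied for {nu} MHz")
        return float(table.rates[int(idx[0])])
    for key, value in table.items():
        if np.isclose(key, nu, rtol=1e-6):
            return float(value)
    raise ValueError(f"no fixed extracellular rate supplied for {nu} MHz")


def _multifield_residual(params, curves, r1_ex_values, sigmas, pol_freq):
    tau_in = params["tau_in"].value
    v_ex = params["v_ex"].value
    amp = params["amp"].value
    chunks = []
    for k, curve in enumerate(curves):
        p = ExchangeParams(
            r1_in=params[f"r1in_{k}"].value,
            r1_ex=r1_ex_values[k],
            tau_in=tau_in,
            v_ex=v_ex,
        )
        bi = apparent_from_physio(p)
        m_eq = amp * curve.evolution_frequency / pol_freq
        m0 = amp if curve.sequence == "PP/S" else 0.0
        env = (1.0 - bi.a_short) * np.exp(-curve.times * bi.r1_long) \
            + bi.a_short * np.exp(-curve.times * bi.r1_short)
        model = m_eq + (m0 - m_eq) * env
        chunks.append((model - curve.magnetization) / sigmas[k])
    return np.concatenate(chunks)


def fit_2sx_multifield(
    curves: list[DecayCurve],
    r1_ex,
    v_ex_bounds: tuple[float, float],
    scheme: AcquisitionScheme | None = None,
    fix_v_ex: float | None = None,
    tau_starts: tuple[float, ...] = TAU_STARTS,
) -> ExchangeFitResult:
    """Simultaneous 2SX inversion over all evolution fields of a specimen.

    One global nonlinear least-squares problem: ``tau_in`` and ``v_ex``
    are shared across fields, one intrinsic intracellular rate ``R1_in``
    is free per field, and the extracellular rate is fixed per field to
    the supplied Matrigel reference (``r1_ex`` may be a mapping
    frequency -> rate or an :class:`NMRDProfile`).  A single overall
    amplitude is shared by all fields: in a field-cycling acquisition the
    pre-polarized initial magnetization is set by the polarization field
    alone, so it cannot vary between evolution fields — and this
    cross-field constraint carries much of the information that separates
    ``tau_in`` from the per-field rates.  Residuals are weighted by each
    curve's noise sigma.  Volume closure and mass balance hold identically
    through the parameterization; ``v_ex`` moves inside box constraints
    (tissue-class bounds), or is frozen with ``fix_v_ex``.

    Raises :class:`IdentifiabilityError` with fewer than 4 fields.
    """
    if len(curves) < 4:
        raise IdentifiabilityError(
            f"need at least 4 evolution fields, got {len(curves)}"
        )
    scheme = scheme or default_scheme()
    lo, hi = v_ex_bounds
    if not 0.0 < lo < hi < 1.0:
        raise ValueError(f"invalid v_ex bounds {v_ex_bounds}")
    curves = sorted(curves, key=lambda c: c.evolution_frequency)
    r1_ex_values = [_lookup_rate(r1_ex, c.evolution_frequency) for c in curves]
    sigmas = [_estimate_sigma(c) for c in curves]
    pol = scheme.polarization_frequency

    # per-field starting values from independent mono fits
    mono_rates, amp0s = [], []
    for c in curves:
        m = fit_monoexponential(c)
        mono_rates.append(m.r1 if m.success else 1.0)
        if c.sequence == "PP/S":
            amp0s.append(float(c.magnetization[0]))
        else:
            amp0s.append(float(c.magnetization[-1]) * pol / c.evolution_frequency)
    amp0 = float(np.median(amp0s)) or 1.0

    best = None
    for tau0 in tau_starts:
        params = lmfit.Parameters()
        params.add("tau_in", value=tau0, min=1e-3, max=50.0)
        if fix_v_ex is not None:
            params.add("v_ex", value=fix_v_ex, vary=False)
        else:
            params.add("v_ex", value=0.5 * (lo + hi), min=lo, max=hi)
        params.add("amp", value=amp0)
        for k, c in enumerate(curves):
            # the apparent rate underestimates R1_in; start slightly above
            params.add(f"r1in_{k}", value=max(mono_rates[k] * 1.2, 0.1),
                       min=1e-6, max=1e4)
        try:
            res = lmfit.minimize(
                _multifield_residual, params,
                args=(curves, r1_ex_values, sigmas, pol),
                method="leastsq", xtol=XTOL, ftol=FTOL, max_nfev=MAX_NFEV,
            )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        return ExchangeFitResult(
            tau_in=float("nan"), v_ex=float("nan"), tau_in_stderr=None,
            v_ex_stderr=None, r1_in_per_field={}, r1_ex_per_field={},
            redchi=float("nan"), nfev=0, success=False,
            message="all starts failed",
        )
    p = best.params
    v_ex_val = float(p["v_ex"].value)
    pinned = fix_v_ex is None and (
        abs(v_ex_val - lo) < 1e-3 * (hi - lo) or abs(v_ex_val - hi) < 1e-3 * (hi - lo)
    )
    if pinned:
        warnings.warn(
            f"v_ex estimate {v_ex_val:.4f} pinned at its bound {v_ex_bounds}",
            stacklevel=2,
        )
    return ExchangeFitResult(
        tau_in=float(p["tau_in"].value),
        v_ex=v_ex_val,
        tau_in_stderr=(float(p["tau_in"].stderr)
                       if p["tau_in"].stderr is not None else None),
        v_ex_stderr=(float(p["v_ex"].stderr)
                     if fix_v_ex is None and p["v_ex"].stderr is not None
                     else None),
        r1_in_per_field={c.evolution_frequency: float(p[f"r1in_{k}"].value)
                         for k, c in enumerate(curves)},
        r1_ex_per_field={c.evolution_frequency: r1_ex_values[k]
                         for k, c in enumerate(curves)},
        redchi=float(best.redchi),
        nfev=int(best.nfev),
        success=bool(best.success),
        v_ex_at_bound=pinned,
    )


def _estimate_sigma(curve: DecayCurve) -> float:
    """Per-curve residual weight: the known noise sigma, or the late-time
    residual scatter of a mono-exponential fit when none is recorded."""
    if curve.noise_sigma is not None and curve.noise_sigma > 0:
        return curve.noise_sigma
    mono = fit_monoexponential(curve)
    if mono.success:
        tail = curve.times >= np.median(curve.times)
        resid = (curve.magnetization
                 - (mono.amplitude * np.exp(-curve.times * mono.r1) + mono.offset))
        s = float(np.std(resid[tail]))
        if s > 0:
            return s
    return 1.0
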