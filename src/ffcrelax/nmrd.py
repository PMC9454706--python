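"""NMRD dispersion analysis: profile assembly, muscle-contribution removal,
regime segmentation and power-law fitting.

An NMRD (nuclear magnetic relaxation dispersion) profile is R1 versus the
evolution-field proton Larmor frequency.  Whole-leg acquisitions detect a
tumor/muscle mixture; with the tumor volume fraction f_tum known, the
tumor rate follows from the volume-weighted rate decomposition

    R1 = f_tum R1_tum + (1 - f_tum) R1_mus.

The dispersive part of the tumor profile is summarized by the power law
R1(nu) = A_P nu**-beta, fitted in log-log space over the points the
gradient-based segmentation labels dispersive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import MixtureSpec, NMRDProfile
from .fitting import MonoExpFit

__all__ = [
    "PowerLawFit",
    "TransitionResult",
    "build_profile",
    "subtract_muscle",
    "detect_transition",
    "fit_power_law",
]

#: a profile whose steepest log-log slope magnitude is below this is flat
FLAT_SLOPE_THRESHOLD = 0.05


@dataclass
class PowerLawFit:
    """Power-law dispersion parameters R1(nu) = A_P nu**-beta.

    ``a_p`` is the rate at 1 MHz (s^-1); ``beta`` the dimensionless
    dispersion exponent.  ``plateau_level`` averages the nondispersive
    points (NaN when every point is dispersive).
    """

    a_p: float
    beta: float
    a_p_stderr: float | None
    beta_stderr: float | None
    transition_frequency: float | None
    dispersive_mask: np.ndarray
    plateau_level: float = float("nan")

    def __post_init__(self) -> None:
        if self.beta < -1e-9:
            raise ValueError(f"beta must be nonnegative, got {self.beta}")
        if np.count_nonzero(self.dispersive_mask) < 2:
            raise ValueError("a power-law fit needs at least 2 dispersive points")


@dataclass
class TransitionResult:
    """Dispersive/nondispersive segmentation of a profile."""

    transition_frequency: float | None
    dispersive_mask: np.ndarray  # True where the point is dispersive
    slopes: np.ndarray  # local d(log R1)/d(log nu) per point
    has_dispersion: bool


def build_profile(records, tissue: str) -> NMRDProfile:
    """Assemble an NMRD profile from per-field mono-exponential fits.

    ``records`` is an iterable of ``(specimen_id, frequency_MHz, fit)``
    where ``fit`` is a :class:`MonoExpFit` or a bare rate.  Every specimen
    must cover the same field set; the profile carries the group mean and
    the standard error across specimens per field (zero when n = 1).
    """
    by_specimen: dict[str, dict[float, float]] = {}
    for sid, nu, fit in records:
        rate = fit.r1 if isinstance(fit, MonoExpFit) else float(fit)
        if isinstance(fit, MonoExpFit) and not fit.success:
            raise ValueError(f"failed fit for specimen {sid} at {nu} MHz")
        by_specimen.setdefault(str(sid), {})[float(nu)] = rate
    if not by_specimen:
        raise ValueError("no fit records supplied")
    field_sets = {sid: tuple(sorted(d)) for sid, d in by_specimen.items()}
    reference = next(iter(field_sets.values()))
    mismatch = {sid: fs for sid, fs in field_sets.items() if fs != reference}
    if mismatch:
        raise ValueError(
            "inconsistent field sets across specimens: "
            + "; ".join(f"{sid}: {fs}" for sid, fs in sorted(mismatch.items()))
        )
    if len(reference) < 2:
        raise ValueError("a profile needs at least 2 evolution fields")
    freqs = np.array(reference)
    matrix = np.array([[by_specimen[sid][nu] for nu in reference]
                       for sid in sorted(by_specimen)])
    n = matrix.shape[0]
    means = matrix.mean(axis=0)
    errors = matrix.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(means)
    return NMRDProfile(tissue=tissue, frequencies=freqs, rates=means,
                       rate_errors=errors, n_specimens=n)


def subtract_muscle(profile: NMRDProfile, mix: MixtureSpec) -> NMRDProfile:
    """Remove the healthy-muscle contribution from a whole-volume profile.

    Inverts the volume-weighted rate decomposition per field:
    ``R1_tum = (R1 - (1 - f_tum) R1_mus) / f_tum``.  Errors propagate in
    quadrature with f_tum treated as exact.  Fields where the subtracted
    rate is nonpositive are excluded with a warning, never clipped.
    """
    f = mix.tumor_fraction
    if f == 0:
        raise ZeroDivisionError("tumor fraction is zero: no tumor signal to extract")
    mus = mix.muscle_profile
    if profile.frequencies.size != mus.frequencies.size or not np.allclose(
        profile.frequencies, mus.frequencies, rtol=1e-6
    ):
        raise ValueError("muscle profile must cover the same evolution fields")
    rates = (profile.rates - (1.0 - f) * mus.rates) / f
    errors = np.hypot(profile.rate_errors, (1.0 - f) * mus.rate_errors) / f
    valid = rates > 0
    if not valid.all():
        bad = profile.frequencies[~valid]
        warnings.warn(
            f"muscle subtraction produced nonpositive tumor rates at "
            f"{bad.tolist()} MHz; points excluded", stacklevel=2,
        )
    if valid.sum() < 2:
        raise ValueError("fewer than 2 valid fields after muscle subtraction")
    return NMRDProfile(
        tissue=f"{profile.tissue} (tumor)",
        frequencies=profile.frequencies[valid],
        rates=rates[valid],
        rate_errors=errors[valid],
        n_specimens=profile.n_specimens,
    )


def _loglog_slopes(freqs: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Local d(log R1)/d(log nu) per point: central differences inside,
    one-sided at the ends."""
    x, y = np.log(freqs), np.log(rates)
    return np.gradient(y, x)


def detect_transition(profile: NMRDProfile) -> TransitionResult:
    """Locate the dispersive/nondispersive transition of a profile.

    The local log-log slope is computed per point; the largest slope
    magnitude on the high-frequency side of the profile is the gradient
    response, and the transition sits where the slope magnitude first
    crosses half that maximum (linear interpolation in log frequency).
    Points below the transition are nondispersive, points at or above it
    dispersive.  A profile whose maximal slope magnitude stays below
    ``FLAT_SLOPE_THRESHOLD`` carries no usable dispersion.
    """
    if profile.frequencies.size < 4:
        raise ValueError("transition detection needs at least 4 fields")
    slopes = _loglog_slopes(profile.frequencies, profile.rates)
    mag = np.abs(slopes)
    peak_idx = int(np.argmax(mag))
    g = float(mag[peak_idx])
    if g < FLAT_SLOPE_THRESHOLD:
        return TransitionResult(
            transition_frequency=None,
            dispersive_mask=np.zeros(mag.size, dtype=bool),
            slopes=slopes, has_dispersion=False,
        )
    half = 0.5 * g
    logf = np.log(profile.frequencies)
    # first upward crossing of half-maximum at or below the peak
    crossing = None
    for i in range(peak_idx):
        if mag[i] < half <= mag[i + 1]:
            frac = (half - mag[i]) / (mag[i + 1] - mag[i])
            crossing = float(np.exp(logf[i] + frac * (logf[i + 1] - logf[i])))
    if crossing is None:
        # slope already above half-maximum at the lowest field:
        # the whole profile is dispersive
        crossing = float(profile.frequencies[0])
    mask = profile.frequencies >= crossing * (1 - 1e-12)
    return TransitionResult(
        transition_frequency=crossing, dispersive_mask=mask,
        slopes=slopes, has_dispersion=True,
    )


def fit_power_law(
    profile: NMRDProfile,
    regime: TransitionResult | np.ndarray | None = None,
) -> PowerLawFit:
    """Weighted log-log regression of the dispersive part of a profile.

    ``log R1 = log A_P - beta log nu`` is fitted by weighted linear least
    squares over the dispersive points (weights from the profile's rate
    errors, propagated to log space; unweighted when no errors are
    recorded).  Nondispersive points are averaged into the plateau level.
    ``regime`` defaults to :func:`detect_transition` on the profile.
    """
    import statsmodels.api as sm

    if regime is None:
        regime = detect_transition(profile)
    mask = regime.dispersive_mask if isinstance(regime, TransitionResult) \
        else np.asarray(regime, dtype=bool)
    if isinstance(regime, TransitionResult) and not regime.has_dispersion:
        raise ValueError("profile carries no dispersion; power law undefined")
    if mask.sum() < 2:
        raise ValueError("a power-law fit needs at least 2 dispersive points")

    nu = profile.frequencies[mask]
    r1 = profile.rates[mask]
    se = profile.rate_errors[mask]
    x = sm.add_constant(np.log(nu))
    if np.all(se > 0):
        w = (r1 / se) ** 2  # Var[log R1] ~ (se/R1)^2
    else:
        w = np.ones_like(r1)
    fit = sm.WLS(np.log(r1), x, weights=w).fit()
    intercept, slope = fit.params
    se_int, se_slope = fit.bse
    beta = max(-slope, 0.0)
    plateau = float(profile.rates[~mask].mean()) if (~mask).any() else float("nan")
    trans = regime.transition_frequency if isinstance(regime, TransitionResult) \
        else float(nu[0])
    return PowerLawFit(
        a_p=float(np.exp(intercept)),
        beta=float(beta),
        a_p_stderr=float(np.exp(intercept) * se_int) if np.isfinite(se_int) else None,
        beta_stderr=float(se_slope) if np.isfinite(se_slope) else None,
        transition_frequency=trans,
        dispersive_mask=mask,
        plateau_level=plateau,
    )
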