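"""Two-site-exchange (2SX) longitudinal relaxation model.

Water in tissue is partitioned into an intracellular and an extracellular
pool that exchange across the cell membrane.  Longitudinal magnetization of
the coupled system relaxes bi-exponentially: the deviation from equilibrium
``m = (m_in, m_ex)`` obeys ``dm/dt = -A m`` with

    A = | R1_in + k_in    -k_ex        |
        | -k_in           R1_ex + k_ex |

where ``R1_in``/``R1_ex`` are the intrinsic relaxation rates of the two
pools and ``k_in = 1/tau_in``, ``k_ex = 1/tau_ex`` the unidirectional
exchange rate constants.  Detailed balance ties the kinetics to the pool
sizes: ``v_in * k_in = v_ex * k_ex`` (equivalently
``v_in * tau_ex = v_ex * tau_in``), so only four of the eight physiological
parameters are free.

The eigenvalues of ``A`` are the apparent relaxation rates ``R1S >= R1L``
(short- and long-T1 components); the eigendecomposition of the population
vector gives the amplitude fraction ``a_s`` of the fast component.  All of
this is closed-form for a 2x2 system and implemented as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExchangeParams",
    "BiExpFit",
    "apparent_from_physio",
    "mono_limit",
    "magnetization_model",
]


@dataclass(frozen=True)
class ExchangeParams:
    """Physiological parameters of the two-site exchange system.

    Parameters
    ----------
    r1_in : float
        Intrinsic intracellular longitudinal relaxation rate (s^-1).
    r1_ex : float
        Intrinsic extracellular rate (s^-1).
    tau_in : float
        Intracellular water residence lifetime (s); ``k_in = 1/tau_in`` is
        the unidirectional efflux rate constant (also written k_io).
    v_ex : float
        Extracellular water volume fraction, strictly inside (0, 1).

    The derived quantities ``v_in``, ``tau_ex``, ``k_in`` and ``k_ex`` are
    fixed by volume closure and mass balance, so mass balance can never be
    violated by construction.
    """

    r1_in: float
    r1_ex: float
    tau_in: float
    v_ex: float

    def __post_init__(self) -> None:
        for name in ("r1_in", "r1_ex", "tau_in", "v_ex"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        if self.r1_in <= 0 or self.r1_ex <= 0:
            raise ValueError("relaxation rates must be positive")
        if self.tau_in <= 0:
            raise ValueError("tau_in must be positive")
        if not 0.0 < self.v_ex < 1.0:
            raise ValueError(f"v_ex must lie in (0, 1), got {self.v_ex}")

    @property
    def v_in(self) -> float:
        return 1.0 - self.v_ex

    @property
    def tau_ex(self) -> float:
        # mass balance: v_in * tau_ex = v_ex * tau_in
        return self.tau_in * self.v_ex / self.v_in

    @property
    def k_in(self) -> float:
        return 1.0 / self.tau_in

    @property
    def k_ex(self) -> float:
        return 1.0 / self.tau_ex


@dataclass
class BiExpFit:
    """Apparent bi-exponential relaxation parameters.

    ``r1_short >= r1_long`` by convention (the short-T1 component relaxes
    faster); ``a_short`` is the amplitude fraction of the short-T1
    component and the two fractions sum to one.
    """

    r1_long: float
    r1_short: float
    a_short: float
    amplitude: float = 1.0
    stderr: dict = field(default_factory=dict)
    redchi: float = float("nan")
    aic: float = float("nan")
    n_points: int = 0
    success: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.r1_long < 0 or self.r1_short < self.r1_long:
            raise ValueError(
                "require r1_short >= r1_long >= 0, got "
                f"({self.r1_short}, {self.r1_long})"
            )
        if not -1e-9 <= self.a_short <= 1 + 1e-9:
            raise ValueError(f"a_short must lie in [0, 1], got {self.a_short}")
        self.a_short = min(max(self.a_short, 0.0), 1.0)


def apparent_from_physio(p: ExchangeParams) -> BiExpFit:
    """Map physiological 2SX parameters to apparent bi-exponential ones.

    The two eigen-rates of the exchange-relaxation matrix are

        R1_{L,S} = (tr -/+ sqrt(tr^2 - 4 det)) / 2,
        tr  = R1_in + k_in + R1_ex + k_ex,
        det = (R1_in + k_in)(R1_ex + k_ex) - k_in k_ex,

    and the amplitudes follow from projecting the field-cycling initial
    condition — both pools polarized in proportion to their populations,
    ``m(0) ∝ (v_in, v_ex)`` — onto the eigenvectors and summing each mode
    over both pools (the detected signal is the total magnetization).
    """
    a11 = p.r1_in + p.k_in
    a22 = p.r1_ex + p.k_ex
    tr = a11 + a22
    # discriminant is (a11-a22)^2 + 4 k_in k_ex >= 0 always
    disc = math.sqrt((a11 - a22) ** 2 + 4.0 * p.k_in * p.k_ex)
    lam_slow = 0.5 * (tr - disc)
    lam_fast = 0.5 * (tr + disc)

    if disc == 0.0:
        # degenerate spectrum (no exchange and equal rates)
        return BiExpFit(r1_long=lam_slow, r1_short=lam_fast, a_short=0.0)

    # Eigenvectors of A = [[a11, -k_ex], [-k_in, a22]] for eigenvalue lam
    # satisfy (a11 - lam) x1 = k_ex x2; pick the numerically larger of the
    # two equivalent forms.  Project m0 = (v_in, v_ex) onto the basis and
    # weight each mode by the sum of its components (the coil detects the
    # total magnetization of both pools).
    def eigvec(lam: float) -> np.ndarray:
        # both rows give a valid representation; the one with lam far from
        # its diagonal entry stays well-conditioned in the weak-exchange limit
        if abs(a11 - lam) >= abs(a22 - lam):
            return np.array([p.k_ex, a11 - lam])
        return np.array([a22 - lam, p.k_in])

    basis = np.column_stack([eigvec(lam_slow), eigvec(lam_fast)])
    coeffs = np.linalg.solve(basis, np.array([p.v_in, p.v_ex]))
    signal = coeffs * basis.sum(axis=0)

    total = signal.sum()  # equals v_in + v_ex = 1 up to round-off
    a_short = float(signal[1] / total)
    a_short = min(max(a_short, 0.0), 1.0)
    return BiExpFit(r1_long=lam_slow, r1_short=lam_fast, a_short=a_short)


def mono_limit(p: ExchangeParams) -> float:
    """Population-weighted mean rate ``v_in R1_in + v_ex R1_ex``.

    This is the apparent mono-exponential rate in the fast-exchange limit
    (exchange much faster than the rate difference).
    """
    return p.v_in * p.r1_in + p.v_ex * p.r1_ex


def magnetization_model(
    p: ExchangeParams,
    scheme,
    field_mhz: float,
    times,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Longitudinal magnetization during field-cycling evolution.

    The curve runs from the sequence-determined initial value — full
    pre-polarization (``amplitude``, proportional to the polarization
    field) for a PP/S acquisition, zero for NP/S — toward the equilibrium
    at the evolution field, ``amplitude * field / polarization_frequency``,
    with the bi-exponential envelope of :func:`apparent_from_physio`:

        M(t) = M_eq + (M_0 - M_eq) [(1 - a_s) e^{-R1L t} + a_s e^{-R1S t}]

    Parameters
    ----------
    scheme : AcquisitionScheme
        Supplies the polarization frequency and the sequence flag for
        ``field_mhz`` (which must be one of its evolution fields).
    times : array_like
        Evolution times t_E in seconds, all nonnegative.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("evolution times must be nonnegative")
    sequence = scheme.sequence_for(field_mhz)
    m_eq = amplitude * field_mhz / scheme.polarization_frequency
    m0 = amplitude if sequence == "PP/S" else 0.0
    bi = apparent_from_physio(p)
    envelope = (1.0 - bi.a_short) * np.exp(-t * bi.r1_long) + bi.a_short * np.exp(
        -t * bi.r1_short
    )
    return m_eq + (m0 - m_eq) * envelope
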