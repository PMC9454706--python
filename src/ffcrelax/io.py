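"""Data model and file I/O for fast-field-cycling relaxometry data.

Units are fixed package-wide: frequencies in MHz (proton Larmor), times in
seconds, relaxation rates in s^-1.  Interchange formats are long-format CSV
and an equivalent JSON array of curve objects; no instrument-native format
is parsed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ffcrelax")

__all__ = [
    "AcquisitionScheme",
    "DecayCurve",
    "NMRDProfile",
    "MixtureSpec",
    "SchemaError",
    "default_scheme",
    "read_decay_curves",
    "write_decay_curves",
]

#: exact column order of the decay-curve CSV schema
CSV_COLUMNS = ("specimen_id", "tissue", "sequence", "nu_E_MHz", "t_E_s", "Mz", "sigma")

SEQUENCES = ("PP/S", "NP/S")


class SchemaError(ValueError):
    """A data file does not match the expected schema."""


@dataclass(frozen=True)
class AcquisitionScheme:
    """Field-cycling acquisition protocol.

    A pre-polarized (PP/S) acquisition polarizes the sample at
    ``polarization_frequency`` for ``polarization_duration`` seconds, lets
    the magnetization evolve at one of the ``evolution_frequencies`` for a
    variable time t_E, then detects at ``detection_frequency``.  A
    non-polarized (NP/S) acquisition skips the polarization step, so the
    magnetization grows from zero toward the evolution-field equilibrium.
    """

    polarization_frequency: float = 14.5
    detection_frequency: float = 13.0
    evolution_frequencies: tuple[float, ...] = ()
    sequence_per_field: tuple[str, ...] = ()
    n_evolution_times: int = 32
    evolution_time_range: tuple[float, float] = (2.8, 4.0)
    polarization_duration: float = 0.5

    def __post_init__(self) -> None:
        nu = np.asarray(self.evolution_frequencies, dtype=float)
        if nu.size == 0:
            raise ValueError("at least one evolution frequency is required")
        if np.any(nu <= 0):
            raise ValueError("evolution frequencies must be positive")
        if np.any(np.diff(nu) <= 0):
            raise ValueError("evolution frequencies must be sorted ascending")
        if len(self.sequence_per_field) != nu.size:
            raise ValueError("one sequence flag is required per evolution field")
        bad = set(self.sequence_per_field) - set(SEQUENCES)
        if bad:
            raise ValueError(f"unknown sequence flags: {sorted(bad)}")
        if self.n_evolution_times < 4:
            raise ValueError("n_evolution_times must be at least 4")
        pp = [f for f, s in zip(nu, self.sequence_per_field) if s == "PP/S"]
        if pp and self.detection_frequency <= max(pp):
            raise ValueError(
                "detection frequency must exceed every pre-polarized evolution field"
            )

    def sequence_for(self, field_mhz: float, rtol: float = 1e-6) -> str:
        """Sequence flag (PP/S or NP/S) of the evolution field ``field_mhz``."""
        nu = np.asarray(self.evolution_frequencies)
        idx = np.flatnonzero(np.isclose(nu, field_mhz, rtol=rtol))
        if idx.size == 0:
            raise ValueError(f"{field_mhz} MHz is not an evolution field of this scheme")
        return self.sequence_per_field[int(idx[0])]

    def max_evolution_time(self, field_mhz: float) -> float:
        """Maximal t_E for one field, log-interpolated across the range.

        The slowest-relaxing (highest-field) acquisition gets the longest
        window; interpolation is linear in log frequency between the
        scheme's ``evolution_time_range`` endpoints.
        """
        self.sequence_for(field_mhz)  # membership check
        lo, hi = min(self.evolution_frequencies), max(self.evolution_frequencies)
        t_lo, t_hi = self.evolution_time_range
        if hi == lo:
            return t_hi
        frac = (np.log10(field_mhz) - np.log10(lo)) / (np.log10(hi) - np.log10(lo))
        return float(t_lo + frac * (t_hi - t_lo))

    def time_grid(self, field_mhz: float, t_min: float = 1e-3) -> np.ndarray:
        """Log-spaced t_E grid for one evolution field.

        Log spacing concentrates samples in the early decay, where the fast
        bi-exponential component lives.
        """
        return np.geomspace(t_min, self.max_evolution_time(field_mhz),
                            self.n_evolution_times)


def default_scheme() -> AcquisitionScheme:
    """The eight-field acquisition protocol used throughout the package.

    Seven evolution fields log-distributed between 0.01 and 1 MHz acquired
    pre-polarized, plus one at 10 MHz acquired non-polarized; 32 evolution
    times per field with per-field maxima between 2.8 and 4 s; polarization
    at 14.5 MHz and detection at 13 MHz.
    """
    freqs = (0.01, 0.02, 0.037, 0.07, 0.15, 0.39, 1.0, 10.0)
    seqs = ("PP/S",) * 7 + ("NP/S",)
    return AcquisitionScheme(
        polarization_frequency=14.5,
        detection_frequency=13.0,
        evolution_frequencies=freqs,
        sequence_per_field=seqs,
        n_evolution_times=32,
        evolution_time_range=(2.8, 4.0),
    )


@dataclass
class DecayCurve:
    """One magnetization-vs-evolution-time record at one evolution field."""

    specimen_id: str
    tissue: str
    evolution_frequency: float
    sequence: str
    times: np.ndarray
    magnetization: np.ndarray
    noise_sigma: float | None = None
    equilibrium_amplitude: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.magnetization = np.asarray(self.magnetization, dtype=float)
        if self.sequence not in SEQUENCES:
            raise ValueError(f"unknown sequence {self.sequence!r}")
        if self.times.size != self.magnetization.size:
            raise ValueError("times and magnetization must have equal length")
        if self.times.size < 4:
            raise ValueError("a decay curve needs at least 4 points")
        if np.any(self.times < 0):
            raise ValueError("evolution times must be nonnegative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"evolution times must be strictly increasing "
                f"(curve {self.specimen_id}/{self.tissue} at "
                f"{self.evolution_frequency} MHz)"
            )
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass
class NMRDProfile:
    """Relaxation-rate dispersion: R1 versus evolution-field frequency."""

    tissue: str
    frequencies: np.ndarray
    rates: np.ndarray
    rate_errors: np.ndarray | None = None
    n_specimens: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rate_errors is None:
            self.rate_errors = np.zeros_like(self.rates)
        else:
            self.rate_errors = np.asarray(self.rate_errors, dtype=float)
        if not (self.frequencies.size == self.rates.size == self.rate_errors.size):
            raise ValueError("frequencies, rates and rate_errors must align")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be sorted ascending")
        if np.any(self.rates <= 0):
            raise ValueError("relaxation rates must be positive")


@dataclass
class MixtureSpec:
    """Tumor volume fraction plus the healthy-tissue reference profile."""

    tumor_fraction: float
    muscle_profile: NMRDProfile

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# file I/O


def _curves_to_frame(curves: Sequence[DecayCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for t, m in zip(c.times, c.magnetization):
            rows.append(
                (c.specimen_id, c.tissue, c.sequence, c.evolution_frequency,
                 t, m, c.noise_sigma if c.noise_sigma is not None else np.nan)
            )
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def _frame_to_curves(df: pd.DataFrame, source: str) -> list[DecayCurve]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c != "sigma"]
    if missing:
        raise SchemaError(f"{source}: missing required column(s) {missing}")
    if "sigma" not in df.columns:
        df = df.assign(sigma=np.nan)

    bad = df.index[pd.to_numeric(df["t_E_s"], errors="coerce").isna()
                   | pd.to_numeric(df["Mz"], errors="coerce").isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise SchemaError(f"{source}: malformed numeric rows at lines {lines}")

    curves = []
    keys = ["specimen_id", "tissue", "sequence", "nu_E_MHz"]
    for (spec, tissue, seq, nu), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("t_E_s")
        t = grp["t_E_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise SchemaError(
                f"{source}: duplicate or non-monotone t_E within curve "
                f"({spec}, {tissue}, {nu} MHz)"
            )
        sigma = grp["sigma"].to_numpy(float)
        noise = None if np.isnan(sigma).all() else float(np.nanmedian(sigma))
        curves.append(
            DecayCurve(
                specimen_id=str(spec),
                tissue=str(tissue),
                sequence=str(seq),
                evolution_frequency=float(nu),
                times=t,
                magnetization=grp["Mz"].to_numpy(float),
                noise_sigma=noise,
            )
        )
    return curves


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_decay_curves(path, fmt: str | None = None) -> list[DecayCurve]:
    """Read decay curves from long-format CSV or a JSON curve array.

    Rows are grouped into one :class:`DecayCurve` per
    (specimen, tissue, sequence, field) and sorted by t_E within a curve.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        df = pd.read_csv(path)
        return _frame_to_curves(df, str(path))
    payload = json.loads(path.read_text())
    curves = []
    for i, obj in enumerate(payload):
        try:
            curves.append(
                DecayCurve(
                    specimen_id=str(obj["specimen_id"]),
                    tissue=str(obj["tissue"]),
                    sequence=str(obj["sequence"]),
                    evolution_frequency=float(obj["nu_E_MHz"]),
                    times=np.asarray(obj["t_E_s"], dtype=float),
                    magnetization=np.asarray(obj["Mz"], dtype=float),
                    noise_sigma=obj.get("sigma"),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: curve {i} missing key {exc}") from None
    return curves


def write_decay_curves(curves: Iterable[DecayCurve], path, fmt: str | None = None) -> Path:
    """Write curves to CSV (fixed column order) or JSON; lossless round-trip."""
    curves = list(curves)
    if not curves:
        raise ValueError("refusing to write an empty curve collection")
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        _curves_to_frame(curves).to_csv(path, index=False)
        return path
    payload = [
        {
            "specimen_id": c.specimen_id,
            "tissue": c.tissue,
            "sequence": c.sequence,
            "nu_E_MHz": c.evolution_frequency,
            "t_E_s": c.times.tolist(),
            "Mz": c.magnetization.tolist(),
            "sigma": c.noise_sigma,
        }
        for c in curves
    ]
    path.write_text(json.dumps(payload, indent=1))
    return path
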