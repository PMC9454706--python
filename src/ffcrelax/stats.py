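"""Group statistics, cross-method lifetime converters, IHC area fractions,
and report generation.

The converters translate water-exchange measurements from two diffusion
MRI techniques into the intracellular lifetime convention used here:
filter-exchange imaging (FEXI) reports an apparent exchange rate AXR with
an extracellular water fraction fe, and time-dependent kurtosis imaging
reports an exchange mixing time with an extracellular volume fraction Ve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "compare_groups",
    "significance_stars",
    "tau_from_axr",
    "tau_from_dki",
    "ihc_area_fraction",
    "make_report",
]


def significance_stars(p: float | None) -> str:
    """Figure-caption star convention: * <0.05, ** <0.01, *** <0.001."""
    if p is None or not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupComparison:
    """One pairwise Welch comparison against the reference group."""

    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_stat: float | None
    p_value: float | None
    stars: str

    @property
    def se_a(self) -> float:
        return self.sd_a / np.sqrt(self.n_a) if self.n_a > 0 else float("nan")

    @property
    def se_b(self) -> float:
        return self.sd_b / np.sqrt(self.n_b) if self.n_b > 0 else float("nan")


def compare_groups(
    values_by_group: dict[str, "np.ndarray | list[float]"],
    reference: str | None = None,
    holm: bool = False,
) -> list[GroupComparison]:
    """Welch two-sample t-tests of every group against the reference.

    The reference defaults to the first key.  No multiplicity correction
    is applied unless ``holm=True`` (Holm step-down on the pairwise
    p-values).  Groups with fewer than 2 values get descriptive output
    only (no test statistic, no stars).
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least 2 groups to compare")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    reference = reference if reference is not None else next(iter(groups))
    ref = groups[reference]
    out = []
    for name, vals in groups.items():
        if name == reference:
            continue
        if ref.size < 2 or vals.size < 2:
            t = p = None
        else:
            t, p = sps.ttest_ind(ref, vals, equal_var=False)
            t, p = float(t), float(p)
        out.append(
            GroupComparison(
                group_a=reference, group_b=name,
                mean_a=float(ref.mean()), mean_b=float(vals.mean()),
                sd_a=float(ref.std(ddof=1)) if ref.size > 1 else float("nan"),
                sd_b=float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                n_a=int(ref.size), n_b=int(vals.size),
                t_stat=t, p_value=p, stars=significance_stars(p),
            )
        )
    if holm:
        from statsmodels.stats.multitest import multipletests

        tested = [c for c in out if c.p_value is not None]
        if tested:
            _, adj, _, _ = multipletests([c.p_value for c in tested], method="holm")
            for c, p_adj in zip(tested, adj):
                c.p_value = float(p_adj)
                c.stars = significance_stars(c.p_value)
    return out


def tau_from_axr(fe: float, axr: float) -> float:
    """Intracellular lifetime from a FEXI measurement: 1 / (fe * AXR).

    ``fe`` is the extracellular water fraction, ``axr`` the apparent
    exchange rate (s^-1); the product fe*AXR is the unidirectional efflux
    rate constant k_io, whose reciprocal is tau_in.
    """
    if not (np.isfinite(fe) and np.isfinite(axr)) or fe <= 0 or axr <= 0:
        raise ValueError("fe and axr must be positive and finite")
    return 1.0 / (fe * axr)


def tau_from_dki(tau_mix: float, ve: float) -> float:
    """Intracellular lifetime from kurtosis imaging: tau_mix / Ve.

    ``tau_mix`` is the water exchange mixing time (s) and ``ve`` the
    extracellular volume fraction, strictly inside (0, 1].
    """
    if not np.isfinite(tau_mix) or tau_mix <= 0:
        raise ValueError("tau_mix must be positive and finite")
    if not np.isfinite(ve) or not 0.0 < ve <= 1.0:
        raise ValueError("ve must lie in (0, 1]")
    return tau_mix / ve


def ihc_area_fraction(positive_mask, total_mask) -> float:
    """Immunopositive area as a percentage of the total analyzed area.

    Both inputs are binary masks of equal shape; positive pixels falling
    outside the total mask are intersected away with a warning.
    """
    pos = np.asarray(positive_mask).astype(bool)
    tot = np.asarray(total_mask).astype(bool)
    if pos.shape != tot.shape:
        raise ValueError(f"mask shapes differ: {pos.shape} vs {tot.shape}")
    n_total = int(tot.sum())
    if n_total == 0:
        raise ValueError("total mask is empty")
    outside = int((pos & ~tot).sum())
    if outside:
        warnings.warn(
            f"{outside} positive pixel(s) outside the total mask were ignored",
            stacklevel=2,
        )
    return 100.0 * int((pos & tot).sum()) / n_total


def make_report(
    out_dir,
    exchange_results: pd.DataFrame | None = None,
    powerlaw_results: pd.DataFrame | None = None,
    comparisons: list[GroupComparison] | None = None,
    profiles=None,
) -> list[Path]:
    """Write CSV summary tables and summary figures into ``out_dir``.

    Deterministic file names; the comparisons table is omitted when no
    comparisons are supplied.  ``profiles`` is an optional iterable of
    NMRD profiles for the log-log dispersion figure.  Returns the list of
    files written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if exchange_results is None and powerlaw_results is None:
        raise ValueError("at least one result table is required")

    if exchange_results is not None:
        path = out_dir / "exchange_summary.csv"
        exchange_results.to_csv(path, index=False)
        written.append(path)
    if powerlaw_results is not None:
        path = out_dir / "powerlaw_summary.csv"
        powerlaw_results.to_csv(path, index=False)
        written.append(path)
    if comparisons:
        rows = [
            dict(reference=c.group_a, group=c.group_b, mean_ref=c.mean_a,
                 mean=c.mean_b, sd_ref=c.sd_a, sd=c.sd_b, n_ref=c.n_a,
                 n=c.n_b, t=c.t_stat, p=c.p_value, stars=c.stars)
            for c in comparisons
        ]
        path = out_dir / "comparisons.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)

    if profiles:
        fig, ax = plt.subplots(figsize=(5, 4))
        for prof in profiles:
            ax.errorbar(prof.frequencies, prof.rates, yerr=prof.rate_errors,
                        marker="o", capsize=3, label=prof.tissue)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel(r"$\nu_0^E$ (MHz)")
        ax.set_ylabel(r"$R_1$ (s$^{-1}$)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out_dir / "nmrd_profiles.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    if exchange_results is not None and {"group", "tau_in_s"} <= set(
        exchange_results.columns
    ):
        summary = exchange_results.groupby("group")["tau_in_s"].agg(["mean", "sem"])
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.bar(summary.index, summary["mean"], yerr=summary["sem"], capsize=4)
        ax.set_ylabel(r"$\tau_{in}$ (s)")
        fig.tight_layout()
        path = out_dir / "tau_in_bars.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    return written
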