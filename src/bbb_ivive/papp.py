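"""Apparent-permeability estimation from sampled receiver timecourses.

The receiver chamber is sampled with replacement, so raw concentrations
underestimate cumulative transport.  The corrected cumulative mass at the
k-th sample is

    M_k = V_receiver * C_k + sum_{i<k} V_sample * C_i

(mass currently in the receiver plus everything removed by earlier samples).
Flux dM/dt comes from ordinary least squares of M against time with a free
intercept (the intercept absorbs lag and pre-steady-state transients), and

    Papp = (dM/dt) / (C0 * SA * 60)        [cm/s]

with dM/dt in nmol/min, C0 in µM (== nmol/mL) and SA in cm²; the factor 60
converts minutes to seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from bbb_ivive.bounds import Bound
from bbb_ivive.synthetic import AssayDesign, TimecourseTable, design_for_direction


class QCFlag(str, Enum):
    SINK_VIOLATION = "SINK_VIOLATION"
    POOR_LINEARITY = "POOR_LINEARITY"
    CENSORED_FAST = "CENSORED_FAST"
    BELOW_LOQ = "BELOW_LOQ"


@dataclass(frozen=True)
class QCThresholds:
    """Quality-control thresholds for Papp estimation.

    sink_fraction: maximum fraction of donor mass transferred before the
        sink-condition assumption is flagged.
    min_r_squared: minimum r² of the flux regression.
    censor_papp: the lower bound (cm/s) reported for runs too fast to
        quantify, mirroring the "> 500e-6" reporting convention.
    fast_equilibrium_fraction: a run is censored-fast when the first sampled
        receiver concentration already exceeds this fraction of its
        equilibrium value.
    """

    sink_fraction: float = 0.10
    min_r_squared: float = 0.90
    censor_papp: float = 500e-6
    fast_equilibrium_fraction: float = 0.50

    def __post_init__(self) -> None:
        for name in (
            "sink_fraction",
            "min_r_squared",
            "censor_papp",
            "fast_equilibrium_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class CumulativeMassSeries:
    """Dilution-corrected cumulative transported mass per timepoint."""

    time_min: np.ndarray
    conc_uM: np.ndarray
    mass_nmol: np.ndarray
    design: AssayDesign

    def __len__(self) -> int:
        return len(self.time_min)


@dataclass(frozen=True)
class FluxFit:
    slope: float  # nmol/min
    intercept: float  # nmol
    r_squared: float


@dataclass(frozen=True)
class PappEstimate:
    """Replicate-aggregated apparent permeability with QC metadata.

    ``papp`` is the point estimate, or the censoring bound when
    ``QCFlag.CENSORED_FAST`` is set (then ``censor_bound`` holds the same
    value and ``as_bound()`` reports kind ``"lower"``).  ``sd`` is the
    sample standard deviation across replicates, ``None`` for n = 1.
    """

    papp: float  # cm/s
    sd: float | None
    n_replicates: int
    r_squared: float
    flags: frozenset[QCFlag] = frozenset()
    censor_bound: float | None = None

    def __post_init__(self) -> None:
        if self.papp < 0:
            raise ValueError("papp must be >= 0")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")
        if QCFlag.CENSORED_FAST in self.flags and self.censor_bound is None:
            raise ValueError("censored estimates must carry a censor bound")

    @property
    def is_censored(self) -> bool:
        return QCFlag.CENSORED_FAST in self.flags

    def as_bound(self) -> Bound:
        if self.is_censored:
            return Bound(float(self.censor_bound), "lower")
        return Bound(self.papp)


def cumulative_receiver_mass(
    samples: pd.DataFrame | Sequence[tuple[float, float]],
    design: AssayDesign,
) -> CumulativeMassSeries:
    """Reconstruct cumulative transported mass from one replicate's samples.

    ``samples`` is either a DataFrame with ``time_min``/``conc_uM`` columns
    or a sequence of (time_min, conc_uM) pairs.  Times must be strictly
    increasing and concentrations non-negative.  Units: nmol for C in µM and
    volumes in mL.
    """
    if isinstance(samples, pd.DataFrame):
        t = np.asarray(samples["time_min"], dtype=float)
        c = np.asarray(samples["conc_uM"], dtype=float)
    else:
        arr = np.asarray(list(samples), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("samples must be (time, concentration) pairs")
        t, c = arr[:, 0], arr[:, 1]
    if len(t) == 0:
        raise ValueError("empty timecourse")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing (no duplicates)")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    removed_before = design.sample_volume * np.concatenate(([0.0], np.cumsum(c)[:-1]))
    mass = design.receiver_volume * c + removed_before
    return CumulativeMassSeries(time_min=t, conc_uM=c, mass_nmol=mass, design=design)


def fit_flux(series: CumulativeMassSeries) -> FluxFit:
    """OLS of cumulative mass against time, free intercept.

    Returns slope (nmol/min), intercept (nmol) and r².  r² is defined as 1
    for a perfectly flat series (zero residuals around a zero-variance
    response).
    """
    t = series.time_min
    m = series.mass_nmol
    if len(t) < 3:
        raise ValueError("flux regression needs at least 3 timepoints")
    if np.ptp(t) == 0:
        raise ValueError("zero variance in time")
    slope, intercept = np.polyfit(t, m, 1)
    resid = m - (slope * t + intercept)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(m - m.mean(), m - m.mean()))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return FluxFit(slope=float(slope), intercept=float(intercept), r_squared=r2)


def compute_papp(slope: float, design: AssayDesign) -> float:
    """Apparent permeability (cm/s) from flux slope (nmol/min)."""
    if design.donor_concentration_C0 <= 0:
        raise ValueError("C0 must be > 0")
    if design.membrane_area_SA <= 0:
        raise ValueError("membrane area must be > 0")
    return slope / (design.donor_concentration_C0 * design.membrane_area_SA * 60.0)


def quality_flags(
    series: CumulativeMassSeries,
    fit: FluxFit,
    design: AssayDesign,
    thresholds: QCThresholds = QCThresholds(),
) -> frozenset[QCFlag]:
    """QC flags for one replicate's fit.  Flags only; never raises."""
    flags: set[QCFlag] = set()
    donor_mass = design.donor_concentration_C0 * design.donor_volume
    if donor_mass > 0 and series.mass_nmol[-1] / donor_mass > thresholds.sink_fraction:
        flags.add(QCFlag.SINK_VIOLATION)
    if fit.r_squared < thresholds.min_r_squared:
        flags.add(QCFlag.POOR_LINEARITY)
    # equilibrium receiver concentration if all donor mass redistributed
    c_eq = donor_mass / (design.donor_volume + design.receiver_volume)
    if c_eq > 0 and series.conc_uM[0] > thresholds.fast_equilibrium_fraction * c_eq:
        flags.add(QCFlag.CENSORED_FAST)
    return frozenset(flags)


def estimate_replicate(
    samples: pd.DataFrame,
    design: AssayDesign,
    thresholds: QCThresholds = QCThresholds(),
    *,
    early_window: bool = False,
) -> tuple[float, FluxFit, frozenset[QCFlag]]:
    """Papp, fit and flags for a single replicate.

    With ``early_window`` a fit that violates sink conditions is retried on
    the first half of the timepoints (at least 3), where the linear-flux
    approximation holds better.
    """
    series = cumulative_receiver_mass(samples, design)
    fit = fit_flux(series)
    flags = quality_flags(series, fit, design, thresholds)
    if early_window and QCFlag.SINK_VIOLATION in flags and len(series) > 3:
        keep = max(3, len(series) // 2)
        sub = CumulativeMassSeries(
            time_min=series.time_min[:keep],
            conc_uM=series.conc_uM[:keep],
            mass_nmol=series.mass_nmol[:keep],
            design=design,
        )
        fit = fit_flux(sub)
        flags = quality_flags(sub, fit, design, thresholds) | {QCFlag.SINK_VIOLATION}
    papp = max(0.0, compute_papp(fit.slope, design))
    return papp, fit, frozenset(flags)


def aggregate_replicates(
    papps: Sequence[float],
    r_squareds: Sequence[float] | None = None,
    flags: Iterable[frozenset[QCFlag]] = (),
    thresholds: QCThresholds = QCThresholds(),
) -> PappEstimate:
    """Pool per-replicate Papp values into one estimate.

    Mean and sample standard deviation (n−1 denominator); a single replicate
    reports ``sd=None`` rather than 0.  Flags are the union over replicates;
    if any replicate is censored-fast the pooled value is reported as the
    censoring lower bound.
    """
    values = [float(p) for p in papps]
    if not values:
        raise ValueError("no replicates to aggregate")
    all_flags: frozenset[QCFlag] = frozenset().union(*flags) if flags else frozenset()
    n = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else None
    r2 = float(np.mean(r_squareds)) if r_squareds else float("nan")
    if QCFlag.CENSORED_FAST in all_flags:
        return PappEstimate(
            papp=thresholds.censor_papp,
            sd=None,
            n_replicates=n,
            r_squared=r2,
            flags=all_flags,
            censor_bound=thresholds.censor_papp,
        )
    return PappEstimate(papp=mean, sd=sd, n_replicates=n, r_squared=r2, flags=all_flags)


def estimate_panel(
    table: TimecourseTable,
    thresholds: QCThresholds = QCThresholds(),
    *,
    early_window: bool = False,
    loq_uM: float | None = None,
) -> pd.DataFrame:
    """Estimate Papp per (compound, direction) across replicates.

    Concentrations below ``loq_uM`` (when given) are replaced by LOQ/2 and
    the estimate flagged ``BELOW_LOQ``.  Returns a tidy frame with one row
    per compound and direction.
    """
    rows = []
    data = table.data
    for (compound, direction), group in data.groupby(["compound_id", "direction"], sort=True):
        design = design_for_direction(table.design, direction)
        papps, fits, flag_sets = [], [], []
        for _, rep_df in group.groupby("replicate"):
            rep_df = rep_df.sort_values("time_min")
            loq_flag: set[QCFlag] = set()
            if loq_uM is not None and (rep_df["conc_uM"] < loq_uM).any():
                rep_df = rep_df.assign(
                    conc_uM=rep_df["conc_uM"].where(rep_df["conc_uM"] >= loq_uM, loq_uM / 2.0)
                )
                loq_flag.add(QCFlag.BELOW_LOQ)
            papp, fit, flags = estimate_replicate(
                rep_df, design, thresholds, early_window=early_window
            )
            papps.append(papp)
            fits.append(fit.r_squared)
            flag_sets.append(flags | frozenset(loq_flag))
        est = aggregate_replicates(papps, fits, flag_sets, thresholds)
        rows.append(
            {
                "compound_id": compound,
                "direction": direction,
                "papp_cm_s": est.papp,
                "sd_cm_s": est.sd,
                "n": est.n_replicates,
                "r_squared": est.r_squared,
                "censored": est.is_censored,
                "censor_bound_cm_s": est.censor_bound,
                "flags": ";".join(sorted(f.value for f in est.flags)),
            }
        )
    return pd.DataFrame(rows)
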