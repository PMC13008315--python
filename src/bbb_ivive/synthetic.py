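"""Synthetic Transwell timecourses and toxicokinetic parameter tables.

The simulator reproduces the bidirectional transport protocol: a compound is
dosed into the donor chamber, the receiver chamber is sampled at fixed times
(default 30–180 min in 30 min steps), and after each sample the withdrawn
volume is replaced with blank buffer.  Between sampling events transport
follows the two-compartment balance

    dM_r/dt = P * SA * (C_d - C_r)

which includes back-diffusion, so tests can probe where the sink-condition
approximation used by the downstream Papp estimator breaks down.  The balance
is linear, so each inter-sample interval is propagated with the exact
exponential solution rather than a numeric integrator.

Measurement noise is multiplicative lognormal on the sampled concentration
(analytic-chemistry errors scale with signal); the underlying mass ledger is
always noise-free, so mass is conserved exactly at every event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

Direction = Literal["AB", "BA"]

#: Standard 12 mm Transwell insert geometry.  Apical volume 0.5 mL,
#: basolateral 1.5 mL, membrane 1.12 cm^2; configurable because the source
#: protocol does not print volumes.
DEFAULT_MEMBRANE_AREA_CM2 = 1.12
DEFAULT_APICAL_VOLUME_ML = 0.5
DEFAULT_BASOLATERAL_VOLUME_ML = 1.5
DEFAULT_SAMPLE_TIMES_MIN = (30.0, 60.0, 90.0, 120.0, 150.0, 180.0)
DEFAULT_SAMPLE_VOLUME_ML = 0.2
DEFAULT_DONOR_CONC_UM = 50.0

TIMECOURSE_COLUMNS = ["compound_id", "direction", "replicate", "time_min", "conc_uM"]


@dataclass(frozen=True)
class AssayDesign:
    """Geometry and sampling schedule of one Transwell permeability run."""

    donor_concentration_C0: float = DEFAULT_DONOR_CONC_UM  # µM
    donor_volume: float = DEFAULT_APICAL_VOLUME_ML  # mL
    receiver_volume: float = DEFAULT_BASOLATERAL_VOLUME_ML  # mL
    membrane_area_SA: float = DEFAULT_MEMBRANE_AREA_CM2  # cm^2
    sample_volume: float = DEFAULT_SAMPLE_VOLUME_ML  # mL
    sample_times: tuple[float, ...] = DEFAULT_SAMPLE_TIMES_MIN  # min
    direction: Direction = "AB"

    def __post_init__(self) -> None:
        if self.donor_concentration_C0 < 0:
            raise ValueError("donor concentration must be >= 0")
        for name in ("donor_volume", "receiver_volume", "membrane_area_SA", "sample_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sample_volume >= self.receiver_volume:
            raise ValueError("sample_volume must be smaller than receiver_volume")
        times = tuple(float(t) for t in self.sample_times)
        if len(times) == 0:
            raise ValueError("sample_times must be nonempty")
        if times[0] <= 0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample_times must be strictly increasing and > 0")
        object.__setattr__(self, "sample_times", times)
        if self.direction not in ("AB", "BA"):
            raise ValueError("direction must be 'AB' or 'BA'")


def design_for_direction(design: AssayDesign, direction: Direction) -> AssayDesign:
    """Return ``design`` oriented for ``direction``.

    AB doses the apical (smaller) chamber; BA doses the basolateral chamber,
    so donor and receiver volumes swap relative to the AB layout.
    """
    if direction == design.direction:
        return design
    return replace(
        design,
        donor_volume=design.receiver_volume,
        receiver_volume=design.donor_volume,
        direction=direction,
    )


@dataclass(frozen=True)
class TransportTruth:
    """Ground-truth transport parameters for recovery tests."""

    compound_id: str
    true_papp_AB: float  # cm/s
    true_papp_BA: float  # cm/s
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_papp_AB < 0 or self.true_papp_BA < 0:
            raise ValueError("permeabilities must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def papp_for(self, direction: Direction) -> float:
        return self.true_papp_AB if direction == "AB" else self.true_papp_BA


@dataclass
class TimecourseTable:
    """Tidy receiver-concentration samples linked to their assay design."""

    data: pd.DataFrame
    design: AssayDesign

    def __post_init__(self) -> None:
        missing = [c for c in TIMECOURSE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"timecourse table missing columns: {missing}")
        if (self.data["conc_uM"] < 0).any():
            raise ValueError("receiver concentrations must be >= 0")
        key = ["compound_id", "direction", "replicate", "time_min"]
        if self.data.duplicated(subset=key).any():
            raise ValueError("duplicate (compound, direction, replicate, time) rows")

    def replicate(self, compound_id: str, direction: Direction, replicate: int) -> pd.DataFrame:
        mask = (
            (self.data["compound_id"] == compound_id)
            & (self.data["direction"] == direction)
            & (self.data["replicate"] == replicate)
        )
        return self.data.loc[mask].sort_values("time_min").reset_index(drop=True)


def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative lognormal factors with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=n)


def _propagate(
    c_d: float, c_r: float, v_d: float, v_r: float, psa_ml_per_min: float, dt_min: float
) -> tuple[float, float]:
    """Exact solution of the linear two-compartment exchange over dt minutes."""
    if psa_ml_per_min == 0 or dt_min == 0:
        return c_d, c_r
    m_tot = c_d * v_d + c_r * v_r
    c_eq = m_tot / (v_d + v_r)
    lam = psa_ml_per_min * (1.0 / v_d + 1.0 / v_r)  # 1/min
    decay = math.exp(-lam * dt_min)
    return c_eq + (c_d - c_eq) * decay, c_eq + (c_r - c_eq) * decay


def simulate_timecourse(
    design: AssayDesign,
    truth: TransportTruth,
    n_replicates: int = 3,
    *,
    lag_min: float = 0.0,
) -> TimecourseTable:
    """Simulate sampled receiver concentrations for one transport direction.

    At each scheduled time the current receiver concentration is recorded
    (with multiplicative lognormal noise of CV ``truth.noise_cv``), then
    ``design.sample_volume`` of receiver content is withdrawn and replaced
    with blank buffer.  The donor is depleted by transferred mass and never
    replenished.  Deterministic given ``truth.seed``.

    ``lag_min`` delays the onset of flux (default 0: no lag simulated).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if lag_min < 0:
        raise ValueError("lag_min must be >= 0")
    papp = truth.papp_for(design.direction)
    # P [cm/s] * SA [cm^2] * 60 [s/min] -> clearance in cm^3/min == mL/min
    psa = papp * design.membrane_area_SA * 60.0
    rng = np.random.default_rng(truth.seed)
    rows: list[tuple[str, str, int, float, float]] = []
    for rep in range(n_replicates):
        noise = _noise_factors(rng, truth.noise_cv, len(design.sample_times))
        c_d = design.donor_concentration_C0
        c_r = 0.0
        t_prev = 0.0
        retained = design.receiver_volume - design.sample_volume
        for j, t in enumerate(design.sample_times):
            active = max(0.0, (t - max(t_prev, lag_min)))
            c_d, c_r = _propagate(
                c_d, c_r, design.donor_volume, design.receiver_volume, psa, active
            )
            measured = c_r * noise[j]
            rows.append((truth.compound_id, design.direction, rep, float(t), float(measured)))
            # withdraw sample_volume at concentration c_r, refill with blank
            c_r = c_r * retained / design.receiver_volume
            t_prev = t
    data = pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS)
    return TimecourseTable(data=data, design=design)


def simulate_bidirectional_panel(
    compounds: Sequence[TransportTruth],
    design: AssayDesign | None = None,
    n_replicates: int = 3,
) -> TimecourseTable:
    """Simulate AB and BA timecourses for a panel of compounds.

    The design is interpreted as the AB layout; BA runs use the same insert
    with donor/receiver volumes swapped.  Replicate streams are seeded per
    compound and direction so the table is byte-identical across calls.
    """
    if len(compounds) == 0:
        raise ValueError("need at least one compound")
    if design is None:
        design = AssayDesign()
    frames = []
    for truth in compounds:
        for direction in ("AB", "BA"):
            d = design_for_direction(design, direction)
            # decorrelate directions without extra user-facing seed plumbing
            t = replace(truth, seed=truth.seed * 2 + (0 if direction == "AB" else 1))
            frames.append(simulate_timecourse(d, t, n_replicates=n_replicates).data)
    data = pd.concat(frames, ignore_index=True)
    return TimecourseTable(data=data, design=design)


def event_ledger(
    design: AssayDesign, truth: TransportTruth, *, lag_min: float = 0.0
) -> pd.DataFrame:
    """Noise-free per-event mass ledger for one replicate.

    Replays the exact dynamics of :func:`simulate_timecourse` and reports, at
    each sampling event, the donor mass, the receiver mass *after* the sample
    is withdrawn, and the mass removed by that sample (all nmol).  Used to
    audit mass conservation: donor + receiver + cumulative removed must equal
    the initial donor mass at every event.
    """
    papp = truth.papp_for(design.direction)
    psa = papp * design.membrane_area_SA * 60.0
    c_d = design.donor_concentration_C0
    c_r = 0.0
    t_prev = 0.0
    retained = design.receiver_volume - design.sample_volume
    rows = []
    for t in design.sample_times:
        active = max(0.0, t - max(t_prev, lag_min))
        c_d, c_r = _propagate(c_d, c_r, design.donor_volume, design.receiver_volume, psa, active)
        removed = c_r * design.sample_volume
        c_r = c_r * retained / design.receiver_volume
        rows.append(
            (
                float(t),
                c_d * design.donor_volume,
                c_r * design.receiver_volume,
                removed,
            )
        )
        t_prev = t
    return pd.DataFrame(
        rows, columns=["time_min", "donor_mass_nmol", "receiver_mass_nmol", "removed_mass_nmol"]
    )


TOXKINETIC_COLUMNS = [
    "compound_id",
    "casrn",
    "fub",
    "css_serum_uM",
    "reference_dose_mg_kg_day",
]


def make_toxkinetic_table(
    compound_ids: Sequence[str],
    seed: int,
    casrns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Synthetic per-compound toxicokinetic parameters at 1 mg/kg/day.

    Fub is drawn log-uniformly in (0.005, 1] and the steady-state serum
    concentration log-uniformly in (0.01, 100] µM, mimicking the dynamic
    range of high-throughput toxicokinetic model outputs.  Deterministic
    given ``seed``.
    """
    ids = list(compound_ids)
    if not ids:
        raise ValueError("compound_ids must be nonempty")
    rng = np.random.default_rng(seed)
    fub = np.exp(rng.uniform(math.log(0.005), math.log(1.0), size=len(ids)))
    fub = np.minimum(fub, 1.0)
    css = np.exp(rng.uniform(math.log(0.01), math.log(100.0), size=len(ids)))
    if casrns is None:
        casrns = ["na"] * len(ids)
    return pd.DataFrame(
        {
            "compound_id": ids,
            "casrn": list(casrns),
            "fub": fub,
            "css_serum_uM": css,
            "reference_dose_mg_kg_day": 1.0,
        }
    )
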