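"""In-vitro-to-in-vivo extrapolation of BBB permeability measurements.

Acute exposure: brain uptake is modeled as a first-order loss from blood with
permeability–surface-area clearance PS = Fub * A_BBB * Papp_AB (volume/time;
only the unbound fraction diffuses).  PS is normalized by a reference
distribution volume V_ref to obtain a rate constant k = PS / V_ref with
units 1/time, and the uptake half-life is t1/2 = ln(2)/k.

.. note::
   The clearance product itself has units of volume per time; the division
   by V_ref (default 5 L, approximately systemic blood) is required for
   dimensional consistency and its value is a modeling choice, not a
   measured quantity.  V_ref is configurable and recorded in all outputs.

Chronic exposure: at steady state the brain:serum concentration ratio is set
by the efflux ratio alone, Css_brain = Css_serum / ER (Fub cancels assuming
similar binding in blood and brain; ionization is not modeled).  Css_serum
scales linearly with dose from its reference-dose value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

from bbb_ivive.bounds import Bound, divide
from bbb_ivive.metrics import BidirectionalResult

ML_PER_L = 1000.0
SECONDS_PER_MIN = 60.0
CM2_PER_M2 = 1e4


@dataclass(frozen=True)
class PhysiologyConfig:
    """Physiological scaling parameters.

    A_BBB_m2: total brain capillary endothelial surface area (20 m² for an
        adult human).
    V_ref_L: reference distribution volume converting the PS clearance to a
        rate constant (see module note).
    """

    A_BBB_m2: float = 20.0
    V_ref_L: float = 5.0

    def __post_init__(self) -> None:
        if self.A_BBB_m2 <= 0 or self.V_ref_L <= 0:
            raise ValueError("physiology parameters must be > 0")

    @property
    def A_BBB_cm2(self) -> float:
        return self.A_BBB_m2 * CM2_PER_M2


@dataclass(frozen=True)
class ToxkineticParams:
    """Per-compound toxicokinetic inputs at a reference dose."""

    compound_id: str
    fub: float  # fraction unbound in blood, (0, 1]
    css_serum_uM: float  # steady-state serum concentration at reference dose
    reference_dose_mg_kg_day: float = 1.0
    casrn: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fub <= 1):
            raise ValueError("Fub must be in (0, 1]")
        if self.css_serum_uM < 0:
            raise ValueError("Css_serum must be >= 0")


@dataclass(frozen=True)
class BrainExposure:
    """Predicted brain exposure for one compound.

    Acute: PS clearance (mL/min), uptake rate constant k (1/s) and half-life
    (s, ``inf`` when k = 0).  Chronic: steady-state brain concentration (µM,
    a typed bound when the efflux ratio is a bound).  Missing toxicokinetic
    inputs leave the corresponding fields ``None`` with a note; rows are
    never silently dropped.
    """

    compound_id: str
    ps_clearance_ml_min: float | Bound | None
    k_per_s: float | Bound | None
    t_half_s: float | Bound | None
    css_brain_uM: Bound | None
    efflux_ratio: Bound | None
    notes: tuple[str, ...] = ()


def ps_clearance(fub: float, papp_ab: float | Bound, physiology: PhysiologyConfig) -> float | Bound:
    """Permeability–surface-area clearance PS = Fub * A_BBB * Papp_AB, mL/min.

    A censored Papp propagates as a bound of the same direction.
    """
    if not (0 < fub <= 1):
        raise ValueError("Fub must be in (0, 1]")
    factor = fub * physiology.A_BBB_cm2 * SECONDS_PER_MIN  # cm/s -> mL/min
    if isinstance(papp_ab, Bound):
        if papp_ab.value < 0:
            raise ValueError("Papp must be >= 0")
        return papp_ab.scaled(factor)
    if papp_ab < 0:
        raise ValueError("Papp must be >= 0")
    return factor * papp_ab


def uptake_rate_constant(ps_ml_min: float | Bound, physiology: PhysiologyConfig) -> float | Bound:
    """First-order uptake rate constant k = PS / V_ref, in 1/s."""
    factor = 1.0 / (physiology.V_ref_L * ML_PER_L * SECONDS_PER_MIN)
    if isinstance(ps_ml_min, Bound):
        return ps_ml_min.scaled(factor)
    if ps_ml_min < 0:
        raise ValueError("PS must be >= 0")
    return ps_ml_min * factor


def uptake_half_life(k_per_s: float | Bound) -> float | Bound:
    """t1/2 = ln(2)/k in seconds; infinite at k = 0.

    A lower-bounded k ("> L") yields an upper-bounded half-life and vice
    versa.
    """
    if isinstance(k_per_s, Bound):
        if k_per_s.value < 0:
            raise ValueError("k must be >= 0")
        if k_per_s.value == 0:
            return Bound(math.inf, k_per_s.reciprocal_kind())
        return Bound(math.log(2) / k_per_s.value, k_per_s.reciprocal_kind())
    if k_per_s < 0:
        raise ValueError("k must be >= 0")
    if k_per_s == 0:
        return math.inf
    return math.log(2) / k_per_s


def css_brain(css_serum_uM: float, er: float | Bound) -> Bound:
    """Steady-state brain concentration Css_brain = Css_serum / ER (µM).

    An upper-bounded ER ("< x") yields a lower-bounded Css_brain and vice
    versa; ER = 0 is rejected.
    """
    if css_serum_uM < 0:
        raise ValueError("Css_serum must be >= 0")
    er_bound = er if isinstance(er, Bound) else Bound(float(er))
    if er_bound.value <= 0:
        raise ValueError("efflux ratio must be > 0")
    return divide(Bound(float(css_serum_uM)), er_bound)


def scale_dose(params: ToxkineticParams, dose_mg_kg_day: float) -> ToxkineticParams:
    """Linearly rescale Css_serum to a new daily dose."""
    if dose_mg_kg_day < 0:
        raise ValueError("dose must be >= 0")
    if params.reference_dose_mg_kg_day == 0:
        raise ValueError("reference dose must be nonzero")
    factor = dose_mg_kg_day / params.reference_dose_mg_kg_day
    return replace(
        params,
        css_serum_uM=params.css_serum_uM * factor,
        reference_dose_mg_kg_day=dose_mg_kg_day,
    )


def predict_panel(
    results: list[BidirectionalResult],
    params: pd.DataFrame | dict[str, ToxkineticParams],
    physiology: PhysiologyConfig = PhysiologyConfig(),
    dose_mg_kg_day: float | None = None,
) -> list[BrainExposure]:
    """Acute and chronic brain-exposure predictions for a compound panel.

    ``params`` is either a DataFrame in the toxicokinetic CSV schema
    (compound_id, casrn, fub, css_serum_uM, reference_dose_mg_kg_day) or a
    mapping of compound_id to :class:`ToxkineticParams`.  Compounds missing
    toxicokinetic parameters emit rows with the affected predictions set to
    ``None`` and an explanatory note.  Raises if no compound matches.
    """
    if isinstance(params, pd.DataFrame):
        lookup: dict[str, ToxkineticParams] = {}
        for _, row in params.iterrows():
            fub = row.get("fub")
            css = row.get("css_serum_uM")
            if pd.isna(fub) and pd.isna(css):
                continue
            lookup[str(row["compound_id"])] = ToxkineticParams(
                compound_id=str(row["compound_id"]),
                fub=float(fub) if not pd.isna(fub) else 1.0,
                css_serum_uM=float(css) if not pd.isna(css) else 0.0,
                reference_dose_mg_kg_day=float(row.get("reference_dose_mg_kg_day", 1.0)),
                casrn=str(row["casrn"]) if "casrn" in row and not pd.isna(row["casrn"]) else None,
            )
            if pd.isna(fub):
                lookup[str(row["compound_id"])] = replace(
                    lookup[str(row["compound_id"])], fub=1.0
                )
    else:
        lookup = dict(params)

    if results and lookup and not any(r.compound_id in lookup for r in results):
        unmatched = sorted(r.compound_id for r in results)
        raise ValueError(f"no toxicokinetic parameters match any compound: {unmatched}")

    exposures: list[BrainExposure] = []
    for result in results:
        notes: list[str] = []
        tk = lookup.get(result.compound_id)
        if tk is not None and dose_mg_kg_day is not None:
            tk = scale_dose(tk, dose_mg_kg_day)

        ps: float | Bound | None = None
        k: float | Bound | None = None
        t_half: float | Bound | None = None
        if tk is not None:
            ab = result.papp_ab.as_bound()
            ps = ps_clearance(tk.fub, ab.value if ab.is_exact else ab, physiology)
            k = uptake_rate_constant(ps, physiology)
            t_half = uptake_half_life(k)
        else:
            notes.append("acute-incomplete: no Fub available")

        css: Bound | None = None
        if tk is not None:
            if result.efflux_ratio.value > 0:
                css = css_brain(tk.css_serum_uM, result.efflux_ratio)
            else:
                notes.append("chronic-incomplete: efflux ratio is zero")
        else:
            notes.append("chronic-incomplete: no Css_serum available")

        exposures.append(
            BrainExposure(
                compound_id=result.compound_id,
                ps_clearance_ml_min=ps,
                k_per_s=k,
                t_half_s=t_half,
                css_brain_uM=css,
                efflux_ratio=result.efflux_ratio,
                notes=tuple(notes),
            )
        )
    return exposures
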