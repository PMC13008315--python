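"""Efflux ratios, uncertainty propagation and transport classification.

ER = Papp_BA / Papp_AB.  ER > 1 indicates net active export toward the
simulated blood space (apical efflux); ER < 1 net import toward brain.  When
a permeability is censored ("> L") the ratio is propagated as a typed bound:
a lower-bounded denominator yields an upper-bounded ER and vice versa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Literal

import pandas as pd

from bbb_ivive.bounds import Bound, divide
from bbb_ivive.papp import PappEstimate


class RateClass(str, Enum):
    SLOW = "Slow"
    MODERATE = "Moderate"
    FAST = "Fast"
    VERY_FAST = "Very fast"


class TransportCall(str, Enum):
    EFFLUX = "Efflux"
    INFLUX = "Influx"
    NO_BIAS = "NoBias"


@dataclass(frozen=True)
class RateThresholds:
    """Permeability-rate class boundaries (cm/s), inferred from the reference
    panel's class labels and configurable: Slow < slow_max <= Moderate <
    moderate_max <= Fast; censored at/above the censor cutoff is Very fast."""

    slow_max: float = 1e-6
    moderate_max: float = 12e-6
    fast_max: float = 500e-6

    def __post_init__(self) -> None:
        if not (0 < self.slow_max < self.moderate_max < self.fast_max):
            raise ValueError("rate-class boundaries must be positive and strictly increasing")


@dataclass(frozen=True)
class TransportThresholds:
    """ER cutoffs for the directional-transport call."""

    efflux_min: float = 2.5
    influx_max: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.influx_max < self.efflux_min):
            raise ValueError("need 0 < influx_max < efflux_min")


UncertaintyMethod = Literal["paper", "quadrature"]


@dataclass(frozen=True)
class BidirectionalResult:
    """Paired AB/BA permeability estimates with derived transport metrics."""

    compound_id: str
    papp_ab: PappEstimate
    papp_ba: PappEstimate
    efflux_ratio: Bound
    er_uncertainty: float | None
    rate_class: RateClass
    transport_call: TransportCall
    transport_indeterminate: bool = False
    casrn: str | None = None


def efflux_ratio(papp_ab: PappEstimate, papp_ba: PappEstimate) -> Bound:
    """ER = Papp_BA / Papp_AB, bound-propagating.

    An AB lower bound "> L" yields an upper bound "< Papp_BA/L"; a BA lower
    bound yields a lower-bounded ER.  The returned value is unrounded; report
    formatting applies the panel's precision conventions separately.
    """
    ab = papp_ab.as_bound()
    ba = papp_ba.as_bound()
    if ab.is_exact and ab.value == 0:
        raise ZeroDivisionError("efflux ratio undefined for uncensored Papp_AB = 0")
    return divide(ba, ab)


def er_uncertainty(
    papp_ab: PappEstimate,
    papp_ba: PappEstimate,
    method: UncertaintyMethod = "quadrature",
) -> float | None:
    """Propagated ER uncertainty from the two Papp standard deviations.

    ``"paper"``: sigma = ER * max(sd_AB/AB, sd_BA/BA) — the largest relative
    error of the two permeabilities.  ``"quadrature"`` (default): standard
    first-order propagation, ER * sqrt((sd_AB/AB)^2 + (sd_BA/BA)^2).  Returns
    ``None`` (never 0) when either sd is unavailable or either estimate is
    censored.
    """
    if papp_ab.sd is None or papp_ba.sd is None:
        return None
    if papp_ab.is_censored or papp_ba.is_censored:
        return None
    if papp_ab.papp == 0 or papp_ba.papp == 0:
        return None
    er = papp_ba.papp / papp_ab.papp
    rel_ab = papp_ab.sd / papp_ab.papp
    rel_ba = papp_ba.sd / papp_ba.papp
    if method == "paper":
        return er * max(rel_ab, rel_ba)
    if method == "quadrature":
        return er * math.sqrt(rel_ab**2 + rel_ba**2)
    raise ValueError(f"unknown uncertainty method: {method!r}")


def classify_rate(
    papp_ab: PappEstimate, thresholds: RateThresholds = RateThresholds()
) -> RateClass:
    """Permeability-rate class from the AB estimate alone."""
    if papp_ab.is_censored and papp_ab.censor_bound >= thresholds.fast_max:
        return RateClass.VERY_FAST
    value = papp_ab.as_bound().value
    if value < thresholds.slow_max:
        return RateClass.SLOW
    if value < thresholds.moderate_max:
        return RateClass.MODERATE
    if value < thresholds.fast_max:
        return RateClass.FAST
    return RateClass.VERY_FAST


def classify_transport(
    er: Bound, thresholds: TransportThresholds = TransportThresholds()
) -> tuple[TransportCall, bool]:
    """Directional-transport call from an ER value or bound.

    Returns (call, indeterminate).  Efflux at ER >= efflux_min, Influx below
    influx_max, NoBias between.  A one-sided bound classifies only when it
    decides the call; otherwise NoBias with ``indeterminate=True``.
    """
    if er.kind == "exact":
        if er.value >= thresholds.efflux_min:
            return TransportCall.EFFLUX, False
        if er.value < thresholds.influx_max:
            return TransportCall.INFLUX, False
        return TransportCall.NO_BIAS, False
    if er.kind == "upper":
        if er.value <= thresholds.influx_max:
            return TransportCall.INFLUX, False
        if er.value <= thresholds.efflux_min:
            # cannot be Efflux, but Influx vs NoBias undecided
            return TransportCall.NO_BIAS, True
        return TransportCall.NO_BIAS, True
    # lower bound "> x"
    if er.value >= thresholds.efflux_min:
        return TransportCall.EFFLUX, False
    if er.value >= thresholds.influx_max:
        return TransportCall.NO_BIAS, True
    return TransportCall.NO_BIAS, True


def format_er(er: Bound) -> str:
    """Render an ER with the reference panel's precision conventions:
    two decimals, one significant figure below 0.01.  Bounds keep their
    comparison sign and round outward (an upper bound up, a lower bound
    down) so the printed bound still holds."""
    v = er.value
    digits = -math.floor(math.log10(abs(v))) if v != 0 and abs(v) < 0.01 else 2
    scale = 10**digits
    if er.kind == "upper":
        rounded = math.ceil(v * scale) / scale
    elif er.kind == "lower":
        rounded = math.floor(v * scale) / scale
    else:
        rounded = round(v, digits)
    prefix = {"exact": "", "lower": "> ", "upper": "< "}[er.kind]
    return prefix + f"{rounded:.{digits}f}"


def build_result(
    compound_id: str,
    papp_ab: PappEstimate,
    papp_ba: PappEstimate,
    *,
    casrn: str | None = None,
    rate_thresholds: RateThresholds = RateThresholds(),
    transport_thresholds: TransportThresholds = TransportThresholds(),
    uncertainty_method: UncertaintyMethod = "quadrature",
) -> BidirectionalResult:
    er = efflux_ratio(papp_ab, papp_ba)
    call, indeterminate = classify_transport(er, transport_thresholds)
    return BidirectionalResult(
        compound_id=compound_id,
        papp_ab=papp_ab,
        papp_ba=papp_ba,
        efflux_ratio=er,
        er_uncertainty=er_uncertainty(papp_ab, papp_ba, uncertainty_method),
        rate_class=classify_rate(papp_ab, rate_thresholds),
        transport_call=call,
        transport_indeterminate=indeterminate,
        casrn=casrn,
    )


def build_results(
    estimates: pd.DataFrame,
    *,
    rate_thresholds: RateThresholds = RateThresholds(),
    transport_thresholds: TransportThresholds = TransportThresholds(),
    uncertainty_method: UncertaintyMethod = "quadrature",
) -> list[BidirectionalResult]:
    """Pair AB/BA rows of an estimates frame (see papp.estimate_panel) into
    per-compound bidirectional results.  Compounds lacking either direction
    are skipped."""
    results = []
    for compound, group in estimates.groupby("compound_id", sort=True):
        by_dir = {row["direction"]: row for _, row in group.iterrows()}
        if "AB" not in by_dir or "BA" not in by_dir:
            continue
        ests = {}
        for direction, row in by_dir.items():
            from bbb_ivive.papp import QCFlag  # local to avoid cycle at import time

            raw_flags = row["flags"] if isinstance(row["flags"], str) else ""
            flags = frozenset(QCFlag(f) for f in raw_flags.split(";") if f)
            sd = row["sd_cm_s"]
            ests[direction] = PappEstimate(
                papp=float(row["papp_cm_s"]),
                sd=None if sd is None or pd.isna(sd) else float(sd),
                n_replicates=int(row["n"]),
                r_squared=float(row["r_squared"]),
                flags=flags,
                censor_bound=(
                    float(row["censor_bound_cm_s"])
                    if row.get("censored") and not pd.isna(row.get("censor_bound_cm_s"))
                    else None
                ),
            )
        results.append(
            build_result(
                str(compound),
                ests["AB"],
                ests["BA"],
                rate_thresholds=rate_thresholds,
                transport_thresholds=transport_thresholds,
                uncertainty_method=uncertainty_method,
            )
        )
    return results
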