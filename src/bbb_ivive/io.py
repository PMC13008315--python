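"""CSV plumbing, packaged reference panel, reports and external comparison.

File conventions: UTF-8 comma-separated with header, ``NA`` for missing
values.  Machine-readable files carry typed bound columns (value +
bound_type); report files render bounds as ``"> x"`` / ``"< x"`` strings.
CASRN is the canonical join key; compounds without one use a slugified name.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from bbb_ivive.bounds import Bound
from bbb_ivive.ivive import BrainExposure
from bbb_ivive.metrics import (
    BidirectionalResult,
    RateThresholds,
    TransportThresholds,
    build_result,
    format_er,
)
from bbb_ivive.papp import PappEstimate, QCFlag
from bbb_ivive.synthetic import AssayDesign, TimecourseTable, TIMECOURSE_COLUMNS

NA = "NA"


def slugify(name: str) -> str:
    """Fallback join key for compounds without a CASRN."""
    return re.sub(r"[^a-z0-9]+", "-", name.lower()).strip("-")


def join_key(casrn: str | None, compound: str) -> str:
    if casrn and casrn.lower() not in ("", "na", "nan"):
        return casrn
    return slugify(compound)


# ---------------------------------------------------------------------------
# timecourse tables


def write_timecourse(table: TimecourseTable, path: str | Path) -> None:
    """Tidy timecourse CSV plus a ``<path>.design`` key=value sidecar."""
    path = Path(path)
    table.data.to_csv(path, index=False)
    d = table.design
    lines = [
        f"donor_concentration_C0 = {d.donor_concentration_C0!r}",
        f"donor_volume = {d.donor_volume!r}",
        f"receiver_volume = {d.receiver_volume!r}",
        f"membrane_area_SA = {d.membrane_area_SA!r}",
        f"sample_volume = {d.sample_volume!r}",
        f"sample_times = {','.join(str(t) for t in d.sample_times)}",
        f"direction = {d.direction}",
    ]
    Path(str(path) + ".design").write_text("\n".join(lines) + "\n")


def read_timecourse(path: str | Path) -> TimecourseTable:
    path = Path(path)
    data = pd.read_csv(path)
    missing = [c for c in TIMECOURSE_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"{path}: missing timecourse columns {missing}")
    sidecar = Path(str(path) + ".design")
    if not sidecar.exists():
        raise FileNotFoundError(f"design sidecar not found: {sidecar}")
    fields: dict[str, str] = {}
    for line in sidecar.read_text().splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
    design = AssayDesign(
        donor_concentration_C0=float(fields["donor_concentration_C0"]),
        donor_volume=float(fields["donor_volume"]),
        receiver_volume=float(fields["receiver_volume"]),
        membrane_area_SA=float(fields["membrane_area_SA"]),
        sample_volume=float(fields["sample_volume"]),
        sample_times=tuple(float(t) for t in fields["sample_times"].split(",")),
        direction=fields["direction"],  # type: ignore[arg-type]
    )
    return TimecourseTable(data=data, design=design)


# ---------------------------------------------------------------------------
# reference panel fixture


def load_table1_frame() -> pd.DataFrame:
    """Raw packaged bidirectional reference panel (48 printed rows).

    Permeability columns are in 1e-6 cm/s as printed; ``ab_bound`` marks the
    two censored "> 500" rows.  ``er_printed`` and ``rate_printed`` keep the
    published derived columns for cross-checks.
    """
    with resources.files("bbb_ivive.data").joinpath("table1.csv").open("r") as fh:
        return pd.read_csv(fh, dtype={"casrn": str})


def load_table1_fixture() -> list[BidirectionalResult]:
    """Reference panel as :class:`BidirectionalResult` objects.

    Papp values are converted to cm/s; censored rows become typed lower
    bounds at 500e-6 cm/s.  Efflux ratios, rate classes and transport calls
    are recomputed from the printed permeabilities with the default
    thresholds (the printed ER/rate columns stay available via
    :func:`load_table1_frame`).
    """
    frame = load_table1_frame()
    results = []
    for _, row in frame.iterrows():
        censored = row["ab_bound"] == "lower"
        ab = PappEstimate(
            papp=float(row["papp_ab_1e6"]) * 1e-6,
            sd=None if pd.isna(row["sd_ab_1e6"]) else float(row["sd_ab_1e6"]) * 1e-6,
            n_replicates=3,
            r_squared=float("nan"),
            flags=frozenset({QCFlag.CENSORED_FAST}) if censored else frozenset(),
            censor_bound=float(row["papp_ab_1e6"]) * 1e-6 if censored else None,
        )
        ba = PappEstimate(
            papp=float(row["papp_ba_1e6"]) * 1e-6,
            sd=None if pd.isna(row["sd_ba_1e6"]) else float(row["sd_ba_1e6"]) * 1e-6,
            n_replicates=3,
            r_squared=float("nan"),
        )
        results.append(
            build_result(
                str(row["compound"]),
                ab,
                ba,
                casrn=None if str(row["casrn"]) == "na" else str(row["casrn"]),
            )
        )
    return results


# ---------------------------------------------------------------------------
# estimates / toxicokinetic tables


def write_estimates(estimates: pd.DataFrame, path: str | Path) -> None:
    estimates.to_csv(path, index=False, na_rep=NA)


def read_estimates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=[NA])


def read_toxkinetic(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA], dtype={"casrn": str})
    required = {"compound_id", "fub", "css_serum_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing toxicokinetic columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# external comparison


@dataclass(frozen=True)
class ComparisonResult:
    r_squared: float
    n_paired: int
    n_censored_excluded: int
    pairs: pd.DataFrame  # casrn, papp_external, papp_measured


def compare_external(measured: pd.DataFrame, external: pd.DataFrame) -> ComparisonResult:
    """Pearson r² between measured AB permeabilities and an external panel.

    Both frames must carry ``casrn`` plus a permeability column
    (``papp_ab_cm_s`` for measured — censored rows are excluded and counted
    — and ``papp_cm_s`` for the external table).  Fewer than 3 pairs after
    the join declines the comparison.
    """
    for frame, col in ((measured, "papp_ab_cm_s"), (external, "papp_cm_s")):
        if "casrn" not in frame.columns or col not in frame.columns:
            raise ValueError(f"comparison input missing 'casrn'/'{col}' columns")
    m = measured.copy()
    n_censored = 0
    if "censored" in m.columns:
        n_censored = int(m["censored"].fillna(False).astype(bool).sum())
        m = m[~m["censored"].fillna(False).astype(bool)]
    joined = m.merge(external, on="casrn", how="inner", suffixes=("_m", "_e"))
    if len(joined) < 3:
        raise ValueError(
            f"comparison declined: only {len(joined)} paired compounds (need >= 3)"
        )
    x = joined["papp_cm_s"].to_numpy(dtype=float)
    y = joined["papp_ab_cm_s"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    pairs = joined[["casrn", "papp_cm_s", "papp_ab_cm_s"]].rename(
        columns={"papp_cm_s": "papp_external", "papp_ab_cm_s": "papp_measured"}
    )
    return ComparisonResult(
        r_squared=r2, n_paired=len(joined), n_censored_excluded=n_censored, pairs=pairs
    )


# ---------------------------------------------------------------------------
# reports


def _fmt_bound_1e6(b: Bound) -> str:
    """Render a permeability bound on the 1e-6 cm/s report scale."""
    prefix = {"exact": "", "lower": "> ", "upper": "< "}[b.kind]
    return f"{prefix}{b.value * 1e6:g}"


def _num(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return NA
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return f"{x:.6g}"


def results_report_frame(results: list[BidirectionalResult]) -> pd.DataFrame:
    """Table-style report: one row per compound, sorted by ascending Papp_AB,
    permeabilities on the 1e-6 cm/s scale and bounds as strings."""
    rows = []
    for r in results:
        rows.append(
            {
                "casrn": r.casrn or NA,
                "compound": r.compound_id,
                "key": join_key(r.casrn, r.compound_id),
                "papp_ab_1e6": _fmt_bound_1e6(r.papp_ab.as_bound()),
                "sd_ab_1e6": _num(None if r.papp_ab.sd is None else r.papp_ab.sd * 1e6),
                "papp_ba_1e6": _fmt_bound_1e6(r.papp_ba.as_bound()),
                "sd_ba_1e6": _num(None if r.papp_ba.sd is None else r.papp_ba.sd * 1e6),
                "efflux_ratio": format_er(r.efflux_ratio),
                "er_uncertainty": _num(r.er_uncertainty),
                "rate_class": r.rate_class.value,
                "transport_call": r.transport_call.value
                + ("?" if r.transport_indeterminate else ""),
                "_sort": r.papp_ab.as_bound().value,
            }
        )
    frame = pd.DataFrame(rows).sort_values(["_sort", "compound"]).drop(columns="_sort")
    return frame.reset_index(drop=True)


def er_plot_frame(results: list[BidirectionalResult]) -> pd.DataFrame:
    """Long-format ER data for bar plots (compound, ER, uncertainty, Papp_AB)."""
    rows = [
        {
            "compound": r.compound_id,
            "er": r.efflux_ratio.value,
            "er_bound_type": r.efflux_ratio.kind,
            "er_uncertainty": _num(r.er_uncertainty),
            "papp_ab_cm_s": r.papp_ab.as_bound().value,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def exposure_report_frame(
    exposures: list[BrainExposure], css_serum: dict[str, float] | None = None
) -> pd.DataFrame:
    """Brain-exposure report; when serum concentrations are supplied the rows
    are sorted by decreasing Css_serum (paired-bar figure convention)."""

    def cell(x: float | Bound | None) -> str:
        if x is None:
            return NA
        if isinstance(x, Bound):
            prefix = {"exact": "", "lower": "> ", "upper": "< "}[x.kind]
            return prefix + ("inf" if math.isinf(x.value) else f"{x.value:.6g}")
        return _num(x)

    rows = []
    for e in exposures:
        rows.append(
            {
                "compound": e.compound_id,
                "ps_clearance_ml_min": cell(e.ps_clearance_ml_min),
                "k_per_s": cell(e.k_per_s),
                "t_half_s": cell(e.t_half_s),
                "css_brain_uM": cell(e.css_brain_uM),
                "css_serum_uM": _num(css_serum.get(e.compound_id)) if css_serum else NA,
                "notes": ";".join(e.notes),
                "_sort": -(css_serum.get(e.compound_id, -math.inf) if css_serum else 0.0),
            }
        )
    frame = pd.DataFrame(rows).sort_values(["_sort", "compound"]).drop(columns="_sort")
    return frame.reset_index(drop=True)


def render_reports(
    results: list[BidirectionalResult],
    exposures: list[BrainExposure] | None,
    out_dir: str | Path,
    *,
    css_serum: dict[str, float] | None = None,
    manifest: dict | None = None,
) -> list[Path]:
    """Write the report bundle; returns the paths written.

    Outputs: ``results_table.csv`` (panel-style, ascending Papp_AB),
    ``er_long.csv`` (figure-ready ER data), ``brain_exposure.csv`` (when
    exposures are given and non-empty; an empty table is skipped with a
    warning) and ``run_manifest.json`` with every threshold applied.
    """
    if not results:
        raise ValueError("cannot render reports from empty results")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    path = out / "results_table.csv"
    results_report_frame(results).to_csv(path, index=False)
    written.append(path)

    path = out / "er_long.csv"
    er_plot_frame(results).to_csv(path, index=False)
    written.append(path)

    if exposures:
        path = out / "brain_exposure.csv"
        exposure_report_frame(exposures, css_serum).to_csv(path, index=False)
        written.append(path)
    elif exposures is not None:
        import logging

        logging.getLogger(__name__).warning("empty exposure table; report skipped")

    path = out / "run_manifest.json"
    payload = {
        "rate_thresholds": asdict(RateThresholds()),
        "transport_thresholds": asdict(TransportThresholds()),
    }
    if manifest:
        payload.update(manifest)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written
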