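"""Clearance-method permeability estimation.

The receiver (basolateral) compartment is fully replaced at every
sampling, which keeps it near sink conditions.  Each interval's receiver
signal is converted into a *clearance* — the donor-equivalent volume
(µL) cleared across the barrier during that interval::

    clearance_n = A_baso,tn * V_baso / A_stock

The cumulative cleared volume is regressed on time; the slope is the
permeability–surface-area product PS (µL/min).  Cell-layer permeability
is isolated from the bare-membrane contribution by treating the cell
layer and the blank membrane as resistances in series::

    1/PS_cell = 1/PS_all - 1/PS_blank

and converted to an apparent permeability coefficient
Papp = 10 * PS_cell / area, where the factor 10 converts
µL·min⁻¹·cm⁻² to µm/min.

Three clearance modes are provided because the printed interval
correction for later timepoints is ambiguous (see the modes' docstrings
and docs/methods.md); ``per_interval`` is the default and is exact for a
receiver that starts every interval fresh.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .plate_io import ExperimentGeometry, StudyTable, WellSeries

ClearanceMode = Literal["literal", "per_interval", "donor_corrected"]
CLEARANCE_MODES = ("literal", "per_interval", "donor_corrected")

#: default applied donor concentrations (µM): paracellular marker CF at
#: 10 µM, every other analyte at 100 µM
DEFAULT_STOCK_UM: dict[str, float] = {"CF": 10.0}
DEFAULT_STOCK_UM_OTHER = 100.0


class BlankDominatedError(ValueError):
    """Cell+membrane PS is not below the blank-membrane PS.

    1/PS_all − 1/PS_blank ≤ 0 is non-physical (adding a cell layer can
    only add resistance) and indicates noise or a failed blank; no
    numeric PS_cell exists for such a well.
    """


@dataclass(frozen=True)
class ClearanceCurve:
    """Per-interval and cumulative cleared volumes (µL) for one series."""

    interval_ul: np.ndarray
    cumulative_ul: np.ndarray
    sampling_times_min: tuple[float, ...]
    mode: str


@dataclass(frozen=True)
class PermeabilitySlope:
    """OLS slope of cumulative cleared volume vs. time."""

    ps_ul_min: float
    intercept_ul: float
    r_squared: float
    n_points: int

    @property
    def reciprocal(self) -> float:
        """1/PS, the series-resistance term used in the blank correction."""
        return 1.0 / self.ps_ul_min


def interval_clearance(
    series: WellSeries,
    geometry: ExperimentGeometry,
    mode: ClearanceMode = "per_interval",
) -> ClearanceCurve:
    """Convert one series' receiver signals into per-interval clearances.

    Modes
    -----
    ``per_interval``
        clearance_n = A_n · V_baso / A_stock for every interval.  No
        cross-interval correction: each interval's receiver starts
        fresh, so A_n already reflects only that interval's transfer.
        Default.
    ``literal``
        The first interval as above; later intervals subtract the
        running correction term Σ_{i<n}(A_i·f − A_1·f) with f the
        basolateral/apical volume factor.  Retained for fidelity
        comparison with legacy spreadsheets; its bias is quantified by
        the simulator.
    ``donor_corrected``
        clearance_n = A_n · V_baso / (A_stock − f·Σ_{i<n} A_i), i.e.
        each interval is referenced to the mass-balance-depleted donor
        signal instead of the initial stock.  Removes the
        donor-depletion bias of the uncorrected modes.
    """
    if mode not in CLEARANCE_MODES:
        raise ValueError(f"unknown clearance mode {mode!r}")
    if series.stock_signal <= 0:
        raise ValueError(f"well {series.well_id}: stock signal must be positive")
    a = np.asarray(series.baso_signal, dtype=float)
    v_baso = geometry.basolateral_volume_ul
    f = geometry.volume_factor
    base = a * v_baso / series.stock_signal
    if mode == "per_interval":
        interval = base
    elif mode == "literal":
        interval = base.copy()
        for n in range(1, len(a)):
            correction = float(np.sum(a[:n] * f - a[0] * f))
            interval[n] = base[n] - correction
    else:  # donor_corrected
        interval = np.empty_like(base)
        depleted = series.stock_signal
        for n in range(len(a)):
            if depleted <= 0:
                raise ValueError(
                    f"well {series.well_id}: donor fully depleted before interval {n + 1}"
                )
            interval[n] = a[n] * v_baso / depleted
            depleted -= f * a[n]
    return ClearanceCurve(
        interval_ul=interval,
        cumulative_ul=np.cumsum(interval),
        sampling_times_min=geometry.sampling_times_min,
        mode=mode,
    )


def fit_ps(
    curve: ClearanceCurve,
    sampling_times_min: Sequence[float] | None = None,
) -> PermeabilitySlope:
    """OLS slope (free intercept) of cumulative cleared volume vs. time.

    The origin (0, 0) is included as a data point: at t=0 nothing has
    been cleared by construction.  A non-positive slope marks a
    non-transporting or inverted well and is flagged by the caller.
    """
    times = tuple(sampling_times_min) if sampling_times_min is not None else curve.sampling_times_min
    if len(times) != len(curve.cumulative_ul):
        raise ValueError("sampling times and cumulative series differ in length")
    x = np.concatenate(([0.0], np.asarray(times, dtype=float)))
    y = np.concatenate(([0.0], np.asarray(curve.cumulative_ul, dtype=float)))
    if len(x) < 2:
        raise ValueError("need at least two points to fit a slope")
    res = stats.linregress(x, y)
    return PermeabilitySlope(
        ps_ul_min=float(res.slope),
        intercept_ul=float(res.intercept),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0,
        n_points=len(x),
    )


def correct_blank(ps_all: float, ps_blank: float) -> float:
    """Series-resistance blank correction: 1/PS_cell = 1/PS_all − 1/PS_blank.

    ``ps_blank`` should be the mean fitted PS of the matched blank group
    (same compound and inhibitor, membranes only).  Raises
    :class:`BlankDominatedError` when ``ps_all >= ps_blank``.
    """
    if ps_all <= 0 or ps_blank <= 0:
        raise ValueError("PS values must be positive")
    if ps_all >= ps_blank:
        raise BlankDominatedError(
            f"PS_all ({ps_all:g}) >= PS_blank ({ps_blank:g}): cell-layer resistance "
            "is indistinguishable from zero"
        )
    return 1.0 / (1.0 / ps_all - 1.0 / ps_blank)


def papp(ps_cell: float, insert_area_cm2: float) -> float:
    """Apparent permeability coefficient in µm/min.

    Papp = 10 · PS_cell / area; 1 µL·min⁻¹·cm⁻² = 10⁻³ cm/min = 10 µm/min.
    """
    if insert_area_cm2 <= 0:
        raise ValueError("insert area must be positive")
    if ps_cell < 0:
        raise ValueError("PS_cell must be non-negative")
    return 10.0 * ps_cell / insert_area_cm2


def normalize_to_cf(papp_compound, papp_cf_matched):
    """Papp expressed as a fold of the matched paracellular-marker (CF) Papp.

    Accepts scalars or equally shaped arrays (per-insert pairing: CF is
    co-applied on every insert, so each insert has its own CF Papp).
    """
    cf = np.asarray(papp_cf_matched, dtype=float)
    if np.any(cf <= 0):
        raise ValueError("CF Papp must be positive")
    out = np.asarray(papp_compound, dtype=float) / cf
    return float(out) if out.ndim == 0 else out


def fold_change(papp_treated, papp_reference) -> float:
    """Ratio of group means (treated over reference).

    Scalars are treated as group means; arrays are averaged first.
    """
    ref = float(np.mean(papp_reference))
    if ref <= 0:
        raise ValueError("reference Papp must be positive")
    return float(np.mean(papp_treated)) / ref


def cumulated_amount(
    series: WellSeries,
    geometry: ExperimentGeometry,
    stock_concentration_um: float,
) -> float:
    """Total analyte amount collected basolaterally, per membrane area (nmol/mm²).

    Signal is assumed linear in concentration, anchored by the stock
    (A_stock ↔ stock concentration).  1 µM = 10⁻³ nmol/µL; 1 cm² = 100 mm².
    """
    if series.stock_signal <= 0:
        raise ValueError(f"well {series.well_id}: stock signal must be positive")
    if stock_concentration_um <= 0:
        raise ValueError("stock concentration must be positive")
    conc_nmol_ul = stock_concentration_um * 1e-3
    frac = np.asarray(series.baso_signal, dtype=float) / series.stock_signal
    amount_nmol = float(np.sum(frac) * conc_nmol_ul * geometry.basolateral_volume_ul)
    area_mm2 = geometry.insert_area_cm2 * 100.0
    return amount_nmol / area_mm2


# ---------------------------------------------------------------------------
# study-level pipeline


@dataclass
class StudyResult:
    """Per-well and per-group permeability results.

    ``wells`` has one row per series with fitted PS_all, blank-corrected
    PS_cell, Papp, CF-normalized Papp, cumulated amount and a status
    flag (``ok``, ``blank_dominated`` or ``excluded``).  ``groups``
    aggregates ok cells wells per (compound, inhibitor, treatment).
    """

    wells: pd.DataFrame
    groups: pd.DataFrame
    exclusions: list[str]


def _group_blank_ps(table: StudyTable, fits: Mapping[tuple[str, str], PermeabilitySlope]) -> dict:
    """Mean fitted PS over each blank group with positive slopes."""
    acc: dict[tuple[str, str, str], list[float]] = {}
    for w in table.wells:
        if w.role != "blank":
            continue
        slope = fits[(w.well_id, w.compound)]
        if slope.ps_ul_min > 0:
            acc.setdefault((w.compound, w.inhibitor, w.treatment), []).append(slope.ps_ul_min)
    return {k: float(np.mean(v)) for k, v in acc.items()}


def analyze_study(
    table: StudyTable,
    mode: ClearanceMode = "per_interval",
    cf_normalization: Literal["per_insert", "group_mean"] = "per_insert",
    stock_concentrations_um: Mapping[str, float] | None = None,
    cf_compound: str = "CF",
) -> StudyResult:
    """Run the full clearance pipeline on a study table.

    Wells with non-positive fitted PS are flagged ``excluded``; cells
    wells whose PS_all reaches the blank PS are flagged
    ``blank_dominated``.  Flagged wells are dropped from group means but
    counted in the group table and listed in ``exclusions``.
    """
    table.require_blanks()
    geometry = table.geometry
    if not table.wells:
        cols = [
            "well_id", "role", "compound", "inhibitor", "treatment", "channel",
            "ps_fit_ul_min", "fit_r2", "flag", "ps_all_ul_min", "ps_blank_ul_min",
            "ps_cell_ul_min", "papp_um_min", "papp_cf_norm", "cumulated_nmol_mm2",
        ]
        return StudyResult(
            wells=pd.DataFrame(columns=cols), groups=pd.DataFrame(), exclusions=[]
        )
    stock_um = dict(DEFAULT_STOCK_UM)
    if stock_concentrations_um:
        stock_um.update(stock_concentrations_um)

    fits: dict[tuple[str, str], PermeabilitySlope] = {}
    for w in table.wells:
        fits[(w.well_id, w.compound)] = fit_ps(interval_clearance(w, geometry, mode))
    blank_ps = _group_blank_ps(table, fits)

    rows = []
    exclusions: list[str] = []
    for w in table.wells:
        slope = fits[(w.well_id, w.compound)]
        row = {
            "well_id": w.well_id,
            "role": w.role,
            "compound": w.compound,
            "inhibitor": w.inhibitor,
            "treatment": w.treatment,
            "channel": w.channel,
            "ps_fit_ul_min": slope.ps_ul_min,
            "fit_r2": slope.r_squared,
            "flag": "ok",
            "ps_all_ul_min": np.nan,
            "ps_blank_ul_min": np.nan,
            "ps_cell_ul_min": np.nan,
            "papp_um_min": np.nan,
            "papp_cf_norm": np.nan,
            "cumulated_nmol_mm2": np.nan,
        }
        if slope.ps_ul_min <= 0:
            row["flag"] = "excluded"
            exclusions.append(f"{w.well_id}/{w.compound}: non-positive fitted PS")
        elif w.role == "cells":
            row["ps_all_ul_min"] = slope.ps_ul_min
            pb = blank_ps.get((w.compound, w.inhibitor, w.treatment))
            if pb is None:
                row["flag"] = "excluded"
                exclusions.append(f"{w.well_id}/{w.compound}: blank group unusable")
            else:
                row["ps_blank_ul_min"] = pb
                try:
                    ps_cell = correct_blank(slope.ps_ul_min, pb)
                except BlankDominatedError:
                    row["flag"] = "blank_dominated"
                    exclusions.append(f"{w.well_id}/{w.compound}: blank dominated")
                else:
                    row["ps_cell_ul_min"] = ps_cell
                    row["papp_um_min"] = papp(ps_cell, geometry.insert_area_cm2)
            conc = stock_um.get(w.compound, DEFAULT_STOCK_UM_OTHER)
            row["cumulated_nmol_mm2"] = cumulated_amount(w, geometry, conc)
        rows.append(row)
    wells = pd.DataFrame(rows)

    # CF normalization
    cf_ok = wells[(wells.compound == cf_compound) & (wells.flag == "ok") & (wells.role == "cells")]
    if len(cf_ok):
        if cf_normalization == "per_insert":
            cf_by_insert = dict(zip(cf_ok.well_id, cf_ok.papp_um_min))
            wells["papp_cf_norm"] = [
                r.papp_um_min / cf_by_insert[r.well_id]
                if (
                    r.role == "cells"
                    and r.flag == "ok"
                    and r.well_id in cf_by_insert
                    and np.isfinite(r.papp_um_min)
                )
                else np.nan
                for r in wells.itertuples()
            ]
        else:  # group_mean
            cf_group_mean = cf_ok.groupby(["inhibitor", "treatment"]).papp_um_min.mean()
            def _norm(r):
                key = (r.inhibitor, r.treatment)
                if r.role == "cells" and r.flag == "ok" and key in cf_group_mean.index:
                    return r.papp_um_min / cf_group_mean[key]
                return np.nan
            wells["papp_cf_norm"] = [_norm(r) for r in wells.itertuples()]

    grp_rows = []
    for (compound, inhibitor, treatment), sub in wells[wells.role == "cells"].groupby(
        ["compound", "inhibitor", "treatment"]
    ):
        ok = sub[sub.flag == "ok"]
        n = len(ok)
        grp = {
            "compound": compound,
            "inhibitor": inhibitor,
            "treatment": treatment,
            "n": n,
            "n_excluded": len(sub) - n,
        }
        for col, label in [
            ("papp_um_min", "papp_um_min"),
            ("papp_cf_norm", "papp_cf_norm"),
            ("ps_cell_ul_min", "ps_cell_ul_min"),
            ("cumulated_nmol_mm2", "cumulated_nmol_mm2"),
        ]:
            vals = ok[col].dropna()
            grp[f"{label}_mean"] = float(vals.mean()) if len(vals) else np.nan
            grp[f"{label}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            grp[f"{label}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            )
        grp_rows.append(grp)
    groups = pd.DataFrame(grp_rows)
    return StudyResult(wells=wells, groups=groups, exclusions=exclusions)
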