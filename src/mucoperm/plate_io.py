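"""Reading, validation and writing of Transwell experiment tables.

The canonical measurement layout is a long delimited table with one row
per (insert, compound, sampling time, replicate).  A wide layout with one
column per sampling time is also accepted.  Replicate readings (e.g.
triplicate basolateral/stock measurements) are averaged on ingest; the
raw replicates are retained on the assembled :class:`WellSeries` for QC.

Column dictionary (long layout)
-------------------------------
well_id        insert identifier; the same id may carry several series
               (e.g. an NSAID plus the co-applied carboxyfluorescein)
role           ``cells`` or ``blank`` (bare membrane, no cell layer)
compound       analyte label (CF, diazepam, ibuprofen, ...)
inhibitor      ``none``, ``verapamil`` or ``probenecid`` (optional)
treatment      ``control``, ``INF``, ``INF+Ibu``, ``Ibu`` or ``n/a``
               (optional)
channel        detection channel: ``RFU`` (fluorescence) or ``mAU_min``
               (HPLC peak area)
time_min       sampling time in minutes; must match the configured
               schedule exactly
baso_signal    basolateral receiver signal for that interval (each
               interval starts with fresh receiver medium)
stock_signal   signal of the applied apical stock solution
replicate      optional replicate index; rows sharing (well_id,
               compound, time_min) are averaged
apical_end_signal  optional end-of-run apical signal (stored, unused by
               default)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ROLES = ("cells", "blank")
INHIBITORS = ("none", "verapamil", "probenecid")
TREATMENTS = ("control", "INF", "INF+Ibu", "Ibu", "n/a")
CHANNELS = ("RFU", "mAU_min")


class PlateIOError(ValueError):
    """Raised for malformed configuration or measurement tables."""


@dataclass(frozen=True)
class ExperimentGeometry:
    """Compartment geometry and sampling schedule of a Transwell run.

    Parameters
    ----------
    apical_volume_ul : float
        Donor (apical) compartment volume in µL.
    basolateral_volume_ul : float
        Receiver (basolateral) compartment volume in µL.
    insert_area_cm2 : float
        Membrane growth area of the insert in cm².
    sampling_times_min : tuple of float
        Times (minutes, strictly increasing, all > 0) at which the
        basolateral medium is collected and replaced.
    """

    apical_volume_ul: float
    basolateral_volume_ul: float
    insert_area_cm2: float
    sampling_times_min: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.apical_volume_ul <= 0 or self.basolateral_volume_ul <= 0:
            raise PlateIOError("compartment volumes must be positive")
        if self.insert_area_cm2 <= 0:
            raise PlateIOError("insert area must be positive")
        times = tuple(float(t) for t in self.sampling_times_min)
        if len(times) == 0:
            raise PlateIOError("sampling schedule is empty")
        if times[0] <= 0:
            raise PlateIOError("sampling times must start after t=0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise PlateIOError(f"sampling times must be strictly increasing, got {times}")
        object.__setattr__(self, "sampling_times_min", times)

    @property
    def volume_factor(self) -> float:
        """Basolateral/apical volume ratio (3 for the 900/300 µL protocol)."""
        return self.basolateral_volume_ul / self.apical_volume_ul

    @classmethod
    def default(cls) -> "ExperimentGeometry":
        """24-well ThinCert protocol: 300/900 µL, 0.336 cm², hourly sampling for 4 h."""
        return cls(300.0, 900.0, 0.336, (60.0, 120.0, 180.0, 240.0))


@dataclass
class WellSeries:
    """One analyte's time course on one insert.

    ``baso_signal`` holds one receiver reading per sampling time; each
    reading comes from a fresh receiver volume because the insert is
    transferred to new basolateral medium at every sampling.
    """

    well_id: str
    role: str
    compound: str
    channel: str
    baso_signal: np.ndarray
    stock_signal: float
    inhibitor: str = "none"
    treatment: str = "n/a"
    apical_end_signal: float | None = None
    baso_replicates: dict[float, list[float]] | None = field(default=None, repr=False)
    stock_replicates: list[float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PlateIOError(f"well {self.well_id}: unknown role {self.role!r}")
        if self.inhibitor not in INHIBITORS:
            raise PlateIOError(f"well {self.well_id}: unknown inhibitor {self.inhibitor!r}")
        if self.treatment not in TREATMENTS:
            raise PlateIOError(f"well {self.well_id}: unknown treatment {self.treatment!r}")
        if self.channel not in CHANNELS:
            raise PlateIOError(f"well {self.well_id}: unknown channel {self.channel!r}")
        self.baso_signal = np.asarray(self.baso_signal, dtype=float)
        if np.any(self.baso_signal < 0):
            raise PlateIOError(f"well {self.well_id}: negative basolateral signal")
        if not math.isfinite(self.stock_signal) or self.stock_signal <= 0:
            raise PlateIOError(f"well {self.well_id}: stock signal must be positive")

    @property
    def group_key(self) -> tuple[str, str, str, str]:
        return (self.compound, self.inhibitor, self.treatment, self.role)


@dataclass
class StudyTable:
    """A validated collection of :class:`WellSeries` sharing one geometry."""

    geometry: ExperimentGeometry
    wells: list[WellSeries]

    def __post_init__(self) -> None:
        n_t = len(self.geometry.sampling_times_min)
        seen: set[tuple[str, str]] = set()
        for w in self.wells:
            if len(w.baso_signal) != n_t:
                raise PlateIOError(
                    f"well {w.well_id} ({w.compound}): {len(w.baso_signal)} basolateral "
                    f"values for {n_t} sampling times"
                )
            key = (w.well_id, w.compound)
            if key in seen:
                raise PlateIOError(f"duplicate series for well {w.well_id}, compound {w.compound}")
            seen.add(key)

    def require_blanks(self) -> None:
        """Fail unless every cells group has a matched blank group.

        Blank inserts are paired per (compound, inhibitor, treatment):
        the blank-membrane permeability enters the series-resistance
        correction, so a cells group without blanks cannot be analysed.
        """
        blanks = {(w.compound, w.inhibitor, w.treatment) for w in self.wells if w.role == "blank"}
        for w in self.wells:
            if w.role == "cells" and (w.compound, w.inhibitor, w.treatment) not in blanks:
                raise PlateIOError(
                    f"no blank group for compound={w.compound}, inhibitor={w.inhibitor}, "
                    f"treatment={w.treatment} (needed for well {w.well_id})"
                )

    def groups(self) -> dict[tuple[str, str, str, str], list[WellSeries]]:
        out: dict[tuple[str, str, str, str], list[WellSeries]] = {}
        for w in self.wells:
            out.setdefault(w.group_key, []).append(w)
        return out


_GEOMETRY_ALIASES = {
    "apical_volume_ul": ("apical_volume_ul", "apical", "apical_ul"),
    "basolateral_volume_ul": ("basolateral_volume_ul", "baso", "basolateral", "baso_ul"),
    "insert_area_cm2": ("insert_area_cm2", "area", "area_cm2"),
    "sampling_times_min": ("sampling_times_min", "times", "times_min"),
}


def read_experiment_config(path: str | Path) -> ExperimentGeometry:
    """Read a YAML geometry config and return a validated geometry.

    The volume factor is always derived from the two volumes; a
    ``volume_factor`` key in the file is ignored.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise PlateIOError(f"{path}: config must be a mapping")
    values: dict[str, object] = {}
    for canonical, aliases in _GEOMETRY_ALIASES.items():
        hits = [k for k in aliases if k in raw]
        if not hits:
            raise PlateIOError(f"{path}: missing geometry key {canonical!r}")
        values[canonical] = raw[hits[0]]
    times = values["sampling_times_min"]
    if not isinstance(times, Sequence) or isinstance(times, str):
        raise PlateIOError(f"{path}: sampling times must be a list")
    return ExperimentGeometry(
        apical_volume_ul=float(values["apical_volume_ul"]),  # type: ignore[arg-type]
        basolateral_volume_ul=float(values["basolateral_volume_ul"]),  # type: ignore[arg-type]
        insert_area_cm2=float(values["insert_area_cm2"]),  # type: ignore[arg-type]
        sampling_times_min=tuple(float(t) for t in times),
    )


def _read_delimited(path: str | Path) -> pd.DataFrame:
    # sniff comma vs. tab on the header line; round_trip parsing keeps
    # write->read lossless at full float precision
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")


def read_timecourse_table(path: str | Path, geometry: ExperimentGeometry) -> StudyTable:
    """Read a long or wide measurement table into a :class:`StudyTable`.

    Long layout (canonical) needs columns ``well_id, role, compound,
    channel, time_min, baso_signal, stock_signal``; wide layout replaces
    ``time_min``/``baso_signal`` with one ``baso_t<time>`` column per
    sampling time.  Replicate rows are averaged (arithmetic mean, no
    outlier rejection) with raw values kept on the series.
    """
    df = _read_delimited(path)
    if "time_min" in df.columns:
        return _assemble_long(df, geometry, str(path))
    return _assemble_wide(df, geometry, str(path))


_META_DEFAULTS = {"inhibitor": "none", "treatment": "n/a"}


def _series_meta(sub: pd.DataFrame, name: str, origin: str) -> dict[str, str]:
    meta = {}
    for col in ("role", "channel", "inhibitor", "treatment"):
        if col in sub.columns:
            vals = sub[col].dropna().unique()
            if len(vals) > 1:
                raise PlateIOError(f"{origin}: inconsistent {col} for series {name}: {list(vals)}")
            meta[col] = str(vals[0]) if len(vals) else _META_DEFAULTS.get(col, "")
        else:
            meta[col] = _META_DEFAULTS.get(col, "")
    if not meta.get("role"):
        raise PlateIOError(f"{origin}: missing role for series {name}")
    if not meta.get("channel"):
        raise PlateIOError(f"{origin}: missing channel for series {name}")
    return meta


def _assemble_long(df: pd.DataFrame, geometry: ExperimentGeometry, origin: str) -> StudyTable:
    required = {"well_id", "role", "compound", "channel", "time_min", "baso_signal", "stock_signal"}
    missing = required - set(df.columns)
    if missing:
        raise PlateIOError(f"{origin}: missing columns {sorted(missing)}")
    if (df["baso_signal"] < 0).any():
        bad = df.loc[df["baso_signal"] < 0, "well_id"].iloc[0]
        raise PlateIOError(f"{origin}: negative basolateral signal for well {bad}")
    times = geometry.sampling_times_min
    wells: list[WellSeries] = []
    for (well_id, compound), sub in df.groupby(["well_id", "compound"], sort=True):
        name = f"{well_id}/{compound}"
        meta = _series_meta(sub, name, origin)
        reps: dict[float, list[float]] = {}
        for t, tsub in sub.groupby("time_min"):
            reps[float(t)] = [float(v) for v in tsub["baso_signal"]]
        missing_t = [t for t in times if t not in reps]
        if missing_t:
            raise PlateIOError(f"{origin}: well {name} missing sampling times {missing_t}")
        extra_t = [t for t in reps if t not in times]
        if extra_t:
            raise PlateIOError(f"{origin}: well {name} has off-schedule times {extra_t}")
        baso = np.array([float(np.mean(reps[t])) for t in times])
        # stock/apical values repeat on every row of a series; distinct
        # readings are replicates to average, repeats are counted once
        stock_reps = [float(v) for v in pd.unique(sub["stock_signal"].dropna())]
        apical = None
        if "apical_end_signal" in sub.columns:
            vals = pd.unique(sub["apical_end_signal"].dropna())
            if len(vals):
                apical = float(np.mean(vals))
        wells.append(
            WellSeries(
                well_id=str(well_id),
                role=meta["role"],
                compound=str(compound),
                channel=meta["channel"],
                inhibitor=meta["inhibitor"] or "none",
                treatment=meta["treatment"] or "n/a",
                baso_signal=baso,
                stock_signal=float(np.mean(stock_reps)),
                apical_end_signal=apical,
                baso_replicates=reps,
                stock_replicates=stock_reps,
            )
        )
    return StudyTable(geometry=geometry, wells=wells)


def _assemble_wide(df: pd.DataFrame, geometry: ExperimentGeometry, origin: str) -> StudyTable:
    times = geometry.sampling_times_min
    time_cols = [f"baso_t{t:g}" for t in times]
    required = {"well_id", "role", "compound", "channel", "stock_signal", *time_cols}
    missing = required - set(df.columns)
    if missing:
        raise PlateIOError(f"{origin}: missing columns {sorted(missing)}")
    long_rows = df.melt(
        id_vars=[c for c in df.columns if c not in time_cols],
        value_vars=time_cols,
        var_name="time_min",
        value_name="baso_signal",
    )
    long_rows["time_min"] = long_rows["time_min"].str.removeprefix("baso_t").astype(float)
    return _assemble_long(long_rows, geometry, origin)


def write_study_table(table: StudyTable, path: str | Path) -> None:
    """Write a StudyTable as a canonical long CSV (round-trips exactly).

    When a series retains raw basolateral replicates, one row per
    replicate is written (with a ``replicate`` index); re-reading the
    file averages them back to the identical per-interval signals.
    """
    rows = []
    for w in table.wells:
        meta = {
            "well_id": w.well_id,
            "role": w.role,
            "compound": w.compound,
            "inhibitor": w.inhibitor,
            "treatment": w.treatment,
            "channel": w.channel,
            "stock_signal": repr(float(w.stock_signal)),
            "apical_end_signal": (
                repr(float(w.apical_end_signal)) if w.apical_end_signal is not None else ""
            ),
        }
        for t in table.geometry.sampling_times_min:
            reps = (
                w.baso_replicates.get(t)
                if w.baso_replicates is not None
                else None
            )
            if reps:
                for j, v in enumerate(reps):
                    rows.append(
                        {**meta, "time_min": t, "replicate": j + 1, "baso_signal": repr(float(v))}
                    )
            else:
                sig = w.baso_signal[list(table.geometry.sampling_times_min).index(t)]
                rows.append({**meta, "time_min": t, "replicate": 1, "baso_signal": repr(float(sig))})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_results_table(results: pd.DataFrame | "object", path: str | Path) -> None:
    """Write per-well and per-group results as one CSV.

    Accepts either a plain per-well DataFrame or a
    :class:`~mucoperm.permeability_core.StudyResult`; in the latter case
    group rows (mean, SD, SEM, n) are appended below the well rows,
    distinguished by a ``row_type`` column.  Units are embedded in the
    column names (``_ul_min``: µL/min, ``_um_min``: µm/min,
    ``_nmol_mm2``: nmol/mm²).
    """
    wells = getattr(results, "wells", results)
    groups = getattr(results, "groups", None)
    if not isinstance(wells, pd.DataFrame):
        raise PlateIOError("results must be a DataFrame or StudyResult")
    wells = wells.copy()
    wells.insert(0, "row_type", "well")
    frames = [wells]
    if groups is not None and len(groups):
        g = groups.copy()
        g.insert(0, "row_type", "group")
        frames.append(g)
    out = pd.concat(frames, ignore_index=True, sort=False) if len(frames) > 1 else frames[0]
    out.to_csv(path, index=False)
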