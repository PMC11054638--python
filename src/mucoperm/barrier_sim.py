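"""Protocol-faithful two-compartment transport simulator.

Generates synthetic Transwell study tables with known ground truth for
pipeline validation.  The physical model is passive exchange between a
well-stirred apical (donor) and basolateral (receiver) compartment::

    dCa/dt = -(PS_all/V_a) (Ca - Cb)
    dCb/dt = +(PS_all/V_b) (Ca - Cb)

solved in closed form per sampling interval; at every sampling the
receiver is replaced with fresh medium (Cb reset to 0) exactly as in the
wet protocol, and the removed amount is booked so mass is conserved to
floating-point precision.

The cell layer and the bare membrane act as series resistances
(1/PS_all = 1/PS_cell + 1/PS_blank); blank inserts use PS_blank alone.
Carrier-mediated transport is a linear PS term switched off by an
inhibitor (one donor concentration is simulated, so no saturable
kinetics), and cytokine-driven barrier opening is a multiplier on the
passive paracellular term for inflamed wells.  Measurement noise is
multiplicative Gaussian on the emitted signals (CV scales with signal,
as plate-reader/HPLC error does), truncated at zero.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .plate_io import ExperimentGeometry, StudyTable, WellSeries

#: inflammation arm labels whose wells get the paracellular multiplier
INFLAMED_TREATMENTS = ("INF", "INF+Ibu")

#: default signal yield per µM of analyte, by detection channel
DEFAULT_SIGNAL_PER_UM = {"RFU": 100.0, "mAU_min": 10.0}

#: replicate readings per sample, as in the wet protocol (basolateral,
#: stock and blank solutions in triplicate, apical samples in duplicate)
BASO_REPLICATES = 3
STOCK_REPLICATES = 3
APICAL_REPLICATES = 2


def series_ps(ps_cell_effective: float, ps_blank: float) -> float:
    """Compose cell-layer and blank-membrane PS as series resistances.

    1/PS_all = 1/PS_cell + 1/PS_blank — the composition direction of the
    blank correction, so ``correct_blank(series_ps(a, b), b) == a``.
    """
    if ps_cell_effective <= 0 or ps_blank <= 0:
        raise ValueError("PS values must be positive")
    return 1.0 / (1.0 / ps_cell_effective + 1.0 / ps_blank)


def simulate_interval(
    ca0: float,
    cb0: float,
    ps_all: float,
    geometry: ExperimentGeometry,
    dt_min: float,
) -> tuple[float, float]:
    """Exact closed-form concentrations after one interval of length ``dt_min``.

    Both compartments relax exponentially toward the common equilibrium
    concentration (Ca0·V_a + Cb0·V_b)/(V_a + V_b) with rate
    k = PS_all·(1/V_a + 1/V_b).
    """
    if dt_min <= 0:
        raise ValueError("interval length must be positive")
    if ps_all < 0:
        raise ValueError("PS_all must be non-negative")
    if ps_all == 0:
        return ca0, cb0
    va, vb = geometry.apical_volume_ul, geometry.basolateral_volume_ul
    ceq = (ca0 * va + cb0 * vb) / (va + vb)
    decay = math.exp(-ps_all * (1.0 / va + 1.0 / vb) * dt_min)
    return ceq + (ca0 - ceq) * decay, ceq + (cb0 - ceq) * decay


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth transport and noise parameters for one well group.

    Attributes
    ----------
    ps_cell_passive : float
        Passive (paracellular + transcellular) cell-layer PS, µL/min.
    ps_blank : float
        Bare-membrane PS, µL/min.
    ps_active : float
        Carrier-mediated net apical→basolateral PS term, µL/min; negative
        values model efflux that reduces net absorptive transport.
    inhibitor_efficacy : float
        Fraction of ``ps_active`` abolished when an inhibitor is present
        (0–1).
    donor_concentration_um : float
        Applied apical concentration, µM (protocol: 100 µM analytes,
        10 µM carboxyfluorescein).
    noise_cv : float
        Coefficient of variation of the multiplicative measurement noise.
    signal_per_um : float or None
        Signal units emitted per µM; ``None`` picks the channel default.
    inflammation_scaler : float
        Multiplier on ``ps_cell_passive`` for wells in an inflamed
        treatment arm (cytokine-opened paracellular route; > 1 loosens).
    seed : int or None
        Fallback seed when no generator is passed to
        :func:`simulate_well`.
    """

    ps_cell_passive: float
    ps_blank: float
    ps_active: float = 0.0
    inhibitor_efficacy: float = 1.0
    donor_concentration_um: float = 100.0
    noise_cv: float = 0.03
    signal_per_um: float | None = None
    inflammation_scaler: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ps_cell_passive < 0 or self.ps_blank <= 0:
            raise ValueError("ps_cell_passive must be >= 0 and ps_blank > 0")
        if not 0.0 <= self.inhibitor_efficacy <= 1.0:
            raise ValueError("inhibitor_efficacy must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.donor_concentration_um <= 0:
            raise ValueError("donor concentration must be positive")

    def effective_ps_cell(self, inhibitor: str, treatment: str) -> float:
        """Cell-layer PS after inhibitor switch and inflammation scaling."""
        scale = self.inflammation_scaler if treatment in INFLAMED_TREATMENTS else 1.0
        active = self.ps_active
        if inhibitor != "none":
            active *= 1.0 - self.inhibitor_efficacy
        eff = scale * self.ps_cell_passive + active
        if eff <= 0:
            raise ValueError("effective cell PS must be positive")
        return eff


@dataclass
class SimulatedWell:
    """One simulated insert series: noiseless state, emitted data, truth."""

    series: WellSeries
    sampling_times_min: tuple[float, ...]
    donor_um: np.ndarray          # apical concentration at each sampling time
    receiver_um: np.ndarray       # receiver concentration just before replacement
    removed_amount_nmol: np.ndarray  # cumulative amount removed by sampling
    true_ps_all: float
    true_ps_cell: float | None    # None for blank inserts
    true_papp_um_min: float | None
    initial_amount_nmol: float
    geometry: ExperimentGeometry

    def mass_balance_error(self) -> float:
        """Max relative deviation of donor+receiver+removed from the initial amount.

        The receiver is empty right after each sampling, so the balance at
        sampling n is donor·V_a + removed(≤n); exact for the closed-form
        propagator up to float rounding.
        """
        va = self.geometry.apical_volume_ul
        totals = self.donor_um * va * 1e-3 + self.removed_amount_nmol
        return float(np.max(np.abs(totals - self.initial_amount_nmol)) / self.initial_amount_nmol)


def simulate_well(
    params: SimulationParams,
    geometry: ExperimentGeometry,
    *,
    well_id: str,
    role: str,
    compound: str,
    channel: str,
    inhibitor: str = "none",
    treatment: str = "n/a",
    rng: np.random.Generator | None = None,
) -> SimulatedWell:
    """Simulate one insert over the sampling schedule and emit its WellSeries.

    Blank inserts transport through the bare membrane alone
    (PS_all = ps_blank); cells inserts compose the effective cell-layer
    PS with the membrane in series.  The receiver is reset to zero
    concentration at every sampling time and the removed amount is
    accumulated for the mass balance.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if role == "blank":
        ps_cell: float | None = None
        ps_all = params.ps_blank
    else:
        ps_cell = params.effective_ps_cell(inhibitor, treatment)
        ps_all = series_ps(ps_cell, params.ps_blank)

    times = geometry.sampling_times_min
    vb = geometry.basolateral_volume_ul
    ca = params.donor_concentration_um
    donor, receiver, removed = [], [], []
    removed_total = 0.0
    prev_t = 0.0
    for t in times:
        ca, cb = simulate_interval(ca, 0.0, ps_all, geometry, t - prev_t)
        removed_total += cb * vb * 1e-3  # nmol taken out with the receiver medium
        donor.append(ca)
        receiver.append(cb)
        removed.append(removed_total)
        prev_t = t

    spc = params.signal_per_um if params.signal_per_um is not None else DEFAULT_SIGNAL_PER_UM[channel]

    def readings(x: float, n: int) -> list[float]:
        """n replicate plate-reader/HPLC readings of the same sample."""
        if params.noise_cv == 0:
            return [x] * n
        return [
            max(0.0, x * (1.0 + params.noise_cv * rng.standard_normal())) for _ in range(n)
        ]

    baso_reps = {
        t: readings(cb * spc, BASO_REPLICATES) for t, cb in zip(times, receiver)
    }
    stock_reps = readings(params.donor_concentration_um * spc, STOCK_REPLICATES)
    apical_reps = readings(donor[-1] * spc, APICAL_REPLICATES)
    series = WellSeries(
        well_id=well_id,
        role=role,
        compound=compound,
        channel=channel,
        inhibitor=inhibitor,
        treatment=treatment,
        baso_signal=np.array([float(np.mean(baso_reps[t])) for t in times]),
        stock_signal=float(np.mean(stock_reps)),
        apical_end_signal=float(np.mean(apical_reps)),
        baso_replicates=baso_reps,
        stock_replicates=stock_reps,
    )
    return SimulatedWell(
        series=series,
        sampling_times_min=times,
        donor_um=np.array(donor),
        receiver_um=np.array(receiver),
        removed_amount_nmol=np.array(removed),
        true_ps_all=ps_all,
        true_ps_cell=ps_cell,
        true_papp_um_min=(10.0 * ps_cell / geometry.insert_area_cm2 if ps_cell else None),
        initial_amount_nmol=params.donor_concentration_um * geometry.apical_volume_ul * 1e-3,
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# study designs


@dataclass(frozen=True)
class GroupSpec:
    """One replicate group: an analyte under one inhibitor/treatment arm.

    ``cf_params`` attaches a co-applied paracellular-marker series (CF,
    fluorescence channel) to every insert of the group, cells and blanks
    alike, mirroring the wet protocol where CF is dosed on each insert.
    """

    compound: str
    params: SimulationParams
    inhibitor: str = "none"
    treatment: str = "n/a"
    channel: str = "mAU_min"
    n_cells: int = 6
    n_blanks: int = 3
    cf_params: SimulationParams | None = None

    @property
    def arm_id(self) -> str:
        parts = [self.compound]
        if self.inhibitor != "none":
            parts.append(self.inhibitor[:4])
        if self.treatment != "n/a":
            parts.append(self.treatment.replace("+", ""))
        return "-".join(parts)


@dataclass(frozen=True)
class StudyDesign:
    """A full synthetic study: geometry plus a list of replicate groups."""

    groups: tuple[GroupSpec, ...]
    geometry: ExperimentGeometry = field(default_factory=ExperimentGeometry.default)
    name: str = "study"


def _series_rng(master_seed: int, well_id: str, compound: str) -> np.random.Generator:
    # per-series entropy keyed on stable ids: generation order cannot matter
    entropy = (master_seed, zlib.crc32(well_id.encode()), zlib.crc32(compound.encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def generate_study(design: StudyDesign, seed: int) -> tuple[StudyTable, pd.DataFrame]:
    """Simulate every insert of a design; return the StudyTable and truth table.

    Deterministic for a given (design, seed); each series draws from its
    own seeded stream keyed on (seed, well id, compound), so permuting
    the groups leaves every emitted value unchanged.  The truth table
    has one row per series with the configured PS values and Papp.
    """
    wells: list[WellSeries] = []
    truth_rows = []
    seen_ids: set[tuple[str, str]] = set()
    for grp in design.groups:
        roles = [("cells", i, grp.n_cells) for i in range(grp.n_cells)] + [
            ("blank", i, grp.n_blanks) for i in range(grp.n_blanks)
        ]
        for role, i, _n in roles:
            well_id = f"{grp.arm_id}-{'c' if role == 'cells' else 'b'}{i + 1}"
            layers = [(grp.compound, grp.channel, grp.params)]
            if grp.cf_params is not None and grp.compound != "CF":
                layers.append(("CF", "RFU", grp.cf_params))
            for compound, channel, params in layers:
                if (well_id, compound) in seen_ids:
                    raise ValueError(f"duplicate well id {well_id} for {compound}")
                seen_ids.add((well_id, compound))
                sim = simulate_well(
                    params,
                    design.geometry,
                    well_id=well_id,
                    role=role,
                    compound=compound,
                    channel=channel,
                    inhibitor=grp.inhibitor,
                    treatment=grp.treatment,
                    rng=_series_rng(seed, well_id, compound),
                )
                wells.append(sim.series)
                truth_rows.append(
                    {
                        "well_id": well_id,
                        "compound": compound,
                        "inhibitor": grp.inhibitor,
                        "treatment": grp.treatment,
                        "role": role,
                        "true_ps_blank_ul_min": params.ps_blank,
                        "true_ps_cell_ul_min": sim.true_ps_cell,
                        "true_ps_all_ul_min": sim.true_ps_all,
                        "true_papp_um_min": sim.true_papp_um_min,
                    }
                )
    return StudyTable(geometry=design.geometry, wells=wells), pd.DataFrame(truth_rows)


def ps_cell_from_papp(papp_um_min: float, insert_area_cm2: float) -> float:
    """Invert the Papp conversion: PS_cell = Papp · area / 10 (µL/min)."""
    return papp_um_min * insert_area_cm2 / 10.0


#: default group-mean Papp targets (µm/min) for the emulated oral-mucosa
#: barrier: paracellular marker CF, transcellular marker diazepam and four
#: NSAIDs, without inhibitor and under verapamil / probenecid
DEFAULT_PAPP_TARGETS: dict[tuple[str, str], float] = {
    ("CF", "none"): 4.63,
    ("diazepam", "none"): 11.90,
    ("celecoxib", "none"): 0.44,
    ("diclofenac", "none"): 3.64,
    ("ibuprofen", "none"): 5.77,
    ("piroxicam", "none"): 4.86,
    ("celecoxib", "verapamil"): 2.10,
    ("diclofenac", "verapamil"): 3.54,
    ("ibuprofen", "verapamil"): 7.13,
    ("piroxicam", "verapamil"): 6.00,
    ("celecoxib", "probenecid"): 12.74,
    ("diclofenac", "probenecid"): 6.66,
    ("ibuprofen", "probenecid"): 7.87,
    ("piroxicam", "probenecid"): 5.81,
}


def nsaid_transport_design(
    n_cells: int = 6,
    n_blanks: int = 3,
    noise_cv: float = 0.03,
    blank_multiple: float = 3.0,
    geometry: ExperimentGeometry | None = None,
    papp_targets: dict[tuple[str, str], float] | None = None,
) -> StudyDesign:
    """NSAID transport study: 4 NSAIDs × {none, verapamil, probenecid} + markers.

    True group Papp values come from ``papp_targets`` (defaults to
    :data:`DEFAULT_PAPP_TARGETS`); blank-membrane PS is set to
    ``blank_multiple`` × the arm's cell PS; CF (10 µM, fluorescence) is
    co-applied on every insert.
    """
    geometry = geometry or ExperimentGeometry.default()
    targets = papp_targets or DEFAULT_PAPP_TARGETS
    area = geometry.insert_area_cm2

    def params_for(papp_um: float, donor_um: float = 100.0) -> SimulationParams:
        ps_cell = ps_cell_from_papp(papp_um, area)
        return SimulationParams(
            ps_cell_passive=ps_cell,
            ps_blank=blank_multiple * ps_cell,
            donor_concentration_um=donor_um,
            noise_cv=noise_cv,
        )

    cf_params = params_for(targets[("CF", "none")], donor_um=10.0)
    groups = []
    for (compound, inhibitor), papp_um in targets.items():
        if compound == "CF":
            continue
        groups.append(
            GroupSpec(
                compound=compound,
                inhibitor=inhibitor,
                params=params_for(papp_um),
                n_cells=n_cells,
                n_blanks=n_blanks,
                cf_params=cf_params,
            )
        )
    # the marker CF is also analysed as a compound in its own arm
    groups.append(
        GroupSpec(
            compound="CF",
            channel="RFU",
            params=cf_params,
            n_cells=n_cells,
            n_blanks=n_blanks,
        )
    )
    return StudyDesign(groups=tuple(groups), geometry=geometry, name="nsaid-transport")


#: group-mean Papp targets (µm/min) for the 48 h cytokine-inflammation
#: study (control / INF cytokine mix / INF+ibuprofen / ibuprofen arms,
#: ibuprofen transport ± probenecid with CF co-applied)
DEFAULT_INFLAMMATION_TARGETS: dict[tuple[str, str, str], float] = {
    ("ibuprofen", "none", "control"): 14.38,
    ("ibuprofen", "none", "INF"): 20.01,
    ("ibuprofen", "none", "INF+Ibu"): 21.06,
    ("ibuprofen", "none", "Ibu"): 11.55,
    ("ibuprofen", "probenecid", "control"): 20.49,   # +42% over control
    ("ibuprofen", "probenecid", "INF"): 20.01,       # no further increase when inflamed
    ("ibuprofen", "probenecid", "INF+Ibu"): 21.06,
    ("ibuprofen", "probenecid", "Ibu"): 17.63,       # +53% over Ibu-alone
}

DEFAULT_INFLAMMATION_CF: dict[str, float] = {
    "control": 14.26,
    "INF": 24.30,
    "INF+Ibu": 25.04,
    "Ibu": 14.39,
}


def inflammation_design(
    n_cells: int = 4,
    n_blanks: int = 3,
    noise_cv: float = 0.03,
    blank_multiple: float = 3.0,
    geometry: ExperimentGeometry | None = None,
) -> StudyDesign:
    """Ibuprofen ± probenecid transport across control and inflamed layers.

    Inflamed arms carry loosened paracellular barriers (higher CF and
    ibuprofen Papp) and no probenecid-inhibitable gain, reflecting a
    transporter shift under cytokine exposure.
    """
    geometry = geometry or ExperimentGeometry.default()
    area = geometry.insert_area_cm2

    def params_for(papp_um: float, donor_um: float = 100.0) -> SimulationParams:
        ps_cell = ps_cell_from_papp(papp_um, area)
        return SimulationParams(
            ps_cell_passive=ps_cell,
            ps_blank=blank_multiple * ps_cell,
            donor_concentration_um=donor_um,
            noise_cv=noise_cv,
        )

    groups = []
    for (compound, inhibitor, treatment), papp_um in DEFAULT_INFLAMMATION_TARGETS.items():
        groups.append(
            GroupSpec(
                compound=compound,
                inhibitor=inhibitor,
                treatment=treatment,
                params=params_for(papp_um),
                n_cells=n_cells,
                n_blanks=n_blanks,
                cf_params=params_for(DEFAULT_INFLAMMATION_CF[treatment], donor_um=10.0),
            )
        )
    return StudyDesign(groups=tuple(groups), geometry=geometry, name="inflammation-transport")
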