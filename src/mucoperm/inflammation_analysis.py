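"""Barrier-integrity filtering, relative expression and group statistics.

Covers the readouts accompanying inflammation transport studies:
area-corrected TEER with a minimum-TEER inclusion filter, qPCR relative
expression (2^-ΔCt against a reference gene, normalized to a reference
treatment group) and one-/two-way ANOVA with step-down Holm–Šidák
post-hoc comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols


# ---------------------------------------------------------------------------
# TEER


def teer_area_corrected(raw_ohm: float, blank_ohm: float, area_cm2: float) -> float:
    """Blank-subtracted, area-corrected TEER: (raw − blank insert) × area, Ω·cm².

    Negative results (raw below the blank insert resistance) are
    returned as-is; records carrying them are flagged, not silently
    clipped.
    """
    if area_cm2 <= 0:
        raise ValueError("area must be positive")
    return (raw_ohm - blank_ohm) * area_cm2


@dataclass
class TeerRecord:
    """One TEER reading on one insert at one timepoint."""

    well_id: str
    treatment: str
    raw_ohm: float
    blank_ohm: float
    area_cm2: float
    timepoint: str = "start"  # "start" or "48h"

    @property
    def teer_ohm_cm2(self) -> float:
        return teer_area_corrected(self.raw_ohm, self.blank_ohm, self.area_cm2)

    @property
    def negative(self) -> bool:
        return self.teer_ohm_cm2 < 0


def filter_teer_threshold(
    records: Iterable[TeerRecord],
    threshold_ohm_cm2: float = 100.0,
) -> tuple[list[TeerRecord], list[TeerRecord]]:
    """Split records into (included, excluded) by start-timepoint TEER.

    An insert is included when its start TEER is at least the threshold
    (boundary inclusive: exactly 100 Ω·cm² passes the default filter).
    Records at other timepoints follow their insert's start reading.
    """
    records = list(records)
    start_teer = {
        r.well_id: r.teer_ohm_cm2 for r in records if r.timepoint == "start"
    }
    included, excluded = [], []
    for r in records:
        if r.well_id not in start_teer:
            raise ValueError(f"no start-timepoint TEER for well {r.well_id}")
        (included if start_teer[r.well_id] >= threshold_ohm_cm2 else excluded).append(r)
    return included, excluded


# ---------------------------------------------------------------------------
# qPCR relative expression


@dataclass(frozen=True)
class QpcrSample:
    """Paired target/reference Ct values for one sample and one target."""

    sample_id: str
    target: str
    ct_target: float
    ct_reference: float
    treatment: str

    def __post_init__(self) -> None:
        for name, ct in (("target", self.ct_target), ("reference", self.ct_reference)):
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError(f"sample {self.sample_id}: Ct {name} must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference

    @property
    def expression(self) -> float:
        """2^-ΔCt relative to the reference gene."""
        return 2.0 ** (-self.delta_ct)


def relative_expression(
    samples: Iterable[QpcrSample],
    reference_group: str = "INF",
) -> pd.DataFrame:
    """2^-ΔCt per sample, normalized per target to the reference-group mean.

    Returns one row per sample with ``expression`` (2^-ΔCt) and
    ``rel_expression`` (expression divided by the mean expression of
    ``reference_group`` samples for the same target); the reference
    group therefore averages to exactly 1 per target.
    """
    rows = [
        {
            "sample_id": s.sample_id,
            "target": s.target,
            "treatment": s.treatment,
            "delta_ct": s.delta_ct,
            "expression": s.expression,
        }
        for s in samples
    ]
    if not rows:
        return pd.DataFrame(
            columns=["sample_id", "target", "treatment", "delta_ct", "expression", "rel_expression"]
        )
    df = pd.DataFrame(rows)
    ref_means = df[df.treatment == reference_group].groupby("target").expression.mean()
    missing = sorted(set(df.target) - set(ref_means.index))
    if missing:
        raise ValueError(f"no {reference_group!r} samples for targets {missing}")
    df["rel_expression"] = df.expression / df.target.map(ref_means)
    return df


# ---------------------------------------------------------------------------
# Holm–Šidák and ANOVA


@dataclass(frozen=True)
class HolmSidakResult:
    p_adjusted: np.ndarray
    reject: np.ndarray
    alpha: float


def holm_sidak(p_values: Sequence[float], alpha: float = 0.05) -> HolmSidakResult:
    """Step-down Holm–Šidák multiple-comparison adjustment.

    Sorted ascending, the i-th smallest of m p-values is adjusted to
    1 − (1 − p_(i))^(m − i + 1), made monotone non-decreasing along the
    ranks, and hypotheses are rejected while the adjusted value stays at
    or below ``alpha``.  Results are returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    # step-down: stop rejecting at the first non-significant rank
    reject_sorted = np.zeros(m, dtype=bool)
    for i, a in enumerate(adj_sorted):
        if a <= alpha:
            reject_sorted[i] = True
        else:
            break
    reject = np.empty(m, dtype=bool)
    reject[order] = reject_sorted
    return HolmSidakResult(p_adjusted=adjusted, reject=reject, alpha=alpha)


def significance_stars(p: float) -> str:
    """SigmaPlot-style star mapping: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AnovaResult:
    """Fixed-effects ANOVA table plus Holm–Šidák pairwise comparisons."""

    table: pd.DataFrame
    pairwise: pd.DataFrame
    design: str
    alpha: float

    def summary(self) -> str:
        lines = [f"{self.design} ANOVA (alpha={self.alpha:g})", self.table.to_string()]
        if len(self.pairwise):
            lines += ["", "Holm-Sidak pairwise comparisons:", self.pairwise.to_string(index=False)]
        return "\n".join(lines)


def group_anova(
    data: pd.DataFrame,
    value: str,
    factors: Sequence[str],
    design: Literal["one_way", "two_way"] | None = None,
    alpha: float = 0.05,
) -> AnovaResult:
    """Fixed-effects ANOVA with Holm–Šidák post-hoc pairwise tests.

    ``factors`` names one (one-way) or two (two-way, with interaction)
    categorical columns of ``data``.  The comparison family is all
    pairwise contrasts between the (combined) factor-level groups —
    i.e. every pair of bars in one figure panel — tested with pooled
    residual-variance t statistics and adjusted together.
    """
    factors = list(factors)
    if design is None:
        design = "one_way" if len(factors) == 1 else "two_way"
    if (design == "one_way") != (len(factors) == 1):
        raise ValueError(f"{design} ANOVA needs {'one factor' if design == 'one_way' else 'two factors'}")
    df = data[[value, *factors]].dropna().copy()
    for f in factors:
        df[f] = df[f].astype(str)
    cell = df[factors].agg(" & ".join, axis=1)
    counts = cell.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than two values: {bad}")

    terms = " * ".join(f"C(Q('{f}'))" for f in factors)
    model = ols(f"Q('{value}') ~ {terms}", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    mse = model.mse_resid
    dof = model.df_resid
    means = df.groupby(cell)[value].mean()
    ns = df.groupby(cell)[value].count()
    pairs = list(itertools.combinations(sorted(means.index), 2))
    raw_p, trows = [], []
    for g1, g2 in pairs:
        se = np.sqrt(mse * (1.0 / ns[g1] + 1.0 / ns[g2]))
        t = (means[g1] - means[g2]) / se if se > 0 else np.inf
        p = 2.0 * sps.t.sf(abs(t), dof)
        raw_p.append(p)
        trows.append({"group1": g1, "group2": g2, "diff": means[g1] - means[g2], "t": t, "p_raw": p})
    if trows:
        hs = holm_sidak(raw_p, alpha=alpha)
        pairwise = pd.DataFrame(trows)
        pairwise["p_adj"] = hs.p_adjusted
        pairwise["reject"] = hs.reject
        pairwise["stars"] = [significance_stars(p) if r else "" for p, r in zip(hs.p_adjusted, hs.reject)]
    else:
        pairwise = pd.DataFrame(
            columns=["group1", "group2", "diff", "t", "p_raw", "p_adj", "reject", "stars"]
        )
    return AnovaResult(table=table, pairwise=pairwise, design=design, alpha=alpha)


def read_teer_table(path, area_cm2: float | None = None) -> list[TeerRecord]:
    """Read TEER records from CSV.

    Needs ``well_id, treatment, raw_ohm, timepoint`` plus either a
    ``teer_ohm_cm2`` column (already corrected; blank/area backed out as
    identity) or ``blank_ohm`` and ``area_cm2`` columns (or a shared
    ``area_cm2`` argument) for correction here.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    records = []
    for r in df.itertuples():
        if hasattr(r, "teer_ohm_cm2") and not pd.isna(r.teer_ohm_cm2):
            records.append(
                TeerRecord(
                    well_id=str(r.well_id),
                    treatment=str(r.treatment),
                    raw_ohm=float(r.teer_ohm_cm2),
                    blank_ohm=0.0,
                    area_cm2=1.0,
                    timepoint=str(getattr(r, "timepoint", "start")),
                )
            )
            continue
        area = float(getattr(r, "area_cm2", area_cm2 or np.nan))
        if not np.isfinite(area):
            raise ValueError(f"no insert area for TEER record {r.well_id}")
        records.append(
            TeerRecord(
                well_id=str(r.well_id),
                treatment=str(r.treatment),
                raw_ohm=float(r.raw_ohm),
                blank_ohm=float(getattr(r, "blank_ohm", 0.0)),
                area_cm2=area,
                timepoint=str(getattr(r, "timepoint", "start")),
            )
        )
    return records


def read_qpcr_table(path) -> list[QpcrSample]:
    """Read qPCR Ct pairs from CSV with columns
    ``sample_id, target, ct_target, ct_reference, treatment``."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"sample_id", "target", "ct_target", "ct_reference", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        QpcrSample(
            sample_id=str(r.sample_id),
            target=str(r.target),
            ct_target=float(r.ct_target),
            ct_reference=float(r.ct_reference),
            treatment=str(r.treatment),
        )
        for r in df.itertuples()
    ]
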