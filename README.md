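# mucoperm

Clearance-based permeability analysis for Transwell barrier experiments,
built around the assay design used for drug transport across epithelial
in vitro models such as the TR146 oral-mucosa (buccal) barrier: small
molecules (e.g. NSAIDs) are applied apically, the basolateral medium is
collected and fully replaced at fixed intervals, and the analyte signal
in each collected receiver volume (fluorescence for carboxyfluorescein,
HPLC peak area for drugs) is turned into an apparent permeability
coefficient.

It is aimed at people running or re-analysing insert-based transport
assays — permeability screens with efflux-transporter inhibitors
(verapamil, probenecid), barrier-integrity (TEER) monitoring, and
cytokine-inflammation studies with qPCR readouts — who want the whole
calculation chain scripted, validated and reproducible.

## Method

For each sampling interval `n` (fresh receiver each time), the cleared
donor-equivalent volume is

```
clearance_n [µL] = A_baso,tn · V_baso / A_stock
```

with `A_baso,tn` the receiver signal, `V_baso` the basolateral volume
and `A_stock` the applied stock signal.  Cumulative cleared volume is
regressed on time (ordinary least squares, free intercept, the origin
included); the slope is the permeability–surface-area product
`PS [µL/min]`.  The cell layer is isolated from the bare insert
membrane as resistances in series,

```
1/PS_cell = 1/PS_all − 1/PS_blank
```

with `PS_blank` the mean fitted slope of matched blank (membrane-only)
inserts, and converted to the apparent permeability coefficient

```
Papp [µm/min] = 10 · PS_cell / A    (A = insert area in cm²)
```

Downstream operations: per-insert normalization to the co-applied
paracellular marker carboxyfluorescein, inhibitor fold-changes from
group means, cumulated basolateral amounts (nmol/mm²), TEER filtering
with a minimum-start-TEER inclusion threshold, relative expression
(2^−ΔCt against a reference gene, normalized to a reference treatment
group), and one-/two-way ANOVA with step-down Holm–Šidák post-hoc
comparisons.

A two-compartment simulator (`mucoperm.barrier_sim`) generates
protocol-faithful synthetic studies — exact interval-wise solution of
the donor/receiver exchange ODEs, receiver replacement at every
sampling, series-resistance membrane composition, inhibitor-switchable
carrier terms, replicate-structured multiplicative measurement noise —
with a ground-truth table, so the whole pipeline is testable end to end
without wet-lab data.  See `docs/methods.md` for the model, parameter
defaults and known limitations.

## Worked example

```python
from mucoperm import (
    ExperimentGeometry, interval_clearance, fit_ps, correct_blank, papp,
)
from mucoperm.plate_io import WellSeries

geom = ExperimentGeometry.default()          # 300/900 µL, 0.336 cm², hourly x4

cells = WellSeries(
    well_id="ibu-c1", role="cells", compound="ibuprofen", channel="mAU_min",
    baso_signal=[11.5, 11.1, 10.8, 10.4], stock_signal=1000.0,
)
blank = WellSeries(
    well_id="ibu-b1", role="blank", compound="ibuprofen", channel="mAU_min",
    baso_signal=[36.9, 33.9, 31.2, 28.7], stock_signal=1000.0,
)

ps_all = fit_ps(interval_clearance(cells, geom)).ps_ul_min
ps_blank = fit_ps(interval_clearance(blank, geom)).ps_ul_min
ps_cell = correct_blank(ps_all, ps_blank)
print(f"PS_all   = {ps_all:.4f} uL/min")
print(f"PS_blank = {ps_blank:.4f} uL/min")
print(f"PS_cell  = {ps_cell:.4f} uL/min")
print(f"Papp     = {papp(ps_cell, geom.insert_area_cm2):.2f} um/min")
```

prints

```
PS_all   = 0.1643 uL/min
PS_blank = 0.4898 uL/min
PS_cell  = 0.2471 uL/min
Papp     = 7.36 um/min
```

The cell-plus-membrane insert clears 0.164 µL of donor per minute; the
bare membrane alone clears 0.490 µL/min, so after removing the membrane
contribution the cell layer passes ibuprofen at 7.36 µm/min.

The same pipeline runs from the shell on whole studies:

```
mucoperm simulate --seed 11 --out sim/          # synthetic study + truth table
mucoperm permeability --table sim/timecourse.csv --config sim/geometry.yaml --out run/
mucoperm report --seed 11 --out report/         # end-to-end with recovery vs truth
```

`run/results.csv` holds one row per insert and one per replicate group
(mean, SD, SEM, n, units in the column names); `summary.md` is a short
human-readable report.

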