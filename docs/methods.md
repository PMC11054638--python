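# Methods

## The assay and its model

The package analyses interval-sampled Transwell transport experiments.
An insert with (or without) a cell layer separates an apical donor
compartment (default 300 µL) from a basolateral receiver (default
900 µL, insert area 0.336 cm²).  The analyte is applied apically; every
60 min for 4 h the insert is moved to fresh receiver medium and the
collected receiver volume is measured (fluorescence or HPLC peak area).
Because the receiver is emptied every hour it stays near sink
conditions, and the hourly receiver signal is proportional to the
donor-equivalent volume cleared across the barrier in that interval.

Both compartments are treated as well stirred, transport as linear in
the concentration difference:

    dCa/dt = −(PS/V_a)(Ca − Cb),   dCb/dt = +(PS/V_b)(Ca − Cb)

with a single permeability–surface-area product PS (µL/min).  The cell
layer and the supporting membrane are resistances in series
(1/PS_all = 1/PS_cell + 1/PS_blank), which is why every cells group
needs a matched blank group: the analysis inverts that relation using
the mean fitted blank slope per (compound × inhibitor × treatment)
group.  Compound-specific blanks matter — membranes interact with
compounds to different degrees, so a shared generic blank would bias
PS_cell compound-dependently.

Papp = 10 · PS_cell / A converts to µm/min (1 µL·min⁻¹·cm⁻² =
10⁻³ cm/min = 10 µm/min); the factor is dimensional, not empirical.

## Clearance modes

The clearance of interval n is referenced to the applied stock signal:
clearance_n = A_baso,tn · V_baso / A_stock.  Historical spreadsheets
additionally subtract a running correction term for later timepoints
whose printed form is ambiguous; the package exposes three modes:

- `per_interval` (default): no cross-interval correction.  Each
  interval's receiver starts fresh, so its signal already reflects only
  that interval's transfer.  This is the physically consistent reading.
- `literal`: subtracts Σ_{i<n}(A_i·f − A_1·f) (f = basolateral/apical
  volume factor, 3 for the default geometry) from later intervals,
  reproducing the legacy spreadsheet expression verbatim for
  comparison.  With an ideally linear time course A_i ≈ A_1 the
  correction vanishes, which is why the two modes agree closely on
  clean data; on noisy data the correction term only adds variance.
- `donor_corrected`: references interval n to the mass-balance-depleted
  donor signal A_stock − f·Σ_{i<n} A_i.  This removes the
  donor-depletion bias of the uncorrected modes and is the right choice
  for fast permeants.

Two biases are inherent to the uncorrected clearance method and are
quantified by the simulator rather than hidden: (i) donor depletion
makes later intervals under-read (grows with PS; ~20 % total depletion
for Papp ≈ 12 µm/min under the default geometry), and (ii) within one
interval the receiver accumulates and back-pressure lowers the average
gradient, an O(k·Δt/2) deficit with k = PS·(1/V_a + 1/V_b).  In the
blank-corrected end point the two uncorrected slopes (cells and blank)
are biased in the same direction and the series-resistance subtraction
cancels most of it: over the default study grid the noise-free Papp
error stays ≈ 2 % even where single-slope errors reach tens of percent.

## Slope fit and flags

Cumulative cleared volume is regressed on time by ordinary least
squares with a free intercept, with (0, 0) included as a data point (at
t = 0 nothing has been cleared by construction).  The reciprocal 1/PS
is what enters the blank correction.  Wells with non-positive fitted
slopes are flagged `excluded`; cells wells whose PS_all reaches the
blank PS are flagged `blank_dominated` (adding a cell layer cannot
reduce resistance, so such wells are noise artifacts).  Flagged wells
are dropped from group means and counted per group, so reported n is
always the n actually averaged.

CF normalization defaults to per-insert pairing (the paracellular
marker is co-applied on every insert), which is not the same number as
the ratio of group means whenever the per-insert values are correlated;
a `group_mean` mode is provided for comparison with tabulated means.

## The simulator

`barrier_sim` emulates the wet protocol exactly: interval-wise
closed-form solution of the two-compartment ODEs (both compartments
relax exponentially to the volume-weighted equilibrium), receiver reset
to zero at each sampling with the removed amount booked (mass balance
holds to float rounding, asserted at 1e-9), apical volume constant,
apical sampling at the end only.  A numerical ODE integrator is used in
the tests as an independent oracle, never in the simulator itself.

Ground truth per well: effective cell PS =
inflammation_scaler(treatment) × ps_cell_passive + ps_active × (1 −
inhibitor_efficacy · [inhibitor present]); blanks use ps_blank alone.
The carrier term is linear, not Michaelis–Menten: only one donor
concentration (100 µM; CF 10 µM) is in scope, so saturation is not
identifiable and a saturable variant would add parameters the data
cannot constrain.  Negative `ps_active` models efflux that reduces net
absorptive transport and is abolished by the inhibitor.

Noise is multiplicative Gaussian (SD = CV × signal, truncated at zero),
because plate-reader and HPLC errors scale with signal, and is applied
per reading with the protocol's replicate structure: triplicate
basolateral and stock readings, duplicate apical readings, averaged on
ingest exactly as the plate-IO layer averages real exports.  The
default CV of 3 % per reading is a stand-in chosen as typical for
fluorescence/HPLC repeatability (no replicate CVs are published for
this assay) and is configurable.

Default study designs: the NSAID transport design (celecoxib,
diclofenac, ibuprofen, piroxicam × {none, verapamil, probenecid}, plus
diazepam and CF marker arms; 6 cells + 3 blank inserts per group) uses
the published group-mean Papp values as ground truth with blank PS set
to 3× the cell PS — blank clearance curves sit well above cell curves
for these compounds, and 3× reproduces that separation.  The
inflammation design carries control / cytokine (INF) / INF+ibuprofen /
ibuprofen arms with loosened paracellular transport in the inflamed
arms and no probenecid-inhibitable gain under inflammation.

What the simulator does **not** emulate: unstirred water layers,
membrane partitioning/retention (binding of lipophilic compounds to the
insert), pH-partition effects, evaporation, intra-well heterogeneity,
or drift in barrier tightness over the 4 h run.  Passing recovery tests
therefore shows the *calculation chain* is unbiased under the stated
transport model, not that the model captures every feature of real
inserts.

## Statistics

TEER is blank-subtracted then area-corrected ((raw − blank insert) ×
area, Ω·cm²); negative values are flagged, not clipped.  The inclusion
filter keeps inserts whose start TEER is at least the threshold
(default 100 Ω·cm², boundary inclusive) and carries the decision to all
timepoints of that insert.

Relative expression is 2^(−(Ct_target − Ct_reference)) per sample,
normalized per target to the mean of the reference treatment group
(default INF), so the reference group averages to exactly 1 by
construction.

Holm–Šidák is the step-down adjustment: with m p-values sorted
ascending, adjusted_i = 1 − (1 − p_(i))^(m − i + 1), made monotone
non-decreasing along the ranks; rejection stops at the first
non-significant rank.  It is implemented in-package (and cross-checked
against an independent implementation in the tests).  ANOVA is the
classical fixed-effects decomposition (one-way, or two-way with
interaction) via an OLS fit; post-hoc pairwise comparisons use pooled
residual-variance t statistics over all pairs of (combined) factor
levels — the set of bars in one figure panel — adjusted together.

## Numerical and design choices

- Replicate averaging is the arithmetic mean with no outlier rejection;
  distinct stock readings on a series are replicates, repeated
  identical values are counted once.
- Table IO is delimiter-sniffing CSV/TSV with round-trip float parsing,
  so write-then-read reproduces signals bit-exactly.
- The volume factor is always derived from the configured volumes,
  never read from a file.
- Per-series random streams are keyed on (seed, well id, compound), so
  generation order cannot change emitted values and equal seeds give
  byte-identical tables.
- Degenerate inputs: zero stock signal, unsorted schedules, missing
  timepoints, missing blank groups and out-of-range p-values all raise
  descriptive errors naming the offending well/time; all-zero series
  yield PS = 0 and are flagged rather than erroring.

## Problem sizes

The validation suite runs the full NSAID design at 6 cells + 3 blank
inserts per group (the typical per-group insert count for this assay)
with 3 % noise, where recovered group-mean Papp values stay within 5 %
of truth and the compound ranking is stable; the noise-free sink-regime
grid (Papp 0.5–12 µm/min, blank 2–5× cell PS) recovers within 2 %
wherever total donor depletion stays below 10 %.  These sizes keep the
whole suite in the seconds range while matching the real study's group
sizes.
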