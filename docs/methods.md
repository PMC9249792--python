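# Methods

`picocell` re-implements, as a tested library, the quantitative analysis
chain used in single-cell studies of salt-stress adaptation with a cell
pressure probe (CPP) coupled to picolitre electrospray mass spectrometry,
together with TEM-based crista morphometrics and a time-derivative kinetics
procedure for ordering cellular events. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Cell water relations

The water potential of a cell is the sum of its turgor (hydrostatic) and
osmotic components, Ψ_w = Ψ_p + Ψ_s (MPa). Turgor is a gauge pressure and is
clamped non-negative: a negative Ψ_p input is a domain error, not a warning.
Osmotic pressure is π = −Ψ_s ≥ 0. For tissue data measured by psychrometry
and osmometry, turgor comes from the rearranged form Ψ_p = Ψ_w − Ψ_s.

The volumetric elastic modulus of the wall is ε = V·ΔP/ΔV from a pressure
pulse; ΔP and ΔV must share a sign (pressurizing swells the cell). Hydraulic
conductivity follows from the pressure-relaxation half-time,

    Lp = ln 2 · V / (A · T½ · (ε + π)),

with V in m³, A in m², T½ in s, ε and π in MPa, giving m s⁻¹ MPa⁻¹. π here
is the cell osmotic pressure (−Ψ_s), not the medium's. The algebraic inverse
`half_time_from_lp` is provided and the pair round-trips to 1e−9 relative
error by construction.

Pressure relaxations are simulated single-exponential,
P(t) = P_eq + (P₀ − P_eq)·2^(−t/T½); only the half-time is identifiable in
practice, so no richer functional form is warranted. `measure_half_time`
reads T½ back off a trace by linear interpolation of the gap to equilibrium
and recovers it to within one time-grid step.

The van't Hoff conversion between an osmotic-potential change and a solute
concentration change is c = ΔΨ_s·10⁶/(R·T) in mol m⁻³ ≡ mM, with
R = 8.314462 J mol⁻¹ K⁻¹ and T in kelvin (°C + 273.15). At the 28 °C growth
temperature, ΔΨ_s = 0.37 MPa gives 147.8 mM — the >147 mM bound on the
mitochondrial solute accumulation needed to drive water inflow.

Capillary sampling volume is calibrated by a user-supplied monotone
(distance, volume) table interpolated piecewise-linearly and anchored at
(0, 0); the working anchor is 500 μm ↔ 200 pL. Extrapolation beyond the
table is refused because tip taper geometry varies between capillaries.

## Ion chemistry and peak annotation

Negative-mode pressure-probe ESI spectra contain deprotonated [M − H]⁻,
chloride-adducted [M + Cl]⁻, doubly deprotonated [M − 2H]²⁻ and cluster
[M′ − H]⁻ species. Theoretical m/z uses standard monoisotopic atomic masses
(C 12 exactly, H 1.0078250319, O 15.9949146221, …), a proton mass of
1.007276 Da and ³⁵Cl only; the electron mass is neglected (< 0.5 ppm at
these masses, below the reporting precision). Cluster compositions add
element-wise.

Cardiolipin with total acyl composition n:d is assigned the composition
C(n+9) H(2n−2d+14) O17 P2 and detected as the dianion; this reproduces the
reported m/z 712 for CL(70:5). The same acyl bookkeeping drives the
decomposition of a cardiolipin into candidate phosphatidylglycerol pairs:
all unordered pairs whose carbons and double bonds sum to the cardiolipin's.
CL(70:4) against the detected PG pool {32:1, 34:1, 34:2, 36:2, 36:3} yields
exactly PG(34:1)+PG(36:3) and PG(34:2)+PG(36:2).

Annotation matches every peak against every (record, allowed ion mode) pair
of a bundled reference table at a relative tolerance of 5 ppm (the
identification rule of the source instrumentation). All hits within
tolerance are reported, sorted by |ppm error| — isobars are reported, not
resolved. The table deliberately contains an exact isobar pair (PC(31:2)
and PE(34:2) share C39H74NO8P) and a genuine near-isobar pair (the CL(74:7)
dianion lies 7.6 ppm from deprotonated PC(33:4)); identification precision
of 1.0 is therefore only guaranteed for reference sets whose ions are
mutually separated by more than five times the tolerance, and the property
suite checks it on such a subset. The limit of detection is 3× the baseline
noise, boundary inclusive.

Printed nominal m/z values truncate the decimal part; for the lipids, whose
monoisotopic ions sit at x.5, truncation and rounding differ and the
truncation convention is used when checking the table against reported
assignments.

## Crista morphometrics and streaming

Crista tortuosity is the arc-chord ratio of an open segmented contour
(polyline arc length over end-to-end distance, ≥ 1, equal to 1 only for
collinear points). Closed contours are rejected rather than reinterpreted —
a closed curve has no chord. The apex angle of an intracrista space is
measured at the two endpoints of its long diameter (the maximal-distance
boundary vertex pair): on each side of an endpoint, boundary vertices within
a window (default 10% of the long diameter) are fitted with a least-squares
direction anchored at the apex, and the angle between the two directions is
taken; the result is the mean over the two endpoints. Segmented polygons
with long straight edges should be densified (`densify_polygon`) so at
least one vertex falls inside the window on each side; too-sparse input is
an error.

Mitochondrial section volume uses a prolate-spheroid rule, (π/6)·L·W² from
the section's major and minor axes. The real measurement procedure behind
published volumes is not fully specified; the rule is isolated in one
function so an alternative stereological estimator can be swapped in.
Organelle censuses are reduced to percent-of-cell and percent-of-cytosol
(cytosol defaults to cell minus vacuole).

Streaming velocity is the vesicle path length over track duration (path
speed, not straight-line displacement speed). The circuit-time worked
example treats the central vacuole as a 298 × 37 μm rectangle: perimeter
2·(298+37) = 670 μm, and at 4.57 μm/s one round takes 670/4.57/60 = 2.44 min
(reported to two decimals). TEM geometry is in nm, light-microscopy geometry
in μm; conversions live at I/O, never inside the geometry operations.

## Time-derivative kinetics (ΔT_df)

Each cellular parameter is observed at 0, 0.5, 1, 3, 6 and 12 h after
treatment. The trajectory is interpolated with a shape-preserving monotone
piecewise cubic — chosen because overshoot would create spurious derivative
extrema — evaluated on a uniform grid (default step 0.01 h, fine enough to
represent two-decimal ΔT_df values), and differentiated by central
differences. The derivative is rescaled so that its largest absolute value
maps to +100% (a maximal increase) or −100% (a maximal decrease), preserving
sign; exactly one of ±100 is attained for any non-constant series. ΔT_df is
the earliest grid time at which ±100% is reached; ties break to the earliest
time, and constant series are flagged degenerate, never assigned 0.

Two numerical choices deserve emphasis.

*Boundary slopes.* The interior slopes are the standard monotone
(Fritsch–Carlson) estimates, but the two boundary slopes are replaced by
the one-sided secants. The default three-point endpoint rule can exceed the
first secant and place the global derivative maximum exactly at t = 0 — an
artifact that destroys the feature being extracted. Secant endpoints keep
the monotonicity bound and leave linear data exactly linear.

*Steady-state anchoring.* With any linear-preserving boundary rule the
derivative maximum inside the first sampling interval is data-independent
(with secant endpoints it sits at exactly one third of the interval), so
transitions occurring within the first 0.5 h cannot be ordered. The analyst,
however, knows the system was at steady state before treatment.
`derivative_curve(..., steady_state_start=True)` encodes that knowledge by
prepending a virtual pre-treatment sample equal to the first observation,
pinning the rate at t = 0 to zero. With anchoring, the recovered extremum
time moves continuously with the data and closely spaced early events
(midpoints 0.16, 0.23, 0.24 h) order correctly. Anchoring is off by default
— without it the derivative of the interpolant is reported exactly as
observed — and on in the pipeline's treatment-kinetics stage.

Hysteresis loops in (Ψ_o − Ψ_w, volume) space are quantified by the signed
shoelace area over the implicitly closed path, computed from per-edge cross
products totalled with compensated summation so that reversing the path
flips the sign exactly. Counterclockwise (positive) loops are labelled
"direct", clockwise "inverse". Ordinary least squares (slope, intercept,
R² = 1 − SS_res/SS_tot) backs the tortuosity-vs-cardiolipin regression and
the calibration curves; zero-variance y is assigned R² = 0 with a warning,
zero-variance x is an error.

## Synthetic data

The generators produce inputs with the statistical and geometric structure
the analysis assumes, so the whole chain is testable without any deposited
data. All generators are deterministic in (seed, config); each consumer
module draws from its own named stream.

Time courses are logistic transitions, value(t) = baseline +
amplitude·σ(k(t − t₀)), sampled at the experimental times with optional
additive Gaussian noise (sd as a fraction of |amplitude|; the real
between-cell error structure is unpublished, so a single noise knob is
exposed). The logistic is used because ΔT_df is defined through a derivative
extremum, which the logistic localizes analytically at its midpoint. The
default scenario encodes the observed event sequence with midpoints
0.16 h (turgor drop, then recovery), 0.23 h (transient mitochondrial
swelling), 0.24 h (cell shrinkage), 0.47 h (osmotic-potential drop),
0.65 h (TCA-metabolite accumulation), 0.69 h (water-potential drop),
0.85 h (tortuosity rise, then recovery) and 0.92 h (cardiolipin
accumulation). The default rate constant is k = 4 h⁻¹ (transition width
≈ 1.1 h): transitions must be resolvable by the 0/0.5/1/3/6/12 h sampling
design — as the real experiment's were, by construction — and sharper
transitions (≳ 6 h⁻¹) concentrate their rise inside a single sampling
interval, where no interpolation method can localize the midpoint.
Transient parameters add an opposite-sign recovery logistic at 6 h with
rate 1 h⁻¹, slow enough that the primary transition always carries the
derivative extremum.

Spectra place one peak per (record, ion mode) at the theoretical m/z
perturbed uniformly within a ppm jitter bound (default 4 ppm, inside the
5 ppm tolerance), plus baseline-noise peaks strictly below 3× the noise
level so the LOD filter removes exactly them. Contours are sine arcs whose
amplitude is solved by bisection so the discrete arc-chord ratio hits a
requested tortuosity within 1e−3 (checked against quadrature of the
continuous arc length). Vesicle tracks are constant-speed walks with random
direction changes, so path speed equals the configured velocity exactly.
Hysteresis loops are seeded star-convex polygons rescaled to a requested
signed area.

What passing these tests shows: the calculators implement their closed
forms; the annotation logic attains perfect recall/precision under the
stated separation conditions; the kinetics machinery recovers generator
parameters under the experimental sampling design at realistic noise. What
it does not show: robustness to matrix effects, isotope interference or
centroiding errors in real spectra; correctness of the prolate-spheroid
volume rule for real mitochondria; ΔT_df behaviour for response shapes far
from sigmoidal.

## Problem sizes and defaults

| knob | default | meaning |
| --- | --- | --- |
| tolerance_ppm | 5 | annotation match tolerance |
| lod_multiplier | 3 | LOD as multiple of baseline noise |
| grid_step_h | 0.01 | derivative grid step (0.001 for fine event ordering) |
| apex window | 10% of long diameter | angle-fit window |
| steepness k | 4 h⁻¹ | logistic rate of synthetic transitions |
| noise_sd_frac | 0 | scenario noise, fraction of amplitude |

Property suites run 50–1000 seeded draws per invariant (50 tortuosity
targets, 100 jittered spectra, 100 loops, 1000 conductivity round trips,
100 regressions), sized to exercise the invariants while keeping the whole
suite around a couple of seconds.

## Known limitations

- Ion chemistry covers the four observed negative-mode species only; no
  isotopologue envelopes, no positive mode, no MS/MS interpretation (a
  static fragment reference for hexose phosphate is shipped, not computed).
- The reported m/z 726 labelled as the CL(74:5) dianion is inconsistent
  with the standard cardiolipin composition formula (which puts CL(74:5) at
  ≈ 740.5); the standard formula is implemented and no agreement with that
  single label is forced.
- ΔT_df is computed on mean curves, not per-cell curves; per-cell variance
  structure is not modelled.
- ε and Lp have no published numeric values for these cells; only the
  formulas and their algebraic consistency are testable.
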