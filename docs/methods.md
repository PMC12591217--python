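# Methods

`beadops` is a desk-scale digital twin of an automated micro-immunobead
electromagnetic operation platform: a sealed oil-filled biochip whose
droplets and magnetic bead clusters are driven by a magnet motor stepping
over a matrix of individually addressable planar coils, executing a
bead-based sandwich immunoassay for exosome-bound amyloid-beta 1-42
(Exo-Ab42) with a colorimetric transmitted-light readout. This note
records the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## Coil matrix and motor kinematics

The actuation chip is modelled as a lattice of 165 coils (2 mm side,
2.1 mm pitch = side + 0.1 mm gap, 0.4 A drive current each), addressed
through 8-port switch devices — 21 devices for the full matrix, the
minimal count `ceil(165/8)`. The 11 x 15 arrangement of the 165 elements
is a configuration choice; any rows x cols (or explicit cell list) is
accepted. The spatial profile of the coil field is deliberately not
modelled: energising a coil relocates the motor to that cell, one cell
per step, and a step to a non-adjacent cell is an actuation fault. Speed
is realised through dwell time per step, `v = pitch / dwell`, since the
platform programs a motor speed without committing to a mechanism.

## Force-balance operation zones

Dragging a magnet under a bead-laden droplet engages three lumped forces:
magnetic `F_mag = k_mag * m` (proportional to bead loading mass `m`), the
droplet's maximum interfacial restoring force
`F_int_max = k_int * m^(1/3)` (the deformed curvature length around the
cluster scales with its linear size, hence the cube root of mass), and
sliding friction `F_fric = k_fric * v` (proportional to transport
velocity). Comparing them partitions the (mass, speed) quadrant:

* droplet operation: `F_fric <= min(F_mag, F_int_max)` — the interface
  transmits enough force to tow the whole droplet;
* bead operation: `F_mag > F_int_max` and `F_fric > F_int_max` — the
  cluster is pulled through the water-oil interface while friction pins
  the droplet;
* no engagement: everything else.

The boundaries are `v = (k_mag/k_fric) m` below the critical mass
`m* = (k_int/k_mag)^(3/2)` and `v = (k_int/k_fric) m^(1/3)` above it,
meeting at a triple point. The inequality structure is forced by the
three stated proportionalities together with the three regime
descriptions; the prefactors `k_mag, k_int, k_fric` are free parameters
with unit defaults (uN, mg, mm/s) because no calibrated values are
available for the physical device. Ties resolve toward the less
energetic regime: equality of friction with the binding force keeps the
droplet engaged, and extraction requires *strictly* exceeding the
interfacial maximum. The degenerate origin (m = 0, v = 0) classifies as
droplet operation — nothing moves and nothing is violated. Classification
is quasi-static; transient dynamics inside a zone are out of scope.

## Biochip fluidics

Droplets are point objects on the coil lattice carrying volume and a
species-amount map; bead clusters ride inside a droplet or through the
oil. The default cartridge holds one 8 ul bead droplet, four 50 ul wash
droplets, one 50 ul HRP-conjugate droplet, one 50 ul TMB substrate
droplet in the detection chamber (height 3 mm), and one 50 ul stop-buffer
droplet that ships its own inert transport beads so it can be towed. All
events conserve volume and species amounts exactly; merging adds both and
assumes instant perfect mixing. Extraction drags a configurable fraction
(default 0.01) of the source droplet's free species along as surface
wetting, so `n` sequential washes attenuate a carried contaminant by
`carryover^n`; the default 0.01 is a plausibility choice, as the washing
efficiency of the real cartridge is not quantified.

## Assay chemistry

The simplest forms consistent with the saturating optimisation behaviour
of the real assay are used, with every rate constant exposed as a
parameter (none are published):

* capture: first-order Langmuir relaxation `Q(t) = Q_eq (1 - e^(-k_cap t))`
  toward `Q_eq = capacity * C/(C + K)`, memoryless across mixing
  intervals, acting only on CD63-bearing species (target Exo-Ab42 and
  bare exosomes);
* labelling: HRP conjugate binds only captured exosomes that carry
  membrane Ab42 (the dual-site requirement) — free Ab42 and bare
  exosomes stay dark, which is what makes the specificity panel clean;
* signal: `S = background + gain * HRP * t`, frozen permanently by the
  stop buffer; optional Gaussian noise, seeded.

Defaults: capacity 500 pg-equivalents/mg beads, `k_cap` 0.15/min
(≈95 % of equilibrium in the 30 min default capture mix), half-saturation
25 pg/ml (placing the calibration inflection inside the 0-50 pg/ml
working range), label efficiency 0.8, gain 2e-3 /pg/min, background 0.05.

Calibration fits the four-parameter logistic
`y = d + (a-d)/(1 + (x/c)^b)` by least squares (scipy `curve_fit`) with a
deterministic initialisation (a, d from the extreme-dose signals, c from
the mid-response concentration, b = 1); at least five distinct
concentrations including a blank are required, and flat data are a fit
error. The limit of detection uses the blank +/- 3 SD convention (sign
chosen by the curve's direction), inverted through the fitted curve in
closed form.

## Optical readout

The chamber read is a transmittance measurement
`I = I0 * 10^(-signal)` over the chamber height. Ambient variation and
warm-up produce a slowly varying multiplicative drift (default:
sinusoidal, 5 % amplitude, 300 s period) plus additive Gaussian sensor
noise. Each intensity is acquired as `round(duration * rate)` samples
(default 10 s at 10 Hz = 100 samples), moving-median filtered (window 5 —
"digital filtering" made concrete; configurable) and averaged. Drift is
compensated by `I_readout = I_raw * I_ref / I_bg`, where `I_ref` is the
initialisation baseline and `I_bg` the background recaptured just before
the read. This is the unique arrangement of the three named intensities
that cancels a common multiplicative factor exactly; the source
typesetting of the relationship is ambiguous, so the arrangement is kept
as a single documented strategy rather than hard-coded in several
places. In the twin, the background and sample windows share one
timeline (droplet insertion is instantaneous), so cancellation is exact
at zero noise. Reading with beads still in the chamber is an error —
bead light-scattering corrupts absorbance — which is why the protocol
extracts all clusters before READ.

## Protocol compilation

Path-finding is breadth-first search on the 4-connected lattice with
row-major neighbour expansion — the simplest complete algorithm, chosen
because the embedded firmware is described only as "simple", and the
tie-break makes replays deterministic. Cells occupied by other droplets
are treated as obstacles (conservative collision avoidance). Per-command
speeds are placed at the geometric midpoint of the feasible interval on
a log scale — between the configurable floor (0.05 mm/s) and the
droplet/bead boundary for tows, and between that boundary and the cap
(50 mm/s) for extractions — maximising margin to both constraints.
Extraction of a cluster at or below the critical mass is a compilation
error: no speed can realise it. Free motor travel (no payload) runs at
20 mm/s. Every motion is re-classified at execution time against the
actual state, so a drifted assumption surfaces as an actuation fault
naming the step.

The shipped six-step program: (1) deliver the capture beads to the
sample and mix 30 min; (2) extract across the interface into the first
wash; (3) label 30 min with the HRP conjugate; (4) three washes, then
delivery to the substrate chamber and 10 min development; (5) tow the
stop droplet over and merge; (6) extract both bead clusters (assay and
transport) from the chamber, then read.

## Synthetic cohorts

Per-group analyte concentrations are log-normal (non-negative,
right-skewed — the standard shape for plasma biomarker levels) with
common sdlog 0.5 and default sizes 20 AD / 10 MCI / 30 CON. The group
separations on the log scale are calibrated so the binormal AUC is 0.94
for AD vs CON and 0.82 for MCI vs CON — i.e. the generator's defaults
*are* the study's reported effect sizes, with the per-subject values
drawn fresh. Concentrations are pushed through the same capture →
label → develop → readout chain as the chip simulation; because the
zero-noise chain is strictly monotone (concentration up, transmitted
intensity down), the readout AUC with the "low score = disease"
convention equals the concentration AUC, and noise only attenuates it.
Readout units are arbitrary sensor units, so cutoff values are not
comparable to any physical instrument's.

The Mann-Whitney U test uses midranks, an exact two-sided p-value by the
classic count recursion when the smaller sample has <= 8 observations
and the pooled data are tie-free, and otherwise the normal approximation
with tie and continuity corrections. The empirical ROC sweeps unique
score values, the trapezoidal AUC satisfies `AUC = U/(n1 n2)` exactly
(ties included), and the default operating point maximises Youden's J
with ties broken toward higher specificity. Two-sided p-values are
reported without multiple-testing correction, matching the platform's
reporting style.

## What the synthetic data do and do not show

The generators emulate the *structure* of the study — group sizes, an
inverse monotone concentration-to-readout relation, saturating capture,
drift and sensor noise — not the laboratory values. Headline wet-lab
numbers (a 2.16 pg/ml detection limit, calibration R² = 0.987, the
animal-study p = 0.0014, the clinical cutoffs) depend on experimental
calibration points that are not published as data, so passing tests here
demonstrate internal consistency and correctness of the algorithms, not
agreement with any particular instrument. Cohort-level AUCs are
reproduced by construction of the generator, and their recovery verifies
the statistics pipeline rather than the biology.

## Numerical choices and problem sizes

Force-balance agreement with the brute-force inequality oracle is
checked on 10^4 random draws; boundary positions by bisection to 1e-9;
conservation on 1000 random event sequences to 1e-12 relative; 4PL
recovery on noiseless data to 1e-6 relative; drift invariance to 1e-12;
the AUC-U identity on 1000 random tied instances; exact p-values against
full enumeration for all sample sizes up to 6; binormal AUC recovery at
10^4 subjects per group (tolerance 0.02) and the end-to-end pipeline
AUC at 2000 per group. Dose-response monotonicity is checked over 10
concentrations at zero noise. These sizes keep the full suite and the
acceptance script in the low minutes on one CPU while leaving the Monte
Carlo tolerances comfortably resolved.

## Known limitations

No electromagnetic field computation, droplet footprint geometry,
evaporation, surfactant effects or satellite droplets; no mechanistic
TMB redox chemistry; single motor only; the labelling step does not
model depletion of the conjugate below the bound amount; hardware
interfaces (SPI daisy-chain, I2C) are represented only by the schedule
log. Coefficients of the force balance are unitless placeholders until a
physical calibration exists.
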