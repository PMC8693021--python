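# Methods

`stimtwin` is a digital twin of a direct-contact in vitro electrical
stimulation chamber: a standard 6-well plate whose lid carries, per well, two
L-shaped platinum wire electrodes immersed in cell-culture medium.  The twin
couples three sub-models — a frequency-domain waveform model, an
equivalent-circuit model of the electrical path, and a finite-element field
model of the well — and closes the loop with monitoring routines that update
the circuit from recorded stimulation pulses.

## Waveforms

Rectangular pulse trains are represented exactly by their Fourier series
under the convention `x(t) = sum_n c_n exp(j 2 pi n f0 t)` with
`c_{-n} = conj(c_n)`; the one-sided amplitude of harmonic `n >= 1` is
`2 |c_n|`.  A monophasic pulse of amplitude `A`, width `tau` and repetition
frequency `f0` starting at `t = 0` has

    c_n = A (tau/T) exp(-j pi n f0 tau) sinc(n f0 tau),      T = 1/f0,

and a symmetric biphasic pulse is the superposition of the monophasic pulse
and its negated copy delayed by `tau + gap`, i.e. the monophasic
coefficients times `1 - exp(-j 2 pi n f0 (tau + gap))`.  Consequences used
throughout: the DC component is `A tau f0` for monophasic and exactly zero
for charge-balanced biphasic pulses, and the biphasic spectrum concentrates
at higher harmonics than the monophasic one.

Time-domain synthesis evaluates the truncated series by inverse FFT over
exactly one period and tiles it, so harmonics sit exactly on FFT bins.  No
window functions are used anywhere; instead records are cropped to whole
periods.  Broadband impedance estimation divides the FFT of the voltage by
the FFT of the current and keeps only bins whose current amplitude reaches
10% (configurable) of the maximum current amplitude — the truncation is
applied to the current spectrum only.

Numerical choices: the default harmonic count is 2000; the maximum-amplitude
screening (`max_harmonic_amplitude`, used against a 250 mV interface
linearity limit) verifies that the spectral tail has decayed below 1% of the
running peak before trusting the maximum.  The one-sided envelope of a
rectangular pulse decays like `2A/(pi n)`, so much stricter tail thresholds
are unreachable at any practical harmonic count; 1% suffices because the
envelope is monotone beyond the main lobe.  Recorded spectra are processed
one record at a time (no averaging over repeats).

## Equivalent circuit

The electrical path is `series[L_lead, R_medium, EEI]`: lead inductance
(long unshielded cables), the ohmic resistance of the medium, and the lumped
electrode-electrolyte interface (EEI).  The two physical interfaces are
electrically indistinguishable in a two-electrode measurement, so they are
modelled as one block.  The default EEI is a constant-phase element
`Z = 1/(Q (j w)^alpha)` (imperfect double-layer capacitor) with no faradaic
charge-transfer path: its DC impedance is infinite, which reproduces the
experimentally observed blocking of the DC component of voltage-controlled
monophasic pulses.  A charge-transfer resistance (and shunt resistor) can be
added; the topology is configurable because the exact platinum-oxidation
interface circuit of a given physical chamber must be identified from its
own EIS data.
Default element values (`R_medium = 166.56` ohm, `L = 1 uH`,
`Q = 2.2e-6 S s^0.8`, `alpha = 0.8`) give a capacitive-to-resistive cutoff
(-45 degree phase crossing) near 1.8 kHz — inside the experimentally
observed 1–10 kHz band — and are the calibration stand-in used by the
synthetic generators.

Fitting is weighted complex nonlinear least squares (lmfit behind the
scenes): `sum w_k |Z_model - Z_k|^2` with modulus weighting `w_k = 1/|Z_k|^2`
(configurable to unweighted); the reported residual is the mean relative
deviation with respect to `|Z|`.  The drift refit frees only the three
parameters identifiable from stimulation pulses — lead inductance, medium
resistance, double-layer capacitance — holding everything else at its
calibrated value; freeing more parameters makes the problem ill-posed for
band-limited pulse spectra.

The linear Kramers-Kronig validity test fits the KK-compliant measurement
model (a ladder of Voigt `R || C` elements with log-spaced time constants
spanning the measured band, 7 per decade, extended while the residual keeps
improving, plus series R, optional series L and a series capacitance for
blocking spectra) by linear least squares with sign-unconstrained ladder
resistances.  Points with relative residual above 1% are flagged; because a
corrupted point drags the weighted fit, an outlier-exclusion refit pass
re-estimates the ladder on the conforming subset before the final
judgement.  Frequencies outside [10 Hz, 1 MHz] are pre-masked by default.

Well networks: `n` nominally identical wells in series (`n z`) or parallel
(`z/n`) plus a series shunt.  Interval inputs propagate by the worst case —
all wells at the minimal (maximal) single-well impedance.

## Geometry and field model

The liquid domain is a cylinder of radius `R` (default 17.4 mm, the growth
area of a standard 6-well plate) capped by a capillary meniscus

    h(r) = h0 (exp(-(R-r)/c) + exp(-(R+r)/c)),

with `h0 = 2.15 mm` and `c = 2 mm` as defaults, minus two L-shaped wire
capsules (radius 0.5 mm; horizontal part 21.65 mm resting 0.755 mm above the
bottom, vertical riser 18 mm; spacing 24 mm — the midpoints of the
uncertainty table below).  The base fill height for a prescribed medium
volume (3.5 mL default) is found by bisection to a 0.1 uL volume tolerance;
the meniscus-cap volume term is evaluated by adaptive quadrature.  The
~0.04 mL displaced by the submerged wires is neglected, consistent with the
volume definition used for the uncertainty study.

Because medium conductivity dominates (`sigma >> w epsilon` through the MHz
range), the electroquasistatic problem reduces to the real Laplace equation
`div(sigma grad Phi) = 0` with Dirichlet electrode potentials (+-U0/2), an
insulating well wall and free surface, solved at the reference state
`U0 = 1 V`, `sigma0 = 1 S/m`.  Currents and fields at other operating points
follow by exact linear scaling `I = (sigma/sigma0)(U/U0) I0`,
`R = (sigma0/sigma)(U0/I0)`.

Discretisation is first-order Lagrange FEM on tetrahedral meshes built by
Delaunay triangulation of structured point clouds — dense shells around the
wires (default 0.25 mm), coarser cylindrical grids in the bulk (default
1.2 mm) — filtered by element centroid against the exact domain.  The choice
of P1 elements with point-insertion refinement keeps the solver dependency-
free and transparent; oracle checks (below) bound its accuracy.  The
reference current is computed from the power dissipation
`I = (1/U) int sigma |grad Phi|^2 dV`, which converges faster than
electrode-surface flux integration (also provided, as a cross-check).  The
reported field `E0` is the volume-weighted mean gradient magnitude within
1.5 mm of the probe point at the centre of the well bottom, where the cells
sit and the field is nearly homogeneous (tangential components < 5% of the
magnitude).

Adaptive refinement uses a Zienkiewicz-Zhu recovered-gradient error
indicator: elements carrying the top 30% of the estimated error receive a
point at their centroid, the cloud is re-triangulated and re-solved, until
`I0` and `E0` change by less than 0.01% or the step limit is hit.  On the
smooth oracle geometries convergence is immediate; the chamber geometry at
desk-scale resolution is instead verified by mesh-independence (coarse vs
fine within 1%) and by bracketing its centre field inside the 90% prediction
interval [37.56, 40.67] V/m per applied volt established for this chamber.

Distributed interface conditions replace an electrode's Dirichlet value with
a Robin condition `sigma dPhi/dn = (Phi_ref - Phi) / (z A_e)` — the lumped
interface impedance spread uniformly over the electrode area `A_e`
(computed from the mesh) — applied either asymmetrically (full impedance on
one electrode) or symmetrically (half on each).  Only real impedances are
supported; the solver is real-valued, and for this chamber the lumped
voltage-divider estimate agrees with both distributed variants to a few
per cent, which is why the lumped path is the default.

Closed-form verification: a rectangular channel with full-face electrodes
(conductance `sigma A / L`, exact for P1 since the potential is linear; the
grid is tangentially jittered so Delaunay output is conforming) and coaxial
cylinders (conductance `2 pi sigma h / ln(b/a)`, within 1% at default
resolution).

## Uncertainty quantification

Inputs and their uniform distributions (mm / mL):

| parameter            | range         | origin               |
|----------------------|---------------|----------------------|
| electrode height h1, h2 | U(0.01, 1.5) | electrode misalignment |
| bottom length l_b    | U(21, 22.3)   | electrode misshaping |
| electrode spacing d  | U(23, 25)     | electrode misalignment |
| meniscus decay c     | U(1.95, 2.05) | literature estimate  |
| meniscus height h0   | U(1.8, 2.5)   | literature estimate  |
| medium volume V      | U(3.4, 3.6)   | pipetting accuracy   |

Point-collocation polynomial chaos of total order 4: responses at
`N = 2 (binom(order + d, d) + 1)` Hammersley nodes (422 for the six
geometric parameters, 72 for the reduced spacing/length/volume study) are
regressed onto the orthonormal Legendre basis.  Mean, variance and
first-order Sobol indices follow exactly from the coefficients by
orthonormality; 5th/95th percentiles are estimated by sampling the surrogate
at 1e4 and 1e5 points (seeded; a relative discrepancy above 0.5% raises a
warning).  The seeded Cranley-Patterson shift of the node set makes designs
reproducible per seed.  Only uniform distributions are implemented, matching
the study assumptions; the container carries a distribution tag for
extension.

Because all inputs are uniform, results are propagated as 90% prediction
intervals.  The +-2% conductivity uncertainty (manufacturer class, about
+-1 degC at 2%/degC) multiplies onto the interval after the fact: currents
and fields scale with `sigma` (bounds times `1 -+ u`), resistances with
`1/sigma` (bounds divided by `1 +- u`).

## Prediction and field estimates

The complementary transient follows from the Fourier series and the circuit:
`I(w_n) = U(w_n)/Z(w_n)` under voltage control, `U = Z I` under current
control.  The DC bin is taken from the circuit's DC limit explicitly rather
than extrapolated: a blocking circuit passes zero mean current, so
voltage-controlled monophasic trains acquire the characteristic negative
current offset during the off-phase; a current-controlled train with a DC
component into a blocking circuit is rejected (the required voltage offset is
unbounded in a linear model).  The default harmonic count keeps the omitted
spectral tail below 0.1% of the AC signal energy.

Field estimates (V/m at the cell layer):

* current-conductivity: `E(t) = i(t) R E0 / U0` with the
  conductivity-adjusted UQ resistance interval; interval arithmetic pairs
  low*low / high*high and swaps bounds with the sign of the current.
* voltage-divider: `U_medium(w_n) = Z_medium/Z_total U_in(w_n)` per
  harmonic (shunt included in `Z_total` when present), synthesized to the
  time domain and scaled by the UQ field interval only — the conductivity
  error cancels in the ratio, so the bounds are tighter.

For multi-well networks the interval network rule supplies worst-case
resistance bounds for the current-conductivity route; the divider route
reuses the single-well field bounds.

## Monitoring

DC (chronoamperometry) records are fitted to
`I(t) = a/sqrt(t) + b exp(-t/c)` with positivity bounds — a faradaic,
diffusion-limited component plus a nonfaradaic capacitive one.  The two
terms are strongly correlated, so the fit profiles the only nonlinear
parameter: for fixed `c` the pair `(a, b)` is linear least squares; a log
grid scan over `c` seeds a bounded Levenberg-style polish.  This recovers
generating parameters exactly on noiseless data and with sub-percent median
error at 2% proportional noise.  No relation to the medium resistance is
implied: DC currents are governed by electrode-surface processes and cannot
validate the field model.

DC contamination is the mean of the voltage over whole periods; it barely
affects the current through the chamber, so the voltage is what must be
monitored.  Temperature inference uses the ~2%/degC temperature coefficient
of the medium conductivity: `dT = ((R_obs - R_ref)/R_ref) / alpha`, positive
for a colder (more resistive) medium.  Peak-to-peak voltages may stand in
for resistances only in medium-dominated regimes (short pulses above the
interface cutoff); the API requires an explicit flag acknowledging that
regime.  The per-epoch drift report chains broadband impedance, the
constrained refit, peak-to-peak, DC offset, the relative deviation from the
reference-model prediction (RMS over the record / peak) and the temperature
track; alarm defaults are 3% deviation and 20 mV DC offset, both
configurable.  Epoch failures are recorded in the report, never fatal.

## Synthetic data

Generators never reuse the estimation code paths they test: spectra are
evaluated in closed form from the circuit tree; transients are synthesized
from the exact Fourier series.  Defaults emulate the study conditions:
proportional complex Gaussian noise at 1% (potentiostat accuracy class) on
spectra, peak-scaled additive Gaussian noise on transients, 10-period
records (about 10 Hz frequency resolution at 130 Hz), and a drift scenario
whose medium resistance relaxes exponentially from +15% over a ~30 min time
constant with optional 100 mV DC contamination — the signature of a medium
starting ~7.5 degC below the incubator temperature.  What the generators do
not emulate: EEI nonlinearity above the ~250 mV linearity limit,
electrochemical memory after polarity reversal, stimulator output impedance,
quantisation and trigger jitter of real oscilloscopes.  Passing tests
therefore demonstrate correctness of the analysis chain under the linear
model, not robustness to every artefact of real hardware.

## Problem sizes and defaults

The shipped tests run the chamber solver at 0.7–1.6 mm bulk resolution
(1.5e4–4e4 nodes, seconds per solve) and the recovery studies at 50–200
seeds; these sizes make the full suite reproducible on a laptop while
keeping every closed-form check at its stated tolerance.  The full 422-run
FEM uncertainty study is exposed through the library API
(`collocation_design` over `solve_laplace`) but is not part of the default
test run; the reduced 72-run study at coarse resolution is the recommended
desk-scale configuration.

## Known limitations

* The field solver is P1; very near the wire surfaces the staircase boundary
  limits local accuracy, which is why reference quantities are the global
  current integral and a probe-averaged field, both verified against closed
  forms elsewhere.
* Complex interface impedances are not supported by the Robin path (real
  solver); use the lumped voltage-divider route.
* The exact platinum-oxidation interface circuit of a physical chamber has
  to be identified from measurements; the default CPE interface reproduces
  its qualitative behaviour (blocking DC, finite high-frequency resistance,
  kHz cutoff) but not its element-by-element values.
* DC stimulation is described, not predicted: the chrono model is empirical
  and deliberately unconnected to the field model.
* Temperature inference assumes a spatially homogeneous temperature change.
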