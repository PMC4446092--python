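# Methods

## The model

`minosc` simulates the MinD/MinE oscillator of rod-shaped bacteria as a
deterministic bulk–surface reaction–diffusion system with six fields:
cytosolic MinD.ATP monomers (`D`, per µm³), cytosolic MinE homodimers
(`E2`, per µm³), and four membrane-bound species (per µm²) — MinD monomers
(`d`), MinD dimers (`d2`), MinE dimers (`e2`) and the MinDE heterotetramer
(`d2e2`).

The reaction network (all reactions irreversible):

| step | rate law | default |
|---|---|---|
| MinD membrane binding | ω_db·D | 4 µm s⁻¹ |
| MinD dimerisation on the membrane | ω_dim·d² (consumes 2 d) | 0.002 µm² s⁻¹ |
| MinE membrane binding | ω_eb·E2 | 0.07 µm s⁻¹ |
| MinE membrane release | ω_er·e2 | 30 s⁻¹ |
| MinE-stimulated monomer release | ω_edf·e2·d (d → D, e2 catalytic) | 22 µm² s⁻¹ |
| heterotetramer formation | ω_edf·e2·d2 | 22 µm² s⁻¹ |
| ATP hydrolysis + dissociation | ω_hydr·d2e2 (→ 2 D + e2) | 0.12 s⁻¹ |

Cytosolic diffusion: D_D = 16, D_E = 20 µm² s⁻¹. Membrane diffusion: D_m =
0.1 µm² s⁻¹ scaled per species by the inverse of its number of membrane
targeting sequences (1, ½, ½, ¼ for d, d2, e2, d2e2).

Two presets model GFP-labelling conditions: `fully_labelled`
(ω_hydr = 0.12 s⁻¹, D_D = 16 µm² s⁻¹ — GFP on every MinD stabilises the
membrane-bound dimer) and `partially_labelled` (ω_hydr = 0.5 s⁻¹,
D_D = 24 µm² s⁻¹). Temperature enters through a Boltzmann factor
exp(ε(T−T₀)/(k·T·T₀)) on ω_hydr with ε = 11.5 kcal mol⁻¹, T₀ = 305.15 K and
k the molar gas constant (ε is quoted per mole).

Assumptions carried from the source model: all cytosolic MinD is treated as
nucleotide-active (no ADP pool); MinE binds the membrane before engaging
MinD (no direct E2·d2 recruitment); every back-rate is zero; one MinE dimer
per MinD dimer suffices for hydrolysis. Mean concentrations are fixed at
1389 µm⁻³ MinD monomers and 486 µm⁻³ MinE dimers.

## Geometry and 1D reduction

The cell is a spherocylinder of radius 0.5 µm. The full axisymmetric
problem is reduced to one axial dimension: cytosolic fields are treated as
radially homogeneous, and membrane fields live on the surface of revolution
of the radius profile r(x). A septal constriction replaces the midcell wall
with two circular arcs concave to the cytoplasm (radius 0.5 µm, tangent to
the wall) joined by a convex arc (radius 0.1 µm) whose lowest point is the
controlled septum radius; the tangency construction is solved in closed
form, and the profile is continuous in x and in time. The minimum septum
radius is floored at 0.077 µm (radius ratio 15.4%, aperture area ratio
2.4%) so the perimeter-to-area coupling stays finite.

The discretization is finite-volume on axial slices: per cell we quadrature
the exact frustum volume (Simpson on πr²), lateral membrane area and arc
length (polyline, 16 sub-samples per cell). Exchange between membrane and
cytosol converts areal fluxes to volumetric rates through each cell's
area/volume ratio; this replaces the thin reaction shell used by the
original 2D implementation, which was explicitly rescaled to be
shell-width-independent. Face conductances use the series (harmonic)
resistance integrated between cell centres — 1/∫dx/(πr²) through the bulk
and 1/∫ds/(2πr) along the membrane — which is exact for steady flux
through a varying cross-section and captures the funnel resistance of the
septum. No-flux conditions hold at both pole apices.

## Time integration

Method of lines with LSODA and a banded Jacobian (species interleaved per
cell, bandwidth 6), rtol = atol = 10⁻⁶. Protein totals are linear
invariants of the semi-discrete system, so the integrator conserves them to
round-off (measured: ~10⁻¹⁴ relative over 1000 s). Stiff membrane exchange
(effective rates up to ~10³ s⁻¹) is handled implicitly by LSODA's BDF
switching; a typical 2000 s cell simulation takes a few seconds. Default
resolution is 0.05 µm per cell; halving it, or tightening tolerances to
10⁻⁸, moves the oscillation period by under 2%.

Integrator overshoot can leave concentrations a hair below zero; values are
clipped to zero at record points and between protocol segments, with the
clipped amount accumulated and bounded (an error is raised if any value
falls below −10⁻⁴ of the mean MinD concentration).

Initial conditions are homogeneous cytosolic `D` and `E2` with membrane
species empty, plus a deterministic linear tilt of relative amplitude 10⁻³
on `D`. The continuous equations are mirror symmetric, so without the tilt
the discrete solution stays symmetric to round-off; the tilt makes the
winning pole a reproducible function of its sign rather than of numerical
noise. Every run starts with a 1000 s burn-in at fixed geometry.

## Protocols

**Fixed length** — burn-in, then record (default every 2 s).

**Growth** — the cylindrical section stretches linearly in time. Each
geometry-update interval (2 s) the PDEs advance on a frozen grid with (i) a
dilution sink −(growth rate)·c/L_cyl applied to every species in cylinder
cells (stretching alone would create material in proportion to local
concentration) and (ii) homogeneous cytosolic production into `D` and `E2`
that relaxes the cell-average concentrations to their targets with a 1 s
time constant (the source protocol specifies homogeneous production but no
rate law). The grid is then stretched, caps unchanged. Mean concentrations
stay within 0.1% of target at wild-type growth rates. The cell count is
chosen for the final length, so resolution is finest early in the run.

**Division** — fixed length; the septum radius ramps linearly from 0.5 µm
to 0.077 µm over 432 s starting at t = 300 s, then holds. At each geometry
update the species amounts per cell are conserved exactly (concentrations
rescale by the old/new volume or area), so totals pass through constriction
unchanged; growing septal membrane therefore dilutes local membrane species,
consistent with new membrane being delivered protein-free.

## Pattern analysis

Trajectories collapse to a kymograph of total-MinD linear density
(monomer equivalents per µm of axis): πr²·D + (perimeter)·(d + 2d2 + 2d2e2),
the quantity a fully-labelled fluorescence kymograph measures. Analysis
uses the trailing 60% of the recorded window.

Classification thresholds (all exposed in `ClassifierThresholds`; the
taxonomy is qualitative in the literature, so values were calibrated once
to reproduce the published classifications at their quoted lengths):

- **stationary**: temporal coefficient of variation < 5% at every axial
  position with significant signal.
- **mode order**: time-anomaly projected on cos(mπx/L), m = 1, 2; the
  dominant power decides first vs second order.
- **mixed travelling**: mode powers within a factor 2 *and* the two mode
  time series in quadrature (|sin Δφ| > 0.5 at the dominant frequency) —
  standing superpositions are in phase or antiphase.
- **midcell antinode**: the instantaneous spatial peak of the signal spends
  ≥ 20% of the window inside the central 40% of the cell while the first
  mode retains ≥ 50% of the second-mode power. The variance-profile
  maximum stays at the poles throughout this regime in the 1D model, so
  peak detachment — not variance position — is the operative signature of
  MinD leaving the pole for the midline.

The period is the dominant rFFT component (Hann window, parabolic peak
interpolation) of the pole-region signal (outer 10% of the axis, the pole
with larger variance); a pole signal completes one cycle per full
pole-to-pole-and-back switch, so its fundamental is the oscillation period.
Regime-transition lengths are found by bisection on fixed-length runs
(tolerance 0.1 µm); an intermediate length counts as transitioned only
once it classifies inside the target regime, so mixed transitional bands
resolve to where the new mode is established.

Division partitioning integrates MinD monomer- and MinE dimer-equivalents
above the midcell plane (the straddling cell split by axial overlap); RMS
statistics are taken from maximal constriction to the projected fission
time (80 s later, the interval the source uses).

## Design choices where the source is silent

- **1D membrane projection**: membrane diffusion acts along the arc length
  s(x) of the profile; the original's own 1D reduction does not state its
  projection.
- **Dilution scope**: the growth dilution term applies to cylinder-section
  cells only, as written in the source; whether cap-adjacent cells received
  it originally is unknown.
- **MinE equilibrium partition**: comparing an areal with a volumetric pool
  needs a surface-to-volume convention; the unit-length (1 µm⁻¹) convention
  is used because it reproduces the published 99.75% cytoplasmic figure
  (the actual surface-to-volume ratio of a 0.5 µm cylinder, 4 µm⁻¹, would
  give ≈99.1%).
- **Reduced-concentration period**: the published ~38 s describes the
  oscillation at the start of a growing run beginning at 2 µm; the period
  of this variant rises with length (34 s at 2 µm, 51 s at 3.5 µm), so the
  measurement here reproduces that protocol (growth 2 → 2.6 µm) rather
  than a longer fixed-length cell.
- **Reduced-MinE second-order transition**: the published 6 µm figure comes
  from a growing simulation; mode switching in a growing cell lags the
  static bifurcation (the established first-order mode persists into
  lengths where both modes are stable), and the fixed-length boundary at
  90% MinE (~5.3 µm) does not show the delay. The growing protocol
  reproduces it (second order established at ~5.4 µm wild type, ~6.0 µm at
  90% MinE).

## Known limitations

- The 1D reduction cannot represent azimuthal structure or the exact 2D
  flow field near the pinch. Its main visible consequence: during division
  the first-order mode decays ~150 s later than in the original 2D
  moving-mesh solution, so the top-half fractions at the end of the
  constriction ramp still deviate ~9% from parity (reaching the published
  ≤4% band ~150–250 s later, within the halted-constriction-to-fission
  window). All other division observables match, including the
  pre-constriction oscillation range (13–79% vs published 13–81%),
  co-directional MinD/MinE deviations, exact conservation, and convergence
  to the symmetric stationary second-order end state.
- Stochastic phase switching of short fully-labelled cells cannot occur in
  a deterministic model; stationary patterns here keep their initial
  polarity indefinitely.
- Protein production/degradation beyond the growth-compensating source, and
  MinC/FtsZ downstream action, are outside the model.
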