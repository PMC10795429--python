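# Methods

This note documents the physics model, the numerical choices, and the
limits of what the test suite demonstrates.

## Transport model

Class-II condensed history with continuous slowing down. Discrete
("catastrophic") channels: δ-electron production above `T_ecut`,
elastic nuclear, inelastic nuclear. Per channel and per step an
independent exponential number of mean free paths is drawn; because the
minimum of independent exponentials is itself exponential with the
summed rate, this is statistically identical to drawing one distance
from the total cross-section and then choosing the channel — the
independent-draw form matches the min-structure of the step-size rule
and is verified by a Kolmogorov–Smirnov test in the suite. Distances
are resampled fresh each step; the exponential's memorylessness makes
this exact and avoids carrying mean-free-path bookkeeping across
boundaries and material changes.

Step physics (stopping power, cross-sections, scattering width,
magnetic kick) is evaluated at the step's starting energy. Steps are
capped at 20% of the residual range (10 mm in range-shifter material,
where parameters vary slowly), so the constant-energy approximation
holds within a few percent per step. An optional global step cap
(`max_step_mm`) exists for convergence studies.

Tracking cutoff 0.5 MeV: the residual energy deposits in the current
voxel (residual range ≪ voxel size). Additionally a proton whose
residual range falls below 1 µm is stopped outright — without this the
20%-of-range cap would shrink steps geometrically to zero near the
cutoff.

### Electromagnetic pieces

- **Restricted stopping power**: Bethe–Bloch restricted to transfers
  below `T_ecut = 0.1 MeV`, per element, combined by Bragg additivity
  (mass-fraction-weighted). Density-effect and shell corrections are
  omitted; for water this lands ~1% above the standard reference
  tabulation at therapeutic energies (the suite checks 3%). Tables:
  600 evenly spaced energies, 0.5–300 MeV; stopping power and range
  interpolate linearly in T, cross-sections linearly in log T.
- **Straggling**: Gaussian with the restricted Bohr variance (second
  moment of the Rutherford spectrum up to `min(T_ecut, T_max)`),
  clamped to [0, T]; the clamp bias is negligible for steps under the
  20% range rule. The same Gaussian applies to steps that end in a
  discrete event (whether the original scheme did is unstated; applied
  uniformly here).
- **δ-electrons**: acceptance–rejection on `1/T² (1 − β² T/T_max)`
  between `T_ecut` and the exact kinematic maximum
  `T_max = 2 m_e c² β²γ² / (1 + 2γ m_e/m_p + (m_e/m_p)²)`. At 250 MeV
  this gives 616 keV (a commonly quoted round figure is ~580 keV; the
  exact formula is used). Electrons deposit locally and the proton's
  direction is unchanged (m_p ≫ m_e).
- **Multiple scattering**: Rossi–Greisen Gaussian,
  `θ0² = (E_s/pv)² · δx ρ / X0`, with `E_s = 17.5 MeV` (the original
  constant; configurable). Azimuth uniform; direction renormalized.
- **Magnetic deflection**: applied once at the end of each step,
  `dir ← normalize(dir + (0.299792 · δx / pc) dir × B)`. The polygonal
  trajectory's vertices converge to the analytic gyroradius circle with
  error O(δx²).

### Nuclear pieces

Elastic p–p: secondary energy uniform on (0, T) (support is a declared
choice), both angles from exact relativistic two-body kinematics,
azimuths back-to-back. Elastic p–X: the scattered proton's retained
energy fraction and angle come from the database's elastic table; the
recoil deposits locally. Inelastic: secondary protons (multiplicity,
energy fraction, angle) come from the database; the remainder splits
into a discarded neutral part and a locally deposited charged part by
the table's neutral fraction, so each event conserves energy exactly —
the fixed reaction offset `Q = 5 MeV` is folded into that split.
Below the 10 MeV database floor an inelastic collision deposits the
proton's energy locally. Neutrons and photons are not transported
(their local dose contribution is below ~0.5%); neither are deuterons,
alphas, or heavier fragments (range ≪ voxel size at these energies —
an acknowledged overestimate in very low-density media).

### Nuclear database

Schema per element and per 10 MeV incident bin: secondary-proton
multiplicity distribution (0–4), a joint table over 24 energy-fraction
× 18 angle-cosine bins, a neutral fraction, and an elastic
(retention × angle) table on 16 × 18 bins. Energies are stored as
fractions of the available energy, making conservation structural.
Incident energies between bins mix the two bracketing bins
stochastically, which preserves normalization without rebuilding
tables. The bundled generator is an analytic stand-in: a forward-peaked
quasi-free knockout component (Gaussian in energy fraction, exp(kμ)
angular shape hardening with energy) plus an isotropic Maxwellian
evaporation component (kT = 4 MeV), with the quasi-free weight and the
proton multiplicity rising with incident energy. The elastic and
inelastic microscopic cross-sections are smooth parameterized fits
(geometric A^(2/3) scaling with threshold behaviour). These shapes have
physically reasonable magnitudes and trends but are **not evaluated
nuclear data**; the HDF5 container schema is documented precisely so
externally derived tables can replace them without code changes. All
sampling-correctness claims in the test suite are about the
schema/sampler, not about the fixture's nuclear realism.

## Materials

13 elements (H, C, N, O, Na, Mg, P, S, Cl, Ar, K, Ca, Fe) with mean
excitation energies and radiation lengths from standard compilations;
24 materials (air, lung at two densities, adipose, water, soft tissue,
muscle, skin, blood, liver, brain, eye lens, cartilage, marrows,
spongiosa, cortical bone at 1.85 g/cm³, PMMA flagged as range-shifter,
and six Schneider-style bone-mixture bins). Mass-normalized tables are
shared by materials of equal composition; density enters only at
lookup. The HU conversion is a configurable piecewise-linear density
ramp with composition bins (air/lung/adipose/water/soft-tissue/muscle/
cartilage/bone segments); the exact breakpoints are a calibration
choice, not physics.

## Scoring and uncertainty

Dose is `MeV/g` per primary (relative dose; absolute calibration is out
of scope — all comparisons here are between relative distributions).
Batches are identical apart from random substreams; σ/D̄ is the mean,
over voxels above 50% of the maximum dose (threshold configurable), of
the relative standard error of the per-batch mean computed from the
unbiased batch variance. Termination: σ/D̄ < 1% or ten batches. Note
that with k batches the sample standard deviation is biased low by the
χ-distribution factor (0.80 at k = 2, 0.97 at k = 10), so σ/D̄ versus k
tracks C/√k only after fitting C — the suite verifies the fitted
scaling to 20% and leaves the estimator uncorrected, as is conventional
for batch statistics.

## Dose-comparison metrics

R80 interpolates the 80%-of-maximum crossing on the distal falloff of
the transversally integrated depth-dose. `ε_rel = 2(d1−d2)/(d1+d2)`
voxelwise; the reported mean is the mean of |ε_rel| over voxels where
the reference exceeds 10% of its maximum. The centre of mass is the
dose-weighted mean coordinate; a voxel-count-normalized variant
(`as_printed`) exists for comparison with conventions that divide by N,
but it is not translation-consistent and is not the default. The gamma
index uses a global dose criterion (fraction of the reference maximum;
a local variant sits behind a flag), a 10%-of-maximum low-dose cutoff,
and an exhaustive voxel-grid search truncated at 3× the distance
criterion (beyond which the distance term alone exceeds γ = 3); no
sub-voxel interpolation, adequate when the voxel pitch is comparable to
the distance criterion.

## Geometry conventions

Half-open voxels `[lower, upper)`, 0-based indices, phantom-local mm;
a point on a shared face belongs to the upper neighbour. After a
boundary crossing the transport loop nudges the particle by
`1e-6 × min(spacing)` along its direction; the geometry module itself
is pure. The magnetic field is uniform over the phantom (all benchmark
scenarios use homogeneous fields).

## Randomness and reproducibility

One splitmix64 counter stream per history, derived from
(seed, history index): stream `2h` feeds the source sampling of history
h and stream `2h+1` its transport, so results are bit-identical for a
given seed regardless of batch partitioning or execution order.

## What the tests show — and what they do not

The suite verifies: exact per-history energy closure; agreement of the
simulated range with an independent ODE integration of the generator's
own stopping power (0.3 mm at 100 MeV); the gyroradius of the tracked
trajectory in a 1 T field (9×10⁻⁵ relative at 0.5 mm steps) and its
O(δx²) convergence — measured against the radius predicted at the
mid-arc energy, because even at 10⁻⁴ g/cm³ the continuous energy loss
makes the raw trajectory a slow spiral; strictly monotone growth of the
beam-centroid deflection over 0–2 T; the second moments of the
scattering and straggling samplers; the exponential law of the
competing discrete channels; and the metric implementations against
brute-force oracles and hand-computed values. Because the nuclear
tables are analytic stand-ins, dose distributions in the nuclear-halo
region should not be read as clinically validated; the electromagnetic
core (which dominates the depth-dose) is the quantitatively tested
part.

## Problem sizes

Tests and the acceptance script use 10³–4×10⁵ histories per scenario
(the package's choice of desk-scale sizes); at these sizes the batch
uncertainty sits at 2–16%, far from the ~1% that ~10⁷-history
production runs reach, and the self-consistency gamma/ε_rel numbers
between two independent runs reflect that statistical noise rather than
any model disagreement.
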