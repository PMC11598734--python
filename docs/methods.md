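# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the numerical choices, what the synthetic data
stand in for, and the known limitations.

## Model structure

The leaf is two plane-parallel mesophyll layers between two air
interfaces; the thin, nearly transparent epidermis is not modelled. Four
flux variables are tracked: forward/backward collimated intensities
(I_C, J_C) travelling at fixed internal angles, and forward/backward
scattered intensities (I_S, J_S) treated as hemispherically diffuse with a
path-length factor of 2. The model is monochromatic per wavelength and
fully linear in the incident intensity, so reflectance and transmittance
are intensity-independent; spectra are computed by evaluating every
wavelength simultaneously with array arithmetic.

### Surfaces

Each surface is a fraction `F_S` rough and `1 - F_S` smooth. Smooth-surface
collimated transfer uses the unpolarized Fresnel transmittance with the
Snell-refracted angle pair; the implementation evaluates the
sine/tangent-ratio form and switches to the analytic normal-incidence
limit `1 - ((n_I - n_O)/(n_I + n_O))^2` below 1e-6 rad, where the printed
form is 0/0. Leaf-to-air collimated transfer is zero at or above the
critical angle `arcsin(n_O/n_I)` (total internal reflection). Rough-surface
transfer — and all scattered-light transfer — uses the hemispherical
average `(2/pi) * Int_0^{pi/2} T_c(beta) d beta` with *equal weight in the
angle* (no cosine weighting; that convention is what reproduces the
constants 0.866 and 0.469 for n_I = 1.415). The average is computed by
adaptive quadrature (absolute error well below 1e-4), cached per
`(direction, n_O, n_I)`, and never hard-coded. Collimated light crossing
the rough fraction emerges scattered, with no facet-slope model beyond the
single scalar `F_S`.

Collimated light that arrives at a surface above the critical angle stays
collimated inside the lamina (exit coefficient 0) and keeps recirculating
until it is absorbed or leaves along the scattered path; no forced
conversion to diffuse light is applied, since none is specified by the
model equations. In practice beams refracted in from outside are always
below the critical angle.

### Palisade layer

Scattering in the palisade is weak (s_P = 5 cm^-1; even at h = 80 um the
single-scatter probability s_P*h is only 4%), so the layer is treated by
Beer-Bouguer-Lambert attenuation: slant path `h/cos(beta)` for collimated
flows, doubled path `2h` for diffuse flows, absorption only. The one
scattering effect retained is the single-scatter backward gain J_S^Add:
forward light scattered backwards at rate `s_P (1 - f)` per unit path,
re-attenuated diffusely on the way back to the top. Its depth integral has
a closed form, implemented through `(1 - e^-k)/k` factors so the
transparent-layer limit (NIR) is exact rather than 0/0. There is no
symmetric forward gain from the backward flows and no `s_P` extinction
term in the collimated attenuation: the asymmetry is part of the model
definition and is preserved, which makes the model slightly
non-conservative (J_S^Add adds flux that is never debited; at most
~s_P*h ~ 2% of the circulating light per pass, and R + T is allowed to
exceed 1 by up to 2% in validation checks). Energy-closure tests therefore
run with s_P = 0.

### Spongy layer

The four-flux Kubelka-Munk system couples the flows through the scattering
coefficient s_Sp and asymmetry factor f (fraction of scattered light
continuing forward; 0.5 = isotropic redistribution). The collimated
equations are autonomous with decay rates `(a_Sp + s_Sp)/cos(beta)`; the
scattered pair forms a 2x2 block driven by them. Eigenvalues are taken
from the characteristic polynomial of that block,
`lambda^2 - (L33 + L44) lambda + (L33 L44 - L34 L43) = 0`, giving
`+/- 2 sqrt(a_Sp (a_Sp + 2 s_Sp (1 - f)))` — the classical KM exponent —
and are cross-checked against a generic eigensolver in the tests. (The
alternative sign under the radical that places `+ L34 L43` outside the
product does not solve the characteristic equation and is not used.)

Numerical choices:

- **Absorption floor.** At a_Sp = 0 the block eigenvalues coincide at zero
  and the constant formulas are singular, so a_Sp is clamped to
  1e-6 cm^-1. The floor is optically negligible (a_Sp*l ~ 1e-8) and the
  tests verify output continuity across it.
- **Overflow-safe evaluation.** Constants multiplying growing exponentials
  are stored rescaled (`C3 e^{lambda3 l}`, etc.) and evaluated as
  `e^{lambda (x1 - l)}`, so optically thick layers (lambda*l of hundreds)
  evaluate without overflow.
- **Resonance guard.** On the measure-zero parameter set where a
  collimated decay rate equals a block eigenvalue (s_Sp = 3 a_Sp at normal
  incidence) the particular-solution denominators vanish; the engine
  perturbs a_Sp by 1e-5 relative at the affected wavelengths. The induced
  error is far below the solver's validated 1e-5 agreement with the
  independent boundary-value oracle.
- **Degenerate scattering.** When `s_Sp (1 - f) = 0` the scattered flows
  decouple into two first-order equations solved directly.
- The collimated angles inside the spongy layer reuse the palisade's
  internal angles: no optical interface is modelled between the two
  mesophyll layers.

### Iterations

The first pass partitions the incident light at the surfaces; the
externally reflected parts count toward the exit totals of iteration 1
only. Each pass propagates forward flows down (palisade, then spongy),
backward flows up (spongy solution evaluated at the top, then palisade
with the J_S^Add gain), and partitions the arriving internal light at both
faces. The internally reflected components seed the next pass with the
forward/backward angle pairs exchanged. When only adaxial light is
incident, the backward external angle defaults to the forward one so the
backward internal angle is defined (it multiplies zero flows in pass 1).
The exit series is geometric with ratio ~0.5 (dominated by the 53%
internal reflection of diffuse light), so N = 6 captures the visible bands
exactly and the NIR to ~1.5%; N is exposed everywhere.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| n_I | leaf interior refractive index | — | 1.415 |
| beta_O1 | adaxial incidence angle | deg | 35 |
| F_S | rough-surface fraction | — | 0.15 |
| h, l | palisade / spongy thickness | um | 35.5 / 58.6 |
| s_P, s_Sp | scattering coefficients | cm^-1 | 5 / 600 |
| f | asymmetry factor | — | 0.5 |
| C_ChA, C_ChB, C_Car | palisade pigment concentrations | mg cm^-3 | 3.19 / 2.09 / 0.94 |
| N_Sp/P | spongy/palisade pigment ratio | — | 0.2 |
| I_0 | incident intensity | umol m^-2 s^-1 | 1000 |
| N | iterations | — | 6 |

These defaults are the parameterized values for a mature pea leaf
(s_Sp reduced from the literature value 1000 to 600 cm^-1, F_S raised from
0 to 0.15, and the chlorophyll concentrations corrected from the measured
2.77/1.69 to 3.19/2.09 mg cm^-3 during that parameterization). Internally
all lengths are cm (coefficients are cm^-1) and all angles radians;
degrees and micrometres appear only at the config/CLI boundary. The
leaf-average concentration a bulk extraction would see follows from
`C_av = C (h + N_Sp/P l)/(h + l)` — with the default geometry the
corrected palisade values map to 1.39/0.85/0.47 mg cm^-3 (a ~0.50
weighting). A uniform-mesophyll (monocot) leaf is the special case
h = 0, N_Sp/P = 1.

## Synthetic data

Two generators stand in for data the package cannot ship:

- **Specific absorption spectra.** Measured in-vivo specific absorption
  curves of chlorophyll a, chlorophyll b and carotenoids are not
  redistributable here, so the fixture builds each as a sum of Gaussian
  bands at the canonical positions (chl a 430/662 nm, chl b 460/644 nm,
  carotenoids 450/480 nm) plus one weak broad component standing in for
  the non-Gaussian green-window tail of real pigment-protein complexes,
  rolled off smoothly to exactly zero above 720 nm. Amplitudes
  (~80-105 cm^2 mg^-1 at the band maxima, in the range of extracted
  pigment absorptivities) were chosen once so that the default leaf shows
  the canonical spectral shape: green maximum ~0.28, red trough ~0.07,
  NIR plateau ~0.66, mid-visible absorptance ~0.5-0.9. Real curves are
  broader and flatter (pigment packaging), so absolute visible
  reflectances with the fixture should not be read as predictions for a
  particular species; every quantitative check in the package is chosen
  to be independent of the exact curves.
- **Pseudo-experimental spectra.** Reference spectra for the fitting
  workflow are forward simulations plus i.i.d. Gaussian reflectance noise
  (sd 0.005, a quiet field spectrometer), clipped at zero,
  seed-reproducible. They share the forward model's physics by
  construction, so recovery tests demonstrate that the scan machinery and
  metrics identify generating parameters under noise — not that the model
  fits real leaves; real-data fits should expect structured (not i.i.d.)
  residuals from instrument response and biological variability.

## Fitting workflow

R^2 is `1 - SS_res/SS_tot` about the reference mean — not squared Pearson
correlation — so systematic offsets are penalized; RMSE is reported
alongside in reflectance-fraction units. The scan is a deterministic grid
search (Cartesian product, rows sorted by R^2 with value tie-breaks),
matching how the model is parameterized in practice: one axis at a time
over physically motivated candidates. No gradient optimizer is built in;
the forward model is cheap (~4 ms per 401-wavelength spectrum), so grids
are the transparent tool of choice.

## Known limitations and observed behaviors

- No polarization, fluorescence, wavelength-dependent refractive index,
  epidermal focusing, or canopy stacking; pigment set is chl a, chl b and
  total carotenoids only (no water or dry-matter absorption, so the model
  is meaningful over ~400-800 nm).
- The flux budget is open by the J_S^Add construction (see above).
- Thinning the palisade alone moves the NIR plateau slightly (about
  5e-3 in reflectance for a 10 um change under the defaults) through the
  h-dependence of J_S^Add; with s_P = 0 the NIR is exactly h-invariant.
  Statements that palisade thickness leaves NIR reflectance unchanged are
  figure-resolution approximations of this.
- Thinning the spongy layer alone lowers NIR reflectance strongly and
  also lowers green reflectance slightly; the green effect tends to zero
  as absorption grows but never changes sign in this model. Observed
  green-reflectance increases in shade-grown leaves are reproduced only
  through the accompanying palisade thinning.
- Test and validation problem sizes — 401-wavelength grids, 60-set
  random sweeps for the boundary-value cross-check, 20 recovery
  replicates — were chosen as the smallest sizes that exercise every
  code path with comfortable statistical margins.
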