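# leafoptics

Analytical four-flux radiative-transfer model of reflectance and
transmittance spectra for dicot leaves with distinct palisade and spongy
mesophyll layers, plus the spectrum-comparison and grid-scan workflow used
to parameterize it against measured reflectance.

Leaf reflectance spectra are the raw material of plant remote and proximal
sensing: pigment content, leaf anatomy and illumination geometry all leave
their signature on them. `leafoptics` is for researchers who want a fast,
fully analytical forward model that separates those influences — how much
of a change in green or near-infrared (NIR) reflectance is pigment, how
much is mesophyll thickness, how much is surface roughness — without the
plate-stack assumption of PROSPECT-style models or the cost of ray tracing.

## The model

The leaf is an optical sandwich: air boundary / palisade mesophyll
(thickness *h*, strong absorption, weak scattering) / spongy mesophyll
(thickness *l*, strong scattering from cell-wall–air interfaces) / air
boundary. Four flux variables are tracked at every depth: forward and
backward collimated intensities *I<sub>C</sub>*, *J<sub>C</sub>* and
forward and backward scattered intensities *I<sub>S</sub>*,
*J<sub>S</sub>*.

- **Surfaces** — Snell refraction plus unpolarized Fresnel transmittance
  for collimated beams; a rough-surface fraction *F<sub>S</sub>* crosses
  with the hemispherically averaged (equal angle-weight) transmittance and
  emerges scattered. For the leaf interior index *n<sub>I</sub>* = 1.415
  the diffuse coefficients are T<sub>s</sub><sup>OI</sup> ≈ 0.866
  (air→leaf) and T<sub>s</sub><sup>IO</sup> ≈ 0.469 (leaf→air, with total
  internal reflection above the ≈45° critical angle). They are always
  computed, never hard-coded, so *n<sub>I</sub>* stays a free parameter.
- **Palisade layer** — Beer–Bouguer–Lambert attenuation:
  *I<sub>C</sub>(h) = I<sub>C</sub>(0) e<sup>−a<sub>P</sub>h/cos β</sup>*
  along the slant beam path and a factor-2 path length for diffuse light,
  plus a closed-form single-scatter backward gain
  *J<sub>S</sub><sup>Add</sup>* ∝ *s<sub>P</sub>(1−f)*.
- **Spongy layer** — the four-flux Kubelka–Munk ODE system, solved
  analytically: the collimated flows decay with
  (*a<sub>Sp</sub>+s<sub>Sp</sub>*)/cos β, the scattered flows form a 2×2
  block with eigenvalues ±2√(*a<sub>Sp</sub>(a<sub>Sp</sub> +
  2s<sub>Sp</sub>(1−f))*) (the classical KM exponent), and the constants
  are matched to the boundary intensities.
- **Iterations** — light internally reflected at either surface re-enters
  the lamina; the pass is repeated (with the forward/backward beam angles
  exchanged) and exit intensities accumulate:
  *R = Σ J<sub>out</sub><sup>i</sup> / I<sub>0</sub>*,
  *T = Σ I<sub>out</sub><sup>i</sup> / I<sub>0</sub>*. Six iterations
  resolve the slow NIR series; visible bands converge in one or two.
- **Pigments** — *a<sub>P</sub>(λ) = C<sub>ChA</sub>a<sub>ChA</sub>(λ) +
  C<sub>ChB</sub>a<sub>ChB</sub>(λ) + C<sub>Car</sub>a<sub>Car</sub>(λ)*
  from specific absorption spectra (cm² mg⁻¹), with the spongy layer at a
  fraction *N<sub>Sp/P</sub>* (default 0.2) of the palisade concentration.

Defaults are the parameterized values for a mature pea leaf: β = 35°,
*F<sub>S</sub>* = 0.15, *h* = 35.5 µm, *l* = 58.6 µm, *s<sub>P</sub>* = 5
cm⁻¹, *s<sub>Sp</sub>* = 600 cm⁻¹, *f* = 0.5, chl a / chl b / carotenoids
= 3.19 / 2.09 / 0.94 mg cm⁻³ in the palisade.

Measured specific absorption spectra are not bundled; the package ships a
clearly labelled synthetic Gaussian-band fixture with maxima at the
canonical pigment band positions (see `docs/methods.md`) and reads user
CSVs.

## Worked example

```python
import leafoptics as lo

params = lo.LeafParams()                 # pea-leaf defaults, 400-800 nm
spec = lo.simulate_spectrum(params)      # N = 6 iterations
print(f"R(550 nm) = {spec.reflectance[150]:.3f}")
print(f"R(680 nm) = {spec.reflectance[280]:.3f}")
print(f"R(780 nm) = {spec.reflectance[380]:.3f}")

# recover the spongy scattering coefficient from a noisy spectrum
ref = lo.make_pseudo_experimental(params, noise_sd=0.005, seed=1)
table = lo.scan({"s_Sp": [400.0, 600.0, 800.0, 1000.0]}, params, ref)
print(table.to_string(index=False))
```

prints

```
R(550 nm) = 0.277
R(680 nm) = 0.066
R(780 nm) = 0.656
  s_Sp       R2     RMSE
 600.0 0.999622 0.004576
 800.0 0.986471 0.027390
 400.0 0.971449 0.039789
1000.0 0.960374 0.046875
```

The spectrum shows the canonical leaf shape — a green local maximum near
550 nm between the chlorophyll absorption troughs, and a high NIR plateau
produced by spongy-mesophyll scattering with no pigment absorption — and
the grid scan ranks the generating scattering coefficient (600 cm⁻¹) first
by R² against the noisy reference.

The same workflow is available from the shell:

```bash
leafoptics constants --n-i 1.415          # diffuse transmittances, critical angle
leafoptics simulate -o spectrum.csv       # forward spectrum CSV
leafoptics fixtures --out-dir fixtures/   # pigment + pseudo-experimental CSVs
leafoptics scan -r fixtures/pseudo_experimental.csv \
    -p s_Sp=400,600,800,1000 -o scan.csv
```

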